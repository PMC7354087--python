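"""Micro-CT densitometry and T2-weighted MRI intensity ratios.

CT side: raw scanner intensities are mapped to Hounsfield units (HU) with
the standard two-point calibration -- the mean raw value of a distilled
water phantom anchors 0 HU and an air region anchors -1000 HU -- then
clamped to the reconstruction range [-1000, 1000].  Lung density is
summarized as the arithmetic mean HU over a supplied volume of interest
(VOI), optionally restricted to voxels inside a parenchyma window (default
[-900, -100] HU) that drops bone/soft tissue and trachea-like pure air.

MRI side: T2-weighted signal is unitless and scanner-scaled, so lung (and
kidney) region means are normalized by the arm-muscle mean in the same
slice; the resulting ratio is gain-invariant.

Percent changes over a longitudinal series are computed on the raw signed
values, ``100 * (v_t - v_0) / v_0``.  Note the sign convention on
negative-valued HU series: a lung getting *less* dense (HU moving from
-357 toward -399) yields a *positive* percent change, because the baseline
is negative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "CalibratedVolume",
    "CtResult",
    "MrSlice",
    "T2RatioResult",
    "HUCalibrator",
    "calibrate_hu",
    "segment_lung",
    "mean_hu",
    "t2_ratio",
    "percent_change",
]

HU_CLAMP = (-1000.0, 1000.0)
DEFAULT_LUNG_WINDOW = (-900.0, -100.0)

# integer codes used in label volumes throughout the package
LABEL_LUNG = 1
LABEL_MUSCLE = 2
LABEL_KIDNEY = 3
LABEL_WATER = 4
LABEL_AIR = 5
LABEL_VOI = 6  # VOI voxels lie inside the lung; lung = {1, 6}


@dataclass
class CalibratedVolume:
    """HU-calibrated voxel grid with its calibration provenance."""

    voxels: np.ndarray
    voxel_size_um: float
    calibration: dict = field(default_factory=dict)
    clamp_range: tuple[float, float] = HU_CLAMP


@dataclass
class CtResult:
    mean_hu: float
    n_voxels_used: int
    lung_window: tuple[float, float] | None


@dataclass
class MrSlice:
    """A T2-weighted slice with integer ROI labels (codes above)."""

    image: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.image.shape != self.labels.shape:
            raise ValueError("image/labels shape mismatch")


@dataclass
class T2RatioResult:
    ratio_lung: float
    ratio_kidney: float | None


class HUCalibrator(TransformerMixin, BaseEstimator):
    """Two-point (water/air) Hounsfield calibration as a transformer.

    Either pass the reference means at construction, or let :meth:`fit`
    estimate them from a raw volume plus a label map containing water
    (code 4) and air (code 5) regions.

    ``transform`` maps raw intensity ``v`` to
    ``1000 * (v - water) / (water - air)`` and clamps to ``clamp_range``,
    so water -> 0 HU and air -> -1000 HU.  The mapping is invariant to any
    affine distortion of the raw intensities, provided the references are
    re-measured on the distorted data.
    """

    def __init__(self, water_raw_mean: float | None = None,
                 air_raw_mean: float | None = None,
                 clamp_range: tuple[float, float] = HU_CLAMP):
        self.water_raw_mean = water_raw_mean
        self.air_raw_mean = air_raw_mean
        self.clamp_range = clamp_range

    def fit(self, X, y=None):
        """Learn reference means; ``y`` may be a label map for ``X``."""
        if y is not None:
            labels = np.asarray(y)
            water = np.asarray(X)[labels == LABEL_WATER]
            air = np.asarray(X)[labels == LABEL_AIR]
            if water.size == 0 or air.size == 0:
                raise ValueError("label map lacks water and/or air voxels")
            self.water_raw_mean_ = float(water.mean())
            self.air_raw_mean_ = float(air.mean())
        else:
            if self.water_raw_mean is None or self.air_raw_mean is None:
                raise ValueError(
                    "no reference means given and no label map to fit from")
            self.water_raw_mean_ = float(self.water_raw_mean)
            self.air_raw_mean_ = float(self.air_raw_mean)
        if self.water_raw_mean_ == self.air_raw_mean_:
            raise ValueError("degenerate calibration: water == air reference")
        return self

    def transform(self, X) -> np.ndarray:
        hu = 1000.0 * (np.asarray(X, dtype=float) - self.water_raw_mean_) / (
            self.water_raw_mean_ - self.air_raw_mean_)
        lo, hi = self.clamp_range
        return np.clip(hu, lo, hi)


def calibrate_hu(raw_volume, water_raw_mean: float, air_raw_mean: float,
                 voxel_size_um: float = 1.0,
                 clamp_range: tuple[float, float] = HU_CLAMP
                 ) -> CalibratedVolume:
    """Calibrate a raw volume to clamped HU using water/air reference means."""
    cal = HUCalibrator(water_raw_mean, air_raw_mean, clamp_range).fit(None)
    return CalibratedVolume(
        voxels=cal.transform(raw_volume),
        voxel_size_um=voxel_size_um,
        calibration={"water_raw_mean": cal.water_raw_mean_,
                     "air_raw_mean": cal.air_raw_mean_},
        clamp_range=clamp_range,
    )


def _voxels(volume) -> np.ndarray:
    return volume.voxels if isinstance(volume, CalibratedVolume) else np.asarray(volume)


def segment_lung(volume, lung_window=DEFAULT_LUNG_WINDOW) -> np.ndarray:
    """Boolean mask of voxels inside the closed HU parenchyma window."""
    lo, hi = lung_window
    if lo > hi:
        raise ValueError("invalid lung window")
    hu = _voxels(volume)
    mask = (hu >= lo) & (hu <= hi)
    if not mask.any():
        warnings.warn("lung window selected no voxels", stacklevel=2)
    return mask


def mean_hu(volume, voi: np.ndarray,
            lung_mask: np.ndarray | None = None,
            lung_window: tuple[float, float] | None = None) -> CtResult:
    """Mean HU over the VOI, optionally intersected with a lung mask."""
    hu = _voxels(volume)
    voi = np.asarray(voi, dtype=bool)
    if voi.shape != hu.shape:
        raise ValueError("VOI shape mismatch")
    used = voi if lung_mask is None else (voi & np.asarray(lung_mask, bool))
    n = int(used.sum())
    if n == 0:
        raise ValueError("no lung voxels inside the VOI")
    return CtResult(float(hu[used].mean()), n, lung_window)


def t2_ratio(slice_: MrSlice) -> T2RatioResult:
    """Lung (and kidney) mean intensity normalized by arm-muscle mean."""
    img, lab = slice_.image, slice_.labels
    muscle = img[lab == LABEL_MUSCLE]
    lung = img[lab == LABEL_LUNG]
    if muscle.size == 0:
        raise ValueError("empty muscle ROI: cannot normalize")
    if lung.size == 0:
        raise ValueError("empty lung ROI")
    kidney = img[lab == LABEL_KIDNEY]
    return T2RatioResult(
        ratio_lung=float(lung.mean() / muscle.mean()),
        ratio_kidney=float(kidney.mean() / muscle.mean()) if kidney.size else None,
    )


def percent_change(series: dict, baseline_week: int = 0) -> dict:
    """Percent change vs baseline for a per-subject longitudinal series.

    ``series`` maps week -> value.  Returns week -> 100*(v_t - v_0)/v_0 on
    the raw signed values (see module docstring for the sign convention on
    negative series).  A missing or zero baseline yields an empty result
    with a warning rather than an exception.
    """
    if baseline_week not in series or series[baseline_week] == 0:
        warnings.warn(
            f"baseline week {baseline_week} missing or zero; skipping subject",
            stacklevel=2)
        return {}
    v0 = series[baseline_week]
    return {wk: 100.0 * (v - v0) / v0 for wk, v in series.items()}
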