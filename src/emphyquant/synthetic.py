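"""Synthetic phantoms with known ground truth for every readout.

No public dataset exists for the modeled study, so every downstream module
is exercised on generated data:

* **Alveolar sections** -- either an analytic parallel-septa grating (every
  air chord perpendicular to the septa is exactly ``period - septum``) or a
  Voronoi foam: a Poisson point process is tessellated, cell boundaries are
  thickened into septa, and "emphysema" removes a fraction of shared walls
  by merging adjacent cells, which strictly enlarges airspaces.  The true
  mean chord of a foam has no closed form; it is established by an
  exhaustive one-pixel-spacing chord scan of the whole mask (same border
  and minimum-length rules as the estimator).
* **Leukocyte point patterns** -- a chosen number of dense, internally
  connected foci plus sparse background cells, placed so foci stay
  separable at the detector's default linking radius.
* **CT volumes** -- a true-HU phantom (water 0, air -1000, lung at a chosen
  level, body tissue +40) pushed through a hidden affine gain/offset so
  calibration is a real step; Gaussian noise is added in HU units.
* **MR slices** -- labeled lung / muscle / kidney ROIs at chosen mean
  levels with Gaussian noise; the true T2 ratio is lung/muscle.
* **Studies** -- a whole cohort (groups x subjects x weeks) written to disk
  as TIFF/CSV/NIfTI plus a manifest, with a per-subject latent severity
  that couples Lm upward and lung HU downward (and T2 upward) so
  cross-modality correlations have a known sign.

Identical (parameters, seed) always reproduce identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .foci import DEFAULT_LINKING_RADIUS_UM, LeukocytePointSet
from .imaging import (LABEL_AIR, LABEL_KIDNEY, LABEL_LUNG, LABEL_MUSCLE,
                      LABEL_VOI, LABEL_WATER, MrSlice)
from .stereology import DEFAULT_MIN_CHORD_UM, HistologySection

__all__ = [
    "GroundTruth",
    "GroupSpec",
    "StudyDesign",
    "DegenerateGeometryError",
    "PlacementError",
    "generate_alveolar_section",
    "inject_leukocyte_foci",
    "generate_ct_volume",
    "generate_mr_slice",
    "generate_study",
    "exhaustive_mean_chord",
    "RawCtVolume",
]


class DegenerateGeometryError(ValueError):
    """Requested geometry is below the raster resolution."""


class PlacementError(RuntimeError):
    """Could not place the requested foci after bounded retries."""


@dataclass
class GroundTruth:
    """Known truth of one generated artifact (unset fields are None)."""

    true_mean_chord_um: float | None = None
    true_n_foci: int | None = None
    true_lung_hu: float | None = None
    true_t2_ratio: float | None = None
    seed: int | None = None
    morphology: str | None = None
    emphysema_fraction: float | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.true_mean_chord_um is not None and self.true_mean_chord_um <= 0:
            raise ValueError("true_mean_chord_um must be positive")
        if self.emphysema_fraction is not None and not (
                0.0 <= self.emphysema_fraction <= 1.0):
            raise ValueError("emphysema_fraction must be in [0, 1]")

    def to_json(self) -> str:
        d = {k: v for k, v in asdict(self).items() if v is not None}
        return json.dumps(d, sort_keys=True)


# ---------------------------------------------------------------------------
# exhaustive chord oracle


def _all_run_lengths(air: np.ndarray) -> np.ndarray:
    """Run lengths of True along axis 1, border-touching runs discarded."""
    h, w = air.shape
    pad = np.zeros((h, w + 2), dtype=np.int8)
    pad[:, 1:-1] = air
    d = np.diff(pad, axis=1)
    _, scol = np.nonzero(d == 1)
    _, ecol = np.nonzero(d == -1)
    keep = (scol > 0) & (ecol < w)
    return (ecol - scol)[keep]


def exhaustive_mean_chord(mask: np.ndarray, pixel_size_um: float,
                          min_chord_um: float = DEFAULT_MIN_CHORD_UM) -> float:
    """True mean air-chord of a whole mask at one-pixel line spacing.

    Scans every row and every column, applying the same border-discard and
    minimum-length rules as the Lm estimator.  This is the internal ground
    truth for foam phantoms, for which no closed form exists.
    """
    air = ~np.asarray(mask, dtype=bool)
    runs = np.concatenate([_all_run_lengths(air), _all_run_lengths(air.T)])
    lengths = runs * pixel_size_um
    lengths = lengths[lengths >= min_chord_um]
    if lengths.size == 0:
        raise ValueError("mask yields no chords above the minimum length")
    return float(lengths.mean())


# ---------------------------------------------------------------------------
# alveolar sections


def _disk(radius_px: float) -> np.ndarray:
    r = int(np.floor(radius_px))
    if r < 1:
        return np.ones((1, 1), dtype=bool)
    yy, xx = np.ogrid[-r:r + 1, -r:r + 1]
    return yy**2 + xx**2 <= radius_px**2


def _voronoi_foam_mask(size_px: int, pixel_size_um: float, period_um: float,
                       septum_um: float, emphysema_fraction: float,
                       rng: np.random.Generator) -> np.ndarray:
    extent_um = size_px * pixel_size_um
    n_seeds = max(4, int(round((extent_um / period_um) ** 2)))
    seeds = rng.uniform(0.0, extent_um, size=(n_seeds, 2))
    coords = (np.arange(size_px) + 0.5) * pixel_size_um
    gy, gx = np.meshgrid(coords, coords, indexing="ij")
    grid = np.column_stack([gy.ravel(), gx.ravel()])
    _, lab = cKDTree(seeds).query(grid)
    labels = lab.reshape(size_px, size_px).astype(np.int32)

    # septal walls live between adjacent Voronoi cells; emphysema removes a
    # fraction of the shared walls.  The removal order is a single seeded
    # permutation, so the removed set is nested in emphysema_fraction and
    # the true mean chord is strictly monotone in it at fixed seed.
    pairs = set()
    for a, b in ((labels[:, :-1], labels[:, 1:]),
                 (labels[:-1, :], labels[1:, :])):
        diff = a != b
        p = np.stack([a[diff], b[diff]], axis=1)
        p.sort(axis=1)
        pairs.update(map(tuple, np.unique(p, axis=0)))
    pairs = sorted(pairs)
    order = rng.permutation(len(pairs))
    n_remove = int(round(emphysema_fraction * len(pairs)))
    removed = {pairs[i] for i in order[:n_remove]}

    def _kept_wall(a: np.ndarray, b: np.ndarray) -> np.ndarray:
        diff = a != b
        if removed and diff.any():
            lo = np.minimum(a, b)
            hi = np.maximum(a, b)
            key = lo.astype(np.int64) * n_seeds + hi
            removed_keys = np.fromiter(
                (p[0] * n_seeds + p[1] for p in sorted(removed)),
                dtype=np.int64)
            diff &= ~np.isin(key, removed_keys)
        return diff

    wall = np.zeros_like(labels, dtype=bool)
    wall[:, :-1] |= _kept_wall(labels[:, :-1], labels[:, 1:])
    wall[:-1, :] |= _kept_wall(labels[:-1, :], labels[1:, :])
    half = septum_um / (2.0 * pixel_size_um)
    tissue = ndimage.binary_dilation(wall, structure=_disk(half))
    return tissue


def generate_alveolar_section(
    morphology: str = "voronoi_foam",
    period_um: float = 55.0,
    septum_um: float = 8.0,
    emphysema_fraction: float = 0.0,
    size_px: int = 1024,
    pixel_size_um: float = 2.0,
    seed: int | None = None,
    section_id: str = "",
    subject_id: str = "",
) -> tuple[HistologySection, GroundTruth]:
    """Generate a binary alveolar tissue mask with known mean chord length.

    ``morphology="parallel_septa"`` builds a vertical grating whose
    horizontal air chords all equal ``period_um - septum_um`` (an analytic
    phantom); ``"voronoi_foam"`` builds an isotropic foam in which
    ``emphysema_fraction`` of the shared cell walls are removed.
    """
    if not (period_um > septum_um > 0):
        raise ValueError("need period_um > septum_um > 0")
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be positive")
    if not (0.0 <= emphysema_fraction <= 1.0):
        raise ValueError("emphysema_fraction must be in [0, 1]")
    period_px = int(round(period_um / pixel_size_um))
    if period_um < 2 * pixel_size_um:
        raise DegenerateGeometryError(
            f"period {period_um} um is under 2 pixels at "
            f"{pixel_size_um} um/px")
    rng = np.random.default_rng(seed)
    if morphology == "parallel_septa":
        septum_px = max(1, int(round(septum_um / pixel_size_um)))
        if septum_px >= period_px:
            raise DegenerateGeometryError("septum fills the whole period")
        col = np.arange(size_px) % period_px < septum_px
        tissue = np.broadcast_to(col, (size_px, size_px)).copy()
        true_chord = (period_px - septum_px) * pixel_size_um
    elif morphology == "voronoi_foam":
        tissue = _voronoi_foam_mask(size_px, pixel_size_um, period_um,
                                    septum_um, emphysema_fraction, rng)
        true_chord = exhaustive_mean_chord(tissue, pixel_size_um)
    else:
        raise ValueError(f"unknown morphology: {morphology!r}")
    section = HistologySection(tissue, pixel_size_um, section_id=section_id,
                               subject_id=subject_id)
    truth = GroundTruth(true_mean_chord_um=true_chord, seed=seed,
                        morphology=morphology,
                        emphysema_fraction=emphysema_fraction)
    return section, truth


# ---------------------------------------------------------------------------
# leukocyte point patterns


def _is_connected(points: np.ndarray, radius: float) -> bool:
    n = len(points)
    if n <= 1:
        return True
    pairs = cKDTree(points).query_pairs(radius, output_type="ndarray")
    graph = coo_matrix((np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])),
                       shape=(n, n))
    n_comp, _ = connected_components(graph, directed=False)
    return n_comp == 1


def inject_leukocyte_foci(
    section,
    n_foci: int,
    cells_per_focus: int = 25,
    focus_radius_um: float = 50.0,
    background_density_per_mm2: float = 0.5,
    seed: int | None = None,
    section_id: str = "",
    subject_id: str = "",
) -> tuple[LeukocytePointSet, GroundTruth]:
    """Place leukocyte foci plus sparse background cells in a section.

    ``section`` is a :class:`HistologySection` (extent taken from its mask
    and pixel size) or a ``(width_um, height_um)`` tuple.  Each focus gets
    ``cells_per_focus`` cells inside a disc of ``focus_radius_um``,
    resampled until internally connected at the detector's default linking
    radius; focus centers keep a mutual gap of several linking radii, and
    background cells are kept out of a margin around foci, so the injected
    count is exactly recoverable at default detection settings.
    """
    if n_foci < 0:
        raise ValueError("n_foci must be >= 0")
    if n_foci > 0 and cells_per_focus < 21:
        raise ValueError("cells_per_focus must be >= 21 to satisfy the "
                         "'more than 20 leukocytes' rule")
    if isinstance(section, HistologySection):
        h_px, w_px = section.shape
        width_um = w_px * section.pixel_size_um
        height_um = h_px * section.pixel_size_um
    else:
        width_um, height_um = map(float, section)
    area_mm2 = width_um * height_um / 1e6
    rng = np.random.default_rng(seed)
    link = DEFAULT_LINKING_RADIUS_UM
    min_sep = 2 * focus_radius_um + 4 * link
    margin = focus_radius_um + link
    if n_foci > 0 and (width_um <= 2 * margin or height_um <= 2 * margin):
        raise PlacementError("section too small for any focus")

    centers: list[np.ndarray] = []
    attempts = 0
    while len(centers) < n_foci:
        attempts += 1
        if attempts > 1000 * max(n_foci, 1):
            raise PlacementError(
                f"could not place {n_foci} foci in {area_mm2:.1f} mm^2")
        c = rng.uniform([margin, margin],
                        [width_um - margin, height_um - margin])
        if all(np.linalg.norm(c - prev) >= min_sep for prev in centers):
            centers.append(c)

    clusters: list[np.ndarray] = []
    for c in centers:
        for _ in range(200):
            r = focus_radius_um * np.sqrt(rng.uniform(size=cells_per_focus))
            th = rng.uniform(0, 2 * np.pi, size=cells_per_focus)
            pts = c + np.column_stack([r * np.cos(th), r * np.sin(th)])
            if _is_connected(pts, link):
                clusters.append(pts)
                break
        else:  # pragma: no cover - essentially unreachable at defaults
            raise PlacementError("focus failed to connect after retries")

    n_bg = rng.poisson(background_density_per_mm2 * area_mm2)
    bg: list[np.ndarray] = []
    tries = 0
    keepout = focus_radius_um + 3 * link
    while len(bg) < n_bg and tries < 100 * max(n_bg, 1):
        tries += 1
        p = rng.uniform([0.0, 0.0], [width_um, height_um])
        if all(np.linalg.norm(p - c) >= keepout for c in centers):
            bg.append(p)

    parts = clusters + ([np.array(bg)] if bg else [])
    points = np.concatenate(parts) if parts else np.empty((0, 2))
    pset = LeukocytePointSet(points, area_mm2, section_id=section_id,
                             subject_id=subject_id)
    truth = GroundTruth(true_n_foci=n_foci, seed=seed,
                        extra={"section_area_mm2": area_mm2})
    return pset, truth


# ---------------------------------------------------------------------------
# CT volumes


@dataclass
class RawCtVolume:
    """Uncalibrated CT voxel grid with its region label map."""

    voxels: np.ndarray
    labels: np.ndarray
    voxel_size_um: float


def _ct_labels(shape: tuple[int, int, int]) -> np.ndarray:
    nz, ny, nx = shape
    labels = np.zeros(shape, dtype=np.int16)
    # water calibration phantom: box in one corner
    labels[:, :ny // 4, :nx // 4] = LABEL_WATER
    # air reference: box in the opposite corner
    labels[:, :ny // 4, 3 * nx // 4:] = LABEL_AIR
    # lung: central ellipsoid; VOI: inner ellipsoid
    zz, yy, xx = np.ogrid[:nz, :ny, :nx]
    cz, cy, cx = (nz - 1) / 2, 0.62 * (ny - 1), (nx - 1) / 2
    rz, ry, rx = 0.38 * nz, 0.28 * ny, 0.38 * nx
    lung = ((zz - cz) / rz) ** 2 + ((yy - cy) / ry) ** 2 + (
        (xx - cx) / rx) ** 2 <= 1.0
    voi = ((zz - cz) / (0.55 * rz)) ** 2 + ((yy - cy) / (0.55 * ry)) ** 2 + (
        (xx - cx) / (0.55 * rx)) ** 2 <= 1.0
    labels[lung] = LABEL_LUNG
    labels[voi] = LABEL_VOI  # VOI voxels are lung voxels; lung = {1, 6}
    return labels


def generate_ct_volume(
    lung_mean_hu: float = -400.0,
    noise_sd_hu: float = 20.0,
    shape: tuple[int, int, int] = (48, 48, 48),
    voxel_size_um: float = 18.0,
    seed: int | None = None,
) -> tuple[RawCtVolume, np.ndarray, GroundTruth]:
    """Generate an uncalibrated CT volume, its VOI mask, and the truth.

    The raw intensities are ``gain * (HU + noise) + offset`` with a seeded
    hidden gain in [0.5, 2] and offset in [-200, 200], so HU calibration
    from the water (0 HU) and air (-1000 HU) regions is a nontrivial,
    exactly invertible step.  Body tissue outside the labeled regions sits
    at +40 HU.
    """
    if min(shape) < 16:
        raise ValueError("shape must be at least 16 voxels per axis")
    if noise_sd_hu < 0:
        raise ValueError("noise_sd_hu must be >= 0")
    rng = np.random.default_rng(seed)
    labels = _ct_labels(tuple(shape))
    hu = np.full(shape, 40.0)
    hu[labels == LABEL_WATER] = 0.0
    hu[labels == LABEL_AIR] = -1000.0
    hu[(labels == LABEL_LUNG) | (labels == LABEL_VOI)] = lung_mean_hu
    gain = rng.uniform(0.5, 2.0)
    offset = rng.uniform(-200.0, 200.0)
    noise = rng.normal(0.0, noise_sd_hu, size=shape) if noise_sd_hu else 0.0
    raw = gain * (hu + noise) + offset
    volume = RawCtVolume(raw, labels, voxel_size_um)
    truth = GroundTruth(true_lung_hu=lung_mean_hu, seed=seed,
                        extra={"gain": gain, "offset": offset,
                               "noise_sd_hu": noise_sd_hu})
    return volume, labels == LABEL_VOI, truth


# ---------------------------------------------------------------------------
# MR slices


def generate_mr_slice(
    lung_level: float = 318.0,
    muscle_level: float = 250.0,
    kidney_level: float = 280.0,
    noise_sd: float = 0.0,
    shape: tuple[int, int] = (128, 128),
    seed: int | None = None,
) -> tuple[MrSlice, GroundTruth]:
    """Generate a labeled T2-weighted slice with known region means."""
    if muscle_level <= 0:
        raise ValueError("muscle_level must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    ny, nx = shape
    rng = np.random.default_rng(seed)
    labels = np.zeros(shape, dtype=np.int16)
    yy, xx = np.ogrid[:ny, :nx]

    def ellipse(cy, cx, ry, rx):
        return ((yy - cy * ny) / (ry * ny)) ** 2 + (
            (xx - cx * nx) / (rx * nx)) ** 2 <= 1.0

    labels[ellipse(0.35, 0.35, 0.15, 0.12)] = LABEL_LUNG
    labels[ellipse(0.35, 0.65, 0.15, 0.12)] = LABEL_LUNG
    labels[ellipse(0.72, 0.40, 0.07, 0.05)] = LABEL_KIDNEY
    labels[ellipse(0.72, 0.60, 0.07, 0.05)] = LABEL_KIDNEY
    labels[int(0.80 * ny):int(0.95 * ny), int(0.05 * nx):int(0.18 * nx)] = \
        LABEL_MUSCLE
    image = np.full(shape, 100.0)
    image[labels == LABEL_LUNG] = lung_level
    image[labels == LABEL_MUSCLE] = muscle_level
    image[labels == LABEL_KIDNEY] = kidney_level
    if noise_sd:
        image = image + rng.normal(0.0, noise_sd, size=shape)
    truth = GroundTruth(true_t2_ratio=lung_level / muscle_level, seed=seed,
                        extra={"lung_level": lung_level,
                               "muscle_level": muscle_level,
                               "kidney_level": kidney_level})
    return MrSlice(image, labels), truth


# ---------------------------------------------------------------------------
# whole-study generator


@dataclass
class GroupSpec:
    """Per-group effect parameters, one knob per modality."""

    name: str
    n_subjects: int = 5
    lm_scale: float = 1.0           # multiplies the foam period
    emphysema_fraction: float = 0.0  # wall-removal alternative/addition
    foci_per_20mm2: float = 1.1     # target subject-level focus density
    lung_hu_week12: float = -384.9
    lung_hu_week6: float = -373.9
    t2_ratio: float = 1.05

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")


def _default_groups() -> list[GroupSpec]:
    # effect sizes mirror the modeled cohorts: smoke exposure raises Lm
    # ~20% and focus density ~10x and lowers lung HU ~15 units; the
    # macrolide-treated group sits between
    return [
        GroupSpec("control", 4, 1.0, 0.0, 1.1, -384.9, -373.9, 1.05),
        GroupSpec("CS", 5, 1.2, 0.0, 10.98, -399.5, -399.1, 1.336),
        GroupSpec("CS_Azi", 5, 0.95, 0.0, 5.147, -377.3, -399.1, 1.08),
    ]


@dataclass
class StudyDesign:
    """Cohort layout plus generator parameters for every modality."""

    groups: list[GroupSpec] = field(default_factory=_default_groups)
    timepoints: tuple[int, ...] = (0, 6, 8, 10, 12)
    sections_per_subject: int = 3
    fields_per_subject: int = 5
    # histology
    histology_size_px: int = 1024
    histology_pixel_size_um: float = 2.0
    period_um: float = 55.0
    septum_um: float = 8.0
    lm_subject_cv: float = 0.04
    # foci (scored on whole low-power sections, independent raster)
    foci_section_um: tuple[float, float] = (6000.0, 4000.0)
    cells_per_focus: int = 25
    focus_radius_um: float = 50.0
    background_density_per_mm2: float = 0.5
    # CT
    ct_shape: tuple[int, int, int] = (32, 32, 32)
    ct_noise_sd_hu: float = 5.0
    hu_baseline_week0: float = -357.0
    hu_subject_sd: float = 4.0
    # MRI
    mr_shape: tuple[int, int] = (128, 128)
    mr_muscle_level: float = 250.0
    mr_noise_sd: float = 3.0
    t2_subject_cv: float = 0.03
    # latent severity coupling (Lm up, HU down, T2 up)
    severity_coupling: float = 0.7

    def __post_init__(self) -> None:
        if self.sections_per_subject < 1 or self.fields_per_subject < 1:
            raise ValueError("sections/fields per subject must be >= 1")
        if not self.groups:
            raise ValueError("need at least one group")


def _group_hu_anchor(spec: GroupSpec, week: int, baseline: float) -> float:
    """Piecewise-linear lung HU trajectory through weeks 0, 6 and 12."""
    if week <= 0:
        return baseline
    if week <= 6:
        return baseline + (spec.lung_hu_week6 - baseline) * week / 6.0
    return spec.lung_hu_week6 + (spec.lung_hu_week12 - spec.lung_hu_week6) * (
        week - 6) / 6.0


def generate_study(design: StudyDesign, seed: int,
                   out_dir: str | Path) -> pd.DataFrame:
    """Write a full synthetic study to disk and return its manifest.

    Layout: ``histology/*.tif`` (8-bit, 255 = tissue), ``points/*.csv``
    (``x_um,y_um``), ``ct/*.nii`` raw volumes + ``*_labels.nii`` region
    maps, ``mr/*.nii`` + labels, and ``manifest.csv`` with columns
    ``subject_id,group,week,modality,path,truth_json``.  Re-running with
    the same design and seed reproduces the tree byte-for-byte.
    """
    import nibabel as nib
    import tifffile

    out = Path(out_dir)
    for sub in ("histology", "points", "ct", "mr"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    root_ss = np.random.SeedSequence(seed)
    rows: list[dict] = []
    final_week = max(design.timepoints)

    def _save_nii(arr: np.ndarray, path: Path) -> None:
        img = nib.Nifti1Image(np.asarray(arr, dtype=np.float32), np.eye(4))
        nib.save(img, path)

    subject_idx = 0
    for g_i, spec in enumerate(design.groups):
        for s_i in range(spec.n_subjects):
            sid = f"{spec.name}_{s_i + 1:02d}"
            ss = np.random.SeedSequence(entropy=root_ss.entropy,
                                        spawn_key=(g_i, s_i))
            rng = np.random.default_rng(ss)
            z = rng.normal()  # latent severity, shared across modalities
            rho = design.severity_coupling

            def coupled(direction: float) -> float:
                return direction * rho * z + np.sqrt(1 - rho**2) * rng.normal()

            # --- histology: Lm effect scales the foam period
            z_lm = coupled(+1.0)
            period = design.period_um * spec.lm_scale * (
                1.0 + design.lm_subject_cv * z_lm)
            for k in range(design.sections_per_subject):
                sec_seed = int(rng.integers(0, 2**31 - 1))
                section, truth = generate_alveolar_section(
                    "voronoi_foam", period_um=period,
                    septum_um=design.septum_um,
                    emphysema_fraction=spec.emphysema_fraction,
                    size_px=design.histology_size_px,
                    pixel_size_um=design.histology_pixel_size_um,
                    seed=sec_seed, section_id=f"{sid}_s{k + 1}",
                    subject_id=sid)
                path = out / "histology" / f"{sid}_s{k + 1}.tif"
                tifffile.imwrite(
                    path, section.tissue_mask.astype(np.uint8) * 255)
                truth.extra.update(
                    pixel_size_um=design.histology_pixel_size_um,
                    section_id=f"{sid}_s{k + 1}")
                rows.append(dict(subject_id=sid, group=spec.name,
                                 week=final_week, modality="histology",
                                 path=str(path.relative_to(out)),
                                 truth_json=truth.to_json()))

            # --- leukocyte foci: subject density around the group level
            area = design.foci_section_um[0] * design.foci_section_um[1] / 1e6
            subj_density = max(0.0, spec.foci_per_20mm2 *
                               (1.0 + 0.10 * coupled(+1.0)))
            for k in range(design.sections_per_subject):
                n_f = int(rng.poisson(subj_density * area / 20.0))
                pts_seed = int(rng.integers(0, 2**31 - 1))
                pset, truth = inject_leukocyte_foci(
                    design.foci_section_um, n_f,
                    cells_per_focus=design.cells_per_focus,
                    focus_radius_um=design.focus_radius_um,
                    background_density_per_mm2=design.background_density_per_mm2,
                    seed=pts_seed, section_id=f"{sid}_s{k + 1}",
                    subject_id=sid)
                path = out / "points" / f"{sid}_s{k + 1}.csv"
                pd.DataFrame(pset.points, columns=["x_um", "y_um"]).to_csv(
                    path, index=False, float_format="%.3f")
                truth.extra["section_id"] = f"{sid}_s{k + 1}"
                rows.append(dict(subject_id=sid, group=spec.name,
                                 week=final_week, modality="points",
                                 path=str(path.relative_to(out)),
                                 truth_json=truth.to_json()))

            # --- CT: one volume per timepoint along the HU trajectory
            hu_shift = design.hu_subject_sd * coupled(-1.0)
            for week in design.timepoints:
                level = _group_hu_anchor(spec, week, design.hu_baseline_week0)
                if week > 0:
                    level += hu_shift
                ct_seed = int(rng.integers(0, 2**31 - 1))
                vol, voi, truth = generate_ct_volume(
                    lung_mean_hu=level, noise_sd_hu=design.ct_noise_sd_hu,
                    shape=design.ct_shape, seed=ct_seed)
                path = out / "ct" / f"{sid}_wk{week:02d}.nii"
                lpath = out / "ct" / f"{sid}_wk{week:02d}_labels.nii"
                _save_nii(vol.voxels, path)
                _save_nii(vol.labels, lpath)
                truth.extra["labels_path"] = str(lpath.relative_to(out))
                rows.append(dict(subject_id=sid, group=spec.name, week=week,
                                 modality="ct",
                                 path=str(path.relative_to(out)),
                                 truth_json=truth.to_json()))

            # --- MRI at the final week
            ratio = max(0.1, spec.t2_ratio *
                        (1.0 + design.t2_subject_cv * coupled(+1.0)))
            mr_seed = int(rng.integers(0, 2**31 - 1))
            mr, truth = generate_mr_slice(
                lung_level=ratio * design.mr_muscle_level,
                muscle_level=design.mr_muscle_level,
                noise_sd=design.mr_noise_sd, shape=design.mr_shape,
                seed=mr_seed)
            path = out / "mr" / f"{sid}_wk{final_week:02d}.nii"
            lpath = out / "mr" / f"{sid}_wk{final_week:02d}_labels.nii"
            _save_nii(mr.image, path)
            _save_nii(mr.labels, lpath)
            truth.extra["labels_path"] = str(lpath.relative_to(out))
            rows.append(dict(subject_id=sid, group=spec.name, week=final_week,
                             modality="mri",
                             path=str(path.relative_to(out)),
                             truth_json=truth.to_json()))
            subject_idx += 1

    manifest = pd.DataFrame(rows, columns=["subject_id", "group", "week",
                                           "modality", "path", "truth_json"])
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest
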