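"""End-to-end orchestration: simulate -> quantify -> stats -> report.

A run is fully described by a :class:`RunConfig` (YAML-serializable, every
parameter explicit after defaulting) and a seed; the same config + seed
regenerate byte-identical outputs.  Stages write tidy per-module CSVs into
the run directory:

* ``lm.csv`` -- per-field chord summaries and subject Lm
* ``foci.csv`` -- per-section focus counts and densities
* ``ct.csv`` -- per-subject-per-week mean lung HU
* ``mri.csv`` -- per-subject T2 intensity ratios
* ``measurements.csv`` -- one row per subject with week-12 values
* ``report.json`` -- group summaries, pairwise exact tests, fold changes,
  cross-modality Spearman correlations, and ground-truth recovery
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import foci as foci_mod
from . import imaging, stats, stereology, synthetic
from .io import (load_manifest, read_ct_volume, read_histology_section,
                 read_mr_slice, read_point_set)

__all__ = ["RunConfig", "StudyReport", "run_pipeline", "correlate_modalities"]

log = logging.getLogger("emphyquant")

DEFAULT_CORRELATION_PAIRS = (
    ("mean_hu", "lm_um"),
    ("t2_ratio", "mean_hu"),
    ("t2_ratio", "lm_um"),
    ("t2_ratio", "foci_per_20mm2"),
)


@dataclass
class RunConfig:
    """Every knob of a pipeline run; round-trips losslessly through YAML."""

    out_dir: str = "run"
    seed: int = 0
    simulate: bool = True
    manifest: str | None = None  # required when simulate=False
    design: synthetic.StudyDesign = field(
        default_factory=synthetic.StudyDesign)
    # stereology
    n_fields: int = 5
    field_size_px: int | None = None
    line_spacing_um: float = stereology.DEFAULT_LINE_SPACING_UM
    min_chord_um: float = stereology.DEFAULT_MIN_CHORD_UM
    # foci
    linking_radius_um: float = foci_mod.DEFAULT_LINKING_RADIUS_UM
    min_cells: int = foci_mod.DEFAULT_MIN_CELLS
    # CT
    lung_window: tuple[float, float] | None = imaging.DEFAULT_LUNG_WINDOW
    baseline_week: int = 0
    # analysis plan
    comparisons: tuple[tuple[str, str], ...] = (
        ("CS", "control"), ("CS_Azi", "control"), ("CS", "CS_Azi"))
    correlation_pairs: tuple[tuple[str, str], ...] = DEFAULT_CORRELATION_PAIRS
    correlation_week: int = 12

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return json.loads(json.dumps(d))  # tuples -> lists

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "design" in d and not isinstance(d["design"],
                                            synthetic.StudyDesign):
            dd = dict(d["design"])
            dd["groups"] = [synthetic.GroupSpec(**g) for g in dd["groups"]]
            for key in ("timepoints", "foci_section_um", "ct_shape",
                        "mr_shape"):
                dd[key] = tuple(dd[key])
            d["design"] = synthetic.StudyDesign(**dd)
        for key in ("comparisons", "correlation_pairs"):
            if key in d:
                d[key] = tuple(tuple(p) for p in d[key])
        if d.get("lung_window") is not None:
            d["lung_window"] = tuple(d["lung_window"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class StudyReport:
    """Tidy outputs of one full run."""

    measurements: pd.DataFrame          # one row per subject, week-12 values
    comparisons: list[dict]             # pairwise tests + fold changes
    correlations: list[dict]            # cross-modality Spearman panel
    recovery: pd.DataFrame              # measured vs generated ground truth
    longitudinal: list[dict]            # per-week Kruskal-Wallis on %change


# ---------------------------------------------------------------------------
# quantification stages


def quantify_lm(manifest: pd.DataFrame, root: str | Path,
                cfg: RunConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Subject-level Lm plus a per-field detail table."""
    rows, detail = [], []
    hist = manifest[manifest.modality == "histology"]
    ss = np.random.SeedSequence(cfg.seed)
    for i, (sid, grp) in enumerate(sorted(hist.groupby("subject_id"))):
        sections = [read_histology_section(r, root)
                    for r in grp.itertuples()]
        res = stereology.compute_lm(
            sections, n_fields=cfg.n_fields, field_size_px=cfg.field_size_px,
            line_spacing_um=cfg.line_spacing_um,
            min_chord_um=cfg.min_chord_um,
            seed=int(np.random.default_rng(
                np.random.SeedSequence(entropy=ss.entropy,
                                       spawn_key=(1, i))).integers(2**31)))
        truths = [json.loads(r.truth_json) for r in grp.itertuples()]
        true_lm = float(np.mean([t["true_mean_chord_um"] for t in truths])) \
            if all("true_mean_chord_um" in t for t in truths) else np.nan
        rows.append(dict(subject_id=sid, group=grp.group.iloc[0],
                         lm_um=res.lm_um, n_chords=res.n_chords_total,
                         true_lm_um=true_lm))
        for sec, means in zip(sections, res.per_field_means_um):
            for f_i, m in enumerate(means):
                detail.append(dict(subject_id=sid,
                                   section_id=sec.section_id,
                                   field_id=f_i, orientation="pooled",
                                   n_chords=np.nan, mean_chord_um=m,
                                   lm_um=res.lm_um))
    return pd.DataFrame(rows), pd.DataFrame(detail)


def quantify_foci(manifest: pd.DataFrame, root: str | Path,
                  cfg: RunConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    rows, detail = [], []
    pts = manifest[manifest.modality == "points"]
    for sid, grp in sorted(pts.groupby("subject_id")):
        densities, true_total = [], 0
        for r in grp.itertuples():
            pset = read_point_set(r, root)
            res = foci_mod.detect_foci(pset, cfg.linking_radius_um,
                                       cfg.min_cells)
            densities.append(res.foci_per_20mm2)
            truth = json.loads(r.truth_json)
            true_total += truth.get("true_n_foci", 0)
            detail.append(dict(subject_id=sid, section_id=pset.section_id,
                               n_foci=res.n_foci,
                               area_mm2=pset.section_area_mm2,
                               foci_per_20mm2=res.foci_per_20mm2))
        rows.append(dict(subject_id=sid, group=grp.group.iloc[0],
                         foci_per_20mm2=float(np.mean(densities)),
                         true_n_foci=true_total))
    return pd.DataFrame(rows), pd.DataFrame(detail)


def quantify_ct(manifest: pd.DataFrame, root: str | Path,
                cfg: RunConfig) -> pd.DataFrame:
    rows = []
    ct = manifest[manifest.modality == "ct"]
    for r in ct.itertuples():
        vol = read_ct_volume(r, root)
        cal = imaging.HUCalibrator().fit(vol.voxels, vol.labels)
        hu = cal.transform(vol.voxels)
        voi = vol.labels == imaging.LABEL_VOI
        lung_mask = (imaging.segment_lung(hu, cfg.lung_window)
                     if cfg.lung_window is not None else None)
        res = imaging.mean_hu(hu, voi, lung_mask, cfg.lung_window)
        truth = json.loads(r.truth_json)
        rows.append(dict(subject_id=r.subject_id, group=r.group, week=r.week,
                         mean_hu=res.mean_hu, n_voxels=res.n_voxels_used,
                         true_lung_hu=truth.get("true_lung_hu", np.nan)))
    return pd.DataFrame(rows).sort_values(
        ["subject_id", "week"]).reset_index(drop=True)


def quantify_mri(manifest: pd.DataFrame, root: str | Path,
                 cfg: RunConfig) -> pd.DataFrame:
    rows = []
    mr = manifest[manifest.modality == "mri"]
    for r in mr.itertuples():
        res = imaging.t2_ratio(read_mr_slice(r, root))
        truth = json.loads(r.truth_json)
        rows.append(dict(subject_id=r.subject_id, group=r.group, week=r.week,
                         t2_ratio=res.ratio_lung,
                         t2_ratio_kidney=res.ratio_kidney,
                         true_t2_ratio=truth.get("true_t2_ratio", np.nan)))
    return pd.DataFrame(rows).sort_values("subject_id").reset_index(drop=True)


# ---------------------------------------------------------------------------
# statistics stages


def compare_groups(measurements: pd.DataFrame,
                   comparisons, variables=("lm_um", "foci_per_20mm2",
                                           "mean_hu", "t2_ratio")
                   ) -> list[dict]:
    """Pairwise exact Mann-Whitney tests + median fold changes per variable."""
    out = []
    for var in variables:
        if var not in measurements.columns:
            continue
        for a, b in comparisons:
            xa = measurements.loc[measurements.group == a, var].dropna()
            xb = measurements.loc[measurements.group == b, var].dropna()
            if xa.empty or xb.empty:
                log.warning("comparison %s vs %s on %s skipped: empty group",
                            a, b, var)
                continue
            res = stats.mann_whitney_exact(xa, xb)
            sa, sb = stats.summarize(xa), stats.summarize(xb)
            fc = (stats.fold_change(sa.median, sb.median)
                  if sb.median != 0 else None)
            out.append(dict(
                variable=var, group_a=a, group_b=b,
                median_a=sa.median, range_a=[sa.min, sa.max], n_a=sa.n,
                median_b=sb.median, range_b=[sb.min, sb.max], n_b=sb.n,
                fold_change=fc, u_statistic=res.statistic,
                p_two_sided=res.p_two_sided, exact=res.exact))
    return out


def correlate_modalities(measurements: pd.DataFrame,
                         pairs=DEFAULT_CORRELATION_PAIRS) -> list[dict]:
    """Cross-modality Spearman panel over subjects with both measurements."""
    out = []
    for a, b in pairs:
        if a not in measurements.columns or b not in measurements.columns:
            log.warning("correlation %s ~ %s skipped: missing modality", a, b)
            continue
        sub = measurements[[a, b]].dropna()
        if len(sub) < 3:
            log.warning("correlation %s ~ %s skipped: <3 shared subjects",
                        a, b)
            continue
        res = stats.spearman(sub[a], sub[b])
        out.append(dict(variable_a=a, variable_b=b, rho=res.rho,
                        p_two_sided=res.p_two_sided, n=res.n,
                        exact=res.exact))
    return out


def longitudinal_hu(ct_table: pd.DataFrame, baseline_week: int) -> list[dict]:
    """Per-week Kruskal-Wallis across groups on HU percent change."""
    pct_rows = []
    for sid, grp in ct_table.groupby("subject_id"):
        series = dict(zip(grp.week, grp.mean_hu))
        pct = imaging.percent_change(series, baseline_week)
        for wk, v in pct.items():
            pct_rows.append(dict(subject_id=sid, group=grp.group.iloc[0],
                                 week=wk, hu_pct_change=v))
    if not pct_rows:
        return []
    pct_df = pd.DataFrame(pct_rows)
    out = []
    for wk, grp in pct_df.groupby("week"):
        if wk == baseline_week:
            continue
        groups = [g["hu_pct_change"].to_numpy()
                  for _, g in grp.groupby("group", sort=True)]
        if len(groups) < 2:
            continue
        res = stats.kruskal_wallis(groups)
        out.append(dict(week=int(wk), h_statistic=res.statistic,
                        p_two_sided=res.p_two_sided, exact=res.exact))
    return out


# ---------------------------------------------------------------------------
# driver


def run_pipeline(config: RunConfig) -> StudyReport:
    """Execute every enabled stage and write the combined report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)
    log.info("effective config: %s",
             json.dumps(config.to_dict(), sort_keys=True))
    config.to_yaml(out / "effective_config.yaml")

    if config.simulate:
        data_dir = out / "data"
        manifest = synthetic.generate_study(config.design, config.seed,
                                            data_dir)
        root = data_dir
    else:
        if not config.manifest:
            raise ValueError("simulate=False requires a manifest path")
        manifest = load_manifest(config.manifest)
        root = Path(manifest.attrs["root"])

    lm_tbl, lm_detail = quantify_lm(manifest, root, config)
    foci_tbl, foci_detail = quantify_foci(manifest, root, config)
    ct_tbl = quantify_ct(manifest, root, config)
    mri_tbl = quantify_mri(manifest, root, config)

    wk = config.correlation_week
    ct_final = ct_tbl[ct_tbl.week == wk][
        ["subject_id", "mean_hu", "true_lung_hu"]]
    measurements = (
        lm_tbl.merge(foci_tbl.drop(columns="group"), on="subject_id",
                     how="outer")
        .merge(ct_final, on="subject_id", how="outer")
        .merge(mri_tbl[["subject_id", "t2_ratio", "true_t2_ratio"]],
               on="subject_id", how="outer")
        .sort_values("subject_id").reset_index(drop=True))

    comparisons = compare_groups(measurements, config.comparisons)
    correlations = correlate_modalities(measurements,
                                        config.correlation_pairs)
    longitudinal = longitudinal_hu(ct_tbl, config.baseline_week)

    recovery = _recovery_table(measurements)

    _write_csv(lm_detail, out / "lm.csv")
    _write_csv(foci_detail, out / "foci.csv")
    _write_csv(ct_tbl, out / "ct.csv")
    _write_csv(mri_tbl, out / "mri.csv")
    _write_csv(measurements, out / "measurements.csv")
    _write_csv(recovery, out / "recovery.csv")
    report = dict(comparisons=comparisons, correlations=correlations,
                  longitudinal=longitudinal, seed=config.seed)
    (out / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True) + "\n")
    return StudyReport(measurements, comparisons, correlations, recovery,
                       longitudinal)


def _recovery_table(measurements: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for var, truth_col in (("lm_um", "true_lm_um"),
                           ("mean_hu", "true_lung_hu"),
                           ("t2_ratio", "true_t2_ratio")):
        if var not in measurements or truth_col not in measurements:
            continue
        sub = measurements[[var, truth_col]].dropna()
        if sub.empty:
            continue
        rel = (sub[var] - sub[truth_col]).abs() / sub[truth_col].abs()
        rows.append(dict(variable=var, n=len(sub),
                         max_rel_error=float(rel.max()),
                         mean_rel_error=float(rel.mean())))
    return pd.DataFrame(rows)


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.6g")
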