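"""Readers for the on-disk study dialect (TIFF masks, point CSVs, NIfTI).

The manifest is a CSV with columns ``subject_id,group,week,modality,path,
truth_json``; paths are relative to the manifest's directory.  Pixel sizes
and section areas travel in ``truth_json`` rather than in image headers,
which sidesteps TIFF-tag dialect ambiguity.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import tifffile

from .foci import LeukocytePointSet
from .imaging import MrSlice
from .stereology import HistologySection
from .synthetic import RawCtVolume

__all__ = [
    "load_manifest",
    "read_histology_section",
    "read_point_set",
    "read_ct_volume",
    "read_mr_slice",
]


def load_manifest(manifest_path: str | Path) -> pd.DataFrame:
    """Load a study manifest; adds a ``root`` attribute for path resolution."""
    path = Path(manifest_path)
    df = pd.read_csv(path)
    required = {"subject_id", "group", "week", "modality", "path",
                "truth_json"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    df.attrs["root"] = str(path.parent)
    return df


def _truth(row) -> dict:
    return json.loads(row.truth_json)


def read_histology_section(row, root: str | Path,
                           invert: bool = False) -> HistologySection:
    """Read an 8-bit mask TIFF (255 = tissue unless ``invert``)."""
    arr = tifffile.imread(Path(root) / row.path)
    tissue = arr > 127
    if invert:
        tissue = ~tissue
    t = _truth(row)
    extra = t.get("extra", {})
    return HistologySection(
        tissue, pixel_size_um=float(extra["pixel_size_um"]),
        section_id=extra.get("section_id", ""), subject_id=row.subject_id)


def read_point_set(row, root: str | Path) -> LeukocytePointSet:
    """Read an ``x_um,y_um`` CSV; area comes from the manifest truth."""
    df = pd.read_csv(Path(root) / row.path)
    t = _truth(row)
    extra = t.get("extra", {})
    return LeukocytePointSet(
        df[["x_um", "y_um"]].to_numpy(), float(extra["section_area_mm2"]),
        section_id=extra.get("section_id", ""), subject_id=row.subject_id)


def read_ct_volume(row, root: str | Path) -> RawCtVolume:
    """Read a raw CT NIfTI plus its integer label map."""
    root = Path(root)
    vox = np.asarray(nib.load(root / row.path).dataobj, dtype=float)
    t = _truth(row)
    labels = np.rint(np.asarray(
        nib.load(root / t["extra"]["labels_path"]).dataobj)).astype(np.int16)
    return RawCtVolume(vox, labels, voxel_size_um=t["extra"].get(
        "voxel_size_um", 18.0))


def read_mr_slice(row, root: str | Path) -> MrSlice:
    root = Path(root)
    img = np.asarray(nib.load(root / row.path).dataobj, dtype=float)
    t = _truth(row)
    labels = np.rint(np.asarray(
        nib.load(root / t["extra"]["labels_path"]).dataobj)).astype(np.int16)
    return MrSlice(img, labels)
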