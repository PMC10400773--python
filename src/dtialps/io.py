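"""File I/O: NIfTI volumes, FSL-style bval/bvec, cohort CSVs, ROI configs.

Conventions: NIfTI-1 for volumes (scalar maps written float32 with the
source affine), FSL dialect for gradients (one whitespace-separated row of
b-values; three rows of direction components), CSV with header for tables
(missing values as empty fields), JSON for results and provenance.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .alps import ROISpec
from .tensor import DWIVolume, GradientTable, GradientTableError

__all__ = [
    "read_bvals_bvecs",
    "write_bvals_bvecs",
    "read_dwi",
    "write_dwi",
    "write_scalar_map",
    "read_cohort",
    "read_rois",
    "write_rois",
    "write_provenance",
]

GROUP_VOCAB = ("NC", "MCI", "AD")
GENDER_VOCAB = ("M", "F")


def read_bvals_bvecs(bval_path, bvec_path) -> tuple[np.ndarray, np.ndarray]:
    """Parse FSL-style gradient text files -> (bvals (N,), bvecs (N, 3))."""
    bvals = np.loadtxt(bval_path, ndmin=2)
    if bvals.shape[0] != 1:
        raise ValueError(f"bval file must contain exactly 1 row, found {bvals.shape[0]}")
    bvals = bvals.ravel()
    bvecs = np.loadtxt(bvec_path, ndmin=2)
    if bvecs.shape[0] != 3:
        raise ValueError(f"bvec file: expected 3 rows, found {bvecs.shape[0]}")
    if bvecs.shape[1] != bvals.shape[0]:
        raise ValueError(
            f"bvec columns ({bvecs.shape[1]}) do not match bval count ({bvals.shape[0]})"
        )
    return bvals, bvecs.T


def write_bvals_bvecs(bvals, bvecs, bval_path, bvec_path) -> None:
    np.savetxt(bval_path, np.asarray(bvals, dtype=float)[None, :], fmt="%.10g")
    np.savetxt(bvec_path, np.asarray(bvecs, dtype=float).T, fmt="%.10g")


def read_dwi(nifti_path, bval_path, bvec_path) -> tuple[DWIVolume, GradientTable]:
    """Load a 4-D DWI volume with its gradient table, cross-validated."""
    img = nib.load(str(nifti_path))
    data = np.asarray(img.get_fdata())
    if data.ndim != 4:
        raise ValueError(f"expected 4-D DWI volume, got shape {data.shape}")
    bvals, bvecs = read_bvals_bvecs(bval_path, bvec_path)
    if data.shape[-1] != bvals.shape[0]:
        raise ValueError(
            f"volume has {data.shape[-1]} frames but gradient table has {bvals.shape[0]}"
        )
    gtab = GradientTable(bvals=bvals, bvecs=bvecs)  # validates norms/directions
    voxel_size = np.asarray(img.header.get_zooms()[:3], dtype=float)
    dwi = DWIVolume(data=data, affine=np.asarray(img.affine), voxel_size=voxel_size)
    return dwi, gtab


def write_dwi(dwi: DWIVolume, gtab: GradientTable, nifti_path, bval_path, bvec_path) -> None:
    img = nib.Nifti1Image(dwi.data.astype(np.float64), dwi.affine)
    img.header.set_zooms(tuple(dwi.voxel_size) + (1.0,))
    nib.save(img, str(nifti_path))
    write_bvals_bvecs(gtab.bvals, gtab.bvecs, bval_path, bvec_path)


def write_scalar_map(data: np.ndarray, affine: np.ndarray, path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine), str(path))


def read_cohort(csv_path, require_features: bool = False) -> pd.DataFrame:
    """Load and validate a cohort table.

    Checks group/gender vocabularies, WMH range [0, 6] and subject-id
    uniqueness; raises ``ValueError`` naming the offending row/column.
    """
    df = pd.read_csv(csv_path)
    required = ["subject_id", "group", "gender", "age", "education", "WMH"]
    if require_features:
        required += ["L_ALPS", "R_ALPS", "Bi_ALPS", "FA_mean"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"cohort CSV missing columns: {missing}")
    dup = df["subject_id"][df["subject_id"].duplicated()]
    if not dup.empty:
        raise ValueError(f"duplicate subject_id: {sorted(dup.unique())}")
    bad_grp = df.loc[~df["group"].isin(GROUP_VOCAB)]
    if not bad_grp.empty:
        raise ValueError(
            f"row {bad_grp.index[0]}, column 'group': unknown label {bad_grp['group'].iloc[0]!r}"
        )
    bad_sex = df.loc[~df["gender"].isin(GENDER_VOCAB)]
    if not bad_sex.empty:
        raise ValueError(
            f"row {bad_sex.index[0]}, column 'gender': unknown label {bad_sex['gender'].iloc[0]!r}"
        )
    wmh = pd.to_numeric(df["WMH"], errors="raise")
    bad_wmh = df.loc[(wmh < 0) | (wmh > 6) | (wmh != wmh.round())]
    if not bad_wmh.empty:
        raise ValueError(
            f"row {bad_wmh.index[0]}, column 'WMH': value {bad_wmh['WMH'].iloc[0]!r} "
            "outside integer range [0, 6]"
        )
    for col in ("L_ALPS", "R_ALPS", "Bi_ALPS"):
        if col in df.columns:
            bad = df.loc[df[col].notna() & (df[col] <= 0)]
            if not bad.empty:
                raise ValueError(f"row {bad.index[0]}, column {col!r}: ALPS must be > 0")
    return df


def read_rois(path) -> list[ROISpec]:
    """ROI config from JSON (list of objects) or CSV with columns
    label, hemisphere, x_mm, y_mm, z_mm, radius_mm."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        records = json.loads(path.read_text())
    else:
        records = pd.read_csv(path).to_dict("records")
    rois = []
    for rec in records:
        rois.append(ROISpec(
            label=str(rec["label"]),
            hemisphere=str(rec["hemisphere"]),
            center_mm=(float(rec["x_mm"]), float(rec["y_mm"]), float(rec["z_mm"])),
            radius_mm=float(rec.get("radius_mm", 5.0)),
        ))
    return rois


def write_rois(rois: list[ROISpec], path) -> None:
    path = Path(path)
    records = [{
        "label": r.label, "hemisphere": r.hemisphere,
        "x_mm": r.center_mm[0], "y_mm": r.center_mm[1], "z_mm": r.center_mm[2],
        "radius_mm": r.radius_mm,
    } for r in rois]
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(records, indent=2, sort_keys=True))
    else:
        pd.DataFrame(records).to_csv(path, index=False)


def write_provenance(path, stage: str, config: dict, seed: int | None) -> None:
    """JSON sidecar recording stage, seed and a hash of the configuration.

    Deliberately timestamp-free so that re-runs with identical inputs are
    byte-identical.
    """
    blob = json.dumps(config, sort_keys=True, default=str)
    record = {
        "stage": stage,
        "seed": seed,
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
        "config": json.loads(blob),
    }
    Path(path).write_text(json.dumps(record, indent=2, sort_keys=True))
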