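"""NIfTI and CSV round-trip helpers."""

from __future__ import annotations

import hashlib
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

COHORT_COLUMNS = ["subject_id", "diagnosis", "visit_j", "visit_k", "t_years",
                  "scan_type", "y_ml"]

BSI_COLUMNS = ["subject_id", "structure", "scan_type", "visit_j", "visit_k",
               "bsi_ml", "n_boundary_voxels", "window_lo", "window_hi"]


def save_nifti(volume: np.ndarray, path, voxel_size=(1.0, 1.0, 1.0)) -> None:
    """Write a volume as NIfTI-1 with an RAS+ diagonal affine."""
    affine = np.diag(list(voxel_size) + [1.0])
    img = nib.Nifti1Image(np.asarray(volume, dtype=np.float32), affine)
    img.header.set_zooms(voxel_size)
    nib.save(img, str(path))


def load_nifti(path):
    """Read a NIfTI volume; returns (array, voxel_size, voxel_volume_ml)."""
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=float)
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    voxel_volume_ml = float(np.prod(zooms)) / 1000.0
    return data, zooms, voxel_volume_ml


def check_same_grid(a: np.ndarray, b: np.ndarray, what: str = "mask") -> None:
    if a.shape != b.shape:
        raise ValueError(f"grid mismatch between image {a.shape} and "
                         f"{what} {b.shape}")


def write_table(df: pd.DataFrame, path) -> None:
    """Deterministic CSV output (fixed float format, no index)."""
    df.to_csv(path, index=False, float_format="%.6f", lineterminator="\n")


def read_cohort_csv(path) -> pd.DataFrame:
    """Read and validate a cohort change table.

    Raises with the offending row number on missing cells or malformed
    headers.
    """
    df = pd.read_csv(path)
    missing_cols = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"{path}: missing columns {missing_cols}")
    for col in COHORT_COLUMNS:
        na = df[col].isna()
        if na.any():
            row = int(na.idxmax()) + 2  # header + 1-based
            raise ValueError(f"{path}: missing {col} at line {row}")
    return df


def sha256_of(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
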