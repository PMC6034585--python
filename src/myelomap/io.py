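"""NIfTI and table I/O helpers."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = ["read_nifti", "write_nifti", "read_lut", "write_lut", "save_subject"]

LUT_COLUMNS = ["region_id", "name", "hemisphere", "homologue_id"]


def read_nifti(path) -> tuple[np.ndarray, np.ndarray]:
    """Load a NIfTI volume; returns (data, affine)."""
    img = nib.load(str(path))
    return np.asarray(img.dataobj), img.affine


def write_nifti(data: np.ndarray, affine: np.ndarray, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(np.asarray(data), affine), str(path))
    return path


def read_lut(path) -> pd.DataFrame:
    """Region lookup table as TSV with columns id, name, hemisphere,
    homologue_id (FreeSurfer-style LUT in spirit)."""
    lut = pd.read_csv(path, sep="\t")
    missing = set(LUT_COLUMNS) - set(lut.columns)
    if missing:
        raise ValueError(f"lut missing columns: {sorted(missing)}")
    return lut[LUT_COLUMNS]


def write_lut(lut: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lut[LUT_COLUMNS].to_csv(path, sep="\t", index=False)
    return path


def save_subject(subject, out_dir, subject_id: str) -> dict:
    """Write one synthetic subject's volumes and truth table under
    ``out_dir/subject_id``; returns the path map for the cohort manifest."""
    base = Path(out_dir) / subject_id
    base.mkdir(parents=True, exist_ok=True)
    aff = subject.affine
    paths = {
        "t1_path": str(write_nifti(subject.intensity, aff, base / "t1.nii.gz")),
        "tissue_path": str(
            write_nifti(subject.tissue_labels.astype(np.int16), aff, base / "tissue.nii.gz")
        ),
        "parcellation_path": str(
            write_nifti(subject.parcellation.astype(np.int32), aff, base / "parcellation.nii.gz")
        ),
        "lut_path": str(write_lut(subject.lut(), base / "lut.tsv")),
        "truth_path": str(base / "truth.csv"),
    }
    subject.truth.to_csv(base / "truth.csv", index=False)
    if subject.lesion_mask.any():
        paths["lesion_path"] = str(
            write_nifti(subject.lesion_mask.astype(np.uint8), aff, base / "lesion.nii.gz")
        )
    else:
        paths["lesion_path"] = ""
    return paths
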