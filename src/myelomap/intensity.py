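"""Per-region white-matter intensity and hemispheric asymmetry ratios.

Operates on *uncorrected* T1-weighted intensities: automated intensity
normalization alters voxel values, so the contract is that the volume passed
in is raw.  Scanner inhomogeneity is instead controlled by comparing the two
hemispheres within each subject.

The asymmetry ratio is (contralesional mean WM intensity) / (ipsilesional
mean WM intensity), lesion excluded; values above 1 indicate lower
ipsilesional intensity, i.e. ipsilesional white-matter injury.  For controls
the same machinery reports right/left.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classify import Parcellation, RegionClassification
from .phantom import (
    PERILESIONAL,
    IPSILESIONAL_REMOTE,
    CONTRALESIONAL_HOMOLOGUE,
    LESION_OVERLAP,
)

logger = logging.getLogger(__name__)

__all__ = ["AsymmetryResult", "region_means", "hemispheric_asymmetry_ratio"]


@dataclass
class AsymmetryResult:
    """Hemispheric and class-level asymmetry summaries for one subject."""

    hemispheric_ratio: float
    remote_vs_homologue_ratio: float | None
    per_class_means: dict = field(default_factory=dict)


def region_means(
    volume: np.ndarray,
    parcellation: Parcellation,
    wm_mask: np.ndarray,
    lesion_mask: np.ndarray | None = None,
    classification: RegionClassification | None = None,
) -> pd.DataFrame:
    """Mean intensity over (region ∩ WM) \\ lesion for every region.

    Returns a table with columns region_id, class, hemisphere, n_voxels,
    mean_intensity, sd_intensity.  Regions left with zero WM voxels after
    exclusions are dropped with a warning rather than reported as zero.
    For controls pass ``classification=None``; the class column then carries
    the hemisphere name.
    """
    labels = parcellation.labels
    for name, arr in (("volume", volume), ("wm_mask", wm_mask)):
        if arr.shape != labels.shape:
            raise ValueError(f"{name} grid does not match parcellation")
    scored = wm_mask.astype(bool)
    if lesion_mask is not None:
        if lesion_mask.shape != labels.shape:
            raise ValueError("lesion_mask grid does not match parcellation")
        scored &= ~lesion_mask.astype(bool)

    lab = labels[scored]
    vals = volume[scored].astype(np.float64)
    nmax = int(labels.max()) + 1
    n = np.bincount(lab.ravel(), minlength=nmax)
    s = np.bincount(lab.ravel(), weights=vals, minlength=nmax)
    s2 = np.bincount(lab.ravel(), weights=vals**2, minlength=nmax)

    rows = []
    for r in parcellation.region_ids:
        if n[r] == 0:
            logger.warning("region %d has no WM voxels after exclusions; dropped", r)
            continue
        mean = s[r] / n[r]
        var = max(s2[r] / n[r] - mean**2, 0.0)
        cls = (
            classification.assignment.get(r, "unclassified")
            if classification is not None
            else parcellation.hemisphere(r)
        )
        rows.append(
            {
                "region_id": r,
                "class": cls,
                "hemisphere": parcellation.hemisphere(r),
                "n_voxels": int(n[r]),
                "mean_intensity": mean,
                "sd_intensity": float(np.sqrt(var)),
            }
        )
    return pd.DataFrame(rows)


def _pooled_mean(table: pd.DataFrame, mask: pd.Series, weighted: bool) -> float:
    sub = table[mask]
    if sub.empty:
        return np.nan
    if weighted:
        return float(
            np.average(sub["mean_intensity"], weights=sub["n_voxels"])
        )
    return float(sub["mean_intensity"].mean())


def hemispheric_asymmetry_ratio(
    table: pd.DataFrame,
    lesion_hemisphere: str | None = None,
    weighted: bool = True,
) -> AsymmetryResult:
    """Contralesional / ipsilesional WM intensity ratio from a region table.

    Aggregation is voxel-weighted by default (the pooled-voxel hemisphere
    mean); ``weighted=False`` averages region means instead, for sensitivity
    analysis.  Lesion-overlapped regions are excluded from scoring.  For
    controls (``lesion_hemisphere=None``) the ratio is right / left.
    """
    if table.empty or table["hemisphere"].nunique() < 2:
        raise ValueError("table must contain rows in both hemispheres")
    tab = table[table["class"] != LESION_OVERLAP]

    if lesion_hemisphere is None:
        numer_hemi, denom_hemi = "right", "left"
    else:
        if lesion_hemisphere not in ("left", "right"):
            raise ValueError("lesion_hemisphere must be 'left' or 'right'")
        denom_hemi = lesion_hemisphere
        numer_hemi = "right" if lesion_hemisphere == "left" else "left"

    numer = _pooled_mean(tab, tab["hemisphere"] == numer_hemi, weighted)
    denom = _pooled_mean(tab, tab["hemisphere"] == denom_hemi, weighted)
    if not np.isfinite(denom) or denom == 0:
        raise ValueError("degenerate intensity: ipsilesional aggregate is zero")

    per_class = {
        cls: _pooled_mean(tab, tab["class"] == cls, weighted)
        for cls in tab["class"].unique()
    }
    rvh = None
    if lesion_hemisphere is not None:
        remote = per_class.get(IPSILESIONAL_REMOTE, np.nan)
        homologue = per_class.get(CONTRALESIONAL_HOMOLOGUE, np.nan)
        if np.isfinite(remote) and np.isfinite(homologue) and remote != 0:
            rvh = float(homologue / remote)

    return AsymmetryResult(
        hemispheric_ratio=float(numer / denom),
        remote_vs_homologue_ratio=rvh,
        per_class_means=per_class,
    )
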