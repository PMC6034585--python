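"""Lesion-adjacency classification of parcellated regions.

Given an integer parcellation and a binary lesion mask on the same grid, every
region is assigned one of five classes relative to the lesion:

- ``perilesional``: at least one region voxel outside the lesion is a
  neighbour (under the chosen voxel connectivity) of a lesion voxel;
- ``lesion_overlap``: at least ``overlap_fraction`` of the region's voxels lie
  inside the lesion (excluded from intensity scoring downstream);
- ``ipsilesional_remote``: same hemisphere as the lesion, no contact;
- ``contralesional_homologue``: the opposite-hemisphere counterpart of an
  ipsilesional remote region;
- ``contralesional_other``: any other contralesional region (homologues of
  perilesional or overlapped parcels), retained so region sets partition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .phantom import (
    PERILESIONAL,
    IPSILESIONAL_REMOTE,
    CONTRALESIONAL_HOMOLOGUE,
    CONTRALESIONAL_OTHER,
    LESION_OVERLAP,
)

logger = logging.getLogger(__name__)

__all__ = ["Parcellation", "RegionClassification", "classify_regions", "hemisphere_of"]

_STRUCTS = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclass
class Parcellation:
    """Integer label grid (0 = unlabeled) plus a region lookup table.

    ``lut`` columns: region_id, name, hemisphere ('left'/'right'),
    homologue_id.  The homologue mapping must be an involution across
    hemispheres.
    """

    labels: np.ndarray
    lut: pd.DataFrame

    def __post_init__(self):
        lut = self.lut.set_index("region_id", drop=False)
        present = set(np.unique(self.labels)) - {0}
        missing = present - set(lut.index)
        if missing:
            raise ValueError(f"labels absent from lut: {sorted(missing)}")
        for r, row in lut.iterrows():
            h = row["homologue_id"]
            if h not in lut.index:
                raise ValueError(f"homologue {h} of region {r} not in lut")
            if lut.loc[h, "homologue_id"] != r:
                raise ValueError(f"homologue mapping not an involution at {r}")
            if lut.loc[h, "hemisphere"] == row["hemisphere"]:
                raise ValueError(f"homologue of {r} is in the same hemisphere")
        self._lut = lut

    def hemisphere(self, region_id: int) -> str:
        return self._lut.loc[region_id, "hemisphere"]

    def homologue(self, region_id: int) -> int:
        return int(self._lut.loc[region_id, "homologue_id"])

    @property
    def region_ids(self) -> list[int]:
        return [int(r) for r in self._lut.index]


@dataclass
class RegionClassification:
    """Class assignment for every region, plus the lesion's hemisphere."""

    assignment: dict[int, str]
    lesion_hemisphere: str

    def regions_in(self, cls: str) -> list[int]:
        return sorted(r for r, c in self.assignment.items() if c == cls)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"region_id": list(self.assignment), "class": list(self.assignment.values())}
        ).sort_values("region_id", ignore_index=True)


def hemisphere_of(voxel, labels: np.ndarray, parcellation: Parcellation | None = None) -> str:
    """Hemisphere of a voxel: left iff x < nx // 2 (midsagittal plane between
    the two central columns of axis 0).

    When a parcellation is supplied and the voxel carries a label, the lut's
    hemisphere takes precedence; a positional disagreement is logged.
    """
    x = voxel[0]
    if not 0 <= x < labels.shape[0]:
        raise IndexError("voxel outside grid")
    positional = "left" if x < labels.shape[0] // 2 else "right"
    if parcellation is not None:
        label = int(labels[tuple(voxel)])
        if label != 0:
            from_lut = parcellation.hemisphere(label)
            if from_lut != positional:
                logger.warning(
                    "voxel %s: lut hemisphere %s overrides positional %s",
                    tuple(voxel), from_lut, positional,
                )
            return from_lut
    return positional


def classify_regions(
    parcellation: Parcellation,
    lesion_mask: np.ndarray,
    connectivity: int = 26,
    overlap_fraction: float = 0.5,
) -> RegionClassification:
    """Classify every region in the lookup table relative to the lesion.

    "Directly touching" is voxel adjacency under ``connectivity`` (6, 18 or
    26); contact is evaluated from region voxels *outside* the lesion.
    Controls have no lesion and bypass this operation entirely.
    """
    if connectivity not in _STRUCTS:
        raise ValueError("connectivity must be 6, 18 or 26")
    labels = parcellation.labels
    if labels.shape != lesion_mask.shape:
        raise ValueError("parcellation and lesion mask grids differ")
    if not lesion_mask.any():
        raise ValueError("classification requires a lesion")

    half = labels.shape[0] // 2
    xs = np.nonzero(lesion_mask)[0]
    if xs.min() < half <= xs.max():
        raise ValueError("lesion spans both hemispheres")
    lesion_hemisphere = "left" if xs.mean() < half else "right"

    ring = ndimage.binary_dilation(lesion_mask, _STRUCTS[connectivity]) & ~lesion_mask
    touching = set(int(v) for v in np.unique(labels[ring])) - {0}
    nmax = int(labels.max()) + 1
    inside = np.bincount(labels[lesion_mask].ravel(), minlength=nmax)
    sizes = np.bincount(labels.ravel(), minlength=nmax)

    assignment: dict[int, str] = {}
    remote: set[int] = set()
    ipsi = [r for r in parcellation.region_ids
            if parcellation.hemisphere(r) == lesion_hemisphere]
    contra = [r for r in parcellation.region_ids
              if parcellation.hemisphere(r) != lesion_hemisphere]
    for r in ipsi:
        frac = inside[r] / sizes[r] if r < nmax and sizes[r] > 0 else 0.0
        if frac >= overlap_fraction:
            assignment[r] = LESION_OVERLAP
        elif r in touching:
            assignment[r] = PERILESIONAL
        else:
            assignment[r] = IPSILESIONAL_REMOTE
            remote.add(r)
    for r in contra:
        assignment[r] = (
            CONTRALESIONAL_HOMOLOGUE
            if parcellation.homologue(r) in remote
            else CONTRALESIONAL_OTHER
        )

    result = RegionClassification(assignment, lesion_hemisphere)
    _check_invariants(result, parcellation, ipsi)
    return result


def _check_invariants(
    result: RegionClassification, parcellation: Parcellation, ipsi: list[int]
) -> None:
    # partition of ipsilesional regions and remote<->homologue bijection
    ipsi_classes = {PERILESIONAL, IPSILESIONAL_REMOTE, LESION_OVERLAP}
    for r in ipsi:
        assert result.assignment[r] in ipsi_classes
    remote = result.regions_in(IPSILESIONAL_REMOTE)
    homologues = result.regions_in(CONTRALESIONAL_HOMOLOGUE)
    assert sorted(parcellation.homologue(r) for r in remote) == homologues
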