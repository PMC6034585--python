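"""Shared fixtures and independent oracles.

The oracles here deliberately avoid the library's code paths: region
adjacency is checked by looping over every labeled voxel's neighbourhood, and
the threshold sweep by enumerating all 255 candidate levels.
"""

import numpy as np
import pandas as pd
import pytest

from myelomap.classify import Parcellation
from myelomap.phantom import (
    CONTRALESIONAL_HOMOLOGUE,
    CONTRALESIONAL_OTHER,
    IPSILESIONAL_REMOTE,
    LESION_OVERLAP,
    PERILESIONAL,
)

# ---------------------------------------------------------------- oracles


def neighbour_offsets(connectivity):
    offs = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if (dx, dy, dz) == (0, 0, 0):
                    continue
                order = abs(dx) + abs(dy) + abs(dz)
                if connectivity == 6 and order > 1:
                    continue
                if connectivity == 18 and order > 2:
                    continue
                offs.append((dx, dy, dz))
    return offs


def oracle_classify(labels, lesion, lut, connectivity=26, overlap_fraction=0.5):
    """Exhaustive voxel-neighbourhood scan, independent of scipy dilation."""
    nx, ny, nz = labels.shape
    offs = neighbour_offsets(connectivity)
    touching = set()
    for x, y, z in zip(*np.nonzero(labels)):
        if lesion[x, y, z]:
            continue
        r = int(labels[x, y, z])
        if r in touching:
            continue
        for dx, dy, dz in offs:
            p = (x + dx, y + dy, z + dz)
            if 0 <= p[0] < nx and 0 <= p[1] < ny and 0 <= p[2] < nz and lesion[p]:
                touching.add(r)
                break
    xs = np.nonzero(lesion)[0]
    half = nx // 2
    lesion_hemi = "left" if xs.mean() < half else "right"
    lut_idx = lut.set_index("region_id")
    assignment = {}
    remote = set()
    for r in lut_idx.index:
        mask = labels == r
        if lut_idx.loc[r, "hemisphere"] == lesion_hemi:
            frac = (mask & lesion).sum() / mask.sum() if mask.sum() else 0.0
            if frac >= overlap_fraction:
                assignment[r] = LESION_OVERLAP
            elif r in touching:
                assignment[r] = PERILESIONAL
            else:
                assignment[r] = IPSILESIONAL_REMOTE
                remote.add(r)
    for r in lut_idx.index:
        if lut_idx.loc[r, "hemisphere"] != lesion_hemi:
            h = lut_idx.loc[r, "homologue_id"]
            assignment[r] = (
                CONTRALESIONAL_HOMOLOGUE if h in remote else CONTRALESIONAL_OTHER
            )
    return assignment, lesion_hemi


def oracle_sweep_slice(slice_img, wm_left, wm_right, m=1):
    """Enumerate every level t in 1..255; T* is the largest with >= m WM
    pixels at or above t in each hemisphere; count pixels >= T* + 1."""
    vl = slice_img[wm_left]
    vr = slice_img[wm_right]
    t_star = None
    for t in range(1, 256):
        if (vl >= t).sum() >= m and (vr >= t).sum() >= m:
            t_star = t
    if t_star is None:
        return None, None, 0
    cutoff = t_star + 1
    return t_star, cutoff, int((vl >= cutoff).sum() + (vr >= cutoff).sum())


# ----------------------------------------------------------- toy builders


def make_toy_parcellation(n_per_hemi=3, shape=(12, 8, 14)):
    """Hand-built mirror pair of WM slabs stacked along z; ids 1..n left,
    n+1..2n right."""
    nx, ny, nz = shape
    labels = np.zeros(shape, dtype=np.int32)
    z_edges = np.linspace(2, nz - 2, n_per_hemi + 1).astype(int)
    for i in range(n_per_hemi):
        labels[2 : nx // 2 - 1, 2 : ny - 2, z_edges[i] : z_edges[i + 1]] = i + 1
    mirrored = labels[::-1, :, :]
    labels = labels + np.where(mirrored > 0, mirrored + n_per_hemi, 0)
    lut = pd.DataFrame(
        {
            "region_id": np.arange(1, 2 * n_per_hemi + 1),
            "name": [f"r{i}" for i in range(1, 2 * n_per_hemi + 1)],
            "hemisphere": ["left"] * n_per_hemi + ["right"] * n_per_hemi,
            "homologue_id": list(range(n_per_hemi + 1, 2 * n_per_hemi + 1))
            + list(range(1, n_per_hemi + 1)),
        }
    )
    return Parcellation(labels, lut)


@pytest.fixture
def toy_parcellation():
    return make_toy_parcellation()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
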