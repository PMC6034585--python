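"""Slice-wise adaptive bilateral threshold sweep.

The score quantifies hemispheric myelination asymmetry without a parcellation.
On each axial slice, working on intensities quantized to the 1-255 brightness
scale, the threshold is pushed upward to the highest level T* that at least
``min_bilateral_pixels`` white-matter pixels in *each* hemisphere still reach.
The cutoff is one level above T*; every remaining WM pixel at or above the
cutoff is counted as positive.  Those pixels are brighter than the dimmer
hemisphere can reach anywhere on the slice, so a mirror-symmetric slice scores
exactly 0 and the per-slice counts, summed from the most inferior slice with
bilateral WM upward, measure the hemispheric intensity difference.  Lesion
pixels are removed from the WM masks before sweeping; lesion and brain
volumetry are accumulated over every slice.

With ``min_bilateral_pixels = 1`` the per-slice count has a closed form: the
number of WM pixels strictly brighter than the dimmer hemisphere's WM maximum
(necessarily all in the brighter hemisphere).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "SliceSweepResult",
    "SweepScore",
    "quantize_to_255",
    "find_start_slice",
    "sweep_slice",
    "sweep_volume",
]


@dataclass
class SliceSweepResult:
    """Sweep outcome for one axial slice.

    ``bilateral_threshold`` is T*, the highest quantized level reached by at
    least ``min_bilateral_pixels`` WM pixels in each hemisphere; ``cutoff`` is
    T* + 1.  On slices where no level is reached bilaterally the slice is
    skipped: ``swept`` is False and the count is 0.
    """

    slice_index: int
    bilateral_threshold: int | None
    cutoff: int | None
    positive_pixel_count: int
    brain_pixels: int = 0
    lesion_pixels: int = 0
    swept: bool = True


@dataclass
class SweepScore:
    """Whole-volume sweep summary: total positive-pixel score and volumetry."""

    total_score: int
    per_slice: list[SliceSweepResult] = field(default_factory=list)
    lesion_volume_mm3: float = 0.0
    brain_volume_mm3: float = 0.0
    lesion_fraction_percent: float = 0.0
    start_slice: int = 0


def quantize_to_255(volume: np.ndarray, brain_mask: np.ndarray) -> np.ndarray:
    """Linearly map intensities over brain voxels onto integer levels 1..255.

    Non-brain voxels are set to 0.  A constant volume maps to level 128.
    """
    if not np.all(np.isfinite(volume[brain_mask])):
        raise ValueError("volume contains non-finite values inside the brain")
    if not brain_mask.any():
        raise ValueError("empty brain mask")
    vals = volume[brain_mask]
    lo, hi = float(vals.min()), float(vals.max())
    out = np.zeros(volume.shape, dtype=np.int16)
    if hi == lo:
        out[brain_mask] = 128
        return out
    scaled = 1.0 + 254.0 * (volume[brain_mask] - lo) / (hi - lo)
    out[brain_mask] = np.rint(scaled).astype(np.int16)
    return out


def find_start_slice(wm_mask: np.ndarray, min_visible_pixels: int = 1) -> int:
    """Most inferior axial slice (axis 2) with at least ``min_visible_pixels``
    WM pixels in each hemisphere."""
    if not wm_mask.any():
        raise ValueError("empty white-matter mask")
    half = wm_mask.shape[0] // 2
    left = wm_mask[:half].sum(axis=(0, 1))
    right = wm_mask[half:].sum(axis=(0, 1))
    ok = (left >= min_visible_pixels) & (right >= min_visible_pixels)
    idx = np.nonzero(ok)[0]
    if idx.size == 0:
        raise ValueError("no slice has bilaterally visible white matter")
    return int(idx[0])


def sweep_slice(
    slice_img: np.ndarray,
    wm_left: np.ndarray,
    wm_right: np.ndarray,
    min_bilateral_pixels: int = 1,
    slice_index: int = 0,
) -> SliceSweepResult:
    """Sweep one quantized slice; lesion pixels must already be removed from
    both WM masks."""
    vals_l = np.asarray(slice_img[wm_left]).ravel()
    vals_r = np.asarray(slice_img[wm_right]).ravel()
    if vals_l.size == 0 and vals_r.size == 0:
        raise ValueError("white matter empty in both hemispheres")
    m = min_bilateral_pixels
    if vals_l.size < m or vals_r.size < m:
        logger.warning(
            "slice %d: fewer than %d WM pixels on one side; skipped", slice_index, m
        )
        return SliceSweepResult(slice_index, None, None, 0, swept=False)
    t_star = int(min(np.sort(vals_l)[-m], np.sort(vals_r)[-m]))
    cutoff = t_star + 1
    count = int((vals_l >= cutoff).sum() + (vals_r >= cutoff).sum())
    return SliceSweepResult(slice_index, t_star, cutoff, count)


def sweep_volume(
    volume: np.ndarray,
    wm_mask: np.ndarray,
    lesion_mask: np.ndarray | None = None,
    voxel_size_mm=(1.0, 1.0, 1.0),
    brain_mask: np.ndarray | None = None,
    min_bilateral_pixels: int = 1,
    min_visible_pixels: int = 1,
    quantize: bool = True,
    normalize_by_brain_volume: bool = False,
) -> SweepScore:
    """Apply the bilateral sweep to every axial slice from the start slice up.

    ``brain_mask`` defaults to nonzero voxels; it drives both the 1..255
    quantization range and the brain volumetry.  Counts are raw pixels unless
    ``normalize_by_brain_volume`` divides the total by brain volume (off by
    default; reported scores are raw counts).
    """
    wm_mask = wm_mask.astype(bool)
    if brain_mask is None:
        brain_mask = volume != 0
    if lesion_mask is not None:
        lesion_mask = lesion_mask.astype(bool)
        wm_eff = wm_mask & ~lesion_mask
    else:
        lesion_mask = np.zeros(volume.shape, dtype=bool)
        wm_eff = wm_mask

    # lesion voxels are excluded from scoring, so they must not drive the
    # quantization range either
    q = (
        quantize_to_255(volume, brain_mask & ~lesion_mask)
        if quantize
        else np.asarray(volume)
    )
    half = volume.shape[0] // 2
    nz = volume.shape[2]
    start = find_start_slice(wm_eff, min_visible_pixels)

    per_slice: list[SliceSweepResult] = []
    total = 0
    for z in range(start, nz):
        sl = q[:, :, z]
        wm_slice = wm_eff[:, :, z]
        left_mask = wm_slice.copy()
        left_mask[half:] = False
        right_mask = wm_slice.copy()
        right_mask[:half] = False
        if not wm_slice.any():
            res = SliceSweepResult(z, None, None, 0, swept=False)
        else:
            res = sweep_slice(sl, left_mask, right_mask,
                              min_bilateral_pixels, slice_index=z)
        res.brain_pixels = int(brain_mask[:, :, z].sum())
        res.lesion_pixels = int(lesion_mask[:, :, z].sum())
        per_slice.append(res)
        total += res.positive_pixel_count

    voxel_vol = float(np.prod(voxel_size_mm))
    brain_volume = float(brain_mask.sum()) * voxel_vol
    lesion_volume = float(lesion_mask.sum()) * voxel_vol
    frac = 100.0 * lesion_volume / brain_volume if brain_volume > 0 else 0.0
    score = total / brain_volume if normalize_by_brain_volume else total
    return SweepScore(
        total_score=score,
        per_slice=per_slice,
        lesion_volume_mm3=lesion_volume,
        brain_volume_mm3=brain_volume,
        lesion_fraction_percent=frac,
        start_slice=start,
    )
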