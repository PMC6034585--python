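"""Threshold sweep: quantization, start slice, per-slice sweep, volumetry."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from myelomap.phantom import PhantomSpec, control_preset, generate_subject, stroke_preset
from myelomap.sweep import (
    find_start_slice,
    quantize_to_255,
    sweep_slice,
    sweep_volume,
)

from conftest import oracle_sweep_slice


# ------------------------------------------------------------- quantization


def test_quantize_identity_on_1_255_integers(rng):
    vol = rng.integers(1, 256, size=(6, 6, 6)).astype(float)
    vol.flat[0], vol.flat[1] = 1, 255  # pin the range
    brain = np.ones(vol.shape, dtype=bool)
    q = quantize_to_255(vol, brain)
    assert np.array_equal(q, vol.astype(int))


def test_quantize_endpoints_and_constant():
    vol = np.zeros((4, 4, 4))
    vol[2, 2, 2] = 100.0
    brain = np.ones(vol.shape, dtype=bool)
    q = quantize_to_255(vol, brain)
    assert q.min() == 1 and q.max() == 255
    const = np.full((4, 4, 4), 7.0)
    assert np.all(quantize_to_255(const, brain) == 128)
    with pytest.raises(ValueError, match="empty brain"):
        quantize_to_255(vol, np.zeros(vol.shape, dtype=bool))


def test_quantize_linear_ramp_matches_closed_form():
    ramp = np.linspace(0.0, 10.0, 64).reshape(4, 4, 4)
    brain = np.ones(ramp.shape, dtype=bool)
    q = quantize_to_255(ramp, brain)
    expected = np.rint(1 + 254 * (ramp - ramp.min()) / (ramp.max() - ramp.min()))
    assert np.array_equal(q, expected.astype(int))


# -------------------------------------------------------------- start slice


def test_find_start_slice_cases():
    wm = np.zeros((8, 4, 20), dtype=bool)
    wm[1, 1, 10:] = True   # left
    wm[6, 1, 10:] = True   # right
    assert find_start_slice(wm) == 10

    wm2 = np.zeros((8, 4, 20), dtype=bool)
    wm2[1, 1, 8:] = True    # left only below slice 12
    wm2[6, 1, 12:] = True
    assert find_start_slice(wm2) == 12

    wm3 = np.zeros((8, 8, 20), dtype=bool)
    wm3[1, 0:6, 8:] = True          # left: 6 pixels from slice 8
    wm3[6, 0:3, 8] = True           # right: 3-pixel sliver at slice 8
    wm3[6, 0:6, 9:] = True          # right: 6 pixels from slice 9
    assert find_start_slice(wm3, min_visible_pixels=5) == 9

    with pytest.raises(ValueError, match="empty"):
        find_start_slice(np.zeros((4, 4, 4), dtype=bool))


# -------------------------------------------------------------- slice sweep


def test_sweep_slice_enumerated_example():
    """left WM {100,110}, right WM {100,110,120,121} -> T*=110, cutoff=111,
    two positive pixels (the 120 and 121)."""
    sl = np.zeros((4, 4), dtype=int)
    left = np.zeros((4, 4), dtype=bool)
    right = np.zeros((4, 4), dtype=bool)
    sl[0, 0], sl[0, 1] = 100, 110
    left[0, 0] = left[0, 1] = True
    sl[2, 0], sl[2, 1], sl[3, 0], sl[3, 1] = 100, 110, 120, 121
    right[2, 0] = right[2, 1] = right[3, 0] = right[3, 1] = True
    res = sweep_slice(sl, left, right, min_bilateral_pixels=1)
    assert (res.bilateral_threshold, res.cutoff, res.positive_pixel_count) == (110, 111, 2)
    t, c, n = oracle_sweep_slice(sl, left, right, 1)
    assert (t, c, n) == (110, 111, 2)


def test_mirror_symmetric_slice_scores_zero(rng):
    half = rng.integers(1, 256, size=(5, 9))
    sl = np.vstack([half, half[::-1]])
    left = np.zeros(sl.shape, dtype=bool)
    right = np.zeros(sl.shape, dtype=bool)
    left[:5] = True
    right[5:] = True
    res = sweep_slice(sl, left, right)
    assert res.positive_pixel_count == 0
    assert res.cutoff == res.bilateral_threshold + 1


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    data=st.data(),
    m=st.integers(min_value=1, max_value=3),
)
def test_sweep_slice_equals_brute_force(data, m):
    """Property: the sweep equals enumeration over all 255 levels."""
    shape = (8, 6)
    vals = data.draw(
        st.lists(
            st.integers(min_value=1, max_value=255),
            min_size=shape[0] * shape[1],
            max_size=shape[0] * shape[1],
        )
    )
    mask_bits = data.draw(
        st.lists(st.booleans(), min_size=shape[0] * shape[1], max_size=shape[0] * shape[1])
    )
    sl = np.array(vals).reshape(shape)
    wm = np.array(mask_bits).reshape(shape)
    left = wm.copy()
    left[4:] = False
    right = wm.copy()
    right[:4] = False
    t, c, n = oracle_sweep_slice(sl, left, right, m)
    if left.sum() == 0 and right.sum() == 0:
        with pytest.raises(ValueError):
            sweep_slice(sl, left, right, m)
        return
    res = sweep_slice(sl, left, right, m)
    if t is None:
        assert not res.swept and res.positive_pixel_count == 0
    else:
        assert (res.bilateral_threshold, res.cutoff, res.positive_pixel_count) == (t, c, n)


def test_sweep_slice_closed_form_when_m_is_1(rng):
    """count = #{pixels brighter than the dimmer hemisphere's WM maximum}."""
    for _ in range(100):
        sl = rng.integers(1, 256, size=(10, 8))
        wm = rng.random(size=(10, 8)) < 0.6
        left = wm.copy()
        left[5:] = False
        right = wm.copy()
        right[:5] = False
        if left.sum() == 0 or right.sum() == 0:
            continue
        res = sweep_slice(sl, left, right, min_bilateral_pixels=1)
        dimmer_max = min(sl[left].max(), sl[right].max())
        closed = int((sl[left] > dimmer_max).sum() + (sl[right] > dimmer_max).sum())
        assert res.positive_pixel_count == closed


# ------------------------------------------------------------ whole volume


def test_symmetric_phantom_scores_zero():
    spec = PhantomSpec(grid_shape=(32, 32, 32), n_regions_per_hemisphere=4)
    s = generate_subject(spec)
    score = sweep_volume(s.intensity, s.wm_mask, brain_mask=s.brain_mask)
    assert score.total_score == 0
    assert all(r.positive_pixel_count == 0 for r in score.per_slice)


def test_volume_score_matches_per_slice_oracle():
    s = generate_subject(control_preset(noise_sd=0.0))
    score = sweep_volume(s.intensity, s.wm_mask, brain_mask=s.brain_mask)
    q = quantize_to_255(s.intensity, s.brain_mask)
    half = s.intensity.shape[0] // 2
    total = 0
    for z in range(score.start_slice, s.intensity.shape[2]):
        wm = s.wm_mask[:, :, z]
        left = wm.copy()
        left[half:] = False
        right = wm.copy()
        right[:half] = False
        if not wm.any():
            continue
        _, _, n = oracle_sweep_slice(q[:, :, z], left, right, 1)
        total += n
    assert score.total_score == total > 0


def test_lesion_exclusion_is_exact():
    """Altering intensities inside the lesion never changes any count."""
    s = generate_subject(stroke_preset(noise_sd=2.0, seed=3))
    a = sweep_volume(s.intensity, s.wm_mask, s.lesion_mask, brain_mask=s.brain_mask)
    tampered = s.intensity.copy()
    tampered[s.lesion_mask] = 255.0
    b = sweep_volume(tampered, s.wm_mask, s.lesion_mask, brain_mask=s.brain_mask)
    assert a.total_score == b.total_score
    assert [r.positive_pixel_count for r in a.per_slice] == [
        r.positive_pixel_count for r in b.per_slice
    ]


def test_monotone_response_to_contralesional_offset():
    scores = []
    for off in (0.0, 5.0, 10.0):
        spec = control_preset(
            noise_sd=0.0, hemisphere_wm_offsets={"left": 0.0, "right": off}
        )
        s = generate_subject(spec)
        scores.append(
            sweep_volume(s.intensity, s.wm_mask, brain_mask=s.brain_mask).total_score
        )
    assert scores[0] == 0
    assert scores[0] <= scores[1] <= scores[2]
    assert scores[2] > 0


def test_volumetry_arithmetic():
    s = generate_subject(stroke_preset(noise_sd=0.0))
    score = sweep_volume(
        s.intensity, s.wm_mask, s.lesion_mask,
        voxel_size_mm=(1.0, 1.0, 1.0), brain_mask=s.brain_mask,
    )
    assert score.lesion_volume_mm3 == float(s.lesion_mask.sum())
    assert score.brain_volume_mm3 == float(s.brain_mask.sum())
    assert score.lesion_fraction_percent == pytest.approx(
        100.0 * s.lesion_mask.sum() / s.brain_mask.sum()
    )
    # anisotropic voxels scale volumetry, not counts
    score2 = sweep_volume(
        s.intensity, s.wm_mask, s.lesion_mask,
        voxel_size_mm=(1.0, 1.0, 5.0), brain_mask=s.brain_mask,
    )
    assert score2.lesion_volume_mm3 == 5.0 * score.lesion_volume_mm3
    assert score2.total_score == score.total_score


def test_rescoring_is_identical():
    """Computational intra-rater analogue: identical rerun, identical scores."""
    s = generate_subject(stroke_preset(noise_sd=5.0, seed=21))
    a = sweep_volume(s.intensity, s.wm_mask, s.lesion_mask, brain_mask=s.brain_mask)
    b = sweep_volume(s.intensity, s.wm_mask, s.lesion_mask, brain_mask=s.brain_mask)
    assert a.total_score == b.total_score
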