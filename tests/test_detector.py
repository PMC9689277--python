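import numpy as np
import pytest

from mlvmf import (
    Round,
    convolve_abs,
    detect,
    make_phantom,
    min_variation,
    variation_tensor,
)
from conftest import naive_convolve_abs, naive_detect, random_rgb


def test_constant_channel_yields_zero_response(bank):
    channel = np.full((9, 9), 128, dtype=np.uint8)
    for k in bank:
        assert (convolve_abs(channel, k) == 0).all()


def test_isolated_impulse_response_is_center_weight_times_amplitude(bank):
    """A 255 spike on a 0 background: the response at the spike is
    |center weight| * 255 for every kernel (all negative taps read 0)."""
    channel = np.zeros((9, 9), dtype=np.uint8)
    channel[4, 4] = 255
    for k in bank:
        assert convolve_abs(channel, k)[4, 4] == int(k.weights[2, 2]) * 255


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_convolve_abs_matches_brute_force(bank, seed):
    rng = np.random.default_rng(seed)
    channel = rng.integers(0, 256, size=(9, 9), dtype=np.uint8)
    for k in bank:
        assert np.array_equal(convolve_abs(channel, k), naive_convolve_abs(channel, k.weights))


def test_variation_tensor_has_24_planes_and_channel_symmetry(bank, rng):
    gray = np.repeat(rng.integers(0, 256, size=(10, 10, 1), dtype=np.uint8), 3, axis=2)
    t = variation_tensor(gray, bank, Round.first)
    assert t.values.shape == (8, 3, 10, 10)
    assert t.values.shape[0] * t.values.shape[1] == 24
    for ki in range(8):  # identical planes for a gray image
        assert np.array_equal(t.values[ki, 0], t.values[ki, 1])
        assert np.array_equal(t.values[ki, 0], t.values[ki, 2])
    constant = np.full((8, 8, 3), 55, dtype=np.uint8)
    assert (variation_tensor(constant, bank, Round.second).values == 0).all()


def test_min_variation_tie_break_prefers_first_kernel_and_red(bank):
    constant = np.full((6, 6, 3), 200, dtype=np.uint8)  # all 24 entries equal 0
    mv = min_variation(variation_tensor(constant, bank, Round.first))
    assert (mv.M == 0).all()
    assert (mv.argmin_kernel == 0).all()
    assert (mv.argmin_channel == 0).all()
    assert mv.kernel_ids[0] == "K1"


def test_min_variation_matches_exhaustive_scan(bank, rng):
    image = random_rgb(rng, 6, 6)
    t = variation_tensor(image, bank, Round.first)
    mv = min_variation(t)
    for i in range(6):
        for j in range(6):
            entries = [(t.values[ki, ch, i, j], ki, ch) for ki in range(8) for ch in range(3)]
            best = min(entries)
            assert mv.M[i, j] == best[0]
            assert (mv.argmin_kernel[i, j], mv.argmin_channel[i, j]) == (best[1], best[2])


def test_constant_image_produces_no_detections(bank):
    constant = np.full((12, 12, 3), 128, dtype=np.uint8)
    mask = detect(constant, min_variation(variation_tensor(constant, bank, Round.first)), 75)
    assert not mask.flagged.any()


def test_isolated_extreme_impulse_is_flagged(bank):
    image = np.full((12, 12, 3), 128, dtype=np.uint8)
    image[6, 6] = 255
    mask = detect(image, min_variation(variation_tensor(image, bank, Round.first)), 75)
    assert mask.flagged[6, 6]
    assert mask.flagged.sum() == 1


def test_non_extreme_outlier_is_never_flagged(bank):
    """A 200-valued spike on black violates the 0/255 rule even though its
    minimum variation clears the threshold."""
    image = np.zeros((12, 12, 3), dtype=np.uint8)
    image[6, 6] = 200
    mv = min_variation(variation_tensor(image, bank, Round.first))
    assert mv.M[6, 6] > 75
    assert not detect(image, mv, 75).flagged.any()


@pytest.mark.parametrize("round_", [Round.first, Round.second])
@pytest.mark.parametrize("seed", [11, 12, 13])
def test_full_chain_matches_naive_reference(bank, round_, seed):
    """detect(min_variation(variation_tensor(.))) agrees exactly with the
    single independently written per-pixel reference."""
    rng = np.random.default_rng(seed)
    image = random_rgb(rng, 10, 9)
    # sprinkle some genuine extremes so the 0/255 branch is exercised
    image[rng.random((10, 9)) < 0.1] = 0
    image[rng.random((10, 9)) < 0.1] = 255
    mv = min_variation(variation_tensor(image, bank, round_))
    mask = detect(image, mv, 75)
    ref_flagged, ref_min, ref_arg = naive_detect(image, bank.round_kernels(round_), 75)
    assert np.array_equal(mv.M, ref_min)
    assert np.array_equal(mv.argmin_kernel, ref_arg[:, :, 0])
    assert np.array_equal(mv.argmin_channel, ref_arg[:, :, 1])
    assert np.array_equal(mask.flagged, ref_flagged)


def test_detections_rotate_with_the_image(bank, rng):
    """90-degree rotation permutes detections identically (bank closure)."""
    image = make_phantom("blocks", 24, 24, seed=8)
    spots = [(5, 7), (12, 3), (20, 18)]
    for r, c in spots:
        image[r, c] = 255
    mask = detect(image, min_variation(variation_tensor(image, bank, Round.first)), 75)
    rotated = np.ascontiguousarray(np.rot90(image))
    mask_rot = detect(rotated, min_variation(variation_tensor(rotated, bank, Round.first)), 75)
    assert np.array_equal(np.rot90(mask.flagged), mask_rot.flagged)


def test_smooth_ramp_is_invisible_to_the_detector(bank):
    """All kernels are point-symmetric and zero-sum, so affine ramps give
    exactly zero response in the interior: no false detections."""
    ramp = make_phantom("gradient", 32, 32, seed=0)
    mv = min_variation(variation_tensor(ramp, bank, Round.first))
    assert not detect(ramp, mv, 75).flagged.any()


def test_bad_border_policy_rejected(bank):
    with pytest.raises(ValueError, match="border"):
        convolve_abs(np.zeros((5, 5), dtype=np.uint8), bank["K1"], border="wrap")


def test_negative_threshold_rejected(bank):
    constant = np.full((8, 8, 3), 9, dtype=np.uint8)
    mv = min_variation(variation_tensor(constant, bank, Round.first))
    with pytest.raises(ValueError, match="threshold"):
        detect(constant, mv, -1)
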