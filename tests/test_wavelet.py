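"""À-trous decomposition: reconstruction, oracle equivalence, masking accuracy."""

import numpy as np
import pytest
from scipy import ndimage

from punctacoloc import (
    CellImage,
    KineticProgram,
    MaskParams,
    SceneConfig,
    atrous_decompose,
    compartment_mask,
    make_scene,
    mask_timelapse,
    render_frame,
    threshold_planes,
)
from punctacoloc.wavelet import B3_KERNEL, dilated_kernel


def dense_atrous_oracle(image, n_scales, mode="mirror"):
    """Brute-force reference: full 2-D convolution with the spaced kernel."""
    nd_mode = {"mirror": "mirror", "periodic": "wrap"}[mode]
    planes, current = [], np.asarray(image, dtype=np.float64)
    for j in range(1, n_scales + 1):
        k1 = dilated_kernel(j)
        smooth = ndimage.convolve(current, np.outer(k1, k1), mode=nd_mode)
        planes.append(current - smooth)
        current = smooth
    return planes, current


@pytest.mark.parametrize("n_scales", [1, 2, 3, 4, 5])
def test_exact_reconstruction(n_scales, rng):
    image = rng.gamma(2.0, 30.0, size=(96, 96))
    dec = atrous_decompose(image, n_scales)
    assert len(dec.planes) == n_scales
    err = np.abs(dec.reconstruct() - image).max() / np.abs(image).max()
    assert err < 1e-6


def test_constant_image_has_zero_detail():
    dec = atrous_decompose(np.full((40, 40), 3.5), 3)
    for plane in dec.planes:
        np.testing.assert_allclose(plane, 0.0, atol=1e-12)
    np.testing.assert_allclose(dec.residual, 3.5, atol=1e-12)


@pytest.mark.parametrize("mode", ["mirror", "periodic"])
def test_separable_matches_dense_convolution_oracle(mode, rng):
    image = rng.normal(100.0, 15.0, size=(64, 64))
    dec = atrous_decompose(image, 3, mode=mode)
    planes, residual = dense_atrous_oracle(image, 3, mode=mode)
    for ours, ref in zip(dec.planes, planes):
        np.testing.assert_allclose(ours, ref, rtol=1e-9, atol=1e-9)
    np.testing.assert_allclose(dec.residual, residual, rtol=1e-9, atol=1e-9)


def test_impulse_detail_centers_match_kernel_arithmetic():
    image = np.zeros((65, 65))
    image[32, 32] = 1.0
    dec = atrous_decompose(image, 2)
    # first smooth leaves (3/8)^2 at the center, so W_1 center = 1 - (3/8)^2
    assert dec.planes[0][32, 32] == pytest.approx(1.0 - (3.0 / 8.0) ** 2, abs=1e-12)
    planes, _ = dense_atrous_oracle(image, 2)
    assert dec.planes[1][32, 32] == pytest.approx(planes[1][32, 32], abs=1e-12)


def test_periodic_decomposition_is_shift_equivariant(rng):
    image = rng.random((48, 48))
    shift = (13, -7)
    dec = atrous_decompose(image, 3, mode="periodic")
    dec_shifted = atrous_decompose(np.roll(image, shift, axis=(0, 1)), 3,
                                   mode="periodic")
    for ours, shifted in zip(dec.planes, dec_shifted.planes):
        np.testing.assert_allclose(
            np.roll(ours, shift, axis=(0, 1)), shifted, atol=1e-12
        )


def test_kernel_span_exceeding_image_raises():
    with pytest.raises(ValueError):
        atrous_decompose(np.zeros((16, 16)), 3)  # span 17 > 16
    atrous_decompose(np.zeros((17, 17)), 3)  # boundary case is fine


def test_b3_kernel_taps_and_dilation():
    np.testing.assert_allclose(B3_KERNEL.sum(), 1.0)
    k2 = dilated_kernel(2)
    assert len(k2) == 9
    np.testing.assert_allclose(k2[::2], B3_KERNEL)
    assert np.all(k2[1::2] == 0.0)


def test_threshold_limits(rng):
    image = rng.normal(0, 1, (64, 64))
    dec = atrous_decompose(image, 3)
    hard = threshold_planes(dec, k=1e9, scales=(2, 3))
    assert all(np.all(p == 0.0) for p in hard)
    soft = threshold_planes(dec, k=1e-9, scales=(2, 3))
    for p, orig in zip(soft, dec.planes[1:]):
        np.testing.assert_array_equal(p, orig)
    with pytest.raises(ValueError):
        threshold_planes(dec, k=3.0, scales=(4,))
    with pytest.raises(ValueError):
        threshold_planes(dec, k=-1.0, scales=(2,))


def test_all_zero_plane_passes_through():
    dec = atrous_decompose(np.full((32, 32), 2.0), 2)
    out = threshold_planes(dec, k=3.0, scales=(1, 2))
    for p in out:
        np.testing.assert_array_equal(p, 0.0)


@pytest.mark.parametrize("seed", range(20))
def test_noise_survival_fraction_below_1pct(seed):
    noise = np.random.default_rng(seed).normal(0.0, 5.0, (128, 128))
    dec = atrous_decompose(noise, 3)
    surviving = threshold_planes(dec, k=3.0, scales=(2, 3))
    for p in surviving:
        assert np.mean(p != 0.0) <= 0.01


def test_blank_image_gives_empty_mask():
    mask = compartment_mask(np.full((64, 64), 10.0))
    assert not mask.mask.any()
    assert mask.params.k == 3.0


def test_all_spots_recalled_at_snr_10(snr_scene, object_metrics):
    scene, marker = snr_scene(10.0, seed=0)
    cm = compartment_mask(marker, roi=scene.cell_mask)
    _, recall, _ = object_metrics(scene, cm.mask)
    assert recall == 1.0
    assert not (cm.mask & ~scene.cell_mask).any()  # mask stays inside the ROI


@pytest.mark.parametrize("seed", range(3))
def test_object_f1_at_snr_5(snr_scene, object_metrics, seed):
    scene, marker = snr_scene(5.0, seed=seed)
    cm = compartment_mask(marker, roi=scene.cell_mask)
    _, _, f1 = object_metrics(scene, cm.mask)
    assert f1 >= 0.9


def test_mask_regeneration_is_bitwise_identical(snr_scene):
    scene, marker = snr_scene(5.0, seed=1)
    m1 = compartment_mask(marker, roi=scene.cell_mask)
    m2 = compartment_mask(marker, roi=scene.cell_mask)
    assert np.array_equal(m1.mask, m2.mask)


def test_object_count_is_non_increasing_in_k(snr_scene):
    from skimage.measure import label

    scene, marker = snr_scene(5.0, seed=2)
    counts = []
    for k in (1.5, 2.0, 3.0, 4.0, 6.0, 10.0):
        cm = compartment_mask(marker, MaskParams(k=k), roi=scene.cell_mask)
        counts.append(label(cm.mask).max())
    assert all(b <= a for a, b in zip(counts, counts[1:]))


def test_timelapse_masks_identical_for_static_noiseless_marker():
    cfg = SceneConfig(
        n_spots=10, n_frames=3, poisson=False, read_noise=0.0, seed=5
    )
    scene = make_scene(cfg)
    stack = CellImage(
        data=np.stack([render_frame(scene, t) for t in range(3)]),
        channels=("probe", "marker"),
        roi=scene.cell_mask,
    )
    masks = mask_timelapse(stack, "marker")
    assert masks[0].frame_index == 0 and masks[2].frame_index == 2
    for m in masks[1:]:
        np.testing.assert_array_equal(m.mask, masks[0].mask)


def test_growing_spots_give_non_decreasing_mask_area():
    kin = (
        KineticProgram("linear_drift", before=1.0, drift=3.0),
        KineticProgram(),
    )
    cfg = SceneConfig(
        n_spots=10, n_frames=5, kinetics=kin, poisson=False, read_noise=0.0,
        amplitude=800.0, seed=6,
    )
    scene = make_scene(cfg)
    stack = CellImage(
        data=np.stack([render_frame(scene, t) for t in range(5)]),
        channels=("marker", "other"),
        roi=scene.cell_mask,
    )
    areas = [m.n_pixels for m in mask_timelapse(stack, "marker")]
    assert all(b >= a for a, b in zip(areas, areas[1:]))


def test_masks_are_stable_frame_to_frame_under_noise():
    cfg = SceneConfig(n_spots=20, n_frames=4, seed=7, min_separation=8.0)
    scene = make_scene(cfg)
    stack = CellImage(
        data=np.stack([render_frame(scene, t) for t in range(4)]),
        channels=("probe", "marker"),
        roi=scene.cell_mask,
    )
    masks = [m.mask for m in mask_timelapse(stack, "marker")]
    for a, b in zip(masks, masks[1:]):
        jaccard = (a & b).sum() / (a | b).sum()
        assert jaccard >= 0.7
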