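"""Whole-cell-normalized compartment intensity and cohort aggregation."""

import logging

import numpy as np
import pandas as pd
import pytest

from punctacoloc import (
    CompartmentMask,
    MaskParams,
    aggregate_cohort,
    compartment_mean,
    dissociation_config,
    expected_frame,
    make_scene,
    normalized_intensity_image,
    percent_change,
    persistence_config,
    render_timelapse,
    select_representative,
    timecourse,
)


def test_normalized_intensity_hand_example():
    raw = np.array([[2.0, 4.0, 9.0]])  # mean 5
    roi = np.ones_like(raw, bool)
    np.testing.assert_allclose(
        normalized_intensity_image(raw, roi), [[0.4, 0.8, 1.8]]
    )


def test_roi_mean_of_normalized_image_is_exactly_one(rng):
    raw = rng.gamma(2.0, 40.0, (50, 50))
    roi = np.zeros((50, 50), bool)
    roi[10:40, 5:45] = True
    norm = normalized_intensity_image(raw, roi)
    assert norm[roi].mean() == pytest.approx(1.0, abs=1e-12)
    assert np.all(norm[~roi] == 0.0)


def test_uniform_image_normalizes_to_one():
    norm = normalized_intensity_image(np.full((8, 8), 9.0), np.ones((8, 8), bool))
    np.testing.assert_allclose(norm, 1.0)


def test_normalization_errors():
    with pytest.raises(ValueError):
        normalized_intensity_image(np.ones((3, 3)), np.zeros((3, 3), bool))
    with pytest.raises(ValueError):
        normalized_intensity_image(np.zeros((3, 3)), np.ones((3, 3), bool))


def test_scale_invariance_of_compartment_mean(rng):
    raw = rng.gamma(2.0, 40.0, (40, 40))
    roi = np.ones((40, 40), bool)
    mask = rng.random((40, 40)) > 0.8
    base = compartment_mean(normalized_intensity_image(raw, roi), mask)
    scaled = compartment_mean(normalized_intensity_image(37.0 * raw, roi), mask)
    assert scaled == pytest.approx(base, rel=1e-9)


def test_compartment_mean_of_uniform_probe_is_one():
    roi = np.ones((10, 10), bool)
    norm = normalized_intensity_image(np.full((10, 10), 4.0), roi)
    mask = np.zeros((10, 10), bool)
    mask[3:5, 3:5] = True
    assert compartment_mean(norm, mask) == pytest.approx(1.0)


def test_mask_from_bright_spots_reports_enrichment(rng):
    raw = np.full((32, 32), 10.0)
    raw[10:13, 10:13] = 100.0
    roi = np.ones((32, 32), bool)
    mask = raw > 50
    value = compartment_mean(normalized_intensity_image(raw, roi), mask)
    assert value > 1.0


def test_empty_mask_reports_nan_with_warning(caplog):
    roi = np.ones((8, 8), bool)
    norm = normalized_intensity_image(np.full((8, 8), 2.0), roi)
    with caplog.at_level(logging.WARNING, logger="punctacoloc.intensity"):
        value = compartment_mean(norm, np.zeros((8, 8), bool))
    assert np.isnan(value)
    assert "empty compartment mask" in caplog.text


def test_compartment_mean_matches_ground_truth_expectation():
    cfg = dissociation_config(
        event_frame=2, n_frames=4, seed=3, poisson=False, read_noise=0.0,
        gain=1.0, offset=0.0,
    )
    scene = make_scene(cfg)
    stack, _ = render_timelapse(scene)
    table = timecourse(stack, ["probe"], "marker", cell_id="c")
    # oracle: same masks applied to the analytic expectation images
    from punctacoloc import compartment_mask

    for t in range(4):
        truth_probe = expected_frame(scene, t)[0]
        truth_marker = expected_frame(scene, t)[1]
        cm = compartment_mask(truth_marker, roi=scene.cell_mask)
        expected = compartment_mean(
            normalized_intensity_image(truth_probe, scene.cell_mask),
            cm.mask & scene.cell_mask,
        )
        got = table.loc[table.frame == t, "normalized_intensity"].iloc[0]
        assert got == pytest.approx(expected, rel=0.02)


def test_dissociation_scenario_reports_large_drop():
    cfg = dissociation_config(event_frame=4, n_frames=16, seed=1)
    stack, _ = render_timelapse(make_scene(cfg))
    table = timecourse(stack, ["probe"], "marker", cell_id="c")
    assert (table["n_mask_pixels"] > 0).all()
    change = percent_change(table, event_frame=4)["percent_change"].iloc[0]
    assert change <= -50.0


def test_persistence_scenario_reports_small_positive_change():
    cfg = persistence_config(n_frames=16, seed=1)
    stack, _ = render_timelapse(make_scene(cfg))
    table = timecourse(stack, ["probe"], "marker", cell_id="c")
    change = percent_change(table, event_frame=4)["percent_change"].iloc[0]
    assert abs(change) <= 10.0
    assert change > 0.0


@pytest.mark.parametrize("seed", range(5))
def test_drop_recovery_matches_noiseless_truth_within_10_points(seed):
    noisy_cfg = dissociation_config(event_frame=4, n_frames=14, seed=seed)
    clean_cfg = dissociation_config(
        event_frame=4, n_frames=14, seed=seed, poisson=False, read_noise=0.0
    )
    drops = []
    for cfg in (noisy_cfg, clean_cfg):
        stack, _ = render_timelapse(make_scene(cfg))
        table = timecourse(stack, ["probe"], "marker", cell_id="c")
        drops.append(percent_change(table, event_frame=4)["percent_change"].iloc[0])
    assert drops[0] == pytest.approx(drops[1], abs=10.0)


def test_single_frame_stack_degenerates_gracefully():
    cfg = dissociation_config(n_frames=1, event_frame=0, seed=2)
    stack, _ = render_timelapse(make_scene(cfg))
    table = timecourse(stack, ["probe"], "marker", cell_id="solo")
    assert len(table) == 1
    agg = aggregate_cohort(table)
    assert len(agg) == 1 and agg["n_cells"].iloc[0] == 1


def test_unknown_channel_is_rejected_before_compute():
    cfg = dissociation_config(n_frames=1, event_frame=0, seed=2)
    stack, _ = render_timelapse(make_scene(cfg))
    with pytest.raises(KeyError):
        timecourse(stack, ["gfp"], "marker")
    with pytest.raises(KeyError):
        timecourse(stack, ["probe"], "rab5")


def test_aggregate_cohort_handles_missing_values():
    table = pd.DataFrame(
        {
            "cell_id": ["a", "b", "c", "a", "b", "c"],
            "frame": [0, 0, 0, 1, 1, 1],
            "time": [0.0, 0.0, 0.0, 2.0, 2.0, 2.0],
            "probe_channel": ["p"] * 6,
            "compartment": ["m"] * 6,
            "normalized_intensity": [2.0, 4.0, np.nan, 1.0, 3.0, 5.0],
            "n_mask_pixels": [5, 5, 0, 5, 5, 5],
        }
    )
    agg = aggregate_cohort(table).set_index("frame")
    assert agg.loc[0, "n_cells"] == 2
    assert agg.loc[0, "mean"] == pytest.approx(3.0)
    assert agg.loc[0, "sem"] == pytest.approx(np.std([2, 4], ddof=1) / np.sqrt(2))
    assert agg.loc[1, "n_cells"] == 3


def test_select_representative_examples():
    assert select_representative([("A", 1.0), ("B", 2.0), ("C", 3.0)]) == "B"
    # median 2.5: B and C tie at distance 0.5 -> smallest id wins
    assert (
        select_representative([("A", 1.0), ("B", 2.0), ("C", 3.0), ("D", 10.0)])
        == "B"
    )
    with pytest.raises(ValueError):
        select_representative([])


@pytest.mark.parametrize("seed", range(5))
def test_representative_score_lies_in_interquartile_range(seed):
    rng = np.random.default_rng(seed)
    cells = [(f"c{i:02d}", float(v)) for i, v in enumerate(rng.normal(size=21))]
    chosen = select_representative(cells)
    scores = dict(cells)
    p25, p75 = np.percentile([v for _, v in cells], [25, 75])
    assert p25 <= scores[chosen] <= p75
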