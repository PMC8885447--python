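"""Simulator contracts: determinism, truth bookkeeping, rendering physics."""

import numpy as np
import pandas as pd
import pytest

from inclusionprofiler.simgen import (ComboTruthSpec, HillCurve, PlacementError,
                                      SceneSpec, generate_checkerboard,
                                      generate_field, generate_plate,
                                      generate_timeseries)

# a cheap scene for tests that need many renders
FAST = dict(image_shape=(300, 300), n_cells=20, cell_diameter_px=(20.0, 1.5),
            cell_diameter_range=(18.0, 24.0), nucleus_diameter_px=(9.0, 1.0),
            puncta_per_cell=(1, 1))


def test_empty_scene_is_noise_only():
    dapi, gfp, truth = generate_field(SceneSpec(n_cells=0, seed=3))
    assert truth.n_cells == 0
    assert truth.cell_masks.max() == 0
    # only background + noise: nothing near the diffuse cell intensity scale
    assert gfp.pixels.max() < 500


def test_identical_seed_is_bit_identical():
    a = generate_field(SceneSpec(seed=7))
    b = generate_field(SceneSpec(seed=7))
    np.testing.assert_array_equal(a[0].pixels, b[0].pixels)
    np.testing.assert_array_equal(a[1].pixels, b[1].pixels)
    pd.testing.assert_frame_equal(a[2].cells, b[2].cells)


def test_different_seeds_differ():
    a = generate_field(SceneSpec(seed=1, **FAST))
    b = generate_field(SceneSpec(seed=2, **FAST))
    assert not np.array_equal(a[1].pixels, b[1].pixels)


def test_inclusion_labels_follow_binomial_sampling():
    """Across seeds, the fraction of inclusion-labeled cells matches the
    requested prevalence (k ~ Binomial(n, p))."""
    p = 0.2
    fracs = []
    for seed in range(200):
        spec = SceneSpec(seed=seed, inclusion_prevalence=p, noise=(0.0, 0.0),
                         bias_field=(0.0, 1.0), **FAST)
        _d, _g, truth = generate_field(spec)
        fracs.append((truth.cells["label"] == "inclusion").mean())
    assert np.mean(fracs) == pytest.approx(p, abs=0.02)


def test_masks_are_disjoint_and_counts_conserved(field_set):
    for _d, _g, truth in field_set:
        labels, counts = np.unique(truth.cell_masks, return_counts=True)
        assert set(labels) - {0} == set(truth.cells["cell_id"])
        assert truth.cells["label"].isin(["inclusion", "no_inclusion"]).all()
        assert len(truth.cells) == truth.spec.n_cells
        # nucleus masks sit inside their cell masks
        inside = truth.cell_masks[truth.nucleus_masks > 0]
        assert np.all(inside == truth.nucleus_masks[truth.nucleus_masks > 0])


def test_puncta_contrast_is_exact_without_noise_or_bias():
    """With noise off and a flat field, the rendered punctum peak over the
    diffuse level equals the requested contrast ratio within 1%."""
    spec = SceneSpec(seed=5, n_cells=1, inclusion_prevalence=1.0,
                     puncta_per_cell=(1, 1), noise=(0.0, 0.0),
                     bias_field=(0.0, 1.0), background_offset=0.0)
    _d, gfp, truth = generate_field(spec)
    diffuse = truth.cells["diffuse_intensity"].iloc[0]
    ratio = gfp.pixels.max() / diffuse
    assert ratio == pytest.approx(spec.puncta_contrast, rel=0.01)


def test_saturation_respects_bit_depth():
    spec = SceneSpec(seed=1, diffuse_intensity=(12.0, 0.2), **FAST)  # e^12 >> 65535
    _d, gfp, _t = generate_field(spec)
    assert gfp.pixels.max() == 65535


def test_placement_failure_names_density():
    spec = SceneSpec(image_shape=(120, 120), n_cells=40)
    with pytest.raises(PlacementError, match="n_cells|diameter"):
        generate_field(spec)


def test_spec_validation():
    with pytest.raises(ValueError):
        SceneSpec(inclusion_prevalence=1.5)
    with pytest.raises(ValueError):
        SceneSpec(puncta_contrast=0.5)
    with pytest.raises(ValueError):
        SceneSpec(n_cells=-1)


def test_plate_tile_scan_counts(tmp_path):
    """A 5x5 tile scan of one well yields 25 GFP fields."""
    layout = pd.DataFrame({"well": ["C7"]})
    spec = SceneSpec(image_shape=(128, 128), n_cells=0)
    generate_plate(layout, tmp_path, base_spec=spec, fields_per_well=25, seed=0)
    gfp = list(tmp_path.glob("*_GFP_*.tif"))
    assert len(gfp) == 25


def test_plate_collision_raises(tmp_path):
    layout = pd.DataFrame({"well": ["A1"]})
    spec = SceneSpec(image_shape=(128, 128), n_cells=0)
    generate_plate(layout, tmp_path, base_spec=spec, fields_per_well=1, seed=0)
    with pytest.raises(FileExistsError):
        generate_plate(layout, tmp_path, base_spec=spec, fields_per_well=1, seed=0)


# ---- checkerboard ----------------------------------------------------------


def test_checkerboard_hsa_additive_construction():
    """With zero synergy offset and zero noise the observed effect equals the
    highest single agent effect exactly."""
    spec = ComboTruthSpec(synergy_offset=0.0, noise_sd=0.0, replicates=1)
    board, truth = generate_checkerboard(spec)
    ea, eb = truth["mono_a"], truth["mono_b"]
    np.testing.assert_allclose(truth["effect"], np.maximum.outer(ea, eb))
    np.testing.assert_allclose(board.response,
                               spec.baseline_pct * (100 - truth["effect"]) / 100)


def test_checkerboard_control_only():
    spec = ComboTruthSpec(doses_a=(0.0,), doses_b=(0.0,), noise_sd=0.0)
    board, truth = generate_checkerboard(spec)
    assert board.response.shape == (1, 1)
    assert truth["effect"][0, 0] == 0.0
    assert board.response[0, 0] == spec.baseline_pct


def test_checkerboard_offset_margins_validated():
    bad = np.zeros((6, 5))
    bad[0, 2] = 5.0
    with pytest.raises(ValueError, match="margins"):
        ComboTruthSpec(synergy_offset=bad).offset_matrix()


def test_hill_curve_zero_dose_effectless():
    h = HillCurve(emax=70, ec50=0.1, hill=1.5)
    assert h.effect(0.0) == 0.0
    assert h.effect(1e9) == pytest.approx(70, rel=1e-3)


# ---- live-cell series ------------------------------------------------------


def test_timeseries_zero_death_rate_constant_mean():
    _counts, truth = generate_timeseries({"vehicle": 0.0}, [0, 24, 48], n0=100, seed=1)
    assert truth["mean_count"].nunique() == 1


def test_timeseries_mutant_declines_monotonically():
    _c, truth = generate_timeseries({"wt": 0.005, "mutant": 0.03}, [0, 12, 24, 36, 48],
                                    n0=200, seed=1)
    wt = truth[truth["arm"] == "wt"].sort_values("time_h")["mean_count"].to_numpy()
    mut = truth[truth["arm"] == "mutant"].sort_values("time_h")["mean_count"].to_numpy()
    rel = (mut / mut[0]) / (wt / wt[0])
    assert np.all(np.diff(rel) < 0)


def test_timeseries_rejects_negative_times():
    with pytest.raises(ValueError):
        generate_timeseries({"a": 0.01}, [-1, 0, 24])
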