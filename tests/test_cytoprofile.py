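"""Per-cell feature families on constructed objects and simulated pools."""

import numpy as np
import pandas as pd
import pytest

from inclusionprofiler.cytoprofile import (apply_normalization, compute_profile,
                                           feature_columns, normalize_features)
from inclusionprofiler.plateio import FieldImage, ImageKey
from inclusionprofiler.segment import CellObject


def _cell_from_patch(patch, mask):
    h, w = mask.shape
    area = mask.sum()
    return CellObject(
        cell_id=1, key=ImageKey("A1", 1, "GFP", 1), bbox=(0, 0, h, w),
        mask=mask, equivalent_diameter_px=float(2 * np.sqrt(area / np.pi)),
        centroid=(w / 2, h / 2),
    ), FieldImage(ImageKey("A1", 1, "GFP", 1), patch)


def _disk(radius=12, size=30, value=100.0):
    yy, xx = np.mgrid[0:size, 0:size]
    c = (size - 1) / 2
    mask = (yy - c) ** 2 + (xx - c) ** 2 <= radius ** 2
    return np.where(mask, value, 0.0), mask


def test_constant_disk_is_featureless():
    """A homogeneous object has zero dispersion in every family."""
    patch, mask = _disk()
    cell, img = _cell_from_patch(patch, mask)
    f = compute_profile(cell, img).features
    assert f["int_sd"] == 0.0
    assert f["int_mean"] == f["int_max"] == 100.0
    assert f["tex_contrast_s3"] == 0.0
    assert f["tex_contrast_s8"] == 0.0
    assert sum(f[f"gran_{i:02d}"] for i in range(1, 17)) == pytest.approx(0.0, abs=1e-12)
    assert all(f[f"rad_cv_{b}"] == pytest.approx(0.0, abs=1e-9) for b in range(1, 5))
    assert sum(f[f"rad_frac_{b}"] for b in range(1, 5)) == pytest.approx(1.0, abs=1e-6)


def test_punctum_shifts_granularity_to_small_scales():
    """Adding one bright compact punctum concentrates removed intensity at
    small opening sizes, spikes the max/mean ratio and lands its radial mass
    in the central bin."""
    patch, mask = _disk()
    c = patch.shape[0] // 2
    patch[c - 1:c + 2, c - 1:c + 2] = 1000.0  # 3x3 punctum at the center
    cell, img = _cell_from_patch(patch, mask)
    f = compute_profile(cell, img).features
    gran = [f[f"gran_{i:02d}"] for i in range(1, 17)]
    assert sum(gran[:3]) > 0.9 * sum(gran)
    assert sum(gran) <= 1.0 + 1e-9
    assert f["int_max"] > 5 * f["int_mean"]
    # central punctum: area-normalized intensity fraction of the core bin rises
    assert f["rad_meanfrac_4"] > 1.5
    assert f["rad_meanfrac_4"] > f["rad_meanfrac_1"]


def test_radial_fraction_sums_to_one(balanced_pool):
    prof = balanced_pool["profiles"]
    sums = prof[[f"rad_frac_{b}" for b in range(1, 5)]].sum(axis=1)
    assert np.allclose(sums, 1.0, atol=1e-6)


def test_granularity_spectrum_is_a_fraction(balanced_pool):
    prof = balanced_pool["profiles"]
    gran = prof[[f"gran_{i:02d}" for i in range(1, 17)]]
    assert (gran.to_numpy() >= 0).all()
    assert (gran.sum(axis=1) <= 1.0 + 1e-9).all()


def test_rotation_changes_angle_averaged_texture_by_under_one_percent():
    rng = np.random.default_rng(0)
    patch, mask = _disk()
    patch = np.where(mask, patch + rng.gamma(2.0, 30.0, patch.shape), 0.0)
    cell, img = _cell_from_patch(patch, mask)
    f0 = compute_profile(cell, img).features
    cell_r, img_r = _cell_from_patch(np.rot90(patch).copy(), np.rot90(mask).copy())
    f90 = compute_profile(cell_r, img_r).features
    for name, v in f0.items():
        if name.startswith("tex_") and abs(v) > 1e-9:
            assert f90[name] == pytest.approx(v, rel=0.01), name


def test_profiles_are_deterministic():
    rng = np.random.default_rng(1)
    patch, mask = _disk()
    patch = np.where(mask, patch + rng.gamma(2.0, 30.0, patch.shape), 0.0)
    cell, img = _cell_from_patch(patch, mask)
    f1 = compute_profile(cell, img).features
    f2 = compute_profile(cell, img).features
    assert f1 == f2


def test_tiny_mask_rejected():
    mask = np.zeros((5, 5), dtype=bool)
    mask[2, 2] = True
    cell, img = _cell_from_patch(np.ones((5, 5)), mask)
    with pytest.raises(ValueError, match="too small"):
        compute_profile(cell, img)


# ---- normalization ---------------------------------------------------------


def test_normalization_yields_zero_mean_unit_sd(balanced_pool):
    norm = balanced_pool["normalized"]
    feats = feature_columns(norm)
    assert np.allclose(norm[feats].mean(), 0.0, atol=1e-9)
    assert np.allclose(norm[feats].std(ddof=0), 1.0, atol=1e-9)


def test_normalization_invariances(balanced_pool):
    prof = balanced_pool["profiles"].head(100)
    norm, _ = normalize_features(prof)
    # duplicating every profile leaves z-scores unchanged
    doubled = pd.concat([prof, prof], ignore_index=True)
    norm2, _ = normalize_features(doubled)
    feats = feature_columns(norm)
    np.testing.assert_allclose(norm2.loc[:99, feats].to_numpy(),
                               norm[feats].to_numpy(), atol=1e-9)
    # shifting all raw intensities is absorbed by the location term
    shifted = prof.copy()
    for c in prof.columns:
        if c.startswith("int_"):
            shifted[c] = shifted[c] + 100.0
    norm3, _ = normalize_features(shifted)
    np.testing.assert_allclose(norm3[feats].to_numpy(), norm[feats].to_numpy(),
                               atol=1e-6)


def test_single_cell_batch_rejected(balanced_pool):
    with pytest.raises(ValueError, match="need >= 2"):
        normalize_features(balanced_pool["profiles"].head(1))


def test_zero_variance_features_dropped_with_warning():
    df = pd.DataFrame({"well": ["A1"] * 4, "field": [1] * 4, "cell_id": range(4),
                       "f_live": [1.0, 2.0, 3.0, 4.0], "f_dead": [5.0] * 4})
    with pytest.warns(UserWarning, match="zero-variance"):
        norm, _stats = normalize_features(df)
    assert "f_dead" not in norm.columns
    assert "f_live" in norm.columns


def test_apply_normalization_matches_training_space(balanced_pool):
    prof = balanced_pool["profiles"]
    stats = balanced_pool["stats"]
    reapplied = apply_normalization(prof, stats)
    feats = feature_columns(balanced_pool["normalized"])
    np.testing.assert_allclose(reapplied[feats].to_numpy(),
                               balanced_pool["normalized"][feats].to_numpy(),
                               atol=1e-9)


def test_granularity_separates_phenotypes(balanced_pool):
    """Small-scale granularity alone separates inclusion from diffuse cells
    (AUC > 0.9), as required for classifier-free sanity."""
    from sklearn.metrics import roc_auc_score

    prof = balanced_pool["profiles"]
    labels = (balanced_pool["labels"] == "inclusion").astype(int)
    score = prof[["gran_01", "gran_02", "gran_03"]].sum(axis=1)
    assert roc_auc_score(labels, score) > 0.9
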