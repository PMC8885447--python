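"""Random-forest phenotype classification, review protocol, well summaries."""

import numpy as np
import pandas as pd
import pytest

from inclusionprofiler.inclusionclass import (INCLUSION, NO_INCLUSION,
                                              ClassifierModel, TrainingSet,
                                              corrected_prevalence,
                                              review_protocol, score_all,
                                              summarize_wells, train)


def _separable_profiles(n_per_class=30, seed=0):
    """Two classes split cleanly by a single feature."""
    rng = np.random.default_rng(seed)
    df = pd.DataFrame({
        "well": ["A1"] * (2 * n_per_class),
        "field": [1] * (2 * n_per_class),
        "cell_id": range(2 * n_per_class),
        "f_sep": np.concatenate([rng.normal(-3, 0.3, n_per_class),
                                 rng.normal(3, 0.3, n_per_class)]),
        "f_noise": rng.normal(0, 1, 2 * n_per_class),
    })
    labels = pd.Series([INCLUSION] * n_per_class + [NO_INCLUSION] * n_per_class)
    return df, labels


def test_separable_classes_reach_perfect_oob():
    df, labels = _separable_profiles()
    model = train(TrainingSet(df, labels), seed=0)
    assert model.oob_accuracy == 1.0


def test_single_class_training_rejected():
    df, labels = _separable_profiles()
    with pytest.raises(ValueError, match="2 classes"):
        TrainingSet(df, pd.Series([INCLUSION] * len(df)))


def test_too_few_cells_per_class_rejected():
    df, labels = _separable_profiles(n_per_class=4)
    with pytest.raises(ValueError, match=">= 5"):
        train(TrainingSet(df, labels))


def test_training_is_seed_deterministic():
    df, labels = _separable_profiles(seed=3)
    m1 = train(TrainingSet(df, labels), seed=42)
    m2 = train(TrainingSet(df, labels), seed=42)
    s1 = score_all(m1, df)
    s2 = score_all(m2, df)
    pd.testing.assert_series_equal(s1["p_inclusion"], s2["p_inclusion"])


def test_scoring_empty_profile_list_is_empty():
    df, labels = _separable_profiles()
    model = train(TrainingSet(df, labels), seed=0)
    out = score_all(model, df.head(0))
    assert len(out) == 0


def test_training_accuracy_at_least_oob():
    df, labels = _separable_profiles(seed=5)
    model = train(TrainingSet(df, labels), seed=0)
    scored = score_all(model, df)
    train_acc = (scored["predicted_label"].to_numpy() == labels.to_numpy()).mean()
    assert train_acc >= model.oob_accuracy


def test_probabilities_are_probabilities():
    df, labels = _separable_profiles()
    model = train(TrainingSet(df, labels), seed=0)
    p = score_all(model, df)["p_inclusion"]
    assert ((p >= 0) & (p <= 1)).all()


def test_probability_tie_resolves_to_no_inclusion():
    df, labels = _separable_profiles()
    model = train(TrainingSet(df, labels), seed=0)
    # force a tie by thresholding at the model's own probability
    scored = score_all(model, df)
    tied = scored["p_inclusion"] == model.threshold
    assert (scored.loc[tied, "predicted_label"] == NO_INCLUSION).all()
    # and strict exceedance is required for an inclusion call
    assert (scored.loc[scored["p_inclusion"] <= model.threshold,
                       "predicted_label"] == NO_INCLUSION).all()


def test_schema_mismatch_rejected():
    df, labels = _separable_profiles()
    model = train(TrainingSet(df, labels), seed=0)
    with pytest.raises(ValueError, match="missing fit-time features"):
        model.predict(df.drop(columns=["f_sep"]))


def test_model_roundtrips_through_file(tmp_path):
    df, labels = _separable_profiles()
    model = train(TrainingSet(df, labels), seed=0)
    path = tmp_path / "model.pkl"
    model.save(path)
    back = ClassifierModel.load(path)
    pd.testing.assert_frame_equal(score_all(back, df), score_all(model, df))


# ---- review protocol -------------------------------------------------------


def test_review_protocol_converges_immediately_when_separable():
    df, labels = _separable_profiles(n_per_class=300, seed=7)
    curve = review_protocol(df, labels, training_sizes=(10, 20, 30), batch=50,
                            seed=0)
    assert curve.attrs["converged"]
    assert curve.attrs["plateau_size"] == 10
    first = curve[curve["bin"] == INCLUSION].iloc[0]
    assert first["mean_accuracy"] == 1.0


def test_review_protocol_flags_adversarial_oracle():
    """Scoring against a flipped oracle collapses accuracy and the protocol
    reports non-convergence."""
    df, labels = _separable_profiles(n_per_class=300, seed=7)
    flipped = labels.map({INCLUSION: NO_INCLUSION, NO_INCLUSION: INCLUSION})
    curve = review_protocol(df, flipped, training_sizes=(10, 20), batch=50,
                            seed=0, training_oracle=labels)
    assert not curve.attrs["converged"]
    assert (curve[curve["bin"] == INCLUSION]["mean_accuracy"] < 0.1).all()


def test_review_protocol_scores_shortfall_batches():
    df, labels = _separable_profiles(n_per_class=30, seed=1)
    curve = review_protocol(df, labels, training_sizes=(10,), batch=1000, seed=0)
    n = curve[curve["bin"] == INCLUSION]["n_scored"].iloc[0]
    assert 0 < n < 1000


# ---- well summaries --------------------------------------------------------


def _scored_frame(wells, labels):
    return pd.DataFrame({"well": wells, "field": 1,
                         "cell_id": range(len(wells)),
                         "predicted_label": labels})


def test_summary_percentage_arithmetic():
    scored = _scored_frame(["A1"] * 30, [INCLUSION] * 3 + [NO_INCLUSION] * 27)
    summary = summarize_wells(scored)
    assert summary.table["pct_with_inclusions"].iloc[0] == 10.0
    assert summary.table["low_n"].iloc[0]  # 30 < default 50


def test_summary_all_negative_is_zero_pct():
    scored = _scored_frame(["B2"] * 60, [NO_INCLUSION] * 60)
    summary = summarize_wells(scored)
    assert summary.table["pct_with_inclusions"].iloc[0] == 0.0
    assert not summary.table["low_n"].iloc[0]


def test_summary_rejects_orphan_wells():
    scored = _scored_frame(["A1", "Z9"], [INCLUSION, NO_INCLUSION])
    layout = pd.DataFrame({"well": ["A1"]})
    with pytest.raises(ValueError, match="Z9"):
        summarize_wells(scored, layout)


def test_summary_carries_layout_metadata():
    scored = _scored_frame(["A1"] * 4, [INCLUSION, NO_INCLUSION, NO_INCLUSION,
                                        NO_INCLUSION])
    layout = pd.DataFrame({"well": ["A1"], "construct": ["A4V"],
                           "dose_a": [0.5], "dose_b": [10.0], "replicate": [2]})
    summary = summarize_wells(scored, layout)
    row = summary.table.iloc[0]
    assert row["construct"] == "A4V" and row["replicate"] == 2


def test_plate_pct_pools_all_cells():
    scored = _scored_frame(["A1"] * 50 + ["A2"] * 50,
                           [INCLUSION] * 10 + [NO_INCLUSION] * 90)
    assert summarize_wells(scored).plate_pct == 10.0


def test_corrected_prevalence_inverts_misclassification():
    """Rogan-Gladen correction recovers the true rate from the apparent one."""
    true_p = 0.277
    sens, spec = 0.95, 0.98
    apparent = true_p * sens + (1 - true_p) * (1 - spec)
    assert corrected_prevalence(apparent, sens, spec) == pytest.approx(true_p, abs=1e-12)
    with pytest.raises(ValueError):
        corrected_prevalence(0.5, 0.5, 0.5)
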