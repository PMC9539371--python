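"""Scorers, fusion weighting, conservative calibration, and the bundle."""

import numpy as np
import pandas as pd
import pytest

from swdspare import (
    FusionModel,
    ModelConfig,
    SwdClassifier,
    calibrate_threshold,
    fit_fusion,
    fuse_scores,
    train_scorer,
)
from swdspare.classification import FeatureCache


# --------------------------------------------------------------------------
# scorers


@pytest.mark.parametrize("kind", ["lda", "svm"])
def test_separable_classes_scored_without_training_error(kind, rng):
    X = np.concatenate([rng.normal(-3, 0.3, 50), rng.normal(3, 0.3, 50)])[:, None]
    y = np.repeat([0, 1], 50)
    scorer = train_scorer(X, y, kind)
    scores = scorer.score(X)
    assert np.all(scores[y == 0] < 0) and np.all(scores[y == 1] > 0)


def test_random_labels_score_at_chance(rng):
    X = rng.standard_normal((200, 4))
    y = np.tile([0, 1], 100)
    scorer = train_scorer(X[:100], y[:100], "lda")
    acc = np.mean((scorer.score(X[100:]) > 0).astype(int) == y[100:])
    assert 0.4 <= acc <= 0.6


def test_duplicated_feature_column_leaves_lda_scores_unchanged(rng):
    X = pd.DataFrame(rng.standard_normal((60, 4)), columns=list("abcd"))
    y = (rng.random(60) < 0.5).astype(int)
    X.loc[y == 1] += 0.8
    s1 = train_scorer(X, y, "lda").score(X)
    X2 = X.assign(dup=X["b"])
    s2 = train_scorer(X2, y, "lda").score(X2)
    assert np.allclose(s1, s2, atol=1e-9)


def test_zero_variance_feature_dropped_with_warning(rng):
    X = pd.DataFrame({"flat": np.ones(40), "ok": rng.standard_normal(40)})
    y = np.repeat([0, 1], 20)
    X.loc[y == 1, "ok"] += 3
    with pytest.warns(UserWarning, match="flat"):
        scorer = train_scorer(X, y, "lda")
    assert scorer.feature_names == ["ok"]


def test_single_class_training_rejected(rng):
    with pytest.raises(ValueError, match="both classes"):
        train_scorer(rng.standard_normal((10, 2)), np.zeros(10, dtype=int), "lda")


def test_feature_name_mismatch_at_predict_time(rng):
    X = pd.DataFrame(rng.standard_normal((40, 2)), columns=["a", "b"])
    y = np.repeat([0, 1], 20)
    scorer = train_scorer(X, y, "svm")
    with pytest.raises(ValueError, match="missing"):
        scorer.score(X.rename(columns={"b": "c"}))


# --------------------------------------------------------------------------
# fusion


def _fusion_model(alpha, mu=None, sigma=None, priors=(0.5, 0.5)):
    mu = mu or {"pre0": -1.0, "pre1": 1.0, "ict0": -1.0, "ict1": 1.0}
    sigma = sigma or {k: 1.0 for k in ("pre0", "pre1", "ict0", "ict1")}
    return FusionModel(alpha=alpha, mu=mu, sigma=sigma,
                       log_prior={0: np.log(priors[0]), 1: np.log(priors[1])})


def test_fusion_at_extreme_alpha_reduces_to_single_window_posterior(rng):
    s_pre = rng.standard_normal(50)
    s_ict = rng.standard_normal(50)
    fm1 = _fusion_model(alpha=1.0)
    fused = fuse_scores(fm1, s_pre, s_ict)
    pre_only = fuse_scores(_fusion_model(alpha=1.0), s_pre, np.zeros(50))
    assert np.allclose(fused, pre_only)  # ictal term weighted out entirely
    assert np.array_equal(np.argsort(fused), np.argsort(s_pre))
    fm0 = _fusion_model(alpha=0.0)
    assert np.array_equal(np.argsort(fuse_scores(fm0, s_pre, s_ict)),
                          np.argsort(s_ict))


def test_symmetric_model_fuses_to_zero_at_the_midpoint():
    fm = _fusion_model(alpha=0.37)
    assert fuse_scores(fm, 0.0, 0.0) == pytest.approx(0.0, abs=1e-12)


def test_uninformative_preictal_scores_push_alpha_to_ictal(rng):
    n = 60
    labels = np.repeat([0, 1], n // 2)
    pre = rng.standard_normal(n)  # pure noise
    ict = np.where(labels == 1, 2.0, -2.0) + 0.1 * rng.standard_normal(n)
    fm = fit_fusion(pre, ict, labels)
    assert fm.alpha <= 0.1


def test_identical_windows_tie_break_to_smallest_alpha(rng):
    labels = np.repeat([0, 1], 20)
    s = np.where(labels == 1, 1.0, -1.0) + 0.05 * rng.standard_normal(40)
    fm = fit_fusion(s, s, labels, alpha_grid=(0.0, 0.25, 0.5, 1.0))
    assert fm.alpha == 0.0


def test_three_point_grid_with_only_ictal_informative(rng):
    labels = np.repeat([0, 1], 25)
    pre = rng.standard_normal(50)
    ict = np.where(labels == 1, 3.0, -3.0) + 0.1 * rng.standard_normal(50)
    fm = fit_fusion(pre, ict, labels, alpha_grid=(0.0, 0.5, 1.0))
    assert fm.alpha == 0.0


def test_fit_fusion_validates_inputs(rng):
    labels = np.repeat([0, 1], 10)
    s = rng.standard_normal(20)
    with pytest.raises(ValueError, match="non-empty"):
        fit_fusion(s, s, labels, alpha_grid=())
    with pytest.raises(ValueError, match="both classes"):
        fit_fusion(s, s, np.zeros(20, dtype=int))


# --------------------------------------------------------------------------
# conservative threshold


def test_edge_rule_threshold_matches_brute_force():
    scores = np.array([-2.0, -1.0, 1.0, 2.0])
    labels = np.array([0, 0, 1, 1])
    cal = calibrate_threshold(scores, labels, margin=0.0, gap_fraction=0.0)
    assert cal.tau == pytest.approx(1.0)
    pred = cal.predict_spared(scores)
    assert pred.tolist() == [True, True, False, False]
    # brute force: any threshold above min impaired admits a false spared
    for tau in np.linspace(-3, 3, 601):
        fp = np.sum((scores < tau) & (labels == 1))
        tp = np.sum((scores < tau) & (labels == 0))
        if fp == 0:
            assert tp <= 2
        if tau > 1.0 + 1e-9:
            assert fp > 0


def test_gap_centered_threshold_still_recovers_separated_spared():
    scores = np.array([-2.0, -1.0, 1.0, 2.0])
    labels = np.array([0, 0, 1, 1])
    cal = calibrate_threshold(scores, labels)  # default gap_fraction 0.5
    assert cal.tau == pytest.approx(0.0)
    pred = cal.predict_spared(scores)
    assert pred.tolist() == [True, True, False, False]


def test_overlapping_classes_sacrifice_spared_but_never_false_spared(rng):
    labels = np.repeat([0, 1], 50)
    scores = np.where(labels == 1, 0.0, 0.5) + rng.standard_normal(100)
    cal = calibrate_threshold(scores, labels)
    pred = cal.predict_spared(scores)
    assert not np.any(pred & (labels == 1))


def test_sensitivity_decreases_monotonically_with_margin(rng):
    labels = np.repeat([0, 1], 50)
    scores = np.where(labels == 1, 3.0, -3.0) + rng.standard_normal(100)
    sens = []
    for margin in np.linspace(0, 8, 9):
        cal = calibrate_threshold(scores, labels, margin=margin, gap_fraction=0.0)
        pred = cal.predict_spared(scores)
        sens.append(np.sum(pred & (labels == 0)) / 50)
    assert all(a >= b for a, b in zip(sens, sens[1:]))


def test_threshold_requires_impaired_examples():
    with pytest.raises(ValueError, match="impaired"):
        calibrate_threshold(np.array([-1.0, -2.0]), np.array([0, 0]))


# --------------------------------------------------------------------------
# end-to-end bundle


def test_concatenation_doubles_scorer_input_dimension(small_cache):
    clf = SwdClassifier(ModelConfig("csp", "concatenation", "lda"),
                        n_csp_filters=5)
    clf.fit(small_cache)
    assert len(clf.scorers["concatenation"].feature_names) == 10


def test_every_strategy_has_zero_false_spared_on_calibration_data(small_cache):
    y = small_cache.labels
    for strategy in ("preictal", "ictal", "concatenation", "fusion"):
        clf = SwdClassifier(ModelConfig("csp", strategy, "lda")).fit(small_cache)
        pred = clf.predict(small_cache)
        assert not np.any((pred == 0) & (y == 1)), strategy


def test_fusion_with_alpha_one_matches_preictal_strategy(small_cache):
    pre = SwdClassifier(ModelConfig("csp", "preictal", "lda")).fit(small_cache)
    fused = SwdClassifier(ModelConfig("csp", "fusion", "lda"),
                          alpha_grid=(1.0,)).fit(small_cache)
    assert np.array_equal(pre.predict(small_cache), fused.predict(small_cache))


def test_unlabeled_events_can_be_predicted(small_cache):
    y = small_cache.labels
    labeled = np.arange(len(small_cache))[:30]
    rest = np.arange(len(small_cache))[30:]
    clf = SwdClassifier(ModelConfig("basic", "ictal", "lda"))
    clf.fit(small_cache, labeled, y[labeled])
    pred = clf.predict(small_cache, rest)
    assert set(np.unique(pred)) <= {0, 1}


def test_bundle_save_load_round_trip(tmp_path, small_cache):
    clf = SwdClassifier(ModelConfig("all", "fusion", "svm")).fit(small_cache)
    path = tmp_path / "bundle.npz"
    clf.save(path)
    back = SwdClassifier.load(path)
    assert back.config == clf.config
    assert np.array_equal(back.predict(small_cache), clf.predict(small_cache))
    assert np.allclose(back.decision_scores(small_cache),
                       clf.decision_scores(small_cache))


def test_unfitted_classifier_refuses_to_predict(small_cache):
    clf = SwdClassifier(ModelConfig("csp", "fusion", "lda"))
    with pytest.raises(ValueError, match="not fitted"):
        clf.predict(small_cache)
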