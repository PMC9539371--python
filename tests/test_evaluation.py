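"""Model grid, cross-validation integrity, and patient-level aggregation."""

import numpy as np
import pandas as pd
import pytest

from swdspare import (
    EvalReport,
    FeatureCache,
    ModelConfig,
    SynthConfig,
    WindowConfig,
    aggregate_patient,
    build_model_grid,
    cross_validate,
    external_validate,
    extract_window_pairs,
    generate_dataset,
    window_grid_search,
)


def test_model_grid_enumerates_32_unique_configs():
    grid = build_model_grid()
    assert len(grid) == 32
    assert len(set(grid)) == 32
    assert sum(cfg.classifier == "lda" for cfg in grid) == 16


def test_report_metrics_from_toy_confusion_counts():
    rep = EvalReport(tp=9, fp=0, fn=1, tn=5)
    assert rep.spared_ppv == pytest.approx(1.0)
    assert rep.spared_sensitivity == pytest.approx(0.9)
    assert rep.n == 15


def test_undefined_ratios_reported_as_nan():
    rep = EvalReport(tp=0, fp=0, fn=3, tn=7)  # no spared predictions
    assert np.isnan(rep.spared_ppv)
    all_impaired = EvalReport(tp=0, fp=2, fn=0, tn=8)  # no true spared
    assert np.isnan(all_impaired.spared_sensitivity)


def test_pooled_fold_counts_sum_to_dataset_size(small_cache):
    rep = cross_validate(small_cache, ModelConfig("csp", "ictal", "lda"),
                         k=5, seed=0)
    assert rep.n == len(small_cache)
    fold_total = sum(f["tp"] + f["fp"] + f["fn"] + f["tn"] for f in rep.per_fold)
    assert fold_total == rep.n


def test_separable_synthetic_classes_reach_perfect_ppv(small_cache):
    for config in (ModelConfig("csp", "fusion", "lda"),
                   ModelConfig("basic", "ictal", "svm")):
        rep = cross_validate(small_cache, config, k=5, seed=0)
        assert rep.spared_ppv == pytest.approx(1.0), config.tag()


def test_cross_validation_is_deterministic(small_cache):
    cfg = ModelConfig("extended", "concatenation", "lda")
    a = cross_validate(small_cache, cfg, k=5, seed=11)
    b = cross_validate(small_cache, cfg, k=5, seed=11)
    assert a.to_dict() == b.to_dict()


def test_group_by_patient_keeps_patients_out_of_their_training_folds(small_cache):
    rep = cross_validate(small_cache, ModelConfig("csp", "ictal", "lda"),
                         k=4, seed=1, group_by_patient=True)
    assert rep.n == len(small_cache)


def test_shuffled_labels_drive_ppv_toward_prevalence(small_cache):
    """Permutation null: spared PPV collapses to the spared base rate."""
    rng = np.random.default_rng(0)
    y = small_cache.labels
    prevalence = np.mean(y == 0)
    ppvs = []
    for _ in range(10):
        perm = rng.permutation(y)
        rep = _cv_with_labels(small_cache, perm, seed=int(rng.integers(2**31)))
        if not np.isnan(rep.spared_ppv):
            ppvs.append(rep.spared_ppv)
    assert abs(np.mean(ppvs) - prevalence) <= 0.15


def _cv_with_labels(cache, y, seed):
    from sklearn.model_selection import StratifiedKFold

    from swdspare.classification import SwdClassifier

    rep = EvalReport()
    cv = StratifiedKFold(n_splits=5, shuffle=True, random_state=seed % (2**31))
    for fold, (tr, te) in enumerate(cv.split(np.zeros((len(cache), 1)), y)):
        clf = SwdClassifier(ModelConfig("basic", "preictal", "lda"))
        clf.fit(cache, tr, y[tr])
        rep.add(clf.predict(cache, te), y[te], fold=fold)
    return rep


def test_cv_rejects_unlabeled_or_undersized_data(small_cache):
    with pytest.raises(ValueError, match="at least k"):
        cross_validate(small_cache, ModelConfig("csp", "ictal", "lda"), k=50)


def test_patient_aggregation_is_a_logical_or():
    df = pd.DataFrame({"patient_id": ["a", "a", "a", "b", "b", "c"],
                       "prediction": [0, 0, 0, 0, 1, 1]})
    out = aggregate_patient(df).set_index("patient_id")["prediction"]
    assert out["a"] == 0  # all spared -> spared
    assert out["b"] == 1  # any impaired -> impaired
    assert out["c"] == 1


def test_patient_aggregation_monotone_under_added_impaired(rng):
    for _ in range(20):
        n = int(rng.integers(1, 8))
        preds = rng.integers(0, 2, n)
        df = pd.DataFrame({"patient_id": ["p"] * n, "prediction": preds})
        before = aggregate_patient(df)["prediction"].iloc[0]
        df2 = pd.concat([df, pd.DataFrame({"patient_id": ["p"],
                                           "prediction": [1]})])
        after = aggregate_patient(df2)["prediction"].iloc[0]
        assert after >= before
    with pytest.raises(ValueError):
        aggregate_patient(pd.DataFrame(columns=["patient_id", "prediction"]))


def _pure_cohort(n_patients, n_spared, n_impaired, seed):
    cfg = SynthConfig(n_patients=n_patients, n_spared_swd=n_spared,
                      n_impaired_swd=n_impaired, patient_purity=1.0, seed=seed)
    recordings, events = generate_dataset(cfg)
    return extract_window_pairs(recordings, events, WindowConfig())


def test_external_validation_on_patient_pure_cohort(small_cache):
    test_pairs = _pure_cohort(n_patients=10, n_spared=14, n_impaired=10, seed=21)
    spared_patients = {wp.event.patient_id for wp in test_pairs
                       if wp.event.label == 0}
    patient_labels = {wp.event.patient_id: wp.event.label for wp in test_pairs}
    report, preds = external_validate(small_cache, FeatureCache(test_pairs),
                                      patient_labels,
                                      ModelConfig("csp", "fusion", "lda"))
    assert report.spared_ppv == pytest.approx(1.0)
    assert len(preds) == len(test_pairs)
    assert report.per_patient["patient_id"].nunique() == len(patient_labels)
    assert 0 < report.spared_sensitivity <= 1.0
    assert report.tp <= len(spared_patients)


def test_external_validation_without_spared_patients_reports_nan(small_cache):
    test_pairs = _pure_cohort(n_patients=4, n_spared=0, n_impaired=10, seed=22)
    patient_labels = {wp.event.patient_id: 1 for wp in test_pairs}
    report, _ = external_validate(small_cache, FeatureCache(test_pairs),
                                  patient_labels,
                                  ModelConfig("csp", "fusion", "lda"))
    assert np.isnan(report.spared_sensitivity)  # no truly spared patients
    assert report.fn == 0 and report.tp == 0


def test_window_grid_search_single_cell_returns_that_cell(small_cohort):
    _, recordings, events = small_cohort
    table, best = window_grid_search(recordings, events,
                                     ModelConfig("basic", "ictal", "lda"),
                                     pre_grid_ms=[1000.0], ict_grid_ms=[500.0],
                                     k=5)
    assert len(table) == 1
    assert (best.pre_ms, best.ict_ms) == (1000.0, 500.0)


def test_window_grid_search_table_covers_grid(small_cohort):
    _, recordings, events = small_cohort
    table, best = window_grid_search(recordings, events,
                                     ModelConfig("basic", "ictal", "lda"),
                                     pre_grid_ms=[500.0, 1000.0],
                                     ict_grid_ms=[250.0, 500.0], k=5)
    assert len(table) == 4
    assert {tuple(r) for r in table[["pre_ms", "ict_ms"]].to_numpy()} == {
        (500.0, 250.0), (500.0, 500.0), (1000.0, 250.0), (1000.0, 500.0)}
    assert best.pre_ms in (500.0, 1000.0)
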