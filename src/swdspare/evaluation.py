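"""Cross-validation, spared-oriented metrics, and patient-level validation.

All metrics treat **spared** as the positive class: spared predictive value
is TP/(TP+FP) — the fraction of spared calls that are truly spared — and
spared sensitivity is TP/(TP+FN). Undefined ratios (zero denominators) are
reported as NaN, never silently as 0 or 1.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold

from .classification import (
    CLASSIFIERS,
    FEATURE_SETS,
    WINDOW_STRATEGIES,
    FeatureCache,
    ModelConfig,
    SwdClassifier,
)
from .io import (
    LABEL_IMPAIRED,
    LABEL_SPARED,
    Recording,
    SwdEvent,
    WindowConfig,
    extract_window_pairs,
)
from .selection import SelectionConfig


@dataclass
class EvalReport:
    """Spared-positive confusion counts plus per-fold breakdowns."""

    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0
    per_fold: list[dict] = field(default_factory=list)
    per_patient: pd.DataFrame | None = None

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def spared_ppv(self) -> float:
        denom = self.tp + self.fp
        return self.tp / denom if denom > 0 else float("nan")

    @property
    def spared_sensitivity(self) -> float:
        denom = self.tp + self.fn
        return self.tp / denom if denom > 0 else float("nan")

    def add(self, pred: np.ndarray, truth: np.ndarray, fold: int | None = None) -> None:
        pred = np.asarray(pred)
        truth = np.asarray(truth)
        tp = int(np.sum((pred == LABEL_SPARED) & (truth == LABEL_SPARED)))
        fp = int(np.sum((pred == LABEL_SPARED) & (truth == LABEL_IMPAIRED)))
        fn = int(np.sum((pred == LABEL_IMPAIRED) & (truth == LABEL_SPARED)))
        tn = int(np.sum((pred == LABEL_IMPAIRED) & (truth == LABEL_IMPAIRED)))
        self.tp += tp
        self.fp += fp
        self.fn += fn
        self.tn += tn
        if fold is not None:
            self.per_fold.append({"fold": fold, "tp": tp, "fp": fp,
                                  "fn": fn, "tn": tn})

    def to_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "fn": self.fn, "tn": self.tn,
            "n": self.n,
            "spared_ppv": self.spared_ppv,
            "spared_sensitivity": self.spared_sensitivity,
            "per_fold": self.per_fold,
        }


def build_model_grid() -> list[ModelConfig]:
    """All 4 feature sets x 4 window strategies x 2 classifiers = 32 configs."""
    return [
        ModelConfig(feature_set=fs, window_strategy=ws, classifier=clf)
        for fs, ws, clf in itertools.product(FEATURE_SETS, WINDOW_STRATEGIES,
                                             CLASSIFIERS)
    ]


def cross_validate(
    cache: FeatureCache,
    config: ModelConfig,
    k: int = 10,
    seed: int = 0,
    selection: SelectionConfig = SelectionConfig(),
    n_csp_filters: int = 5,
    margin: float = 0.0,
    group_by_patient: bool = False,
) -> EvalReport:
    """Stratified k-fold CV at the discharge level, pooled across folds.

    Every supervised step — feature selection, CSP fitting, scorer training,
    fusion-weight search, threshold calibration — runs inside the training
    fold only. ``group_by_patient`` keeps each patient's discharges in a
    single fold (guards against patient-identity leakage; the default mirrors
    plain per-discharge stratification).
    """
    y = cache.labels
    if np.any(y < 0):
        raise ValueError("cross-validation requires fully labeled data")
    counts = [int((y == c).sum()) for c in (LABEL_SPARED, LABEL_IMPAIRED)]
    if min(counts) < k:
        raise ValueError(f"need at least k={k} discharges per class, have {counts}")

    fixed_masks = None
    if selection.scope == "global" and config.feature_set in ("basic", "extended", "all"):
        from .selection import select_features

        fixed_masks = {}
        for tag in ("preictal", "ictal"):
            base = cache.table("basic" if config.feature_set == "basic"
                               else "extended", tag)
            mask, _ = select_features(base, y, selection)
            if not mask.any():
                mask = mask.copy()
                mask[0] = True
            fixed_masks[tag] = mask

    X_dummy = np.zeros((len(cache), 1))
    if group_by_patient:
        cv = StratifiedGroupKFold(n_splits=k, shuffle=True, random_state=seed)
        splits = cv.split(X_dummy, y, groups=cache.patient_ids)
    else:
        cv = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        splits = cv.split(X_dummy, y)

    report = EvalReport()
    for fold, (tr, te) in enumerate(splits):
        if np.unique(y[tr]).size < 2:
            raise ValueError(f"fold {fold}: training split lost a class")
        clf = SwdClassifier(config, n_csp_filters=n_csp_filters,
                            selection=selection, margin=margin,
                            fixed_masks=fixed_masks)
        clf.fit(cache, tr, y[tr])
        report.add(clf.predict(cache, te), y[te], fold=fold)
    return report


def window_grid_search(
    recordings: list[Recording],
    events: list[SwdEvent],
    config: ModelConfig,
    pre_grid_ms: list[float],
    ict_grid_ms: list[float],
    k: int = 10,
    seed: int = 0,
    **cv_kwargs,
) -> tuple[pd.DataFrame, WindowConfig]:
    """Evaluate every (preictal, ictal) window-length pair by CV.

    Returns the full result table and the best pair, ranked by spared
    predictive value with spared sensitivity as tie-break. Cells whose CV
    fails are recorded with NaN metrics.
    """
    if not pre_grid_ms or not ict_grid_ms:
        raise ValueError("window grids must be non-empty")
    rows = []
    for pre_ms in pre_grid_ms:
        for ict_ms in ict_grid_ms:
            cfg = WindowConfig(pre_ms=pre_ms, ict_ms=ict_ms)
            row = {"pre_ms": pre_ms, "ict_ms": ict_ms,
                   "spared_ppv": float("nan"), "spared_sensitivity": float("nan")}
            try:
                pairs = extract_window_pairs(recordings, events, cfg)
                rep = cross_validate(FeatureCache(pairs), config, k=k, seed=seed,
                                     **cv_kwargs)
                row["spared_ppv"] = rep.spared_ppv
                row["spared_sensitivity"] = rep.spared_sensitivity
            except ValueError as exc:
                warnings.warn(f"window cell ({pre_ms}, {ict_ms}) failed: {exc}")
            rows.append(row)
    table = pd.DataFrame(rows)
    ranked = table.sort_values(["spared_ppv", "spared_sensitivity"],
                               ascending=False, na_position="last", kind="stable")
    best = ranked.iloc[0]
    return table, WindowConfig(pre_ms=float(best["pre_ms"]),
                               ict_ms=float(best["ict_ms"]))


def aggregate_patient(predictions: pd.DataFrame) -> pd.DataFrame:
    """Patient-level labels by the safety rule: any impaired SWD ⇒ impaired.

    ``predictions`` needs columns ``patient_id`` and ``prediction`` (0/1).
    A patient is spared only if every one of their discharges is predicted
    spared (logical OR over impaired predictions).
    """
    if predictions.empty:
        raise ValueError("no predictions to aggregate")
    if predictions["prediction"].isna().any():
        raise ValueError("predictions must be 0/1")
    grouped = predictions.groupby("patient_id")["prediction"].max()
    return grouped.rename("prediction").reset_index()


def external_validate(
    train_cache: FeatureCache,
    test_cache: FeatureCache,
    patient_labels: dict[str, int],
    config: ModelConfig,
    selection: SelectionConfig = SelectionConfig(),
    n_csp_filters: int = 5,
    margin: float = 0.0,
) -> tuple[EvalReport, pd.DataFrame]:
    """Train on labeled discharges, score an unseen cohort at patient level.

    Test discharges need no per-SWD labels; each test patient needs one
    spared/impaired label. Patients present in ``patient_labels`` but without
    any discharge are excluded with a warning.
    """
    clf = SwdClassifier(config, n_csp_filters=n_csp_filters,
                        selection=selection, margin=margin)
    clf.fit(train_cache)
    preds = pd.DataFrame({
        "patient_id": test_cache.patient_ids,
        "swd_id": test_cache.swd_ids,
        "prediction": clf.predict(test_cache),
    })
    per_patient = aggregate_patient(preds[["patient_id", "prediction"]])
    missing = [p for p in patient_labels if p not in set(per_patient["patient_id"])]
    if missing:
        warnings.warn(f"patients without discharges excluded: {missing}")
    per_patient = per_patient[per_patient["patient_id"].isin(patient_labels)]
    truth = per_patient["patient_id"].map(patient_labels).to_numpy()
    report = EvalReport()
    report.add(per_patient["prediction"].to_numpy(), truth)
    report.per_patient = per_patient.assign(truth=truth)
    return report, preds
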