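"""Scoring, weighted Bayesian score fusion, and conservative calibration.

Spared-vs-impaired classification is safety-asymmetric: a discharge (or a
patient) must never be called spared when it is impaired. Every trained
bundle therefore ends in a conservative threshold τ placed at the minimum
fused score of the impaired training examples (minus an optional margin), so
zero false-spared on the calibration data holds by construction.

Scores from the preictal and ictal windows are combined by weighted
probabilistic fusion: per class c the two scalar scores get class-conditional
Gaussian likelihoods, weighted geometrically by the preictal weight α,

    log L_c = α log N(s_pre; μ_pre,c, σ_pre,c)
            + (1-α) log N(s_ict; μ_ict,c, σ_ict,c) + log π_c,

and the fused impaired-score is log L_impaired - log L_spared. α is chosen
on a grid to maximize spared predictive value (then spared sensitivity, then
the smaller α) under an inner stratified cross-validation of the training
scores.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .csp import CspModel, csp_features, fit_csp
from .features import feature_table
from .io import LABEL_IMPAIRED, LABEL_SPARED, WindowPair
from .selection import SelectionConfig, select_features

FEATURE_SETS = ("basic", "extended", "csp", "all")
WINDOW_STRATEGIES = ("preictal", "ictal", "concatenation", "fusion")
CLASSIFIERS = ("lda", "svm")

DEFAULT_ALPHA_GRID = tuple(np.round(np.arange(0.0, 1.0001, 0.01), 2))


@dataclass(frozen=True)
class ModelConfig:
    feature_set: str = "csp"
    window_strategy: str = "fusion"
    classifier: str = "lda"

    def __post_init__(self) -> None:
        if self.feature_set not in FEATURE_SETS:
            raise ValueError(f"feature_set must be one of {FEATURE_SETS}")
        if self.window_strategy not in WINDOW_STRATEGIES:
            raise ValueError(f"window_strategy must be one of {WINDOW_STRATEGIES}")
        if self.classifier not in CLASSIFIERS:
            raise ValueError(f"classifier must be one of {CLASSIFIERS}")

    def tag(self) -> str:
        return f"{self.feature_set}-{self.window_strategy}-{self.classifier}"


# --------------------------------------------------------------------------
# scalar scorers


@dataclass
class Scorer:
    """Linear decision score w·z + b on z-scored features; larger = more impaired."""

    kind: str
    feature_names: list[str]
    mean: np.ndarray
    std: np.ndarray
    weights: np.ndarray
    bias: float

    def score(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            missing = [c for c in self.feature_names if c not in X.columns]
            if missing:
                raise ValueError(f"features missing at predict time: {missing}")
            X = X[self.feature_names].to_numpy(dtype=float)
        else:
            X = np.asarray(X, dtype=float)
            if X.shape[1] != len(self.feature_names):
                raise ValueError("feature count mismatch between train and predict")
        z = (X - self.mean) / self.std
        return z @ self.weights + self.bias


def train_scorer(X: pd.DataFrame | np.ndarray, y: np.ndarray, kind: str) -> Scorer:
    """Fit an LDA or linear-SVM scalar scorer on z-scored features.

    Zero-variance columns are dropped with a warning; exact collinearity is
    handled by LDA's SVD (pseudo-inverse) path. Scores are oriented so that
    larger means more impaired (label 1).
    """
    if kind not in CLASSIFIERS:
        raise ValueError(f"kind must be one of {CLASSIFIERS}")
    if isinstance(X, np.ndarray):
        X = pd.DataFrame(X, columns=[f"f{i}" for i in range(X.shape[1])])
    y = np.asarray(y, dtype=int)
    if np.unique(y).size != 2:
        raise ValueError("training labels must contain both classes")

    raw = X.to_numpy(dtype=float)
    std = raw.std(axis=0)
    keep = std > 0
    if not keep.all():
        dropped = [c for c, k in zip(X.columns, keep) if not k]
        warnings.warn(f"dropping zero-variance features: {dropped}")
    if not keep.any():
        raise ValueError("all features have zero variance")
    names = [c for c, k in zip(X.columns, keep) if k]
    raw = raw[:, keep]
    mean = raw.mean(axis=0)
    std = raw.std(axis=0)
    z = (raw - mean) / std

    if kind == "lda":
        model = LinearDiscriminantAnalysis(solver="svd").fit(z, y)
    else:
        model = SVC(kernel="linear", C=1.0).fit(z, y)
    w = np.asarray(model.coef_, dtype=float).ravel()
    b = float(np.asarray(model.intercept_).ravel()[0])
    # sklearn orients decision_function toward classes_[1]; flip if the
    # larger class label is not "impaired"
    if int(model.classes_[1]) != LABEL_IMPAIRED:
        w, b = -w, -b
    return Scorer(kind=kind, feature_names=names, mean=mean, std=std,
                  weights=w, bias=b)


# --------------------------------------------------------------------------
# weighted probabilistic fusion


@dataclass
class FusionModel:
    alpha: float
    mu: dict[str, float]  # keys like "pre0", "ict1"
    sigma: dict[str, float]
    log_prior: dict[int, float]

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError("alpha must lie in [0, 1]")
        if any(s <= 0 for s in self.sigma.values()):
            raise ValueError("score sigmas must be positive")


def _log_normal_pdf(x: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    return -0.5 * np.log(2 * np.pi * sigma**2) - (x - mu) ** 2 / (2 * sigma**2)


def _fit_gaussians(pre: np.ndarray, ict: np.ndarray,
                   labels: np.ndarray) -> tuple[dict, dict, dict]:
    mu, sigma = {}, {}
    floor_pre = max(1e-6 * float(np.ptp(pre)), 1e-12)
    floor_ict = max(1e-6 * float(np.ptp(ict)), 1e-12)
    for c in (LABEL_SPARED, LABEL_IMPAIRED):
        sel = labels == c
        mu[f"pre{c}"] = float(pre[sel].mean())
        mu[f"ict{c}"] = float(ict[sel].mean())
        sigma[f"pre{c}"] = max(float(pre[sel].std()), floor_pre, 1e-12)
        sigma[f"ict{c}"] = max(float(ict[sel].std()), floor_ict, 1e-12)
    n = labels.size
    log_prior = {c: float(np.log(max((labels == c).sum(), 1) / n))
                 for c in (LABEL_SPARED, LABEL_IMPAIRED)}
    return mu, sigma, log_prior


def fuse_scores(fm: FusionModel, s_pre: np.ndarray | float,
                s_ict: np.ndarray | float) -> np.ndarray | float:
    """Fused impaired-score: weighted log posterior ratio impaired/spared."""
    s_pre = np.asarray(s_pre, dtype=float)
    s_ict = np.asarray(s_ict, dtype=float)
    ll = {}
    for c in (LABEL_SPARED, LABEL_IMPAIRED):
        ll[c] = (fm.alpha * _log_normal_pdf(s_pre, fm.mu[f"pre{c}"], fm.sigma[f"pre{c}"])
                 + (1 - fm.alpha) * _log_normal_pdf(s_ict, fm.mu[f"ict{c}"], fm.sigma[f"ict{c}"])
                 + fm.log_prior[c])
    out = ll[LABEL_IMPAIRED] - ll[LABEL_SPARED]
    return float(out) if out.ndim == 0 else out


def _spared_confusion(pred_spared: np.ndarray, labels: np.ndarray) -> tuple[int, int, int]:
    tp = int(np.sum(pred_spared & (labels == LABEL_SPARED)))
    fp = int(np.sum(pred_spared & (labels == LABEL_IMPAIRED)))
    fn = int(np.sum(~pred_spared & (labels == LABEL_SPARED)))
    return tp, fp, fn


def fit_fusion(
    pre_scores: np.ndarray,
    ict_scores: np.ndarray,
    labels: np.ndarray,
    alpha_grid: tuple[float, ...] = DEFAULT_ALPHA_GRID,
    margin: float = 0.0,
    gap_fraction: float = 0.5,
) -> FusionModel:
    """Fit class-conditional Gaussians and pick the preictal weight α.

    Candidate α values are scored by pooled spared predictive value under an
    inner stratified 5-fold cross-validation of the training scores (each
    inner fold refits the Gaussians and the conservative threshold); ties go
    to higher spared sensitivity, then to the smaller α.
    """
    pre_scores = np.asarray(pre_scores, dtype=float)
    ict_scores = np.asarray(ict_scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(alpha_grid) == 0:
        raise ValueError("alpha_grid must be non-empty")
    if any(not (0 <= a <= 1) for a in alpha_grid):
        raise ValueError("alpha values must lie in [0, 1]")
    if np.unique(labels).size != 2:
        raise ValueError("need both classes to fit fusion")

    min_class = min(int((labels == c).sum()) for c in (0, 1))
    n_splits = min(5, min_class)
    if n_splits >= 2:
        cv = StratifiedKFold(n_splits=n_splits, shuffle=False)
        folds = list(cv.split(pre_scores.reshape(-1, 1), labels))
    else:
        idx = np.arange(labels.size)
        folds = [(idx, idx)]  # degenerate: evaluate on the training scores

    best = None
    best_key = None
    for a in alpha_grid:
        tp = fp = fn = 0
        for tr, te in folds:
            mu, sigma, log_prior = _fit_gaussians(pre_scores[tr], ict_scores[tr],
                                                  labels[tr])
            fm = FusionModel(alpha=float(a), mu=mu, sigma=sigma, log_prior=log_prior)
            fused_tr = np.asarray(fuse_scores(fm, pre_scores[tr], ict_scores[tr]))
            cal = calibrate_threshold(fused_tr, labels[tr], margin=margin,
                                      gap_fraction=gap_fraction)
            fused_te = np.asarray(fuse_scores(fm, pre_scores[te], ict_scores[te]))
            pred_spared = cal.predict_spared(fused_te)
            dtp, dfp, dfn = _spared_confusion(pred_spared, labels[te])
            tp, fp, fn = tp + dtp, fp + dfp, fn + dfn
        ppv = tp / (tp + fp) if (tp + fp) > 0 else -1.0
        sens = tp / (tp + fn) if (tp + fn) > 0 else 0.0
        key = (ppv, sens, -float(a))
        if best_key is None or key > best_key:
            best_key = key
            best = float(a)

    mu, sigma, log_prior = _fit_gaussians(pre_scores, ict_scores, labels)
    return FusionModel(alpha=best, mu=mu, sigma=sigma, log_prior=log_prior)


# --------------------------------------------------------------------------
# conservative threshold


@dataclass(frozen=True)
class ThresholdCal:
    """Decision threshold τ on the impaired-score; spared iff score < τ."""

    tau: float
    margin: float = 0.0
    gap_fraction: float = 0.5

    def predict_spared(self, scores: np.ndarray) -> np.ndarray:
        return np.asarray(scores, dtype=float) < self.tau


def calibrate_threshold(fused_scores: np.ndarray, labels: np.ndarray,
                        margin: float = 0.0,
                        gap_fraction: float = 0.5) -> ThresholdCal:
    """Conservative threshold with zero false-spared on the calibration data.

    Starting from the minimum impaired score, τ is pushed down by ``margin``
    and by ``gap_fraction`` of the empirical separation gap (minimum impaired
    minus maximum spared score, clamped at 0 when the classes overlap):

        τ = min_impaired − margin − gap_fraction · max(0, min_impaired − max_spared)

    Any gap_fraction in [0, 1] keeps every impaired calibration example at or
    above τ, so zero false-spared holds by construction; the default 0.5
    centers τ in the gap, which is far more robust to a new impaired example
    landing just under the calibration minimum than the gap_fraction = 0
    edge rule.
    """
    fused_scores = np.asarray(fused_scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if margin < 0:
        raise ValueError("margin must be >= 0")
    if not (0 <= gap_fraction <= 1):
        raise ValueError("gap_fraction must lie in [0, 1]")
    if not np.any(labels == LABEL_IMPAIRED):
        raise ValueError("cannot calibrate a safety threshold without impaired examples")
    min_impaired = float(fused_scores[labels == LABEL_IMPAIRED].min())
    gap = 0.0
    if np.any(labels == LABEL_SPARED):
        gap = max(0.0, min_impaired - float(fused_scores[labels == LABEL_SPARED].max()))
    tau = min_impaired - margin - gap_fraction * gap
    return ThresholdCal(tau=tau, margin=margin, gap_fraction=gap_fraction)


# --------------------------------------------------------------------------
# feature cache and the end-to-end bundle


class FeatureCache:
    """Lazy per-dataset store of window epochs and unsupervised feature tables.

    Basic/extended tables and raw epochs depend only on the windows, so they
    are computed once and shared across folds and model configurations; CSP
    (supervised) is always refit per training set by the classifier.
    """

    def __init__(self, pairs: list[WindowPair]):
        if not pairs:
            raise ValueError("no window pairs")
        self.pairs = pairs
        self._tables: dict[tuple[str, str], pd.DataFrame] = {}
        self._epochs: dict[str, np.ndarray] = {}

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def labels(self) -> np.ndarray:
        return np.array([-1 if wp.event.label is None else wp.event.label
                         for wp in self.pairs], dtype=int)

    @property
    def patient_ids(self) -> list[str]:
        return [wp.event.patient_id for wp in self.pairs]

    @property
    def swd_ids(self) -> list[str]:
        return [wp.event.swd_id for wp in self.pairs]

    def epochs(self, window_tag: str) -> np.ndarray:
        if window_tag not in self._epochs:
            attr = "preictal" if window_tag == "preictal" else "ictal"
            self._epochs[window_tag] = np.stack(
                [getattr(wp, attr) for wp in self.pairs])
        return self._epochs[window_tag]

    def table(self, set_tag: str, window_tag: str) -> pd.DataFrame:
        key = (set_tag, window_tag)
        if key not in self._tables:
            self._tables[key] = feature_table(self.pairs, set_tag, window_tag)
        return self._tables[key]

    @property
    def channel_names(self) -> list[str]:
        return list(self.pairs[0].channel_names)


_WINDOW_KEYS = {"preictal": "pre", "ictal": "ict"}


class SwdClassifier:
    """One trained model bundle for a (feature set, window strategy, classifier).

    ``fit`` performs — on the training rows only — univariate feature
    selection (non-CSP features), CSP filter fitting, scorer training,
    fusion-weight search (fusion strategy), and conservative threshold
    calibration. ``predict`` maps rows of a :class:`FeatureCache` to 0/1.
    """

    def __init__(
        self,
        config: ModelConfig,
        n_csp_filters: int = 5,
        selection: SelectionConfig = SelectionConfig(),
        alpha_grid: tuple[float, ...] = DEFAULT_ALPHA_GRID,
        margin: float = 0.0,
        gap_fraction: float = 0.5,
        fixed_masks: dict[str, np.ndarray] | None = None,
    ):
        self.config = config
        self.n_csp_filters = n_csp_filters
        self.selection = selection
        self.alpha_grid = alpha_grid
        self.margin = margin
        self.gap_fraction = gap_fraction
        self.fixed_masks = fixed_masks  # for global-scope selection
        self.csp_models: dict[str, CspModel] = {}
        self.masks: dict[str, np.ndarray] = {}
        self.p_tables: dict[str, pd.DataFrame] = {}
        self.scorers: dict[str, Scorer] = {}
        self.fusion: FusionModel | None = None
        self.threshold: ThresholdCal | None = None
        self._fitted = False

    # -- design matrices ---------------------------------------------------

    def _windows_needed(self) -> list[str]:
        if self.config.window_strategy == "preictal":
            return ["preictal"]
        if self.config.window_strategy == "ictal":
            return ["ictal"]
        return ["preictal", "ictal"]

    def _selected_table(self, cache: FeatureCache, window_tag: str,
                        idx: np.ndarray) -> pd.DataFrame:
        base = cache.table("basic" if self.config.feature_set == "basic"
                           else "extended", window_tag)
        mask = self.masks[window_tag]
        return base.iloc[idx, :].loc[:, mask]

    def _csp_table(self, cache: FeatureCache, window_tag: str,
                   idx: np.ndarray) -> pd.DataFrame:
        model = self.csp_models[window_tag]
        epochs = cache.epochs(window_tag)[idx]
        rows = [csp_features(model, e).values for e in epochs]
        return pd.DataFrame(rows, index=np.asarray(cache.swd_ids)[idx])

    def _design(self, cache: FeatureCache, window_tag: str,
                idx: np.ndarray) -> pd.DataFrame:
        fs = self.config.feature_set
        if fs == "csp":
            return self._csp_table(cache, window_tag, idx)
        if fs in ("basic", "extended"):
            return self._selected_table(cache, window_tag, idx)
        sel = self._selected_table(cache, window_tag, idx)
        return pd.concat([sel, self._csp_table(cache, window_tag, idx)], axis=1)

    def _fit_window_models(self, cache: FeatureCache, idx: np.ndarray,
                           y: np.ndarray) -> None:
        for tag in self._windows_needed():
            if self.config.feature_set in ("basic", "extended", "all"):
                base = cache.table("basic" if self.config.feature_set == "basic"
                                   else "extended", tag)
                if self.fixed_masks is not None:
                    mask = np.asarray(self.fixed_masks[tag], dtype=bool)
                    table = None
                else:
                    mask, table = select_features(base.iloc[idx, :], y, self.selection)
                if not mask.any():
                    # keep the most discriminative single feature so the
                    # scorer always has an input
                    if table is None:
                        _, table = select_features(base.iloc[idx, :], y, self.selection)
                    mask = mask.copy()
                    mask[int(np.argmin(table["p_value"].to_numpy()))] = True
                self.masks[tag] = mask
                if table is not None:
                    self.p_tables[tag] = table
            if self.config.feature_set in ("csp", "all"):
                epochs = cache.epochs(tag)[idx]
                self.csp_models[tag] = fit_csp(
                    list(epochs[y == LABEL_SPARED]),
                    list(epochs[y == LABEL_IMPAIRED]),
                    k=self.n_csp_filters,
                    window_tag=tag,
                    channel_names=cache.channel_names,
                )

    # -- training ----------------------------------------------------------

    def fit(self, cache: FeatureCache, idx: np.ndarray | None = None,
            y: np.ndarray | None = None) -> "SwdClassifier":
        idx = np.arange(len(cache)) if idx is None else np.asarray(idx)
        y = cache.labels[idx] if y is None else np.asarray(y, dtype=int)
        if np.unique(y).size != 2:
            raise ValueError("training set must contain both classes")
        self._fit_window_models(cache, idx, y)

        strategy = self.config.window_strategy
        if strategy in ("preictal", "ictal"):
            X = self._design(cache, strategy, idx)
            self.scorers[strategy] = train_scorer(X, y, self.config.classifier)
            scores = self.scorers[strategy].score(X)
        elif strategy == "concatenation":
            X = pd.concat(
                [self._design(cache, tag, idx).add_prefix(f"{_WINDOW_KEYS[tag]}_")
                 for tag in ("preictal", "ictal")], axis=1)
            self.scorers["concatenation"] = train_scorer(X, y, self.config.classifier)
            scores = self.scorers["concatenation"].score(X)
        else:  # fusion
            s = {}
            for tag in ("preictal", "ictal"):
                X = self._design(cache, tag, idx)
                self.scorers[tag] = train_scorer(X, y, self.config.classifier)
                s[tag] = self.scorers[tag].score(X)
            self.fusion = fit_fusion(s["preictal"], s["ictal"], y,
                                     alpha_grid=self.alpha_grid, margin=self.margin,
                                     gap_fraction=self.gap_fraction)
            scores = np.asarray(fuse_scores(self.fusion, s["preictal"], s["ictal"]))

        self.threshold = calibrate_threshold(scores, y, margin=self.margin,
                                             gap_fraction=self.gap_fraction)
        self._fitted = True
        # safety invariant: no impaired calibration example below τ
        pred_spared = self.threshold.predict_spared(scores)
        assert not np.any(pred_spared & (y == LABEL_IMPAIRED)), \
            "calibration produced a false-spared prediction"
        return self

    # -- prediction --------------------------------------------------------

    def decision_scores(self, cache: FeatureCache,
                        idx: np.ndarray | None = None) -> np.ndarray:
        if not self._fitted:
            raise ValueError("classifier is not fitted")
        idx = np.arange(len(cache)) if idx is None else np.asarray(idx)
        strategy = self.config.window_strategy
        if strategy in ("preictal", "ictal"):
            return self.scorers[strategy].score(self._design(cache, strategy, idx))
        if strategy == "concatenation":
            X = pd.concat(
                [self._design(cache, tag, idx).add_prefix(f"{_WINDOW_KEYS[tag]}_")
                 for tag in ("preictal", "ictal")], axis=1)
            return self.scorers["concatenation"].score(X)
        s_pre = self.scorers["preictal"].score(self._design(cache, "preictal", idx))
        s_ict = self.scorers["ictal"].score(self._design(cache, "ictal", idx))
        return np.asarray(fuse_scores(self.fusion, s_pre, s_ict))

    def predict(self, cache: FeatureCache,
                idx: np.ndarray | None = None) -> np.ndarray:
        scores = self.decision_scores(cache, idx)
        spared = self.threshold.predict_spared(scores)
        return np.where(spared, LABEL_SPARED, LABEL_IMPAIRED)

    # -- serialization -----------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Single-archive bundle: JSON metadata plus binary arrays (.npz)."""
        if not self._fitted:
            raise ValueError("cannot save an unfitted classifier")
        meta = {
            "config": vars(self.config).copy(),
            "n_csp_filters": self.n_csp_filters,
            "selection": {"p_threshold": self.selection.p_threshold,
                          "scope": self.selection.scope},
            "alpha_grid": list(map(float, self.alpha_grid)),
            "margin": self.margin,
            "threshold": {"tau": self.threshold.tau, "margin": self.threshold.margin,
                          "gap_fraction": self.threshold.gap_fraction},
            "fusion": None,
            "scorers": {},
            "csp": {},
            "masks": {k: np.asarray(v).astype(int).tolist()
                      for k, v in self.masks.items()},
        }
        arrays: dict[str, np.ndarray] = {}
        if self.fusion is not None:
            meta["fusion"] = {"alpha": self.fusion.alpha, "mu": self.fusion.mu,
                              "sigma": self.fusion.sigma,
                              "log_prior": {str(k): v for k, v in
                                            self.fusion.log_prior.items()}}
        for key, sc in self.scorers.items():
            meta["scorers"][key] = {"kind": sc.kind, "bias": sc.bias,
                                    "feature_names": sc.feature_names}
            arrays[f"scorer_{key}_mean"] = sc.mean
            arrays[f"scorer_{key}_std"] = sc.std
            arrays[f"scorer_{key}_weights"] = sc.weights
        for key, cm in self.csp_models.items():
            meta["csp"][key] = {"window_tag": cm.window_tag,
                                "channel_names": cm.channel_names}
            arrays[f"csp_{key}_filters"] = cm.filters
            arrays[f"csp_{key}_eigenvalues"] = cm.eigenvalues
        np.savez(path, meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                 **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "SwdClassifier":
        with np.load(path) as data:
            meta = json.loads(bytes(data["meta"]).decode())
            obj = cls(
                config=ModelConfig(**meta["config"]),
                n_csp_filters=meta["n_csp_filters"],
                selection=SelectionConfig(**meta["selection"]),
                alpha_grid=tuple(meta["alpha_grid"]),
                margin=meta["margin"],
            )
            obj.threshold = ThresholdCal(**meta["threshold"])
            if meta["fusion"] is not None:
                fz = meta["fusion"]
                obj.fusion = FusionModel(alpha=fz["alpha"], mu=fz["mu"],
                                         sigma=fz["sigma"],
                                         log_prior={int(k): v for k, v in
                                                    fz["log_prior"].items()})
            for key, sm in meta["scorers"].items():
                obj.scorers[key] = Scorer(
                    kind=sm["kind"], feature_names=sm["feature_names"],
                    mean=data[f"scorer_{key}_mean"], std=data[f"scorer_{key}_std"],
                    weights=data[f"scorer_{key}_weights"], bias=sm["bias"])
            for key, cm in meta["csp"].items():
                obj.csp_models[key] = CspModel(
                    filters=data[f"csp_{key}_filters"],
                    eigenvalues=data[f"csp_{key}_eigenvalues"],
                    window_tag=cm["window_tag"],
                    channel_names=cm["channel_names"])
            obj.masks = {k: np.asarray(v, dtype=bool)
                         for k, v in meta["masks"].items()}
            obj._fitted = True
        return obj
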