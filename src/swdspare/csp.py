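"""Common spatial patterns (CSP) for two-class EEG discrimination.

CSP finds channel-weight vectors w maximizing the variance of one class
while minimizing the other. With per-epoch covariances normalized by trace
and averaged to class means C_s (spared) and C_i (impaired), the filters
solve the generalized eigenproblem

    C_i w = λ (C_s + C_i) w,

so each eigenvalue λ ∈ [0, 1] is the share of the composite variance carried
by the impaired class along that filter: λ near 1 or near 0 is maximally
discriminative, λ = 0.5 carries no class information. Filters are kept in
decreasing order of max(λ, 1-λ), which allows an odd filter count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import linalg

from .features import FeatureVector


@dataclass
class CspModel:
    """k spatial filters (rows) with their impaired-variance shares λ."""

    filters: np.ndarray  # k x channels
    eigenvalues: np.ndarray  # k, sorted by max(λ, 1-λ) descending
    window_tag: str
    channel_names: list[str]

    @property
    def n_filters(self) -> int:
        return self.filters.shape[0]


def _epoch_covariance(epoch: np.ndarray) -> np.ndarray:
    x = np.asarray(epoch, dtype=float)
    x = x - x.mean(axis=1, keepdims=True)
    c = x @ x.T
    tr = np.trace(c)
    if tr <= 0:
        raise ValueError("epoch with zero total variance")
    return c / tr


def class_covariance(epochs: list[np.ndarray]) -> np.ndarray:
    """Trace-normalized spatial covariance averaged over epochs."""
    if len(epochs) == 0:
        raise ValueError("no epochs")
    return np.mean([_epoch_covariance(e) for e in epochs], axis=0)


def fit_csp(
    epochs_spared: list[np.ndarray],
    epochs_impaired: list[np.ndarray],
    k: int = 5,
    window_tag: str = "ictal",
    channel_names: list[str] | None = None,
) -> CspModel:
    """Fit k CSP filters from spared/impaired epochs (channels x time each).

    The filters are orthonormal in the whitened metric of the composite
    covariance: W (C_s + C_i) Wᵀ = I. A rank-deficient composite is ridge-
    regularized by ε·trace/channels·I (ε = 1e-8) with a warning.
    """
    if len(epochs_spared) < 2 or len(epochs_impaired) < 2:
        raise ValueError("need at least 2 epochs per class")
    n_ch = np.asarray(epochs_spared[0]).shape[0]
    for e in (*epochs_spared, *epochs_impaired):
        if np.asarray(e).shape[0] != n_ch:
            raise ValueError("all epochs must share the channel dimension")
    if k > n_ch:
        raise ValueError(f"k={k} exceeds channel count {n_ch}")

    c_s = class_covariance(epochs_spared)
    c_i = class_covariance(epochs_impaired)
    composite = c_s + c_i
    evals = linalg.eigvalsh(composite)
    if evals[0] < 1e-10 * max(evals[-1], 1e-300):
        warnings.warn("rank-deficient composite covariance; ridge-regularizing")
        composite = composite + 1e-8 * (np.trace(composite) / n_ch) * np.eye(n_ch)

    lam, vecs = linalg.eigh(c_i, composite)  # ascending λ, vecs Cc-orthonormal
    lam = np.clip(lam, 0.0, 1.0)
    order = np.argsort(-np.maximum(lam, 1.0 - lam), kind="stable")[:k]
    filters = vecs[:, order].T
    if channel_names is None:
        channel_names = [f"ch{i}" for i in range(n_ch)]
    return CspModel(filters=filters, eigenvalues=lam[order],
                    window_tag=window_tag, channel_names=list(channel_names))


def csp_features(model: CspModel, window: np.ndarray) -> FeatureVector:
    """Normalized log-variance of the window projected onto each filter.

    feature_j = log( var(w_jᵀ x) / Σ_j' var(w_j'ᵀ x) ); invariant to any
    positive rescaling of the window.
    """
    x = np.asarray(window, dtype=float)
    if x.shape[0] != model.filters.shape[1]:
        raise ValueError("window channel count does not match the CSP model")
    x = x - x.mean(axis=1, keepdims=True)
    proj = model.filters @ x
    variances = proj.var(axis=1)
    total = variances.sum()
    if total <= 0:
        raise ValueError("zero variance on every CSP projection")
    values = {
        f"csp{j}_logvar": float(np.log(variances[j] / total))
        for j in range(model.n_filters)
    }
    return FeatureVector(values, window_tag=model.window_tag, set_tag="csp")


def export_filters(model: CspModel, path: str | Path | None = None) -> pd.DataFrame:
    """Long-format table (channel, filter_index, weight, eigenvalue).

    One row per channel per filter, ordered as in the model (descending
    discriminability), for topographic inspection outside the package.
    """
    rows = []
    for j in range(model.n_filters):
        for c, ch in enumerate(model.channel_names):
            rows.append({
                "channel": ch,
                "filter_index": j,
                "weight": model.filters[j, c],
                "eigenvalue": model.eigenvalues[j],
            })
    df = pd.DataFrame(rows, columns=["channel", "filter_index", "weight", "eigenvalue"])
    if path is not None:
        df.to_csv(path, index=False)
    return df
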