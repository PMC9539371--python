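"""Univariate feature selection by Wilcoxon rank-sum.

Each candidate feature is compared between spared and impaired discharges
with a two-sided rank-sum (Mann-Whitney) test; features with p below a
threshold (default 0.001, the level that maximized spared predictive value)
are kept. CSP log-variance features bypass this screen — their number is
fixed by the filter count, not by univariate significance.

No multiple-testing correction is applied: the selection threshold is a raw
per-feature criterion, by design.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats


@dataclass(frozen=True)
class SelectionConfig:
    p_threshold: float = 0.001
    scope: str = "per_fold"  # "per_fold" | "global"

    def __post_init__(self) -> None:
        if not (0 < self.p_threshold < 1):
            raise ValueError("p_threshold must lie in (0, 1)")
        if self.scope not in ("per_fold", "global"):
            raise ValueError("scope must be 'per_fold' or 'global'")


def rank_sum_test(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided rank-sum p-value between two samples.

    Exact null enumeration when the combined sample has at most 12 values
    and no ties; otherwise the normal approximation with tie and continuity
    corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if x.size + y.size < 4:
        raise ValueError("need at least 4 values in the combined sample")
    combined = np.concatenate([x, y])
    no_ties = np.unique(combined).size == combined.size
    method = "exact" if (combined.size <= 12 and no_ties) else "asymptotic"
    res = sstats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                              use_continuity=True)
    return float(res.pvalue)


def p_value_table(feature_matrix: pd.DataFrame, labels: np.ndarray) -> pd.DataFrame:
    """Per-feature class means and rank-sum p, one row per feature column."""
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError("need exactly two classes for feature selection")
    lo, hi = classes  # 0 = spared, 1 = impaired under canonical labels
    rows = []
    for col in feature_matrix.columns:
        v = feature_matrix[col].to_numpy(dtype=float)
        rows.append({
            "feature": col,
            "mean_spared": float(v[labels == lo].mean()),
            "mean_impaired": float(v[labels == hi].mean()),
            "p_value": rank_sum_test(v[labels == lo], v[labels == hi]),
        })
    return pd.DataFrame(rows).set_index("feature")


def select_features(
    feature_matrix: pd.DataFrame,
    labels: np.ndarray,
    cfg: SelectionConfig = SelectionConfig(),
) -> tuple[np.ndarray, pd.DataFrame]:
    """Boolean keep-mask (p < threshold) plus the full p-value table.

    The mask may be empty; classifiers that need a non-empty design matrix
    fall back to the smallest-p feature themselves (the screen itself stays
    an honest thresholding).
    """
    table = p_value_table(feature_matrix, labels)
    mask = (table["p_value"] < cfg.p_threshold).to_numpy()
    return mask, table
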