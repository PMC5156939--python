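"""Per-metabolite differential statistics.

Fold change is the ratio of arithmetic group means on the normalized
linear scale; the two-sided Student (pooled-variance) t-test runs on
log2 intensities; Benjamini-Hochberg adjustment supports an external
total-test count ``m_total`` so that adjusted values can be reproduced
from a published subset of the smallest p-values; volcano selection
combines a fold-change dead band with a raw p-value cut, all strict
inequalities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import AbundanceMatrix

__all__ = [
    "Thresholds",
    "fold_change",
    "t_test",
    "bh_adjust",
    "volcano_select",
    "annotated_subset",
    "differential_analysis",
]


@dataclass(frozen=True)
class Thresholds:
    """Selection thresholds for the univariate screen.

    ``fc_high``/``fc_low`` bound the fold-change dead band (select when
    FC > fc_high or FC < fc_low), ``p_volcano`` is the raw p cut used
    jointly with fold change, ``p_raw`` the screening cut for reporting,
    ``fdr_level`` the nominal FDR, and ``m_total`` the total number of
    tests behind the BH adjustment (``None`` = number of features
    supplied).
    """

    fc_high: float = 1.20
    fc_low: float = 0.83
    p_volcano: float = 0.1
    p_raw: float = 0.05
    fdr_level: float = 0.05
    m_total: int | None = None

    def __post_init__(self):
        if not 0 < self.fc_low < 1 < self.fc_high:
            raise ValueError("need 0 < fc_low < 1 < fc_high")
        for name in ("p_volcano", "p_raw", "fdr_level"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1)")


def fold_change(M: AbundanceMatrix) -> np.ndarray:
    """Per-feature case-mean / control-mean ratio on the linear scale."""
    M.require_scale("linear", "fold_change")
    M.require_both_groups()
    case_mean = M.values[M.case_mask].mean(axis=0)
    ctrl_mean = M.values[M.control_mask].mean(axis=0)
    if np.any(ctrl_mean == 0):
        raise ValueError("zero control mean")
    return case_mean / ctrl_mean


def t_test(M: AbundanceMatrix):
    """Two-sided pooled-variance Student t-test per feature on log2 data.

    Returns ``(t_stat, p_value)`` arrays; p comes from the t distribution
    with ``n1 + n2 - 2`` degrees of freedom.
    """
    M.require_scale("log2", "t_test")
    case = M.values[M.case_mask]
    ctrl = M.values[M.control_mask]
    if len(case) < 2 or len(ctrl) < 2:
        raise ValueError("each group needs at least 2 samples")
    t, p = stats.ttest_ind(case, ctrl, axis=0, equal_var=True)
    return np.asarray(t), np.asarray(p)


def bh_adjust(p_values, m_total: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    When ``m_total`` exceeds the number of supplied p-values, the
    supplied values are treated as the smallest among ``m_total`` tests;
    the absent tests are imputed as p = 1 occupying the highest ranks
    (they can never lower the step-up minimum).  adjusted(i) =
    min over ranks j >= i of p_(j) * m_total / j, capped at 1, returned
    in input order.  Ties in p share the rank-induced adjusted value.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    k = len(p)
    m = k if m_total is None else int(m_total)
    if m < k:
        raise ValueError(f"m_total={m} smaller than number of p-values ({k})")
    order = np.argsort(p, kind="stable")
    ranks = np.arange(1, k + 1)
    stepup = p[order] * m / ranks
    # running minimum from the largest rank down; imputed p=1 tests at
    # ranks k+1..m contribute ratios >= 1 and never bind below the cap
    # tied p-values share the block value automatically: the running min
    # propagates the smallest ratio of a tie block to every member
    adj_sorted = np.minimum.accumulate(stepup[::-1])[::-1]
    adj_sorted = np.minimum(adj_sorted, 1.0)
    out = np.empty(k)
    out[order] = adj_sorted
    return out


def volcano_select(
    fold_changes, p_values, thresholds: Thresholds = Thresholds()
) -> np.ndarray:
    """Boolean mask: FC outside the (fc_low, fc_high) dead band AND raw
    p below p_volcano, all strict."""
    fc = np.asarray(fold_changes, dtype=float)
    p = np.asarray(p_values, dtype=float)
    return ((fc > thresholds.fc_high) | (fc < thresholds.fc_low)) & (
        p < thresholds.p_volcano
    )


def annotated_subset(results: pd.DataFrame) -> pd.DataFrame:
    """Keep rows for library-annotated metabolites.

    Uses the ``annotation`` column when present, otherwise the fixture
    convention that unidentified features are named ``Unknown ...``.
    """
    if results.empty:
        return results.copy()
    if "annotation" in results.columns:
        keep = results["annotation"] == "known"
    else:
        keep = ~results["feature_id"].str.startswith("Unknown")
    return results.loc[keep].copy()


def differential_analysis(
    M_linear: AbundanceMatrix, thresholds: Thresholds = Thresholds()
) -> pd.DataFrame:
    """Full univariate screen on a normalized linear-scale matrix.

    Computes linear fold change, the pooled t-test on log2 values, BH
    adjustment at ``thresholds.m_total``, and the volcano flag.  Returns
    one row per feature, sorted by raw p.
    """
    from .preprocess import log2_transform

    M_log2 = log2_transform(M_linear)
    fc = fold_change(M_linear)
    t, p = t_test(M_log2)
    log2fc = (
        M_log2.values[M_log2.case_mask].mean(axis=0)
        - M_log2.values[M_log2.control_mask].mean(axis=0)
    )
    padj = bh_adjust(p, thresholds.m_total)
    out = pd.DataFrame(
        {
            "feature_id": list(M_linear.feature_ids),
            "annotation": list(M_linear.annotation),
            "fold_change": fc,
            "log2fc": log2fc,
            "t_stat": t,
            "p_value": p,
            "p_adjusted": padj,
            "selected": volcano_select(fc, p, thresholds),
        }
    )
    return out.sort_values("p_value", kind="stable").reset_index(drop=True)
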