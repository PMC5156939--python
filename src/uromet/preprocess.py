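"""Normalization, transformation, scaling and PCA-based sample screening.

Pipeline order matters: per-sample normalization happens on the linear
scale, the t-test runs on log2 intensities, and autoscaling (unit
variance, mean centering) is applied only ahead of the multivariate
steps (PCA screening, PLS-DA, network inference).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.decomposition import PCA

from .containers import AbundanceMatrix

__all__ = [
    "OutlierReport",
    "normalize_per_sample",
    "log2_transform",
    "autoscale",
    "pca_outlier_exclude",
]


@dataclass(frozen=True)
class OutlierReport:
    """Outcome of the PCA score-distance screen."""

    excluded_sample_ids: tuple
    score_distances: np.ndarray
    threshold: float
    n_components: int


def normalize_per_sample(M: AbundanceMatrix, factors="ones") -> AbundanceMatrix:
    """Divide each sample's intensities by a positive per-sample factor.

    ``factors`` may be a vector of positive reals (one per sample, e.g.
    creatinine equivalents), the policy string ``"total"`` (scale every
    sample's sum to the cohort median sum), or ``"ones"`` (pass-through,
    the default: the reference workflow adjusted sample volumes at the
    bench, not in software).
    """
    M.require_scale("linear", "normalize_per_sample")
    if isinstance(factors, str):
        if factors == "ones":
            return M.with_values(M.values.copy())
        if factors == "total":
            sums = M.values.sum(axis=1)
            f = sums / np.median(sums)
        else:
            raise ValueError(f"unknown normalization policy {factors!r}")
    else:
        f = np.asarray(factors, dtype=float)
        if f.shape != (M.n_samples,):
            raise ValueError(
                f"expected {M.n_samples} factors, got shape {f.shape}"
            )
        if not (f > 0).all():
            bad = int(np.flatnonzero(f <= 0)[0])
            raise ValueError(f"non-positive factor for sample {M.sample_ids[bad]!r}")
    return M.with_values(M.values / f[:, None])


def log2_transform(M: AbundanceMatrix) -> AbundanceMatrix:
    """Elementwise log2; requires strictly positive input, no pseudocount."""
    if not (M.values > 0).all():
        i, j = np.argwhere(M.values <= 0)[0]
        raise ValueError(
            f"non-positive value at sample {M.sample_ids[i]!r}, "
            f"feature {M.feature_ids[j]!r}: {M.values[i, j]}"
        )
    return M.with_values(np.log2(M.values), scale="log2")


def autoscale(M: AbundanceMatrix) -> AbundanceMatrix:
    """Center each feature to mean 0 and scale to unit sample SD (n-1).

    Zero-variance features cannot be scaled; they are dropped with a
    warning rather than raising, which keeps degenerate synthetic inputs
    usable.
    """
    if M.n_samples < 2:
        raise ValueError("autoscale needs at least 2 samples")
    sd = M.values.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.all():
        dropped = [M.feature_ids[i] for i in np.flatnonzero(~keep)]
        warnings.warn(
            f"dropping {len(dropped)} zero-variance feature(s): {dropped[:5]}...",
            UserWarning,
            stacklevel=2,
        )
        M = M.select_features(keep)
        sd = sd[keep]
    centered = (M.values - M.values.mean(axis=0)) / sd
    return M.with_values(centered, scale="autoscaled")


def pca_outlier_exclude(
    M: AbundanceMatrix, n_components: int = 2, alpha: float = 0.025
):
    """Drop samples far out in principal-component score space.

    Scores are computed on autoscaled data; a sample is flagged when its
    squared score distance (sum over retained components of
    score^2 / component variance, a Hotelling-type statistic) exceeds
    the chi-square quantile with ``n_components`` degrees of freedom at
    ``1 - alpha``.  Single pass: the screen is not re-run after removal.

    Returns the reduced matrix (original scale) and an
    :class:`OutlierReport`.
    """
    if not 0 < alpha < 0.5:
        raise ValueError("alpha must lie in (0, 0.5)")
    if M.n_samples <= n_components + 1:
        raise ValueError("need more samples than components + 1")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        scaled = autoscale(M)
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(scaled.values)
    comp_var = scores.var(axis=0, ddof=1)
    d2 = (scores**2 / comp_var).sum(axis=1)
    threshold = float(stats.chi2.ppf(1 - alpha, df=n_components))
    flagged = d2 > threshold

    report = OutlierReport(
        excluded_sample_ids=tuple(
            M.sample_ids[i] for i in np.flatnonzero(flagged)
        ),
        score_distances=d2,
        threshold=threshold,
        n_components=n_components,
    )
    return M.select_samples(~flagged), report
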