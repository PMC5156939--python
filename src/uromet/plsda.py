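"""PLS discriminant analysis with LOO cross-validation and a
permutation test on a separation-distance statistic.

The model is a NIPALS-style PLS1 fit: the class label (1 = case,
0 = control) is centered and used as the response; each component's
weight vector maximizes covariance between the X-score and the centered
label, and X is deflated by the score-loading outer product.  Model
significance is assessed by permuting labels and comparing the observed
between-group / within-group sum-of-squares ratio of the score matrix
(the "separation distance") against its permutation null.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PlsdaModel",
    "PermutationResult",
    "fit_plsda",
    "predict",
    "loo_cv",
    "separation_distance",
    "permutation_test",
]


@dataclass(frozen=True)
class PlsdaModel:
    n_components: int
    x_scores: np.ndarray      # (n, k)
    x_weights: np.ndarray     # (p, k)
    x_loadings: np.ndarray    # (p, k)
    y_loadings: np.ndarray    # (k,)
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: float


@dataclass(frozen=True)
class PermutationResult:
    observed_stat: float
    permuted_stats: np.ndarray
    p_value: float
    B: int
    seed: int | None


def _scale_params(X, scale):
    mean = X.mean(axis=0)
    if scale:
        sd = X.std(axis=0, ddof=1)
        sd = np.where(sd > 0, sd, 1.0)
    else:
        sd = np.ones(X.shape[1])
    return mean, sd


def fit_plsda(
    X: np.ndarray, y: np.ndarray, n_components: int = 3, scale: bool = True
) -> PlsdaModel:
    """Fit a two-class PLS-DA model.

    ``X`` is samples x features; ``y`` binary 0/1 with both classes
    present.  With ``scale=True`` (default) X is autoscaled internally
    and the means/SDs stored for prediction; pass ``scale=False`` for
    pre-autoscaled input.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n, p = X.shape
    if set(np.unique(y)) != {0, 1}:
        raise ValueError("y must contain both classes, coded 0/1")
    if not 1 <= n_components <= min(n - 1, p):
        raise ValueError(
            f"n_components={n_components} invalid for {n} samples x {p} features"
        )
    mean, sd = _scale_params(X, scale)
    Xc = (X - mean) / sd
    if np.linalg.matrix_rank(Xc) < n_components:
        raise ValueError("n_components exceeds the rank of the centered data")
    y_mean = float(y.mean())
    yc = y.astype(float) - y_mean

    T = np.empty((n, n_components))
    W = np.empty((p, n_components))
    P = np.empty((p, n_components))
    q = np.empty(n_components)
    Xd, yd = Xc.copy(), yc.copy()
    for a in range(n_components):
        w = Xd.T @ yd
        nw = np.linalg.norm(w)
        if nw == 0:
            raise ValueError("degenerate component: zero covariance with labels")
        w /= nw
        t = Xd @ w
        tt = t @ t
        pl = Xd.T @ t / tt
        qa = yd @ t / tt
        Xd -= np.outer(t, pl)
        yd -= qa * t
        T[:, a], W[:, a], P[:, a], q[a] = t, w, pl, qa

    return PlsdaModel(
        n_components=n_components,
        x_scores=T,
        x_weights=W,
        x_loadings=P,
        y_loadings=q,
        x_mean=mean,
        x_scale=sd,
        y_mean=y_mean,
    )


def transform(model: PlsdaModel, X_new: np.ndarray) -> np.ndarray:
    """Project new samples onto the model's score space."""
    X_new = np.asarray(X_new, dtype=float)
    if X_new.shape[1] != model.x_mean.shape[0]:
        raise ValueError(
            f"feature mismatch: model has {model.x_mean.shape[0]}, "
            f"input has {X_new.shape[1]}"
        )
    Xc = (X_new - model.x_mean) / model.x_scale
    # rotation mapping raw (scaled) X to scores under NIPALS deflation
    R = model.x_weights @ np.linalg.inv(model.x_loadings.T @ model.x_weights)
    return Xc @ R


def decision_values(model: PlsdaModel, X_new: np.ndarray) -> np.ndarray:
    """Regression prediction of the centered label for new samples."""
    return transform(model, X_new) @ model.y_loadings


def predict(model: PlsdaModel, X_new: np.ndarray) -> np.ndarray:
    """Predicted class labels: 1 iff the centered-label prediction is
    above 0 (the centered midpoint)."""
    return (decision_values(model, X_new) > 0).astype(int)


def loo_cv(X: np.ndarray, y: np.ndarray, n_components: int = 3):
    """Leave-one-out cross-validation.

    Scaling and the model are refit on each training fold (no leakage);
    returns ``(held_out_predictions, accuracy)``.  Every class needs at
    least 2 members so that no fold empties a class.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n = len(y)
    if n < 3:
        raise ValueError("leave-one-out needs at least 3 samples")
    counts = np.bincount(y, minlength=2)
    if counts.min() < 2:
        raise ValueError("a fold would leave a class empty: need >= 2 per class")
    preds = np.empty(n, dtype=int)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        k = min(n_components, n - 2, X.shape[1])
        model = fit_plsda(X[mask], y[mask], n_components=k, scale=True)
        preds[i] = predict(model, X[i : i + 1])[0]
    return preds, float((preds == y).mean())


def separation_distance(x_scores: np.ndarray, y: np.ndarray) -> float:
    """Between-group over within-group sum of squares of the scores,
    summed over components.  Zero within-group scatter returns +inf."""
    T = np.atleast_2d(np.asarray(x_scores, dtype=float))
    if T.ndim == 2 and T.shape[0] == 1:
        T = T.T
    y = np.asarray(y)
    grand = T.mean(axis=0)
    between = 0.0
    within = 0.0
    for g in (0, 1):
        Tg = T[y == g]
        if len(Tg) == 0:
            raise ValueError("both classes must be present")
        mg = Tg.mean(axis=0)
        between += len(Tg) * float(((mg - grand) ** 2).sum())
        within += float(((Tg - mg) ** 2).sum())
    if within == 0.0:
        return float("inf")
    return between / within


def permutation_test(
    X: np.ndarray,
    y: np.ndarray,
    n_components: int = 3,
    B: int = 2000,
    seed: int | None = None,
    scale: bool = True,
) -> PermutationResult:
    """Permutation test of class separation.

    Refits the model under ``B`` label permutations and compares the
    observed separation distance against the permuted statistics;
    p = (1 + #{permuted >= observed}) / (B + 1), so ties count as
    extreme and p is never 0.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng(seed)
    y = np.asarray(y)

    def _stat(labels):
        try:
            model = fit_plsda(X, labels, n_components=n_components, scale=scale)
        except ValueError:
            # degenerate refit (e.g. zero covariance under this labeling)
            return float("inf")
        return separation_distance(model.x_scores, labels)

    observed = _stat(y)
    permuted = np.empty(B)
    for b in range(B):
        permuted[b] = _stat(rng.permutation(y))
    n_ge = int(np.sum(permuted >= observed))
    return PermutationResult(
        observed_stat=observed,
        permuted_stats=permuted,
        p_value=(1 + n_ge) / (B + 1),
        B=B,
        seed=seed,
    )
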