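"""Sparse local graphical model: common and differential metabolite
networks from per-node lasso regressions with group interactions.

Each metabolite x_i is regressed, in turn, on the remaining metabolites
X_{-i}, the binary condition label y, and the interactions y * X_{-i}:

    x_i = alpha_i0 + alpha_i' X_{-i} + beta_i0 y + beta_i' (y X_{-i}) + eps_i

with an L1 penalty on the alpha block (condition-independent partial
correlations) and on the beta block (condition-dependent deviations);
the intercept and the y main effect are left unpenalized so that pure
mean shifts are not absorbed into beta edges.  A nonzero alpha_ij is a
*common* edge between metabolites i and j; a nonzero beta_ij is a
*differential* edge, i.e. a partial correlation that changes between
case and control.  Collecting the supports over all node regressions
and symmetrizing yields the common and differential networks.

The penalized solver is a covariance-update coordinate descent on the
standardized design (glmnet-style 1/(2n) least-squares scaling), with
per-column penalty factors so the two blocks can carry different
penalties and unpenalized columns carry zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

__all__ = [
    "NodeRegression",
    "NetworkPair",
    "Subnetwork",
    "node_lasso",
    "select_lambda",
    "build_networks",
    "extract_module",
    "export_network",
    "read_sif",
]

_NONZERO_TOL = 1e-8


@dataclass(frozen=True)
class NodeRegression:
    """One node's fitted sparse regression."""

    target_index: int
    alpha: np.ndarray          # (p-1,) coefficients on X_{-i}
    beta: np.ndarray           # (p-1,) coefficients on y * X_{-i}
    alpha_0: float             # intercept
    beta_0: float              # y main effect (unpenalized)
    lambda_alpha: float
    lambda_beta: float
    residual_variance: float


@dataclass(frozen=True)
class NetworkPair:
    """Common (alpha) and differential (beta) weighted edge lists."""

    nodes: tuple
    common_edges: tuple        # ((node_a, node_b, weight), ...)
    diff_edges: tuple

    def edge_set(self, layer: str) -> set:
        edges = self.common_edges if layer == "common" else self.diff_edges
        return {frozenset((a, b)) for a, b, _ in edges}


@dataclass(frozen=True)
class Subnetwork:
    seed_node: str
    nodes: tuple
    edges: tuple               # ((node_a, node_b, weight), ...)
    upregulated: dict = field(default_factory=dict)


def _coordinate_descent(G, c, penalties, lam, theta, tol, max_iter):
    """Minimize (1/2n)||x - Z theta||^2 + lam * sum_j penalties[j] |theta_j|
    given Gram G = Z'Z/n and c = Z'x/n, warm-started at ``theta``."""
    d = len(c)
    g_diag = np.diag(G).copy()
    g_diag[g_diag == 0] = 1.0  # dead columns stay at zero
    for _ in range(max_iter):
        delta = 0.0
        for j in range(d):
            if G[j, j] == 0:
                continue
            rho = c[j] - G[j] @ theta + G[j, j] * theta[j]
            pen = lam * penalties[j]
            if pen > 0:
                new = np.sign(rho) * max(abs(rho) - pen, 0.0) / g_diag[j]
            else:
                new = rho / g_diag[j]
            delta = max(delta, abs(new - theta[j]))
            theta[j] = new
        if delta < tol:
            break
    return theta


def _node_design(i, X, y):
    """Standardized design [X_{-i} | y | y*X_{-i}] and the centered target.

    X is assumed autoscaled.  Interaction columns are standardized after
    forming the product; zero-variance columns are left as dead zeros
    (their coefficients stay 0).  Everything is centered so no explicit
    intercept column is needed.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if p < 2:
        raise ValueError("need at least 2 features")
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("y must be binary 0/1")
    others = np.delete(np.arange(p), i)
    Xmi = X[:, others]
    inter = y[:, None] * Xmi
    inter_c = inter - inter.mean(axis=0)
    sd = inter_c.std(axis=0, ddof=1)
    live = sd > 0
    inter_std = np.zeros_like(inter_c)
    inter_std[:, live] = inter_c[:, live] / sd[live]
    yc = y - y.mean()
    Z = np.hstack([Xmi, yc[:, None], inter_std])
    Z = Z - Z.mean(axis=0)
    target = X[:, i] - X[:, i].mean()
    pm1 = p - 1
    # per-column penalty factors: 1 for alpha block, 0 for y, 1 for beta block
    pen_alpha = np.concatenate([np.ones(pm1), [0.0], np.zeros(pm1)])
    pen_beta = np.concatenate([np.zeros(pm1), [0.0], np.ones(pm1)])
    return Z, target, others, pen_alpha, pen_beta


def node_lasso(
    i: int,
    X: np.ndarray,
    y: np.ndarray,
    lambda_alpha: float,
    lambda_beta: float,
    tol: float = 1e-7,
    max_iter: int = 100_000,
) -> NodeRegression:
    """Fit the sparse node regression for metabolite ``i``.

    ``X`` is the autoscaled log2 matrix restricted to the features being
    modeled; ``y`` the binary condition label.  ``lambda_alpha`` and
    ``lambda_beta`` penalize the main-effect and interaction blocks; the
    intercept and the y main effect are never penalized.
    """
    if lambda_alpha < 0 or lambda_beta < 0:
        raise ValueError("penalties must be non-negative")
    Z, target, _, pen_a, pen_b = _node_design(i, X, y)
    n, d = Z.shape
    G = Z.T @ Z / n
    c = Z.T @ target / n
    penalties = pen_a * lambda_alpha + pen_b * lambda_beta
    # lam=1: the per-column factor already carries the full penalty
    theta = _coordinate_descent(G, c, penalties, 1.0, np.zeros(d), tol, max_iter)

    pm1 = X.shape[1] - 1
    resid = target - Z @ theta
    yf = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    return NodeRegression(
        target_index=i,
        alpha=theta[:pm1].copy(),
        beta=theta[pm1 + 1 :].copy(),
        alpha_0=float(X[:, i].mean() - 0.0),  # design fully centered
        beta_0=float(theta[pm1]),
        lambda_alpha=float(lambda_alpha),
        lambda_beta=float(lambda_beta),
        residual_variance=float(resid @ resid / max(n - 1, 1)),
    )


def _lambda_max(Z, target, penalized) -> float:
    """Smallest penalty that zeroes every penalized coefficient, after
    partialling the unpenalized columns out of the target."""
    n = len(target)
    U = Z[:, ~penalized]
    r = target
    if U.shape[1]:
        coef, *_ = np.linalg.lstsq(U, target, rcond=None)
        r = target - U @ coef
    grad = np.abs(Z[:, penalized].T @ r) / n
    return float(grad.max()) if grad.size else 0.0


def _path_fits(Z, target, pen_factors, lambdas, tol=1e-7, max_iter=100_000):
    """Warm-started coordinate-descent fits along a decreasing path."""
    n, d = Z.shape
    G = Z.T @ Z / n
    c = Z.T @ target / n
    theta = np.zeros(d)
    out = []
    for lam in lambdas:
        theta = _coordinate_descent(G, c, pen_factors, lam, theta, tol, max_iter)
        out.append(theta.copy())
    return out


def select_lambda(
    i: int,
    X: np.ndarray,
    y: np.ndarray,
    method: str = "bic",
    n_lambdas: int = 50,
    lambda_min_ratio: float = 0.01,
    n_folds: int = 5,
    seed: int = 0,
    ebic_gamma: float = 0.5,
):
    """Choose the penalty level for one node regression.

    A single scalar is shared by the alpha and beta blocks and swept
    over ``n_lambdas`` log-spaced values from the null-solution penalty
    down to ``lambda_min_ratio`` times it.  ``"bic"`` (default,
    deterministic) minimizes the extended BIC
    n log(RSS/n) + k log n + 2 gamma k log d, with k the number of
    nonzero penalized coefficients and d the number of candidate
    columns; the extended term (gamma=0.5 by default, 0 recovers the
    classical BIC) guards against noise coefficients slipping in when
    many candidates compete, the standard choice for sparse
    neighborhood selection.  ``"cv"`` uses ``n_folds``-fold
    cross-validation with a fixed shuffle seed and the one-standard-error
    rule.  Returns ``(lambda_alpha, lambda_beta)``.
    """
    if method not in ("bic", "cv"):
        raise ValueError(f"unknown method {method!r}")
    Z, target, _, pen_a, pen_b = _node_design(i, X, y)
    n, d = Z.shape
    pen = pen_a + pen_b  # shared scalar across both blocks
    lam_max = _lambda_max(Z, target, pen > 0)
    if lam_max == 0:
        return 0.0, 0.0
    lambdas = np.geomspace(lam_max, lam_max * lambda_min_ratio, n_lambdas)

    if method == "bic":
        fits = _path_fits(Z, target, pen, lambdas)
        G = Z.T @ Z / n
        c = Z.T @ target / n
        tss = float(target @ target) / n
        unpen = np.flatnonzero(pen == 0)
        best, best_bic, seen = lambdas[0], np.inf, set()
        for lam, theta in zip(lambdas, fits):
            active = np.flatnonzero((pen > 0) & (np.abs(theta) > _NONZERO_TOL))
            key = tuple(active)
            if key in seen:
                continue
            seen.add(key)
            # score the support by an unpenalized refit: shrinkage-free
            # RSS keeps correlated columns from sneaking in at small lam
            cols = np.concatenate([unpen, active]).astype(int)
            live = np.diag(G)[cols] > 0
            cols = cols[live]
            theta_ols = np.linalg.lstsq(G[np.ix_(cols, cols)], c[cols], rcond=None)[0]
            rss_n = max(tss - c[cols] @ theta_ols, 1e-300)
            k = len(active)
            bic = n * np.log(rss_n) + k * np.log(n) + 2.0 * ebic_gamma * k * np.log(d)
            if bic < best_bic - 1e-12:
                best, best_bic = lam, bic
        return float(best), float(best)

    rng = np.random.default_rng(seed)
    idx = rng.permutation(n)
    folds = np.array_split(idx, n_folds)
    mse = np.zeros((n_folds, len(lambdas)))
    for f, test in enumerate(folds):
        train = np.setdiff1d(idx, test)
        fits = _path_fits(Z[train], target[train], pen, lambdas)
        for li, theta in enumerate(fits):
            err = target[test] - Z[test] @ theta
            mse[f, li] = float(err @ err) / len(test)
    mean = mse.mean(axis=0)
    se = mse.std(axis=0, ddof=1) / np.sqrt(n_folds)
    best_i = int(np.argmin(mean))
    bound = mean[best_i] + se[best_i]
    # largest lambda (earliest on the decreasing path) within one SE
    one_se_i = int(np.flatnonzero(mean <= bound)[0])
    lam = float(lambdas[one_se_i])
    return lam, lam


def build_networks(
    X: np.ndarray,
    y: np.ndarray,
    feature_ids,
    symmetrize: str = "or",
    lambda_method: str = "bic",
    seed: int = 0,
) -> NetworkPair:
    """Run every node regression and assemble the two networks.

    For each unordered pair (i, j), an edge enters the common network
    when alpha_ij or alpha_ji is nonzero ("or" rule, the neighborhood-
    selection default; "and" requires both), with weight the mean of the
    nonzero estimates; the differential network is assembled the same
    way from the beta blocks.
    """
    if symmetrize not in ("or", "and"):
        raise ValueError(f"unknown symmetrize rule {symmetrize!r}")
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    feature_ids = tuple(str(f) for f in feature_ids)
    if len(feature_ids) != p:
        raise ValueError("feature_ids length mismatch")
    if n < 10:
        raise ValueError("need at least 10 samples for network inference")

    alpha_hat = np.zeros((p, p))
    beta_hat = np.zeros((p, p))
    for i in range(p):
        la, lb = select_lambda(i, X, y, method=lambda_method, seed=seed)
        fit = node_lasso(i, X, y, la, lb)
        others = np.delete(np.arange(p), i)
        alpha_hat[i, others] = fit.alpha
        beta_hat[i, others] = fit.beta

    def _symmetrize(coef):
        edges = []
        for i in range(p):
            for j in range(i + 1, p):
                a, b = coef[i, j], coef[j, i]
                nz_a, nz_b = abs(a) > _NONZERO_TOL, abs(b) > _NONZERO_TOL
                keep = (nz_a or nz_b) if symmetrize == "or" else (nz_a and nz_b)
                if keep:
                    vals = [v for v, nz in ((a, nz_a), (b, nz_b)) if nz]
                    edges.append((feature_ids[i], feature_ids[j], float(np.mean(vals))))
        return tuple(edges)

    return NetworkPair(
        nodes=feature_ids,
        common_edges=_symmetrize(alpha_hat),
        diff_edges=_symmetrize(beta_hat),
    )


def _graph(nodes, edges) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(nodes)
    g.add_weighted_edges_from(edges)
    return g


def extract_module(
    net: NetworkPair,
    seed_node: str,
    mode: str = "component",
    upregulated: dict | None = None,
) -> Subnetwork:
    """Pull the seed metabolite's module out of the differential network.

    ``"component"`` returns the connected component containing the seed;
    ``"radius1"`` the seed plus its direct neighbors.  ``upregulated``
    maps node -> bool (e.g. volcano-selected with fold change > 1) and
    is joined onto the module nodes.
    """
    if seed_node not in net.nodes:
        raise KeyError(f"seed node {seed_node!r} not in network")
    if mode not in ("component", "radius1"):
        raise ValueError(f"unknown mode {mode!r}")
    g = _graph(net.nodes, net.diff_edges)
    if mode == "component":
        members = nx.node_connected_component(g, seed_node)
    else:
        members = {seed_node} | set(g.neighbors(seed_node))
    sub = g.subgraph(members)
    flags = {n: bool((upregulated or {}).get(n, False)) for n in members}
    return Subnetwork(
        seed_node=seed_node,
        nodes=tuple(sorted(members)),
        edges=tuple((a, b, float(w)) for a, b, w in sub.edges.data("weight")),
        upregulated=flags,
    )


def export_network(obj, fmt: str, path) -> None:
    """Write a network or subnetwork for Cytoscape.

    ``"sif"``: one line per edge ``nodeA <tag> nodeB`` where the tag is
    ``common``/``diff`` (or ``module`` for a subnetwork); isolated nodes
    are listed one per line.  ``"graphml"``: standard XML with edge
    ``weight``/``layer`` and node ``upregulated`` attributes.
    """
    if fmt not in ("sif", "graphml"):
        raise ValueError(f"unknown format {fmt!r}")

    if isinstance(obj, NetworkPair):
        layers = [("common", obj.common_edges), ("diff", obj.diff_edges)]
        nodes = obj.nodes
        flags = {}
    elif isinstance(obj, Subnetwork):
        layers = [("module", obj.edges)]
        nodes = obj.nodes
        flags = obj.upregulated
    else:
        raise TypeError("expected NetworkPair or Subnetwork")

    if fmt == "sif":
        touched = set()
        lines = []
        for tag, edges in layers:
            for a, b, _ in edges:
                lines.append(f"{a}\t{tag}\t{b}")
                touched.update((a, b))
        lines.extend(n for n in nodes if n not in touched)
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")
        return

    g = nx.Graph()
    for n in nodes:
        g.add_node(n, upregulated=bool(flags.get(n, False)))
    for tag, edges in layers:
        for a, b, w in edges:
            g.add_edge(a, b, weight=float(w), layer=tag)
    nx.write_graphml(g, path)


def read_sif(path):
    """Read a SIF file back as (nodes, edges) with edges as
    (node_a, tag, node_b) triples."""
    nodes, edges = set(), []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) == 1 and parts[0]:
                nodes.add(parts[0])
            elif len(parts) == 3:
                a, tag, b = parts
                nodes.update((a, b))
                edges.append((a, tag, b))
    return nodes, edges
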