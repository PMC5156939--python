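"""Synthetic two-group metabolomics cohorts with known ground truth.

The generator emulates an untargeted GC-MS urine study: a case/control
cohort (defaults: 42 cases, 21 controls), 490 features of which 200 are
library-annotated ("known") and 290 are unidentified ``Unknown BB_*``
signals, planted log2 fold changes on chosen features, and group-specific
partial-correlation structure encoded by a pair of sparse precision
matrices.  The two precisions share a set of *common* edges; the case
precision carries additional *differential* edges absent from the
control precision.  Log2 intensities are drawn group-wise from the
corresponding multivariate normal and returned on the linear intensity
scale so that downstream log2 transformation is exercised.

Ground truth (planted effects and edge supports) is returned alongside
the data for recovery testing of the univariate screen and the sparse
local graphical model.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .containers import KNOWN, UNKNOWN, AbundanceMatrix

__all__ = [
    "InvalidSpecError",
    "SyntheticSpec",
    "GroundTruth",
    "Table1Fixture",
    "make_precision_pair",
    "generate_dataset",
    "table1_fixture",
    "write_ground_truth",
    "edge_recovery",
]


class InvalidSpecError(ValueError):
    """Raised when a :class:`SyntheticSpec` is internally inconsistent."""


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic cohort generator.

    Attributes
    ----------
    n_case, n_control
        Group sizes; defaults mirror a 42-case / 21-control cohort.
    p_known, p_unknown
        Counts of annotated and unidentified features (defaults 200/290).
    effects
        ``(feature_index, log2_fold_change)`` pairs planted as case-group
        mean shifts on the log2 scale.
    n_common_edges, n_diff_edges
        Numbers of planted partial-correlation edges shared by both
        groups and present only in the case group, respectively.  Edges
        are planted among annotated features (the network stage models
        annotated metabolites only).
    edge_strength
        Magnitude of planted off-diagonal precision entries, in (0, 1).
        After diagonal loading the implied absolute partial correlation
        is at most this value.
    base_intensity
        Linear-scale location: output is ``base_intensity * 2**z`` for
        log2-scale draws ``z``.
    noise_sd
        Optional multiplicative technical noise, expressed as an extra
        independent normal SD on the log2 scale (default 0 = off).
    seed
        Seed for all randomness; identical spec + seed gives bitwise
        identical output.
    """

    n_case: int = 42
    n_control: int = 21
    p_known: int = 200
    p_unknown: int = 290
    effects: tuple = ()
    n_common_edges: int = 0
    n_diff_edges: int = 0
    edge_strength: float = 0.3
    base_intensity: float = 1000.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "effects", tuple((int(i), float(f)) for i, f in self.effects))
        if self.n_case < 2 or self.n_control < 2:
            raise InvalidSpecError("need at least 2 samples per group")
        if self.p_known + self.p_unknown < 2:
            raise InvalidSpecError("need at least 2 features")
        if self.p_known < 0 or self.p_unknown < 0:
            raise InvalidSpecError("feature counts must be non-negative")
        if not 0 < self.edge_strength < 1:
            raise InvalidSpecError("edge_strength must lie in (0, 1)")
        if self.base_intensity <= 0:
            raise InvalidSpecError("base_intensity must be positive")
        if self.noise_sd < 0:
            raise InvalidSpecError("noise_sd must be non-negative")
        if self.n_common_edges < 0 or self.n_diff_edges < 0:
            raise InvalidSpecError("edge counts must be non-negative")
        idx = [i for i, _ in self.effects]
        if len(set(idx)) != len(idx):
            raise InvalidSpecError("effect feature indices must be unique")
        if any(i < 0 or i >= self.p_total for i in idx):
            raise InvalidSpecError("effect feature index out of range")
        pool = self.p_known if self.p_known >= 2 else self.p_total
        capacity = pool * (pool - 1) // 2
        if self.n_common_edges + self.n_diff_edges > capacity:
            raise InvalidSpecError(
                f"{self.n_common_edges + self.n_diff_edges} edges requested but only "
                f"{capacity} pairs available"
            )

    @property
    def p_total(self) -> int:
        return self.p_known + self.p_unknown

    def feature_ids(self) -> tuple:
        known = [f"met_{i + 1:04d}" for i in range(self.p_known)]
        unknown = [f"Unknown BB_{10001 + i}" for i in range(self.p_unknown)]
        return tuple(known + unknown)

    def annotation(self) -> tuple:
        return tuple([KNOWN] * self.p_known + [UNKNOWN] * self.p_unknown)


@dataclass(frozen=True)
class GroundTruth:
    """Planted truths behind one generated dataset."""

    true_log2fc: np.ndarray
    common_edges: frozenset
    diff_edges: frozenset
    precision_control: np.ndarray
    precision_case: np.ndarray


@dataclass(frozen=True)
class Table1Fixture:
    """The 30 published screening rows (see :mod:`uromet._table1`)."""

    rows: tuple
    m_total: int

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            list(self.rows), columns=["num", "name", "fold_change", "p_value", "fdr"]
        )

    @property
    def p_values(self) -> np.ndarray:
        return np.array([r[3] for r in self.rows])

    @property
    def annotated_rows(self) -> tuple:
        return tuple(r for r in self.rows if not r[1].startswith("Unknown"))


def _load_diagonals(omega0: np.ndarray, omega1: np.ndarray, margin: float) -> None:
    """Raise each diagonal entry to the larger of the two matrices'
    absolute off-diagonal row sums plus ``margin`` whenever it falls
    short (strict diagonal dominance, hence positive definiteness,
    without touching planted supports).

    The *same* loaded diagonal is written into both matrices so that
    the group-wise conditional regressions differ only at the planted
    differential off-diagonal supports, keeping the ground truth
    unambiguous.
    """
    def _off(om):
        return np.abs(om).sum(axis=1) - np.abs(np.diag(om))

    need = np.maximum(_off(omega0), _off(omega1)) + margin
    diag = np.maximum(np.diag(omega0), np.diag(omega1))
    loaded = np.maximum(diag, need)
    np.fill_diagonal(omega0, loaded)
    np.fill_diagonal(omega1, loaded)


def make_precision_pair(spec: SyntheticSpec, margin: float = 0.1):
    """Build the (control, case) precision matrices for a spec.

    Both matrices share ``n_common_edges`` off-diagonal supports with
    entries of magnitude ``edge_strength`` and random sign; the case
    matrix additionally carries ``n_diff_edges`` supports.  Positive
    definiteness is enforced by diagonal loading, which preserves the
    planted off-diagonal supports exactly.
    """
    rng = np.random.default_rng(spec.seed)
    p = spec.p_total
    pool = range(spec.p_known) if spec.p_known >= 2 else range(p)
    pairs = list(itertools.combinations(pool, 2))
    n_edges = spec.n_common_edges + spec.n_diff_edges
    chosen = [pairs[k] for k in rng.choice(len(pairs), size=n_edges, replace=False)] if n_edges else []
    common = chosen[: spec.n_common_edges]
    diff = chosen[spec.n_common_edges :]

    omega0 = np.eye(p)
    for i, j in common:
        s = spec.edge_strength * rng.choice((-1.0, 1.0))
        omega0[i, j] = omega0[j, i] = s
    omega1 = omega0.copy()
    for i, j in diff:
        s = spec.edge_strength * rng.choice((-1.0, 1.0))
        omega1[i, j] = omega1[j, i] = s

    _load_diagonals(omega0, omega1, margin)
    return omega0, omega1


def generate_dataset(spec: SyntheticSpec):
    """Draw one cohort; returns ``(AbundanceMatrix, GroundTruth)``.

    Log2 intensities are multivariate normal per group with the group's
    precision matrix; case means are shifted by the planted log2 fold
    changes.  The returned matrix is on the linear scale,
    ``base_intensity * 2**z``, hence strictly positive.  Cases are
    listed first (labels 1), controls after (labels 0).
    """
    omega0, omega1 = make_precision_pair(spec)
    # reuse the spec seed stream past the edge draws so one seed fixes everything
    rng = np.random.default_rng((spec.seed, 1))

    p = spec.p_total
    true_log2fc = np.zeros(p)
    for i, f in spec.effects:
        true_log2fc[i] = f

    cov0 = np.linalg.inv(omega0)
    cov1 = np.linalg.inv(omega1)
    chol0 = np.linalg.cholesky(cov0)
    chol1 = np.linalg.cholesky(cov1)
    z_case = rng.standard_normal((spec.n_case, p)) @ chol1.T + true_log2fc
    z_ctrl = rng.standard_normal((spec.n_control, p)) @ chol0.T
    z = np.vstack([z_case, z_ctrl])
    if spec.noise_sd > 0:
        z = z + rng.normal(0.0, spec.noise_sd, size=z.shape)

    values = spec.base_intensity * np.exp2(z)
    sample_ids = [f"IC_{i + 1:03d}" for i in range(spec.n_case)] + [
        f"CTRL_{i + 1:03d}" for i in range(spec.n_control)
    ]
    y = np.array([1] * spec.n_case + [0] * spec.n_control)

    matrix = AbundanceMatrix(
        values=values,
        sample_ids=tuple(sample_ids),
        feature_ids=spec.feature_ids(),
        annotation=spec.annotation(),
        y=y,
        scale="linear",
    )

    def _offdiag_pairs(om):
        ii, jj = np.nonzero(np.triu(om, k=1))
        return {(int(a), int(b)) for a, b in zip(ii, jj)}

    sup0 = _offdiag_pairs(omega0)
    sup1 = _offdiag_pairs(omega1)
    truth = GroundTruth(
        true_log2fc=true_log2fc,
        common_edges=frozenset(sup0 & sup1),
        diff_edges=frozenset(sup1 ^ sup0),
        precision_control=omega0,
        precision_case=omega1,
    )
    return matrix, truth


def table1_fixture() -> Table1Fixture:
    """Return the packaged 30-row published screening table."""
    from . import _table1

    return Table1Fixture(rows=tuple(_table1.ROWS), m_total=_table1.M_TOTAL)


def edge_recovery(found_edges, true_pairs, feature_ids):
    """Recall and precision of recovered edges against planted pairs.

    ``found_edges`` are ``(id_a, id_b, weight)`` triples as produced by
    the network stage; ``true_pairs`` are unordered feature-index pairs
    from a :class:`GroundTruth`.  Precision is 1 when nothing was found.
    """
    id2i = {f: i for i, f in enumerate(feature_ids)}
    found = {frozenset((id2i[a], id2i[b])) for a, b, _ in found_edges}
    true = {frozenset(p) for p in true_pairs}
    tp = len(found & true)
    recall = tp / len(true) if true else 1.0
    precision = tp / len(found) if found else 1.0
    return recall, precision


def write_ground_truth(truth: GroundTruth, feature_ids, effects_path, edges_path) -> None:
    """Serialize planted effects and edge supports as plain-text tables."""
    import pandas as pd

    fids = list(feature_ids)
    pd.DataFrame(
        {"feature_id": fids, "log2fc": truth.true_log2fc}
    ).to_csv(effects_path, sep="\t", index=False)

    rows = []
    for layer, edges, omega in (
        ("common", truth.common_edges, truth.precision_control),
        ("diff", truth.diff_edges, truth.precision_case),
    ):
        for i, j in sorted(edges):
            rows.append((fids[i], fids[j], layer, omega[i, j]))
    pd.DataFrame(rows, columns=["feature_a", "feature_b", "layer", "precision_entry"]).to_csv(
        edges_path, sep="\t", index=False
    )
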