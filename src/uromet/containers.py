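"""Core in-memory container for two-group metabolomics feature tables.

An :class:`AbundanceMatrix` holds a samples x features intensity matrix
together with sample identifiers, feature identifiers, a per-feature
annotation flag (``known`` for library-matched metabolites, ``unknown``
for unidentified signals) and a binary group label per sample
(1 = case, 0 = control).

All pipeline operations treat the container as immutable: they return a
new instance and never write into the caller's arrays.  The underlying
numpy arrays are marked read-only to enforce this.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = ["AbundanceMatrix"]

#: Allowed values of the per-feature annotation flag.
KNOWN = "known"
UNKNOWN = "unknown"


def _frozen_array(a, dtype=float) -> np.ndarray:
    out = np.array(a, dtype=dtype)
    out.setflags(write=False)
    return out


@dataclass(frozen=True)
class AbundanceMatrix:
    """Samples x features intensity matrix with group labels.

    Parameters
    ----------
    values
        ``(n_samples, n_features)`` matrix.  On the ``linear`` scale all
        entries must be strictly positive; ``log2`` and ``autoscaled``
        matrices are unconstrained.
    sample_ids, feature_ids
        Unique identifiers for rows and columns.
    annotation
        Per-feature flag, ``"known"`` or ``"unknown"``.
    y
        Per-sample binary label, 1 = case, 0 = control.
    scale
        Bookkeeping tag: ``"linear"``, ``"log2"`` or ``"autoscaled"``.
        Operations that only make sense on one scale check it.
    """

    values: np.ndarray
    sample_ids: tuple
    feature_ids: tuple
    annotation: tuple
    y: np.ndarray
    scale: str = "linear"

    def __post_init__(self):
        object.__setattr__(self, "values", _frozen_array(self.values))
        object.__setattr__(self, "y", _frozen_array(self.y, dtype=int))
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        object.__setattr__(self, "feature_ids", tuple(str(f) for f in self.feature_ids))
        object.__setattr__(self, "annotation", tuple(self.annotation))

        n, p = self.values.shape
        if len(self.sample_ids) != n:
            raise ValueError(f"{len(self.sample_ids)} sample ids for {n} rows")
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample ids")
        if len(self.feature_ids) != p:
            raise ValueError(f"{len(self.feature_ids)} feature ids for {p} columns")
        if len(set(self.feature_ids)) != p:
            raise ValueError("duplicate feature ids")
        if len(self.annotation) != p:
            raise ValueError("annotation length mismatch")
        bad = set(self.annotation) - {KNOWN, UNKNOWN}
        if bad:
            raise ValueError(f"invalid annotation values: {sorted(bad)}")
        if self.y.shape != (n,):
            raise ValueError("y length mismatch")
        if not np.isin(self.y, (0, 1)).all():
            raise ValueError("y must be binary 0/1")
        if self.scale not in ("linear", "log2", "autoscaled"):
            raise ValueError(f"unknown scale tag {self.scale!r}")
        if self.scale == "linear" and not (self.values > 0).all():
            raise ValueError("linear-scale intensities must be strictly positive")

    # -- basic geometry -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def case_mask(self) -> np.ndarray:
        return self.y == 1

    @property
    def control_mask(self) -> np.ndarray:
        return self.y == 0

    @property
    def known_mask(self) -> np.ndarray:
        return np.array([a == KNOWN for a in self.annotation])

    def require_scale(self, scale: str, op: str) -> None:
        if self.scale != scale:
            raise ValueError(f"{op} expects a {scale}-scale matrix, got {self.scale!r}")

    def require_both_groups(self) -> None:
        if self.case_mask.sum() == 0 or self.control_mask.sum() == 0:
            raise ValueError("both groups must be non-empty")

    # -- derived views --------------------------------------------------
    def with_values(self, values: np.ndarray, scale: str | None = None) -> "AbundanceMatrix":
        return replace(self, values=values, scale=scale or self.scale)

    def select_samples(self, index: Sequence[int] | np.ndarray) -> "AbundanceMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return replace(
            self,
            values=self.values[index],
            sample_ids=tuple(self.sample_ids[i] for i in index),
            y=self.y[index],
        )

    def select_features(self, index: Sequence[int] | np.ndarray) -> "AbundanceMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return replace(
            self,
            values=self.values[:, index],
            feature_ids=tuple(self.feature_ids[i] for i in index),
            annotation=tuple(self.annotation[i] for i in index),
        )

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            self.values, index=list(self.sample_ids), columns=list(self.feature_ids)
        )
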