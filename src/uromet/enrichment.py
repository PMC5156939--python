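"""Over-representation analysis of metabolite lists (MSEA-style).

Given a query list of metabolites (e.g. a differential-network module),
a measured universe, and a named metabolite-set library (GMT format),
each set is scored with the hypergeometric upper tail
P(X >= k) for the observed overlap k, followed by Benjamini-Hochberg
adjustment across the sets that intersect the universe.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .univariate import bh_adjust

__all__ = ["MetaboliteSetLibrary", "read_gmt", "write_gmt", "ora"]


@dataclass(frozen=True)
class MetaboliteSetLibrary:
    """Named, non-empty metabolite sets with unique names."""

    sets: dict          # name -> frozenset of member ids
    descriptions: dict  # name -> free-text description

    def __post_init__(self):
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"set {name!r} is empty")


def read_gmt(path) -> MetaboliteSetLibrary:
    """Parse a GMT file: ``name<TAB>description<TAB>member...`` per line.

    Duplicate members within a set are deduplicated; a duplicate set
    name or a line with fewer than three fields is an error naming the
    line number.
    """
    sets, desc = {}, {}
    with open(path) as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}: line {ln}: expected name, description, members")
            name, description, *members = parts
            if name in sets:
                raise ValueError(f"{path}: line {ln}: duplicate set name {name!r}")
            members = frozenset(m for m in members if m)
            if not members:
                raise ValueError(f"{path}: line {ln}: set {name!r} has no members")
            sets[name] = members
            desc[name] = description
    return MetaboliteSetLibrary(sets=sets, descriptions=desc)


def write_gmt(library: MetaboliteSetLibrary, path) -> None:
    with open(path, "w") as fh:
        for name, members in library.sets.items():
            desc = library.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *sorted(members)]) + "\n")


def ora(query, universe, library: MetaboliteSetLibrary) -> pd.DataFrame:
    """Hypergeometric over-representation analysis.

    ``query`` must be contained in ``universe``; each library set is
    intersected with the universe before testing.  Per set with K
    universe members and overlap k with the n-element query drawn from
    the N-element universe, p = P(X >= k).  BH adjustment runs across
    the sets with nonzero universe intersection.  Results are sorted by
    p-value.
    """
    query = set(query)
    universe = set(universe)
    extra = query - universe
    if extra:
        raise ValueError(f"query metabolites outside the universe: {sorted(extra)[:5]}")
    N, n = len(universe), len(query)

    rows = []
    for name, members in library.sets.items():
        in_universe = members & universe
        K = len(in_universe)
        if K == 0:
            continue
        k = len(in_universe & query)
        # upper tail P(X >= k); survival function is P(X > k-1)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if k > 0 else 1.0
        rows.append((name, k, K, n, N, min(p, 1.0)))

    out = pd.DataFrame(
        rows, columns=["set_name", "overlap", "set_size", "query_size", "universe_size", "p_value"]
    )
    if len(out):
        out["p_adjusted"] = bh_adjust(out["p_value"].to_numpy())
        out = out.sort_values("p_value", kind="stable").reset_index(drop=True)
    else:
        out["p_adjusted"] = []
    return out
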