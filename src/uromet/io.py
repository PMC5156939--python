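"""Reading and writing the feature-table dialect used throughout.

Matrices travel as CSV/TSV with sample IDs in the first column and
feature IDs in the header; group membership comes either from a
``group`` column inside the matrix file or from a separate two-column
metadata file (``sample_id``, ``group``) with groups coded ``1``/``0``
or ``IC``/``control``.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .containers import KNOWN, UNKNOWN, AbundanceMatrix

__all__ = ["read_abundance", "write_abundance"]

_GROUP_CODES = {"1": 1, "0": 0, "ic": 1, "case": 1, "control": 0, "ctrl": 0}


def _sep_for(path) -> str:
    return "\t" if str(path).endswith((".tsv", ".txt")) else ","


def _parse_group(value, sample_id):
    code = _GROUP_CODES.get(str(value).strip().lower())
    if code is None:
        raise ValueError(f"unrecognized group {value!r} for sample {sample_id!r}")
    return code


def read_abundance(path, metadata_path=None) -> AbundanceMatrix:
    """Load a feature table (and optional sample metadata file).

    Raises on duplicate sample IDs, non-numeric cells (named by
    coordinates), and samples missing from the metadata.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0, dtype=str)
    df.index = df.index.astype(str)
    if df.index.duplicated().any():
        dupes = sorted(set(df.index[df.index.duplicated()]))
        raise ValueError(f"duplicate sample IDs: {dupes}")

    if metadata_path is not None:
        meta = pd.read_csv(metadata_path, sep=_sep_for(metadata_path), dtype=str)
        meta.columns = [c.strip().lower() for c in meta.columns]
        meta = meta.set_index(meta.columns[0])
        missing = [s for s in df.index if s not in meta.index]
        if missing:
            raise ValueError(f"samples missing from metadata: {missing}")
        groups = [meta.loc[s].iloc[0] for s in df.index]
    else:
        if "group" not in df.columns:
            raise ValueError("no metadata file and no 'group' column in the matrix")
        groups = df.pop("group").tolist()

    y = np.array([_parse_group(g, s) for g, s in zip(groups, df.index)])

    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        try:
            values[:, j] = pd.to_numeric(df[col], errors="raise")
        except (ValueError, TypeError):
            bad = df[col].apply(lambda v: pd.to_numeric(v, errors="coerce")).isna()
            i = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"non-numeric cell at sample {df.index[i]!r}, feature {col!r}: "
                f"{df[col].iloc[i]!r}"
            ) from None

    annotation = tuple(
        UNKNOWN if str(c).startswith("Unknown") else KNOWN for c in df.columns
    )
    return AbundanceMatrix(
        values=values,
        sample_ids=tuple(df.index),
        feature_ids=tuple(df.columns),
        annotation=annotation,
        y=y,
        scale="linear",
    )


def write_abundance(M: AbundanceMatrix, path, metadata_path=None) -> None:
    """Write the matrix (and metadata: separate file if a path is given,
    otherwise an embedded ``group`` column)."""
    path = Path(path)
    df = M.to_frame()
    if metadata_path is None:
        df.insert(0, "group", M.y)
    df.index.name = "sample_id"
    df.to_csv(path, sep=_sep_for(path))
    if metadata_path is not None:
        pd.DataFrame({"sample_id": list(M.sample_ids), "group": M.y}).to_csv(
            metadata_path, sep=_sep_for(metadata_path), index=False
        )
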