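"""Readers and writers for the delimited-text interchange formats.

Phenotypes: TSV with columns ``line``, ``env``, optional ``rep``, and an
integer ordinal response ``y``.  Markers: TSV with line ids in the first
column and one numeric column per marker.  Relationship override: square TSV
with line ids as both header and first column.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .design import MarkerMatrix, Relationship, psd_sqrt

__all__ = ["read_phenotypes", "read_markers", "read_relationship",
           "write_markers", "write_phenotypes"]


def read_phenotypes(path: str | Path) -> tuple[pd.DataFrame, dict[int, int]]:
    """Read the phenotype table and relabel categories to contiguous 1..C.

    Returns the table (row order preserved; ``y`` replaced by contiguous
    codes) and the mapping from original category values to the new codes.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("line", "env", "y"):
        if col not in df.columns:
            raise ValueError(f"phenotype file lacks required column {col!r}")
    y_raw = pd.to_numeric(df["y"], errors="coerce")
    bad = y_raw.isna() | (y_raw != y_raw.round())
    if bad.any():
        row = int(np.flatnonzero(bad)[0])
        raise ValueError(
            f"non-integer response {df['y'].iloc[row]!r} at data row {row + 1}")
    y_int = y_raw.astype(int)
    levels = sorted(y_int.unique())
    mapping = {orig: c + 1 for c, orig in enumerate(levels)}
    out = df.copy()
    out["y"] = y_int.map(mapping)
    return out, mapping


def read_markers(path: str | Path) -> MarkerMatrix:
    """Read a raw (unscaled) marker matrix; missing cells are rejected."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate line id {dup!r} in marker file")
    arr = df.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    if np.isnan(arr).any():
        i, j = np.argwhere(np.isnan(arr))[0]
        raise ValueError(
            f"missing/non-numeric marker value at line {df.index[i]!r}, "
            f"marker {df.columns[j]!r}; impute before import")
    return MarkerMatrix(values=arr,
                        line_ids=list(df.index.astype(str)),
                        marker_ids=list(df.columns.astype(str)))


def read_relationship(path: str | Path) -> Relationship:
    """Read a precomputed square relationship matrix (e.g. pedigree-based)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index.astype(str)) != list(df.columns.astype(str)):
        raise ValueError("relationship matrix rows and columns must match")
    G = df.to_numpy(dtype=float)
    G = (G + G.T) / 2.0
    return Relationship(G=G, sqrt_G=psd_sqrt(G),
                        line_ids=list(df.index.astype(str)), q=0)


def write_markers(markers: MarkerMatrix | np.ndarray, path: str | Path,
                  line_ids=None, marker_ids=None) -> None:
    if isinstance(markers, MarkerMatrix):
        df = pd.DataFrame(markers.values, index=markers.line_ids,
                          columns=markers.marker_ids)
    else:
        df = pd.DataFrame(np.asarray(markers), index=line_ids,
                          columns=marker_ids)
    df.index.name = "line"
    df.to_csv(path, sep="\t", float_format="%.10g")


def write_phenotypes(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)
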