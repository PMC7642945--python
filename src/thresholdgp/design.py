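"""Genomic design construction.

Builds the fixed-effect design matrix used by the ordinal threshold model:
marker standardisation, the genomic relationship matrix (GRM) ``G = W W' / q``,
its positive semi-definite square root, and the E / G / GE / A / Rep predictor
blocks.

The G block is the line-incidence matrix post-multiplied by the matrix square
root of G.  This converts a correlated genetic random effect with covariance
``sigma^2 * G`` into independent ridge coefficients: if ``u = sqrt(G) b`` with
``b ~ N(0, sigma^2 I)`` then ``Cov(u) = sigma^2 G``.  The GE block is the
row-wise (face-splitting) product of the E and G blocks, whose implied
covariance kernel is the Hadamard product of the environment and genomic
kernels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MarkerMatrix",
    "Relationship",
    "DesignSpec",
    "DesignMatrix",
    "scale_markers",
    "compute_grm",
    "psd_sqrt",
    "build_design",
]

# Blocks based on the genomic relationship (G) and, analogously, on a
# pedigree/additive relationship (A).  Rep blocks use replicate indicators.
KNOWN_BLOCKS = ("E", "G", "GE", "A", "AE", "Rep", "ERep", "GRep", "ARep")


@dataclass
class MarkerMatrix:
    """Numeric marker matrix (lines x markers) with row/column labels."""

    values: np.ndarray
    line_ids: list[str]
    marker_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("marker matrix must be two-dimensional")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("marker matrix contains missing/non-finite entries")
        if len(self.line_ids) != len(set(self.line_ids)):
            raise ValueError("duplicate line ids in marker matrix")
        if self.values.shape != (len(self.line_ids), len(self.marker_ids)):
            raise ValueError("marker matrix shape does not match labels")

    @property
    def n_lines(self) -> int:
        return self.values.shape[0]

    @property
    def n_markers(self) -> int:
        return self.values.shape[1]


@dataclass
class Relationship:
    """A relationship matrix among lines together with its PSD square root."""

    G: np.ndarray
    sqrt_G: np.ndarray
    line_ids: list[str]
    q: int = 0


@dataclass
class DesignSpec:
    """Ordered predictor blocks and a per-block penalisation flag.

    ``penalized`` maps block name -> bool; blocks absent from the mapping
    default to penalised (ridge/normal prior).  Unpenalised blocks receive the
    flat-prior coefficient update.
    """

    blocks: list[str]
    penalized: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ValueError("at least one design block is required")
        if len(self.blocks) != len(set(self.blocks)):
            raise ValueError("duplicate block names")
        for b in self.blocks:
            if b not in KNOWN_BLOCKS:
                raise ValueError(f"unknown block {b!r}; choose from {KNOWN_BLOCKS}")

    @classmethod
    def parse(cls, text: str, unpenalized: tuple[str, ...] = ()) -> "DesignSpec":
        """Parse a '+'-separated block string such as ``"E+G+GE"``."""
        blocks = [b.strip() for b in text.split("+") if b.strip()]
        pen = {b: b not in unpenalized for b in blocks}
        return cls(blocks=blocks, penalized=pen)

    def is_penalized(self, block: str) -> bool:
        return self.penalized.get(block, True)


@dataclass
class DesignMatrix:
    """Records x p design with per-column block labels and a record map."""

    X: np.ndarray
    column_block: list[str]
    record_map: pd.DataFrame  # columns: line, env (and rep when present)

    def __post_init__(self) -> None:
        if self.X.shape[1] != len(self.column_block):
            raise ValueError("column_block length must equal number of columns")

    @property
    def n_records(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def penalized_mask(self, spec: DesignSpec) -> np.ndarray:
        return np.array([spec.is_penalized(b) for b in self.column_block])


def scale_markers(raw: np.ndarray | pd.DataFrame,
                  line_ids: list[str] | None = None,
                  marker_ids: list[str] | None = None) -> MarkerMatrix:
    """Centre each marker column and scale it to unit variance.

    Zero-variance (monomorphic) columns carry no information and are removed.

    Returns
    -------
    MarkerMatrix
        The scaled matrix W with the retained marker ids.
    """
    if isinstance(raw, pd.DataFrame):
        line_ids = list(raw.index.astype(str)) if line_ids is None else line_ids
        marker_ids = list(raw.columns.astype(str)) if marker_ids is None else marker_ids
        raw = raw.to_numpy(dtype=float)
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 2 or raw.shape[0] < 1 or raw.shape[1] < 1:
        raise ValueError("marker matrix must have at least one line and one marker")
    if not np.all(np.isfinite(raw)):
        raise ValueError("marker matrix contains missing/non-finite entries")
    if line_ids is None:
        line_ids = [f"L{i + 1}" for i in range(raw.shape[0])]
    if marker_ids is None:
        marker_ids = [f"M{j + 1}" for j in range(raw.shape[1])]

    sd = raw.std(axis=0)  # population sd; any positive spread is informative
    keep = sd > 0
    if not keep.any():
        raise ValueError("no informative markers: all columns have zero variance")
    W = (raw[:, keep] - raw[:, keep].mean(axis=0)) / sd[keep]
    kept_ids = [m for m, k in zip(marker_ids, keep) if k]
    return MarkerMatrix(values=W, line_ids=list(line_ids), marker_ids=kept_ids)


def compute_grm(W: MarkerMatrix) -> Relationship:
    """Genomic relationship matrix ``G = W W' / q`` with q = number of markers."""
    q = W.n_markers
    if q == 0:
        raise ValueError("cannot build a relationship matrix from zero markers")
    G = W.values @ W.values.T / q
    G = (G + G.T) / 2.0
    return Relationship(G=G, sqrt_G=psd_sqrt(G), line_ids=list(W.line_ids), q=q)


def psd_sqrt(G: np.ndarray, clamp: float = 1e-10) -> np.ndarray:
    """Symmetric PSD square root of a symmetric matrix via eigendecomposition.

    Eigenvalues below ``clamp`` are treated as exactly zero (relationship
    matrices are rank-deficient whenever lines share identical markers).
    """
    G = np.asarray(G, dtype=float)
    if G.ndim != 2 or G.shape[0] != G.shape[1]:
        raise ValueError("matrix must be square")
    if np.max(np.abs(G - G.T)) > 1e-8:
        raise ValueError("matrix not symmetric")
    vals, vecs = np.linalg.eigh((G + G.T) / 2.0)
    if vals.min() < -1e-6:
        raise ValueError(f"matrix not PSD (min eigenvalue {vals.min():.3e})")
    vals = np.where(vals < clamp, 0.0, vals)
    S = (vecs * np.sqrt(vals)) @ vecs.T
    return (S + S.T) / 2.0


def _indicator(labels: pd.Series) -> tuple[np.ndarray, list[str]]:
    """0/1 incidence matrix for a categorical label, columns in sorted order."""
    cats = sorted(labels.astype(str).unique())
    idx = {c: j for j, c in enumerate(cats)}
    Z = np.zeros((len(labels), len(cats)))
    Z[np.arange(len(labels)), [idx[str(v)] for v in labels]] = 1.0
    return Z, cats


def _face_split(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Row-wise Khatri-Rao (face-splitting) product."""
    return (A[:, :, None] * B[:, None, :]).reshape(A.shape[0], -1)


def build_design(phenotypes: pd.DataFrame,
                 relationship: Relationship,
                 spec: DesignSpec,
                 pedigree: Relationship | None = None) -> DesignMatrix:
    """Assemble the design matrix for the requested predictor blocks.

    Parameters
    ----------
    phenotypes : DataFrame with columns ``line``, ``env`` and optionally ``rep``.
    relationship : genomic Relationship providing the G-block features.
    spec : ordered blocks to include.
    pedigree : optional second Relationship used for the A blocks.
    """
    for col in ("line", "env"):
        if col not in phenotypes.columns:
            raise ValueError(f"phenotype table lacks required column {col!r}")
    lines = phenotypes["line"].astype(str)
    known = set(relationship.line_ids)
    missing = sorted(set(lines) - known)
    if missing:
        raise ValueError(f"lines absent from relationship matrix: {missing[:5]}")

    if "GE" in spec.blocks and not ({"E", "G"} <= set(spec.blocks)):
        raise ValueError("GE block requires both E and G blocks")
    for b in ("A", "AE", "ARep"):
        if b in spec.blocks and pedigree is None:
            raise ValueError(f"block {b} requires a pedigree relationship")

    Z_env, env_cats = _indicator(phenotypes["env"])
    line_pos = {l: i for i, l in enumerate(relationship.line_ids)}
    Z_line = np.zeros((len(phenotypes), len(relationship.line_ids)))
    Z_line[np.arange(len(phenotypes)), [line_pos[l] for l in lines]] = 1.0
    X_G = Z_line @ relationship.sqrt_G

    X_A = None
    if pedigree is not None:
        apos = {l: i for i, l in enumerate(pedigree.line_ids)}
        miss = sorted(set(lines) - set(pedigree.line_ids))
        if miss:
            raise ValueError(f"lines absent from pedigree matrix: {miss[:5]}")
        Z_a = np.zeros((len(phenotypes), len(pedigree.line_ids)))
        Z_a[np.arange(len(phenotypes)), [apos[l] for l in lines]] = 1.0
        X_A = Z_a @ pedigree.sqrt_G

    Z_rep = None
    if any(b in spec.blocks for b in ("Rep", "ERep", "GRep", "ARep")):
        if "rep" not in phenotypes.columns:
            raise ValueError("Rep blocks require a 'rep' column in the phenotypes")
        Z_rep, _ = _indicator(phenotypes["rep"])

    pieces: list[np.ndarray] = []
    labels: list[str] = []
    for b in spec.blocks:
        if b == "E":
            M = Z_env
        elif b == "G":
            M = X_G
        elif b == "GE":
            M = _face_split(Z_env, X_G)
        elif b == "A":
            M = X_A
        elif b == "AE":
            M = _face_split(Z_env, X_A)
        elif b == "Rep":
            M = Z_rep
        elif b == "ERep":
            M = _face_split(Z_rep, Z_env)
        elif b == "GRep":
            M = _face_split(Z_rep, X_G)
        elif b == "ARep":
            M = _face_split(Z_rep, X_A)
        pieces.append(M)
        labels.extend([b] * M.shape[1])

    X = np.hstack(pieces)
    cols = ["line", "env"] + (["rep"] if "rep" in phenotypes.columns else [])
    record_map = phenotypes[cols].reset_index(drop=True)
    return DesignMatrix(X=X, column_block=labels, record_map=record_map)
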