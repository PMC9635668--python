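"""Signature catalogs, cosine similarity, and pattern clustering.

Reads COSMIC-style 96-row signature tables, compares spectra by cosine
similarity (1 for proportional patterns, 0 for disjoint support), ranks
catalog matches for a query pattern, and orders pattern sets by
average-linkage hierarchical clustering on 1 - cosine for heatmap
display.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform
from skbio import TreeNode

from .sbs import CHANNEL_LABELS, SbsSpectrum, channel_index


@dataclass
class SignatureCatalog:
    """Named 96-channel frequency vectors in canonical channel order."""

    names: list[str]
    vectors: np.ndarray  # shape (n_signatures, 96)

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.ndim != 2 or self.vectors.shape != (len(self.names), 96):
            raise ValueError("catalog vectors must be (n_signatures, 96)")
        if np.any(self.vectors < 0):
            raise ValueError("negative catalog entry")
        sums = self.vectors.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-6):
            bad = [self.names[i] for i in np.flatnonzero(np.abs(sums - 1) > 1e-6)]
            raise ValueError(f"catalog columns do not sum to 1: {bad}")

    def __len__(self) -> int:
        return len(self.names)

    def vector(self, name: str) -> np.ndarray:
        return self.vectors[self.names.index(name)]


def _channel_from_row(row: pd.Series, columns: list[str]) -> int:
    """Map a catalog row to its canonical channel index.

    Supports the single-column dialect ("A[C>A]A" in the first column)
    and the split "Type"/"Subtype" dialect ("C>A" + "ACA").
    """
    cols_lower = [c.lower() for c in columns]
    if "type" in cols_lower and "subtype" in cols_lower:
        sub = str(row[columns[cols_lower.index("type")]])
        ctx = str(row[columns[cols_lower.index("subtype")]])
        return channel_index(f"{ctx[0]}[{sub}]{ctx[2]}")
    return channel_index(str(row[columns[0]]))


def read_catalog(path: str | Path, normalize: bool = True) -> SignatureCatalog:
    """Read a COSMIC-style tab-separated signature table.

    The first column (or Type/Subtype pair) identifies the channel; every
    remaining numeric column is one signature. Rows may be in any order
    and are mapped onto the canonical channel order. Columns are
    renormalized to sum to 1 by default, so count-scale catalogs are
    accepted.
    """
    df = pd.read_csv(path, sep="\t")
    columns = list(df.columns)
    cols_lower = [c.lower() for c in columns]
    n_key = 2 if ("type" in cols_lower and "subtype" in cols_lower) else 1
    sig_cols = columns[n_key:]
    if not sig_cols:
        raise ValueError(f"no signature columns in {path}")
    if len(df) != 96:
        raise ValueError(f"expected 96 rows in {path}, found {len(df)}")
    vectors = np.zeros((len(sig_cols), 96))
    seen = np.zeros(96, dtype=bool)
    for _, row in df.iterrows():
        chan = _channel_from_row(row, columns)
        if seen[chan]:
            raise ValueError(f"duplicate channel {CHANNEL_LABELS[chan]} in {path}")
        seen[chan] = True
        vectors[:, chan] = [float(row[c]) for c in sig_cols]
    if not seen.all():
        raise ValueError(f"channels missing from {path}")
    if normalize:
        sums = vectors.sum(axis=1, keepdims=True)
        if np.any(sums <= 0):
            raise ValueError(f"zero-total signature column in {path}")
        vectors = vectors / sums
    return SignatureCatalog(names=[str(c) for c in sig_cols], vectors=vectors)


def write_catalog(catalog: SignatureCatalog, path: str | Path) -> None:
    df = pd.DataFrame(
        catalog.vectors.T, index=list(CHANNEL_LABELS), columns=catalog.names
    )
    df.to_csv(path, sep="\t", index_label="channel")


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """dot(a, b) / (||a|| * ||b||) for non-negative, nonzero vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if np.any(a < 0) or np.any(b < 0):
        raise ValueError("cosine similarity expects non-negative spectra")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(np.dot(a, b) / (na * nb))


def similarity_matrix(
    patterns: dict[str, np.ndarray] | list[tuple[str, np.ndarray]]
) -> pd.DataFrame:
    """Symmetric pairwise-cosine matrix with unit diagonal."""
    items = list(patterns.items()) if isinstance(patterns, dict) else list(patterns)
    if len(items) < 2:
        raise ValueError("similarity matrix requires at least 2 patterns")
    names = [n for n, _ in items]
    for name, vec in items:
        if np.linalg.norm(np.asarray(vec, dtype=float)) == 0:
            raise ValueError(f"zero pattern {name!r}")
    n = len(items)
    mat = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = cosine_similarity(items[i][1], items[j][1])
    return pd.DataFrame(mat, index=names, columns=names)


def best_matches(
    query: SbsSpectrum | np.ndarray, catalog: SignatureCatalog, k: int = 5
) -> list[tuple[str, float]]:
    """Top-k catalog signatures by cosine similarity to the query.

    Ties are broken by catalog order (stable sort on descending
    similarity).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(catalog) == 0:
        raise ValueError("empty catalog")
    vec = query.counts if isinstance(query, SbsSpectrum) else np.asarray(query)
    sims = [cosine_similarity(vec, catalog.vectors[i]) for i in range(len(catalog))]
    order = sorted(range(len(catalog)), key=lambda i: (-sims[i], i))
    return [(catalog.names[i], sims[i]) for i in order[:k]]


def cluster_order(
    matrix: pd.DataFrame,
) -> tuple[list[str], np.ndarray, TreeNode]:
    """Leaf order and dendrogram from average-linkage clustering.

    Clusters on distance 1 - similarity. Returns (ordered names, scipy
    linkage matrix, dendrogram as a scikit-bio tree — serializable to
    newick via ``tree.write``). Deterministic for a fixed input; the
    tree topology is invariant to input permutation.
    """
    mat = matrix.to_numpy(dtype=float)
    if mat.shape[0] != mat.shape[1] or not np.allclose(mat, mat.T, atol=1e-8):
        raise ValueError("similarity matrix must be square and symmetric")
    dist = 1.0 - mat
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    z = linkage(squareform(dist, checks=False), method="average")
    order = leaves_list(z)
    names = [str(matrix.index[i]) for i in order]
    tree = TreeNode.from_linkage_matrix(z, [str(n) for n in matrix.index])
    return names, z, tree
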