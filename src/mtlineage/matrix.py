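"""Variant-by-cell matrix algebra.

The central container is :class:`VariantCellMatrix`: a sparse cells x
variants matrix of consensus-molecule counts ``C`` with derived views —
heteroplasmy ``H`` (counts over per-position per-cell mtDNA copy number,
capped at 1) and the binarized ``C_bin`` used for all distance and
embedding computations.  Binarization deliberately discards heteroplasmy
magnitude: with sparse molecule sampling the binary carrier profile is the
more reliable signal.

Distances: the prior-weighted Jaccard distance down-weights recurrent
(homoplasic) mutations via per-variant priors (1 - average mutation rate
across donors); the TF-IDF/SVD (LSI) embedding provides a Euclidean
alternative for dense stem-cell subsets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.linalg import svds

__all__ = [
    "VariantCellMatrix",
    "binarize",
    "heteroplasmy",
    "weighted_jaccard",
    "lsi_embed",
    "LSIEmbedding",
    "connectedness",
]


@dataclass
class VariantCellMatrix:
    """Sparse cells x variants consensus-molecule count matrix.

    ``variants`` is a table with columns ``variant, pos, ref, alt``;
    ``coverage`` (optional) holds the molecule copy number per cell at each
    variant's position, enabling the heteroplasmy view.
    """

    C: sp.csr_matrix
    cells: list[str]
    variants: pd.DataFrame
    coverage: np.ndarray | None = None
    report: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.C.shape != (len(self.cells), len(self.variants)):
            raise ValueError("matrix shape inconsistent with sidecar id lists")
        if (self.C.data < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def shape(self):
        return self.C.shape

    @property
    def variant_ids(self) -> list[str]:
        return list(self.variants["variant"])

    def binarize(self, min_support: int = 1) -> sp.csr_matrix:
        return binarize(self.C, min_support)

    def heteroplasmy(self) -> np.ndarray:
        if self.coverage is None:
            raise ValueError("heteroplasmy requires per-position coverage")
        return heteroplasmy(self.C, self.coverage)


def binarize(C: sp.spmatrix, min_support: int = 1) -> sp.csr_matrix:
    """Binary carrier matrix: 1 iff count >= ``min_support``."""
    if (C.data < 0).any():
        raise ValueError("counts must be non-negative")
    if min_support < 1:
        raise ValueError("min_support must be >= 1")
    B = C.copy().tocsr()
    B.data = (B.data >= min_support).astype(np.int8)
    B.eliminate_zeros()
    return B


def heteroplasmy(C: sp.spmatrix, copy_number: np.ndarray) -> np.ndarray:
    """Heteroplasmy H = C / copy number, capped at 1.

    Entries with zero coverage are set to 0; entries where the count
    exceeded the recorded copy number are capped at 1 with a warning.
    """
    C = np.asarray(C.todense()) if sp.issparse(C) else np.asarray(C)
    copy_number = np.asarray(copy_number)
    if C.shape != copy_number.shape:
        raise ValueError("count and copy-number matrices must have equal shape")
    over = C > copy_number
    if over.any():
        warnings.warn(f"capping {int(over.sum())} heteroplasmy entries at 1")
    H = np.where(copy_number > 0, C / np.maximum(copy_number, 1), 0.0)
    return np.minimum(H, 1.0)


def weighted_jaccard(C_bin: sp.spmatrix, priors: pd.Series | np.ndarray | None = None,
                     variant_ids: list[str] | None = None) -> np.ndarray:
    """Prior-weighted Jaccard distance between cell mutation profiles.

    ``D(x, y) = 1 - sum(prior_i, i in x&y) / sum(prior_i, i in x|y)``:
    the denominator runs over the union of the two cells' variants, the
    classical weighted Jaccard.  All priors equal to 1 recovers the
    unweighted Jaccard distance.  Two empty profiles are at distance 0
    (identical); an empty profile is at distance 1 from any non-empty one.

    ``priors`` may be a Series indexed by variant id (missing variants
    default to 1 with a warning) or a vector aligned to the columns.
    """
    B = C_bin.tocsr().astype(np.float64)
    B.data = np.ones_like(B.data)
    n, m = B.shape
    if priors is None:
        w = np.ones(m)
    elif isinstance(priors, pd.Series):
        if variant_ids is None:
            raise ValueError("variant_ids needed to align a prior Series")
        w = priors.reindex(variant_ids).to_numpy(dtype=float)
        if np.isnan(w).any():
            warnings.warn(f"{int(np.isnan(w).sum())} variants missing from the "
                          "prior table; their prior defaults to 1")
            w = np.nan_to_num(w, nan=1.0)
    else:
        w = np.asarray(priors, dtype=float)
        if w.shape != (m,):
            raise ValueError("prior vector length must match variant count")
    if ((w < 0) | (w > 1)).any():
        raise ValueError("priors must lie in [0, 1]")

    shared = np.asarray((B.multiply(w) @ B.T).todense())
    totals = B @ w
    union = totals[:, None] + totals[None, :] - shared
    with np.errstate(invalid="ignore", divide="ignore"):
        D = 1.0 - np.where(union > 0, shared / np.where(union > 0, union, 1.0), 1.0)
    # pairs with empty union (two empty profiles) are identical
    D[union <= 0] = 0.0
    np.fill_diagonal(D, 0.0)
    return np.clip((D + D.T) / 2.0, 0.0, 1.0)  # enforce exact symmetry


@dataclass
class LSIEmbedding:
    """TF-IDF/SVD embedding: cells x n_components scores and the singular
    values, with a mask of the cells that carried no variant."""

    embedding: np.ndarray
    singular_values: np.ndarray
    cells: list[str]
    empty_cells: np.ndarray

    @property
    def n_components(self) -> int:
        return self.embedding.shape[1]


def lsi_embed(C_bin: sp.spmatrix, n_components: int = 30, seed: int = 0,
              cells: list[str] | None = None) -> LSIEmbedding:
    """Latent semantic indexing of the binary carrier matrix.

    TF(i, j) = b_ij / rowsum_i; IDF(j) = log(1 + n_cells / df_j);
    the embedding is the top ``n_components`` left singular components of
    TF * IDF scaled by their singular values.  All components are retained
    (none dropped).  Cells with empty profiles embed at the origin and are
    flagged with a warning.  The sign of each component is fixed so the
    largest-magnitude loading is positive, making the embedding
    deterministic given the seed.
    """
    B = C_bin.tocsr().astype(np.float64)
    B.data = np.ones_like(B.data)
    n, m = B.shape
    if n_components > min(n, m):
        raise ValueError("n_components exceeds the matrix rank bound")
    rowsum = np.asarray(B.sum(axis=1)).ravel()
    empty = rowsum == 0
    if empty.any():
        warnings.warn(f"{int(empty.sum())} cells carry no variant; they embed "
                      "at the origin")
    tf = sp.diags(np.where(rowsum > 0, 1.0 / np.maximum(rowsum, 1), 0.0)) @ B
    df = np.asarray(B.sum(axis=0)).ravel()
    idf = np.log(1.0 + n / np.maximum(df, 1))
    X = tf @ sp.diags(idf)

    rng = np.random.default_rng(seed)
    v0 = rng.standard_normal(min(X.shape))
    k = min(n_components, min(X.shape) - 1)
    U, S, Vt = svds(X, k=k, v0=v0)
    order = np.argsort(S)[::-1]
    U, S, Vt = U[:, order], S[order], Vt[order]
    # deterministic sign: largest |loading| of each right singular vector > 0
    flip = np.sign(Vt[np.arange(k), np.abs(Vt).argmax(axis=1)])
    flip[flip == 0] = 1.0
    U = U * flip
    emb = U * S
    return LSIEmbedding(emb, S, cells if cells is not None else
                        [str(i) for i in range(n)], empty)


def connectedness(C_bin: sp.spmatrix) -> np.ndarray:
    """Number of other cells sharing at least one variant with each cell."""
    B = C_bin.tocsr().astype(np.int32)
    B.data = np.ones_like(B.data)
    S = B @ B.T
    S.data = np.ones_like(S.data)
    counts = np.asarray(S.sum(axis=1)).ravel()
    self_nonempty = np.asarray(B.sum(axis=1)).ravel() > 0
    return (counts - self_nonempty.astype(np.int32)).astype(np.int64)
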