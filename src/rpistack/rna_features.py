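"""RNA features: positional k-mer sparse matrix and SVD compression.

An RNA of length L is encoded as a binary occurrence matrix M with 4^k
rows (one per k-mer, lexicographic over A < C < G < U) and L - k + 1
columns (one per sequence window): a_ij = 1 iff the window starting at
position j spells k-mer i.  Columns over windows containing an ambiguous
base are all-zero, preserving positional register instead of truncating.

The fixed-length feature vector is the descending top-d singular values
of M (zero-padded below the rank), i.e. a low-rank spectral summary of
the k-mer occurrence structure that does not depend on L.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .io_formats import RnaSequence, ValidationError

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "U": 3}

#: above this row count the truncated sparse SVD is used instead of a
#: dense decomposition
_DENSE_ROW_LIMIT = 4096


@dataclass
class KmerSparseMatrix:
    """Binary 4^k x (L-k+1) occurrence matrix, stored sparsely."""

    rna_id: str
    k: int
    M: sp.spmatrix

    @property
    def shape(self) -> tuple[int, int]:
        return self.M.shape

    @property
    def n_windows(self) -> int:
        return self.M.shape[1]


@dataclass
class RnaFeature:
    """Top-d singular values of the k-mer matrix, descending."""

    rna_id: str
    sv: np.ndarray

    def __post_init__(self) -> None:
        self.sv = np.asarray(self.sv, dtype=np.float64)
        if (self.sv < -1e-12).any():
            raise ValidationError(f"RNA feature '{self.rna_id}': negative singular value")
        if (np.diff(self.sv) > 1e-9).any():
            raise ValidationError(f"RNA feature '{self.rna_id}': not non-increasing")


def kmer_index(kmer: str) -> int:
    """Lexicographic index of a k-mer over A < C < G < U."""
    idx = 0
    for base in kmer:
        idx = idx * 4 + _BASE_INDEX[base]
    return idx


def kmer_matrix(seq: RnaSequence, k: int = 4) -> KmerSparseMatrix:
    """Build the binary k-mer occurrence matrix of a sequence.

    Raises if L < k or k outside [1, 8] (4^k rows must be addressable).
    """
    if not 1 <= k <= 8:
        raise ValidationError(f"k = {k} outside the supported range [1, 8]")
    L = len(seq.bases)
    if L < k:
        raise ValidationError(
            f"RNA '{seq.id}': length {L} shorter than k = {k}"
        )
    n_cols = L - k + 1
    codes = np.array([_BASE_INDEX.get(b, -1) for b in seq.bases], dtype=np.int64)
    rows, cols = [], []
    for j in range(n_cols):
        window = codes[j : j + k]
        if (window < 0).any():
            continue  # ambiguous base: all-zero column
        idx = 0
        for c in window:
            idx = idx * 4 + int(c)
        rows.append(idx)
        cols.append(j)
    data = np.ones(len(rows), dtype=np.float64)
    M = sp.coo_matrix(
        (data, (rows, cols)), shape=(4**k, n_cols), dtype=np.float64
    ).tocsr()
    return KmerSparseMatrix(rna_id=seq.id, k=k, M=M)


def svd_features(m: KmerSparseMatrix, d: int = 16) -> RnaFeature:
    """Top-d singular values of the k-mer matrix, descending, zero-padded.

    Small matrices are densified for an exact decomposition; large ones
    go through the truncated sparse solver.
    """
    if d < 1:
        raise ValidationError(f"d = {d} must be >= 1")
    n_rows, n_cols = m.shape
    rank_bound = min(n_rows, n_cols)
    if m.M.nnz == 0:
        return RnaFeature(rna_id=m.rna_id, sv=np.zeros(d))
    if n_rows <= _DENSE_ROW_LIMIT or rank_bound <= d:
        sv = np.linalg.svd(m.M.toarray(), compute_uv=False)
    else:
        k_trunc = min(d, rank_bound - 1)
        sv = spla.svds(m.M, k=k_trunc, return_singular_vectors=False)
        sv = np.sort(sv)[::-1]
    sv = np.sort(sv)[::-1]
    out = np.zeros(d)
    n_keep = min(d, sv.size)
    out[:n_keep] = np.clip(sv[:n_keep], 0.0, None)
    return RnaFeature(rna_id=m.rna_id, sv=out)


def rna_feature_matrix(
    seqs: list[RnaSequence], k: int = 4, d: int = 16
) -> tuple[list[str], np.ndarray]:
    """Convenience: stack SVD features of many sequences into an n x d matrix."""
    ids, rows = [], []
    for seq in seqs:
        feat = svd_features(kmer_matrix(seq, k=k), d=d)
        ids.append(seq.id)
        rows.append(feat.sv)
    return ids, np.vstack(rows)
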