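"""Protein features: PSSM normalization and bi-gram transition extraction.

A PSI-BLAST profile is first normalized into a row-stochastic matrix
P = {p_ij}, i = 1..r, j = 1..20, where p_ij is the relative probability
of amino acid j at sequence position i (each row sums to 1).  The
bi-gram encoder then accumulates expected consecutive-position
transitions

    b_mn = sum_{i=1}^{r-1} p_im * p_{i+1,n},   1 <= m, n <= 20,

and flattens the 20 x 20 matrix B row-major into the 400-dimensional
feature vector F = (b_11, b_12, ..., b_20_20).  Because every row of P
sums to 1, the entries of F always sum to r - 1; this mass-conservation
identity is asserted on every extraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import RawPssm, ValidationError

_ROW_SUM_TOL = 1e-9
_MASS_TOL = 1e-6


@dataclass
class Pssm:
    """Row-stochastic position-specific probability matrix (r x 20)."""

    protein_id: str
    P: np.ndarray

    def __post_init__(self) -> None:
        self.P = np.asarray(self.P, dtype=np.float64)
        if self.P.ndim != 2 or self.P.shape[1] != 20:
            raise ValidationError(
                f"PSSM '{self.protein_id}': expected r x 20, got {self.P.shape}"
            )
        if self.P.shape[0] < 2:
            raise ValidationError(
                f"PSSM '{self.protein_id}': r = {self.P.shape[0]} < 2; "
                "bi-gram features need at least two positions"
            )
        if (self.P < 0).any() or (self.P > 1).any():
            raise ValidationError(
                f"PSSM '{self.protein_id}': probabilities outside [0, 1]"
            )
        row_err = np.abs(self.P.sum(axis=1) - 1.0)
        if (row_err > _ROW_SUM_TOL).any():
            i = int(np.argmax(row_err))
            raise ValidationError(
                f"PSSM '{self.protein_id}': row {i + 1} sums to "
                f"{self.P[i].sum():.12f}, not 1"
            )

    @property
    def r(self) -> int:
        return self.P.shape[0]


@dataclass
class BigramFeature:
    """400-dimensional bi-gram vector, row-major (b_11 ... b_20_20)."""

    protein_id: str
    F: np.ndarray

    def __post_init__(self) -> None:
        self.F = np.asarray(self.F, dtype=np.float64)
        if self.F.shape != (400,):
            raise ValidationError(
                f"bigram feature '{self.protein_id}': expected length 400, "
                f"got shape {self.F.shape}"
            )
        if (self.F < -1e-12).any():
            raise ValidationError(
                f"bigram feature '{self.protein_id}': negative entries"
            )


def normalize_pssm(raw: RawPssm, mode: str = "percentages") -> Pssm:
    """Turn a raw integer PSSM into the row-stochastic probability matrix.

    mode='percentages' divides each row of the observed-percentage block
    by its sum; an all-zero row (a position PSI-BLAST saw no hits for)
    falls back to the uniform row 1/20.  mode='softmax' exponentiates the
    log-odds rows and normalizes, for profiles whose percentage block is
    unavailable or degenerate.
    """
    if mode not in ("percentages", "softmax"):
        raise ValueError(f"unknown normalization mode {mode!r}")
    if raw.r < 2:
        raise ValidationError(
            f"PSSM '{raw.protein_id}': r = {raw.r} < 2; bi-gram undefined"
        )
    if mode == "percentages":
        rows = raw.percentages.astype(np.float64)
        sums = rows.sum(axis=1, keepdims=True)
        zero = sums[:, 0] == 0
        rows[zero] = 1.0  # uniform fallback
        sums = rows.sum(axis=1, keepdims=True)
        P = rows / sums
    else:
        # subtract the row max before exponentiating for numerical safety
        lo = raw.log_odds.astype(np.float64)
        lo -= lo.max(axis=1, keepdims=True)
        rows = np.exp(lo)
        P = rows / rows.sum(axis=1, keepdims=True)
    return Pssm(protein_id=raw.protein_id, P=P)


def bigram_features(pssm: Pssm, length_normalize: bool = False) -> BigramFeature:
    """Extract the 400-d bi-gram transition vector from a normalized PSSM.

    With ``length_normalize`` the vector is divided by r - 1, making
    features comparable across protein lengths; default off, keeping the
    literal transition-mass definition.
    """
    B = pssm.P[:-1].T @ pssm.P[1:]  # 20 x 20: sum_i p_im p_{i+1,n}
    F = B.ravel(order="C")
    total = F.sum()
    expected = pssm.r - 1
    if abs(total - expected) > _MASS_TOL * max(1.0, expected):
        raise ValidationError(
            f"bigram '{pssm.protein_id}': mass {total:.9f} != r-1 = {expected}"
        )
    if length_normalize:
        F = F / expected
    return BigramFeature(protein_id=pssm.protein_id, F=F)
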