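"""Readers and writers for every on-disk artifact of the pipeline.

Sequence input is FASTA (protein: 20-letter amino-acid alphabet; RNA:
A/C/G/U with T accepted and mapped to U).  Evolutionary profiles are
PSI-BLAST ASCII position-specific scoring matrices (the 40-column
``-out_ascii_pssm`` dialect: 20 log-odds columns followed by 20
weighted-observed-percentage columns).  Interaction pairs travel as TSV
with columns ``protein_id``, ``rna_id``, ``label``; feature matrices as
TSV with an ``id`` column and deterministic per-dimension column names;
metric reports as JSON.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

#: PSI-BLAST column order, identical for the log-odds and percentage blocks.
PSSM_COLUMNS = "ARNDCQEGHILKMFPSTWYV"

#: The 20 standard amino-acid one-letter codes.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

RNA_BASES = "ACGU"

# Ambiguity resolution applied at read time: B (Asx) -> D, Z (Glx) -> E.
# X, U (Sec) and O (Pyl) are retained verbatim so sequence length stays in
# register with the PSSM row count.
_AA_SUBSTITUTIONS = str.maketrans({"B": "D", "Z": "E"})


class RpistackError(Exception):
    """Base class for all errors raised by this package."""


class ParseError(RpistackError):
    """A file did not follow its expected dialect."""


class ValidationError(RpistackError):
    """Input values violated a contract (bad label, unknown id, ...)."""


@dataclass(frozen=True)
class ProteinSequence:
    """An amino-acid sequence; ``len`` >= 2 is required downstream because
    the bi-gram sum runs over consecutive position pairs."""

    id: str
    residues: str

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class RnaSequence:
    """An RNA sequence over A/C/G/U; other letters are treated as
    ambiguous positions by the k-mer encoder."""

    id: str
    bases: str

    def __len__(self) -> int:
        return len(self.bases)


@dataclass
class RawPssm:
    """A parsed PSI-BLAST ASCII PSSM: integer log-odds and integer
    observed percentages, both r x 20 in the A R N D ... V column order."""

    protein_id: str
    log_odds: np.ndarray
    percentages: np.ndarray
    residue_column: str

    def __post_init__(self) -> None:
        self.log_odds = np.asarray(self.log_odds, dtype=np.int64)
        self.percentages = np.asarray(self.percentages, dtype=np.int64)
        if self.log_odds.shape != self.percentages.shape:
            raise ValidationError(
                f"PSSM '{self.protein_id}': log-odds shape {self.log_odds.shape} "
                f"!= percentages shape {self.percentages.shape}"
            )
        if self.log_odds.ndim != 2 or self.log_odds.shape[1] != 20:
            raise ValidationError(
                f"PSSM '{self.protein_id}': expected r x 20 matrices, "
                f"got {self.log_odds.shape}"
            )
        if len(self.residue_column) != self.log_odds.shape[0]:
            raise ValidationError(
                f"PSSM '{self.protein_id}': residue column length "
                f"{len(self.residue_column)} != row count {self.log_odds.shape[0]}"
            )
        if ((self.percentages < 0) | (self.percentages > 100)).any():
            raise ValidationError(
                f"PSSM '{self.protein_id}': percentages outside [0, 100]"
            )

    @property
    def r(self) -> int:
        return self.log_odds.shape[0]


@dataclass
class PairTable:
    """Interaction pairs: one row per (protein_id, rna_id) with a binary
    label (1 = interacting)."""

    frame: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        required = ["protein_id", "rna_id", "label"]
        missing = [c for c in required if c not in self.frame.columns]
        if missing:
            raise ValidationError(f"pair table missing columns: {missing}")
        labels = self.frame["label"]
        bad = ~labels.isin([0, 1])
        if bad.any():
            first = self.frame.loc[bad].iloc[0]
            raise ValidationError(
                f"pair ({first['protein_id']}, {first['rna_id']}): "
                f"label {first['label']!r} not in {{0, 1}}"
            )
        self.frame = self.frame[required].reset_index(drop=True)
        self.frame["label"] = self.frame["label"].astype(np.int64)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def labels(self) -> np.ndarray:
        return self.frame["label"].to_numpy()

    def validate_ids(
        self,
        protein_ids: Iterable[str],
        rna_ids: Iterable[str],
    ) -> None:
        """Check that every referenced id resolves; name the first offender."""
        known_p, known_r = set(protein_ids), set(rna_ids)
        for pid in self.frame["protein_id"]:
            if pid not in known_p:
                raise ValidationError(f"unknown protein id '{pid}' in pair table")
        for rid in self.frame["rna_id"]:
            if rid not in known_r:
                raise ValidationError(f"unknown RNA id '{rid}' in pair table")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path, moltype: str = "protein"):
    """Read a FASTA file into :class:`ProteinSequence` or :class:`RnaSequence`
    records.

    Protein mode uppercases and resolves B->D, Z->E (X/U/O retained);
    RNA mode uppercases and maps T->U.  Duplicate ids and empty files
    are errors.
    """
    if moltype not in ("protein", "rna"):
        raise ValueError(f"moltype must be 'protein' or 'rna', got {moltype!r}")
    path = Path(path)
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise ParseError(f"{path}: FASTA record with empty header")
        if rec.id in seen:
            raise ParseError(f"{path}: duplicate FASTA id '{rec.id}'")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if moltype == "protein":
            seq = seq.translate(_AA_SUBSTITUTIONS)
            odd = set(seq) - set(AMINO_ACIDS)
            if odd:
                warnings.warn(
                    f"{path}: protein '{rec.id}' contains non-standard "
                    f"letters {sorted(odd)}; retained verbatim",
                    stacklevel=2,
                )
            records.append(ProteinSequence(id=rec.id, residues=seq))
        else:
            seq = seq.replace("T", "U")
            records.append(RnaSequence(id=rec.id, bases=seq))
    if not records:
        raise ParseError(f"{path}: empty FASTA file")
    return records


def write_fasta(path: str | Path, records: Sequence, width: int = 60) -> None:
    """Write sequence records as wrapped FASTA (deterministic layout)."""
    with open(path, "w") as fh:
        for rec in records:
            seq = rec.residues if hasattr(rec, "residues") else rec.bases
            fh.write(f">{rec.id}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# PSI-BLAST ASCII PSSM
# ---------------------------------------------------------------------------

def read_pssm(path: str | Path, protein_id: str | None = None) -> RawPssm:
    """Parse a PSI-BLAST ASCII PSSM (``-out_ascii_pssm`` 40-column dialect).

    The file carries three header lines, then one line per residue with a
    position index, the residue letter, 20 integer log-odds and 20 integer
    percentages; trailing statistics lines are ignored.  Any residue line
    with fewer than 40 numeric columns is a parse error citing its line
    number.
    """
    path = Path(path)
    if protein_id is None:
        protein_id = path.stem
    lines = path.read_text().splitlines()
    log_odds: list[list[int]] = []
    percentages: list[list[int]] = []
    residues: list[str] = []
    in_body = False
    for lineno, line in enumerate(lines, start=1):
        if lineno <= 3:
            continue
        tokens = line.split()
        if not tokens or not tokens[0].lstrip("-").isdigit():
            if in_body:
                break  # trailing statistics block
            continue
        if len(tokens) < 2 or not tokens[1].isalpha() or len(tokens[1]) != 1:
            raise ParseError(f"{path}: line {lineno}: malformed residue line")
        numbers = tokens[2:]
        if len(numbers) < 40:
            raise ParseError(
                f"{path}: line {lineno}: expected 40 numeric columns, "
                f"found {len(numbers)}"
            )
        try:
            values = [int(round(float(tok))) for tok in numbers[:40]]
        except ValueError as exc:
            raise ParseError(f"{path}: line {lineno}: non-numeric column: {exc}")
        in_body = True
        residues.append(tokens[1].upper())
        log_odds.append(values[:20])
        percentages.append(values[20:40])
    if not residues:
        raise ParseError(f"{path}: no PSSM residue lines found")
    return RawPssm(
        protein_id=protein_id,
        log_odds=np.array(log_odds, dtype=np.int64),
        percentages=np.array(percentages, dtype=np.int64),
        residue_column="".join(residues),
    )


def write_pssm(path: str | Path, pssm: RawPssm) -> None:
    """Write a :class:`RawPssm` in the same ASCII dialect :func:`read_pssm`
    accepts (bit-exact integer round trip)."""
    cols = " ".join(f"{c:>3}" for c in PSSM_COLUMNS)
    header = (
        "\n"
        "Last position-specific scoring matrix computed, weighted observed "
        "percentages rounded down, information per position, and relative "
        "weight of gapped matches\n"
        f"          {cols}  {cols}\n"
    )
    body_lines = []
    for i in range(pssm.r):
        lo = " ".join(f"{v:>3d}" for v in pssm.log_odds[i])
        pc = " ".join(f"{v:>3d}" for v in pssm.percentages[i])
        body_lines.append(
            f"{i + 1:>5d} {pssm.residue_column[i]}  {lo}  {pc}  0.00 0.00"
        )
    footer = (
        "\n"
        "                      K         Lambda\n"
        "Standard Ungapped    0.1347     0.3179\n"
    )
    Path(path).write_text(header + "\n".join(body_lines) + "\n" + footer)


# ---------------------------------------------------------------------------
# Pair tables, feature matrices, metric reports
# ---------------------------------------------------------------------------

def read_pairs(path: str | Path) -> PairTable:
    """Read a TSV pair table with header protein_id, rna_id, label."""
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", dtype={"protein_id": str, "rna_id": str})
    required = {"protein_id", "rna_id", "label"}
    if not required.issubset(frame.columns):
        raise ParseError(
            f"{path}: pair table must have columns {sorted(required)}, "
            f"got {list(frame.columns)}"
        )
    labels = frame["label"]
    if not np.isin(labels.to_numpy(), [0, 1]).all():
        bad = labels[~labels.isin([0, 1])].iloc[0]
        raise ValidationError(f"{path}: label {bad!r} not in {{0, 1}}")
    return PairTable(frame=frame)


def write_pairs(path: str | Path, pairs: PairTable) -> None:
    pairs.frame.to_csv(path, sep="\t", index=False)


def bigram_feature_names() -> list[str]:
    """Column names b_1_1 ... b_20_20 in the row-major flattening order."""
    return [f"b_{m}_{n}" for m in range(1, 21) for n in range(1, 21)]


def sv_feature_names(d: int) -> list[str]:
    return [f"sv_{i}" for i in range(1, d + 1)]


def write_features(
    path: str | Path,
    ids: Sequence[str],
    matrix: np.ndarray,
    columns: Sequence[str],
) -> None:
    """Write a feature matrix as self-describing TSV (id column + one
    column per feature dimension), round-trippable to full precision."""
    matrix = np.asarray(matrix, dtype=np.float64)
    if matrix.shape != (len(ids), len(columns)):
        raise ValidationError(
            f"feature matrix shape {matrix.shape} inconsistent with "
            f"{len(ids)} ids x {len(columns)} columns"
        )
    frame = pd.DataFrame(matrix, index=pd.Index(ids, name="id"), columns=list(columns))
    frame.to_csv(path, sep="\t", float_format="%.17g")


def read_features(path: str | Path) -> pd.DataFrame:
    """Read a feature TSV back into a DataFrame indexed by id."""
    frame = pd.read_csv(path, sep="\t", index_col="id", float_precision="round_trip")
    return frame.astype(np.float64)


def write_report(path: str | Path, report) -> None:
    """Serialize a metrics report (anything with ``to_dict``) as JSON."""
    payload = report.to_dict() if hasattr(report, "to_dict") else report
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_report(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
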