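"""Shared record types and plain-text I/O (FASTA, TSV matrices, JSON report).

Coordinates everywhere in the package are 1-based and inclusive, matching
the residue-numbering convention of the structural literature (e.g. the
disulfide pair C140-C167).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Optional

import pandas as pd
from Bio import SeqIO

PROTEIN_LETTERS = set("ACDEFGHIKLMNPQRSTVWYX")
DNA_LETTERS = set("ACGTN")
GAP = "-"


class Pa2cError(Exception):
    """Base class for all package errors."""


class ParseError(Pa2cError):
    """Malformed input file."""


class ValidationError(Pa2cError):
    """Input violates a documented invariant."""


@dataclass(frozen=True)
class ProteinRecord:
    """A named amino-acid sequence.

    ``true_clade`` is set only by the synthetic generator and carries the
    ground-truth family label (``alpha``, ``beta``, ``pla2like`` or
    ``none``); it is never consulted by the classifier.
    """

    id: str
    sequence: str
    source: str = ""
    true_clade: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValidationError(f"record {self.id!r}: empty sequence")
        bad = set(self.sequence) - PROTEIN_LETTERS
        if bad:
            raise ValidationError(
                f"record {self.id!r}: illegal protein letters {sorted(bad)}"
            )
        if self.true_clade not in (None, "alpha", "beta", "pla2like", "none"):
            raise ValidationError(f"record {self.id!r}: bad clade label")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PromoterRecord:
    """A promoter DNA sequence, by convention ~2 kb upstream of the start codon."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValidationError(f"promoter {self.id!r}: empty sequence")
        bad = set(self.sequence) - DNA_LETTERS
        if bad:
            raise ValidationError(
                f"promoter {self.id!r}: illegal DNA letters {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class ExpressionMatrix:
    """Gene-by-tissue expression values in TPM (all non-negative)."""

    genes: list[str]
    tissues: list[str]
    values: pd.DataFrame = field(repr=False)

    def __init__(self, values: pd.DataFrame):
        if values.index.duplicated().any():
            raise ValidationError("duplicate gene ids")
        if values.columns.duplicated().any():
            raise ValidationError("duplicate tissue names")
        if (values.values < 0).any():
            raise ValidationError("negative TPM value")
        self.values = values.astype(float)
        self.genes = list(values.index)
        self.tissues = list(values.columns)


def _normalize_protein(seq: str, record_id: str, aligned: bool) -> str:
    seq = seq.upper()
    if seq.endswith("*"):
        warnings.warn(f"record {record_id!r}: stripping trailing stop codon '*'")
        seq = seq.rstrip("*")
    if "*" in seq:
        warnings.warn(f"record {record_id!r}: stripping internal stop codons '*'")
        seq = seq.replace("*", "")
    if not aligned and GAP in seq:
        raise ParseError(
            f"record {record_id!r}: gap characters present; "
            "pass aligned=True to read an alignment"
        )
    return seq


def read_fasta(
    path: str | Path,
    alphabet: Literal["protein", "dna"] = "protein",
    aligned: bool = False,
) -> list[ProteinRecord] | list[PromoterRecord]:
    """Read a FASTA file into protein or promoter records.

    Sequences are upper-cased; line-wrapped and single-line dialects are
    treated identically.  Illegal characters raise :class:`ParseError`
    naming the offending line; an empty file is an error.
    """
    path = Path(path)
    records = []
    seen: set[str] = set()
    letters = PROTEIN_LETTERS if alphabet == "protein" else DNA_LETTERS
    allowed = letters | ({GAP} if aligned else set())
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ParseError(f"duplicate id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if alphabet == "protein":
            seq = _normalize_protein(seq, rec.id, aligned)
        bad = set(seq) - allowed
        if bad:
            raise ParseError(
                f"record {rec.id!r}: illegal character(s) {sorted(bad)} "
                f"near line {_find_line(path, rec.id)}"
            )
        if not seq:
            raise ParseError(f"record {rec.id!r}: empty sequence")
        if alphabet == "protein":
            if aligned:
                records.append((rec.id, seq))
            else:
                records.append(ProteinRecord(id=rec.id, sequence=seq, source=str(path)))
        else:
            records.append(PromoterRecord(id=rec.id, sequence=seq))
    if not records:
        raise ParseError(f"{path}: no FASTA records found")
    return records


def _find_line(path: Path, record_id: str) -> int:
    """Best-effort line number of a record header, for error messages."""
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            if line.startswith(">") and line[1:].split()[0] == record_id:
                return i
    return 0


def read_alignment(path: str | Path) -> dict[str, str]:
    """Read an aligned FASTA (gaps allowed); returns an ordered id -> row map."""
    rows = read_fasta(path, alphabet="protein", aligned=True)
    out = dict(rows)
    lengths = {len(s) for s in out.values()}
    if len(lengths) > 1:
        raise ParseError(f"{path}: alignment rows have unequal lengths {sorted(lengths)}")
    return out


def write_fasta(records: Iterable, path: str | Path, width: int = 60) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            seq = rec.sequence
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_expression_tsv(path: str | Path) -> ExpressionMatrix:
    """Read a gene-by-tissue TPM table (first row tissues, first column gene ids)."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ParseError(f"{path}: {exc}") from exc
    if df.empty:
        raise ParseError(f"{path}: empty expression table")
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric cell ({exc})") from exc
    if df.isna().any().any():
        raise ParseError(f"{path}: missing or ragged cells")
    return ExpressionMatrix(df)


def write_expression_tsv(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", float_format="%.6g")


def write_report(calls: list, path: str | Path) -> None:
    """Write classification calls as a deterministic JSON array.

    One object per input sequence; keys sorted; QC flags serialized as a
    string list.  Refuses an empty call list.
    """
    if not calls:
        raise ValidationError("write_report: empty call list")
    payload = [call.to_dict() for call in calls]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
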