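"""Promoter scanning for cis-regulatory elements and the count heatmap matrix.

The bundled element library carries the cis-acting elements with a
published consensus: stress-responsive MYB/MYC-type sites, the W-box and
WRE3 wound elements, hormone-responsive ABRE / methyl-jasmonate / ERE /
GARE / auxRR elements and the light-responsive G-box.  Elements that are
named in the literature without a printed consensus (I-box, GATA-motif,
GA motif, TCT motif, Box 4, MRE, TATC box, PA box, TGA element, as-1,
WUN) ship as disabled placeholders: a consensus must be supplied by the
user before they scan, because inventing one would silently change every
count.

Both strands are scanned; a locus matched on both strands (palindromes
such as the G-box CACGTG) is counted once.  ``N`` in a promoter never
matches; IUPAC degeneracy codes in a consensus match their base sets.
Display counts are clipped at 5 copies, matching the convention of
promoter-element heatmaps (cyan = absent, red = 5+ copies).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pandas as pd
from Bio.Seq import Seq

from pa2c.core import Pa2cError, PromoterRecord

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC", "B": "CGT", "D": "AGT",
    "H": "ACT", "V": "ACG", "N": "ACGT",
}

DISPLAY_CEILING = 5


class LibraryError(Pa2cError):
    pass


@dataclass(frozen=True)
class CisElement:
    """A named promoter element with an IUPAC consensus and a category."""

    name: str
    consensus: Optional[str]  # None for placeholder entries
    category: str             # common | stress | hormone | light | wound

    def __post_init__(self) -> None:
        if self.consensus is not None:
            bad = set(self.consensus.upper()) - set(IUPAC)
            if bad:
                raise LibraryError(f"{self.name}: illegal IUPAC codes {sorted(bad)}")

    @property
    def enabled(self) -> bool:
        return self.consensus is not None


def default_library(include_placeholders: bool = False) -> list[CisElement]:
    """The bundled cis-element dictionary (published consensi only by default)."""
    lib = [
        CisElement("MBS", "TAACTG", "stress"),
        CisElement("Myb", "CAACTG", "stress"),
        CisElement("MYB", "CAACAG", "stress"),
        CisElement("MYB-like", "TAACCA", "stress"),
        CisElement("MYC", "CATTTG", "stress"),
        CisElement("W-box", "TTGACC", "wound"),
        CisElement("WRE3", "CCACCT", "wound"),
        CisElement("ABRE", "TACGTG", "hormone"),
        CisElement("MeJA-CGTCA", "CGTCA", "hormone"),
        CisElement("MeJA-TGACG", "TGACG", "hormone"),
        CisElement("ERE", "ATTTCAAA", "hormone"),
        CisElement("GARE", "AAACAGA", "hormone"),
        CisElement("auxRR", "GGTCCAT", "hormone"),
        CisElement("G-box", "CACGTG", "light"),
    ]
    if include_placeholders:
        for name, cat in [
            ("I-box", "light"), ("GATA-motif", "light"), ("GA-motif", "light"),
            ("TCT-motif", "light"), ("Box4", "light"), ("MRE", "light"),
            ("TATC-box", "hormone"), ("PA-box", "hormone"),
            ("TGA-element", "hormone"), ("as-1", "wound"), ("WUN", "wound"),
        ]:
            lib.append(CisElement(name, None, cat))
    names = [e.name for e in lib]
    assert len(names) == len(set(names))
    return lib


@dataclass(frozen=True)
class CisHit:
    """One element occurrence; start is 1-based on the forward strand."""

    element: str
    strand: str  # '+' or '-'
    start: int


def _consensus_regex(consensus: str) -> re.Pattern:
    parts = ["(?=("]
    for code in consensus.upper():
        bases = IUPAC[code]
        parts.append(bases if len(bases) == 1 else f"[{bases}]")
    parts.append("))")
    return re.compile("".join(parts))


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def scan_promoter(
    promoter: PromoterRecord, library: Sequence[CisElement]
) -> list[CisHit]:
    """All element occurrences on both strands, strand-collapsed per locus.

    A minus-strand hit is reported at the forward-strand start of the
    matched locus.  When a palindromic element matches a locus on both
    strands, only the forward record is kept, so each physical occurrence
    counts once.  Disabled placeholder elements are skipped.
    """
    seq = promoter.sequence
    hits: list[CisHit] = []
    for element in library:
        if not element.enabled:
            continue
        fwd_starts = {m.start() for m in _consensus_regex(element.consensus).finditer(seq)}
        rc = reverse_complement(element.consensus)
        rev_starts = {m.start() for m in _consensus_regex(rc).finditer(seq)}
        for off in sorted(fwd_starts):
            hits.append(CisHit(element.name, "+", off + 1))
        for off in sorted(rev_starts - fwd_starts):
            hits.append(CisHit(element.name, "-", off + 1))
    hits.sort(key=lambda h: (h.start, h.element, h.strand))
    return hits


@dataclass
class CisElementCountMatrix:
    """Promoter-by-element occurrence counts plus a clipped display copy."""

    counts: pd.DataFrame
    ceiling: int = DISPLAY_CEILING

    @property
    def display(self) -> pd.DataFrame:
        return self.counts.clip(upper=self.ceiling)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# raw counts\n")
            self.counts.to_csv(fh, sep="\t")
            fh.write(f"# display counts (clipped at {self.ceiling})\n")
            self.display.to_csv(fh, sep="\t")


def count_matrix(
    promoters: Iterable[PromoterRecord],
    library: Sequence[CisElement],
    ceiling: int = DISPLAY_CEILING,
) -> CisElementCountMatrix:
    """Per-promoter per-element locus counts (strand-collapsed)."""
    enabled = [e.name for e in library if e.enabled]
    rows = {}
    for promoter in promoters:
        counts = dict.fromkeys(enabled, 0)
        for hit in scan_promoter(promoter, library):
            counts[hit.element] += 1
        rows[promoter.id] = counts
    df = pd.DataFrame.from_dict(rows, orient="index")
    df = df.reindex(columns=enabled, fill_value=0).fillna(0).astype(int)
    df.index.name = "promoter"
    return CisElementCountMatrix(counts=df, ceiling=ceiling)


def load_library_tsv(path) -> list[CisElement]:
    """Load a custom element library from a TSV (name, consensus, category)."""
    out = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise LibraryError(f"{path}:{line_no}: expected 3 columns")
            name, consensus, category = fields
            out.append(CisElement(name, consensus or None, category))
    return out
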