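"""Diagnostic feature extraction and family/clade assignment.

A protein is assigned to one of three families from its sequence alone:

* **sPLA2** (canonical secreted phospholipase A2): N-terminal signal
  peptide, canonical calcium loop (YGKYCGxxxxGC) and catalytic dyad
  (DxCCxxHDxC), twelve cysteines in the domain region, mature length
  90-191 residues.  Canonical proteins split phylogenetically into an
  alpha and a beta clade; since no single-site signature separates them,
  the clade call here is a nearest-centroid decision over global-alignment
  similarity to a small labeled reference panel (the phylo module offers
  tree placement as an alternative).
* **PLA2-like**: no signal peptide, a long disordered N-terminal
  extension, the variant motifs YGHYCGxxxxxGK / DxCCxxHDxG, six
  cysteines, total length 143-320 residues.
* **nonPA2c**: anything missing either diagnostic motif.

Signal-peptide detection is a transparent hydrophobicity heuristic
(Kyte-Doolittle window), not a trained predictor; thresholds are exposed
as module constants and every assignment carries QC flags rather than
silent coercion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from pa2c.core import Pa2cError, ProteinRecord
from pa2c.motifs import DomainSpan, builtin_patterns, pa2c_domain_span, scan

# Kyte-Doolittle hydropathy; X (unknown residue) scored neutral.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
    "X": 0.0,
}

# Signal-peptide heuristic parameters.
SP_WINDOW = 8            # residues in the qualifying hydrophobic window
SP_THRESHOLD = 1.6       # mean hydropathy the window must reach
SP_ONSET_LAST = 12       # window must begin within residues 2..12 (1-based)
SP_MIN_LENGTH = 25       # shorter sequences are undetermined
SP_CLEAVAGE_CAP = 35     # cleavage estimate never exceeds this residue

# Disorder-promoting residues for the N-terminal disorder proxy.
DISORDER_PROMOTING = set("PESKQAGR")
MIN_NTERM_LEN = 10

# Family QC windows (mature length for sPLA2, total length for PLA2-like).
SPLA2_MATURE_RANGE = (90, 191)
PLA2LIKE_TOTAL_RANGE = (143, 320)
SPLA2_CYS = 12
PLA2LIKE_CYS = 6

# Nearest-centroid margin: below this fraction of the observed score
# range the alpha/beta call is reported as unresolved.
CENTROID_MARGIN_FRACTION = 0.02


class ConfigurationError(Pa2cError):
    """Missing or unusable reference panel / configuration."""


def detect_signal_peptide(
    record: ProteinRecord,
) -> tuple[bool, Optional[int], list[str]]:
    """Hydrophobicity-window heuristic for an N-terminal secretory peptide.

    Positive iff the sequence starts with M and a window of ``SP_WINDOW``
    consecutive residues with mean Kyte-Doolittle hydropathy >=
    ``SP_THRESHOLD`` begins within residues 2-12.  The cleavage estimate
    is the end of the contiguous hydrophobic run (per-residue hydropathy
    >= threshold) plus 3, capped at residue 35.

    Returns ``(present, cleavage_position, flags)``; sequences shorter
    than 25 residues are undetermined (flagged, treated as absent).
    """
    seq = record.sequence
    if len(seq) < SP_MIN_LENGTH:
        return False, None, ["SP_UNDETERMINED"]
    if seq[0] != "M":
        return False, None, []
    hydro = [KYTE_DOOLITTLE[c] for c in seq]
    onset = None
    for s in range(1, SP_ONSET_LAST):  # 0-based starts for residues 2..12
        window = hydro[s : s + SP_WINDOW]
        if len(window) < SP_WINDOW:
            break
        if sum(window) / SP_WINDOW >= SP_THRESHOLD:
            onset = s
            break
    if onset is None:
        return False, None, []
    # contiguous hydrophobic run: first per-residue-hydrophobic position at
    # or after the window onset, extended while residues stay hydrophobic
    run_start = onset
    while run_start < len(seq) and hydro[run_start] < SP_THRESHOLD:
        run_start += 1
    run_end = run_start
    while run_end + 1 < len(seq) and hydro[run_end + 1] >= SP_THRESHOLD:
        run_end += 1
    cleavage = min(run_end + 1 + 3, SP_CLEAVAGE_CAP, len(seq))
    return True, cleavage, []


def cys_census(record: ProteinRecord, span: Optional[DomainSpan]) -> int:
    """Count cysteines from the domain start to the sequence end.

    The domain region is taken as [span start, sequence end]; with no
    span the whole sequence is counted.  The open right edge reflects
    that the family-defining cysteine inventories are quoted per protein,
    not per exactly delimited domain.
    """
    start = span.start if span is not None else 1
    return record.sequence[start - 1 :].count("C")


def detect_kxel(record: ProteinRecord) -> bool:
    """True iff the last four residues are K-x-E-L (ER-retention signal)."""
    if len(record.sequence) < 4:
        return False
    tail = record.sequence[-4:]
    return tail[0] == "K" and tail[2] == "E" and tail[3] == "L"


def nterm_disorder_proxy(
    record: ProteinRecord, span: Optional[DomainSpan]
) -> tuple[float, list[str]]:
    """Fraction of disorder-promoting residues (P,E,S,K,Q,A,G,R) before the domain.

    Returns 0 with a ``SHORT_NTERM`` flag when the region upstream of the
    domain span is shorter than 10 residues; 0 without a flag when there
    is no domain span at all.
    """
    if span is None:
        return 0.0, []
    region = record.sequence[: span.start - 1]
    if len(region) < MIN_NTERM_LEN:
        return 0.0, ["SHORT_NTERM"]
    promoting = sum(1 for c in region if c in DISORDER_PROMOTING)
    return promoting / len(region), []


@dataclass(frozen=True)
class FeatureProfile:
    """Extracted diagnostic features for one protein."""

    has_signal_peptide: bool
    sp_end: Optional[int]
    ca_variant: str   # canon | like | none
    cat_variant: str  # canon | like | none
    n_cys_domain: int
    total_length: int
    mature_length: int
    has_kxel: bool
    nterm_disorder_score: float
    has_dacc_dyad: bool = False
    flags: tuple[str, ...] = ()
    span: Optional[DomainSpan] = None


@dataclass(frozen=True)
class CladeCall:
    """Family/clade assignment with QC flags and the underlying evidence."""

    sequence_id: str
    family: str  # sPLA2 | PLA2like | nonPA2c
    clade: str   # alpha | beta | unresolved | not_applicable
    flags: tuple[str, ...]
    evidence: FeatureProfile

    def to_dict(self) -> dict:
        ev = self.evidence
        return {
            "id": self.sequence_id,
            "family": self.family,
            "clade": self.clade,
            "flags": sorted(self.flags),
            "has_signal_peptide": ev.has_signal_peptide,
            "sp_end": ev.sp_end,
            "ca_variant": ev.ca_variant,
            "cat_variant": ev.cat_variant,
            "n_cys_domain": ev.n_cys_domain,
            "total_length": ev.total_length,
            "mature_length": ev.mature_length,
            "has_kxel": ev.has_kxel,
            "has_dacc_dyad": ev.has_dacc_dyad,
            "nterm_disorder_score": round(ev.nterm_disorder_score, 4),
        }


def _variant(matches, prefix: str) -> tuple[str, Optional[object]]:
    """Left-most motif variant of one class: ('canon'|'like'|'none', match)."""
    for m in matches:
        if m.pattern == f"{prefix}_CANON":
            return "canon", m
    for m in matches:
        if m.pattern == f"{prefix}_LIKE":
            return "like", m
    return "none", None


def compute_profile(record: ProteinRecord) -> FeatureProfile:
    """Run all feature extractors on one protein."""
    matches = scan(record, builtin_patterns())
    ca_variant, ca_match = _variant(matches, "CA")
    cat_variant, cat_match = _variant(matches, "CAT")
    span, span_flags = pa2c_domain_span(
        [m for m in (ca_match, cat_match) if m is not None]
    )
    has_sp, sp_end, sp_flags = detect_signal_peptide(record)
    total = len(record.sequence)
    mature = total - sp_end if (has_sp and sp_end) else total
    disorder, dis_flags = nterm_disorder_proxy(record, span)
    has_dacc = cat_match is not None and cat_match.matched.startswith("DA")
    return FeatureProfile(
        has_signal_peptide=has_sp,
        sp_end=sp_end,
        ca_variant=ca_variant,
        cat_variant=cat_variant,
        n_cys_domain=cys_census(record, span),
        total_length=total,
        mature_length=mature,
        has_kxel=detect_kxel(record),
        nterm_disorder_score=disorder,
        has_dacc_dyad=has_dacc,
        flags=tuple(span_flags + sp_flags + dis_flags),
        span=span,
    )


@dataclass
class ReferencePanel:
    """Labeled canonical references for the alpha/beta nearest-centroid call."""

    alpha: list[ProteinRecord] = field(default_factory=list)
    beta: list[ProteinRecord] = field(default_factory=list)

    def validate(self) -> None:
        if len(self.alpha) < 2 or len(self.beta) < 2:
            raise ConfigurationError(
                "reference panel needs >= 2 labeled alpha and >= 2 beta sequences"
            )


def _centroid_clade(record: ProteinRecord, panel: ReferencePanel) -> str:
    """Nearest-centroid alpha/beta call by mean global-alignment score."""
    from pa2c.phylo import alignment_score  # deferred: avoids import cycle

    scores_a = [alignment_score(record.sequence, r.sequence) for r in panel.alpha]
    scores_b = [alignment_score(record.sequence, r.sequence) for r in panel.beta]
    mean_a = sum(scores_a) / len(scores_a)
    mean_b = sum(scores_b) / len(scores_b)
    all_scores = scores_a + scores_b
    score_range = max(all_scores) - min(all_scores)
    margin = abs(mean_a - mean_b)
    if score_range == 0 or margin < CENTROID_MARGIN_FRACTION * score_range:
        return "unresolved"
    return "alpha" if mean_a > mean_b else "beta"


def classify(
    record: ProteinRecord,
    profile: Optional[FeatureProfile] = None,
    panel: Optional[ReferencePanel] = None,
) -> CladeCall:
    """Assign a family (and clade, for canonical proteins) with QC flags.

    Decision cascade, in order:

    1. either diagnostic motif absent -> nonPA2c;
    2. both motifs in PLA2-like form and no signal peptide -> PLA2like;
    3. both motifs canonical and signal peptide present -> sPLA2, clade by
       nearest centroid against the reference panel (unresolved inside the
       margin band);
    4. any mixed combination -> the family of the calcium-loop variant,
       flagged MOTIF_CONFLICT (variant mix) and/or SP_CONFLICT (signal
       peptide inconsistent with the family).

    QC flags: CYS_COUNT_ATYPICAL when the census deviates from 12 (sPLA2)
    or 6 (PLA2-like); LENGTH_OUT_OF_RANGE when the sPLA2 mature length
    leaves [90, 191] or the PLA2-like total length leaves [143, 320].
    """
    if panel is None:
        from pa2c.simulate import default_reference_panel

        panel = default_reference_panel()
    panel.validate()
    if profile is None:
        profile = compute_profile(record)

    flags = list(profile.flags)
    family: str
    clade = "not_applicable"

    if profile.ca_variant == "none" or profile.cat_variant == "none":
        family = "nonPA2c"
    elif (
        profile.ca_variant == "like"
        and profile.cat_variant == "like"
        and not profile.has_signal_peptide
    ):
        family = "PLA2like"
    elif (
        profile.ca_variant == "canon"
        and profile.cat_variant == "canon"
        and profile.has_signal_peptide
    ):
        family = "sPLA2"
    else:
        # mixed evidence: calcium-loop variant dominates, conflicts flagged
        family = "sPLA2" if profile.ca_variant == "canon" else "PLA2like"
        if profile.ca_variant != profile.cat_variant:
            flags.append("MOTIF_CONFLICT")
        sp_expected = family == "sPLA2"
        if profile.has_signal_peptide != sp_expected:
            flags.append("SP_CONFLICT")

    if family == "sPLA2":
        clade = _centroid_clade(record, panel)
        if profile.n_cys_domain != SPLA2_CYS:
            flags.append("CYS_COUNT_ATYPICAL")
        lo, hi = SPLA2_MATURE_RANGE
        if not lo <= profile.mature_length <= hi:
            flags.append("LENGTH_OUT_OF_RANGE")
    elif family == "PLA2like":
        if profile.n_cys_domain != PLA2LIKE_CYS:
            flags.append("CYS_COUNT_ATYPICAL")
        lo, hi = PLA2LIKE_TOTAL_RANGE
        if not lo <= profile.total_length <= hi:
            flags.append("LENGTH_OUT_OF_RANGE")

    return CladeCall(
        sequence_id=record.id,
        family=family,
        clade=clade,
        flags=tuple(sorted(set(flags))),
        evidence=profile,
    )
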