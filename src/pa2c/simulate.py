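"""Synthetic PA2c families: proteins, promoters and expression matrices.

The generator emits sequences that carry, by construction, the diagnostic
features that define the three families:

* canonical sPLA2 (alpha / beta): an N-terminal signal peptide (Met, a
  charged di-residue, a 12-residue hydrophobic run), a mature core with
  one canonical calcium loop (YGKYCGxxxxGC), one canonical catalytic dyad
  (DxCCxxHDxC) downstream, exactly twelve cysteines from the calcium loop
  to the C-terminus and a mature length inside [90, 191].  The beta
  centroid ends in KDEL (an ER-retention signal seen in part of the beta
  clade).
* PLA2-like: no signal peptide, a ~100-residue disorder-biased N-terminal
  extension, the variant motifs YGHYCGxxxxxGK / DxCCxxHDxG, exactly six
  cysteines and a total length inside [143, 320].

Alpha and beta descend from distinct fixed centroid cores (divergence
well above 25% outside the anchors).  Point mutations apply everywhere
except the motif literal positions and the counted cysteines, so the
family-diagnostic anchors are invariable by construction at any mutation
rate; ``protect=False`` lifts that guarantee for robustness testing.
Substitutions never introduce new cysteines, keeping the census exact.

All randomness flows through ``numpy.random.Generator`` objects seeded
from the configuration; no global RNG state is touched.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from pa2c.core import ExpressionMatrix, Pa2cError, ProteinRecord, PromoterRecord
from pa2c.promoter import (
    IUPAC,
    CisElement,
    CisHit,
    _consensus_regex,
    default_library,
    reverse_complement,
)

#: substitution alphabet: the 19 standard residues other than cysteine,
#: so mutations can never perturb the cysteine census
AA_NO_CYS = "ADEFGHIKLMNPQRSTVWY"
HYDROPHOBIC = "LIVF"
DISORDER_AA = "PESKQAGR"

#: fixed stream for building the clade centroids (independent of user seeds)
_CENTROID_SEED = 20200521


class GenerationError(Pa2cError):
    pass


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic families.

    Defaults encode the documented family features: mutation rate 0.05
    substitutions/site outside protected anchors, 2000-nt promoters,
    8 sequences per clade, and clade-tissue lognormal expression with the
    alpha clade hard-zeroed in pollen and pollen tube and the beta clade
    given the largest location parameter in male-gametophyte tissues.
    """

    seed: int = 0
    n_per_clade: int = 8
    mutation_rate: float = 0.05
    promoter_length: int = 2000
    gc_content: float = 0.5
    tissues: tuple[str, ...] = (
        "leaf", "stem", "root", "seed", "flower",
        "anther", "pollen", "pollen tube", "carpel", "ovule",
    )
    male_tissues: tuple[str, ...] = ("anther", "pollen", "pollen tube")
    # natural-log lognormal location/scale per clade: (male mu, other mu, sigma)
    expression_params: Mapping[str, tuple[float, float, float]] = field(
        default_factory=lambda: {
            "alpha": (0.0, 3.0, 0.6),   # male mu unused: hard zero in pollen
            "beta": (5.0, 2.0, 0.5),
            "pla2like": (2.5, 2.5, 0.5),
        }
    )

    def __post_init__(self) -> None:
        if not 0 <= self.mutation_rate < 1:
            raise GenerationError("mutation_rate must be in [0, 1)")
        if self.n_per_clade < 1:
            raise GenerationError("n_per_clade must be >= 1")


@dataclass(frozen=True)
class _Centroid:
    """A clade centroid: residue list plus per-position protection mask."""

    clade: str
    residues: tuple[str, ...]
    protected: tuple[bool, ...]
    ca_start: int          # 1-based calcium-loop start
    extra_insert_at: int   # 0-based index where tail padding is inserted
    extra_max: int         # maximum number of padding residues


def _pick(rng: np.random.Generator, alphabet: str, n: int) -> list[str]:
    return [alphabet[i] for i in rng.integers(0, len(alphabet), size=n)]


def _motif_segment(
    literals: str, rng: np.random.Generator
) -> tuple[list[str], list[bool]]:
    """Instantiate a pattern: x -> random non-Cys residue (unprotected)."""
    residues, protected = [], []
    for ch in literals:
        if ch == "x":
            residues.append(_pick(rng, AA_NO_CYS, 1)[0])
            protected.append(False)
        else:
            residues.append(ch)
            protected.append(True)
    return residues, protected


def _plant_cys(
    segment: list[str], protected: list[bool], n: int, rng: np.random.Generator
) -> None:
    """Replace n distinct positions of a filler segment with protected Cys."""
    positions = rng.choice(len(segment), size=n, replace=False)
    for p in sorted(positions):
        segment[p] = "C"
        protected[p] = True


@lru_cache(maxsize=1)
def _centroids() -> dict[str, _Centroid]:
    rng = np.random.default_rng(_CENTROID_SEED)
    out: dict[str, _Centroid] = {}

    for clade in ("alpha", "beta"):
        residues: list[str] = []
        protected: list[bool] = []

        def add(res, prot):
            residues.extend(res)
            protected.extend(prot)

        # signal peptide: M + charged pair + hydrophobic dozen + polar break
        add(list("MKR"), [False] * 3)
        add(_pick(rng, HYDROPHOBIC, 12), [False] * 12)
        add(list("SA"), [False] * 2)
        # mature core
        add(_pick(rng, AA_NO_CYS, 20), [False] * 20)          # pre-loop filler
        ca_start = len(residues) + 1
        add(*_motif_segment("YGKYCGxxxxGC", rng))              # calcium loop
        mid, mid_prot = _pick(rng, AA_NO_CYS, 30), [False] * 30
        _plant_cys(mid, mid_prot, 4, rng)
        add(mid, mid_prot)
        add(*_motif_segment("DxCCxxHDxC", rng))                # catalytic dyad
        tail, tail_prot = _pick(rng, AA_NO_CYS, 25), [False] * 25
        _plant_cys(tail, tail_prot, 3, rng)
        add(tail, tail_prot)
        extra_at = len(residues)
        if clade == "beta":
            add(list("KDEL"), [False] * 4)                     # ER retention
        else:
            add(_pick(rng, AA_NO_CYS, 4), [False] * 4)
        out[clade] = _Centroid(
            clade=clade,
            residues=tuple(residues),
            protected=tuple(protected),
            ca_start=ca_start,
            extra_insert_at=extra_at,
            extra_max=90,  # heuristic mature length spans [100, 190] in [90, 191]
        )

    residues, protected = [], []

    def add(res, prot):
        residues.extend(res)
        protected.extend(prot)

    add(["M"], [False])
    add(_pick(rng, DISORDER_AA, 99), [False] * 99)            # disordered extension
    add(_pick(rng, AA_NO_CYS, 15), [False] * 15)
    ca_start = len(residues) + 1
    add(*_motif_segment("YGHYCGxxxxxGK", rng))
    mid, mid_prot = _pick(rng, AA_NO_CYS, 30), [False] * 30
    _plant_cys(mid, mid_prot, 2, rng)
    add(mid, mid_prot)
    add(*_motif_segment("DxCCxxHDxG", rng))
    tail, tail_prot = _pick(rng, AA_NO_CYS, 16), [False] * 16
    _plant_cys(tail, tail_prot, 1, rng)
    add(tail, tail_prot)
    extra_at = len(residues)
    add(_pick(rng, AA_NO_CYS, 4), [False] * 4)
    out["pla2like"] = _Centroid(
        clade="pla2like",
        residues=tuple(residues),
        protected=tuple(protected),
        ca_start=ca_start,
        extra_insert_at=extra_at,
        extra_max=130,  # total length spans [188, 318] in [143, 320]
    )
    return out


def make_protein(
    clade: str,
    config: Optional[GeneratorConfig] = None,
    rng: Optional[np.random.Generator] = None,
    record_id: Optional[str] = None,
    protect: bool = True,
    fixed_length: bool = False,
) -> ProteinRecord:
    """One synthetic protein of the requested clade, with true_clade set.

    ``fixed_length`` suppresses the random C-terminal padding so all
    members of a clade share the centroid length (used by
    :func:`make_family` to keep the reference alignment indel-free).
    ``protect=False`` lets mutations hit the motif anchors and counted
    cysteines, for classifier robustness testing.
    """
    if clade not in ("alpha", "beta", "pla2like"):
        raise GenerationError(f"unknown clade {clade!r}")
    config = config or GeneratorConfig()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    centroid = _centroids()[clade]

    residues = list(centroid.residues)
    protected = list(centroid.protected)
    if not fixed_length:
        extra = int(rng.integers(0, centroid.extra_max + 1))
        pad = _pick(rng, AA_NO_CYS, extra)
        residues[centroid.extra_insert_at : centroid.extra_insert_at] = pad
        protected[centroid.extra_insert_at : centroid.extra_insert_at] = [False] * extra

    rate = config.mutation_rate
    if rate > 0:
        hits = rng.random(len(residues)) < rate
        for i in np.flatnonzero(hits):
            if protect and protected[i]:
                continue
            current = residues[i]
            choices = [a for a in AA_NO_CYS if a != current]
            residues[i] = choices[int(rng.integers(0, len(choices)))]

    return ProteinRecord(
        id=record_id or f"{clade}_1",
        sequence="".join(residues),
        source="synthetic",
        true_clade=clade,
    )


@dataclass
class FamilyData:
    """A labeled synthetic family plus its indel-free reference alignment."""

    records: list[ProteinRecord]
    labels: dict[str, str]
    alignment: dict[str, str]
    true_tree_newick: str


def make_family(
    config: Optional[GeneratorConfig] = None,
    rng: Optional[np.random.Generator] = None,
) -> FamilyData:
    """n_per_clade descendants of each clade centroid, plus a reference MSA.

    Members are mutation-only descendants (no length padding), so rows of
    one clade are equal-length; the multiple alignment pads every row so
    the calcium-loop anchors coincide, which is exact because the cores
    are indel-free by construction.
    """
    config = config or GeneratorConfig()
    if config.n_per_clade < 2:
        raise GenerationError("make_family needs n_per_clade >= 2")
    if rng is None:
        rng = np.random.default_rng(config.seed)

    records: list[ProteinRecord] = []
    labels: dict[str, str] = {}
    for clade in ("alpha", "beta", "pla2like"):
        for k in range(config.n_per_clade):
            rec = make_protein(
                clade, config, rng, record_id=f"{clade}_{k + 1}", fixed_length=True
            )
            records.append(rec)
            labels[rec.id] = clade

    max_ca = max(c.ca_start for c in _centroids().values())
    padded: dict[str, str] = {}
    for rec in records:
        ca = _centroids()[rec.true_clade].ca_start
        padded[rec.id] = "-" * (max_ca - ca) + rec.sequence
    width = max(len(row) for row in padded.values())
    alignment = {rid: row + "-" * (width - len(row)) for rid, row in padded.items()}

    clades = ("alpha", "beta", "pla2like")
    subtrees = [
        "(" + ",".join(f"{c}_{k + 1}" for k in range(config.n_per_clade)) + ")"
        for c in clades
    ]
    newick = "(" + ",".join(subtrees) + ");"
    return FamilyData(
        records=records, labels=labels, alignment=alignment, true_tree_newick=newick
    )


@lru_cache(maxsize=1)
def default_reference_panel():
    """Bundled labeled references for the alpha/beta nearest-centroid call."""
    from pa2c.features import ReferencePanel

    rng = np.random.default_rng(7_777_777)
    cfg = GeneratorConfig(mutation_rate=0.02)
    panel = ReferencePanel()
    for k in range(2):
        panel.alpha.append(
            make_protein("alpha", cfg, rng, record_id=f"ref_alpha_{k + 1}",
                         fixed_length=True)
        )
    for k in range(2):
        panel.beta.append(
            make_protein("beta", cfg, rng, record_id=f"ref_beta_{k + 1}",
                         fixed_length=True)
        )
    return panel


_BASES = "ACGT"
_MAX_CLEANUP_ROUNDS = 200


def _random_dna(rng: np.random.Generator, n: int, gc: float) -> list[str]:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return [_BASES[i] for i in rng.choice(4, size=n, p=probs)]


def _self_hits(consensus: str, library: Sequence[CisElement]) -> list[tuple[str, str, int]]:
    """Library hits contained in a planted consensus itself (both strands).

    These are inherent to the planted sequence (e.g. the two
    methyl-jasmonate elements are reverse complements of each other) and
    belong in the ground truth rather than being scrubbed.
    """
    hits = []
    for element in library:
        if not element.enabled:
            continue
        fwd = {m.start() for m in _consensus_regex(element.consensus).finditer(consensus)}
        rc = reverse_complement(element.consensus)
        rev = {m.start() for m in _consensus_regex(rc).finditer(consensus)}
        for off in sorted(fwd):
            hits.append((element.name, "+", off))
        for off in sorted(rev - fwd):
            hits.append((element.name, "-", off))
    return hits


def make_promoter(
    planted: Mapping[str, int],
    config: Optional[GeneratorConfig] = None,
    rng: Optional[np.random.Generator] = None,
    library: Optional[Sequence[CisElement]] = None,
    promoter_id: str = "promoter_1",
) -> tuple[PromoterRecord, list[CisHit]]:
    """A promoter with exactly the requested element copies planted.

    Background bases are drawn at the configured GC content and then
    scrubbed: any accidental library match outside the planted loci is
    rewritten with fresh random bases until the scan of the finished
    promoter reproduces the planted ground truth exactly.  Planted loci
    are spaced so they never overlap.  Returns the promoter and the
    ground-truth locus table (element, strand, 1-based start).
    """
    config = config or GeneratorConfig()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    library = list(library) if library is not None else default_library()
    by_name = {e.name: e for e in library if e.enabled}
    for name in planted:
        if name not in by_name:
            raise GenerationError(f"element {name!r} not in library (or disabled)")

    length = config.promoter_length
    max_len = max((len(e.consensus) for e in library if e.enabled), default=0)
    footprint = sum((len(by_name[n].consensus) + 2 * max_len) * c
                    for n, c in planted.items())
    if footprint >= length:
        raise GenerationError("planted elements do not fit in the promoter")

    seq = _random_dna(rng, length, config.gc_content)

    # choose non-overlapping planted loci with a max_len buffer on each side
    reserved: list[tuple[int, int]] = []  # 0-based [start, end) of planted loci
    truth: list[CisHit] = []
    for name in sorted(planted):
        consensus = by_name[name].consensus
        for _ in range(planted[name]):
            for _attempt in range(10_000):
                start = int(rng.integers(0, length - len(consensus) + 1))
                lo, hi = start - max_len, start + len(consensus) + max_len
                if all(hi <= s or lo >= e for s, e in reserved):
                    break
            else:
                raise GenerationError("could not place planted elements")
            reserved.append((start, start + len(consensus)))
            concrete = "".join(
                c if c in _BASES else IUPAC[c][int(rng.integers(0, len(IUPAC[c])))]
                for c in consensus.upper()
            )
            seq[start : start + len(consensus)] = list(concrete)
            for el_name, strand, off in _self_hits(concrete, library):
                truth.append(CisHit(el_name, strand, start + off + 1))

    expected = {(h.element, h.start) for h in truth}
    from pa2c.promoter import scan_promoter  # local import avoids a cycle

    for _round in range(_MAX_CLEANUP_ROUNDS):
        record = PromoterRecord(id=promoter_id, sequence="".join(seq))
        observed = {(h.element, h.start) for h in scan_promoter(record, library)}
        extra = observed - expected
        if not extra and observed == expected:
            truth.sort(key=lambda h: (h.start, h.element, h.strand))
            return record, truth
        for el_name, start in sorted(extra):
            width = len(by_name[el_name].consensus)
            for pos in range(start - 1, start - 1 + width):
                if any(s <= pos < e for s, e in reserved):
                    continue
                seq[pos] = _BASES[int(rng.integers(0, 4))]
    raise GenerationError("promoter scrubbing did not converge")


def make_expression(
    config: Optional[GeneratorConfig] = None,
    rng: Optional[np.random.Generator] = None,
) -> tuple[ExpressionMatrix, dict[str, str]]:
    """A TPM matrix with the clade-tissue structure of the three families.

    Alpha genes are exactly zero in pollen and pollen tube and lognormal
    elsewhere; beta genes draw their male-gametophyte values with the
    largest location parameter; PLA2-like genes are moderate everywhere.
    Returns the matrix and the gene-to-clade map.
    """
    config = config or GeneratorConfig()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if not {"pollen", "pollen tube"} <= set(config.tissues):
        raise GenerationError("tissue list must include pollen and pollen tube")

    rows = {}
    clade_map = {}
    for clade in ("alpha", "beta", "pla2like"):
        male_mu, other_mu, sigma = config.expression_params[clade]
        for k in range(config.n_per_clade):
            gene = f"{clade}_{k + 1}"
            clade_map[gene] = clade
            values = []
            for tissue in config.tissues:
                if clade == "alpha" and tissue in ("pollen", "pollen tube"):
                    values.append(0.0)
                    continue
                mu = male_mu if tissue in config.male_tissues else other_mu
                values.append(float(rng.lognormal(mean=mu, sigma=sigma)))
            rows[gene] = values
    df = pd.DataFrame.from_dict(rows, orient="index", columns=list(config.tissues))
    df.index.name = "gene"
    return ExpressionMatrix(df), clade_map
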