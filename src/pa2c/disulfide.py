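"""Disulfide-bridge arithmetic and template-based bridge conservation.

Canonical plant sPLA2 proteins carry twelve cysteines forming six
disulfide bridges; PLA2-like proteins carry six cysteines, allowing at
most three.  Structural comparison further shows that only four of the
twelve canonical cysteine positions are conserved in PLA2-like
sequences, forming two retained bridges (C140-C167 and C166-C192 in
PLA2-like residue numbering), which correspond structurally to the
porcine PLA2 anchors C29-C45 and C44-C105.

The two statements (six cysteines / up to three bridges, versus four
conserved positions / two retained bridges) answer different questions —
combinatorial capacity versus template conservation — and both are
exposed here without forcing them to agree.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from pa2c.core import ValidationError


@dataclass(frozen=True)
class BridgePair:
    """An ordered cysteine pair on a reference numbering.

    ``specified=False`` marks placeholder pairs whose partners are not
    published; they are carried for completeness but excluded from
    retained-bridge claims.
    """

    first: int
    second: int
    specified: bool = True

    def as_tuple(self) -> tuple[int, int]:
        return (self.first, self.second)


#: The two published PLA2-like bridge pairs plus four unspecified
#: placeholders completing the canonical six-bridge topology.
CANONICAL_TEMPLATE: tuple[BridgePair, ...] = (
    BridgePair(140, 167),
    BridgePair(166, 192),
    BridgePair(0, 0, specified=False),
    BridgePair(0, 0, specified=False),
    BridgePair(0, 0, specified=False),
    BridgePair(0, 0, specified=False),
)

#: Structurally corresponding bridges of porcine pancreatic PLA2.
PORCINE_ANCHORS: tuple[tuple[int, int], ...] = ((29, 45), (44, 105))


def max_bridge_count(n_cys: int) -> int:
    """Maximum number of disulfide bridges formable from ``n_cys`` cysteines."""
    if n_cys < 0:
        raise ValidationError(f"negative cysteine count: {n_cys}")
    return n_cys // 2


def retained_bridges(
    conserved_positions: Iterable[int],
    template: Sequence[BridgePair] = CANONICAL_TEMPLATE,
) -> list[tuple[int, int]]:
    """Template pairs whose both partners are conserved, in template order.

    Placeholder (unspecified) template pairs never count as retained.
    """
    conserved = set(conserved_positions)
    return [
        pair.as_tuple()
        for pair in template
        if pair.specified and pair.first in conserved and pair.second in conserved
    ]


@dataclass(frozen=True)
class BridgeTopology:
    """Bridge capacity and template conservation for one protein."""

    n_cys: int
    max_bridges: int
    template_bridges: tuple[BridgePair, ...] = CANONICAL_TEMPLATE
    retained: tuple[tuple[int, int], ...] = field(default_factory=tuple)

    @classmethod
    def from_census(
        cls,
        n_cys: int,
        conserved_positions: Iterable[int] = (),
        template: Sequence[BridgePair] = CANONICAL_TEMPLATE,
    ) -> "BridgeTopology":
        return cls(
            n_cys=n_cys,
            max_bridges=max_bridge_count(n_cys),
            template_bridges=tuple(template),
            retained=tuple(retained_bridges(conserved_positions, template)),
        )
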