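"""Consequence classes and their fixed severity order."""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Optional


class Consequence(str, enum.Enum):
    synonymous = "synonymous"
    missense = "missense"
    stop_gain = "stop_gain"
    stop_loss = "stop_loss"
    splice_donor = "splice_donor"
    splice_acceptor = "splice_acceptor"
    frameshift = "frameshift"
    inframe_indel = "inframe_indel"
    utr5 = "utr5"
    utr3 = "utr3"
    intronic = "intronic"
    intergenic = "intergenic"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Larger = more severe.  The donor/acceptor pair and the two UTR classes
#: are deliberate ties.
SEVERITY: dict[Consequence, int] = {
    Consequence.stop_gain: 11,
    Consequence.stop_loss: 10,
    Consequence.frameshift: 9,
    Consequence.splice_donor: 8,
    Consequence.splice_acceptor: 8,
    Consequence.missense: 7,
    Consequence.inframe_indel: 6,
    Consequence.synonymous: 5,
    Consequence.utr5: 4,
    Consequence.utr3: 4,
    Consequence.intronic: 2,
    Consequence.intergenic: 1,
}

_ORDER = list(Consequence)


def most_severe(classes: Iterable[Consequence]) -> Consequence:
    """Highest-severity class; severity ties resolve by enum order."""
    classes = list(classes)
    if not classes:
        raise ValueError("no consequence classes given")
    return max(classes, key=lambda c: (SEVERITY[c], -_ORDER.index(c)))


@dataclass(frozen=True)
class ConsequenceCall:
    """One (variant, transcript) consequence with optional codon detail."""

    consequence: Consequence
    transcript_id: Optional[str] = None
    gene_id: Optional[str] = None
    codon_change: Optional[str] = None
    protein_change: Optional[str] = None
    flags: tuple[str, ...] = field(default_factory=tuple)

    @property
    def severity(self) -> int:
        return SEVERITY[self.consequence]
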