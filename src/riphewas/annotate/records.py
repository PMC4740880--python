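"""Variant records (VCF conventions: 1-based position, anchored indels)."""

from __future__ import annotations

from dataclasses import dataclass

_DNA = set("ACGT")


class ReferenceMismatchError(ValueError):
    """Raised when a variant's REF disagrees with the genome sequence."""


@dataclass(frozen=True)
class VariantRecord:
    """A sequence variant in VCF convention.

    ``position`` is 1-based; indel records carry the usual shared anchor
    base.  ``ref``/``alt`` are non-empty strings over ACGT.
    """

    chromosome: str
    position: int
    ref: str
    alt: str

    def __post_init__(self):
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        for name in ("ref", "alt"):
            allele = getattr(self, name)
            if not allele or not set(allele) <= _DNA:
                raise ValueError(f"invalid {name} allele {allele!r}")

    @property
    def variant_class(self) -> str:
        """'SNV', 'insertion' or 'deletion' (net length change sign)."""
        if len(self.ref) == 1 and len(self.alt) == 1:
            return "SNV"
        return "insertion" if len(self.alt) > len(self.ref) else "deletion"

    @property
    def is_snv(self) -> bool:
        return self.variant_class == "SNV"

    @property
    def pos0(self) -> int:
        """0-based position of the first REF base."""
        return self.position - 1

    @property
    def variant_id(self) -> str:
        return f"{self.chromosome}:{self.position}:{self.ref}>{self.alt}"

    def affected_interval(self) -> tuple[int, int]:
        """0-based half-open genomic interval the variant alters.

        SNV: the single base.  Deletion (anchored): the deleted bases,
        excluding the anchor.  Insertion: the zero-width insertion point
        after the anchor base.
        """
        if self.is_snv:
            return (self.pos0, self.pos0 + 1)
        if self.variant_class == "deletion":
            return (self.pos0 + len(self.alt), self.pos0 + len(self.ref))
        point = self.pos0 + len(self.ref)
        return (point, point)
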