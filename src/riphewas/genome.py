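"""Genome sequence access and transcript models.

All internal coordinates are 0-based half-open.  Conversion to/from the
1-based conventions of VCF and GFF3 happens at the IO boundary only
(:mod:`riphewas.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse-complement a DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


class Genome:
    """Random-access view over chromosome sequences.

    Wraps a plain ``{name: sequence}`` mapping (in-memory genomes from the
    simulators) or any object with the same ``__getitem__`` semantics, e.g.
    ``pyfaidx.Fasta`` records exposed through :func:`riphewas.io.read_fasta`.
    """

    def __init__(self, sequences: Mapping[str, str]):
        self._seqs = {name: str(seq) for name, seq in sequences.items()}

    @property
    def chromosomes(self) -> list[str]:
        return list(self._seqs)

    def length(self, chrom: str) -> int:
        return len(self._seq(chrom))

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Sequence of ``chrom[start:end)`` (0-based half-open), uppercased."""
        if start < 0 or end > self.length(chrom):
            raise ValueError(
                f"interval [{start}, {end}) outside {chrom} "
                f"(length {self.length(chrom)})"
            )
        return self._seq(chrom)[start:end].upper()

    def base(self, chrom: str, pos: int) -> str:
        """Single base at 0-based ``pos``."""
        return self.fetch(chrom, pos, pos + 1)

    def _seq(self, chrom: str) -> str:
        try:
            return self._seqs[chrom]
        except KeyError:
            raise KeyError(
                f"unknown chromosome {chrom!r}; known: {sorted(self._seqs)}"
            ) from None

    def reverse_complemented(self) -> "Genome":
        """Mirror genome with every chromosome reverse-complemented."""
        return Genome({c: revcomp(s) for c, s in self._seqs.items()})


@dataclass(frozen=True)
class TranscriptModel:
    """A transcript with exon and CDS structure.

    ``exons`` and ``cds`` are sorted tuples of 0-based half-open genomic
    intervals.  A model whose total CDS length is not divisible by 3 is
    flagged incomplete and never receives codon-level consequence calls.
    """

    transcript_id: str
    gene_id: str
    chromosome: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds: tuple[tuple[int, int], ...] = ()

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        for name in ("exons", "cds"):
            ivs = getattr(self, name)
            object.__setattr__(self, name, tuple(tuple(iv) for iv in ivs))
            ivs = getattr(self, name)
            for s, e in ivs:
                if e <= s:
                    raise ValueError(f"empty/inverted {name} interval ({s}, {e})")
            for (s0, e0), (s1, e1) in zip(ivs, ivs[1:]):
                if s1 < e0:
                    raise ValueError(f"{name} intervals overlap or are unsorted")

    # -- basic geometry -----------------------------------------------------

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds)

    @property
    def is_coding(self) -> bool:
        return bool(self.cds)

    @property
    def cds_complete(self) -> bool:
        return self.is_coding and self.cds_length % 3 == 0

    def introns(self) -> list[tuple[int, int]]:
        """Genomic intron intervals (between consecutive exons)."""
        return [
            (e0, s1) for (_, e0), (s1, _) in zip(self.exons, self.exons[1:])
        ]

    # -- strand-aware views -------------------------------------------------

    def cds_positions(self) -> list[int]:
        """Genomic positions of CDS bases in translation order.

        Ascending for '+' transcripts, descending for '-'.
        """
        pos = [p for s, e in self.cds for p in range(s, e)]
        return pos if self.strand == "+" else pos[::-1]

    def exon_positions(self) -> set[int]:
        return {p for s, e in self.exons for p in range(s, e)}

    def cds_position_set(self) -> set[int]:
        return {p for s, e in self.cds for p in range(s, e)}

    def splice_sites(self) -> dict[int, str]:
        """Map genomic position -> 'donor'/'acceptor' for the 2 intronic
        bases flanking each exon boundary.

        Donor = the two intron bases adjacent to the transcriptionally
        upstream exon (sense GT); acceptor = the two adjacent to the
        downstream exon (sense AG).
        """
        sites: dict[int, str] = {}
        for s, e in self.introns():
            left = {s, s + 1}
            right = {e - 2, e - 1}
            if self.strand == "+":
                donor, acceptor = left, right
            else:
                donor, acceptor = right, left
            for p in donor:
                sites[p] = "donor"
            for p in acceptor:
                sites[p] = "acceptor"
        return sites

    def sense_base(self, genome: Genome, pos: int) -> str:
        """Base at genomic ``pos`` read on the coding strand."""
        b = genome.base(self.chromosome, pos)
        return b if self.strand == "+" else revcomp(b)

    def cds_start_genomic(self) -> int:
        """Genomic coordinate of the first translated base."""
        if not self.is_coding:
            raise ValueError(f"{self.transcript_id} is non-coding")
        return self.cds[0][0] if self.strand == "+" else self.cds[-1][1] - 1

    def mirrored(self, chrom_length: int) -> "TranscriptModel":
        """Model on the reverse-complemented chromosome (for symmetry tests)."""
        flip = lambda s, e: (chrom_length - e, chrom_length - s)  # noqa: E731
        return TranscriptModel(
            transcript_id=self.transcript_id,
            gene_id=self.gene_id,
            chromosome=self.chromosome,
            strand="-" if self.strand == "+" else "+",
            exons=tuple(sorted(flip(s, e) for s, e in self.exons)),
            cds=tuple(sorted(flip(s, e) for s, e in self.cds)),
        )
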