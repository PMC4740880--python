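"""Synthetic genome + transcript model generation.

Emits multi-exon protein-coding transcripts on both strands whose
sequence and structure are mutually consistent: ATG start, single
terminal stop, no internal in-frame stop, CDS length divisible by 3,
UTRs on both ends, and canonical GT donor / AG acceptor intron
dinucleotides on the coding strand.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from riphewas.genome import Genome, TranscriptModel, revcomp

_BASES = np.array(list("ACGT"))
_STOPS = ("TAA", "TAG", "TGA")


@dataclass
class GeneModels:
    """Bundle of a synthetic genome and its transcript models."""

    genome: Genome
    transcripts: list[TranscriptModel]


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_BASES, size=n))


def _random_codon(rng: np.random.Generator) -> str:
    while True:
        c = _random_seq(rng, 3)
        if c not in _STOPS and c != "ATG":
            return c


def _build_sense_gene(
    rng: np.random.Generator,
) -> tuple[str, list[tuple[int, int]], list[tuple[int, int]]]:
    """One gene in local sense coordinates.

    Returns (sense sequence, exon intervals, cds intervals), both interval
    lists 0-based half-open in local sense coordinates.
    """
    n_codons = int(rng.integers(30, 81))
    cds_seq = (
        "ATG"
        + "".join(_random_codon(rng) for _ in range(n_codons - 2))
        + str(rng.choice(_STOPS))
    )
    n_exons = int(rng.integers(2, 5))
    # split CDS into n_exons non-empty pieces
    cuts = np.sort(rng.choice(np.arange(1, len(cds_seq)), n_exons - 1, replace=False))
    pieces = np.split(np.frombuffer(cds_seq.encode(), dtype="S1"), cuts)
    cds_parts = [b"".join(p).decode() for p in pieces]
    utr5 = _random_seq(rng, int(rng.integers(20, 61)))
    utr3 = _random_seq(rng, int(rng.integers(20, 61)))

    seq_parts: list[str] = []
    exons: list[tuple[int, int]] = []
    cds: list[tuple[int, int]] = []
    pos = 0

    def _append(s: str) -> tuple[int, int]:
        nonlocal pos
        start = pos
        seq_parts.append(s)
        pos += len(s)
        return (start, pos)

    for i, part in enumerate(cds_parts):
        exon_start = pos
        if i == 0:
            _append(utr5)
        cds.append(_append(part))
        if i == len(cds_parts) - 1:
            _append(utr3)
        exons.append((exon_start, pos))
        if i < len(cds_parts) - 1:
            intron_mid = _random_seq(rng, int(rng.integers(26, 77)))
            _append("GT" + intron_mid + "AG")
    return "".join(seq_parts), exons, cds


def simulate_gene_models(
    n_genes: int,
    seed: int,
    chrom: str = "chr1",
    spacer: int = 400,
) -> GeneModels:
    """Generate ``n_genes`` coding transcripts on one synthetic chromosome.

    Strands alternate deterministically so both are always exercised.
    Genes are separated by random intergenic spacers of length ``spacer``.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = np.random.default_rng(seed)
    chrom_parts: list[str] = [_random_seq(rng, spacer)]
    offset = spacer
    transcripts: list[TranscriptModel] = []
    for gi in range(n_genes):
        sense_seq, exons, cds = _build_sense_gene(rng)
        strand = "+" if gi % 2 == 0 else "-"
        glen = len(sense_seq)
        if strand == "+":
            genomic_seq = sense_seq
            gexons = [(offset + s, offset + e) for s, e in exons]
            gcds = [(offset + s, offset + e) for s, e in cds]
        else:
            genomic_seq = revcomp(sense_seq)
            gexons = sorted((offset + glen - e, offset + glen - s) for s, e in exons)
            gcds = sorted((offset + glen - e, offset + glen - s) for s, e in cds)
        transcripts.append(
            TranscriptModel(
                transcript_id=f"tx{gi:04d}",
                gene_id=f"gene{gi:04d}",
                chromosome=chrom,
                strand=strand,
                exons=tuple(gexons),
                cds=tuple(gcds),
            )
        )
        chrom_parts.append(genomic_seq)
        offset += glen
        chrom_parts.append(_random_seq(rng, spacer))
        offset += spacer
    genome = Genome({chrom: "".join(chrom_parts)})
    return GeneModels(genome=genome, transcripts=transcripts)
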