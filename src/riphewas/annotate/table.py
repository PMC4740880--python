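"""Whole-catalog annotation: one row per variant, most severe transcript."""

from __future__ import annotations

from typing import Sequence

import pandas as pd

from riphewas.annotate.classify import classify_variant
from riphewas.annotate.consequence import Consequence, ConsequenceCall
from riphewas.annotate.records import VariantRecord
from riphewas.genome import Genome, TranscriptModel

TABLE_COLUMNS = [
    "variant_id",
    "chromosome",
    "position",
    "ref",
    "alt",
    "variant_class",
    "gene_id",
    "transcript_id",
    "consequence",
    "codon_change",
    "protein_change",
    "flags",
]


def annotate_variants(
    variants: Sequence[VariantRecord],
    transcripts: Sequence[TranscriptModel],
    genome: Genome,
) -> tuple[pd.DataFrame, pd.Series]:
    """Annotate variants; aggregate multi-transcript hits by severity.

    Returns the annotation table (sorted by chrom, position, ref, alt;
    deterministic) and per-class counts over all consequence classes.
    """
    by_chrom: dict[str, list[TranscriptModel]] = {}
    for t in transcripts:
        by_chrom.setdefault(t.chromosome, []).append(t)

    rows = []
    for v in sorted(variants, key=lambda x: (x.chromosome, x.position, x.ref, x.alt)):
        a, b = v.affected_interval()
        hits = [
            t
            for t in by_chrom.get(v.chromosome, [])
            if t.span[0] < max(b, a + 1) and a < t.span[1]
        ]
        if hits:
            calls = [classify_variant(v, t, genome) for t in hits]
            # most severe; ties resolve toward lower transcript id
            call = min(
                calls, key=lambda c: (-c.severity, c.transcript_id or "")
            )
        else:
            call = ConsequenceCall(Consequence.intergenic)
        rows.append(
            (
                v.variant_id,
                v.chromosome,
                v.position,
                v.ref,
                v.alt,
                v.variant_class,
                call.gene_id,
                call.transcript_id,
                call.consequence.value,
                call.codon_change,
                call.protein_change,
                ";".join(call.flags),
            )
        )
    table = pd.DataFrame(rows, columns=TABLE_COLUMNS)
    counts = (
        table["consequence"]
        .value_counts()
        .reindex([c.value for c in Consequence], fill_value=0)
        .rename("count")
    )
    return table, counts


def annotate_vcf(
    vcf_path: str,
    transcripts: Sequence[TranscriptModel],
    genome: Genome,
) -> tuple[pd.DataFrame, pd.Series]:
    """Annotate a VCF file (wrapper over :func:`annotate_variants`)."""
    from riphewas.io import read_vcf

    return annotate_variants(read_vcf(vcf_path), transcripts, genome)
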