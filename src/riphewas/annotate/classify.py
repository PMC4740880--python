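"""Consequence classification of SNVs and indels against transcript models.

Coordinates are 0-based half-open internally; :class:`VariantRecord`
carries the VCF 1-based position and is converted here.  Codon-level
calls are computed on the coding strand (reverse-complemented for '-'
transcripts).  Splice calls cover the two intronic bases adjacent to
each exon boundary (donor GT / acceptor AG on the coding strand) and
outrank plain intronic assignment.
"""

from __future__ import annotations

from Bio.Seq import Seq

from riphewas.annotate.consequence import Consequence, ConsequenceCall, most_severe
from riphewas.annotate.records import ReferenceMismatchError, VariantRecord
from riphewas.genome import Genome, TranscriptModel, revcomp


def _translate(codon: str) -> str:
    return str(Seq(codon).translate())


def _check_ref(v: VariantRecord, genome: Genome) -> None:
    observed = genome.fetch(v.chromosome, v.pos0, v.pos0 + len(v.ref))
    if observed != v.ref:
        raise ReferenceMismatchError(
            f"REF mismatch at {v.chromosome}:{v.position}: "
            f"variant says {v.ref!r}, genome has {observed!r}"
        )


def normalize_variant(v: VariantRecord, genome: Genome) -> VariantRecord:
    """Left-normalize an indel to VCF parsimony (SNVs pass through).

    Trims shared suffix/prefix bases, then shifts left while the trailing
    allele base matches the reference base to the left.
    """
    _check_ref(v, genome)
    if v.is_snv:
        return v
    pos0, ref, alt = v.pos0, v.ref, v.alt
    while True:
        if len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
            ref, alt = ref[:-1], alt[:-1]
            continue
        if len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
            ref, alt = ref[1:], alt[1:]
            pos0 += 1
            continue
        break
    while (
        len(ref) != len(alt)
        and ref[-1] == alt[-1]
        and pos0 > 0
    ):
        prev = genome.base(v.chromosome, pos0 - 1)
        ref = prev + ref[:-1]
        alt = prev + alt[:-1]
        pos0 -= 1
    return VariantRecord(v.chromosome, pos0 + 1, ref, alt)


def _utr_side(t: TranscriptModel, pos: int) -> Consequence:
    """UTR class for an exonic, non-CDS position of a coding transcript."""
    if t.strand == "+":
        return Consequence.utr5 if pos < t.cds[0][0] else Consequence.utr3
    return Consequence.utr5 if pos >= t.cds[-1][1] else Consequence.utr3


def _noncoding_class(t: TranscriptModel, pos: int) -> tuple[Consequence, tuple[str, ...]]:
    """Class for a position inside the transcript span, ignoring codons."""
    sites = t.splice_sites()
    if pos in sites:
        return (
            Consequence.splice_donor
            if sites[pos] == "donor"
            else Consequence.splice_acceptor,
            (),
        )
    in_exon = any(s <= pos < e for s, e in t.exons)
    if not in_exon:
        return Consequence.intronic, ()
    if not t.is_coding:
        # non-coding transcript: exonic hit reported as intronic-to-gene
        return Consequence.intronic, ("noncoding_transcript",)
    if not t.cds_complete:
        flags = ("incomplete_cds",)
        if any(s <= pos < e for s, e in t.cds):
            # codon call impossible; fall back to the nearest UTR side
            side = (
                Consequence.utr5
                if (t.strand == "+" and pos < t.cds[0][0] + 1)
                or (t.strand == "-" and pos >= t.cds[-1][1] - 1)
                else Consequence.utr3
            )
            return side, flags
        return _utr_side(t, pos), flags
    if any(s <= pos < e for s, e in t.cds):
        raise AssertionError("CDS positions handled by the codon path")
    return _utr_side(t, pos), ()


def classify_snv(
    v: VariantRecord, t: TranscriptModel, genome: Genome
) -> ConsequenceCall:
    """Classify a single-nucleotide variant against one transcript."""
    if not v.is_snv:
        raise ValueError("classify_snv requires an SNV")
    _check_ref(v, genome)
    pos = v.pos0
    lo, hi = t.span
    base = dict(transcript_id=t.transcript_id, gene_id=t.gene_id)
    if not lo <= pos < hi:
        return ConsequenceCall(Consequence.intergenic, **base)
    if t.cds_complete and any(s <= pos < e for s, e in t.cds):
        cds_pos = t.cds_positions()
        idx = cds_pos.index(pos)
        codon_i, off = divmod(idx, 3)
        codon_positions = cds_pos[3 * codon_i : 3 * codon_i + 3]
        ref_codon = "".join(t.sense_base(genome, p) for p in codon_positions)
        alt_base = v.alt if t.strand == "+" else revcomp(v.alt)
        alt_codon = ref_codon[:off] + alt_base + ref_codon[off + 1 :]
        ref_aa, alt_aa = _translate(ref_codon), _translate(alt_codon)
        if ref_aa == "*" and alt_aa != "*":
            cls = Consequence.stop_loss
        elif alt_aa == "*" and ref_aa != "*":
            cls = Consequence.stop_gain
        elif ref_aa == alt_aa:
            cls = Consequence.synonymous
        else:
            cls = Consequence.missense
        return ConsequenceCall(
            cls,
            codon_change=f"{ref_codon}>{alt_codon}",
            protein_change=f"{ref_aa}{codon_i + 1}{alt_aa}",
            **base,
        )
    cls, flags = _noncoding_class(t, pos)
    return ConsequenceCall(cls, flags=flags, **base)


def classify_indel(
    v: VariantRecord, t: TranscriptModel, genome: Genome
) -> ConsequenceCall:
    """Classify an indel against one transcript.

    The variant is left-normalized first.  A CDS-overlapping indel is a
    frameshift when the net length change is not a multiple of 3, else an
    in-frame indel.  Boundary-spanning indels take the most severe class
    among all regions overlapped.
    """
    if v.is_snv:
        raise ValueError("classify_indel requires an indel")
    v = normalize_variant(v, genome)
    a, b = v.affected_interval()
    base = dict(transcript_id=t.transcript_id, gene_id=t.gene_id)
    lo, hi = t.span
    is_insertion = a == b

    def overlaps(s: int, e: int) -> bool:
        if is_insertion:
            return s < a < e
        return a < e and s < b

    if not overlaps(lo, hi):
        return ConsequenceCall(Consequence.intergenic, **base)

    classes: list[Consequence] = []
    flags: tuple[str, ...] = ()
    net = abs(len(v.ref) - len(v.alt))
    if any(overlaps(s, e) for s, e in t.cds):
        if t.cds_complete:
            classes.append(
                Consequence.frameshift if net % 3 else Consequence.inframe_indel
            )
        else:
            flags = ("incomplete_cds",)
    sites = t.splice_sites()
    hit_sites = (
        {kind for p, kind in sites.items() if a - 1 < p < b}
        if not is_insertion
        # an insertion disrupts a site only when it lands between the
        # two bases of the dinucleotide
        else {
            kind
            for p, kind in sites.items()
            if p + 1 in sites and sites[p + 1] == kind and p + 1 == a
        }
    )
    if "donor" in hit_sites:
        classes.append(Consequence.splice_donor)
    if "acceptor" in hit_sites:
        classes.append(Consequence.splice_acceptor)
    exon_hit = any(overlaps(s, e) for s, e in t.exons)
    cds_hit = any(overlaps(s, e) for s, e in t.cds)
    if exon_hit and t.is_coding and not cds_hit:
        probe = a if not is_insertion else a - 1
        classes.append(_utr_side(t, min(max(probe, lo), hi - 1)))
    if not exon_hit and not hit_sites:
        classes.append(Consequence.intronic)
    if not classes:
        classes.append(Consequence.intronic)
    return ConsequenceCall(most_severe(classes), flags=flags, **base)


def classify_variant(
    v: VariantRecord, t: TranscriptModel, genome: Genome
) -> ConsequenceCall:
    """Dispatch to :func:`classify_snv` or :func:`classify_indel`."""
    if v.is_snv:
        return classify_snv(v, t, genome)
    return classify_indel(v, t, genome)
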