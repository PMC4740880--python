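"""Variant catalogs with known-truth consequence labels.

Truth labels come from the generative construction itself (codon-table
edits, splice-dinucleotide positions, indel length arithmetic), never
from the classifier under test, so the catalog doubles as an oracle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from riphewas.annotate.classify import normalize_variant
from riphewas.annotate.records import VariantRecord
from riphewas.genome import Genome, TranscriptModel, revcomp
from riphewas.simulate.genes import GeneModels

_BASES = "ACGT"
_STOPS = {"TAA", "TAG", "TGA"}

SNV_CLASSES = (
    "synonymous",
    "missense",
    "stop_gain",
    "stop_loss",
    "splice_donor",
    "splice_acceptor",
    "utr5",
    "utr3",
    "intronic",
    "intergenic",
)
INDEL_CLASSES = ("frameshift", "inframe_indel", "intronic_indel")


@dataclass
class VariantCatalog:
    """Planted variants plus their construction-truth labels."""

    variants: list[VariantRecord]
    truth: pd.DataFrame  # variant_id, chromosome, position, ref, alt, true_class


def _aa(codon: str) -> str:
    return str(Seq(codon).translate())


def _snv_candidates_for_transcript(
    t: TranscriptModel, genome: Genome
) -> dict[str, list[tuple[int, str, str]]]:
    """Per-class SNV candidates as (pos0, ref, alt) on the plus strand."""
    out: dict[str, list[tuple[int, str, str]]] = {c: [] for c in SNV_CLASSES}
    cds_pos = t.cds_positions()
    n_codons = len(cds_pos) // 3
    for ci in range(1, n_codons):  # skip the start codon
        cpos = cds_pos[3 * ci : 3 * ci + 3]
        ref_codon = "".join(t.sense_base(genome, p) for p in cpos)
        is_stop = ref_codon in _STOPS
        for off in range(3):
            for alt_sense in _BASES:
                if alt_sense == ref_codon[off]:
                    continue
                alt_codon = ref_codon[:off] + alt_sense + ref_codon[off + 1 :]
                if is_stop:
                    cls = None if alt_codon in _STOPS else "stop_loss"
                elif alt_codon in _STOPS:
                    cls = "stop_gain"
                elif _aa(alt_codon) == _aa(ref_codon):
                    cls = "synonymous"
                else:
                    cls = "missense"
                if cls is None:
                    continue
                gpos = cpos[off]
                ref_plus = genome.base(t.chromosome, gpos)
                alt_plus = alt_sense if t.strand == "+" else revcomp(alt_sense)
                out[cls].append((gpos, ref_plus, alt_plus))
    for pos, kind in t.splice_sites().items():
        ref_plus = genome.base(t.chromosome, pos)
        for alt in _BASES:
            if alt != ref_plus:
                out[f"splice_{kind}"].append((pos, ref_plus, alt))
    cds_set = t.cds_position_set()
    for s, e in t.exons:
        for p in range(s, e):
            if p in cds_set:
                continue
            side = _utr_side_label(t, p)
            ref_plus = genome.base(t.chromosome, p)
            for alt in _BASES:
                if alt != ref_plus:
                    out[side].append((p, ref_plus, alt))
    for s, e in t.introns():
        for p in range(s + 6, e - 6):
            ref_plus = genome.base(t.chromosome, p)
            for alt in _BASES:
                if alt != ref_plus:
                    out["intronic"].append((p, ref_plus, alt))
    return out


def _utr_side_label(t: TranscriptModel, pos: int) -> str:
    if t.strand == "+":
        return "utr5" if pos < t.cds[0][0] else "utr3"
    return "utr5" if pos >= t.cds[-1][1] else "utr3"


def _intergenic_candidates(
    models: GeneModels, margin: int = 25
) -> list[tuple[str, int, str]]:
    out = []
    spans: dict[str, list[tuple[int, int]]] = {}
    for t in models.transcripts:
        spans.setdefault(t.chromosome, []).append(t.span)
    for chrom in models.genome.chromosomes:
        occupied = np.zeros(models.genome.length(chrom), dtype=bool)
        for s, e in spans.get(chrom, []):
            occupied[max(0, s - margin) : e + margin] = True
        free = np.flatnonzero(~occupied)
        for p in free:
            out.append((chrom, int(p), models.genome.base(chrom, int(p))))
    return out


def _stable(v: VariantRecord, genome: Genome) -> bool:
    """True when left-normalization leaves the record unchanged."""
    return normalize_variant(v, genome) == v


def _indel_candidates_for_transcript(
    t: TranscriptModel, genome: Genome, rng: np.random.Generator
) -> dict[str, list[VariantRecord]]:
    """Indel candidates per class (deletions and insertions mixed)."""
    out: dict[str, list[VariantRecord]] = {c: [] for c in INDEL_CLASSES}
    chrom = t.chromosome
    for s, e in t.cds:
        for a in range(s + 4, e - 8):
            for cls, length in (
                ("frameshift", 1),
                ("frameshift", 2),
                ("frameshift", 4),
                ("inframe_indel", 3),
            ):
                if a + length >= e - 2:
                    continue
                ref = genome.fetch(chrom, a - 1, a + length)
                v = VariantRecord(chrom, a, ref, ref[0])  # deletion
                if _stable(v, genome):
                    out[cls].append(v)
            # insertions after base a-1 (insertion point = a)
            anchor = genome.base(chrom, a - 1)
            for cls, ins_len in (("frameshift", 2), ("inframe_indel", 3)):
                ins = "".join(
                    rng.choice(list(_BASES), size=ins_len)
                )
                v = VariantRecord(chrom, a, anchor, anchor + ins)
                if _stable(v, genome):
                    out[cls].append(v)
    for s, e in t.introns():
        for a in range(s + 16, e - 16 - 11):
            ref = genome.fetch(chrom, a - 1, a + 11)
            v = VariantRecord(chrom, a, ref, ref[0])
            if _stable(v, genome):
                out["intronic_indel"].append(v)
    return out


def simulate_variant_catalog(
    models: GeneModels,
    counts: dict[str, int],
    seed: int,
) -> VariantCatalog:
    """Plant ``counts[class]`` variants of each requested class.

    Supported classes: the SNV classes (synonymous, missense, stop_gain,
    stop_loss, splice_donor, splice_acceptor, utr5, utr3, intronic,
    intergenic) plus ``frameshift``, ``inframe_indel`` and
    ``intronic_indel``.  Raises if the gene models cannot supply enough
    non-colliding sites of a class.
    """
    unknown = set(counts) - set(SNV_CLASSES) - set(INDEL_CLASSES)
    if unknown:
        raise ValueError(f"unknown variant classes requested: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    genome = models.genome

    snv_pool: dict[str, list[tuple[str, int, str, str]]] = {
        c: [] for c in SNV_CLASSES
    }
    indel_pool: dict[str, list[VariantRecord]] = {c: [] for c in INDEL_CLASSES}
    for t in models.transcripts:
        for cls, cands in _snv_candidates_for_transcript(t, genome).items():
            snv_pool[cls].extend(
                (t.chromosome, p, ref, alt) for p, ref, alt in cands
            )
        for cls, cands in _indel_candidates_for_transcript(t, genome, rng).items():
            indel_pool[cls].extend(cands)
    snv_pool["intergenic"] = [
        (chrom, p, ref) for chrom, p, ref in _intergenic_candidates(models)
    ]

    used: set[tuple[str, int]] = set()
    variants: list[VariantRecord] = []
    rows = []

    def _claim(chrom: str, lo: int, hi: int) -> bool:
        span = {(chrom, p) for p in range(lo, hi + 1)}
        if span & used:
            return False
        used.update(span)
        return True

    for cls in sorted(counts):
        want = counts[cls]
        if want == 0:
            continue
        if cls in INDEL_CLASSES:
            pool = indel_pool[cls]
            order = rng.permutation(len(pool))
            taken = 0
            for i in order:
                v = pool[i]
                a, b = v.affected_interval()
                if not _claim(v.chromosome, v.pos0, max(b, a + 1)):
                    continue
                variants.append(v)
                rows.append(
                    (v.variant_id, v.chromosome, v.position, v.ref, v.alt, cls)
                )
                taken += 1
                if taken == want:
                    break
            if taken < want:
                raise ValueError(
                    f"could only place {taken}/{want} variants of class {cls}"
                )
        else:
            pool = snv_pool[cls]
            order = rng.permutation(len(pool))
            taken = 0
            for i in order:
                entry = pool[i]
                if cls == "intergenic":
                    chrom, p, ref = entry
                    alts = [b for b in _BASES if b != ref]
                    alt = alts[int(rng.integers(len(alts)))]
                else:
                    chrom, p, ref, alt = entry
                if not _claim(chrom, p, p + 1):
                    continue
                v = VariantRecord(chrom, p + 1, ref, alt)
                variants.append(v)
                rows.append(
                    (v.variant_id, v.chromosome, v.position, v.ref, v.alt, cls)
                )
                taken += 1
                if taken == want:
                    break
            if taken < want:
                raise ValueError(
                    f"could only place {taken}/{want} variants of class {cls}"
                )

    truth = pd.DataFrame(
        rows,
        columns=["variant_id", "chromosome", "position", "ref", "alt", "true_class"],
    ).sort_values(["chromosome", "position", "ref", "alt"], ignore_index=True)
    # class label as the annotator reports it (intronic indels collapse
    # onto the plain intronic consequence)
    truth["expected_consequence"] = truth["true_class"].replace(
        {"intronic_indel": "intronic"}
    )
    variants.sort(key=lambda v: (v.chromosome, v.position, v.ref, v.alt))
    return VariantCatalog(variants=variants, truth=truth)
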