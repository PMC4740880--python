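"""Readers and writers for the pipeline's plain-text formats.

Coordinate conventions are converted strictly at these boundaries:
VCF and GFF3 are 1-based (GFF3 end-inclusive), BED/bedGraph and all
internal intervals are 0-based half-open.
"""

from __future__ import annotations

import textwrap
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from riphewas.cnv import CNVCall, WindowDepthTrack
from riphewas.containers import GenotypeMatrix, PhenomeTable
from riphewas.genome import Genome, TranscriptModel
from riphewas.annotate.records import ReferenceMismatchError, VariantRecord
from riphewas.markers import COLUMNS as MAP_COLUMNS, MarkerMap


# ---------------------------------------------------------------------------
# FASTA


def write_fasta(genome: Genome, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom in genome.chromosomes:
            fh.write(f">{chrom}\n")
            seq = genome.fetch(chrom, 0, genome.length(chrom))
            fh.write(textwrap.fill(seq, width) + "\n")


def read_fasta(path: str | Path) -> Genome:
    import pyfaidx

    fa = pyfaidx.Fasta(str(path), as_raw=True, sequence_always_upper=True)
    return Genome({name: str(fa[name][:]) for name in fa.keys()})


# ---------------------------------------------------------------------------
# GFF3


def write_gff3(
    transcripts: Sequence[TranscriptModel], path: str | Path
) -> None:
    """GFF3 with gene/mRNA/exon/CDS rows (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for t in sorted(transcripts, key=lambda x: (x.chromosome, x.span[0])):
            lo, hi = t.span
            fh.write(
                f"{t.chromosome}\triphewas\tgene\t{lo + 1}\t{hi}\t.\t"
                f"{t.strand}\t.\tID={t.gene_id}\n"
            )
            fh.write(
                f"{t.chromosome}\triphewas\tmRNA\t{lo + 1}\t{hi}\t.\t"
                f"{t.strand}\t.\tID={t.transcript_id};Parent={t.gene_id}\n"
            )
            for i, (s, e) in enumerate(t.exons):
                fh.write(
                    f"{t.chromosome}\triphewas\texon\t{s + 1}\t{e}\t.\t"
                    f"{t.strand}\t.\tID={t.transcript_id}.exon{i};"
                    f"Parent={t.transcript_id}\n"
                )
            for i, (s, e) in enumerate(t.cds):
                fh.write(
                    f"{t.chromosome}\triphewas\tCDS\t{s + 1}\t{e}\t.\t"
                    f"{t.strand}\t0\tID={t.transcript_id}.cds{i};"
                    f"Parent={t.transcript_id}\n"
                )


def read_gff3(path: str | Path) -> list[TranscriptModel]:
    """Parse transcript models from GFF3 via gffutils (in-memory db)."""
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    out = []
    for mrna in db.features_of_type("mRNA"):
        exons = sorted(
            (f.start - 1, f.end)
            for f in db.children(mrna, featuretype="exon")
        )
        cds = sorted(
            (f.start - 1, f.end)
            for f in db.children(mrna, featuretype="CDS")
        )
        gene_id = mrna.attributes.get("Parent", [mrna.id])[0]
        out.append(
            TranscriptModel(
                transcript_id=mrna.id,
                gene_id=gene_id,
                chromosome=mrna.seqid,
                strand=mrna.strand,
                exons=tuple(exons),
                cds=tuple(cds),
            )
        )
    out.sort(key=lambda t: (t.chromosome, t.span[0], t.transcript_id))
    return out


# ---------------------------------------------------------------------------
# VCF


def write_vcf(
    variants: Sequence[VariantRecord],
    path: str | Path,
    contigs: Sequence[tuple[str, int]] = (),
) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=riphewas\n")
        for name, length in contigs:
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in sorted(
            variants, key=lambda x: (x.chromosome, x.position, x.ref, x.alt)
        ):
            fh.write(
                f"{v.chromosome}\t{v.position}\t.\t{v.ref}\t{v.alt}\t.\t"
                f"PASS\t.\n"
            )


def read_vcf(path: str | Path, genome: Genome | None = None) -> list[VariantRecord]:
    """Read variant records via cyvcf2; multi-allelic sites expand per ALT.

    With ``genome`` given, every REF is checked against the sequence and a
    :class:`ReferenceMismatchError` naming the position is raised on
    disagreement.
    """
    from cyvcf2 import VCF

    out = []
    for rec in VCF(str(path)):
        for alt in rec.ALT:
            v = VariantRecord(rec.CHROM, rec.POS, rec.REF, alt)
            if genome is not None:
                observed = genome.fetch(
                    v.chromosome, v.pos0, v.pos0 + len(v.ref)
                )
                if observed != v.ref:
                    raise ReferenceMismatchError(
                        f"REF mismatch at {v.chromosome}:{v.position}: "
                        f"VCF says {v.ref!r}, genome has {observed!r}"
                    )
            out.append(v)
    return out


# ---------------------------------------------------------------------------
# BED / bedGraph


def write_bed(table: pd.DataFrame, path: str | Path) -> None:
    """BED3(+score): columns chrom, start, end [, score]."""
    cols = ["chrom", "start", "end"] + (
        ["score"] if "score" in table.columns else []
    )
    table[cols].to_csv(path, sep="\t", header=False, index=False)


def read_bed(path: str | Path, scored: bool = False) -> pd.DataFrame:
    names = ["chrom", "start", "end"] + (["score"] if scored else [])
    df = pd.read_csv(path, sep="\t", header=None, names=names,
                     usecols=range(len(names)))
    if (df["end"] <= df["start"]).any():
        raise ValueError(f"{path}: empty/inverted BED interval")
    return df


def write_bedgraph(table: pd.DataFrame, path: str | Path) -> None:
    table[["chrom", "start", "end", "value"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def read_bedgraph(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "value"]
    )


# ---------------------------------------------------------------------------
# TSV matrices


def write_marker_map(m: MarkerMap, path: str | Path) -> None:
    m.table.to_csv(path, sep="\t", index=False)


def read_marker_map(path: str | Path) -> MarkerMap:
    return MarkerMap(pd.read_csv(path, sep="\t", dtype={"chromosome": str}))


def write_genotypes(g: GenotypeMatrix, path: str | Path) -> None:
    g.genotypes.to_csv(path, sep="\t", index_label="strain")


def read_genotypes(path: str | Path, markers: MarkerMap) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col="strain")
    return GenotypeMatrix(df, markers)


def write_phenome(p: PhenomeTable, values_path: str | Path,
                  traits_path: str | Path) -> None:
    p.values.to_csv(values_path, sep="\t", index_label="strain")
    p.traits.to_csv(traits_path, sep="\t", index_label="trait_id")


def read_phenome(values_path: str | Path,
                 traits_path: str | Path | None = None) -> PhenomeTable:
    values = pd.read_csv(values_path, sep="\t", index_col="strain")
    traits = (
        pd.read_csv(traits_path, sep="\t", index_col="trait_id")
        if traits_path is not None
        else None
    )
    return PhenomeTable(values, traits)


def write_depth_track(t: WindowDepthTrack, path: str | Path) -> None:
    pd.DataFrame(
        {
            "chrom": t.chromosome,
            "window_start": np.arange(t.n_windows) * t.window_size,
            "count": t.counts,
            "masked": t.mask.astype(int),
        }
    ).to_csv(path, sep="\t", index=False)


def read_depth_track(path: str | Path) -> WindowDepthTrack:
    df = pd.read_csv(path, sep="\t")
    chroms = df["chrom"].unique()
    if len(chroms) != 1:
        raise ValueError("depth track files hold a single chromosome")
    starts = df["window_start"].to_numpy()
    sizes = np.diff(starts)
    if len(sizes) and not (sizes == sizes[0]).all():
        raise ValueError("windows are not contiguous/constant-width")
    window = int(sizes[0]) if len(sizes) else 100
    return WindowDepthTrack(
        chromosome=str(chroms[0]),
        window_size=window,
        counts=df["count"].to_numpy(),
        mask=df["masked"].to_numpy(dtype=bool)
        if "masked" in df.columns
        else None,
    )


def write_cnv_calls(calls: Sequence[CNVCall], path: str | Path) -> None:
    pd.DataFrame(
        [
            (c.chromosome, c.start_bp, c.end_bp, c.type, c.n_windows,
             c.mean_ratio, c.event_p)
            for c in calls
        ],
        columns=["chrom", "start", "end", "type", "n_windows", "mean_ratio",
                 "event_p"],
    ).to_csv(path, sep="\t", index=False)


def write_icd_records(records: pd.DataFrame, path: str | Path) -> None:
    records.to_csv(path, index=False)


def read_icd_records(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"icd9_code": str, "person_id": str})


def write_phecode_map(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)


def read_phecode_map(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        dtype={"icd9_code": str, "phecode": str, "parent": str,
               "exclude_control_of": str},
    )
    return df.fillna({"parent": "", "exclude_control_of": ""})
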