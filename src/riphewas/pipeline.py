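"""End-to-end pipeline: simulate -> annotate -> score -> cnv -> scan -> clinical.

Every stage reads its inputs from and writes plain-text outputs to the
run directory, so stages can be re-run from cached intermediates.  A
fixed global seed is split into per-stage substreams; two runs with the
same config produce byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from riphewas import clinical, cnv, impact, io, scan
from riphewas.annotate import annotate_variants
from riphewas.config import PipelineConfig
from riphewas.simulate import (
    SimulationConfig,
    TraitSpec,
    random_marker_map,
    simulate_conservation_tracks,
    simulate_depth_track,
    simulate_gene_models,
    simulate_icd_cohort,
    simulate_phenome,
    simulate_ri_genotypes,
    simulate_variant_catalog,
    toy_phecode_map,
)

log = logging.getLogger(__name__)

_DEFAULT_CLASS_COUNTS = {
    "synonymous": 6,
    "missense": 6,
    "stop_gain": 3,
    "stop_loss": 2,
    "splice_donor": 3,
    "splice_acceptor": 3,
    "frameshift": 4,
    "inframe_indel": 3,
    "intronic": 6,
    "intergenic": 6,
    "utr5": 3,
    "utr3": 3,
}


def _stage_simulate(cfg: PipelineConfig, out: Path) -> None:
    seed = cfg.stage_seed("simulate")
    rng = np.random.default_rng(seed)

    markers = random_marker_map(
        {"chr1": cfg.n_markers}, chrom_length_bp=100_000_000, seed=seed
    )
    geno = simulate_ri_genotypes(markers, cfg.n_strains, seed)
    io.write_marker_map(markers, out / "markers.tsv")
    io.write_genotypes(geno, out / "genotypes.tsv")

    marker_ids = markers.marker_ids
    planted = marker_ids[len(marker_ids) // 2]
    specs = [TraitSpec("trait_planted", planted, 0.5)]
    specs += [TraitSpec(f"trait{i:03d}") for i in range(cfg.n_traits - 1)]
    phenome = simulate_phenome(
        geno,
        SimulationConfig(
            n_strains=cfg.n_strains, seed=seed, trait_spec=specs,
            missing_rate=0.02,
        ),
    )
    io.write_phenome(phenome, out / "phenome.tsv", out / "traits.tsv")

    models = simulate_gene_models(cfg.n_genes, seed)
    io.write_fasta(models.genome, out / "genome.fa")
    io.write_gff3(models.transcripts, out / "models.gff3")
    catalog = simulate_variant_catalog(models, _DEFAULT_CLASS_COUNTS, seed)
    chrom = models.genome.chromosomes[0]
    io.write_vcf(
        catalog.variants, out / "variants.vcf",
        contigs=[(chrom, models.genome.length(chrom))],
    )
    catalog.truth.to_csv(out / "variant_truth.tsv", sep="\t", index=False)

    cnv_region = (60_000, 90_000, 8.0)  # 30 kb four-fold expansion
    track = simulate_depth_track(
        cfg.genome_length_bp, cfg.depth_mean, [cnv_region], seed=seed,
        window=cfg.cnv_window_bp,
    )
    io.write_depth_track(track, out / "depth.tsv")
    pd.DataFrame(
        [cnv_region], columns=["start", "end", "copy_ratio"]
    ).to_csv(out / "cnv_truth.tsv", sep="\t", index=False)

    tracks = simulate_conservation_tracks(
        models.genome.length(chrom), seed=seed, chromosome=chrom
    )
    io.write_bed(tracks.regulatory, out / "regulatory.bed")
    io.write_bed(tracks.conserved, out / "conserved.bed")
    io.write_bedgraph(tracks.per_base, out / "conservation.bedGraph")

    phemap = toy_phecode_map()
    io.write_phecode_map(phemap, out / "phecode_map.csv")
    cohort = simulate_icd_cohort(
        cfg.n_individuals, phemap, planted=(0.2, 1.8, "P001"),
        seed=int(rng.integers(2**31)),
    )
    io.write_icd_records(cohort.records, out / "icd_records.csv")
    cohort.genotype.to_frame().to_csv(out / "human_genotype.tsv", sep="\t",
                                      index_label="person_id")
    cohort.covariates.to_csv(out / "covariates.tsv", sep="\t")


def _stage_annotate(cfg: PipelineConfig, out: Path) -> None:
    genome = io.read_fasta(out / "genome.fa")
    transcripts = io.read_gff3(out / "models.gff3")
    variants = io.read_vcf(out / "variants.vcf", genome=genome)
    table, counts = annotate_variants(variants, transcripts, genome)
    table.to_csv(out / "annotation.tsv", sep="\t", index=False)
    counts.to_csv(out / "annotation_counts.tsv", sep="\t")


def _stage_score(cfg: PipelineConfig, out: Path) -> None:
    ann = impact.FunctionalAnnotations(
        io.read_bed(out / "regulatory.bed"),
        io.read_bed(out / "conserved.bed", scored=True),
        io.read_bedgraph(out / "conservation.bedGraph"),
    )
    table = pd.read_csv(out / "annotation.tsv", sep="\t")
    noncoding = table[
        table["consequence"].isin(["intronic", "intergenic", "utr5", "utr3"])
        & (table["variant_class"] == "SNV")
    ]
    scores = impact.score_positions(
        (noncoding["position"] - 1).tolist(), ann
    )
    scores.insert(0, "variant_id", noncoding["variant_id"].to_numpy())
    scores.to_csv(out / "impact_scores.tsv", sep="\t", index=False)


def _stage_cnv(cfg: PipelineConfig, out: Path) -> None:
    track = io.read_depth_track(out / "depth.tsv")
    calls = cnv.ewt_scan(
        track, alpha=cfg.cnv_alpha, min_consec=cfg.cnv_min_consec,
        min_bp=cfg.cnv_min_bp,
    )
    io.write_cnv_calls(calls, out / "cnv_calls.tsv")


def _stage_scan(cfg: PipelineConfig, out: Path) -> None:
    markers = io.read_marker_map(out / "markers.tsv")
    geno = io.read_genotypes(out / "genotypes.tsv", markers)
    phenome = io.read_phenome(out / "phenome.tsv", out / "traits.tsv")
    blocks = scan.select_block_markers(geno.drop_monomorphic())
    blocks.blocks.to_csv(out / "blocks.tsv", sep="\t", index=False)

    ann = pd.read_csv(out / "annotation.tsv", sep="\t")
    strong = ann[
        ann["consequence"].isin(
            ["missense", "stop_gain", "stop_loss", "splice_donor",
             "splice_acceptor", "frameshift"]
        )
    ]
    # scan synthetic variants against the panel chromosome's markers:
    # variant coordinates live on the gene-model contig, so map them
    # proportionally onto the marker chromosome for the demo pipeline
    chrom = markers.chromosomes()[0]
    span = markers.table["position_bp"].max()
    gmax = max(strong["position"].max(), 1)
    variants = pd.DataFrame(
        {
            "variant_id": strong["variant_id"],
            "chromosome": chrom,
            "position": (strong["position"] / gmax * span).astype(int) + 1,
        }
    )
    table = scan.phewas(
        variants, blocks.geno, phenome, q_threshold=cfg.q_threshold,
        map_window_bp=cfg.map_window_bp,
    )
    table.to_csv(out / "associations.tsv", sep="\t", index=False)
    with open(out / "scan_summary.json", "w") as fh:
        json.dump(scan.phewas_summary(table, cfg.q_threshold), fh, indent=2)
    plot_data = table.loc[
        table["status"] == "ok",
        ["variant_id", "trait_id", "category", "neg_log10_q"],
    ]
    plot_data.to_csv(out / "manhattan.tsv", sep="\t", index=False)


def _stage_human_phewas(cfg: PipelineConfig, out: Path) -> None:
    records = io.read_icd_records(out / "icd_records.csv")
    phemap = clinical.PhecodeMap(io.read_phecode_map(out / "phecode_map.csv"))
    genotype = pd.read_csv(
        out / "human_genotype.tsv", sep="\t", index_col="person_id"
    )["genotype"]
    covars = pd.read_csv(out / "covariates.tsv", sep="\t",
                         index_col="person_id")
    status = clinical.assign_case_control(
        records, phemap, min_code_count=cfg.min_code_count
    )
    status = status.reindex(genotype.index, fill_value=clinical.CONTROL)
    retained = clinical.filter_phenotypes(status, cfg.min_individuals)
    result = clinical.logistic_scan(genotype, status, covars, retained)
    threshold = clinical.bonferroni_threshold(
        cfg.bonferroni_alpha, max(len(retained), 1)
    )
    result["pass_bonferroni"] = result["p"] < threshold
    result.to_csv(out / "human_phewas.tsv", sep="\t")


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "annotate": _stage_annotate,
    "score": _stage_score,
    "cnv": _stage_cnv,
    "scan": _stage_scan,
    "human_phewas": _stage_human_phewas,
}

_STAGE_INPUTS = {
    "annotate": ["genome.fa", "models.gff3", "variants.vcf"],
    "score": ["regulatory.bed", "conserved.bed", "conservation.bedGraph",
              "annotation.tsv"],
    "cnv": ["depth.tsv"],
    "scan": ["markers.tsv", "genotypes.tsv", "phenome.tsv", "annotation.tsv"],
    "human_phewas": ["icd_records.csv", "phecode_map.csv",
                     "human_genotype.tsv", "covariates.tsv"],
}


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Run the configured stages; returns the results directory."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    # fail early if a later stage lacks inputs
    for stage in cfg.stages:
        for name in _STAGE_INPUTS.get(stage, []):
            if "simulate" in cfg.stages and stage != "simulate":
                continue
            if stage != "simulate" and not (out / name).exists():
                raise FileNotFoundError(
                    f"stage {stage!r} needs missing input {name!r}"
                )
    for stage in cfg.stages:
        log.info("running stage %s", stage)
        _STAGE_FUNCS[stage](cfg, out)
    cfg.write_provenance(out / "provenance.json")
    return out
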