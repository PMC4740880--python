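# riphewas

A phenome-wide association (PheWAS) toolkit for two-parent recombinant-inbred
(RI) panels and EHR-style clinical cohorts. It implements the full analysis
chain around a joint mouse–human PheWAS:

- **`riphewas.simulate`** — generators for every pipeline input: RI genotype
  mosaics with sib-mating map expansion `R = 4r/(1+6r)`, phenomes with planted
  marker effects, multi-exon gene models + genome sequence, variant catalogs
  with construction-truth labels, Poisson windowed depth tracks with planted
  copy-number events, conservation/regulatory tracks, and ICD-coded cohorts
  with a planted additive genotype effect.
- **`riphewas.annotate`** — variant consequence classification (codon-level
  SNV calls on either strand, splice-dinucleotide logic, frameshift/in-frame
  indels, severity-ranked multi-transcript aggregation) plus dual-platform
  false-positive-rate arithmetic.
- **`riphewas.impact`** — composite impact scores for noncoding SNPs
  (functional-element score × ECDF-normalized conservation score, with an
  epsilon rule for single missing components) and rule-based comparative
  deleteriousness calls from ortholog alignment columns.
- **`riphewas.cnv`** — event-wise read-depth CNV detection on 100-bp windows:
  robust median/MAD normalization, same-direction run merging, Fisher-combined
  event significance at 1e-6, ≥10 windows / ≥1 kb filters.
- **`riphewas.scan`** — the RI PheWAS engine: haplotype-block marker
  collapsing, variant→nearest-marker mapping (±1 Mb), vectorized Pearson
  correlation scans with two-tailed t p-values, Storey q-values with smoothed
  π0 estimation (π0=1 reproduces Benjamini–Hochberg exactly), and PC1 group
  scans.
- **`riphewas.clinical`** — phecode-based case/control assignment (≥2 codes on
  distinct dates per case, hierarchy propagation, control exclusions), SNP and
  sample QC, additive logistic scans with age/sex/PC covariates, Bonferroni
  thresholds.

## Command-line interface

```bash
riphewas run --seed 1 --out results_dir          # full pipeline on synthetic data
riphewas simulate --config sim.yaml --out DIR    # single stages:
riphewas annotate --out DIR                      #   (each reads cached
riphewas score --out DIR                         #    intermediates from DIR)
riphewas cnv --out DIR
riphewas scan --out DIR
riphewas human-phewas --out DIR
riphewas report --out DIR                        # summarize a finished run
```

All stages exchange plain-text intermediates (TSV/CSV/VCF/GFF3/FASTA/BED) in
the output directory, emit a provenance block (`provenance.json`), and are
bit-reproducible under a fixed `--seed`. Defaults (q < 0.01, CNV α = 1e-6 with
≥10 windows/≥1 kb, ±1 Mb marker window, ≥2 codes, ≥20 cases, MAF > 1%) are the
published analysis values; override any of them via `--config sim.yaml`.

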