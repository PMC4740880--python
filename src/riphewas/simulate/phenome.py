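"""Phenome simulation with planted marker effects.

Each trait is ``a * genotype + Gaussian noise`` with the noise variance
chosen so the planted marker explains a requested fraction of trait
variance in expectation; traits without a planted marker are pure noise.
Missing values are inserted completely at random.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from riphewas.containers import GenotypeMatrix, PhenomeTable

#: 15 broad phenotype category labels used for classic-trait metadata.
TRAIT_CATEGORIES = (
    "behavior",
    "cardiovascular",
    "central_nervous_system",
    "endocrine",
    "gastrointestinal",
    "hematology",
    "immune_system",
    "metabolism",
    "morphology",
    "musculoskeletal",
    "pharmacology",
    "renal",
    "reproduction",
    "respiratory",
    "toxicology",
)


@dataclass(frozen=True)
class TraitSpec:
    """One simulated trait: optional planted marker and its variance share."""

    trait_id: str
    planted_marker: Optional[str] = None
    effect_fraction: float = 0.0

    def __post_init__(self):
        if not 0.0 <= self.effect_fraction <= 1.0:
            raise ValueError(
                f"effect_fraction must be in [0, 1], got {self.effect_fraction}"
            )
        if self.planted_marker is None and self.effect_fraction > 0:
            raise ValueError(
                f"trait {self.trait_id}: effect without a planted marker"
            )


@dataclass
class SimulationConfig:
    """Knobs for the synthetic pipeline inputs.

    ``trait_spec`` lists the phenome traits; every referenced marker must
    exist in the genotype matrix handed to :func:`simulate_phenome`.
    ``cnv_spec`` rows are ``(chrom, start_bp, end_bp, copy_ratio)`` with
    copy_ratio 2 = diploid baseline.
    """

    n_strains: int = 80
    seed: int = 0
    trait_spec: Sequence[TraitSpec] = field(default_factory=tuple)
    cnv_spec: Sequence[tuple[str, int, int, float]] = field(default_factory=tuple)
    depth_mean: float = 30.0
    missing_rate: float = 0.0

    def __post_init__(self):
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be positive")
        for _, start, end, ratio in self.cnv_spec:
            if end <= start:
                raise ValueError("cnv_spec interval empty")
            if ratio < 0:
                raise ValueError("cnv_spec copy_ratio must be >= 0")


def simulate_phenome(
    geno: GenotypeMatrix, config: SimulationConfig
) -> PhenomeTable:
    """Simulate a strains x traits phenome from a genotype matrix.

    For a trait with planted marker g and effect fraction h2, the trait is
    ``g + e`` with ``e ~ N(0, var(g) * (1 - h2)/h2)`` so the marker explains
    h2 of the variance in expectation (empirical genotype variance is used).
    ``h2 = 0`` yields pure N(0, 1) noise, ``h2 = 1`` the genotype itself.
    """
    rng = np.random.default_rng(config.seed)
    n = geno.n_strains
    cols, cats, planted = {}, [], []
    for i, spec in enumerate(config.trait_spec):
        if spec.planted_marker is not None:
            if spec.planted_marker not in geno.genotypes.columns:
                raise ValueError(
                    f"trait {spec.trait_id}: unknown marker {spec.planted_marker}"
                )
            g = geno.marker_vector(spec.planted_marker)
            h2 = spec.effect_fraction
            if h2 == 0.0:
                y = rng.standard_normal(n)
            else:
                var_g = np.nanvar(g)
                if var_g == 0:
                    raise ValueError(
                        f"planted marker {spec.planted_marker} is monomorphic"
                    )
                noise_sd = np.sqrt(var_g * (1.0 - h2) / h2)
                y = g + noise_sd * rng.standard_normal(n)
        else:
            y = rng.standard_normal(n)
        cols[spec.trait_id] = y
        cats.append(TRAIT_CATEGORIES[i % len(TRAIT_CATEGORIES)])
        planted.append(spec.planted_marker)
    values = pd.DataFrame(cols, index=geno.strains)
    if config.missing_rate > 0:
        mask = rng.random(values.shape) < config.missing_rate
        values = values.mask(mask)
    traits = pd.DataFrame(
        {"category": cats, "planted_marker": planted},
        index=list(values.columns),
    )
    return PhenomeTable(values, traits)
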