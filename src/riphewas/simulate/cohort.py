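"""Synthetic ICD-coded cohorts with a planted additive genotype effect.

Produces per-individual ICD9 code records (with code multiplicity so the
>=2-code case rule is exercised), an additive genotype vector at a stated
minor-allele frequency, age/sex/PC covariates, and case status for one
planted phecode drawn from a logistic model at a stated odds ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class ICDCohort:
    """Simulated EHR cohort bundle."""

    records: pd.DataFrame     # person_id, icd9_code, date
    genotype: pd.Series       # person_id -> 0/1/2 minor-allele count
    covariates: pd.DataFrame  # person_id x (age, sex, PC1..PC3)
    truth: pd.DataFrame       # person_id, is_case (planted phecode)
    planted_phecode: str


def toy_phecode_map(n_phecodes: int = 8) -> pd.DataFrame:
    """Small phecode map with a parent/child pair and control exclusions.

    Columns: icd9_code, phecode, parent (may be empty), exclude_control_of
    (phecode whose controls must not carry this phecode's codes; empty =
    none).  Phecode 'P001.1' is a child of 'P001'; 'P001.9' is in P001's
    control-exclusion range.
    """
    rows = []
    for i in range(n_phecodes):
        code = f"P{i + 1:03d}"
        rows.append((f"{400 + i}.0", code, "", ""))
        rows.append((f"{400 + i}.1", code, "", ""))
    # hierarchical pair: P001.1 child of P001
    rows.append(("410.0", "P001.1", "P001", ""))
    rows.append(("410.1", "P001.1", "P001", ""))
    # exclusion code: carriers are excluded from P001 controls
    rows.append(("419.9", "P001.9", "", "P001"))
    return pd.DataFrame(
        rows, columns=["icd9_code", "phecode", "parent", "exclude_control_of"]
    )


def simulate_icd_cohort(
    n_individuals: int,
    phecode_map: pd.DataFrame,
    planted: tuple[float, float, str],
    seed: int = 0,
    baseline_prevalence: float = 0.15,
    two_code_fraction: float = 0.8,
    background_code_rate: float = 0.5,
) -> ICDCohort:
    """Simulate an EHR cohort with one planted genotype->phecode effect.

    ``planted`` is ``(snp_maf, odds_ratio, phecode)``.  Case status for
    the planted phecode follows a logistic model with additive genotype
    effect ``log(odds_ratio)`` plus small age/sex/PC terms.  A case
    receives codes for the phecode on two distinct dates with probability
    ``two_code_fraction`` and on a single date otherwise (so it lands in
    the neither-case-nor-control bin downstream).  All individuals
    additionally receive Poisson background codes for other phecodes.

    A MAF of 0 is allowed and yields a monomorphic genotype; downstream
    scans must skip it with an explicit status.
    """
    maf, odds_ratio, phecode = planted
    if not 0.0 <= maf <= 0.5:
        raise ValueError("snp_maf must be in [0, 0.5]")
    if odds_ratio <= 0:
        raise ValueError("odds_ratio must be positive")
    if phecode not in set(phecode_map["phecode"]):
        raise ValueError(f"planted phecode {phecode!r} not in map")
    rng = np.random.default_rng(seed)
    persons = [f"ind{i:05d}" for i in range(n_individuals)]

    g = rng.binomial(2, maf, size=n_individuals).astype(float)
    age = rng.normal(55.0, 12.0, size=n_individuals)
    sex = rng.integers(0, 2, size=n_individuals).astype(float)
    pcs = rng.normal(0.0, 1.0, size=(n_individuals, 3))
    covariates = pd.DataFrame(
        {
            "age": age,
            "sex": sex,
            "PC1": pcs[:, 0],
            "PC2": pcs[:, 1],
            "PC3": pcs[:, 2],
        },
        index=pd.Index(persons, name="person_id"),
    )

    beta0 = np.log(baseline_prevalence / (1.0 - baseline_prevalence))
    eta = (
        beta0
        + np.log(odds_ratio) * g
        + 0.01 * (age - 55.0)
        + 0.1 * (sex - 0.5)
        + 0.05 * pcs[:, 0]
    )
    p_case = 1.0 / (1.0 + np.exp(-eta))
    is_case = rng.random(n_individuals) < p_case

    code_by_phecode: dict[str, list[str]] = {}
    for _, row in phecode_map.iterrows():
        code_by_phecode.setdefault(row["phecode"], []).append(row["icd9_code"])
    other_phecodes = [p for p in code_by_phecode if p != phecode]

    recs: list[tuple[str, str, str]] = []
    for i, person in enumerate(persons):
        if is_case[i]:
            codes = code_by_phecode[phecode]
            n_dates = 2 if rng.random() < two_code_fraction else 1
            days = rng.choice(np.arange(1, 29), size=n_dates, replace=False)
            for d in days:
                recs.append(
                    (person, codes[int(rng.integers(len(codes)))],
                     f"2015-01-{int(d):02d}")
                )
        n_bg = rng.poisson(background_code_rate)
        for _ in range(n_bg):
            other = other_phecodes[int(rng.integers(len(other_phecodes)))]
            codes = code_by_phecode[other]
            recs.append(
                (
                    person,
                    codes[int(rng.integers(len(codes)))],
                    f"2015-{int(rng.integers(2, 13)):02d}-"
                    f"{int(rng.integers(1, 29)):02d}",
                )
            )
    records = pd.DataFrame(recs, columns=["person_id", "icd9_code", "date"])
    truth = pd.DataFrame({"person_id": persons, "is_case": is_case})
    return ICDCohort(
        records=records,
        genotype=pd.Series(g, index=persons, name="genotype"),
        covariates=covariates,
        truth=truth,
        planted_phecode=phecode,
    )
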