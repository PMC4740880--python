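"""Phecode-based clinical PheWAS: case/control logic and logistic scans.

ICD9 records are aggregated into hierarchical phecodes; a person is a
case for a phecode with mapped codes on at least two distinct dates, is
neither case nor control with exactly one, and is a control otherwise
unless they carry a code in the phecode's control-exclusion set.  Scans
fit additive logistic models adjusted for age, sex and three PCs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

log = logging.getLogger(__name__)

CASE, CONTROL, EXCLUDED = "case", "control", "excluded"


# ---------------------------------------------------------------------------
# phecode map


@dataclass
class PhecodeMap:
    """ICD9 -> phecode mapping with hierarchy and control exclusions.

    Built from a frame with columns icd9_code, phecode, parent,
    exclude_control_of (both optional, empty string = none).  The
    hierarchy must be acyclic; child cases count toward parents.
    """

    table: pd.DataFrame

    def __post_init__(self):
        required = {"icd9_code", "phecode"}
        if not required <= set(self.table.columns):
            raise ValueError(f"phecode map needs columns {sorted(required)}")
        t = self.table.copy()
        for col in ("parent", "exclude_control_of"):
            if col not in t.columns:
                t[col] = ""
            t[col] = t[col].fillna("")
        self.table = t
        self._icd_to_phecode = dict(zip(t["icd9_code"], t["phecode"]))
        self._parent = {
            row["phecode"]: row["parent"]
            for _, row in t.iterrows()
            if row["parent"]
        }
        # cycle check
        for node in self._parent:
            seen = set()
            cur: Optional[str] = node
            while cur:
                if cur in seen:
                    raise ValueError(f"phecode hierarchy cycle at {cur!r}")
                seen.add(cur)
                cur = self._parent.get(cur)
        self._exclusions: dict[str, set[str]] = {}
        for _, row in t.iterrows():
            if row["exclude_control_of"]:
                self._exclusions.setdefault(
                    row["exclude_control_of"], set()
                ).add(row["phecode"])

    @property
    def phecodes(self) -> list[str]:
        out = list(dict.fromkeys(self.table["phecode"]))
        for parent in self._parent.values():
            if parent not in out:
                out.append(parent)
        return out

    def map_icd(self, icd9_code: str) -> Optional[str]:
        return self._icd_to_phecode.get(icd9_code)

    def ancestors(self, phecode: str) -> list[str]:
        """The phecode itself plus every ancestor, leaf first."""
        chain = [phecode]
        cur = phecode
        while cur in self._parent:
            cur = self._parent[cur]
            chain.append(cur)
        return chain

    def control_exclusions(self, phecode: str) -> set[str]:
        """Phecodes whose carriers may not serve as controls for ``phecode``."""
        return self._exclusions.get(phecode, set())


# ---------------------------------------------------------------------------
# case/control assignment


def assign_case_control(
    records: pd.DataFrame,
    phecode_map: PhecodeMap,
    min_code_count: int = 2,
) -> pd.DataFrame:
    """Person x phecode status table ('case' / 'control' / 'excluded').

    Code instances are counted as distinct dates per (person, phecode),
    child instances propagating to parents.  >= ``min_code_count``
    instances -> case; exactly one or more but fewer than the threshold
    -> excluded; zero -> control, unless the person carries any code of a
    phecode in the target's control-exclusion set (-> excluded).
    Unmapped ICD codes are ignored; their count is logged.
    """
    required = {"person_id", "icd9_code", "date"}
    if not required <= set(records.columns):
        raise ValueError(f"records need columns {sorted(required)}")
    persons = sorted(records["person_id"].unique())
    phecodes = phecode_map.phecodes

    mapped = records.assign(
        phecode=records["icd9_code"].map(phecode_map.map_icd)
    )
    n_unmapped = int(mapped["phecode"].isna().sum())
    if n_unmapped:
        log.info("ignored %d records with unmapped ICD codes", n_unmapped)
    mapped = mapped.dropna(subset=["phecode"])

    # propagate each record to the phecode and all its ancestors
    expanded = []
    for _, row in mapped.iterrows():
        for code in phecode_map.ancestors(row["phecode"]):
            expanded.append((row["person_id"], code, row["date"]))
    exp = pd.DataFrame(expanded, columns=["person_id", "phecode", "date"])
    counts = (
        exp.drop_duplicates()
        .groupby(["person_id", "phecode"])
        .size()
        .unstack(fill_value=0)
        .reindex(index=persons, columns=phecodes, fill_value=0)
    )

    status = pd.DataFrame(CONTROL, index=persons, columns=phecodes)
    status = status.mask(counts >= min_code_count, CASE)
    status = status.mask((counts > 0) & (counts < min_code_count), EXCLUDED)
    for phecode in phecodes:
        exclusions = phecode_map.control_exclusions(phecode)
        if not exclusions:
            continue
        carriers = (counts[list(exclusions & set(counts.columns))] > 0).any(
            axis=1
        )
        is_control = status[phecode] == CONTROL
        status.loc[carriers & is_control, phecode] = EXCLUDED
    status.index.name = "person_id"
    return status


def filter_phenotypes(
    status: pd.DataFrame, min_individuals: int = 20
) -> list[str]:
    """Phecodes retained for analysis: at least ``min_individuals`` cases."""
    case_counts = (status == CASE).sum(axis=0)
    return case_counts.index[case_counts >= min_individuals].tolist()


# ---------------------------------------------------------------------------
# SNP / sample QC


@dataclass
class SnpQcResult:
    snp_pass: pd.Series      # per SNP
    sample_pass: pd.Series   # per sample
    maf: pd.Series
    snp_call_rate: pd.Series
    sample_call_rate: pd.Series


def snp_qc(
    genotypes: pd.DataFrame,
    maf_min: float = 0.01,
    snp_call_rate_min: float = 0.95,
    sample_call_rate_min: float = 0.99,
) -> SnpQcResult:
    """QC additive genotypes (samples x SNPs, values 0/1/2/NaN).

    Samples are filtered first (call rate strictly > ``sample_call_rate_min``);
    SNP call rate and MAF are then computed over passing samples only.
    All thresholds are strict inequalities (MAF exactly 1% fails).
    """
    g = genotypes.astype(float)
    sample_cr = g.notna().mean(axis=1)
    sample_pass = sample_cr > sample_call_rate_min
    kept = g.loc[sample_pass]
    snp_cr = kept.notna().mean(axis=0)
    af = kept.mean(axis=0) / 2.0
    maf = np.minimum(af, 1.0 - af)
    snp_pass = (snp_cr > snp_call_rate_min) & (maf > maf_min)
    return SnpQcResult(
        snp_pass=snp_pass,
        sample_pass=sample_pass,
        maf=maf,
        snp_call_rate=snp_cr,
        sample_call_rate=sample_cr,
    )


# ---------------------------------------------------------------------------
# logistic scan


def fit_additive_logistic(
    y: np.ndarray,
    genotype: np.ndarray,
    covariates: Optional[pd.DataFrame] = None,
    tol: float = 1e-8,
    maxiter: int = 25,
) -> dict:
    """One additive logistic fit; Wald two-tailed p on the genotype term.

    Newton/IRLS via statsmodels.  Returns a dict with beta, se, odds
    ratio, p and status ('ok', 'monomorphic', 'separation',
    'not_converged').  Separation and non-convergence yield no estimate.
    """
    g = np.asarray(genotype, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(np.unique(g[np.isfinite(g)])) < 2:
        return {"status": "monomorphic", "beta": np.nan, "se": np.nan,
                "odds_ratio": np.nan, "p": np.nan}
    x = pd.DataFrame({"genotype": g})
    if covariates is not None:
        x = pd.concat([x, covariates.reset_index(drop=True)], axis=1)
    x = sm.add_constant(x, prepend=True)
    keep = np.isfinite(g) & np.isfinite(y) & np.isfinite(
        x.to_numpy(dtype=float)
    ).all(axis=1)
    x, y = x.loc[keep], y[keep]
    try:
        import warnings

        from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

        with np.errstate(all="ignore"), warnings.catch_warnings():
            # separation is detected and flagged below via beta/se
            warnings.simplefilter("ignore", PerfectSeparationWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            fit = sm.Logit(y, x).fit(
                method="newton", tol=tol, maxiter=maxiter, disp=0,
                warn_convergence=False,
            )
    except (PerfectSeparationError, np.linalg.LinAlgError):
        return {"status": "separation", "beta": np.nan, "se": np.nan,
                "odds_ratio": np.nan, "p": np.nan}
    beta = float(fit.params["genotype"])
    se = float(fit.bse["genotype"])
    if not fit.mle_retvals.get("converged", False):
        return {"status": "not_converged", "beta": np.nan, "se": np.nan,
                "odds_ratio": np.nan, "p": np.nan}
    if not np.isfinite(se) or abs(beta) > 15:
        # quasi-separation: estimates diverging without an explicit raise
        return {"status": "separation", "beta": np.nan, "se": np.nan,
                "odds_ratio": np.nan, "p": np.nan}
    from scipy import stats as sps

    p = float(2.0 * sps.norm.sf(abs(beta / se)))
    return {"status": "ok", "beta": beta, "se": se,
            "odds_ratio": float(np.exp(beta)), "p": p}


def logistic_scan(
    genotype: pd.Series,
    status: pd.DataFrame,
    covariates: pd.DataFrame,
    phecodes: Optional[list[str]] = None,
) -> pd.DataFrame:
    """Additive logistic PheWAS of one SNP across phecodes.

    For each phecode only cases and controls enter the fit (excluded
    individuals are dropped).  Returns a frame indexed by phecode with
    n_case, n_control, beta, odds_ratio, p and status.
    """
    if phecodes is None:
        phecodes = list(status.columns)
    rows = []
    for phecode in phecodes:
        st = status[phecode]
        use = st.isin([CASE, CONTROL])
        idx = status.index[use]
        y = (st[use] == CASE).astype(float).to_numpy()
        res = fit_additive_logistic(
            y,
            genotype.loc[idx].to_numpy(dtype=float),
            covariates.loc[idx],
        )
        rows.append(
            (
                phecode,
                int((st == CASE).sum()),
                int((st == CONTROL).sum()),
                res["beta"],
                res["odds_ratio"],
                res["p"],
                res["status"],
            )
        )
    return pd.DataFrame(
        rows,
        columns=["phecode", "n_case", "n_control", "beta", "odds_ratio",
                 "p", "status"],
    ).set_index("phecode")


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Per-test significance threshold alpha / m."""
    if m < 1:
        raise ValueError("m must be >= 1")
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    return alpha / m
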