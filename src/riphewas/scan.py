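"""RI-panel PheWAS engine.

Markers with identical strain-distribution patterns are collapsed into
haplotype blocks; variants map to the nearest block marker within
+/- 1 Mb; each mapped marker is scanned against the phenome by Pearson
correlation with two-tailed t-based p-values; q-values follow Storey's
method with smoothed pi0 estimation, computed separately per scan family.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from riphewas.containers import GenotypeMatrix, PhenomeTable
from riphewas.markers import MarkerMap

log = logging.getLogger(__name__)

MIN_PAIRWISE_N = 6


# ---------------------------------------------------------------------------
# marker selection and variant mapping


@dataclass
class BlockMarkers:
    """Reduced genotype matrix: one representative per haplotype block."""

    geno: GenotypeMatrix
    blocks: pd.DataFrame  # representative, chromosome, start_bp, end_bp, n_markers


def select_block_markers(geno: GenotypeMatrix) -> BlockMarkers:
    """Collapse consecutive markers with identical genotype vectors.

    Per chromosome, runs of markers whose strain-genotype vectors are
    identical (including the missingness pattern) form one haplotype
    block represented by the leftmost member.
    """
    reps: list[str] = []
    rows = []
    table = geno.markers.table
    for chrom in geno.markers.chromosomes():
        view = geno.markers.chromosome_view(chrom)
        ids = view["marker_id"].tolist()
        bps = view["position_bp"].tolist()
        run_rep, run_start, run_n = ids[0], bps[0], 1
        prev_vec = geno.genotypes[ids[0]]
        prev_bp = bps[0]
        for mid, bp in zip(ids[1:], bps[1:]):
            vec = geno.genotypes[mid]
            same = (
                (vec == prev_vec) | (vec.isna() & prev_vec.isna())
            ).all()
            if same:
                run_n += 1
            else:
                reps.append(run_rep)
                rows.append((run_rep, chrom, run_start, prev_bp, run_n))
                run_rep, run_start, run_n = mid, bp, 1
            prev_vec, prev_bp = vec, bp
        reps.append(run_rep)
        rows.append((run_rep, chrom, run_start, prev_bp, run_n))
    blocks = pd.DataFrame(
        rows,
        columns=["representative", "chromosome", "start_bp", "end_bp", "n_markers"],
    )
    reduced = GenotypeMatrix(
        geno.genotypes[reps],
        MarkerMap(
            table[table["marker_id"].isin(reps)].reset_index(drop=True)
        ),
    )
    return BlockMarkers(geno=reduced, blocks=blocks)


def map_variant_to_marker(
    chromosome: str,
    position_bp: int,
    markers: MarkerMap,
    window_bp: int = 1_000_000,
) -> Optional[str]:
    """Nearest same-chromosome marker within +/- ``window_bp``, or None.

    Distance ties break toward the lower-coordinate marker.
    """
    view = markers.chromosome_view(chromosome)
    if view.empty:
        return None
    bp = view["position_bp"].to_numpy()
    dist = np.abs(bp - position_bp)
    best = int(np.flatnonzero(dist == dist.min())[0])  # lowest coordinate
    if dist[best] > window_bp:
        return None
    return view["marker_id"].iloc[best]


# ---------------------------------------------------------------------------
# correlation scan


def correlation_scan(
    genotype: np.ndarray,
    phenome: PhenomeTable,
    min_n: int = MIN_PAIRWISE_N,
) -> pd.DataFrame:
    """Pearson correlation of one marker against every trait.

    Pairwise-complete strains per trait; two-tailed p from the t
    transform ``t = r * sqrt((n - 2) / (1 - r^2))`` with n-2 df; |r| = 1
    maps to p = 0 by convention.  Traits with fewer than ``min_n``
    complete pairs, or with zero genotype/trait variance over the
    complete pairs, are reported with a skip status and NaN statistics.

    Returns a frame indexed by trait id: r, n, p, status.
    """
    g = np.asarray(genotype, dtype=float)
    y = phenome.values.to_numpy(dtype=float)
    if len(g) != y.shape[0]:
        raise ValueError("genotype length does not match phenome strains")
    gm = np.isfinite(g)
    valid = gm[:, None] & np.isfinite(y)
    n = valid.sum(axis=0).astype(float)

    g0 = np.where(gm, g, 0.0)
    y0 = np.where(valid, y, 0.0)
    vg = valid * g0[:, None]
    sum_g = vg.sum(axis=0)
    sum_g2 = (valid * (g0**2)[:, None]).sum(axis=0)
    sum_y = y0.sum(axis=0)
    sum_y2 = (y0**2).sum(axis=0)
    sum_gy = (y0 * g0[:, None]).sum(axis=0)

    with np.errstate(invalid="ignore", divide="ignore"):
        cov = n * sum_gy - sum_g * sum_y
        var_g = n * sum_g2 - sum_g**2
        var_y = n * sum_y2 - sum_y**2
        r = cov / np.sqrt(var_g * var_y)

    status = np.full(len(n), "ok", dtype=object)
    status[n < min_n] = "skipped_low_n"
    zero_var = (np.isclose(var_g, 0.0) | np.isclose(var_y, 0.0)) & (n >= min_n)
    status[zero_var] = "skipped_zero_variance"
    ok = status == "ok"

    r = np.where(ok, np.clip(r, -1.0, 1.0), np.nan)
    p = np.full(len(n), np.nan)
    exact = ok & (np.abs(r) >= 1.0)
    p[exact] = 0.0
    reg = ok & ~exact
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r[reg] * np.sqrt((n[reg] - 2) / (1 - r[reg] ** 2))
    p[reg] = 2.0 * stats.t.sf(np.abs(t), n[reg] - 2)

    return pd.DataFrame(
        {"r": r, "n": n.astype(int), "p": p, "status": status},
        index=phenome.values.columns.rename("trait_id"),
    )


# ---------------------------------------------------------------------------
# Storey q-values


def storey_pi0(p: np.ndarray, lambdas: np.ndarray) -> float:
    """Smoothed pi0: cubic fit to pi0(lambda), evaluated at the grid max."""
    m = len(p)
    pi0_grid = np.array(
        [(p > lam).sum() / (m * (1.0 - lam)) for lam in lambdas]
    )
    coef = np.polyfit(lambdas, pi0_grid, deg=3)
    pi0 = float(np.polyval(coef, lambdas.max()))
    return min(max(pi0, 1.0 / m), 1.0)  # clamp to (0, 1]


def storey_qvalues(
    p: np.ndarray,
    lambda_grid: Optional[np.ndarray] = None,
    pi0: Optional[float] = None,
) -> np.ndarray:
    """Storey q-values with smoother-based pi0 estimation.

    ``q_i = min over p_j >= p_i of pi0 * m * p_j / rank(p_j)``, capped at
    1.  With fewer than 20 p-values pi0 falls back to 1 (the
    Benjamini-Hochberg-equivalent), logged; ``pi0`` may also be forced
    explicitly (pi0=1 reproduces BH exactly).
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise ValueError("p must be a non-empty 1-d array")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must be in [0, 1]")
    m = len(p)
    if pi0 is None:
        if m < 20:
            log.info("m=%d < 20: falling back to pi0 = 1", m)
            pi0 = 1.0
        else:
            if lambda_grid is None:
                lambda_grid = np.arange(0.05, 0.96, 0.05)
            pi0 = storey_pi0(p, np.asarray(lambda_grid))
    if not 0 < pi0 <= 1:
        raise ValueError("pi0 must be in (0, 1]")
    order = np.argsort(p, kind="stable")
    ecdf = np.arange(1, m + 1) / m
    # operation order chosen to be bit-identical to BH when pi0 == 1
    q_sorted = pi0 * (p[order] / ecdf)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


# ---------------------------------------------------------------------------
# the PheWAS driver


def phewas(
    variants: pd.DataFrame,
    geno: GenotypeMatrix,
    phenome: PhenomeTable,
    q_threshold: float = 0.01,
    map_window_bp: int = 1_000_000,
) -> pd.DataFrame:
    """Scan each variant's nearest marker against the whole phenome.

    ``variants`` needs columns variant_id, chromosome, position.
    q-values are computed per scan family — one (variant, phenome table)
    scan at a time — and rows with q < ``q_threshold`` are flagged.
    Output includes trait category and -log10(q) for Manhattan plots.
    Variants with no marker within the window get a single unmapped row.
    """
    required = {"variant_id", "chromosome", "position"}
    if not required <= set(variants.columns):
        raise ValueError(f"variants table needs columns {sorted(required)}")
    cols = [
        "variant_id", "marker_id", "trait_id", "category",
        "r", "n", "p", "q", "flagged", "status",
    ]
    if variants.empty:
        empty = pd.DataFrame(columns=cols)
        empty["neg_log10_q"] = pd.Series(dtype=float)
        return empty
    out = []
    for _, var in variants.iterrows():
        marker = map_variant_to_marker(
            var["chromosome"], var["position"], geno.markers, map_window_bp
        )
        if marker is None:
            out.append(
                pd.DataFrame(
                    {
                        "variant_id": [var["variant_id"]],
                        "marker_id": [None],
                        "trait_id": [None],
                        "category": [None],
                        "r": [np.nan],
                        "n": [0],
                        "p": [np.nan],
                        "q": [np.nan],
                        "flagged": [False],
                        "status": ["unmapped"],
                    }
                )
            )
            continue
        res = correlation_scan(geno.marker_vector(marker), phenome)
        ok = res["status"] == "ok"
        q = np.full(len(res), np.nan)
        if ok.any():
            q[ok.to_numpy()] = storey_qvalues(res.loc[ok, "p"].to_numpy())
        res = res.assign(
            q=q,
            flagged=(q < q_threshold) & ok.to_numpy(),
            variant_id=var["variant_id"],
            marker_id=marker,
            category=phenome.traits["category"].to_numpy(),
        )
        out.append(res.reset_index())
    table = pd.concat(out, ignore_index=True)
    table = table[cols]
    with np.errstate(divide="ignore"):
        table["neg_log10_q"] = -np.log10(table["q"])
    return table


def phewas_summary(table: pd.DataFrame, q_threshold: float = 0.01) -> dict:
    flagged = table[table["flagged"] == True]  # noqa: E712
    return {
        "n_tests": int((table["status"] == "ok").sum()),
        "n_flagged": int(len(flagged)),
        "n_variants": int(table["variant_id"].nunique()),
        "n_flagged_variants": int(flagged["variant_id"].nunique()),
        "q_threshold": q_threshold,
    }


# ---------------------------------------------------------------------------
# PC-group scan


@dataclass
class GroupPCScan:
    scores: pd.Series              # strain -> PC1 score
    explained_variance: np.ndarray  # fraction per component
    associations: pd.DataFrame     # marker_id x (r, n, p)


def group_pc_scan(
    phenome: PhenomeTable,
    trait_ids: Sequence[str],
    geno: GenotypeMatrix,
) -> GroupPCScan:
    """Scan PC1 strain scores of a trait group against every marker.

    Traits are centered and scaled (unit variance); strains missing any
    group trait are dropped; components come from the SVD of the
    standardized matrix.
    """
    sub = phenome.values[list(trait_ids)].dropna(axis=0, how="any")
    if sub.shape[0] < 3:
        raise ValueError("fewer than 3 complete strains in trait group")
    x = sub.to_numpy(dtype=float)
    x = x - x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    if (sd == 0).any():
        raise ValueError("constant trait in group")
    x = x / sd
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    explained = (s**2) / (s**2).sum()
    pc1 = pd.Series(u[:, 0] * s[0], index=sub.index, name="PC1")

    rows = []
    for marker in geno.genotypes.columns:
        g = geno.genotypes.loc[sub.index, marker]
        single = PhenomeTable(pc1.to_frame())
        res = correlation_scan(g.to_numpy(dtype=float), single)
        row = res.iloc[0]
        rows.append((marker, row["r"], row["n"], row["p"], row["status"]))
    assoc = pd.DataFrame(
        rows, columns=["marker_id", "r", "n", "p", "status"]
    ).set_index("marker_id")
    return GroupPCScan(
        scores=pc1, explained_variance=explained, associations=assoc
    )
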