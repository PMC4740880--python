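"""PheWAS engine: blocks, mapping, correlation p-values, Storey q-values."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from statsmodels.stats.multitest import multipletests

from riphewas.containers import GenotypeMatrix, PhenomeTable
from riphewas.scan import (
    correlation_scan,
    group_pc_scan,
    map_variant_to_marker,
    phewas,
    select_block_markers,
    storey_pi0,
    storey_qvalues,
)
from riphewas.simulate import (
    MarkerMap,
    SimulationConfig,
    TraitSpec,
    random_marker_map,
    simulate_phenome,
    simulate_ri_genotypes,
)


def _geno_from_codes(codes, chrom="chr1"):
    codes = np.asarray(codes, dtype=float)
    n_strains, n_markers = codes.shape
    ids = [f"m{i}" for i in range(n_markers)]
    mmap = MarkerMap(
        pd.DataFrame(
            {
                "marker_id": ids,
                "chromosome": chrom,
                "position_bp": np.arange(1, n_markers + 1) * 1000,
                "position_cM": np.arange(n_markers, dtype=float),
            }
        )
    )
    geno = pd.DataFrame(
        codes, index=[f"s{i}" for i in range(n_strains)], columns=ids
    )
    return GenotypeMatrix(geno, mmap)


# ---------------------------------------------------------------------------
# block markers


class TestSelectBlockMarkers:
    def test_identical_run_collapses_to_one(self):
        col = [0, 2, 2, 0, 2]
        geno = _geno_from_codes(np.tile(col, (10, 1)).T.T[:, [0] * 10])
        blocks = select_block_markers(geno)
        assert len(blocks.geno.genotypes.columns) == 1
        assert blocks.blocks["n_markers"].iloc[0] == 10
        assert blocks.blocks["representative"].iloc[0] == "m0"

    def test_alternating_patterns_not_collapsed(self):
        a = [0, 2, 0, 2]
        b = [2, 0, 2, 0]
        codes = np.column_stack([a, b, a, b])
        blocks = select_block_markers(_geno_from_codes(codes))
        assert len(blocks.geno.genotypes.columns) == 4

    def test_against_brute_force_run_count(self):
        mmap = random_marker_map({"chr1": 60}, seed=31)
        geno = simulate_ri_genotypes(mmap, 30, seed=32)
        blocks = select_block_markers(geno)
        # brute force: count distinct consecutive strain-vector runs
        cols = geno.genotypes.columns
        expected = 1
        for prev, cur in zip(cols, cols[1:]):
            if not geno.genotypes[prev].equals(geno.genotypes[cur]):
                expected += 1
        assert len(blocks.geno.genotypes.columns) == expected
        assert blocks.blocks["n_markers"].sum() == len(cols)


class TestMapVariantToMarker:
    @pytest.fixture()
    def markers(self):
        return MarkerMap(
            pd.DataFrame(
                {
                    "marker_id": ["a", "b", "c"],
                    "chromosome": ["chr1", "chr1", "chr2"],
                    "position_bp": [2_000_000, 3_000_000, 2_000_000],
                    "position_cM": [2.0, 3.0, 2.0],
                }
            )
        )

    def test_nearest_within_window(self, markers):
        assert map_variant_to_marker("chr1", 1_500_000, markers) == "a"

    def test_beyond_window_unmapped(self, markers):
        assert map_variant_to_marker("chr1", 4_200_000, markers) is None

    def test_tie_goes_to_lower_coordinate(self, markers):
        assert map_variant_to_marker("chr1", 2_500_000, markers) == "a"

    def test_chromosome_respected(self, markers):
        assert map_variant_to_marker("chr2", 2_100_000, markers) == "c"
        assert map_variant_to_marker("chr3", 2_100_000, markers) is None


# ---------------------------------------------------------------------------
# correlation scan


def _phenome(arrays, index):
    return PhenomeTable(pd.DataFrame(arrays, index=index))


class TestCorrelationScan:
    def test_exact_match_gives_p_zero(self):
        g = np.array([0, 0, 2, 2, 0, 2, 0, 2.0])
        p = _phenome({"t": g.copy()}, [f"s{i}" for i in range(8)])
        res = correlation_scan(g, p)
        assert res.loc["t", "r"] == pytest.approx(1.0)
        assert res.loc["t", "p"] == 0.0

    def test_matches_scipy_pearsonr(self):
        rng = np.random.default_rng(41)
        g = rng.choice([0.0, 2.0], size=30)
        y = 0.4 * g + rng.standard_normal(30)
        res = correlation_scan(g, _phenome({"t": y}, [f"s{i}" for i in range(30)]))
        r_ref, p_ref = stats.pearsonr(g, y)
        assert res.loc["t", "r"] == pytest.approx(r_ref)
        assert res.loc["t", "p"] == pytest.approx(p_ref)

    def test_pairwise_complete_with_missing(self):
        g = np.array([0, 0, 2, 2, 0, 2, 0, 2.0])
        y = np.array([1.0, 2.0, np.nan, 3.0, 0.5, 2.5, 1.5, np.nan])
        res = correlation_scan(g, _phenome({"t": y}, [f"s{i}" for i in range(8)]))
        keep = ~np.isnan(y)
        r_ref, p_ref = stats.pearsonr(g[keep], y[keep])
        assert res.loc["t", "n"] == keep.sum()
        assert res.loc["t", "r"] == pytest.approx(r_ref)
        assert res.loc["t", "p"] == pytest.approx(p_ref)

    def test_low_n_skipped(self):
        g = np.array([0, 2, 0, 2, 0.0])
        y = np.array([1, 2, np.nan, np.nan, 3.0])
        res = correlation_scan(g, _phenome({"t": y}, [f"s{i}" for i in range(5)]))
        assert res.loc["t", "status"] == "skipped_low_n"
        assert np.isnan(res.loc["t", "p"])

    def test_zero_variance_skipped(self):
        g = np.zeros(10)
        y = np.arange(10.0)
        res = correlation_scan(g, _phenome({"t": y}, [f"s{i}" for i in range(10)]))
        assert res.loc["t", "status"] == "skipped_zero_variance"

    def test_null_p_uniform(self):
        rng = np.random.default_rng(42)
        g = rng.choice([0.0, 2.0], size=60)
        traits = {f"t{i}": rng.standard_normal(60) for i in range(400)}
        res = correlation_scan(g, _phenome(traits, [f"s{i}" for i in range(60)]))
        ks = stats.kstest(res["p"], "uniform")
        assert ks.pvalue > 1e-3

    def test_permutation_oracle(self):
        # t-based two-tailed p vs a 1e5-permutation estimate
        rng = np.random.default_rng(43)
        n = 30
        g = rng.choice([0.0, 2.0], size=n)
        y = 0.55 * (g - g.mean()) + rng.standard_normal(n)
        res = correlation_scan(g, _phenome({"t": y}, [f"s{i}" for i in range(n)]))
        r_obs = abs(res.loc["t", "r"])
        n_perm = 100_000
        perm = np.tile(y, (n_perm, 1))
        perm = rng.permuted(perm, axis=1)
        gc = g - g.mean()
        pc = perm - perm.mean(axis=1, keepdims=True)
        r_perm = (pc @ gc) / (
            np.sqrt((pc**2).sum(axis=1)) * np.sqrt((gc**2).sum())
        )
        p_perm = (np.abs(r_perm) >= r_obs - 1e-12).mean()
        se = np.sqrt(max(p_perm * (1 - p_perm), 1e-12) / n_perm)
        assert abs(res.loc["t", "p"] - p_perm) <= 3 * se + 1e-6

    def test_invariant_to_strain_order(self):
        rng = np.random.default_rng(44)
        g = rng.choice([0.0, 2.0], size=20)
        y = rng.standard_normal(20)
        idx = [f"s{i}" for i in range(20)]
        res1 = correlation_scan(g, _phenome({"t": y}, idx))
        order = rng.permutation(20)
        res2 = correlation_scan(g[order], _phenome({"t": y[order]},
                                                   [idx[i] for i in order]))
        assert res1.loc["t", "p"] == pytest.approx(res2.loc["t", "p"])


# ---------------------------------------------------------------------------
# Storey q-values


class TestStoreyQvalues:
    def test_all_ones(self):
        q = storey_qvalues(np.ones(30))
        assert (q == 1.0).all()

    def test_pi0_one_reproduces_bh_exactly(self):
        rng = np.random.default_rng(51)
        p = rng.random(500)
        bh = multipletests(p, method="fdr_bh")[1]
        q = storey_qvalues(p, pi0=1.0)
        np.testing.assert_array_equal(q, bh)

    def test_pi0_near_one_under_null(self):
        lambdas = np.arange(0.05, 0.96, 0.05)
        for seed in range(5):
            p = np.random.default_rng(seed).random(10_000)
            pi0 = storey_pi0(p, lambdas)
            assert 0.9 <= pi0 <= 1.0

    def test_monotone_in_p(self):
        rng = np.random.default_rng(52)
        p = rng.random(200) ** 2
        q = storey_qvalues(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()

    def test_q_at_least_scaled_p(self):
        # for the minimizing j, m*p_j/rank_j >= p_j >= p_i, so q_i >= pi0*p_i
        rng = np.random.default_rng(53)
        p = rng.random(100)
        q = storey_qvalues(p, pi0=0.8)
        assert (q >= 0.8 * p - 1e-12).all()
        assert (q <= 1.0).all()

    def test_small_m_falls_back_to_bh(self):
        p = np.array([0.01, 0.2, 0.5, 0.9])
        q = storey_qvalues(p)
        bh = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(q, bh)

    def test_invalid_input(self):
        with pytest.raises(ValueError):
            storey_qvalues(np.array([0.5, 1.5]))
        with pytest.raises(ValueError):
            storey_qvalues(np.array([]))


# ---------------------------------------------------------------------------
# phewas driver + PC scan


@pytest.fixture(scope="module")
def planted_panel():
    mmap = random_marker_map({"chr1": 40}, seed=61)
    geno = simulate_ri_genotypes(mmap, 80, seed=62)
    planted = mmap.marker_ids[20]
    specs = [TraitSpec("planted_trait", planted, 0.5)] + [
        TraitSpec(f"null{i:03d}") for i in range(99)
    ]
    phenome = simulate_phenome(
        geno, SimulationConfig(n_strains=80, seed=63, trait_spec=specs)
    )
    return mmap, geno, planted, phenome


class TestPhewas:
    def test_planted_pair_flagged(self, planted_panel):
        mmap, geno, planted, phenome = planted_panel
        pos = mmap.table.set_index("marker_id").loc[planted, "position_bp"]
        variants = pd.DataFrame(
            {"variant_id": ["v1"], "chromosome": ["chr1"], "position": [pos + 10]}
        )
        table = phewas(variants, geno, phenome)
        hit = table[(table["variant_id"] == "v1")
                    & (table["trait_id"] == "planted_trait")]
        assert hit["marker_id"].iloc[0] == planted
        assert bool(hit["flagged"].iloc[0])

    def test_empty_variant_list(self, planted_panel):
        _, geno, _, phenome = planted_panel
        table = phewas(
            pd.DataFrame(columns=["variant_id", "chromosome", "position"]),
            geno, phenome,
        )
        assert table.empty

    def test_unmapped_variant_reported(self, planted_panel):
        _, geno, _, phenome = planted_panel
        variants = pd.DataFrame(
            {"variant_id": ["far"], "chromosome": ["chr9"], "position": [1]}
        )
        table = phewas(variants, geno, phenome)
        assert (table["status"] == "unmapped").all()

    def test_invariant_to_trait_order(self, planted_panel):
        mmap, geno, planted, phenome = planted_panel
        pos = mmap.table.set_index("marker_id").loc[planted, "position_bp"]
        variants = pd.DataFrame(
            {"variant_id": ["v1"], "chromosome": ["chr1"], "position": [pos]}
        )
        shuffled = PhenomeTable(
            phenome.values[phenome.values.columns[::-1]],
            phenome.traits.iloc[::-1],
        )
        t1 = phewas(variants, geno, phenome).set_index("trait_id")
        t2 = phewas(variants, geno, shuffled).set_index("trait_id")
        for trait in t1.index:
            assert t1.loc[trait, "q"] == pytest.approx(t2.loc[trait, "q"])


class TestGroupPcScan:
    def test_single_trait_equals_that_trait(self, planted_panel):
        _, geno, _, phenome = planted_panel
        res = group_pc_scan(phenome, ["planted_trait"], geno)
        direct = correlation_scan(
            geno.marker_vector(geno.genotypes.columns[0]),
            PhenomeTable(phenome.values[["planted_trait"]]),
        )
        first = res.associations.iloc[0]
        assert abs(first["r"]) == pytest.approx(
            abs(direct.iloc[0]["r"]), abs=1e-12
        )
        assert res.explained_variance[0] == pytest.approx(1.0)

    def test_explained_variance_matches_eigh_oracle(self, planted_panel):
        _, geno, _, phenome = planted_panel
        traits = phenome.trait_ids[:6]
        res = group_pc_scan(phenome, traits, geno)
        x = phenome.values[traits].to_numpy()
        x = (x - x.mean(0)) / x.std(0, ddof=1)
        evals = np.linalg.eigvalsh(x.T @ x)[::-1]
        np.testing.assert_allclose(
            res.explained_variance, evals / evals.sum(), atol=1e-10
        )

    def test_coregulated_traits_peak_at_driver(self):
        mmap = random_marker_map({"chr1": 30}, seed=71)
        geno = simulate_ri_genotypes(mmap, 80, seed=72)
        driver = mmap.marker_ids[15]
        specs = [TraitSpec(f"co{i}", driver, 0.5) for i in range(6)]
        phenome = simulate_phenome(
            geno, SimulationConfig(n_strains=80, seed=73, trait_spec=specs)
        )
        res = group_pc_scan(phenome, [s.trait_id for s in specs], geno)
        best = res.associations["p"].idxmin()
        # peak at the driver or a marker in perfect LD with it
        g_best = geno.genotypes[best]
        g_driver = geno.genotypes[driver]
        assert abs(np.corrcoef(g_best, g_driver)[0, 1]) > 0.9
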