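import itertools
import math

import numpy as np
import pytest
from hypothesis import given, strategies as hst
from scipy import stats

from screentrace.screen_scoring import (
    ScoringConfig,
    compute_rho,
    empirical_fdr,
    exact_rank_sum_pvalue,
    filter_sgrnas,
    gene_phenotype,
    gene_pvalue,
    genes_at_fdr,
    make_pseudogenes,
    score_screen,
    volcano_score,
)
from screentrace.synthetic_data import ScreenSimParams, simulate_screen

from conftest import build_counts, build_library


def two_arm_counts(ctrl: dict, treat: dict, dd=(8.4, 6.4)):
    return build_counts(
        {"c1": ctrl, "t1": treat},
        arms={"c1": "control", "t1": "treatment"},
        doublings={"c1": dd[0], "t1": dd[1]},
    )


class TestFilter:
    @pytest.mark.parametrize(
        "ctrl,treat,expected",
        [(100, 5, True), (5, 100, True), (99, 99, False), (100, 100, True)],
    )
    def test_threshold_on_best_condition(self, ctrl, treat, expected):
        counts = two_arm_counts({"g1": ctrl, "n1": 500}, {"g1": treat, "n1": 500})
        flags = filter_sgrnas(counts, ScoringConfig())
        assert flags["g1"] == expected

    def test_condition_totals_sum_over_replicates(self):
        counts = build_counts(
            {
                "c1": {"g1": 60}, "c2": {"g1": 50},
                "t1": {"g1": 0}, "t2": {"g1": 0},
            },
            arms={"c1": "control", "c2": "control", "t1": "treatment", "t2": "treatment"},
            doublings={"c1": 8.4, "c2": 8.4, "t1": 6.4, "t2": 6.4},
        )
        assert filter_sgrnas(counts, ScoringConfig())["g1"]  # 60 + 50 >= 100

    def test_min_count_zero_passes_all(self):
        counts = two_arm_counts({"g1": 0}, {"g1": 0})
        assert filter_sgrnas(counts, ScoringConfig(min_count=0)).all()


class TestRho:
    def lib(self):
        return build_library({"GENEA": 1}, n_ntc=3)

    def counts(self, ctrl_g=990, treat_g=90, dd=(8.4, 6.4)):
        ctrl = {"GENEA_sg1": ctrl_g, "NTC_1": 500, "NTC_2": 600, "NTC_3": 700}
        treat = {"GENEA_sg1": treat_g, "NTC_1": 500, "NTC_2": 600, "NTC_3": 700}
        return two_arm_counts(ctrl, treat, dd)

    def test_direct_formula(self):
        """990 -> 90 counts with pseudocount 10 and dd = 8.4 - 6.4 = 2:
        rho = log2(100/1000)/2."""
        cfg = ScoringConfig(rpm_normalize=False)
        rho = compute_rho(self.counts(), self.lib(), cfg)["rho"]
        assert rho["GENEA_sg1"] == pytest.approx(math.log2(0.1) / 2.0, abs=1e-12)
        assert rho["GENEA_sg1"] == pytest.approx(-1.6610, abs=5e-5)

    def test_equal_counts_give_zero(self):
        cfg = ScoringConfig(rpm_normalize=False)
        rho = compute_rho(self.counts(ctrl_g=500, treat_g=500), self.lib(), cfg)["rho"]
        assert rho["GENEA_sg1"] == 0.0

    def test_rho_linear_in_inverse_doubling_difference(self):
        cfg = ScoringConfig(rpm_normalize=False)
        r2 = compute_rho(self.counts(dd=(8.4, 6.4)), self.lib(), cfg)["rho"]["GENEA_sg1"]
        r4 = compute_rho(self.counts(dd=(10.4, 6.4)), self.lib(), cfg)["rho"]["GENEA_sg1"]
        assert r4 == pytest.approx(r2 / 2.0, rel=1e-12)

    def test_zero_doubling_difference_rejected(self):
        with pytest.raises(ValueError, match="doubling"):
            compute_rho(self.counts(dd=(6.4, 6.4)), self.lib(), ScoringConfig())

    def test_ntc_median_exactly_zero(self):
        params = ScreenSimParams(n_genes=20, n_ntc=50, seed=5)
        library, counts, _ = simulate_screen(params)
        cfg = ScoringConfig()
        pheno = compute_rho(counts, library, cfg)
        passing_ntc = [
            i for i in library.ntc_ids if pheno.loc[i, "passed_filter"]
        ]
        assert abs(np.median(pheno.loc[passing_ntc, "rho"])) <= 1e-12

    def test_rpm_equivariance(self):
        """Scaling one sample's counts leaves rhos unchanged (pseudocount 0)."""
        lib = self.lib()
        cfg = ScoringConfig(pseudocount=0, min_count=1)
        base = self.counts()
        scaled = self.counts()
        scaled.counts["t1"] = scaled.counts["t1"] * 7
        r1 = compute_rho(base, lib, cfg)["rho"]
        r2 = compute_rho(scaled, lib, cfg)["rho"]
        assert np.allclose(r1, r2, atol=1e-12)


class TestGenePhenotype:
    def test_seven_ones_three_zeros(self):
        assert gene_phenotype([1, 1, 1, 1, 1, 1, 1, 0, 0, 0], top_k=7) == 1.0

    @given(hst.floats(-5, 5), hst.integers(1, 10))
    def test_constant_vector(self, c, n):
        assert gene_phenotype([c] * n, top_k=7) == pytest.approx(c)

    @given(hst.lists(hst.floats(-10, 10), min_size=1, max_size=15))
    def test_matches_bruteforce_sort(self, rhos):
        order = sorted(range(len(rhos)), key=lambda i: (-abs(rhos[i]), i))
        expected = float(np.mean([rhos[i] for i in order[:7]]))
        assert gene_phenotype(rhos, top_k=7) == pytest.approx(expected, abs=1e-12)

    @given(hst.lists(hst.floats(-10, 10), min_size=1, max_size=10))
    def test_topk_equal_n_is_plain_mean(self, rhos):
        assert gene_phenotype(rhos, top_k=len(rhos)) == pytest.approx(
            float(np.mean(rhos)), abs=1e-12
        )

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            gene_phenotype([])


def enumeration_pvalue(x, y):
    """Exhaustive two-sided rank-sum oracle: P(|W - E[W]| >= |w_obs - E[W]|)."""
    pooled = np.concatenate([x, y])
    n1, n = len(x), len(pooled)
    ranks = stats.rankdata(pooled)
    mu = n1 * (n + 1) / 2
    dev = abs(ranks[:n1].sum() - mu) - 1e-9
    hits = total = 0
    for idx in itertools.combinations(range(n), n1):
        total += 1
        if abs(ranks[list(idx)].sum() - mu) >= dev:
            hits += 1
    return hits / total


class TestGenePvalue:
    def test_all_ties_give_one(self):
        assert gene_pvalue([2.0, 2.0, 2.0], [2.0, 2.0, 2.0, 2.0]) == 1.0

    def test_two_vs_three_enumeration(self):
        # {5,6} vs {1,2,3}: 2 of C(5,2)=10 regroupings are as extreme
        assert gene_pvalue([5, 6], [1, 2, 3]) == pytest.approx(0.2)

    def test_complete_separation_exact_tail(self):
        x = [11.0, 12.0, 13.0]
        y = [1.0, 2.0, 3.0, 4.0]
        # U = n1*n2: both tails contribute 1/C(7,3) each
        assert gene_pvalue(x, y) == pytest.approx(2 / math.comb(7, 3))

    @given(
        hst.integers(1, 5),
        hst.integers(1, 5),
        hst.booleans(),
        hst.randoms(use_true_random=False),
    )
    def test_matches_exhaustive_enumeration(self, n1, n2, ties, rnd):
        if ties:
            x = [rnd.randint(0, 3) for _ in range(n1)]
            y = [rnd.randint(0, 3) for _ in range(n2)]
        else:
            x = [rnd.gauss(0, 1) for _ in range(n1)]
            y = [rnd.gauss(0, 1) for _ in range(n2)]
        assert gene_pvalue(x, y) == pytest.approx(enumeration_pvalue(x, y), abs=1e-12)

    def test_asymptotic_close_to_exact_at_boundary(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=10), rng.normal(size=14)
        exact = exact_rank_sum_pvalue(x, y)
        approx = gene_pvalue(x, y, exact_max_n=5)  # force asymptotic path
        assert approx == pytest.approx(exact, abs=0.03)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            gene_pvalue([], [1.0])


class TestPseudogenes:
    def test_study_geometry(self):
        pool = [f"NTC_{i}" for i in range(730)]
        groups = make_pseudogenes(pool, 489, group_size=10, seed=1)
        assert len(groups) == 489
        for ids in groups.values():
            assert len(set(ids)) == 10
            assert set(ids) <= set(pool)

    def test_seeded_determinism(self):
        pool = [f"n{i}" for i in range(30)]
        a = make_pseudogenes(pool, 5, 10, seed=9)
        b = make_pseudogenes(pool, 5, 10, seed=9)
        assert a == b

    def test_group_size_equals_pool(self):
        pool = [f"n{i}" for i in range(10)]
        groups = make_pseudogenes(pool, 3, 10, seed=0)
        assert all(sorted(ids) == sorted(pool) for ids in groups.values())

    def test_group_size_exceeding_pool_rejected(self):
        with pytest.raises(ValueError):
            make_pseudogenes(["a", "b"], 1, 3, seed=0)


class TestVolcanoScore:
    @pytest.mark.parametrize(
        "pheno,p,expected",
        [(0.0, 0.5, 0.0), (1.3, 1.0, 0.0), (-0.5, 0.01, -1.0), (2.0, 0.1, 2.0)],
    )
    def test_values(self, pheno, p, expected):
        assert volcano_score(pheno, p) == pytest.approx(expected)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            volcano_score(1.0, 0.0)


class TestScoreScreen:
    def test_planted_depleting_gene_has_most_negative_volcano(self):
        params = ScreenSimParams(
            n_genes=50, n_ntc=150, reads_per_sgrna=500,
            fraction_hits=1 / 50, hit_effect_size=-1.0, seed=21,
        )
        library, counts, truth = simulate_screen(params)
        table = score_screen(counts, library, ScoringConfig(seed=22))
        real = table[~table["is_pseudogene"]]
        assert real["volcano_score"].idxmin() == truth.hit_genes[0]
        assert real.loc[truth.hit_genes[0], "rank"] == 1

    def test_pseudogene_count_matches_real_genes(self):
        params = ScreenSimParams(n_genes=25, n_ntc=60, seed=4)
        library, counts, _ = simulate_screen(params)
        table = score_screen(counts, library, ScoringConfig(seed=0))
        assert table["is_pseudogene"].sum() == (~table["is_pseudogene"]).sum() == 25

    def test_gene_table_contract(self):
        params = ScreenSimParams(n_genes=10, n_ntc=40, seed=8)
        library, counts, _ = simulate_screen(params)
        table = score_screen(counts, library, ScoringConfig(seed=1))
        assert (table["p_value"] > 0).all() and (table["p_value"] <= 1).all()
        expected = table["phenotype"] * -np.log10(table["p_value"])
        assert np.allclose(table["volcano_score"], expected, atol=1e-12)


class TestEmpiricalFdr:
    def table(self, seed=31):
        params = ScreenSimParams(n_genes=30, n_ntc=100, seed=seed)
        library, counts, _ = simulate_screen(params)
        return score_screen(counts, library, ScoringConfig(seed=seed))

    def test_extreme_threshold_has_zero_fdr(self):
        table = self.table().copy()
        # push one real gene beyond every pseudogene score
        top = table.loc[~table["is_pseudogene"]].index[0]
        table.loc[top, "volcano_score"] = 1e6
        fdr = empirical_fdr(table)
        assert fdr.iloc[0]["fdr"] == 0.0

    def test_threshold_zero_fdr_near_one_when_matched(self):
        fdr = empirical_fdr(self.table())
        assert fdr.iloc[-1]["fdr"] == pytest.approx(1.0, abs=0.15)

    def test_q_monotone_non_increasing_in_threshold(self):
        fdr = empirical_fdr(self.table())
        assert (np.diff(fdr["q"]) >= -1e-12).all()  # thresholds descend

    def test_requires_pseudogenes(self):
        table = self.table()
        with pytest.raises(ValueError):
            empirical_fdr(table[~table["is_pseudogene"]])

    def test_planted_hits_recovered(self):
        params = ScreenSimParams(
            fraction_hits=10 / 489, hit_effect_size=-1.0,
            reads_per_sgrna=500, seed=11,
        )
        library, counts, truth = simulate_screen(params)
        table = score_screen(counts, library, ScoringConfig(seed=12))
        recovered = set(genes_at_fdr(table, alpha=0.1))
        assert set(truth.hit_genes) <= recovered
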