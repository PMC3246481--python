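import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from pathperm.geneset import build_regions
from pathperm.permutation import (
    _prune_and_mean,
    binomial_ci,
    empirical_pvalue,
    ld_r2,
    mean_p_set_test,
    permute_labels_within_clusters,
    prob_random_set_contains_associated,
    random_set_calibration,
    run_pathway_test,
)
from pathperm.synthetic_data import GeneSpec, generate_panel, study_config


class TestPermuteLabels:
    @given(st.lists(st.sampled_from(["A", "B", "C"]), min_size=1, max_size=40),
           st.integers(0, 2**31 - 1))
    def test_per_cluster_counts_conserved(self, clusters, seed):
        clusters = np.array(clusters)
        rng = np.random.default_rng(seed)
        y = (rng.random(clusters.size) < 0.4).astype(int)
        y_perm = permute_labels_within_clusters(y, clusters, rng)
        for lab in np.unique(clusters):
            sel = clusters == lab
            assert y_perm[sel].sum() == y[sel].sum()
        assert y_perm.sum() == y.sum()

    def test_single_sample_cluster_fixed(self):
        y = np.array([1, 0, 0])
        clusters = np.array(["solo", "pair", "pair"])
        rng = np.random.default_rng(0)
        for _ in range(20):
            assert permute_labels_within_clusters(y, clusters, rng)[0] == 1

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            permute_labels_within_clusters(np.array([1]), np.array(["a", "b"]),
                                           np.random.default_rng(0))


class TestEmpiricalPvalue:
    def test_strict_exceedance_with_tie(self):
        assert empirical_pvalue(4.0, [3.0, 5.0, 2.0, 4.0]) == 0.25

    def test_observed_above_all_gives_zero(self):
        assert empirical_pvalue(9.0, [1.0, 2.0]) == 0.0

    def test_observed_below_all_gives_one(self):
        assert empirical_pvalue(0.0, [1.0, 2.0]) == 1.0

    def test_unbiased_variant_never_zero(self):
        assert empirical_pvalue(9.0, [1.0, 2.0], unbiased=True) == pytest.approx(1 / 3)

    def test_less_tail_orientation(self):
        assert empirical_pvalue(0.02, [0.01, 0.5, 0.6, 0.7], tail="less") == 0.25

    def test_nan_permutations_never_count(self):
        assert empirical_pvalue(1.0, [np.nan, 2.0]) == 0.5
        assert empirical_pvalue(1.0, [np.nan, 0.5], tail="less") == 0.5

    @given(st.lists(st.floats(-5, 5), min_size=1, max_size=30),
           st.floats(-6, 6), st.floats(-6, 6))
    def test_antitone_in_observed(self, permuted, obs1, obs2):
        lo, hi = sorted([obs1, obs2])
        assert empirical_pvalue(lo, permuted) >= empirical_pvalue(hi, permuted)


class TestBinomialCi:
    def test_ten_of_hundred_matches_beta_quantiles(self):
        lo, hi = binomial_ci(10, 100)
        assert lo == pytest.approx(float(stats.beta.ppf(0.025, 10, 91)), rel=1e-12)
        assert hi == pytest.approx(float(stats.beta.ppf(0.975, 11, 90)), rel=1e-12)

    def test_zero_successes_lower_bound_zero(self):
        lo, hi = binomial_ci(0, 20)
        assert lo == 0.0
        assert 0 < hi < 1

    def test_all_successes_upper_bound_one(self):
        lo, hi = binomial_ci(20, 20)
        assert hi == 1.0
        assert 0 < lo < 1

    def test_interval_covers_point_estimate(self):
        lo, hi = binomial_ci(7, 31)
        assert lo <= 7 / 31 <= hi

    def test_bad_counts_rejected(self):
        with pytest.raises(ValueError):
            binomial_ci(5, 4)


class TestOverlapProbability:
    def test_no_associated_genes_gives_zero(self):
        assert prob_random_set_contains_associated(n_associated=0) == 0.0

    def test_empty_set_gives_zero(self):
        assert prob_random_set_contains_associated(set_size=0) == 0.0

    def test_exact_close_to_approximation(self):
        approx = prob_random_set_contains_associated(20_000, 24, 43)
        exact = prob_random_set_contains_associated(20_000, 24, 43, exact=True)
        assert exact == pytest.approx(approx, rel=0.01)


class TestLdR2:
    def test_self_is_one(self):
        g = np.array([0, 1, 2, 1, 0, 2])
        assert ld_r2(g, g) == pytest.approx(1.0)

    def test_anticorrelated_is_one(self):
        g = np.array([0, 1, 2, 1, 0, 2])
        assert ld_r2(g, 2 - g) == pytest.approx(1.0)

    def test_independent_snps_near_zero(self):
        rng = np.random.default_rng(4)
        a = rng.binomial(2, 0.3, 1000)
        b = rng.binomial(2, 0.3, 1000)
        assert ld_r2(a, b) < 0.02

    def test_constant_rejected(self):
        with pytest.raises(ValueError):
            ld_r2(np.ones(10), np.arange(10) % 3)

    def test_jointly_missing_excluded(self):
        a = np.array([0.0, 1, 2, np.nan, 1, 0])
        b = np.array([0.0, 1, 2, 2, np.nan, 0])
        assert ld_r2(a, b) == pytest.approx(1.0)


class TestMeanPPruning:
    def test_single_selected_snp_is_its_p(self):
        p = np.array([0.01, 0.5, 0.9])
        r2 = np.eye(3)
        cand = np.arange(3)
        assert _prune_and_mean(p, cand, r2, 0.05, 0.5) == pytest.approx(0.01)

    def test_correlated_pair_keeps_smaller_p(self):
        p = np.array([0.01, 0.02])
        r2 = np.array([[1.0, 0.95], [0.95, 1.0]])
        cand = np.arange(2)
        assert _prune_and_mean(p, cand, r2, 0.05, 0.5) == pytest.approx(0.01)

    def test_uncorrelated_pair_averaged(self):
        p = np.array([0.01, 0.03])
        r2 = np.array([[1.0, 0.1], [0.1, 1.0]])
        assert _prune_and_mean(p, np.arange(2), r2, 0.05, 0.5) == pytest.approx(0.02)

    def test_nothing_selected_is_nan(self):
        p = np.array([0.2, 0.3])
        assert np.isnan(_prune_and_mean(p, np.arange(2), np.eye(2), 0.05, 0.5))


@pytest.fixture(scope="module")
def null_run():
    cfg = study_config(n_clusters=2, cases_per_cluster=60, controls_per_cluster=60,
                       n_genes=5, snps_per_gene=2, seed=21)
    panel = generate_panel(cfg)
    regions = build_regions(cfg.region_records(), 10_000)
    return panel, regions, cfg


class TestRunPathwayTest:
    def test_same_seed_reproducible(self, null_run):
        panel, regions, _ = null_run
        a = run_pathway_test(panel, regions, n_perm=50, seed=9)
        b = run_pathway_test(panel, regions, n_perm=50, seed=9)
        for ra, rb in zip(a, b):
            assert ra.p_emp == rb.p_emp
            np.testing.assert_array_equal(ra.permuted, rb.permuted)

    def test_both_statistics_reported_per_set(self, null_run):
        panel, regions, _ = null_run
        sets = {"All genes": [r.region_id for r in regions],
                "first two": [r.region_id for r in regions[:2]]}
        res = run_pathway_test(panel, regions, sets=sets, n_perm=30, seed=1)
        key = {(r.set_label, r.statistic) for r in res}
        assert key == {("All genes", "SUMSTAT"), ("All genes", "SUMSQ"),
                       ("first two", "SUMSTAT"), ("first two", "SUMSQ")}

    def test_pemp_counts_are_integers(self, null_run):
        panel, regions, _ = null_run
        for r in run_pathway_test(panel, regions, n_perm=40, seed=3):
            assert (r.p_emp * r.n_perm) == pytest.approx(round(r.p_emp * r.n_perm))

    def test_strong_causal_set_detected(self):
        """A set holding an OR = 2 SNP is usually flagged at alpha = 0.05."""
        hits = 0
        n_rep = 10
        for rep in range(n_rep):
            cfg = study_config(
                n_clusters=2, cases_per_cluster=500, controls_per_cluster=500,
                n_genes=5, snps_per_gene=2, causal_beta=float(np.log(2.0)),
                seed=7000 + rep,
            )
            panel = generate_panel(cfg)
            regions = build_regions(cfg.region_records(), 10_000)
            res = run_pathway_test(panel, regions, n_perm=100, seed=7500 + rep)
            r = next(x for x in res if x.statistic == "SUMSTAT")
            hits += int(r.p_emp <= 0.05)
        assert hits > n_rep / 2


class TestMeanPSetTest:
    def test_no_snp_selected_reported_nonsignificant(self, null_run):
        panel, regions, _ = null_run
        res = mean_p_set_test(panel, regions, p_threshold=1e-12, n_perm=20, seed=2)
        assert np.isnan(res.observed)
        assert res.p_emp == 1.0

    def test_reproducible_and_oriented(self, null_run):
        panel, regions, _ = null_run
        a = mean_p_set_test(panel, regions, p_threshold=0.9, n_perm=60, seed=5)
        b = mean_p_set_test(panel, regions, p_threshold=0.9, n_perm=60, seed=5)
        assert a.p_emp == b.p_emp
        assert a.statistic == "MEANP"
        assert 0 <= a.p_emp <= 1

    def test_null_pvalues_roughly_uniform(self):
        """Mean-p empirical p over null replicates has ~uniform tail mass."""
        n_rep, n_perm, alpha = 40, 60, 0.25
        hits = 0
        for rep in range(n_rep):
            cfg = study_config(n_clusters=2, cases_per_cluster=40,
                               controls_per_cluster=40, n_genes=4,
                               snps_per_gene=2, seed=8200 + rep)
            panel = generate_panel(cfg)
            regions = build_regions(cfg.region_records(), 10_000)
            res = mean_p_set_test(panel, regions, p_threshold=0.9,
                                  n_perm=n_perm, seed=8600 + rep)
            hits += int(res.p_emp <= alpha)
        # P(p_emp <= k/N) = (k+1)/(N+1) under exchangeability
        level = (alpha * n_perm + 1) / (n_perm + 1)
        lo = stats.binom.ppf(0.0005, n_rep, level)
        hi = stats.binom.ppf(0.9995, n_rep, level)
        assert lo <= hits <= hi


class TestRandomSetCalibration:
    def test_zero_sets_rejected(self, null_run):
        panel, _, cfg = null_run
        with pytest.raises(ValueError):
            random_set_calibration(panel, list(cfg.gene_specs), n_sets=0)

    def test_universe_smaller_than_set_rejected(self, null_run):
        panel, _, cfg = null_run
        with pytest.raises(ValueError):
            random_set_calibration(panel, list(cfg.gene_specs),
                                   n_sets=2, genes_per_set=99)

    def test_alpha_above_one_flags_everything(self, null_run):
        panel, _, cfg = null_run
        res = random_set_calibration(
            panel, list(cfg.gene_specs), n_sets=5, genes_per_set=3,
            alpha=1.0001, seed=3, n_perm=20,
        )
        assert res.rate == 1.0

    def test_null_rate_moderate_with_ci(self, null_run):
        panel, _, cfg = null_run
        universe = list(cfg.gene_specs) + [
            GeneSpec(f"X{i}", "21", 5_000_000 + i * 300_000,
                     5_050_000 + i * 300_000) for i in range(10)
        ]
        res = random_set_calibration(panel, universe, n_sets=20, genes_per_set=4,
                                     alpha=0.05, seed=13, n_perm=60)
        assert 0 <= res.ci_low <= res.rate <= res.ci_high <= 1
        assert res.n_significant <= 5  # grossly anticonservative would exceed
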