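"""Overlap significance, correlation comparisons, MDS and bootstrap clustering."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dimoshift import (
    LeadingLogFCMDS,
    SimulationConfig,
    TMMNormalizer,
    bootstrap_cluster,
    compare_dimorphism_correlation,
    fisher_z_test,
    filter_low_expression,
    leading_logfc_mds,
    overlap_test,
    response_correlation,
    simulate_counts,
)


# ---------------------------------------------------------------------------
# overlap test
# ---------------------------------------------------------------------------

class TestOverlap:
    def test_complete_overlap_hypergeometric(self):
        u = set(range(10))
        a = set(range(5))
        res = overlap_test([a, set(a)], u)
        assert res.p_value == pytest.approx(1 / math.comb(10, 5))

    def test_zero_overlap_has_p_one(self):
        u = set(range(10))
        res = overlap_test([{0, 1}, {5, 6}], u)
        assert res.observed_overlap == 0
        # P(X >= 0) = 1 regardless of configuration
        res2 = overlap_test([{0, 1}, set()], u)
        assert res2.p_value == pytest.approx(1.0)

    def test_expected_overlap_formula(self):
        u = set(range(100))
        res = overlap_test([set(range(20)), set(range(10, 40))], u)
        assert res.expected_overlap == pytest.approx(20 * 30 / 100)

    def test_stray_element_rejected(self):
        with pytest.raises(ValueError, match="outside the universe"):
            overlap_test([{1, 99}, {2}], {1, 2, 3})

    def test_two_set_matches_exhaustive_enumeration(self):
        # p equals the fraction of placements of B with |A ∩ B| >= observed
        rng = np.random.default_rng(0)
        for _ in range(5):
            n = int(rng.integers(6, 13))
            universe = set(range(n))
            a = set(rng.choice(n, size=int(rng.integers(2, n - 1)), replace=False).tolist())
            b = set(rng.choice(n, size=int(rng.integers(2, n - 1)), replace=False).tolist())
            obs = len(a & b)
            hits = total = 0
            for comb in itertools.combinations(range(n), len(b)):
                total += 1
                hits += len(a & set(comb)) >= obs
            res = overlap_test([a, b], universe)
            assert res.p_value == pytest.approx(hits / total)

    def test_three_set_matches_enumeration(self):
        universe = set(range(8))
        a, b, c = {0, 1, 2, 3}, {1, 2, 3, 4, 5}, {0, 1, 2, 5}
        obs = len(a & b & c)
        hits = total = 0
        for bb in itertools.combinations(range(8), len(b)):
            for cc in itertools.combinations(range(8), len(c)):
                total += 1
                hits += len(a & set(bb) & set(cc)) >= obs
        res = overlap_test([a, b, c], universe)
        assert res.method == "exact-convolution"
        assert res.p_value == pytest.approx(hits / total)

    def test_two_set_agrees_with_fisher_exact(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            n = int(rng.integers(30, 120))
            a = set(rng.choice(n, size=int(rng.integers(5, n // 2)), replace=False).tolist())
            b = set(rng.choice(n, size=int(rng.integers(5, n // 2)), replace=False).tolist())
            res = overlap_test([a, b], set(range(n)))
            k = len(a & b)
            table = [[k, len(a) - k], [len(b) - k, n - len(a) - len(b) + k]]
            _, p = stats.fisher_exact(table, alternative="greater")
            assert res.p_value == pytest.approx(p, rel=1e-9)

    def test_monte_carlo_close_to_exact(self):
        universe = set(range(6000))
        rng = np.random.default_rng(1)
        sets = [set(rng.choice(6000, 800, replace=False).tolist()) for _ in range(4)]
        exact = overlap_test(sets, universe, mc_threshold=(10**9, 99))
        mc = overlap_test(sets, universe, mc_threshold=(5000, 3), seed=2)
        assert mc.method == "monte-carlo"
        assert mc.p_value == pytest.approx(exact.p_value, abs=0.02)


# ---------------------------------------------------------------------------
# correlations
# ---------------------------------------------------------------------------

class TestCorrelation:
    def test_identical_vectors(self):
        x = np.arange(10.0)
        rho, _ = response_correlation(x, x)
        assert rho == pytest.approx(1.0)

    def test_exact_reversal(self):
        x = np.arange(10.0)
        rho, _ = response_correlation(x, x[::-1])
        assert rho == pytest.approx(-1.0)

    def test_matches_midrank_pearson(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=10)
        y = np.round(rng.normal(size=10), 1)  # force some ties
        rho, _ = response_correlation(x, y)
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        assert rho == pytest.approx(np.corrcoef(rx, ry)[0, 1], rel=1e-12)

    def test_constant_vector_warns_nan(self):
        with pytest.warns(RuntimeWarning):
            rho, p = response_correlation(np.ones(5), np.arange(5.0))
        assert np.isnan(rho)

    def test_fisher_z_equal_correlations(self):
        z, p = fisher_z_test(0.5, 0.5, 100, 100)
        assert z == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_fisher_z_closed_form(self):
        z, p = fisher_z_test(0.0, 0.3, 103, 103)
        expected_z = math.atanh(0.3) / math.sqrt(2 / 100)
        assert z == pytest.approx(expected_z)
        assert p == pytest.approx(2 * stats.norm.sf(abs(expected_z)))

    def test_fisher_z_sign_flips_on_swap(self):
        z1, p1 = fisher_z_test(0.2, 0.6, 50, 50)
        z2, p2 = fisher_z_test(0.6, 0.2, 50, 50)
        assert z1 == pytest.approx(-z2)
        assert p1 == pytest.approx(p2)

    def test_cold_compression_detected(self, de_chain):
        # the default simulation feminizes the male transcriptome in cold,
        # so male/female expression correlates higher at 6C than 19C
        _, norm, _, _ = de_chain
        cc = compare_dimorphism_correlation(norm)
        assert cc.r_cold > cc.r_control

    def test_detection_power_matches_closed_form(self):
        # Delta r = 0.02 (0.70 vs 0.72) at n = 9000 genes: the empirical
        # rejection rate must track the analytic normal-approximation power
        # (~75% for a two-sided alpha = 0.05 test at this effect size)
        n, reps, hits = 9000, 60, 0
        se = math.sqrt(2 / (n - 3))
        theory = stats.norm.sf(1.96 - (math.atanh(0.72) - math.atanh(0.70)) / se)
        rng = np.random.default_rng(42)
        for _ in range(reps):
            base = rng.normal(size=n)
            x1 = base + rng.normal(0, np.sqrt(1 / 0.70 - 1), n)
            y1 = base + rng.normal(0, np.sqrt(1 / 0.70 - 1), n)
            x2 = base + rng.normal(0, np.sqrt(1 / 0.72 - 1), n)
            y2 = base + rng.normal(0, np.sqrt(1 / 0.72 - 1), n)
            r1 = stats.spearmanr(x1, y1).statistic
            r2 = stats.spearmanr(x2, y2).statistic
            z, p = fisher_z_test(r1, r2, n, n)
            hits += (p < 0.05) and (r2 > r1)
        assert abs(hits / reps - theory) < 0.17
        assert hits / reps > 0.5


# ---------------------------------------------------------------------------
# MDS
# ---------------------------------------------------------------------------

def small_norm(seed=15, n_genes=300):
    cm, _ = simulate_counts(SimulationConfig(n_genes=n_genes, seed=seed))
    f = filter_low_expression(cm)
    return TMMNormalizer().fit(f).transform(f)


class TestMDS:
    def test_duplicated_library_distance_zero(self):
        norm = small_norm()
        lcpm = norm.log_cpm.copy()
        lcpm["F_control_2"] = lcpm["F_control_1"]
        norm2 = norm
        norm2.log_cpm = lcpm
        est = LeadingLogFCMDS(top=100).fit(norm2)
        assert est.distances_.loc["F_control_1", "F_control_2"] == pytest.approx(0.0)

    def test_distance_matrix_symmetric_zero_diagonal(self):
        est = LeadingLogFCMDS(top=100).fit(small_norm())
        d = est.distances_.to_numpy()
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0.0)

    def test_distances_match_bruteforce_per_pair(self):
        norm = small_norm(seed=3, n_genes=120)
        top = 50
        est = LeadingLogFCMDS(top=top).fit(norm)
        lcpm = norm.log_cpm.to_numpy()
        libs = list(norm.log_cpm.columns)
        for i in range(0, len(libs), 5):
            for j in range(i + 1, len(libs), 3):
                diffs = np.sort(np.abs(lcpm[:, i] - lcpm[:, j]))[::-1][:top]
                expected = np.sqrt(np.mean(diffs**2))
                assert est.distances_.iloc[i, j] == pytest.approx(expected, rel=1e-12)

    def test_gene_order_invariance(self):
        norm = small_norm(seed=5, n_genes=150)
        est1 = LeadingLogFCMDS(top=60).fit(norm)
        rng = np.random.default_rng(0)
        perm = rng.permutation(norm.log_cpm.index)
        norm.log_cpm = norm.log_cpm.loc[perm]
        est2 = LeadingLogFCMDS(top=60).fit(norm)
        assert np.allclose(est1.distances_.to_numpy(), est2.distances_.to_numpy())

    def test_top_clamped_with_warning(self):
        norm = small_norm(seed=6, n_genes=80)
        with pytest.warns(RuntimeWarning, match="clamp"):
            coords = leading_logfc_mds(norm, top=10_000)
        assert coords.shape[1] == 2


# ---------------------------------------------------------------------------
# bootstrap clustering
# ---------------------------------------------------------------------------

class TestBootstrapCluster:
    def test_supports_bounded_and_deterministic(self):
        norm = small_norm(seed=8)
        a = bootstrap_cluster(norm, n_boot=50, seed=1)
        b = bootstrap_cluster(norm, n_boot=50, seed=1)
        assert a.support == b.support
        assert all(0 <= v <= 100 for v in a.support.values())

    def test_invalid_n_boot(self):
        with pytest.raises(ValueError, match="n_boot"):
            bootstrap_cluster(small_norm(seed=8), n_boot=0)

    def test_null_data_has_weak_pair_support(self):
        # no sex/temperature structure: 2-library nodes are unstable
        cfg = SimulationConfig(
            n_genes=400, frac_female_biased=0, frac_male_biased=0,
            frac_cold_responsive=0, frac_interaction=0,
            feminization_delta_male=0, feminization_delta_female=0, seed=17,
        )
        cm, _ = simulate_counts(cfg)
        norm = TMMNormalizer().fit(filter_low_expression(cm)).transform(
            filter_low_expression(cm))
        res = bootstrap_cluster(norm, n_boot=100, seed=3)
        pair_supports = [v for s, v in res.support.items() if len(s) == 2]
        assert np.mean(pair_supports) < 70

    def test_newick_contains_all_libraries(self):
        norm = small_norm(seed=8)
        res = bootstrap_cluster(norm, n_boot=20, seed=1)
        nwk = res.to_newick()
        assert nwk.endswith(";")
        for lib in res.labels:
            assert lib in nwk
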