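"""Sex-bias classification, Wilcoxon shift tests and Hodges-Lehmann summaries."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from dimoshift import (
    classify_sex_bias,
    filter_conserved_bias,
    hodges_lehmann,
    normalized_shift_summary,
    pseudomedian,
    shift_test,
)
from dimoshift.sexbias import _signrank_cdf, walsh_averages


def de_table(lfc, fdr, genes=None):
    genes = genes or [f"g{i}" for i in range(len(lfc))]
    return pd.DataFrame({"log2_fc": lfc, "fdr": fdr}, index=pd.Index(genes, name="gene_id"))


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

class TestClassify:
    def test_male_biased_when_significant_and_large_in_both(self):
        ctrl = de_table([1.5], [0.01])
        cold = de_table([1.2], [0.01])
        out = classify_sex_bias(ctrl, cold)
        assert out["label"].iloc[0] == "male_biased"

    def test_failing_one_condition_is_unbiased(self):
        ctrl = de_table([1.5], [0.01])
        cold = de_table([1.5], [0.2])
        assert classify_sex_bias(ctrl, cold)["label"].iloc[0] == "unbiased"

    def test_female_symmetry(self):
        ctrl = de_table([-1.5], [0.001])
        cold = de_table([-2.0], [0.001])
        assert classify_sex_bias(ctrl, cold)["label"].iloc[0] == "female_biased"

    def test_opposite_signs_flagged_discordant_and_unbiased(self):
        ctrl = de_table([1.5], [0.001])
        cold = de_table([-1.5], [0.001])
        out = classify_sex_bias(ctrl, cold)
        assert out["label"].iloc[0] == "unbiased"
        assert bool(out["discordant"].iloc[0])

    def test_mismatched_gene_sets_error_lists_difference(self):
        ctrl = de_table([1.0], [0.5], genes=["a"])
        cold = de_table([1.0], [0.5], genes=["b"])
        with pytest.raises(ValueError, match="a"):
            classify_sex_bias(ctrl, cold)

    def test_randomized_table_matches_row_by_row_rule(self):
        rng = np.random.default_rng(4)
        lfc_a, lfc_b = rng.normal(0, 1.5, 50), rng.normal(0, 1.5, 50)
        fdr_a, fdr_b = rng.uniform(size=50), rng.uniform(size=50)
        out = classify_sex_bias(de_table(lfc_a, fdr_a), de_table(lfc_b, fdr_b))
        for i in range(50):
            sig = fdr_a[i] < 0.05 and fdr_b[i] < 0.05 \
                and abs(lfc_a[i]) >= 1 and abs(lfc_b[i]) >= 1
            if sig and lfc_a[i] >= 1 and lfc_b[i] >= 1:
                expected = "male_biased"
            elif sig and lfc_a[i] <= -1 and lfc_b[i] <= -1:
                expected = "female_biased"
            else:
                expected = "unbiased"
            assert out["label"].iloc[i] == expected, i


class TestConservedFilter:
    def labels(self):
        return pd.DataFrame(
            {"label": ["male_biased", "male_biased", "female_biased", "unbiased"]},
            index=pd.Index(["a", "b", "c", "d"], name="gene_id"),
        )

    def test_agreeing_retained_absent_dropped(self):
        ext = pd.Series({"a": "male_biased", "c": "male_biased"})
        out = filter_conserved_bias(self.labels(), ext)
        assert out.loc["a", "label"] == "male_biased"     # agrees
        assert out.loc["b", "label"] == "unbiased"        # absent
        assert out.loc["c", "label"] == "unbiased"        # direction conflict

    def test_equals_set_intersection(self):
        rng = np.random.default_rng(9)
        genes = [f"g{i}" for i in range(60)]
        mine = pd.DataFrame(
            {"label": rng.choice(["male_biased", "female_biased", "unbiased"], 60)},
            index=pd.Index(genes, name="gene_id"),
        )
        ext = pd.Series(
            rng.choice(["male_biased", "female_biased", "unbiased"], 40),
            index=rng.choice(genes, 40, replace=False),
        )
        out = filter_conserved_bias(mine, ext)
        for cls in ("male_biased", "female_biased"):
            expected = set(mine.index[mine["label"] == cls]) & set(ext.index[ext == cls])
            assert set(out.index[out["label"] == cls]) == expected

    def test_original_untouched(self):
        lab = self.labels()
        filter_conserved_bias(lab, pd.Series(dtype=object))
        assert lab.loc["a", "label"] == "male_biased"


# ---------------------------------------------------------------------------
# Wilcoxon shift test
# ---------------------------------------------------------------------------

def labels_for(values: dict) -> pd.DataFrame:
    ids, labs = [], []
    for lab, n in values.items():
        for i in range(n):
            ids.append(f"{lab}_{i}")
            labs.append(lab)
    return pd.DataFrame({"label": labs}, index=pd.Index(ids, name="gene_id"))


class TestShiftTest:
    def test_exact_small_sample_p(self):
        # {1,2} vs {3,4}: 1 of C(4,2)=6 rank splits is as extreme each side
        lab = labels_for({"male_biased": 2, "unbiased": 2, "female_biased": 1})
        lfc = pd.Series([1, 2, 3, 4, 0.5],
                        index=["male_biased_0", "male_biased_1",
                               "unbiased_0", "unbiased_1", "female_biased_0"])
        p = shift_test(lfc, lab)
        assert p["male_biased"] == pytest.approx(1 / 3)

    def test_identical_constants_give_p_one(self):
        lab = labels_for({"male_biased": 3, "unbiased": 3, "female_biased": 1})
        lfc = pd.Series(
            [1.0] * 7,
            index=[f"male_biased_{i}" for i in range(3)]
            + [f"unbiased_{i}" for i in range(3)] + ["female_biased_0"],
        )
        p = shift_test(lfc, lab)
        assert p["male_biased"] == pytest.approx(1.0)

    def test_empty_class_warns_and_returns_nan(self):
        lab = labels_for({"male_biased": 2, "unbiased": 2})
        lfc = pd.Series([1, 2, 3, 4],
                        index=["male_biased_0", "male_biased_1",
                               "unbiased_0", "unbiased_1"])
        with pytest.warns(RuntimeWarning, match="female_biased"):
            p = shift_test(lfc, lab)
        assert np.isnan(p["female_biased"])

    def test_type_one_error_rate(self):
        rng = np.random.default_rng(12)
        lab = labels_for({"male_biased": 30, "unbiased": 100, "female_biased": 1})
        hits = 0
        reps = 400
        for _ in range(reps):
            lfc = pd.Series(rng.normal(size=131), index=lab.index)
            hits += shift_test(lfc, lab)["male_biased"] < 0.05
        assert abs(hits / reps - 0.05) < 3 * np.sqrt(0.05 * 0.95 / reps) + 0.005


# ---------------------------------------------------------------------------
# pseudomedian / Hodges-Lehmann CI
# ---------------------------------------------------------------------------

class TestPseudomedian:
    def test_symmetric_sample_gives_zero(self):
        assert pseudomedian([-1, 0, 1]) == pytest.approx(0.0)

    def test_walsh_enumeration_example(self):
        # {1,2,3} -> Walsh averages {1, 1.5, 2, 2, 2.5, 3} -> median 2
        assert sorted(walsh_averages(np.array([1, 2, 3.0]))) == [1, 1.5, 2, 2, 2.5, 3]
        assert pseudomedian([1, 2, 3]) == pytest.approx(2.0)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(st.lists(st.floats(-50, 50), min_size=1, max_size=30), st.integers(0, 100))
    def test_matches_bruteforce_walsh_median(self, xs, _seed):
        xs = np.asarray(xs)
        brute = np.median(
            [(xs[i] + xs[j]) / 2 for i in range(len(xs)) for j in range(i, len(xs))]
        )
        assert pseudomedian(xs) == pytest.approx(brute, nan_ok=True)

    def test_signrank_distribution_matches_enumeration(self):
        for n in (3, 5, 8):
            cdf = _signrank_cdf(n)
            m = n * (n + 1) // 2
            counts = np.zeros(m + 1)
            for signs in itertools.product([0, 1], repeat=n):
                counts[sum((i + 1) * s for i, s in enumerate(signs))] += 1
            assert np.allclose(cdf, np.cumsum(counts) / 2**n)

    def test_ci_brackets_estimate(self):
        rng = np.random.default_rng(5)
        for n in (5, 20, 80):
            x = rng.normal(0.3, 1.0, n)
            est, lo, hi = hodges_lehmann(x)
            assert lo <= est <= hi

    def test_ci_coverage_near_nominal(self):
        # 95% CI covers the true shift in ~95% of replicates
        rng = np.random.default_rng(99)
        reps, n, delta = 500, 40, 0.5
        hits = sum(
            lo <= delta <= hi
            for lo, hi in (
                hodges_lehmann(rng.normal(delta, 1.0, n))[1:] for _ in range(reps)
            )
        )
        assert abs(hits / reps - 0.95) < 0.03


# ---------------------------------------------------------------------------
# normalized shift summary
# ---------------------------------------------------------------------------

class TestShiftSummary:
    def test_unbiased_median_normalization_centers_at_zero(self):
        rng = np.random.default_rng(2)
        lab = labels_for({"male_biased": 20, "unbiased": 101, "female_biased": 20})
        lfc = pd.Series(rng.normal(0.7, 1.0, len(lab)), index=lab.index)
        med = lfc[lab["label"] == "unbiased"].median()
        centered = lfc[lab["label"] == "unbiased"] - med
        assert np.median(centered) == pytest.approx(0.0, abs=1e-12)

    def test_summary_recovers_known_shift(self):
        rng = np.random.default_rng(8)
        lab = labels_for({"male_biased": 200, "unbiased": 1000, "female_biased": 200})
        vals = {}
        lfc = pd.Series(0.0, index=lab.index)
        lfc[lab["label"] == "unbiased"] = rng.normal(0.0, 0.3, 1000)
        lfc[lab["label"] == "male_biased"] = rng.normal(-0.5, 0.3, 200)
        lfc[lab["label"] == "female_biased"] = rng.normal(0.5, 0.3, 200)
        out = normalized_shift_summary({"M": lfc}, lab).set_index("bias_class")
        m = out.loc["male_biased"]
        assert m["ci_low"] <= -0.5 <= m["ci_high"]
        f = out.loc["female_biased"]
        assert f["ci_low"] <= 0.5 <= f["ci_high"]
        assert (out["wilcoxon_fdr"] < 0.05).all()

    def test_ci_bounds_order(self):
        rng = np.random.default_rng(3)
        lab = labels_for({"male_biased": 15, "unbiased": 50, "female_biased": 15})
        lfc = pd.Series(rng.normal(size=80), index=lab.index)
        out = normalized_shift_summary({"F": lfc, "M": lfc + 0.1}, lab)
        ok = out.dropna(subset=["ci_low"])
        assert (ok["ci_low"] <= ok["pseudomedian_normalized"]).all()
        assert (ok["pseudomedian_normalized"] <= ok["ci_high"]).all()

    def test_singleton_class_gets_nan_ci(self):
        lab = labels_for({"male_biased": 1, "unbiased": 10, "female_biased": 2})
        lfc = pd.Series(np.arange(13, dtype=float), index=lab.index)
        with pytest.warns(RuntimeWarning, match="male_biased"):
            out = normalized_shift_summary({"M": lfc}, lab).set_index("bias_class")
        assert np.isnan(out.loc["male_biased", "ci_low"])
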