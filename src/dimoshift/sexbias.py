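"""Sex-bias classification and the cold-induced shift in dimorphic expression.

A gene is called sex-biased only when the male-vs-female contrast is
significant (FDR < 0.05) with |log2FC| >= 1 in *both* temperature
conditions, with a consistent direction (positive log2FC = higher in males,
so male-biased).  The headline quantity is then how sex-biased genes move
under cold: each bias class's cold log2FC distribution is (a) compared to
unbiased genes by a two-sample Wilcoxon rank-sum test and (b) summarized,
after subtracting the unbiased genes' median cold change, by the
Hodges-Lehmann pseudomedian with a distribution-free signed-rank 95% CI.
A feminized male transcriptome appears as a negative pseudomedian for
male-biased genes and a positive one for female-biased genes in males.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .de import bh_adjust

__all__ = [
    "classify_sex_bias",
    "filter_conserved_bias",
    "shift_test",
    "normalized_shift_summary",
    "pseudomedian",
    "hodges_lehmann",
]

BIAS_CLASSES = ("female_biased", "male_biased")


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def classify_sex_bias(
    de_sex_control: pd.DataFrame,
    de_sex_cold: pd.DataFrame,
    fdr_cut: float = 0.05,
    lfc_cut: float = 1.0,
) -> pd.DataFrame:
    """Three-way sex-bias labels from the two condition-specific sex contrasts.

    Returns a frame indexed by gene id with columns ``label``,
    ``log2_fc_sex_control``, ``log2_fc_sex_cold``, ``fdr_sex_control``,
    ``fdr_sex_cold`` and ``discordant`` (significant and large in both
    conditions but with opposite signs — labelled unbiased, reported as a
    diagnostic).
    """
    a, b = de_sex_control, de_sex_cold
    if not a.index.equals(b.index):
        diff = a.index.symmetric_difference(b.index).tolist()
        raise ValueError(f"DE tables cover different gene sets; differing ids: {diff[:10]}")

    lfc_a = a["log2_fc"].to_numpy()
    lfc_b = b["log2_fc"].to_numpy()
    with np.errstate(invalid="ignore"):
        sig_a = (a["fdr"].to_numpy() < fdr_cut) & (np.abs(lfc_a) >= lfc_cut)
        sig_b = (b["fdr"].to_numpy() < fdr_cut) & (np.abs(lfc_b) >= lfc_cut)
    both = sig_a & sig_b
    male = both & (lfc_a >= lfc_cut) & (lfc_b >= lfc_cut)
    female = both & (lfc_a <= -lfc_cut) & (lfc_b <= -lfc_cut)
    discordant = both & ~male & ~female

    label = np.full(len(a), "unbiased", dtype=object)
    label[male] = "male_biased"
    label[female] = "female_biased"
    return pd.DataFrame(
        {
            "label": label,
            "log2_fc_sex_control": lfc_a,
            "log2_fc_sex_cold": lfc_b,
            "fdr_sex_control": a["fdr"].to_numpy(),
            "fdr_sex_cold": b["fdr"].to_numpy(),
            "discordant": discordant,
        },
        index=a.index,
    )


def filter_conserved_bias(
    labels: pd.DataFrame, external_labels: pd.Series | pd.DataFrame
) -> pd.DataFrame:
    """Conservative label set: keep a bias call only if an external species'
    label agrees in direction; disagreeing or absent genes become unbiased.

    ``external_labels`` maps gene id -> {female_biased, male_biased,
    unbiased}; genes missing from it count as absent.  The input frame is
    not modified.
    """
    if isinstance(external_labels, pd.DataFrame):
        external_labels = external_labels.iloc[:, 0]
    out = labels.copy()
    ext = external_labels.reindex(labels.index)
    keep = (out["label"].isin(BIAS_CLASSES)) & (ext == out["label"])
    out.loc[~keep, "label"] = "unbiased"
    return out


# ---------------------------------------------------------------------------
# Hodges-Lehmann pseudomedian and signed-rank confidence interval
# ---------------------------------------------------------------------------

def walsh_averages(x: np.ndarray) -> np.ndarray:
    """All pairwise averages (x_i + x_j)/2 for i <= j (self-pairs included)."""
    x = np.asarray(x, float)
    n = x.size
    iu = np.triu_indices(n)
    return (x[iu[0]] + x[iu[1]]) / 2.0


def pseudomedian(x: np.ndarray) -> float:
    """Hodges-Lehmann one-sample estimator: median of all Walsh averages."""
    x = np.asarray(x, float)
    if x.size == 0:
        raise ValueError("empty sample")
    return float(np.median(walsh_averages(x)))


def _signrank_cdf(n: int) -> np.ndarray:
    """Null CDF of the Wilcoxon signed-rank statistic W+ for sample size n.

    Counts sign assignments by the generating polynomial prod(1 + z^i);
    exact in float64 for n <= 50.
    """
    m = n * (n + 1) // 2
    counts = np.zeros(m + 1)
    counts[0] = 1.0
    for i in range(1, n + 1):
        counts[i:] += counts[:-i].copy()
    return np.cumsum(counts) / counts.sum()


def _qsignrank(p: float, n: int) -> int:
    """Smallest q with P(W+ <= q) >= p under the null."""
    cdf = _signrank_cdf(n)
    return int(np.searchsorted(cdf, p - 1e-12))


def hodges_lehmann(
    x: np.ndarray,
    conf_level: float = 0.95,
    exact_max_n: int = 50,
) -> tuple[float, float, float]:
    """Pseudomedian with a distribution-free signed-rank CI.

    The CI takes order statistics of the sorted Walsh averages at depth k,
    where k comes from the exact signed-rank null distribution for
    n <= ``exact_max_n`` and from its normal approximation otherwise.
    Returns (pseudomedian, ci_low, ci_high); the CI is NaN for n < 2.
    """
    x = np.asarray(x, float)
    n = x.size
    if n == 0:
        raise ValueError("empty sample")
    w = np.sort(walsh_averages(x))
    est = float(np.median(w))
    if n < 2:
        return est, float("nan"), float("nan")
    alpha = 1.0 - conf_level
    m = w.size
    if n <= exact_max_n:
        k = _qsignrank(alpha / 2.0, n)
    else:
        mean = n * (n + 1) / 4.0
        sd = np.sqrt(n * (n + 1) * (2 * n + 1) / 24.0)
        k = int(np.floor(mean + stats.norm.ppf(alpha / 2.0) * sd))
    k = max(k, 1)
    if k > m - k + 1:
        return est, float(w[0]), float(w[-1])
    return est, float(w[k - 1]), float(w[m - k])


# ---------------------------------------------------------------------------
# shift tests and summaries
# ---------------------------------------------------------------------------

def shift_test(
    cold_lfc_by_sex: pd.Series,
    labels: pd.DataFrame,
    exact_max_n: int = 50,
) -> dict[str, float]:
    """Two-sided Wilcoxon rank-sum p per bias class vs unbiased genes.

    Exact enumeration when both groups have <= ``exact_max_n`` values and no
    ties; normal approximation with tie correction otherwise.  Empty classes
    yield NaN with a warning.
    """
    lab = labels["label"].reindex(cold_lfc_by_sex.index)
    unbiased = cold_lfc_by_sex[lab == "unbiased"].dropna().to_numpy()
    out: dict[str, float] = {}
    for cls in BIAS_CLASSES:
        vals = cold_lfc_by_sex[lab == cls].dropna().to_numpy()
        if vals.size == 0 or unbiased.size == 0:
            warnings.warn(f"empty class {cls!r}; Wilcoxon p set to NaN", RuntimeWarning)
            out[cls] = float("nan")
            continue
        has_ties = np.unique(np.concatenate([vals, unbiased])).size < vals.size + unbiased.size
        method = (
            "exact"
            if (vals.size <= exact_max_n and unbiased.size <= exact_max_n and not has_ties)
            else "asymptotic"
        )
        out[cls] = float(
            stats.mannwhitneyu(vals, unbiased, alternative="two-sided", method=method).pvalue
        )
    return out


@dataclass
class ShiftSummary:
    """One row of the normalized-shift table (one sex x bias class)."""

    sex: str
    bias_class: str
    n_genes: int
    wilcoxon_p: float
    wilcoxon_fdr: float
    pseudomedian_normalized: float
    ci_low: float
    ci_high: float


def normalized_shift_summary(
    cold_lfc: dict[str, pd.Series],
    labels: pd.DataFrame,
    conf_level: float = 0.95,
    exact_max_n: int = 50,
) -> pd.DataFrame:
    """Normalized cold shifts of sex-biased genes, per sex and bias class.

    ``cold_lfc`` maps sex ("F"/"M") to the per-gene cold log2FC observed in
    that sex.  Within each sex the unbiased genes' median cold change is
    subtracted from every biased gene's change (so "no shift beyond the
    global cold response" is 0 by construction), then each class is
    summarized by the Hodges-Lehmann pseudomedian and its signed-rank CI.
    Wilcoxon p-values (class vs unbiased, un-normalized scale — the median
    offset cancels in a rank test) are BH-corrected across the four
    sex x class tests.
    """
    rows = []
    for sex, lfc in cold_lfc.items():
        lab = labels["label"].reindex(lfc.index)
        unb = lfc[lab == "unbiased"].dropna()
        if unb.empty:
            raise ValueError(f"no unbiased genes for sex {sex!r}; cannot normalize")
        med = float(unb.median())
        pvals = shift_test(lfc, labels, exact_max_n=exact_max_n)
        for cls in BIAS_CLASSES:
            vals = lfc[lab == cls].dropna().to_numpy() - med
            if vals.size == 0:
                rows.append((sex, cls, 0, pvals[cls], np.nan, np.nan, np.nan, np.nan))
                continue
            if vals.size < 2:
                warnings.warn(
                    f"class {cls!r} in sex {sex!r} has < 2 genes; CI unavailable",
                    RuntimeWarning,
                )
                est, lo, hi = pseudomedian(vals), float("nan"), float("nan")
            else:
                est, lo, hi = hodges_lehmann(vals, conf_level, exact_max_n)
            rows.append((sex, cls, vals.size, pvals[cls], np.nan, est, lo, hi))

    out = pd.DataFrame(
        rows,
        columns=[
            "sex", "bias_class", "n_genes", "wilcoxon_p", "wilcoxon_fdr",
            "pseudomedian_normalized", "ci_low", "ci_high",
        ],
    )
    out["wilcoxon_fdr"] = bh_adjust(out["wilcoxon_p"].to_numpy())
    return out
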