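"""Differential expression: NB GLM with quasi-likelihood F-tests.

The model is a group-means parameterization of the 2 x 2 design
(F.control, F.cold, M.control, M.cold) with a log effective-library-size
offset.  Five named contrasts cover the model terms:

========================  =============================================
``cold_in_females``       cold minus control, females
``cold_in_males``         cold minus control, males
``sex_in_control``        male minus female at control temperature
``sex_in_cold``           male minus female in cold
``interaction``           (cold effect in males) minus (in females)
========================  =============================================

Significance uses a quasi-F statistic: the contrast's deviance drop divided
by a moderated gene-wise quasi-dispersion (residual deviance / residual df,
squeezed toward its expression-level trend with a prior df), referred to an
F distribution whose denominator df is augmented by the prior df.  This
accounts for uncertainty in the per-gene dispersion at small replication.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import null_space
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from . import glm
from .containers import CountMatrix, NormalizedExpression, GROUPS
from .normalization import TMMNormalizer

__all__ = [
    "CONTRASTS",
    "QLDifferentialExpression",
    "fit_nb_glm",
    "ql_f_test",
    "bh_adjust",
]

_LN2 = np.log(2.0)

#: contrast vectors on the group-mean coefficients, GROUPS order
#: (F.control, F.cold, M.control, M.cold)
CONTRASTS: dict[str, np.ndarray] = {
    "cold_in_females": np.array([-1.0, 1.0, 0.0, 0.0]),
    "cold_in_males": np.array([0.0, 0.0, -1.0, 1.0]),
    "sex_in_control": np.array([-1.0, 0.0, 1.0, 0.0]),
    "sex_in_cold": np.array([0.0, -1.0, 0.0, 1.0]),
    "interaction": np.array([1.0, -1.0, -1.0, 1.0]),
}


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    NaN entries (untested genes) are excluded from the number of tests and
    returned as NaN; everything else is order-preserving and capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    ok = ~np.isnan(p)
    if ((p[ok] < 0) | (p[ok] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    out = np.full(p.shape, np.nan)
    if ok.sum():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def _design_matrix(design: pd.DataFrame) -> np.ndarray:
    X = np.zeros((len(design), 4))
    for g, (sex, temp) in enumerate(GROUPS):
        X[((design["sex"] == sex) & (design["temperature"] == temp)).to_numpy(), g] = 1.0
    return X


class QLDifferentialExpression(BaseEstimator):
    """NB quasi-likelihood differential expression over the 2 x 2 design.

    Parameters
    ----------
    dispersion_prior_df : float
        Pseudo-information (df) pulled from the common APL curve when
        shrinking tagwise NB dispersions.
    ql_prior_df : float
        Prior df of the quasi-dispersion moderation; also added to the
        F denominator df.
    trend_bins : int
        Number of average-log-CPM bins used for the quasi-dispersion trend.
    prior_count : float
        Display prior for log-CPM (visualization only; test statistics use
        the raw GLM).

    Attributes
    ----------
    dispersion_ : ndarray of tagwise NB dispersions
    dispersion_common_ : float
    quasi_dispersion_ : ndarray of moderated quasi-dispersions
    converged_ : boolean ndarray (full-model IRLS convergence)
    results_ : dict of contrast name -> DataFrame (gene_id index; columns
        log2_fc, avg_log_cpm, quasi_f, df1, df2, p_value, fdr)
    """

    def __init__(
        self,
        dispersion_prior_df: float = 10.0,
        ql_prior_df: float = 10.0,
        dispersion_grid_size: int = 41,
        trend_bins: int = 20,
        prior_count: float = 2.0,
    ):
        self.dispersion_prior_df = dispersion_prior_df
        self.ql_prior_df = ql_prior_df
        self.dispersion_grid_size = dispersion_grid_size
        self.trend_bins = trend_bins
        self.prior_count = prior_count

    # ------------------------------------------------------------------
    def fit(self, X: CountMatrix, y=None, norm: NormalizedExpression | None = None):
        counts = X
        yv = counts.counts.to_numpy().astype(float)
        if (yv.sum(axis=1) == 0).any():
            bad = counts.gene_ids[yv.sum(axis=1) == 0].tolist()
            raise ValueError(
                f"all-zero genes reached the GLM (filter first): {bad[:5]}"
            )
        design = _design_matrix(counts.design)
        if len(counts.design) - design.shape[1] <= 0:
            raise ValueError(
                "saturated design: no residual degrees of freedom "
                "(need more than one replicate per group)"
            )
        if norm is None:
            norm = TMMNormalizer(prior_count=self.prior_count).fit(counts).transform(counts)
        offset = np.log(norm.effective_lib_sizes.reindex(counts.library_ids).to_numpy())

        df_res = len(counts.design) - design.shape[1]
        grid = glm.default_dispersion_grid(size=self.dispersion_grid_size)
        prior_weight = self.dispersion_prior_df / df_res
        tagwise, common = glm.estimate_dispersion(
            yv, design, offset, grid=grid, prior_weight=prior_weight
        )
        full = glm.fit_glm(yv, design, offset, tagwise)

        self.gene_ids_ = counts.gene_ids
        self.design_matrix_ = design
        self.offset_ = offset
        self.counts_ = yv
        self.dispersion_ = tagwise
        self.dispersion_common_ = common
        self.full_fit_ = full
        self.converged_ = full.converged
        self.avg_log_cpm_ = norm.log_cpm.mean(axis=1).to_numpy()
        self.df_residual_ = df_res

        s2 = full.deviance / df_res
        trend = self._trend(self.avg_log_cpm_, s2)
        d0 = self.ql_prior_df
        self.quasi_dispersion_trend_ = trend
        self.quasi_dispersion_ = (d0 * trend + df_res * s2) / (d0 + df_res)

        self.results_ = {name: self._test(name) for name in CONTRASTS}
        return self

    # ------------------------------------------------------------------
    def _trend(self, a: np.ndarray, s2: np.ndarray) -> np.ndarray:
        """Running-mean trend of quasi-dispersions against avg log CPM."""
        G = a.size
        nbins = min(self.trend_bins, max(1, G // 50))
        if nbins <= 1:
            return np.full(G, s2.mean())
        order = np.argsort(a)
        edges = np.array_split(order, nbins)
        centers = np.array([a[e].mean() for e in edges])
        means = np.array([s2[e].mean() for e in edges])
        return np.interp(a, centers, means)

    def _test(self, contrast: str) -> pd.DataFrame:
        if contrast not in CONTRASTS:
            raise ValueError(
                f"unknown contrast {contrast!r}; valid: {sorted(CONTRASTS)}"
            )
        c = CONTRASTS[contrast]
        reduced_basis = null_space(c[None, :])
        x_reduced = self.design_matrix_ @ reduced_basis
        red = glm.fit_glm(self.counts_, x_reduced, self.offset_, self.dispersion_)
        dev_drop = np.maximum(red.deviance - self.full_fit_.deviance, 0.0)

        df1 = 1.0
        df2 = self.df_residual_ + self.ql_prior_df
        f_stat = (dev_drop / df1) / self.quasi_dispersion_
        p = stats.f.sf(f_stat, df1, df2)
        p = np.where(dev_drop <= 0, 1.0, p)

        ok = self.converged_ & red.converged
        if not ok.all():
            warnings.warn(
                f"{(~ok).sum()} gene(s) did not converge for contrast "
                f"{contrast!r}; statistics set to NaN",
                RuntimeWarning,
            )
        f_stat = np.where(ok, f_stat, np.nan)
        p = np.where(ok, p, np.nan)

        log2_fc = (self.full_fit_.beta @ c) / _LN2
        return pd.DataFrame(
            {
                "log2_fc": log2_fc,
                "avg_log_cpm": self.avg_log_cpm_,
                "quasi_f": f_stat,
                "df1": df1,
                "df2": df2,
                "p_value": p,
                "fdr": bh_adjust(p),
            },
            index=self.gene_ids_,
        )


# ---------------------------------------------------------------------------
# thin functional wrappers
# ---------------------------------------------------------------------------

def fit_nb_glm(
    norm: NormalizedExpression,
    counts: CountMatrix,
    **params,
) -> QLDifferentialExpression:
    """Fit the per-gene NB GLM (all five contrasts); returns the estimator."""
    return QLDifferentialExpression(**params).fit(counts, norm=norm)


def ql_f_test(fits: QLDifferentialExpression, contrast: str) -> pd.DataFrame:
    """Quasi-F DE table for one named contrast of a fitted model."""
    if contrast not in CONTRASTS:
        raise ValueError(f"unknown contrast {contrast!r}; valid: {sorted(CONTRASTS)}")
    return fits.results_[contrast]
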