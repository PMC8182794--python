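"""Expression filtering and TMM normalization.

TMM (trimmed mean of M-values) estimates a relative scaling factor per
library from a doubly trimmed, precision-weighted mean of per-gene log2
expression ratios against a reference library, so that composition changes
(a few very highly expressed genes) do not masquerade as depth changes.
Factors are rescaled to geometric mean 1 and multiply the raw library sizes
to give effective sizes used for CPM.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, TransformerMixin

from .containers import CountMatrix, NormalizedExpression, GROUPS

__all__ = ["filter_low_expression", "tmm_factors", "log_cpm", "TMMNormalizer"]


def filter_low_expression(
    counts: CountMatrix,
    cpm_threshold: float = 0.5,
    min_failing_libs: int = 2,
    grouping: str = "sex_temperature",
) -> CountMatrix:
    """Remove genes expressed below ``cpm_threshold`` CPM in any condition.

    A gene is dropped iff at least one condition group contains
    ``min_failing_libs`` or more libraries with CPM below the threshold.
    CPM here uses raw library sums — filtering precedes normalization.

    ``grouping`` selects what a "condition" is: ``"sex_temperature"`` (the
    four factorial groups; default), ``"temperature"`` (pooling sexes), or
    ``"all"`` (any libraries, ignoring groups).
    """
    lib_sizes = counts.library_sizes.to_numpy().astype(float)
    cpm = counts.counts.to_numpy() / lib_sizes * 1e6
    low = cpm < cpm_threshold

    design = counts.design
    if grouping == "sex_temperature":
        groups = [counts.group_columns(s, t) for s, t in GROUPS]
    elif grouping == "temperature":
        groups = [design.index[design["temperature"] == t] for t in ("control", "cold")]
    elif grouping == "all":
        groups = [design.index]
    else:
        raise ValueError(f"unknown grouping {grouping!r}")

    col_pos = {c: i for i, c in enumerate(counts.library_ids)}
    drop = np.zeros(counts.n_genes, dtype=bool)
    for g in groups:
        idx = [col_pos[c] for c in g]
        drop |= low[:, idx].sum(axis=1) >= min_failing_libs
    if drop.all():
        raise ValueError(
            "expression filter removed every gene "
            f"(cpm_threshold={cpm_threshold}, min_failing_libs={min_failing_libs})"
        )
    return CountMatrix(counts.counts.loc[~drop], counts.design.copy())


def _quantile_rate(counts: np.ndarray, lib_sizes: np.ndarray, p: float = 0.75) -> np.ndarray:
    """Per-library p-quantile of count rates (count / library size)."""
    return np.quantile(counts / lib_sizes, p, axis=0)


def _as_frame(counts) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Accept a CountMatrix or a bare genes x libraries DataFrame."""
    if isinstance(counts, CountMatrix):
        return counts.counts, counts.design
    if isinstance(counts, pd.DataFrame):
        return counts, None
    raise TypeError(f"expected CountMatrix or DataFrame, got {type(counts).__name__}")


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    n_obs: float,
    n_ref: float,
    logratio_trim: float,
    abs_trim: float,
    a_cutoff: float,
) -> float:
    """log2 TMM factor of one library against the reference."""
    keep = (obs > 0) & (ref > 0)
    if not keep.any():
        raise ValueError("library shares no expressed genes with the reference")
    obs, ref = obs[keep].astype(float), ref[keep].astype(float)
    p_obs, p_ref = obs / n_obs, ref / n_ref
    m = np.log2(p_obs / p_ref)
    a = 0.5 * np.log2(p_obs * p_ref)
    v = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)

    ok = a > a_cutoff
    m, a, v = m[ok], a[ok], v[ok]
    if m.size == 0:
        raise ValueError("no usable genes above the A-value cutoff")
    if np.max(np.abs(m)) < 1e-6:
        return 0.0

    n = m.size
    lo_m = np.floor(n * logratio_trim) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * abs_trim) + 1
    hi_a = n + 1 - lo_a
    rm = rankdata(m)
    ra = rankdata(a)
    keep2 = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    if not keep2.any():
        return 0.0
    return float(np.sum(m[keep2] / v[keep2]) / np.sum(1.0 / v[keep2]))


def tmm_factors(
    counts: CountMatrix,
    logratio_trim: float = 0.3,
    abs_trim: float = 0.05,
    a_cutoff: float = -1e10,
    reference: str | None = None,
) -> pd.Series:
    """TMM normalization factors, geometric mean 1.

    The reference library is the one whose upper-quartile count rate is
    closest to the mean upper-quartile, unless ``reference`` names one.
    Accepts a CountMatrix or a bare genes x libraries DataFrame.
    """
    frame, _ = _as_frame(counts)
    library_ids = frame.columns
    x = frame.to_numpy().astype(float)
    lib_sizes = x.sum(axis=0)
    if (lib_sizes <= 0).any():
        bad = library_ids[lib_sizes <= 0].tolist()
        raise ValueError(f"libraries with zero total count: {bad}")

    if reference is None:
        f75 = _quantile_rate(x, lib_sizes)
        ref_idx = int(np.argmin(np.abs(f75 - f75.mean())))
    else:
        if reference not in library_ids:
            raise ValueError(f"reference library {reference!r} not in matrix")
        ref_idx = library_ids.get_loc(reference)

    log_factors = np.zeros(len(library_ids))
    for j in range(len(library_ids)):
        if j == ref_idx:
            continue
        try:
            log_factors[j] = _tmm_pair(
                x[:, j], x[:, ref_idx], lib_sizes[j], lib_sizes[ref_idx],
                logratio_trim, abs_trim, a_cutoff,
            )
        except ValueError as exc:
            raise ValueError(f"library {library_ids[j]!r}: {exc}") from None
    factors = 2.0 ** log_factors
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=library_ids, name="tmm_factor")


def log_cpm(
    counts: CountMatrix,
    factors: pd.Series,
    prior_count: float = 2.0,
) -> NormalizedExpression:
    """CPM and log2 CPM against TMM-effective library sizes.

    The prior count is scaled per library in proportion to its effective
    size (so a fixed prior means the same thing at every depth):
    log_cpm = log2((count + prior_j) / (N_j + 2 * prior_j) * 1e6) with
    prior_j = prior_count * N_j / mean(N).  Zero counts map to finite values.
    """
    if prior_count < 0:
        raise ValueError("prior_count must be non-negative")
    raw, design = _as_frame(counts)
    factors = factors.reindex(raw.columns)
    if factors.isna().any() or (factors <= 0).any():
        raise ValueError("factors must be positive and cover every library")
    eff = raw.sum(axis=0).astype(float) * factors
    if (eff <= 0).any():
        raise ValueError("non-positive effective library size")

    x = raw.to_numpy().astype(float)
    n_eff = eff.to_numpy()
    cpm = x / n_eff * 1e6
    prior_j = prior_count * n_eff / n_eff.mean()
    with np.errstate(divide="raise"):
        lcpm = np.log2((x + prior_j) / (n_eff + 2 * prior_j) * 1e6)
    frame = lambda arr: pd.DataFrame(arr, index=raw.index, columns=raw.columns)
    return NormalizedExpression(
        tmm_factors=factors,
        effective_lib_sizes=eff.rename("effective_lib_size"),
        cpm=frame(cpm),
        log_cpm=frame(lcpm),
        prior_count=prior_count,
        design=None if design is None else design.copy(),
    )


class TMMNormalizer(BaseEstimator, TransformerMixin):
    """Estimator wrapper: fit learns TMM factors, transform yields log2 CPM.

    Parameters
    ----------
    logratio_trim, abs_trim : float
        Two-sided trim fractions on M-values and A-values.
    prior_count : float
        Prior added (library-size-scaled) before the log for display values.

    Attributes
    ----------
    factors_ : Series
        Per-library TMM factors (geometric mean 1).
    effective_lib_sizes_ : Series
        Raw library sums times factors.
    """

    def __init__(
        self,
        logratio_trim: float = 0.3,
        abs_trim: float = 0.05,
        a_cutoff: float = -1e10,
        prior_count: float = 2.0,
    ):
        self.logratio_trim = logratio_trim
        self.abs_trim = abs_trim
        self.a_cutoff = a_cutoff
        self.prior_count = prior_count

    def fit(self, X: CountMatrix, y=None) -> "TMMNormalizer":
        self.factors_ = tmm_factors(
            X, self.logratio_trim, self.abs_trim, self.a_cutoff
        )
        self.effective_lib_sizes_ = X.library_sizes.astype(float) * self.factors_
        return self

    def transform(self, X: CountMatrix) -> NormalizedExpression:
        if not hasattr(self, "factors_"):
            raise RuntimeError("TMMNormalizer is not fitted")
        return log_cpm(X, self.factors_, self.prior_count)
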