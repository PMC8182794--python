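"""Chill-coma onset (CTmin) phenotype model.

CTmin values sit a few degrees below zero, so an offset of 5 degC is added
before log-transforming; the model on the transformed scale is a linear
mixed model with sex, treatment, their interaction and body weight as fixed
effects and assay batch as a random intercept, fitted by REML.  Each fixed
term is tested by a 1-df Wald chi-square, (estimate / SE)^2.

The assay this models reports one Wald chi-square per term (sex, cold
treatment, weight, sex x cold treatment); the output table mirrors that
shape.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats
from sklearn.base import BaseEstimator

__all__ = ["transform_ctmin", "CTminMixedModel", "fit_ctmin_model"]

TERMS = ("sex", "treatment", "weight", "sex:treatment")


def transform_ctmin(ctmin, offset: float = 5.0, base: str = "e"):
    """log(CTmin + offset); errors on records at or below -offset."""
    arr = np.asarray(ctmin, dtype=float)
    bad = arr + offset <= 0
    if np.any(bad):
        where = np.flatnonzero(np.atleast_1d(bad))
        raise ValueError(
            f"CTmin <= -{offset} at record index(es) {where[:5].tolist()}; "
            "log transform undefined"
        )
    out = np.log(arr + offset)
    if base == "10":
        out = out / math.log(10.0)
    elif base != "e":
        raise ValueError("base must be 'e' or '10'")
    return out if np.ndim(ctmin) else float(out)


@dataclass
class CTminFit:
    fixed_effects: pd.DataFrame  # estimate, se per term (+ intercept)
    wald_table: pd.DataFrame     # term, wald_chisq, p
    batch_variance: float
    residual_variance: float
    n_obs: int
    converged: bool
    method: str                  # "mixed-reml", "mixed-ml" or "ols-fallback"


class CTminMixedModel(BaseEstimator):
    """Mixed model of log(CTmin + offset) with a batch random intercept.

    Parameters
    ----------
    offset : float
        Added to CTmin before the log (default 5 degC).
    log_base : {"e", "10"}
        Base of the transform.
    reml : bool
        REML (default) or ML fitting.

    Attributes
    ----------
    wald_table_ : DataFrame with one row per fixed term (sex, treatment,
        weight, sex:treatment): ``wald_chisq`` and ``p_value`` (1-df).
    batch_variance_ : float (0 allowed at the boundary)
    converged_ : bool
    """

    def __init__(self, offset: float = 5.0, log_base: str = "e", reml: bool = True):
        self.offset = offset
        self.log_base = log_base
        self.reml = reml

    def fit(self, X: pd.DataFrame, y=None) -> "CTminMixedModel":
        records = X
        required = {"sex", "treatment", "weight_mg", "batch", "ctmin_c"}
        missing = required - set(records.columns)
        if missing:
            raise ValueError(f"CTmin table lacks columns: {sorted(missing)}")
        df = records.copy()
        if (df["weight_mg"] <= 0).any():
            raise ValueError("weights must be positive")
        for col in ("sex", "treatment"):
            if df[col].nunique() != 2:
                raise ValueError(f"need exactly two levels of {col!r}")
        df["log_ctmin"] = transform_ctmin(
            df["ctmin_c"].to_numpy(), self.offset, self.log_base
        )
        # stable level coding: F/19C are the reference levels
        df["sex"] = pd.Categorical(df["sex"], categories=sorted(df["sex"].unique()))
        treat_levels = sorted(df["treatment"].unique(), key=lambda t: ("6" in str(t)))
        df["treatment"] = pd.Categorical(df["treatment"], categories=treat_levels)

        formula = "log_ctmin ~ sex * treatment + weight_mg"
        n_batches = df["batch"].nunique()
        if n_batches < 2:
            warnings.warn(
                "single batch: falling back to a fixed-effects-only model "
                "(no random intercept can be estimated)",
                RuntimeWarning,
            )
            res = smf.ols(formula, data=df).fit()
            params, bse = res.params, res.bse
            self.batch_variance_ = 0.0
            self.residual_variance_ = float(res.mse_resid)
            self.converged_ = True
            self.method_ = "ols-fallback"
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = smf.mixedlm(formula, data=df, groups=df["batch"])
                res = None
                # gradient methods can hit singular information at the
                # zero-variance boundary; fall back to derivative-free ones
                for method in ("lbfgs", "powell", "nm"):
                    try:
                        res = model.fit(reml=self.reml, method=method)
                        break
                    except (np.linalg.LinAlgError, ValueError):
                        continue
                if res is None:
                    raise RuntimeError("mixed-model fit failed with every optimizer")
            params, bse = res.params, res.bse
            self.batch_variance_ = float(np.asarray(res.cov_re)[0, 0])
            self.residual_variance_ = float(res.scale)
            self.converged_ = bool(res.converged)
            self.method_ = "mixed-reml" if self.reml else "mixed-ml"

        name_map = self._term_names(params.index)
        rows = []
        fixed = []
        for label, pname in name_map.items():
            est, se = float(params[pname]), float(bse[pname])
            chisq = (est / se) ** 2
            rows.append((label, chisq, float(stats.chi2.sf(chisq, 1))))
            fixed.append((label, est, se))
        self.wald_table_ = pd.DataFrame(
            rows, columns=["term", "wald_chisq", "p_value"]
        ).set_index("term")
        self.fixed_effects_ = pd.DataFrame(
            fixed, columns=["term", "estimate", "se"]
        ).set_index("term")
        self.n_obs_ = len(df)
        self.result_ = res
        return self

    @staticmethod
    def _term_names(index: pd.Index) -> dict[str, str]:
        """Map canonical term labels to patsy coefficient names."""
        out: dict[str, str] = {}
        for name in index:
            if name in ("Intercept", "Group Var") or "Var" in name:
                continue
            if name == "weight_mg":
                out["weight"] = name
            elif ":" in name:
                out["sex:treatment"] = name
            elif name.startswith("sex"):
                out["sex"] = name
            elif name.startswith("treatment"):
                out["treatment"] = name
        missing = set(TERMS) - set(out)
        if missing:
            raise ValueError(f"model is rank deficient; missing terms {sorted(missing)}")
        return out

    def summary(self) -> CTminFit:
        return CTminFit(
            fixed_effects=self.fixed_effects_,
            wald_table=self.wald_table_,
            batch_variance=self.batch_variance_,
            residual_variance=self.residual_variance_,
            n_obs=self.n_obs_,
            converged=self.converged_,
            method=self.method_,
        )


def fit_ctmin_model(
    records: pd.DataFrame, offset: float = 5.0, log_base: str = "e", reml: bool = True
) -> CTminFit:
    """Fit the CTmin mixed model and return the Wald table bundle."""
    return CTminMixedModel(offset, log_base, reml).fit(records).summary()
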