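"""Synthetic data generators with known ground truth.

Two generators mirror the study design being modelled:

* :func:`simulate_counts` draws a gene x library RNA-seq count matrix for a
  2 sexes x 2 temperatures x n replicates factorial (the deposited design is
  12 libraries = 2 x 2 x 3, ~9,338 expressed genes), with negative-binomial
  counts whose group means encode sex-biased expression, a shared cold
  response, sex-by-temperature interactions, and a "feminization" shift —
  an additional cold-only log2 change applied to sex-biased genes in a named
  sex (negative on male-biased genes in males pushes the male transcriptome
  toward the female profile).
* :func:`simulate_ctmin` draws per-fly chill-coma onset temperatures (CTmin)
  from a linear model with sex, treatment, their interaction, body weight and
  a batch random effect.

Every applied effect is recorded per gene/fly so downstream estimates can be
checked against truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd

from .containers import CountMatrix, GROUPS

__all__ = [
    "SimulationConfig",
    "CTminSimConfig",
    "simulate_counts",
    "simulate_ctmin",
    "random_annotation",
]


def _require(condition: bool, name: str, message: str) -> None:
    if not condition:
        raise ValueError(f"invalid {name}: {message}")


def _finite(value: float, name: str) -> None:
    _require(math.isfinite(float(value)), name, "must be finite")


@dataclass
class SimulationConfig:
    """Parameters of the count simulator.

    Defaults encode the modelled study's conditions: 9,338 expressed genes in
    12 libraries (3 replicates per sex x temperature group), sex-bias
    fractions near the reported 1682 female- / 2023 male-biased of 9338,
    a cold response touching ~15% of genes, a rare interaction (64/9338),
    and feminization deltas of -0.5 (males) / -0.1 (females) on the cold
    log2 fold change of sex-biased genes.  Sequencing depth and dispersion
    are not reported for the study; 2e7 reads and phi = 0.1 are conventional
    bulk RNA-seq values.
    """

    n_genes: int = 9338
    n_reps_per_group: int = 3
    library_size_mean: float = 2e7
    library_size_cv: float = 0.2
    baseline_log_mean_sd: float = 2.0
    nb_dispersion: float = 0.1
    frac_female_biased: float = 0.18
    frac_male_biased: float = 0.21
    sex_effect_log2fc: float = 2.0
    frac_cold_responsive: float = 0.15
    cold_effect_sd: float = 1.0
    frac_interaction: float = 0.01
    feminization_delta_male: float = -0.5
    feminization_delta_female: float = -0.1
    seed: int = 0

    def __post_init__(self) -> None:
        for f in fields(self):
            if f.name == "seed":
                continue
            _finite(getattr(self, f.name), f.name)
        _require(self.n_genes >= 1, "n_genes", "must be a positive integer")
        _require(self.n_reps_per_group >= 1, "n_reps_per_group", "must be a positive integer")
        _require(self.library_size_mean > 0, "library_size_mean", "must be positive")
        _require(self.library_size_cv >= 0, "library_size_cv", "must be non-negative")
        _require(self.baseline_log_mean_sd >= 0, "baseline_log_mean_sd", "must be non-negative")
        _require(self.nb_dispersion > 0, "nb_dispersion", "must be positive")
        for name in ("frac_female_biased", "frac_male_biased",
                     "frac_cold_responsive", "frac_interaction"):
            _require(0 <= getattr(self, name) <= 1, name, "must lie in [0, 1]")
        _require(
            self.frac_female_biased + self.frac_male_biased <= 1,
            "frac_female_biased", "frac_female_biased + frac_male_biased must be <= 1",
        )
        _require(self.sex_effect_log2fc > 0, "sex_effect_log2fc", "must be positive")
        _require(self.cold_effect_sd > 0, "cold_effect_sd", "must be positive")
        for name in ("feminization_delta_male", "feminization_delta_female"):
            _finite(getattr(self, name), name)

    @classmethod
    def from_mapping(cls, mapping: dict) -> "SimulationConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown simulation parameters: {sorted(unknown)}")
        return cls(**mapping)


@dataclass
class CTminSimConfig:
    """Parameters of the CTmin phenotype simulator.

    Defaults emulate the modelled assay: ~34 flies per sex x treatment group
    (the study ran 32-37, 137 flies total) scored in 6 batches, CTmin around
    -3 degC with a -1 degC cold-acclimation effect and ~2 mg flies.
    """

    n_flies_per_group: int = 34
    intercept_ctmin: float = -3.0
    sex_effect: float = 0.0
    treatment_effect: float = -1.0
    interaction_effect: float = 0.0
    weight_slope: float = 0.0
    weight_mean: float = 2.0
    weight_sd: float = 0.3
    batch_sd: float = 0.3
    residual_sd: float = 0.7
    n_batches: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        for f in fields(self):
            if f.name == "seed":
                continue
            _finite(getattr(self, f.name), f.name)
        _require(self.n_flies_per_group >= 1, "n_flies_per_group", "must be a positive integer")
        _require(self.weight_mean > 0, "weight_mean", "must be positive")
        _require(self.weight_sd > 0, "weight_sd", "must be positive")
        _require(self.batch_sd >= 0, "batch_sd", "must be non-negative")
        _require(self.residual_sd > 0, "residual_sd", "must be positive")
        _require(self.n_batches >= 1, "n_batches", "must be a positive integer")

    @classmethod
    def from_mapping(cls, mapping: dict) -> "CTminSimConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown CTmin simulation parameters: {sorted(unknown)}")
        return cls(**mapping)


def _exact_subset(rng: np.random.Generator, n: int, count: int) -> np.ndarray:
    """Boolean mask selecting exactly ``count`` of ``n`` items."""
    mask = np.zeros(n, dtype=bool)
    if count > 0:
        mask[rng.choice(n, size=count, replace=False)] = True
    return mask


def simulate_counts(config: SimulationConfig) -> tuple[CountMatrix, pd.DataFrame]:
    """Draw a count matrix and its per-gene ground truth.

    Returns
    -------
    (CountMatrix, DataFrame)
        The ground-truth frame is indexed by gene id with columns
        ``bias_class`` (female_biased / male_biased / unbiased),
        ``cold_lfc_F`` / ``cold_lfc_M`` (total true cold log2FC per sex,
        feminization included), ``interaction`` (bool) and
        ``fem_shift_F`` / ``fem_shift_M`` (the feminization component).

    Notes
    -----
    Group means live on the log2 scale: a per-gene baseline, a +/- sex effect
    on sex-biased genes (male minus female convention), a shared cold log2FC
    on cold-responsive genes, an extra male-only cold term on interaction
    genes, and the feminization delta on sex-biased genes in the cold
    condition only (sign flipped for female-biased genes, so a negative male
    delta moves male expression toward the female profile).  Counts are
    NB(mu, phi) with variance mu + phi * mu^2; library sizes are log-normal
    with the configured mean and CV and set the depth of the baseline
    (female-control) profile — effects are exact on the expected-count
    scale, so a group's realized total varies with its net regulation.
    Genes are independent.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_genes

    baseline = rng.normal(0.0, cfg.baseline_log_mean_sd, size=n)

    # exact class counts, drawn deterministically from the seeded stream
    n_f = int(round(cfg.frac_female_biased * n))
    n_m = int(round(cfg.frac_male_biased * n))
    order = rng.permutation(n)
    bias = np.full(n, "unbiased", dtype=object)
    bias[order[:n_f]] = "female_biased"
    bias[order[n_f:n_f + n_m]] = "male_biased"

    # sex offset applied to males (log2): +s for male-biased, -s for female-biased
    sex_offset = np.where(
        bias == "male_biased", cfg.sex_effect_log2fc,
        np.where(bias == "female_biased", -cfg.sex_effect_log2fc, 0.0),
    )

    cold_mask = _exact_subset(rng, n, int(round(cfg.frac_cold_responsive * n)))
    cold_base = np.where(cold_mask, rng.normal(0.0, cfg.cold_effect_sd, size=n), 0.0)

    inter_mask = _exact_subset(rng, n, int(round(cfg.frac_interaction * n)))
    inter_lfc = np.where(inter_mask, rng.normal(0.0, cfg.cold_effect_sd, size=n), 0.0)

    # feminization: cold-only shift on sex-biased genes; the named sex's delta
    # applies as-is to male-biased genes and negated to female-biased genes
    fem_sign = np.where(
        bias == "male_biased", 1.0, np.where(bias == "female_biased", -1.0, 0.0)
    )
    fem_shift_m = fem_sign * cfg.feminization_delta_male
    fem_shift_f = fem_sign * cfg.feminization_delta_female

    cold_lfc_f = cold_base + fem_shift_f
    cold_lfc_m = cold_base + inter_lfc + fem_shift_m

    log2_mean = {
        ("F", "control"): baseline,
        ("F", "cold"): baseline + cold_lfc_f,
        ("M", "control"): baseline + sex_offset,
        ("M", "cold"): baseline + sex_offset + cold_lfc_m,
    }
    # All groups share the baseline profile's normalizing constant, so every
    # configured effect is exact on the expected-count scale (a gene with a
    # +2 sex effect has exactly 4x the expected male count).  Groups with net
    # up-regulation therefore sequence proportionally deeper; the TMM stage
    # downstream is what corrects such composition-driven depth differences.
    shift = baseline.max()
    denom = np.exp2(baseline - shift).sum()
    proportions = {
        group: np.exp2(lm - shift) / denom for group, lm in log2_mean.items()
    }

    n_libs = 4 * cfg.n_reps_per_group
    if cfg.library_size_cv > 0:
        sigma2 = math.log1p(cfg.library_size_cv ** 2)
        mu_log = math.log(cfg.library_size_mean) - sigma2 / 2
        lib_sizes = rng.lognormal(mu_log, math.sqrt(sigma2), size=n_libs)
    else:
        lib_sizes = np.full(n_libs, cfg.library_size_mean)

    phi = cfg.nb_dispersion
    columns, design_rows, data = [], [], []
    lib_idx = 0
    for sex, temp in GROUPS:
        for rep in range(1, cfg.n_reps_per_group + 1):
            lib_id = f"{sex}_{temp}_{rep}"
            mu = lib_sizes[lib_idx] * proportions[(sex, temp)]
            if phi < 1e-12:
                counts = rng.poisson(mu)
            else:
                r = 1.0 / phi
                counts = rng.negative_binomial(r, r / (r + mu))
            columns.append(lib_id)
            design_rows.append({"library_id": lib_id, "sex": sex,
                                "temperature": temp, "replicate": rep})
            data.append(counts)
            lib_idx += 1

    gene_ids = pd.Index([f"gene_{i + 1:05d}" for i in range(n)], name="gene_id")
    counts_df = pd.DataFrame(np.column_stack(data), index=gene_ids, columns=columns)
    design = pd.DataFrame(design_rows).set_index("library_id")

    truth = pd.DataFrame(
        {
            "bias_class": bias,
            "cold_lfc_F": cold_lfc_f,
            "cold_lfc_M": cold_lfc_m,
            "interaction": inter_mask,
            "fem_shift_F": fem_shift_f,
            "fem_shift_M": fem_shift_m,
            "baseline_log2": baseline,
        },
        index=gene_ids,
    )
    return CountMatrix(counts_df, design), truth


def simulate_ctmin(config: CTminSimConfig) -> pd.DataFrame:
    """Draw a per-fly CTmin table.

    CTmin = intercept + sex + treatment + interaction + weight_slope * weight
    + batch deviate + residual, with residuals redrawn where necessary so
    every CTmin exceeds -5 degC (the log(CTmin + 5) transform must be
    defined).  Batches are assigned cyclically, so group composition is
    balanced across batches up to rounding.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    groups = [("F", "19C"), ("F", "6C"), ("M", "19C"), ("M", "6C")]
    n_total = cfg.n_flies_per_group * 4

    sex = np.repeat([g[0] for g in groups], cfg.n_flies_per_group)
    treatment = np.repeat([g[1] for g in groups], cfg.n_flies_per_group)
    is_m = (sex == "M").astype(float)
    is_cold = (treatment == "6C").astype(float)

    weight = rng.normal(cfg.weight_mean, cfg.weight_sd, size=n_total)
    for _ in range(100):
        bad = weight <= 0
        if not bad.any():
            break
        weight[bad] = rng.normal(cfg.weight_mean, cfg.weight_sd, size=bad.sum())

    batch = np.arange(n_total) % cfg.n_batches
    batch_dev = rng.normal(0.0, cfg.batch_sd, size=cfg.n_batches) if cfg.batch_sd > 0 \
        else np.zeros(cfg.n_batches)

    mean = (
        cfg.intercept_ctmin
        + cfg.sex_effect * is_m
        + cfg.treatment_effect * is_cold
        + cfg.interaction_effect * is_m * is_cold
        + cfg.weight_slope * weight
        + batch_dev[batch]
    )
    ctmin = mean + rng.normal(0.0, cfg.residual_sd, size=n_total)
    for _ in range(1000):
        bad = ctmin <= -5.0
        if not bad.any():
            break
        ctmin[bad] = mean[bad] + rng.normal(0.0, cfg.residual_sd, size=bad.sum())
    else:  # pragma: no cover - pathological configs only
        ctmin = np.maximum(ctmin, -5.0 + 1e-6)

    return pd.DataFrame(
        {
            "fly_id": [f"fly_{i + 1:04d}" for i in range(n_total)],
            "sex": sex,
            "treatment": treatment,
            "weight_mg": np.round(weight, 4),
            "batch": [f"batch_{b + 1}" for b in batch],
            "ctmin_c": np.round(ctmin, 4),
        }
    )


def random_annotation(
    gene_ids,
    n_terms: int = 50,
    term_size_range: tuple[int, int] = (5, 100),
    seed: int = 0,
) -> dict[str, set[str]]:
    """Random gene -> term map for exercising the enrichment stage.

    Terms draw their member genes uniformly without replacement; a gene may
    belong to many terms.  No ontology structure is emulated.
    """
    rng = np.random.default_rng(seed)
    gene_ids = list(gene_ids)
    lo, hi = term_size_range
    if not (1 <= lo <= hi <= len(gene_ids)):
        raise ValueError("term_size_range must satisfy 1 <= lo <= hi <= n_genes")
    annotation = {}
    for t in range(n_terms):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(len(gene_ids), size=size, replace=False)
        annotation[f"TERM:{t + 1:04d}"] = {gene_ids[i] for i in members}
    return annotation
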