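"""End-to-end orchestration of the cold-response analysis.

``run_full_pipeline`` composes the stages — expression filter, TMM, NB
quasi-likelihood GLM with the five contrasts, BH correction, sex-bias
classification, normalized shift summaries, DE-set overlap, between-sex
correlations, MDS and bootstrap clustering, optional enrichment and the
CTmin mixed model — writing each stage's table plus a manifest of
checksums, so a rerun with identical inputs and seed is byte-reproducible.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .containers import CountMatrix
from .concordance import (
    bootstrap_cluster,
    compare_dimorphism_correlation,
    leading_logfc_mds,
    overlap_test,
    response_correlation,
)
from .ctmin import fit_ctmin_model
from .de import QLDifferentialExpression, CONTRASTS
from .enrichment import direction_summary, fisher_term_enrichment
from .io import write_table
from .normalization import TMMNormalizer, filter_low_expression
from .sexbias import classify_sex_bias, filter_conserved_bias, normalized_shift_summary

__all__ = ["PipelineConfig", "RunManifest", "run_full_pipeline"]


@dataclass
class PipelineConfig:
    out_dir: str = "dimoshift_out"
    fdr: float = 0.05
    lfc: float = 1.0
    cpm_threshold: float = 0.5
    min_failing_libs: int = 2
    conf_level: float = 0.95
    top_mds: int = 500
    n_boot: int = 1000
    prior_count: float = 2.0
    ql_prior_df: float = 10.0
    seed: int = 1
    # optional inputs (objects, pre-loaded by the caller or the CLI)
    external_bias: pd.Series | None = field(default=None, repr=False)
    annotation: dict | None = field(default=None, repr=False)
    ctmin_records: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not (0 < self.fdr < 1):
            raise ValueError("fdr must lie in (0, 1)")
        if not (0 < self.conf_level < 1):
            raise ValueError("conf_level must lie in (0, 1)")
        if self.lfc < 0 or self.cpm_threshold < 0:
            raise ValueError("thresholds must be non-negative")
        if self.top_mds < 1 or self.n_boot < 1:
            raise ValueError("top_mds and n_boot must be positive")


@dataclass
class RunManifest:
    version: str
    config: dict
    seed: int
    stages: dict[str, dict] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    wall_time_s: float = 0.0

    def to_json(self, path) -> Path:
        path = Path(path)
        payload = asdict(self)
        payload["config"] = {
            k: v for k, v in payload["config"].items()
            if not isinstance(v, (pd.Series, pd.DataFrame, dict)) or k == "stages"
        }
        path.write_text(json.dumps(payload, indent=2, default=str))
        return path


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _child_seed(seed: int, stage: int) -> int:
    return int(np.random.SeedSequence([seed, stage]).generate_state(1)[0] % (2**31))


def run_full_pipeline(counts: CountMatrix, config: PipelineConfig) -> RunManifest:
    """Run every stage on an in-memory count matrix; returns the manifest."""
    t0 = time.perf_counter()
    cfg = config
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        version=__version__,
        config={k: v for k, v in asdict(cfg).items()
                if k not in ("external_bias", "annotation", "ctmin_records")},
        seed=cfg.seed,
    )
    meta = {"dimoshift_version": __version__, "seed": cfg.seed}

    def record(stage: str, path: Path, **extra) -> None:
        manifest.stages[stage] = {"output": str(path), "sha256": _checksum(path), **extra}

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")

        # 1. filter -------------------------------------------------------
        filtered = filter_low_expression(counts, cfg.cpm_threshold, cfg.min_failing_libs)
        p = write_table(filtered.counts, out / "counts_filtered.tsv", meta)
        record("filter", p, genes_in=counts.n_genes, genes_out=filtered.n_genes)

        # 2. TMM + log-CPM ------------------------------------------------
        norm_est = TMMNormalizer(prior_count=cfg.prior_count).fit(filtered)
        norm = norm_est.transform(filtered)
        p = write_table(
            pd.DataFrame({"tmm_factor": norm.tmm_factors,
                          "effective_lib_size": norm.effective_lib_sizes}),
            out / "normalization.tsv", meta)
        record("tmm", p)
        record("log_cpm", write_table(norm.log_cpm, out / "log_cpm.tsv", meta))

        # 3. GLM + contrasts ---------------------------------------------
        de = QLDifferentialExpression(
            ql_prior_df=cfg.ql_prior_df, prior_count=cfg.prior_count
        ).fit(filtered, norm=norm)
        de_tables = de.results_
        for name in CONTRASTS:
            p = write_table(de_tables[name], out / f"de_{name}.tsv", meta)
            record(f"de_{name}", p,
                   n_significant=int((de_tables[name]["fdr"] < cfg.fdr).sum()))

        # 4. sex-bias classification + shifts -----------------------------
        labels = classify_sex_bias(
            de_tables["sex_in_control"], de_tables["sex_in_cold"], cfg.fdr, cfg.lfc
        )
        p = write_table(labels, out / "sex_bias_labels.tsv", meta)
        record("sex_bias", p,
               n_female_biased=int((labels["label"] == "female_biased").sum()),
               n_male_biased=int((labels["label"] == "male_biased").sum()),
               n_discordant=int(labels["discordant"].sum()))

        cold_lfc = {
            "F": de_tables["cold_in_females"]["log2_fc"],
            "M": de_tables["cold_in_males"]["log2_fc"],
        }
        shifts = normalized_shift_summary(cold_lfc, labels, cfg.conf_level)
        record("shift_summary", write_table(shifts, out / "shift_summary.tsv", meta, index=False))

        if cfg.external_bias is not None:
            conserved = filter_conserved_bias(labels, cfg.external_bias)
            record("sex_bias_conserved",
                   write_table(conserved, out / "sex_bias_labels_conserved.tsv", meta))
            shifts_c = normalized_shift_summary(cold_lfc, conserved, cfg.conf_level)
            record("shift_summary_conserved",
                   write_table(shifts_c, out / "shift_summary_conserved.tsv", meta, index=False))

        # 5. concordance --------------------------------------------------
        universe = set(filtered.gene_ids)
        de_f = set(de_tables["cold_in_females"].index[de_tables["cold_in_females"]["fdr"] < cfg.fdr])
        de_m = set(de_tables["cold_in_males"].index[de_tables["cold_in_males"]["fdr"] < cfg.fdr])
        ov = overlap_test([de_f, de_m], universe, seed=_child_seed(cfg.seed, 51))
        rho_all, p_all = response_correlation(cold_lfc["F"], cold_lfc["M"])
        union = sorted(de_f | de_m)
        rho_de, p_de = (response_correlation(cold_lfc["F"], cold_lfc["M"], subset=union)
                        if len(union) >= 4 else (float("nan"), float("nan")))
        cc = compare_dimorphism_correlation(norm)
        p = write_table(
            pd.DataFrame([
                ("overlap_p", ov.p_value), ("overlap_observed", ov.observed_overlap),
                ("overlap_expected", ov.expected_overlap),
                ("n_de_females", len(de_f)), ("n_de_males", len(de_m)),
                ("rho_all", rho_all), ("rho_all_p", p_all),
                ("rho_de_union", rho_de), ("rho_de_union_p", p_de),
                ("r_control", cc.r_control), ("r_cold", cc.r_cold),
                ("fisher_z", cc.z_statistic), ("fisher_z_p", cc.p_value),
            ], columns=["quantity", "value"]),
            out / "concordance.tsv", meta, index=False)
        record("concordance", p)

        coords = leading_logfc_mds(norm, top=cfg.top_mds)
        record("mds", write_table(coords, out / "mds_coordinates.tsv", meta))

        clust = bootstrap_cluster(norm, n_boot=cfg.n_boot, seed=_child_seed(cfg.seed, 52))
        nwk = out / "dendrogram.nwk"
        nwk.write_text(clust.to_newick() + "\n")
        record("bootstrap_cluster", nwk)

        # 6. enrichment (optional) ---------------------------------------
        if cfg.annotation is not None:
            for name, genes in (("both_sexes", de_f & de_m),
                                ("females_only", de_f - de_m),
                                ("males_only", de_m - de_f)):
                if not genes:
                    continue
                enr = fisher_term_enrichment(genes, universe, cfg.annotation)
                record(f"enrichment_{name}",
                       write_table(enr, out / f"enrichment_{name}.tsv", meta))
            sig_terms = {t: cfg.annotation[t] for t in cfg.annotation}
            dirs = direction_summary(sig_terms, de_tables["cold_in_females"], cfg.fdr)
            record("direction_summary",
                   write_table(dirs, out / "direction_summary.tsv", meta))

        # 7. CTmin (optional) --------------------------------------------
        if cfg.ctmin_records is not None:
            fit = fit_ctmin_model(cfg.ctmin_records)
            tbl = fit.wald_table.copy()
            tbl["batch_variance"] = fit.batch_variance
            record("ctmin", write_table(tbl, out / "ctmin_wald.tsv", meta),
                   n_obs=fit.n_obs, method=fit.method)

        manifest.warnings = [str(w.message) for w in caught]

    manifest.wall_time_s = round(time.perf_counter() - t0, 3)
    manifest.to_json(out / "manifest.json")
    return manifest
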