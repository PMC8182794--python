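"""Term-level Fisher enrichment and cluster enrichment scores.

Per-term significance is a one-tailed Fisher's exact test (enrichment) on
the 2x2 table of set/term membership within a background of expressed
genes.  Term clusters — accepted as given groupings, no clustering is
performed here — are scored by the negative log10 of the geometric mean of
their members' p-values; a score above 1.3 corresponds to a geometric-mean
p below 0.05 and flags the cluster significant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .de import bh_adjust

__all__ = [
    "fisher_term_enrichment",
    "cluster_enrichment_score",
    "direction_summary",
    "ClusterScore",
]


def fisher_term_enrichment(
    gene_set: set,
    background: set,
    annotation: dict[str, set],
    ease: bool = False,
) -> pd.DataFrame:
    """One-tailed enrichment p per term, BH-corrected across terms.

    The 2x2 table per term is (in-set & in-term, in-set & not, out-of-set &
    in-term, out-of-set & not).  ``ease=True`` applies the DAVID-style EASE
    penalty, removing one gene from the in-set/in-term cell before taking
    the hypergeometric tail (conservative for small overlaps).
    """
    gene_set, background = set(gene_set), set(background)
    stray = gene_set - background
    if stray:
        raise ValueError(f"gene_set not contained in background: {sorted(stray)[:5]}")
    n_bg = len(background)
    n_set = len(gene_set)
    rows = []
    for term, members in annotation.items():
        members = set(members) & background
        if not members:
            continue
        k = len(members & gene_set)
        m = len(members)
        a, b = k, n_set - k
        c, d = m - k, n_bg - n_set - (m - k)
        draw = k - 1 if ease else k
        p = float(stats.hypergeom.sf(draw - 1, n_bg, m, n_set))
        p = min(p, 1.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            odds = (a * d) / (b * c) if b * c > 0 else np.inf if a * d > 0 else np.nan
        rows.append((term, k, n_set, m, n_bg, odds, p))
    out = pd.DataFrame(
        rows,
        columns=[
            "term_id", "genes_in_set", "set_size", "genes_in_background",
            "background_size", "odds_ratio", "p_value",
        ],
    ).set_index("term_id")
    out["fdr"] = bh_adjust(out["p_value"].to_numpy()) if len(out) else []
    return out.sort_values("p_value")


@dataclass
class ClusterScore:
    term_ids: list[str]
    member_p: list[float]
    enrichment_score: float
    significant: bool


def cluster_enrichment_score(
    member_p, term_ids=None, threshold: float = 1.3
) -> ClusterScore:
    """DAVID-style cluster score: -log10(geometric mean of member p-values)."""
    p = np.asarray(list(member_p), float)
    if p.size == 0:
        raise ValueError("cluster has no member p-values")
    if (p <= 0).any():
        raise ValueError("p = 0 is not allowed (score undefined)")
    if (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    score = float(-np.mean(np.log10(p)))
    ids = list(term_ids) if term_ids is not None else [f"term_{i}" for i in range(p.size)]
    return ClusterScore(ids, p.tolist(), score, score > threshold)


def direction_summary(
    enriched_terms: dict[str, set],
    de_results: pd.DataFrame,
    fdr_cut: float = 0.05,
) -> pd.DataFrame:
    """Per-term up/down counts of significant member genes' cold log2FC.

    ``de_results`` is one contrast's DE table (index gene id, columns
    ``log2_fc`` and ``fdr``).  Terms whose significant members all move the
    same way are flagged direction-pure (e.g. "all decreased").
    """
    rows = []
    for term, members in enriched_terms.items():
        sub = de_results.loc[de_results.index.intersection(list(members))]
        sig = sub[sub["fdr"] < fdr_cut]
        up = int((sig["log2_fc"] > 0).sum())
        down = int((sig["log2_fc"] < 0).sum())
        if up + down == 0:
            flag = "none_significant"
        elif down == 0:
            flag = "all_increased"
        elif up == 0:
            flag = "all_decreased"
        else:
            flag = "mixed"
        rows.append((term, len(members), up, down, flag))
    return pd.DataFrame(
        rows, columns=["term_id", "n_members", "n_up", "n_down", "direction"]
    ).set_index("term_id")
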