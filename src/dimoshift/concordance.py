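"""Between-sex concordance: overlap tests, correlations, MDS, clustering.

* :func:`overlap_test` — exact significance of the intersection of k gene
  sets drawn from a common universe.  For k = 2 this is the hypergeometric
  upper tail; for k > 2 the exact intersection-size distribution is built
  by successive hypergeometric conditioning (the running intersection of the
  first j sets is itself a uniform random subset of its size), with a seeded
  Monte-Carlo fallback for very large instances.
* :func:`compare_dimorphism_correlation` — Spearman correlation of mean male
  vs female log2 CPM within each temperature, compared by Fisher's z.
* :class:`LeadingLogFCMDS` — classical (Torgerson) MDS of libraries where
  each pairwise distance is the RMS of that pair's largest absolute log2-CPM
  differences ("leading log fold change").
* :func:`bootstrap_cluster` — average-linkage hierarchical clustering of
  libraries with gene-resampled bootstrap support per node.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage, to_tree
from sklearn.base import BaseEstimator

from .containers import NormalizedExpression

__all__ = [
    "OverlapResult",
    "CorrComparison",
    "overlap_test",
    "response_correlation",
    "compare_dimorphism_correlation",
    "LeadingLogFCMDS",
    "leading_logfc_mds",
    "bootstrap_cluster",
    "BootstrapClustering",
]


# ---------------------------------------------------------------------------
# multi-set overlap
# ---------------------------------------------------------------------------

@dataclass
class OverlapResult:
    set_sizes: list[int]
    universe_size: int
    observed_overlap: int
    expected_overlap: float
    p_value: float
    method: str = "exact"


def _intersection_distribution(sizes: list[int], universe: int) -> np.ndarray:
    """Exact pmf of |A_1 ∩ ... ∩ A_k| for uniform random subsets of fixed sizes.

    The running intersection of the first j sets is itself uniform given its
    size, so conditioning on it makes each step hypergeometric.
    """
    dist = np.zeros(sizes[0] + 1)
    dist[sizes[0]] = 1.0
    for n_k in sizes[1:]:
        new = np.zeros(min(dist.size - 1, n_k) + 1)
        for m in np.flatnonzero(dist > 0):
            j = np.arange(0, min(m, n_k) + 1)
            new[: j.size] += dist[m] * stats.hypergeom.pmf(j, universe, m, n_k)
        dist = new
    return dist


def overlap_test(
    sets: list[set],
    universe: set,
    mc_draws: int = 100_000,
    mc_threshold: tuple[int, int] = (5000, 3),
    seed: int = 0,
) -> OverlapResult:
    """Significance of a k-way gene-set intersection (enrichment tail).

    Exact by hypergeometric tail (k = 2) or successive conditioning (k > 2);
    falls back to Monte-Carlo (``mc_draws`` seeded draws) when the universe
    exceeds ``mc_threshold[0]`` and k exceeds ``mc_threshold[1]``.
    """
    if len(sets) < 2:
        raise ValueError("need at least two sets")
    universe = set(universe)
    for i, s in enumerate(sets):
        stray = set(s) - universe
        if stray:
            raise ValueError(
                f"set {i} contains elements outside the universe: {sorted(stray)[:5]}"
            )
    n = len(universe)
    sizes = [len(s) for s in sets]
    inter = set(sets[0])
    for s in sets[1:]:
        inter &= set(s)
    observed = len(inter)
    expected = float(np.prod([float(sz) for sz in sizes]) / n ** (len(sets) - 1))

    if len(sets) == 2:
        p = float(stats.hypergeom.sf(observed - 1, n, sizes[0], sizes[1]))
        method = "hypergeometric"
    elif n > mc_threshold[0] and len(sets) > mc_threshold[1]:
        # sample the null intersection size by the same conditioning chain
        rng = np.random.default_rng(seed)
        cur = np.full(mc_draws, sizes[0])
        for sz in sizes[1:]:
            cur = rng.hypergeometric(cur, n - cur, sz)
        p = (np.count_nonzero(cur >= observed) + 1) / (mc_draws + 1)
        method = "monte-carlo"
    else:
        dist = _intersection_distribution(sizes, n)
        p = float(dist[observed:].sum()) if observed < dist.size else 0.0
        p = min(max(p, 0.0), 1.0)
        method = "exact-convolution"
    return OverlapResult(sizes, n, observed, expected, p, method)


# ---------------------------------------------------------------------------
# correlations
# ---------------------------------------------------------------------------

def response_correlation(
    lfc_female: pd.Series | np.ndarray,
    lfc_male: pd.Series | np.ndarray,
    subset=None,
) -> tuple[float, float]:
    """Spearman rho (midrank ties) and p for paired male/female responses."""
    f = pd.Series(lfc_female)
    m = pd.Series(lfc_male)
    if subset is not None:
        subset = list(subset)
        f, m = f.loc[subset], m.loc[subset]
    if len(f) != len(m):
        raise ValueError("paired vectors differ in length")
    if len(f) < 4:
        raise ValueError("need at least 4 pairs")
    fv, mv = f.to_numpy(float), m.to_numpy(float)
    if np.unique(fv).size < 2 or np.unique(mv).size < 2:
        warnings.warn("constant vector; correlation undefined", RuntimeWarning)
        return float("nan"), float("nan")
    res = stats.spearmanr(fv, mv)
    return float(res.statistic), float(res.pvalue)


@dataclass
class CorrComparison:
    r_control: float
    r_cold: float
    n_genes: int
    z_statistic: float
    p_value: float


def fisher_z_test(r1: float, r2: float, n1: int, n2: int) -> tuple[float, float]:
    """Two-sided Fisher z comparison of two (independent) correlations."""
    if min(n1, n2) <= 3:
        raise ValueError("need n > 3 in each group")
    z = (np.arctanh(r2) - np.arctanh(r1)) / np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    return float(z), float(2 * stats.norm.sf(abs(z)))


def compare_dimorphism_correlation(expr: NormalizedExpression, design=None) -> CorrComparison:
    """Does cold increase the male-female expression correlation?

    Within each temperature, genes' mean log2 CPM in males is correlated
    (Spearman) with the mean in females; the two coefficients are compared
    with Fisher's z.  A caveat: the z-test treats the coefficients as
    independent although both use the same genes, so its p is approximate.
    """
    r = {}
    n = expr.log_cpm.shape[0]
    if n <= 3:
        raise ValueError("need more than 3 genes")
    for temp in ("control", "cold"):
        male = expr.group_mean_log_cpm("M", temp)
        female = expr.group_mean_log_cpm("F", temp)
        r[temp] = float(stats.spearmanr(male, female).statistic)
    z, p = fisher_z_test(r["control"], r["cold"], n, n)
    return CorrComparison(r["control"], r["cold"], n, z, p)


# ---------------------------------------------------------------------------
# leading log-FC MDS
# ---------------------------------------------------------------------------

def _leading_distance_matrix(lcpm: np.ndarray, top: int) -> np.ndarray:
    n = lcpm.shape[1]
    top = min(top, lcpm.shape[0])
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            diff2 = (lcpm[:, i] - lcpm[:, j]) ** 2
            if top < diff2.size:
                sel = np.partition(diff2, diff2.size - top)[-top:]
            else:
                sel = diff2
            d[i, j] = d[j, i] = np.sqrt(sel.mean())
    return d


class LeadingLogFCMDS(BaseEstimator):
    """Classical MDS of libraries on leading log-fold-change distances.

    The distance between two libraries is the root-mean-square of the
    ``top`` largest absolute log2-CPM differences for that pair (pairwise
    gene selection), embedded by Torgerson double-centering.

    Attributes
    ----------
    distances_ : DataFrame (libraries x libraries)
    embedding_ : DataFrame (libraries x dims), centered
    eigenvalues_ : ndarray
    """

    def __init__(self, top: int = 500, dims: int = 2):
        self.top = top
        self.dims = dims

    def fit(self, X: NormalizedExpression, y=None) -> "LeadingLogFCMDS":
        lcpm = X.log_cpm.to_numpy()
        n = lcpm.shape[1]
        if n < 3:
            raise ValueError("need at least 3 libraries")
        top = self.top
        if top > lcpm.shape[0]:
            warnings.warn(
                f"top={top} exceeds gene count {lcpm.shape[0]}; clamping", RuntimeWarning
            )
            top = lcpm.shape[0]
        d = _leading_distance_matrix(lcpm, top)
        j = np.eye(n) - np.ones((n, n)) / n
        b = -0.5 * j @ (d ** 2) @ j
        vals, vecs = np.linalg.eigh(b)
        order = np.argsort(vals)[::-1]
        vals, vecs = vals[order], vecs[:, order]
        k = self.dims
        coords = vecs[:, :k] * np.sqrt(np.maximum(vals[:k], 0.0))
        libs = X.log_cpm.columns
        self.distances_ = pd.DataFrame(d, index=libs, columns=libs)
        self.embedding_ = pd.DataFrame(
            coords, index=libs, columns=[f"dim{i + 1}" for i in range(k)]
        )
        self.eigenvalues_ = vals
        return self

    def fit_transform(self, X: NormalizedExpression, y=None) -> pd.DataFrame:
        return self.fit(X).embedding_


def leading_logfc_mds(expr: NormalizedExpression, top: int = 500, dims: int = 2) -> pd.DataFrame:
    return LeadingLogFCMDS(top=top, dims=dims).fit_transform(expr)


# ---------------------------------------------------------------------------
# bootstrap hierarchical clustering
# ---------------------------------------------------------------------------

@dataclass
class BootstrapClustering:
    """Average-linkage dendrogram of libraries with per-node bootstrap support."""

    linkage_matrix: np.ndarray
    labels: list[str]
    node_sets: list[frozenset] = field(repr=False)
    support: dict[frozenset, float] = field(repr=False)
    n_boot: int = 0

    def support_for(self, members) -> float:
        """Support (%) of the node containing exactly these libraries."""
        key = frozenset(members)
        if key not in self.support:
            raise KeyError(f"no dendrogram node with member set {sorted(key)}")
        return self.support[key]

    def to_newick(self) -> str:
        tree = to_tree(self.linkage_matrix)

        def rec(node):
            if node.is_leaf():
                return self.labels[node.id]
            left, right = rec(node.get_left()), rec(node.get_right())
            members = frozenset(self.labels[i] for i in node.pre_order(lambda l: l.id))
            sup = self.support.get(members)
            tag = "" if sup is None else f"{sup:.0f}"
            return f"({left},{right}){tag}:{node.dist:.6g}"

        body = rec(tree)
        return body.rsplit(":", 1)[0] + ";"


def _node_sets(link: np.ndarray, labels: list[str]) -> list[frozenset]:
    n = link.shape[0] + 1
    clusters: dict[int, frozenset] = {i: frozenset([labels[i]]) for i in range(n)}
    sets = []
    for k, row in enumerate(link):
        merged = clusters[int(row[0])] | clusters[int(row[1])]
        clusters[n + k] = merged
        sets.append(merged)
    return sets


def bootstrap_cluster(
    expr: NormalizedExpression,
    n_boot: int = 1000,
    seed: int = 0,
    method: str = "average",
    metric: str = "euclidean",
) -> BootstrapClustering:
    """Cluster libraries and attach gene-resampling bootstrap support.

    Support of a node is the percentage of bootstrap dendrograms (genes
    resampled with replacement) containing a node with exactly the same
    library set — cluster-wise recovery, not topology-weighted.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    lcpm = expr.log_cpm.to_numpy()
    if lcpm.shape[1] < 3:
        raise ValueError("need at least 3 libraries")
    labels = list(expr.log_cpm.columns)
    link = linkage(lcpm.T, method=method, metric=metric)
    original = _node_sets(link, labels)

    counts = {s: 0 for s in original}
    rng = np.random.default_rng(seed)
    g = lcpm.shape[0]
    for _ in range(n_boot):
        idx = rng.integers(0, g, size=g)
        blink = linkage(lcpm[idx].T, method=method, metric=metric)
        bsets = set(_node_sets(blink, labels))
        for s in counts:
            if s in bsets:
                counts[s] += 1
    support = {s: 100.0 * c / n_boot for s, c in counts.items()}
    return BootstrapClustering(link, labels, original, support, n_boot)
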