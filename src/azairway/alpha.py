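"""Within-sample (alpha) diversity metrics and their group comparisons.

Metrics mirror a standard amplicon workflow: Chao1 richness (bias-corrected),
Shannon diversity (natural log), Camargo evenness, and Faith's phylogenetic
diversity on a rooted tree. Group comparison follows the nonparametric
Kruskal–Wallis / Dunn / Holm chain, with the Wilcoxon signed-rank test for
paired within-patient contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from skbio.diversity import alpha as skbio_alpha
from statsmodels.stats.multitest import multipletests

from .core import FeatureTable, PhyloTree, SampleMetadata

__all__ = [
    "chao1",
    "shannon",
    "camargo_evenness",
    "faith_pd",
    "alpha_diversity_table",
    "GroupTestResult",
    "compare_groups",
    "wilcoxon_paired",
]

ALPHA_METRICS = ("chao1", "shannon", "camargo_evenness", "faith_pd")


def _as_counts(counts) -> np.ndarray:
    arr = np.asarray(counts)
    if arr.ndim != 1:
        raise ValueError("counts must be one sample's 1-D vector")
    if np.any(arr < 0) or np.any(arr != np.floor(arr)):
        raise ValueError("counts must be non-negative integers")
    if arr.sum() == 0:
        raise ValueError("all-zero sample has no diversity")
    return arr.astype(np.int64)


def chao1(counts) -> float:
    """Bias-corrected Chao1 richness: S_obs + f1(f1-1) / (2(f2+1))."""
    return float(skbio_alpha.chao1(_as_counts(counts), bias_corrected=True))


def shannon(counts) -> float:
    """Shannon diversity H = -sum p_i ln p_i (natural log)."""
    return float(skbio_alpha.shannon(_as_counts(counts)))


def camargo_evenness(counts) -> float:
    """Camargo evenness over the observed ASVs.

    E = 1 - sum_{i<j} |p_i - p_j| / S with S the observed richness and p the
    relative abundances of the S observed (nonzero) ASVs; E in (0, 1], with 1
    exactly when all observed abundances are equal.
    """
    arr = _as_counts(counts)
    obs = arr[arr > 0].astype(float)
    p = obs / obs.sum()
    s = len(p)
    if s == 1:
        return 1.0
    # sum of absolute pairwise differences via the sorted-order identity
    q = np.sort(p)
    idx = np.arange(1, s + 1)
    pairwise_sum = float(np.sum((2 * idx - s - 1) * q))
    return 1.0 - pairwise_sum / s


def faith_pd(counts, asv_ids, tree: PhyloTree, include_root: bool = True) -> float:
    """Faith's phylogenetic diversity of one sample on a rooted tree.

    Sum of branch lengths of the minimal subtree connecting the observed ASVs
    to the root. With ``include_root=False`` the stem between the root and the
    most recent common ancestor of the observed ASVs is excluded.
    """
    arr = _as_counts(counts)
    asv_ids = list(asv_ids)
    if len(asv_ids) != len(arr):
        raise ValueError("counts and asv_ids must align")
    observed = [a for a, c in zip(asv_ids, arr) if c > 0]
    tree.require_leaves(observed)
    # union of the root-ward paths of all observed leaves
    tips = {t.name: t for t in tree.tree.tips()}
    seen: set[int] = set()
    pd_rooted = 0.0
    for name in observed:
        node = tips[name]
        while node.parent is not None:
            if id(node) in seen:
                break
            seen.add(id(node))
            pd_rooted += node.length or 0.0
            node = node.parent
    if include_root:
        return pd_rooted
    if len(observed) == 1:
        return 0.0
    mrca = tree.tree.lca(observed)
    stem = float(mrca.accumulate_to_ancestor(tree.tree.root()))
    return pd_rooted - stem


def alpha_diversity_table(
    table: FeatureTable,
    meta: SampleMetadata,
    tree: PhyloTree | None = None,
    metrics=ALPHA_METRICS,
) -> pd.DataFrame:
    """Tidy long table: sample_id, site, phase, metric, value."""
    meta.require_cover(table)
    rows = []
    asv_ids = table.asv_ids
    for sample_id, counts in table.data.iterrows():
        arr = counts.to_numpy()
        info = meta.data.loc[sample_id]
        for metric in metrics:
            if metric == "faith_pd":
                if tree is None:
                    raise ValueError("faith_pd requires a phylogenetic tree")
                value = faith_pd(arr, asv_ids, tree)
            elif metric == "chao1":
                value = chao1(arr)
            elif metric == "shannon":
                value = shannon(arr)
            elif metric == "camargo_evenness":
                value = camargo_evenness(arr)
            else:
                raise ValueError(f"unknown metric {metric!r}")
            rows.append(
                {
                    "sample_id": sample_id,
                    "site": info["site"],
                    "phase": info["phase"],
                    "metric": metric,
                    "value": value,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class GroupTestResult:
    """Kruskal–Wallis omnibus plus Dunn pairwise z-tests with Holm adjustment."""

    statistic: float
    pvalue: float
    pairwise: pd.DataFrame  # group1, group2, z, pvalue, pvalue_adj
    adjustment: str = "holm"

    def significant_pairs(self, alpha: float = 0.05) -> pd.DataFrame:
        return self.pairwise[self.pairwise["pvalue_adj"] <= alpha]


def _dunn_pairwise(values: np.ndarray, labels: np.ndarray) -> pd.DataFrame:
    """Dunn's z-tests on all group pairs using tie-corrected rank variance."""
    n = len(values)
    ranks = stats.rankdata(values)
    groups = pd.unique(labels)
    mean_ranks = {g: ranks[labels == g].mean() for g in groups}
    sizes = {g: int((labels == g).sum()) for g in groups}
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n - 1))
    var_base = n * (n + 1) / 12.0 - tie_term
    rows = []
    for g1, g2 in combinations(groups, 2):
        se = np.sqrt(var_base * (1.0 / sizes[g1] + 1.0 / sizes[g2]))
        z = 0.0 if se == 0 else (mean_ranks[g1] - mean_ranks[g2]) / se
        p = 1.0 if se == 0 else 2.0 * stats.norm.sf(abs(z))
        rows.append({"group1": g1, "group2": g2, "z": z, "pvalue": p})
    return pd.DataFrame(rows)


def compare_groups(values, groups) -> GroupTestResult:
    """Kruskal–Wallis with Dunn's post hoc test and Holm's adjustment.

    All-tied data yield statistic 0 and p = 1 rather than an error. Requires
    at least two groups with at least two observations each.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(groups)
    if len(values) != len(labels):
        raise ValueError("values and groups must align")
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("need at least two groups")
    small = uniq[counts < 2].tolist()
    if small:
        raise ValueError(f"groups with fewer than 2 observations: {small}")
    samples = [values[labels == g] for g in uniq]
    if np.all(values == values[0]):
        stat, p = 0.0, 1.0
    else:
        stat, p = stats.kruskal(*samples)
    pairwise = _dunn_pairwise(values, labels)
    adj = multipletests(pairwise["pvalue"].to_numpy(), method="holm")[1]
    pairwise = pairwise.assign(pvalue_adj=adj)
    return GroupTestResult(float(stat), float(p), pairwise)


def wilcoxon_paired(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired values.

    Zero differences are dropped; at least five informative pairs are
    required. Uses the exact null distribution when there are no ties and
    n is small, the normal approximation otherwise (scipy's default).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("paired vectors must have equal length")
    diffs = y - x
    informative = diffs[diffs != 0]
    if len(informative) == 0:
        raise ValueError("no informative pairs: all differences are zero")
    if len(informative) < 5:
        raise ValueError(
            f"need >= 5 informative pairs, got {len(informative)}"
        )
    stat, p = stats.wilcoxon(x, y, zero_method="wilcox", alternative="two-sided")
    return float(stat), float(p)
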