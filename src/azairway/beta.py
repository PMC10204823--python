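"""Between-sample (beta) diversity: UniFrac distances, ordination and tests.

UniFrac distances are computed on the rooted ASV tree (unweighted from
presence/absence, weighted from relative abundances, normalized by default).
Ordination is classical PCoA with Lingoes correction when the matrix is not
Euclidean-embeddable; group structure is tested by one-way PERMANOVA with
permutation p-values. Two study-specific constructions are included: the
per-phase distance of each oropharyngeal (URT) sample to the centroid of the
sputum (LRT) samples in corrected PCoA space, and Pavoine-style double
principal coordinate analysis (DPCoA) on the dominant genera.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
import skbio
from skbio.diversity import beta_diversity

from .core import FeatureTable, PhyloTree, SampleMetadata

__all__ = [
    "DistanceMatrix",
    "OrdinationResult",
    "PermanovaResult",
    "unweighted_unifrac",
    "weighted_unifrac",
    "distance_matrix",
    "pcoa",
    "permanova",
    "distance_to_sputum_centroid",
    "genus_distance_matrix",
    "dpcoa",
]

BETA_METRICS = ("unweighted_unifrac", "weighted_unifrac")


@dataclass
class DistanceMatrix:
    """Symmetric non-negative distance matrix with a metric label."""

    ids: list[str]
    data: np.ndarray
    metric: str

    def __post_init__(self):
        self.ids = list(self.ids)
        self.data = np.asarray(self.data, dtype=float)
        n = len(self.ids)
        if self.data.shape != (n, n):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(self.data, self.data.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.abs(np.diag(self.data)) > 1e-12):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(self.data < -1e-12):
            raise ValueError("distances must be non-negative")
        np.fill_diagonal(self.data, 0.0)
        self.data = np.clip(self.data, 0.0, None)
        self.data = (self.data + self.data.T) / 2.0

    def to_skbio(self) -> skbio.DistanceMatrix:
        return skbio.DistanceMatrix(self.data, ids=self.ids)

    def subset(self, ids) -> "DistanceMatrix":
        idx = [self.ids.index(i) for i in ids]
        return DistanceMatrix(list(ids), self.data[np.ix_(idx, idx)], self.metric)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.data, index=self.ids, columns=self.ids)

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="sample_id")


def _pair_unifrac(counts_a, counts_b, asv_ids, tree: PhyloTree, metric, **kwargs) -> float:
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if np.any(a < 0) or np.any(b < 0):
        raise ValueError("counts must be non-negative")
    if a.sum() == 0 and b.sum() == 0:
        raise ValueError("UniFrac undefined for two empty samples")
    asv_ids = list(asv_ids)
    observed = [x for x, c in zip(asv_ids, a + b) if c > 0]
    tree.require_leaves(observed)
    mat = np.vstack([a, b])
    # validation is done above; skbio's own check would reject the
    # multifurcating (e.g. star) trees this package supports
    dm = beta_diversity(
        metric, mat, ids=["a", "b"], taxa=asv_ids, tree=tree.tree,
        validate=False, **kwargs
    )
    return float(dm["a", "b"])


def unweighted_unifrac(counts_a, counts_b, asv_ids, tree: PhyloTree) -> float:
    """Unweighted UniFrac: unique branch length / total observed branch length.

    Branches are classified by presence of descendant ASVs in each sample;
    the result lies in [0, 1].
    """
    return _pair_unifrac(counts_a, counts_b, asv_ids, tree, "unweighted_unifrac")


def weighted_unifrac(
    counts_a, counts_b, asv_ids, tree: PhyloTree, normalized: bool = True
) -> float:
    """Weighted UniFrac: sum over branches of L_b |P_a(b) - P_b(b)|.

    P_s(b) is the fraction of sample s descending through branch b. With
    ``normalized=True`` (the default) the value is scaled into [0, 1].
    """
    return _pair_unifrac(
        counts_a, counts_b, asv_ids, tree, "weighted_unifrac", normalized=normalized
    )


def distance_matrix(
    table: FeatureTable,
    tree: PhyloTree,
    metric: str = "unweighted_unifrac",
    normalized: bool = True,
) -> DistanceMatrix:
    """All-pairs UniFrac distance matrix for a feature table."""
    if metric not in BETA_METRICS:
        raise ValueError(f"metric must be one of {BETA_METRICS}, got {metric!r}")
    tree.require_leaves(table.asv_ids)
    kwargs = {"normalized": normalized} if metric == "weighted_unifrac" else {}
    counts = table.data.to_numpy()
    if table.shape[0] == 1:
        return DistanceMatrix(table.sample_ids, np.zeros((1, 1)), metric)
    if (counts.sum(axis=1) == 0).any():
        empty = [s for s, t in zip(table.sample_ids, counts.sum(axis=1)) if t == 0]
        raise ValueError(f"samples with no reads: {empty}")
    dm = beta_diversity(
        metric,
        counts,
        ids=table.sample_ids,
        taxa=table.asv_ids,
        tree=tree.tree,
        validate=False,
        **kwargs,
    )
    return DistanceMatrix(list(dm.ids), dm.data, metric)


# ---------------------------------------------------------------------------
# Ordination
# ---------------------------------------------------------------------------

@dataclass
class OrdinationResult:
    """PCoA/DPCoA embedding: sample coordinates and axis decomposition."""

    coordinates: pd.DataFrame  # samples x axes
    eigenvalues: np.ndarray  # sorted descending, retained axes
    proportion_explained: np.ndarray
    correction: str | None = None
    feature_scores: pd.DataFrame | None = None  # genus coordinates (DPCoA)

    def distances(self) -> DistanceMatrix:
        """Euclidean inter-sample distances in the embedding."""
        x = self.coordinates.to_numpy()
        sq = np.sum(x**2, axis=1)
        d2 = np.clip(sq[:, None] + sq[None, :] - 2 * x @ x.T, 0.0, None)
        return DistanceMatrix(list(self.coordinates.index), np.sqrt(d2), "embedding")


def _double_center(d2: np.ndarray) -> np.ndarray:
    n = d2.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    return -0.5 * j @ d2 @ j


def pcoa(dm: DistanceMatrix, neg_tol: float = 1e-8) -> OrdinationResult:
    """Classical (metric) multidimensional scaling of a distance matrix.

    Gower double-centring followed by eigendecomposition. If negative
    eigenvalues beyond ``neg_tol`` (relative to the largest eigenvalue)
    remain, the Lingoes correction (adding a constant to all squared
    off-diagonal distances) is applied and flagged in the result. For a
    Euclidean-embeddable input the embedding reproduces all pairwise
    distances exactly.
    """
    d2 = dm.data**2
    n = d2.shape[0]
    if n < 2:
        raise ValueError("PCoA needs at least 2 samples")
    eigval, eigvec = np.linalg.eigh(_double_center(d2))
    correction = None
    scale = max(eigval.max(), 1.0e-12)
    if eigval.min() < -neg_tol * scale:
        # Lingoes: d'^2_ij = d^2_ij + 2c for i != j, c = -smallest eigenvalue
        c = -eigval.min()
        d2c = d2 + 2.0 * c * (1.0 - np.eye(n))
        eigval, eigvec = np.linalg.eigh(_double_center(d2c))
        correction = "lingoes"
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    keep = eigval > neg_tol * scale
    eigval_pos = eigval[keep]
    coords = eigvec[:, keep] * np.sqrt(eigval_pos)
    total = eigval_pos.sum() if eigval_pos.size else 1.0
    axes = [f"PC{i + 1}" for i in range(coords.shape[1])]
    return OrdinationResult(
        coordinates=pd.DataFrame(coords, index=dm.ids, columns=axes),
        eigenvalues=eigval_pos,
        proportion_explained=eigval_pos / total,
        correction=correction,
    )


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

@dataclass
class PermanovaResult:
    """One-way PERMANOVA: pseudo-F, effect size and permutation p-value."""

    pseudo_f: float
    r_squared: float
    pvalue: float
    n_permutations: int
    seed: int | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "pseudo_F": self.pseudo_f,
                    "R2": self.r_squared,
                    "pvalue": self.pvalue,
                    "n_permutations": self.n_permutations,
                    "seed": self.seed,
                }
            ]
        )


def _permanova_ss(d2: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """(SS_among, SS_within) from squared distances and group labels."""
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, k=1)].sum() / n
    ss_within = 0.0
    for g in np.unique(labels):
        idx = np.flatnonzero(labels == g)
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(len(idx), k=1)].sum() / len(idx)
    return ss_total - ss_within, ss_within


def _pseudo_f(d2: np.ndarray, labels: np.ndarray) -> float:
    n = d2.shape[0]
    k = len(np.unique(labels))
    ss_among, ss_within = _permanova_ss(d2, labels)
    if ss_within <= 0:
        return np.inf if ss_among > 0 else 0.0
    return (ss_among / (k - 1)) / (ss_within / (n - k))


def permanova(
    dm: DistanceMatrix,
    groups,
    n_perm: int = 999,
    seed: int | None = None,
    strata=None,
) -> PermanovaResult:
    """One-way PERMANOVA with free (or within-strata) label permutations.

    The p-value uses the (1 + #{F_perm >= F_obs}) / (1 + n_perm) convention,
    so it is never zero, and is deterministic for a fixed seed. ``strata``
    (e.g. patient ids) restricts permutations to within-stratum shuffles.
    """
    labels = np.asarray(groups)
    if len(labels) != len(dm.ids):
        raise ValueError("groups must align with distance-matrix ids")
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("PERMANOVA needs at least two groups")
    small = uniq[counts < 2].tolist()
    if small:
        raise ValueError(f"groups of size < 2: {small}")
    d2 = dm.data**2
    f_obs = _pseudo_f(d2, labels)
    ss_among, ss_within = _permanova_ss(d2, labels)
    r2 = ss_among / (ss_among + ss_within) if (ss_among + ss_within) > 0 else 0.0
    rng = np.random.default_rng(seed)
    if strata is not None:
        strata = np.asarray(strata)
        if len(strata) != len(labels):
            raise ValueError("strata must align with groups")
        strata_idx = [np.flatnonzero(strata == s) for s in np.unique(strata)]
    exceed = 0
    for _ in range(n_perm):
        perm = labels.copy()
        if strata is None:
            perm = labels[rng.permutation(len(labels))]
        else:
            for idx in strata_idx:
                perm[idx] = labels[idx[rng.permutation(len(idx))]]
        if _pseudo_f(d2, perm) >= f_obs:
            exceed += 1
    p = (1.0 + exceed) / (1.0 + n_perm)
    return PermanovaResult(float(f_obs), float(r2), float(p), n_perm, seed)


# ---------------------------------------------------------------------------
# Per-phase URT-to-sputum-centroid distance
# ---------------------------------------------------------------------------

def distance_to_sputum_centroid(
    dm: DistanceMatrix, meta: SampleMetadata, phase: str
) -> pd.Series:
    """Distance of each URT (OPS) sample to the LRT (sputum) centroid, per phase.

    All samples of the phase are embedded by corrected PCoA of the supplied
    distance matrix; the centroid is the coordinate mean of the phase's
    sputum samples, and the returned series holds the Euclidean distance of
    each of the phase's URT samples to that centroid (the construction used
    by dispersion analyses, where a mean community profile would not be
    distance-consistent in UniFrac space).
    """
    phase_meta = meta.data[meta.data["phase"] == phase]
    ids = [s for s in dm.ids if s in phase_meta.index]
    sputum = [s for s in ids if phase_meta.loc[s, "site"] == "LRT"]
    ops = [s for s in ids if phase_meta.loc[s, "site"] == "URT"]
    if not sputum:
        raise ValueError(f"phase {phase!r} has no sputum (LRT) samples")
    if not ops:
        raise ValueError(f"phase {phase!r} has no OPS (URT) samples")
    sub = dm.subset(ids)
    coords = pcoa(sub).coordinates
    centroid = coords.loc[sputum].mean(axis=0).to_numpy()
    diffs = coords.loc[ops].to_numpy() - centroid
    return pd.Series(np.linalg.norm(diffs, axis=1), index=ops, name=f"dist_to_LRT_centroid_{phase}")


# ---------------------------------------------------------------------------
# DPCoA
# ---------------------------------------------------------------------------

def genus_distance_matrix(tree: PhyloTree, taxonomy: pd.Series, genera=None) -> pd.DataFrame:
    """Mean patristic distance between the ASVs of each pair of genera."""
    leaf_tax = taxonomy[taxonomy.index.isin(tree.leaf_names)]
    if genera is None:
        genera = sorted(leaf_tax.unique())
    pat = tree.patristic_distances(list(leaf_tax.index))
    out = pd.DataFrame(0.0, index=genera, columns=genera)
    members = {g: list(leaf_tax[leaf_tax == g].index) for g in genera}
    for g1, g2 in combinations(genera, 2):
        d = float(pat.loc[members[g1], members[g2]].to_numpy().mean())
        out.loc[g1, g2] = out.loc[g2, g1] = d
    return out


def dpcoa(
    genus_table: FeatureTable,
    genus_distances: pd.DataFrame,
    n_genera: int = 15,
    neg_tol: float = 1e-8,
) -> OrdinationResult:
    """Double principal coordinate analysis on the dominant genera.

    The ``n_genera`` most abundant genera (mean relative abundance, ties
    broken by genus name) are embedded so that their squared Euclidean
    distances equal the supplied pairwise dissimilarities (Lingoes-corrected
    and flagged if that embedding does not exist); each sample is placed at
    the relative-abundance-weighted centroid of its genus points, and the
    cloud is rotated onto principal axes weighted by sample totals. Squared
    inter-sample distances then equal the Rao dissimilarity
    2Q(mix) - Q(a) - Q(b).

    Returns sample coordinates plus genus coordinates (``feature_scores``)
    in the same space.
    """
    if n_genera > genus_table.shape[1]:
        raise ValueError(
            f"requested {n_genera} genera but table has {genus_table.shape[1]}"
        )
    mean_abund = genus_table.relative_abundance().mean(axis=0)
    # ties on mean abundance broken lexicographically by genus name
    order = sorted(mean_abund.index, key=lambda g: (-mean_abund[g], g))
    top = order[:n_genera]
    missing = [g for g in top if g not in genus_distances.index]
    if missing:
        raise ValueError(f"genus distances missing for: {missing}")
    sub = genus_table.data[top]
    totals = sub.sum(axis=1)
    keep = totals > 0
    if not keep.all():
        dropped = list(sub.index[~keep])
        warnings.warn(
            f"samples with no reads in the top genera dropped: {dropped}",
            stacklevel=2,
        )
        sub, totals = sub[keep], totals[keep]
    p = sub.div(totals, axis=0).to_numpy()

    # genus embedding with squared distances equal to the dissimilarities
    delta = genus_distances.loc[top, top].to_numpy(dtype=float)
    genus_dm = DistanceMatrix(top, np.sqrt(delta), "genus")
    genus_ord = pcoa(genus_dm, neg_tol=neg_tol)
    z = genus_ord.coordinates.to_numpy()

    x = p @ z  # samples at abundance-weighted centroids
    w = totals.to_numpy(dtype=float)
    w = w / w.sum()
    mean = w @ x
    xc = x - mean
    cov = xc.T @ (xc * w[:, None])
    eigval, eigvec = np.linalg.eigh(cov)
    order_ax = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order_ax], eigvec[:, order_ax]
    keep_ax = eigval > max(eigval.max(), 1e-12) * 1e-12
    eigval = np.clip(eigval[keep_ax], 0.0, None)
    rot = eigvec[:, keep_ax]
    axes = [f"DPC{i + 1}" for i in range(rot.shape[1])]
    sample_coords = pd.DataFrame(xc @ rot, index=sub.index, columns=axes)
    genus_coords = pd.DataFrame((z - mean) @ rot, index=top, columns=axes)
    total = eigval.sum() if eigval.size else 1.0
    return OrdinationResult(
        coordinates=sample_coords,
        eigenvalues=eigval,
        proportion_explained=eigval / total,
        correction=genus_ord.correction,
        feature_scores=genus_coords,
    )
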