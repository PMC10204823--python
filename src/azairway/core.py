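"""Core data containers and shared operations.

The central objects of a longitudinal paired-site amplicon survey:

* :class:`FeatureTable` — integer ASV read counts, samples in rows;
* :class:`SampleMetadata` — patient / site / treatment-phase labels that
  define every grouping and pairing downstream;
* :class:`PhyloTree` — a rooted, branch-length-weighted tree over the ASVs,
  required by Faith's PD, UniFrac and DPCoA;
* a taxonomy map (plain ``pandas.Series``, ASV id -> genus label).

Shared operations: TSV/newick I/O, rarefaction to a common sequencing depth,
genus-level collapse, and the core-community dominance summary.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import TreeNode

__all__ = [
    "PHASES",
    "SITES",
    "UNASSIGNED_GENUS",
    "FeatureTable",
    "SampleMetadata",
    "PhyloTree",
    "RarefactionResult",
    "read_feature_table",
    "read_metadata",
    "read_tree",
    "read_taxonomy",
    "write_taxonomy",
    "rarefy",
    "collapse_to_genus",
    "core_community_dominance",
]

#: Treatment phases in study order: before azithromycin (only observable in
#: patients randomised to placebo first), start / end of the 3-month course,
#: one month after cessation, and three or more months after cessation.
PHASES = ("PreAZT", "StartAZT", "EndAZT", "PostAZT_1mo", "PostAZT_ge3mo")

#: Sampling sites: lower respiratory tract (sputum) and upper respiratory
#: tract (oropharyngeal swab).
SITES = ("LRT", "URT")

#: Sentinel genus label for ASVs without a taxonomic assignment.
UNASSIGNED_GENUS = "unassigned"


class FeatureTable:
    """Integer read counts per (sample, ASV).

    Parameters
    ----------
    data : pandas.DataFrame
        Samples in rows, ASVs in columns, non-negative integer cells.

    Raises
    ------
    ValueError
        On duplicate ids, negative or non-integer counts.
    """

    def __init__(self, data: pd.DataFrame):
        if data.index.has_duplicates:
            dups = data.index[data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        if data.columns.has_duplicates:
            dups = data.columns[data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate ASV ids: {dups}")
        values = data.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.integer):
            if not np.all(np.isfinite(values)) or np.any(values != np.floor(values)):
                bad = np.argwhere(values != np.floor(values))
                r, c = bad[0] if len(bad) else (0, 0)
                raise ValueError(
                    f"non-integer count at sample {data.index[r]!r}, "
                    f"ASV {data.columns[c]!r}"
                )
            values = values.astype(np.int64)
        if values.size and values.min() < 0:
            r, c = np.argwhere(values < 0)[0]
            raise ValueError(
                f"negative count at sample {data.index[r]!r}, ASV {data.columns[c]!r}"
            )
        self.data = pd.DataFrame(
            values.astype(np.int64, copy=False), index=data.index, columns=data.columns
        )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def asv_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def sample_sums(self) -> pd.Series:
        return self.data.sum(axis=1)

    def relative_abundance(self) -> pd.DataFrame:
        """Per-sample proportions; rows sum to 1 (all-zero rows stay zero)."""
        totals = self.data.sum(axis=1).to_numpy(dtype=float)
        totals[totals == 0] = 1.0
        return self.data.div(totals, axis=0)

    def presence(self) -> pd.DataFrame:
        """Boolean presence (>= 1 read) per (sample, ASV)."""
        return self.data > 0

    def filter_samples(self, sample_ids) -> "FeatureTable":
        missing = [s for s in sample_ids if s not in self.data.index]
        if missing:
            raise KeyError(f"samples not in table: {missing}")
        return FeatureTable(self.data.loc[list(sample_ids)])

    def write_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index_label="sample_id")

    def __eq__(self, other) -> bool:
        return isinstance(other, FeatureTable) and self.data.equals(other.data)

    def __repr__(self) -> str:
        n, m = self.data.shape
        return f"<FeatureTable {n} samples x {m} ASVs>"


METADATA_COLUMNS = ("sample_id", "patient_id", "site", "phase", "time_months")


class SampleMetadata:
    """Patient, site, phase and timing labels keyed by sample id.

    Enforces the closed site/phase vocabularies and uniqueness of both
    sample ids and (patient, site, phase) triples.
    """

    def __init__(self, data: pd.DataFrame):
        missing = [c for c in METADATA_COLUMNS if c not in data.columns and c != "sample_id"]
        if data.index.name != "sample_id":
            if "sample_id" not in data.columns:
                raise ValueError("metadata requires a sample_id column")
            data = data.set_index("sample_id")
            missing = [c for c in METADATA_COLUMNS[1:] if c not in data.columns]
        if missing:
            raise ValueError(f"metadata missing columns: {missing}")
        if data.index.has_duplicates:
            dups = data.index[data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids in metadata: {dups}")
        bad_site = sorted(set(data["site"]) - set(SITES))
        if bad_site:
            raise ValueError(f"unknown site value(s) {bad_site}; allowed: {list(SITES)}")
        bad_phase = sorted(set(data["phase"]) - set(PHASES))
        if bad_phase:
            raise ValueError(f"unknown phase value(s) {bad_phase}; allowed: {list(PHASES)}")
        triple = data[["patient_id", "site", "phase"]]
        if triple.duplicated().any():
            dup = triple[triple.duplicated()].iloc[0].tolist()
            raise ValueError(f"more than one sample for (patient, site, phase) = {dup}")
        self.data = data[list(METADATA_COLUMNS[1:])].copy()
        self.data["time_months"] = self.data["time_months"].astype(float)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def require_cover(self, table: FeatureTable) -> None:
        """Check every table sample has exactly one metadata row."""
        missing = [s for s in table.sample_ids if s not in self.data.index]
        if missing:
            raise ValueError(f"samples without metadata: {missing}")

    def select(self, site=None, phase=None, patient_id=None) -> pd.DataFrame:
        """Rows matching the given (optional) site / phase / patient filters."""
        out = self.data
        if site is not None:
            out = out[out["site"] == site]
        if phase is not None:
            out = out[out["phase"] == phase]
        if patient_id is not None:
            out = out[out["patient_id"] == patient_id]
        return out

    def sample_for(self, patient_id, site, phase) -> str | None:
        """Sample id for a (patient, site, phase) triple, or None if absent."""
        rows = self.select(site=site, phase=phase, patient_id=patient_id)
        if rows.empty:
            return None
        return rows.index[0]

    def write_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index_label="sample_id")

    def __repr__(self) -> str:
        return f"<SampleMetadata {len(self.data)} samples>"


class PhyloTree:
    """Rooted phylogenetic tree over the ASVs, wrapping ``skbio.TreeNode``.

    Branch lengths must be non-negative and total length positive. Leaves
    not present in a feature table are tolerated and can be pruned with
    :meth:`shear`.
    """

    def __init__(self, tree: TreeNode):
        n_missing = 0
        for node in tree.traverse(include_self=False):
            if node.length is None:
                node.length = 0.0
                n_missing += 1
            elif node.length < 0:
                raise ValueError(f"negative branch length at node {node.name!r}")
        if n_missing:
            warnings.warn(
                f"{n_missing} branch(es) without length set to 0", stacklevel=2
            )
        tree.length = tree.length or 0.0
        leaves = [leaf.name for leaf in tree.tips()]
        if len(leaves) != len(set(leaves)):
            raise ValueError("duplicate leaf labels in tree")
        if self._total_length(tree) <= 0:
            raise ValueError("tree has no positive branch length")
        self.tree = tree

    @staticmethod
    def _total_length(tree: TreeNode) -> float:
        return sum(n.length or 0.0 for n in tree.traverse(include_self=False))

    @property
    def leaf_names(self) -> list[str]:
        return [leaf.name for leaf in self.tree.tips()]

    @property
    def total_length(self) -> float:
        return self._total_length(self.tree)

    def require_leaves(self, asv_ids) -> None:
        missing = sorted(set(asv_ids) - set(self.leaf_names))
        if missing:
            raise ValueError(f"ASVs absent from tree: {missing}")

    def shear(self, asv_ids) -> "PhyloTree":
        """Prune the tree down to the given leaves."""
        self.require_leaves(asv_ids)
        return PhyloTree(self.tree.shear(set(asv_ids)))

    def patristic_distances(self, names=None) -> pd.DataFrame:
        """Pairwise leaf-to-leaf path-length (patristic) distance matrix."""
        dm = self.tree.tip_tip_distances()
        out = pd.DataFrame(dm.data, index=list(dm.ids), columns=list(dm.ids))
        if names is not None:
            out = out.loc[list(names), list(names)]
        return out

    def write_newick(self, path) -> None:
        self.tree.write(str(path), format="newick")

    def __repr__(self) -> str:
        return f"<PhyloTree {len(self.leaf_names)} leaves, total length {self.total_length:.4g}>"


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_feature_table(path) -> FeatureTable:
    """Read a samples x ASVs TSV (first column sample ids, header ASV ids)."""
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        mask = numeric.isna()
        r = mask.any(axis=1).idxmax()
        c = mask.loc[r].idxmax()
        raise ValueError(
            f"non-numeric count {raw.loc[r, c]!r} at sample {r!r}, ASV {c!r}"
        )
    return FeatureTable(numeric)


def read_metadata(path) -> SampleMetadata:
    """Read a sample metadata TSV with the fixed column names."""
    return SampleMetadata(pd.read_csv(path, sep="\t", dtype={"sample_id": str}))


def read_tree(source) -> PhyloTree:
    """Read a rooted newick tree (path or newick string)."""
    text = str(source)
    if text.lstrip().startswith("("):
        handle: object = io.StringIO(text)
    else:
        handle = text
    try:
        tree = TreeNode.read(handle, format="newick")
    except Exception as exc:  # skbio raises its own parse errors
        raise ValueError(f"newick parse error: {exc}") from exc
    return PhyloTree(tree)


def read_taxonomy(path) -> pd.Series:
    """Read an ASV -> genus TSV (columns asv_id, genus)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"asv_id", "genus"} <= set(df.columns):
        raise ValueError("taxonomy requires columns asv_id, genus")
    if df["asv_id"].duplicated().any():
        raise ValueError("duplicate asv_id in taxonomy")
    tax = df.set_index("asv_id")["genus"]
    return tax.fillna(UNASSIGNED_GENUS)


def write_taxonomy(tax: pd.Series, path) -> None:
    tax.rename("genus").to_csv(path, sep="\t", index_label="asv_id")


# ---------------------------------------------------------------------------
# Rarefaction
# ---------------------------------------------------------------------------

@dataclass
class RarefactionResult:
    """Outcome of rarefying: the subsampled table plus the drop report."""

    table: FeatureTable
    depth: int
    seed: int
    dropped: list[str] = field(default_factory=list)


def rarefy(table: FeatureTable, depth: int, seed: int) -> RarefactionResult:
    """Subsample every sample to exactly ``depth`` reads without replacement.

    Samples with fewer than ``depth`` total reads are dropped and listed in
    the result's ``dropped`` report. One multivariate-hypergeometric draw is
    made per sample; the draw is deterministic for a fixed seed.
    """
    if depth <= 0:
        raise ValueError(f"rarefaction depth must be positive, got {depth}")
    rng = np.random.default_rng(seed)
    kept_rows: dict[str, np.ndarray] = {}
    dropped: list[str] = []
    for sample_id, row in table.data.iterrows():
        counts = row.to_numpy()
        total = int(counts.sum())
        if total < depth:
            dropped.append(sample_id)
            continue
        if total == depth:
            kept_rows[sample_id] = counts.copy()
        else:
            kept_rows[sample_id] = rng.multivariate_hypergeometric(counts, depth)
    kept = pd.DataFrame.from_dict(kept_rows, orient="index", dtype=np.int64)
    if kept.empty:
        kept = pd.DataFrame(
            np.empty((0, table.shape[1]), dtype=np.int64), columns=table.asv_ids
        )
    else:
        kept.columns = table.asv_ids
    return RarefactionResult(FeatureTable(kept), depth=depth, seed=seed, dropped=dropped)


def collapse_to_genus(table: FeatureTable, taxonomy: pd.Series) -> FeatureTable:
    """Sum ASV counts into genus-level columns; per-sample totals conserved.

    ASVs missing from the taxonomy are pooled under the sentinel genus.
    """
    genera = pd.Series(
        [taxonomy.get(a, UNASSIGNED_GENUS) for a in table.asv_ids], index=table.asv_ids
    ).fillna(UNASSIGNED_GENUS)
    collapsed = table.data.T.groupby(genera, sort=True).sum().T
    return FeatureTable(collapsed)


def core_community_dominance(
    table: FeatureTable,
    abundance_threshold: float = 0.001,
    prevalence_threshold: float = 0.5,
) -> pd.Series:
    """Per-sample summed relative abundance of the core-community ASVs.

    The core set contains ASVs whose relative abundance exceeds
    ``abundance_threshold`` (default 0.1%) in at least ``prevalence_threshold``
    (default 50%) of samples. Returns a series in [0, 1] indexed by sample.
    """
    if table.shape[0] == 0 or table.shape[1] == 0:
        raise ValueError("core-community dominance requires a non-empty table")
    rel = table.relative_abundance()
    prevalence = (rel > abundance_threshold).mean(axis=0)
    core = prevalence[prevalence >= prevalence_threshold].index
    return rel[core].sum(axis=1).rename("core_dominance")
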