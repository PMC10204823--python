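"""Synthetic longitudinal paired-site cohort generator with ground truth.

Generates amplicon count tables, metadata, a taxonomy map, an ASV phylogeny
and ARG qPCR panels with the statistical structure the analysis pipeline
assumes: ~24 patients sampled at upper (URT) and lower (LRT) airway sites
over five treatment phases; Dirichlet-multinomial read counts around
patient-specific baseline compositions (per-patient community persistence);
natural presence churn between phases; a treatment window that clears a
planted fraction of taxa and suppresses acquisition of new ones, followed by
a post-treatment acquisition burst; enrichment of a designated genus
(Streptococcus-like or Prevotella_7-like) from the end of treatment; and an
ARG carriage increase with lower bacterial density in a patient subset. The
generator emits a :class:`SimulationTruth` record against which recovery of
every planted effect can be tested.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from skbio import TreeNode

from .core import PHASES, SITES, FeatureTable, PhyloTree, SampleMetadata, write_taxonomy
from .resistome import ARG_GENES, ARGPanel

__all__ = [
    "CohortConfig",
    "PatientTruth",
    "SimulationTruth",
    "SyntheticCohort",
    "simulate_tree",
    "simulate_cohort",
]

#: Months relative to the start of the azithromycin course.
PHASE_MONTHS = {
    "PreAZT": -4.0,
    "StartAZT": 0.0,
    "EndAZT": 3.0,
    "PostAZT_1mo": 4.0,
    "PostAZT_ge3mo": 6.0,
}

TREATMENT_WINDOW = ("StartAZT", "EndAZT")


@dataclass
class CohortConfig:
    """Generator parameters; defaults emulate the study's cohort shape.

    The five-phase, two-site design with 24 patients, 300 ASVs in 30 genera
    and a rarefaction depth of 10 055 reads mirrors the observed data
    structure. ``clearance_fraction`` is the fraction of a patient's present
    taxa cleared over the treatment window (weaker in the URT by
    ``urt_clearance_scale``); ``churn_rate`` is the natural per-transition
    presence turnover outside treatment, balanced so richness is stationary;
    ``acquisition_suppression`` damps acquisitions during treatment and
    ``post_burst`` amplifies them in the month after. Half the cohort
    (placebo-first patients) contributes PreAZT samples. ARG carriage is
    multiplied ``arg_fold_increase``-fold at the end of treatment in the
    ``resistance_increase_fraction`` of patients whose designated genus is
    Streptococcus; those patients also have log-normally lower bacterial
    density.
    """

    n_patients: int = 24
    n_asvs: int = 300
    n_genera: int = 30
    rarefaction_depth: int = 10055
    raw_depth_range: tuple[int, int] = (12000, 20000)
    prop_present: float = 0.6
    churn_rate: float = 0.3
    clearance_fraction: float = 0.2
    urt_clearance_scale: float = 0.6
    acquisition_suppression: float = 0.75
    post_burst: float = 1.5
    resilience_fraction: float = 0.2
    n_core_protected: int = 10
    urt_dropout: float = 0.25
    urt_extra: float = 0.05
    genus_enrichment: float = 3.0
    resistance_increase_fraction: float = 0.5
    arg_fold_increase: float = 4.0
    arg_base_norm: float = 1e-4
    density_log10_mean: float = np.log10(2e5)
    density_log10_sd: float = 0.45
    density_increased_log10_shift: float = -0.6
    persistence_kappa: float = 2000.0
    patient_sigma: float = 0.5
    pre_azt_fraction: float = 0.5
    n_low_depth: int = 0
    seed: int = 0

    def validate(self) -> None:
        fractions = {
            "prop_present": self.prop_present,
            "churn_rate": self.churn_rate,
            "clearance_fraction": self.clearance_fraction,
            "urt_clearance_scale": self.urt_clearance_scale,
            "acquisition_suppression": self.acquisition_suppression,
            "resilience_fraction": self.resilience_fraction,
            "urt_dropout": self.urt_dropout,
            "urt_extra": self.urt_extra,
            "resistance_increase_fraction": self.resistance_increase_fraction,
            "pre_azt_fraction": self.pre_azt_fraction,
        }
        for name, value in fractions.items():
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2")
        if self.n_asvs < 2:
            raise ValueError("n_asvs must be >= 2")
        if self.rarefaction_depth < 100:
            raise ValueError("rarefaction_depth must be >= 100")
        if self.raw_depth_range[0] < self.rarefaction_depth:
            raise ValueError("raw depth range must start at or above the rarefaction depth")
        if self.n_genera < 2 or self.n_genera > self.n_asvs:
            raise ValueError("need 2 <= n_genera <= n_asvs")

    @classmethod
    def null(cls, **overrides) -> "CohortConfig":
        """A generator with no treatment effect: every phase transition has
        the same natural churn and neither genus enrichment, ARG increase nor
        density shift is applied, so phases are exchangeable."""
        base = cls(**overrides)
        base.clearance_fraction = base.churn_rate
        base.urt_clearance_scale = 1.0
        base.acquisition_suppression = 0.0
        base.post_burst = 1.0
        base.resilience_fraction = 1.0
        base.n_core_protected = 0
        base.genus_enrichment = 1.0
        base.arg_fold_increase = 1.0
        base.density_increased_log10_shift = 0.0
        return base


@dataclass
class PatientTruth:
    """Planted per-patient effects."""

    patient_id: str
    stratum: str  # "increased" or "stable"
    enriched_genus: str
    placebo_first: bool
    cleared: dict[str, frozenset] = field(default_factory=dict)  # site -> ASVs
    acquired: dict[str, frozenset] = field(default_factory=dict)
    baseline_present: dict[str, frozenset] = field(default_factory=dict)

    def cleared_fraction(self, site: str) -> float:
        start = self.present_at_start(site)
        return len(self.cleared[site]) / len(start) if start else 0.0

    def present_at_start(self, site: str) -> frozenset:
        # cleared and retained taxa together are the window-start presence set
        return self._start_presence[site]

    _start_presence: dict = field(default_factory=dict, repr=False)


@dataclass
class SimulationTruth:
    """Ground truth for the whole cohort."""

    config: CohortConfig
    patients: dict[str, PatientTruth]
    sample_composition: dict[str, np.ndarray]  # expected proportions per sample
    sample_density: dict[str, float]  # true 16S copies/µL (LRT samples)

    def strata(self) -> pd.Series:
        return pd.Series({p: t.stratum for p, t in self.patients.items()}).sort_index()


def simulate_tree(n_asvs: int, seed: int) -> PhyloTree:
    """Random rooted bifurcating ASV tree with exponential branch lengths."""
    if n_asvs < 2:
        raise ValueError("need at least 2 ASVs for a tree")
    rng = np.random.default_rng(seed)
    nodes = [TreeNode(name=_asv_name(i, n_asvs)) for i in range(n_asvs)]
    for node in nodes:
        node.length = float(rng.exponential(0.1)) + 1e-3
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        right = nodes.pop(j)
        left = nodes.pop(i)
        parent = TreeNode(children=[left, right])
        parent.length = float(rng.exponential(0.1)) + 1e-3
        nodes.append(parent)
    root = nodes[0]
    root.length = None
    return PhyloTree(root)


def _asv_name(i: int, n: int) -> str:
    width = len(str(n))
    return f"ASV_{i + 1:0{width}d}"


def _genus_names(n_genera: int) -> list[str]:
    names = ["Streptococcus", "Prevotella_7"]
    names += [f"Genus_{i:02d}" for i in range(3, n_genera + 1)]
    return names[:n_genera]


@dataclass
class SyntheticCohort:
    """Everything the pipeline consumes, plus the generating truth."""

    table: FeatureTable
    meta: SampleMetadata
    taxonomy: pd.Series
    tree: PhyloTree
    arg: ARGPanel
    truth: SimulationTruth

    def write(self, outdir) -> None:
        """Emit the TSV/newick files the readers consume plus a manifest."""
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.table.write_tsv(out / "feature_table.tsv")
        self.meta.write_tsv(out / "metadata.tsv")
        write_taxonomy(self.taxonomy, out / "taxonomy.tsv")
        self.tree.write_newick(out / "tree.nwk")
        self.arg.write_tsv(out / "arg_panel.tsv")
        manifest = {k: v for k, v in asdict(self.truth.config).items()}
        manifest["raw_depth_range"] = list(manifest["raw_depth_range"])
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")


def _natural_transition(present, absent, churn, acq_scale, rng, protected=()):
    """One presence-churn step; expected acquisitions balance expected drops."""
    present, absent = list(present), list(absent)
    keep_mask = rng.random(len(present)) >= churn
    kept = {a for a, k in zip(present, keep_mask) if k or a in protected}
    dropped = set(present) - kept
    pool = [a for a in absent]
    p_acq = 0.0
    if pool:
        p_acq = min(1.0, churn * len(present) * acq_scale / len(pool))
    acq_mask = rng.random(len(pool)) < p_acq
    acquired = {a for a, m in zip(pool, acq_mask) if m}
    return kept | acquired, dropped, acquired


def simulate_cohort(config: CohortConfig | None = None) -> SyntheticCohort:
    """Generate a full synthetic cohort; deterministic for a fixed seed."""
    config = config or CohortConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_asvs
    asv_ids = [_asv_name(i, n) for i in range(n)]
    tree = simulate_tree(n, seed=int(rng.integers(2**31)))

    # --- taxonomy: skewed genus sizes, dominant airway genera first --------
    genera = _genus_names(config.n_genera)
    genus_w = np.sort(rng.lognormal(0.0, 1.2, size=config.n_genera))[::-1]
    genus_w /= genus_w.sum()
    sizes = np.ones(config.n_genera, dtype=int)
    sizes += rng.multinomial(n - config.n_genera, genus_w)
    genus_of = np.repeat(np.arange(config.n_genera), sizes)
    rng.shuffle(genus_of)
    taxonomy = pd.Series([genera[g] for g in genus_of], index=asv_ids, name="genus")

    # base ASV weight: genus weight split within genus with log-normal noise
    base_w = genus_w[genus_of] / sizes[genus_of] * rng.lognormal(0.0, 0.8, size=n)
    base_w /= base_w.sum()

    # --- patient assignments ----------------------------------------------
    width = len(str(config.n_patients))
    patients = [f"P{i + 1:0{width}d}" for i in range(config.n_patients)]
    order = rng.permutation(config.n_patients)
    n_increased = int(round(config.resistance_increase_fraction * config.n_patients))
    increased = {patients[i] for i in order[:n_increased]}
    n_pre = int(round(config.pre_azt_fraction * config.n_patients))
    placebo_first = {patients[i] for i in rng.permutation(config.n_patients)[:n_pre]}

    m_present = max(2, int(round(config.prop_present * n)))
    counts_rows: dict[str, np.ndarray] = {}
    meta_rows = []
    truth_patients: dict[str, PatientTruth] = {}
    sample_comp: dict[str, np.ndarray] = {}
    sample_density: dict[str, float] = {}
    arg_rows: dict[str, dict] = {}

    for patient in patients:
        stratum = "increased" if patient in increased else "stable"
        enriched_genus = "Streptococcus" if stratum == "increased" else "Prevotella_7"
        ptruth = PatientTruth(
            patient_id=patient,
            stratum=stratum,
            enriched_genus=enriched_genus,
            placebo_first=patient in placebo_first,
        )
        # patient-specific taxon preferences around the cohort base weights
        w_patient = base_w * rng.lognormal(0.0, config.patient_sigma, size=n)

        present_lrt = set(
            rng.choice(n, size=m_present, replace=False, p=w_patient / w_patient.sum())
        )
        n_drop = int(round(config.urt_dropout * m_present))
        dropped_urt = set(rng.choice(sorted(present_lrt), size=n_drop, replace=False))
        absent = sorted(set(range(n)) - present_lrt)
        n_extra = min(len(absent), int(round(config.urt_extra * n)))
        extra_urt = set(rng.choice(absent, size=n_extra, replace=False)) if n_extra else set()
        site_presence = {
            "LRT": present_lrt,
            "URT": (present_lrt - dropped_urt) | extra_urt,
        }
        ptruth.baseline_present = {
            s: frozenset(asv_ids[i] for i in p) for s, p in site_presence.items()
        }

        # per-site presence trajectories across the five phases
        enriched_mask = taxonomy.to_numpy() == enriched_genus
        arg_base = rng.lognormal(np.log(config.arg_base_norm), 0.5, size=len(ARG_GENES))
        density_mu = config.density_log10_mean + (
            config.density_increased_log10_shift if stratum == "increased" else 0.0
        )
        for site in SITES:
            presence = set(site_presence[site])
            all_absent = set(range(n)) - presence
            clearance = config.clearance_fraction * (
                1.0 if site == "LRT" else config.urt_clearance_scale
            )
            cleared_set: set = set()
            acquired_set: set = set()
            phase_presence = {}
            # protect the most abundant taxa from clearance (core community)
            ranked = sorted(presence, key=lambda i: -w_patient[i])
            protected = set(ranked[: config.n_core_protected])
            for k, phase in enumerate(PHASES):
                if phase == "PreAZT":
                    phase_presence[phase] = set(presence)
                    continue
                prev = phase_presence[PHASES[k - 1]]
                absent_now = set(range(n)) - prev
                if (PHASES[k - 1], phase) == TREATMENT_WINDOW:
                    candidates = sorted(prev - protected)
                    n_clear = min(len(candidates), int(round(clearance * len(prev))))
                    cleared_set = set(
                        rng.choice(candidates, size=n_clear, replace=False)
                    ) if n_clear else set()
                    pool = sorted(absent_now)
                    p_acq = 0.0
                    if pool:
                        p_acq = min(
                            1.0,
                            config.churn_rate
                            * len(prev)
                            * (1.0 - config.acquisition_suppression)
                            / len(pool),
                        )
                    acq_mask = rng.random(len(pool)) < p_acq
                    acquired_set = {a for a, m_ in zip(pool, acq_mask) if m_}
                    phase_presence[phase] = (prev - cleared_set) | acquired_set
                else:
                    burst = config.post_burst if PHASES[k - 1] == "EndAZT" else 1.0
                    # cleared taxa stay out until the last phase (partial resilience)
                    blocked = cleared_set if phase != "PostAZT_ge3mo" else set()
                    pool = absent_now - blocked
                    nxt, _, _ = _natural_transition(
                        prev, pool, config.churn_rate, burst, rng, protected
                    )
                    if phase == "PostAZT_ge3mo" and cleared_set:
                        # only a resilience_fraction of cleared taxa may return
                        returned = nxt & cleared_set
                        n_allow = int(round(config.resilience_fraction * len(cleared_set)))
                        drop_back = sorted(returned)[n_allow:]
                        nxt -= set(drop_back)
                    phase_presence[phase] = nxt
            ptruth.cleared[site] = frozenset(asv_ids[i] for i in cleared_set)
            ptruth.acquired[site] = frozenset(asv_ids[i] for i in acquired_set)
            ptruth._start_presence[site] = frozenset(
                asv_ids[i] for i in phase_presence["StartAZT"]
            )

            for phase in PHASES:
                if phase == "PreAZT" and patient not in placebo_first:
                    continue
                sample_id = f"{patient}_{site}_{phase}"
                pres = sorted(phase_presence[phase])
                w = w_patient[pres].copy()
                if config.genus_enrichment != 1.0 and phase in (
                    "EndAZT",
                    "PostAZT_1mo",
                    "PostAZT_ge3mo",
                ):
                    w = w * np.where(enriched_mask[pres], config.genus_enrichment, 1.0)
                comp_phase = w / w.sum()
                alpha = config.persistence_kappa * comp_phase
                comp = rng.dirichlet(np.maximum(alpha, 1e-6))
                depth = int(rng.integers(*config.raw_depth_range))
                counts = np.zeros(n, dtype=np.int64)
                counts[pres] = rng.multinomial(depth, comp)
                counts_rows[sample_id] = counts
                full_comp = np.zeros(n)
                full_comp[pres] = comp_phase
                sample_comp[sample_id] = full_comp
                meta_rows.append(
                    {
                        "sample_id": sample_id,
                        "patient_id": patient,
                        "site": site,
                        "phase": phase,
                        "time_months": PHASE_MONTHS[phase],
                    }
                )
                if site == "LRT":
                    density = float(10 ** rng.normal(density_mu, config.density_log10_sd))
                    sample_density[sample_id] = density
                    fold = 1.0
                    if stratum == "increased" and phase in (
                        "EndAZT",
                        "PostAZT_1mo",
                        "PostAZT_ge3mo",
                    ):
                        fold = config.arg_fold_increase
                    noise = rng.lognormal(0.0, 0.25, size=len(ARG_GENES))
                    norm_vals = arg_base * fold * noise
                    row = {"copies_16s": density}
                    row.update(
                        {g: v * density for g, v in zip(ARG_GENES, norm_vals)}
                    )
                    arg_rows[sample_id] = row
        truth_patients[patient] = ptruth

    table = FeatureTable(
        pd.DataFrame.from_dict(counts_rows, orient="index", columns=asv_ids)
    )
    meta = SampleMetadata(pd.DataFrame(meta_rows))

    if config.n_low_depth:
        # deliberately push a few URT samples below the rarefaction threshold
        urt_ids = [s for s in table.sample_ids if "_URT_" in s]
        low = rng.choice(urt_ids, size=min(config.n_low_depth, len(urt_ids)), replace=False)
        data = table.data.copy()
        for sid in low:
            row = data.loc[sid].to_numpy()
            target = config.rarefaction_depth // 2
            data.loc[sid] = np.random.default_rng(
                int(rng.integers(2**31))
            ).multivariate_hypergeometric(row, target)
        table = FeatureTable(data)

    arg = ARGPanel(pd.DataFrame.from_dict(arg_rows, orient="index"))
    truth = SimulationTruth(
        config=config,
        patients=truth_patients,
        sample_composition=sample_comp,
        sample_density=sample_density,
    )
    return SyntheticCohort(
        table=table, meta=meta, taxonomy=taxonomy, tree=tree, arg=arg, truth=truth
    )
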