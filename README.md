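# azairway

Longitudinal, paired-site analysis of the airway microbiota under macrolide
(azithromycin) treatment, built for 16S rRNA gene amplicon cohorts in which
each patient is sampled at two sites — lower respiratory tract (LRT, sputum)
and upper respiratory tract (URT, oropharyngeal swab) — across five
treatment phases (`PreAZT`, `StartAZT`, `EndAZT`, `PostAZT_1mo`,
`PostAZT_ge3mo`). The package targets researchers studying how a prolonged
antibiotic course reshapes airway communities, for example in idiopathic
pulmonary fibrosis, where a dense, low-turnover lower-airway microbiota is a
marker of disease.

## What it computes

Given an ASV count table, sample metadata, a rooted ASV phylogeny, a
genus-level taxonomy map and a qPCR antibiotic-resistance-gene (ARG) panel:

* **Alpha diversity** on tables rarefied to a common depth (default
  10 055 reads): bias-corrected Chao1
  `S_obs + f1(f1−1)/(2(f2+1))`, Shannon `H = −Σ pᵢ ln pᵢ`, Camargo evenness
  `E = 1 − Σ_{i<j}|pᵢ−pⱼ|/S`, and Faith's phylogenetic diversity (total
  branch length subtending the observed ASVs). Phases are compared with the
  Kruskal–Wallis test, Dunn's post hoc z-tests and Holm's step-down
  adjustment; paired contrasts use the Wilcoxon signed-rank test.
* **Beta diversity**: unweighted and (normalized) weighted UniFrac on the
  rooted tree; principal coordinate analysis with Lingoes correction for
  non-Euclidean matrices; one-way PERMANOVA with 999 seeded permutations
  (optionally restricted within patients); the per-phase distance of each
  URT sample to the centroid of the sputum samples in corrected PCoA space;
  and double principal coordinate analysis (DPCoA) on the most abundant
  genera, which places samples at the abundance-weighted centroids of
  phylogenetically embedded genera.
* **Turnover**: per patient and site, ASVs are classified over a treatment
  window as retained, cleared (no reads at the window end) or acquired (no
  reads at the window start); site overlap (LRT-only / URT-only / shared)
  is tested with a chi-squared goodness-of-fit test, and the community share
  of cleared or acquired sets is tracked across all phases.
* **Resistome**: qPCR copy numbers of seven ARGs — erm(B), erm(F), mel,
  msr(E), mef, tet(M), tet(W) — are normalised to 16S rRNA gene copies,
  min–max scaled per gene across the analysis set, and summed into a
  cumulative carriage score (0–7); patients are stratified into stable vs
  increased carriage at the cohort-median fold change of that score over
  treatment.
* **Synthetic cohorts**: a seed-controlled Dirichlet-multinomial generator
  emulates the full study design (24 patients, paired sites, five phases,
  per-patient persistence, treatment-induced clearance and acquisition
  suppression, genus enrichment, ARG increase in a patient subset) and
  records the ground truth, so every stage can be validated by parameter
  recovery without any external data.

## Worked example

```python
import numpy as np
import azairway as az

cfg = az.CohortConfig(seed=1)          # default study conditions
cohort = az.simulate_cohort(cfg)

lrt = cohort.table.filter_samples(
    cohort.meta.data[cohort.meta.data["site"] == "LRT"].index)
rare = az.rarefy(lrt, cfg.rarefaction_depth, seed=1).table

tidy = az.alpha_diversity_table(rare, cohort.meta, cohort.tree, metrics=("chao1",))
print(tidy.groupby("phase")["value"].median().round(1))

test = az.compare_groups(tidy["value"].to_numpy(), tidy["phase"].to_numpy())
print(f"Kruskal-Wallis H = {test.statistic:.1f}, p = {test.pvalue:.2e}")

turn = az.classify_cohort_turnover(rare, cohort.meta, "LRT", "StartAZT", "EndAZT")
print(f"mean cleared fraction: {np.mean([t.cleared_fraction() for t in turn]):.3f}")

strata = az.stratify_resistance(cohort.arg, cohort.meta)
print(f"median ARG fold change: {strata.median_fold_change:.2f}")
```

prints

```
phase
EndAZT           156.2
PostAZT_1mo      183.5
PostAZT_ge3mo    175.1
PreAZT           180.0
StartAZT         180.8
Name: value, dtype: float64
Kruskal-Wallis H = 53.6, p = 6.25e-11
mean cleared fraction: 0.210
median ARG fold change: 2.90
```

Median Chao1 richness in the lower airway drops at the end of treatment
(156 vs ~180 ASVs before) and partially recovers afterwards; the omnibus
test detects the phase effect; about 21% of each patient's observed ASVs
are cleared over the treatment window (the generator planted 20%); and the
cohort splits at its median ARG fold change into stable and increased
carriage groups.

The same pipeline runs from the shell:

```sh
azairway all --out results/ --seed 1
```

which writes the simulated cohort plus per-stage TSV outputs (alpha
diversity and tests, UniFrac distance matrix, PCoA coordinates, PERMANOVA,
URT-to-sputum-centroid distances, turnover classifications, site-overlap
Venn counts, ARG scores and strata) and a run log with all seeds.

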