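# Methods

## Study design assumed by the pipeline

The package analyses a longitudinal, paired-site amplicon cohort: each
patient contributes sputum (LRT) and oropharyngeal-swab (URT) samples over
five phases relative to a 3-month azithromycin course — `PreAZT` (available
only in patients who received placebo first in the crossover design),
`StartAZT`, `EndAZT`, `PostAZT_1mo` and `PostAZT_ge3mo`. All presence-based
analyses run on a table rarefied to a common depth so that "no reads"
means the same thing in every sample; the depth defaults to 10 055 reads
and samples below it are dropped and reported.

Rarefaction is a single multivariate-hypergeometric draw per sample (no
averaging over repeated draws), with a user-supplied seed logged in every
output. Presence everywhere downstream means at least one read in the
rarefied table.

## Diversity metrics

* **Chao1** is the bias-corrected form `S_obs + f1(f1−1)/(2(f2+1))` with
  `f1`/`f2` the singleton/doubleton counts, so it is defined when `f2 = 0`
  and equals observed richness when there are no singletons.
* **Shannon** uses the natural logarithm.
* **Camargo evenness** is computed over the observed (nonzero) ASVs only:
  `E = 1 − Σ_{i<j}|pᵢ−pⱼ|/S`. The implementation uses the sorted-order
  identity for the pairwise sum; a single-ASV sample has `E = 1`.
* **Faith's PD** follows the rooted convention: the stem between the root
  and the MRCA of the observed taxa is included (`include_root=False`
  excludes it). It is computed as the union of root-ward paths of the
  observed leaves, which also handles multifurcating (e.g. star) trees.

Group comparison is the Kruskal–Wallis omnibus (tie-corrected; all-tied
data are defined as statistic 0, p = 1 rather than an error), Dunn's
pairwise z-tests with tie-corrected rank variance, and Holm's step-down
adjustment applied across the pairwise comparisons of one metric-site
family (the multiplicity family is not uniquely dictated by the design;
per metric-site was chosen as the narrowest family actually interpreted
together). Paired data use the two-sided Wilcoxon signed-rank test with
zero differences dropped and at least five informative pairs required.

## Distances, ordination and tests

Unweighted UniFrac is the unique-branch fraction of the observed branch
length; weighted UniFrac is `Σ_b L_b |P_a(b) − P_b(b)|` and defaults to the
normalized variant so both metrics live on [0, 1]. Both are evaluated on
the rooted tree via scikit-bio, with input validation (leaf coverage,
non-negative counts, tree invariants) done by this package so that
multifurcating trees are accepted.

PCoA is classical Gower double-centring with an eigendecomposition.
Negative eigenvalues beyond a relative tolerance of 1e-8 trigger the
Lingoes correction (adding twice the magnitude of the most negative
eigenvalue to all squared off-diagonal distances), and the applied
correction is flagged in the result. Axes with eigenvalues at or below the
tolerance are dropped; proportions explained are relative to the positive
eigenvalue sum.

PERMANOVA is the one-way pseudo-F over squared distances with permutation
p-values under the `(1 + exceedances)/(1 + permutations)` convention
(never zero) and a fixed seed; 999 permutations by default. Labels are
permuted freely, as nothing in the design forbids it, but a within-patient
strata option is provided for sensitivity analyses.

The spatial-dissimilarity statistic embeds all samples of one phase by
corrected PCoA, takes the coordinate mean of the sputum samples as the
centroid, and reports each URT sample's Euclidean distance to it. The
centroid is defined in embedding space (the dispersion-analysis
construction) because UniFrac space is non-Euclidean: a mean community
profile would not be distance-consistent. Embeddings are per phase, since
the statistic is defined per treatment phase.

DPCoA restricts the genus table to the `k` most abundant genera (default
15; ties in mean relative abundance broken lexicographically), embeds the
genera so that their squared Euclidean distances equal the supplied
pairwise dissimilarities (Lingoes-corrected and flagged when that embedding
does not exist), places each sample at the relative-abundance-weighted
centroid of its genus points, and rotates onto principal axes weighted by
sample totals. With this convention the squared inter-sample distance
equals the Rao dissimilarity `2Q(mix) − Q(a) − Q(b)` with the supplied
dissimilarities as `δ`; in the equal-dissimilarity limit `δ ≡ d` it reduces
to `(d/2)·Σ(pᵢ−qᵢ)²`, which the tests verify to 1e-8. Genus
dissimilarities default to mean inter-genus patristic distance.

## Turnover and resistome

Turnover windows default to `StartAZT → EndAZT` (treatment) and
`PreAZT → StartAZT` (the 3-month no-treatment contrast available in
placebo-first patients). Retained/cleared/acquired are exact set
partitions of window-start and window-end presence, asserted on every run.
Patients missing either paired sample are skipped with a log record. The
chi-squared goodness-of-fit test defaults to uniform expected proportions,
with a configurable expected vector. Because presence is evaluated on
rarefied counts, taxa near the detection limit can be misclassified as
cleared or acquired; this is an inherent property of presence-based
turnover at finite depth.

ARG scoring: per-gene copy numbers are divided by 16S rRNA gene copies,
min–max scaled per gene across all samples in the analysis set (not per
phase, since one longitudinal score per sample is the endpoint), and
summed; genes with zero range contribute 0. Stratification uses the fold
change of the cumulative score between `StartAZT` and `EndAZT` sputum
samples; "median change" is interpreted as a ratio (a difference mode is
retained). A zero start score is handled by adding the smallest positive
cumulative score in the cohort to numerator and denominator. Patients above
the cohort median are "increased", at or below "stable", which yields an
even split for even cohorts with distinct fold changes; all-tied cohorts
go entirely to "stable" with a warning.

## Synthetic cohort generator

The generator emulates the statistical structure the pipeline assumes,
with defaults chosen as the study conditions: 24 patients, 300 ASVs in 30
genera with skewed sizes (the two largest labelled Streptococcus and
Prevotella_7), two sites, five phases, raw depths of 12 000–20 000 reads,
rarefaction depth 10 055, and PreAZT present in half the cohort.

Each patient has a baseline composition built from cohort-level genus
weights with patient-specific log-normal taxon preferences; ~60% of ASVs
are present per patient, with the URT derived from the LRT by dropping 25%
of taxa (lower-airway richness exceeds upper in this population) and
adding 5% URT-only taxa. Between phases, presence churns naturally at rate
0.3 with acquisitions balanced to keep richness stationary. Over the
treatment window a planted fraction of present taxa (default 0.2 in the
LRT, 60% of that in the URT) is cleared — excluding the ten most abundant
taxa, since treatment does not primarily target the dominant core — and
acquisitions are suppressed by 75%; the month after treatment has a 1.5×
acquisition burst, and only 20% of cleared taxa may return by the final
phase. The designated genus (Streptococcus in the increased-resistance
subset, Prevotella_7 otherwise) is enriched 3-fold from the end of
treatment. Counts are Dirichlet-multinomial: the phase composition is
resampled per sample with concentration `κ = 2000` and read counts drawn
multinomially. κ was set so that within-patient replicate noise is
moderate and, in particular, every truly present taxon has a Dirichlet
concentration comfortably above the detection limit at the rarefaction
depth — with much smaller κ, presence truth is not identifiable from
rarefied counts and recovery of the planted clearance fraction is
systematically inflated.

ARG panels are generated for sputum samples: bacterial density is
log-normal (median 2×10⁵ 16S copies·µL⁻¹, 0.45 log₁₀ SD), shifted
−0.6 log₁₀ in the increased subset; per-gene normalised carriage has a
per-patient log-normal baseline around 10⁻⁴ and is multiplied 4-fold from
the end of treatment in the increased subset.

`CohortConfig.null()` removes every treatment effect (clearance equals the
natural churn, no suppression, burst or enrichment, full resilience, no
ARG or density shift) so that phases are exchangeable; it is used to check
test size. Note one subtlety found during design: a null generator must
allow window-churned taxa to return like any other absent taxon —
forbidding their return depresses late-phase richness and manufactures a
spurious treatment effect.

The generator does **not** emulate: sequencing error, chimeras or
contamination; taxonomic misassignment; crossover carry-over effects;
correlated phylogenetic structure between genus membership and the
simulated tree (taxonomy is assigned independently of the topology); or
the real data's irregular missingness (only PreAZT availability and an
optional count of deliberately shallow samples are modelled). Passing
recovery tests therefore demonstrates that the pipeline measures what the
generator plants under realistic count noise — not that real airway data
satisfy these distributional assumptions.

## Problem sizes and numerical choices

Recovery checks run 50 replicates of the full default cohort per
condition; the acceptance script uses 25 replicates per quantity. Metric
oracles use 100 random instances of ≤ 10 ASVs at 1e-10 agreement;
geometry oracles use planted configurations at 1e-8; permutation oracles
enumerate all label assignments at n ≤ 8. Distance matrices are symmetrised
and clipped at ±1e-12 to absorb floating-point asymmetry; the null
generator's rejection-rate check allows [0, 0.12] around the nominal 5%
(two binomial standard errors at 50 replicates, with repeated-measures
correlation expected to push the realised rate below nominal).

## Known limitations

* The Dunn/Holm family choice (per metric-site) is one of several
  defensible conventions; switching families changes adjusted p-values.
* Permutation p-values are lower-bounded at `1/(n_perm+1)`; small groups
  bound attainable significance (e.g. two groups of three cannot reach
  p < 0.1 under free permutation).
* Min–max ARG scaling depends on the composition of the analysis set;
  adding samples rescales scores, so scores are comparable only within one
  analysis set.
* Fold-change stratification with the zero-start pseudocount is exact when
  all start scores are positive but compresses extreme ratios when many
  start scores are zero.
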