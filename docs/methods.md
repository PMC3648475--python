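# Methods

## Problem and approach

The package asks whether germplasm selected purely on collection-site
climate ("dry" 300–550 mm/yr vs "wet" > 800 mm/yr origins) differs in
measurable leaf morpho-physiology, i.e. whether ecotypic differentiation
driven by moisture availability is detectable. Two complementary analyses
operate on the same accession-level trait table: univariate pooled
t-tests per trait, and a multivariate learning-based harness that tries
to recover set membership from the traits alone.

## Set construction

Dry-set algorithm, in order, with per-stage conservation accounting
(input = kept + dropped at every stage):

1. **Rain band.** Keep accessions whose site precipitation lies in the
   closed interval [300, 550] mm/yr. The rule is stated as an exclusion
   ("below 300 or greater than 550 not considered"), so the bounds
   themselves are retained; the wet-set rule "over 800" is read strictly.
2. **One per site.** One accession per collection site, drawn uniformly.
   Sites are visited in sorted order and candidates sorted by id before
   the draw, so the result is a pure function of the seed.
3. **Clustering.** Agglomerative hierarchical clustering of the retained
   accessions on the eight climate variables, average ("between-groups")
   linkage over squared Euclidean distances, dendrogram cut at k = 20
   (a configuration default, not a constant). The eight variables span
   four orders of magnitude, so they are z-scored first by default
   (toggleable, `standardize_before_clustering`); unstandardized squared
   Euclidean distance would be dominated by the precipitation variables.
4. **Aridity pruning.** Drop clusters whose mean aridity index is above
   0.6 or below 0.1 (the latter indicating likely irrigated sites).
   Strict inequalities: a cluster mean exactly at a bound survives.
5. **Seasonality filter.** Discard accessions with bio15 ≤ 50
   (low seasonal variation in rainfall).
6. **Round-robin pick.** Within each surviving cluster rank by ascending
   precipitation (ties by accession id); cycle clusters in ascending
   cluster-id order taking each cluster's next accession; skip exhausted
   clusters; stop at 201 picks or exhaustion (short sets are returned
   with a warning, not an error).

All tie-breaks are by accession id, making the whole selection
deterministic given (collection, config, seed). An independent audit pass
(`audit_set`) re-derives every predicate from the raw collection and is
run in the tests and the stage reports.

## Trait derivation

Ratio and product traits (SA, SAAL, WUE, RWC, temperature depressions)
are computed per replicate and then averaged per accession: the mean of
per-plant products is not the product of means, and the reference set
means follow the replicate-first convention. Replicate-level leaflet area
is the mean of up to four leaflets per plant. Missing replicates are
tolerated (mean over those available, count recorded); an accession needs
at least one replicate per trait. Where raw gas-exchange measurements
exist at two dates they are expected pre-averaged into one value per
replicate (the analysis uses a single value per trait).

Seed-size classes: the class bounds are conventional *V. faba*
botanical-variety mass ranges — minor < 0.5 g ≤ equina < 1.0 g ≤ major —
with seed length as tie-breaker at a bound. These numeric bounds are an
assumption of this package (the tradition defines the classes by seed
length and mass without universal cut-offs) and are fully configurable.

## Set comparison

Pooled (Student) two-sample t with df = n_wet + n_dry − 2, matching the
reported df = 400 at 201 accessions per set; Welch's correction is
deliberately not used. Sample (n−1) standard deviations throughout. The
summary-statistic path and the raw path agree algebraically; reproducing
reported t values from printed summaries tolerates ±2.5% relative error,
the slack implied by two-significant-figure rounding of printed SDs.
Shapiro–Wilk normality screening is reported but never blocks the test
(all 16 traits are tested regardless). No multiple-testing correction.

Two reference rows are excluded from numeric t reproduction: the reported
t for leaflet temperature (34.98) and canopy temperature (13.77) are not
recoverable from the reported means/SDs under any standard two-sample
formula (the pooled formula gives ≈ 21.4 and ≈ 8.6). The package reports
the recomputed values and flags the discrepancy in
`reference.TRAIT_SUMMARY` (`t_reproducible=False`). Similarly, the
transpiration contrast is taken from the summary table (dry +0.16,
nominally higher), not from the prose, which describes it inconsistently.

## Classification harness

Accession-level data for both sets are combined and standardized to
mean 0, SD 1 (sample SD) before splitting — standardization is part of
the data preparation, not re-estimated per fold. Each of the 10 runs
draws a uniform random 2/3–1/3 partition (|train| = round(2n/3)); each
family is fitted on the train fold and scored on the held-out third.

Model defaults (all overridable): random forest with 500 trees and
√p candidate predictors per node; RBF SVM with γ = 1/p and C = 1 (after
standardization the features have unit variance, so this matches the
common variance-scaled default); CART with cost-complexity pruning
(ccp_alpha = 0.01, the conventional pruning default). Classification
threshold: probability ≥ 0.5, or decision value ≥ 0 for the SVM, with
the dry set as the positive class. AUC uses the continuous score and is
rank-invariant to its scale, so calibrated probabilities are not needed.

Metric kernels are implemented in-package: AUC in the midrank
(Mann–Whitney) form, which equals the trapezoidal area under the ROC and
the pairwise-ordering probability with ties counted half; sensitivity /
specificity / omission (= 1 − sensitivity) / correct classification rate
from the confusion matrix; Cohen's kappa with chance agreement from the
marginal products (defined as 0 when expected agreement is 1). Run
summaries report mean, lower and upper per metric, where lower/upper are
the min/max over the runs.

Variable importance is defined for the tree families only: random-forest
Gini (impurity-decrease) importance, permutation importance (mean
decrease in accuracy, floored at 0 since negative values are sampling
noise), and single-tree impurity importance. The headline rank follows
the forest Gini importance; the absolute scores depend on implementation
normalization and are not comparable across packages — only orderings
are meaningful here.

## Synthetic data generator

The generator emulates the study conditions, not any real genebank.

**Climate.** A configurable mixture of site regimes: dry-band sites
(precipitation uniform on [300, 550] mm/yr; bio15 ~ N(62, 14²) straddling
the 50 cut; aridity ~ N(0.35, 0.14²) straddling the 0.1/0.6 pruning
bounds), wet sites (uniform (800, 1500]; aridity ~ N(0.85, 0.25²)), and
out-of-band sites below the dry band and between the bands, so every
selection branch is exercised. Default: 2,000 sites, 50% dry / 30% wet,
1–3 accessions per site. Temperatures, bio4, bio16 and bio19 are drawn
so the physical invariants (tmax ≥ tmin, bio16 ≤ precyr) hold by
construction. There is no spatial autocorrelation and no dependence
between the climate variables beyond these constraints — real bioclim
surfaces are strongly intercorrelated, so passing selection tests here
says nothing about the geographic realism of cluster shapes.

**Traits.** Per set, accession-level latent vectors are drawn from a
multivariate normal with the bundled reference means and SDs for the 16
variables — independent marginals by default. Each accession gets 4
replicate observations = latent + Gaussian noise with SD equal to 0.5×
the between-accession SD (the within-accession spread was not reported;
0.5 is a modest repeatability assumption and only accession-level
statistics are validated). Default sizes reproduce the reference design:
201 + 201 accessions × 4 replicates = 1,608 replicate rows. Non-negative
traits are truncated at 0 (RWC additionally at 100) by marginal redraw,
which keeps means unbiased to first order; redraw counts are logged.
Fertile tillers are rounded to whole counts per replicate. Seed classes
are drawn per accession from per-set mixtures (dry 0.75/0.125/0.125,
wet 0.20/0.40/0.40 for major/equina/minor).

**Correlations.** Independence is the default. An optional preset injects
leaflet-area–RWC r = +0.54 and RWC–canopy-depression r = +0.73 (the
square roots of pooled R² ≈ 0.29 and 0.54 reported for this system). The
pooled sign of the RWC–canopy association conflicts with the between-set
mean structure (the dry set pairs *higher* RWC with *cooler* canopies),
so no single homogeneous within-set correlation can reproduce both; the
preset is a documented choice, not a resolution.

**What passing tests show.** With independent normal traits the
separation between the sets is governed by D² = Σᵢ dᵢ² over the 16
standardized mean differences (D ≈ 3.0 at the defaults, Bayes-optimal
AUC ≈ Φ(D/√2) ≈ 0.98). Harness results on this generator therefore
validate the machinery — splitting, fitting, scoring, ranking — under
the reference effect sizes, not the biological claim itself: real trait
data are correlated, non-normal (seed-class mixtures induce multimodality)
and heteroscedastic in ways the default generator does not emulate.

## Numerical conventions

- Sample (ddof = 1) SDs everywhere.
- Collections iterate in accession-id order; all "random" choices flow
  from explicit seeds through `numpy.random.default_rng`.
- CSV I/O: comma, decimal point, UTF-8, header mandatory; floats written
  with 17 significant digits and read with round-trip parsing, so
  read∘write is the identity.
- Constant trait columns are dropped (with a record) before
  standardization.
- Cluster counts below k can occur only for degenerate tied data; inputs
  with |collection| < k are a configuration error.

## Limitations

- The aridity index is consumed as an opaque number; no particular
  formulation (e.g. precipitation/PET) is assumed.
- Absolute variable-importance scores are implementation-relative; only
  ranks are stable reproduction surfaces.
- The harness is binary (wet/dry) by design; no multiclass support.
- The generator draws each climate variable independently within a
  regime; selection results on it exercise correctness, not geography.
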