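# Methods

This note records the models, numerical choices and limitations behind
`benthosom`.  Everything stated here is computed by the test suite or the
acceptance script; nothing is an external claim.

## Data model and transforms

The community matrix holds raw densities (individuals/m²) per site visit
and taxon, with per-site biomass (g/m²) and lake/season metadata; the
environment matrix holds 13 water variables in field units.  Missing
values are refused rather than imputed — downstream permutation tests and
ordinations assume complete cases, and silent imputation would change
their null distributions.

Two transforms are used, each where linear Euclidean machinery needs it:

* **ln(x+1)** for abundances (zeros are ubiquitous in count data) before
  SOM training and the DCA check; **ln(x)** for environmental variables
  before PCA/RDA, with pH exempt because it is already a log-scale
  quantity.  Natural logarithms throughout.
* **Hellinger** (square root of row-relative abundance) before RDA, so
  that Euclidean distances on the transformed data approximate a
  composition-appropriate distance and the linear ordination is defensible
  for species data.

## SOM

Batch training: each epoch assigns every site to its best-matching unit
(BMU) and replaces each codebook vector by the Gaussian-kernel-weighted
mean of the sites, the kernel acting on lattice distance.  Batch rather
than online training makes the fit deterministic given the seed and
independent of presentation order.  Defaults: hexagonal lattice, 100
rough + 200 fine epochs, neighbourhood radius decaying linearly from
max(rows, cols)/2 to 0.5 during the rough phase and held there during the
fine phase.  The codebook initializes on the seeded random span of the
first two principal components — on small surveys (tens of sites) random
sampling initialization is noticeably less stable.

Output-layer size: round(5·√n) neurons as a target (43 at n = 74), then
near-square factorizations with 0.8–1.3× that many neurons are trained and
ranked by rank(QE) + rank(TE); the smallest grid wins ties.  A rank sum is
used because QE and TE are on incommensurable scales and no weighting
between them is canonical.

## Group number: K-means + SSI

K-means (best of 100 k-means++ restarts) clusters the codebook neurons,
and the Simple Structure Index picks k over 2–10.  The SSI implemented is
the weighted ("ssiw") cascade-K-means variant: per feature, the span
between the extreme cluster centers, down-weighted by the deviation of the
cluster-mean level from the grand mean, scaled by the geometric mean of
the two contrasting clusters' sizes, averaged over features and
normalised so the score is comparable across k.  Ties break toward
smaller k.

Two deliberate choices depart from the naive "cluster all neurons"
recipe:

* only **occupied** neurons (BMU of at least one site) are clustered.
  Unoccupied neurons are interpolation artifacts of the neighbourhood
  kernel that sit between data regions; including them builds bridges
  between genuine clusters and inflates the optimal k.
* SSI cluster sizes are counted in **mapped sites**, not neurons, so the
  size element reflects sampling events rather than map geometry.

On synthetic five-group data at the default effect sizes this chain
selects k = 5 in ≥ 80 % of seeds with median adjusted Rand index ≥ 0.8
(the acceptance suite runs 25 seeds); with all neurons and neuron-count
sizes the SSI curve keeps rising past the planted k.  Unoccupied neurons
are attached to the nearest cluster center afterwards so every neuron
carries a label.

## IndVal

Specificity uses group means of raw densities (A_ij = mean_ij / Σ_g
mean_ig), fidelity uses presence/absence occupancy, IndVal = A·B·100.
Raw densities are used deliberately: the transforms exist for the
Euclidean methods, and IndVal's ratio structure is already
scale-invariant per species.  The species-level statistic is the maximum
IndVal over groups; whole sites are permuted; the add-one estimator
p = (1 + exceedances)/(1 + n_perm) keeps p strictly positive.  The
indicator threshold is **inclusive** (IndVal ≥ 50) and configurable;
species significant below the threshold are flagged separately
("sub-50"), as survey reports conventionally list them.  Reported p are
raw, not multiplicity-adjusted, matching how indicator tables are
conventionally printed; a BH adjustment is available via
`benjamini_hochberg` if wanted.

## Diversity indices

Shannon H′ in nats (natural log; a base flag exists), Pielou J = H′/ln S
reported as missing when S ≤ 1 (division by ln 1 is undefined; a
one-species community has no evenness).  Summaries use the sample (n−1)
SD; single-observation levels report SD 0 with n = 1 flagged.

## Ordination battery

**PCA** is an eigendecomposition of the correlation matrix, so
eigenvalues sum to the number of variables p and each axis explains
eigenvalue/p — the convention under which an eigenvalue of 3.10 among 13
variables is 23.8 % of the variance.

**DCA gradient length.** Correspondence analysis by reciprocal averaging
gives the first axis; the axis is rescaled so that the abundance-weighted
mean within-site SD of species scores equals one (a "species turnover"
unit), and the gradient length is the range of site scores.  This one-pass
rescaling tracks the true gradient length of simulated coenoclines within
~10 % across 1–10 SD, which is ample for the only decision it feeds: below
4 SD the pipeline runs the linear RDA, above it stops with a unimodal
recommendation.  Detrending-by-segments is not implemented because it
only affects axes ≥ 2, which nothing downstream consumes.  The pipeline
measures the gradient on the same ln(x+1) matrix the ordination models;
raw counts of high-contrast communities overstate turnover.

**RDA** is the PCA (via SVD) of the fitted values of the multivariate
regression of the centered Hellinger community on standardized
predictors, eigenvalues scaled by 1/(n−1) and proportions taken against
the total variance of Y.  Species scores use correlation-biplot (type 2)
scaling; variable scores are correlations of the predictors with the
constrained site scores.  Collinearity is screened first: variables with
VIF = 1/(1−R²) above 10 are dropped iteratively, worst first.

**Forward selection** adds, per step, the candidate with the largest
additional constrained variance, admitting it only if its conditional
pseudo-F beats a permutation null in which residuals of the reduced model
are permuted and the **maximum** pseudo-F over all remaining candidates
is recorded.  Testing the best candidate against a best-candidate null is
what keeps the inclusion decision level-α under the global null (measured
inclusion rate ≈ 0.02–0.04 at α = 0.05 over 500 null replicates in the
acceptance suite); testing it against its own marginal null — as common
implementations do — is anti-conservative at exactly this step.  Axis
significance uses marginal row permutations of Y.

## Group-wise and correlation tests

Kruskal–Wallis uses the tie-corrected H with a χ²(k−1) reference; when
all values are identical H = 0 and p = 1 by convention.  At n = 6 the χ²
approximation lands within 0.2 of the exact permutation tail; the test
suite pins this.  Post-hoc letters come from Dunn-type pairwise rank z
statistics (tie-corrected pooled variance), BH-adjusted, rendered as a
compact letter display via maximal cliques of the non-significance graph,
so two groups share a letter iff their difference is not significant.
Spearman rho is ranked Pearson with average ranks; p from the two-tailed
t transform; the 5 × 13 screen adjusts p within each community index's 13
tests (matching the per-index layout of survey reports; a global option
exists).

## Synthetic generator

The generator is the package's ground-truth instrument, emulating the
study scale: 74 site visits (13 lakes × 3 seasons), 44 taxa in the six
higher groups (23 insects, 10 gastropods, 4 bivalves, 4 oligochaetes,
2 leeches, 1 crustacean), 13 environmental variables, 5 planted groups of
14–15 sites.  Per group, 4 indicator taxa occur with probability
B* = 0.9 in-group and B*(1−A*) = 0.09 out-group (A* = 0.9), with in-group
negative-binomial mean 8× the 20-count baseline (dispersion k = 1,
overdispersed as benthic counts are); non-indicator taxa share one mean
everywhere (occupancy 0.6).  Counts are multiplied by 16, the density
quantum of one 0.0625 m² Petersen grab.  Environmental variables start at
field-realistic baselines (pH ≈ 8.5 ± 0.3, conductivity ~600 µS/cm) and
six of them (WT, DO, pH, COND, TP, Chla) receive group-mean shifts of up
to ±1 × the 0.3 log-SD scale (env_effect_size = 2 spans the group range);
per-site biomass is the abundance-weighted sum of per-taxon mass draws so
mollusc-rich sites are heavy.

What the generator does **not** emulate: spatial/seasonal autocorrelation
(lake and season labels are assigned independently of group), calibrated
absolute densities (totals run higher than typical lake surveys; every
downstream statistic that matters — Shannon, Hellinger, IndVal ratios,
rank tests — is insensitive to the overall scale), taxon-specific
abundance distributions, or gradients in the strict coenocline sense.
Passing recovery tests therefore shows the chain detects planted
group/indicator/environment structure of the stated strength under
overdispersed noise, not that it would resolve weaker or spatially
confounded structure in real surveys.

## Problem sizes and determinism

Default analyses run at the study scale (74 × 44, 999 permutations) in
seconds.  The validation suites use 500 null replicates with 99
permutations each for the level-α checks and 25 seeds for
planted-structure recovery; these sizes give Monte Carlo SEs comfortably
inside the asserted margins.  A single run seed fans out to per-stage
seeds through a BLAKE2 hash (all < 2³¹), so any stage can be replayed in
isolation; identical seeds give bit-identical outputs.

## Known limitations

* The SSI is one of several published cluster-validity indices; its
  normalisation constants differ among implementations.  The variant here
  is pinned by explicit equations and a hand-computed test case.
* The DCA rescaling is one-pass, not Hill's iterative segment-wise
  algorithm; gradient lengths near the 4 SD boundary (± ~10 %) could be
  decided differently by other software.
* Forward selection's max-F null is deliberately conservative relative to
  per-candidate testing; with highly collinear "true" predictors it will
  select fewer variables than marginal-test implementations.
* The Kruskal–Wallis χ² reference is coarse below ~8 observations; an
  exact test is not provided because the pipeline's group sizes are ≥ 10.
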