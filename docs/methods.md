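# Methods

## Dendritic network model

A river network is a strict rooted tree of reaches directed toward a single
outlet; every node except the outlet has exactly one downstream reach.
Braided channels and distributaries are rejected with an explicit error —
all dendritic statistics presume tree topology, and a site that falls
mid-reach must be represented by splitting the reach at import time.
Units are fixed throughout: km for lengths, km² for areas, m⁻¹ for the
contact-zone ratio.

**Mean dendritic stream length** at a site is the unweighted arithmetic mean
of the path lengths from every upstream spring to the site; reaches below a
confluence are counted in every path through them.  Equal per-spring weights
encode the assumption of randomly distributed spring discharges; combined
with a constant-velocity assumption the quantity is proportional to mean
in-stream residence time.  No discharge weighting is applied.
**Cumulative dendritic distance** counts each upstream reach once and is a
drainage-density measure; **catchment area** sums per-reach lateral areas.
All three are validated against an exhaustive path-enumeration oracle on
randomly generated trees.

## OTU-table processing

Tables are non-negative integer matrices, samples × OTUs (the canonical
internal orientation), read from TSV (either orientation, auto-detected from
the header) or BIOM v1 JSON.  The processing order mirrors standard
amplicon practice: (1) removal of unwanted lineages (plastid, mitochondrial,
archaeal) by literal case-insensitive substring match on the rank-delimited
lineage — no synonym expansion, so "Chloroplast" must be listed explicitly
if wanted; (2) rarefaction; (3) a minimum-total-read OTU drop (default 2,
discarding global singletons) for dissimilarity analyses.  Rarefaction is a
multivariate-hypergeometric draw (sampling without replacement) to exactly
the requested depth; samples below the depth are dropped and reported, and
the seed is a required, logged parameter.  Presence means count ≥ 1.

Default depths: 7000 reads for alpha diversity (a depth at which richness
and evenness trends in water samples are essentially saturated) and the
minimum sample total for beta diversity, so no sample is lost.

## Diversity estimators and inference

* **Chao1** is the bias-corrected variant
  S_obs + F₁(F₁−1)/(2(F₂+1)); it always dominates observed richness, with
  equality iff F₁ ≤ 1.  Empty or all-zero inputs are errors, not NaNs.
* **Pielou's J** = H′/ln S with natural-log Shannon entropy over positive
  counts; a single-taxon sample is an error (ln 1 = 0 makes J undefined).
* **Bray–Curtis** uses the standard Σ|x−y|/Σ(x+y) form (scipy's
  implementation); any zero-total sample is rejected.
* **NMDS** minimises Kruskal stress-1 by isotonic-regression SMACOF
  (scikit-learn's non-metric majorisation), run from 20 random starts plus
  one classical-MDS (principal coordinates) start; the reported stress is
  recomputed from the returned configuration with the package's own
  stress-1 formula (monotone fit with primary/weak tie treatment: within
  tie groups of equal dissimilarities the fitted values follow the observed
  distances), which makes the reported value self-consistent to machine
  precision.  Default tolerance 1e-7, max 300 iterations.
* **Permutation tests** (one-way PERMANOVA on squared distances, PROTEST on
  centred unit-norm configurations with r = √(1−m²), beta-dispersion
  homogeneity, envfit vector fitting) share the convention
  p = (1 + #{perm ≥ obs})/(1 + n_perm), default n_perm = 999, and an
  explicit seed; permutation statistics are computed vectorised so exact
  label enumeration is feasible at small n.  Beta dispersion embeds the
  distance matrix by principal coordinates and handles negative eigenvalues
  by subtracting their squared contribution to centroid distances (floored
  at zero), the standard correction for semi-metric dissimilarities; group
  labels are then permuted over the per-sample distances.  Because "higher
  variability by a factor of x" is ambiguous between a difference and a
  ratio of group means, both are reported.

## Continuum statistics

The core community of a size fraction comprises the OTUs present in at
least q (default 0.90) of that fraction's mainstem samples; "at least 90%"
is implemented as occupancy ≥ ceil(q·n), and tributary samples never enter
the occupancy computation.  Core membership is computed on the unrarefied,
lineage-filtered table so that membership is not seed-dependent.  Trend
fits are ordinary least squares of per-sample responses on a dendritic
predictor (default mean dendritic stream length), tributaries excluded,
p-values two-sided and unadjusted.  Per-sample values are used rather than
site averages.  Habitat-term proportions normalise each OTU's term profile
to sum 1 and exclude unprofiled OTUs from both numerator and denominator,
so annotation missingness does not dilute the terms; freshwater-annotation
proportions (tribe / clade-lineage / non-typical) partition each sample's
reads exactly.

## The synthetic generator

The generator is a deliberately minimal statistical formalisation of the
mass-effects/species-sorting mechanism — all of its equations are this
package's own construction, not published estimates — and exists so that
every pipeline stage can be exercised against known ground truth.

A random binary-merge (coalescent-style) tree with `n_springs` springs
(default 64) carries log-normal reach lengths (median 25 km) and lateral
areas proportional to reach length (8 km²/km).  The longest spring-to-outlet
path is the mainstem; a site sits at every mainstem node and at the head of
each tributary branch entering it.  Flow velocity is set so the mainstem
residence time is 32 days, a realistic value for a large river.

Four disjoint OTU pools with log-normal abundance profiles represent soil
(600 OTUs), groundwater (300), typical-freshwater (80) and particle
(500) communities; "typical freshwater" ground truth is pool membership, so
the taxonomy and habitat-term annotations derived from it are exact.  Every
spring starts from the same 60:40 soil:groundwater mix plus a 4% freshwater
seed (standing variation for sorting to act on).  Along a reach of length L:

1. sorting: xᵢ ← xᵢ·exp(gᵢ·L/v), renormalised, with gᵢ = σₛ (default
   0.30 d⁻¹, between realistic mean and maximum bulk growth rates of ~0.2
   and ~1 d⁻¹) for freshwater-pool taxa and 0 otherwise;
2. lateral mass effect: contact ratio c = c₀·(A₀/(A₀+A_up))^γ with
   c₀ = 0.83 m⁻¹ (headwater value), A₀ = 200 km², γ = 1; mixing fraction
   m = 1 − exp(−μ_L·c·L) with μ_L = 0.03; the riparian end-member equals
   the spring inoculum (the same terrestrial source feeds springs and
   banks);
3. confluences average inflows weighted by accumulated catchment area, a
   discharge proxy.

Free-living samples are multinomial draws (7000 reads) from the resulting
expectation field.  Particle-associated samples admix the particle pool at
a Beta-distributed, sample-specific load (mean 0.3, s.d. 0.22 — particle
quantity and quality vary between sites) and add mild Dirichlet
overdispersion (concentration 4000) before the multinomial draw.  This
combination reproduces the two qualitative particle-fraction patterns at
once: higher richness (extra pool, little taxon dropout) and higher beta
dispersion (variable admixture).  A sparser Dirichlet alone cannot do both,
because low concentrations sparsify taxa and destroy the richness excess.

The **null preset** sets σₛ = 0 and γ = 0; because all springs share one
inoculum and the riparian mix equals it, the expectation field is then
exactly identical at every site, and any detected downstream trend is a
false positive by construction.  The **default (sorting) preset** was sized
so the expectation field shows the strong-sorting regime a large river
continuum represents: the freshwater-pool share rises from 4% to ~0.9 at
the mouth and expected richness declines monotonically by ~40%.

## What the simulations do and do not show

The generator emulates dendritic topology, headwater inoculation from
high-richness terrestrial pools, downstream decay of lateral input,
growth-based sorting and two size fractions.  It does not emulate
hydrodynamic routing, seasonality, chemistry, particle mechanics, taxonomy
assignment error or PCR/sequencing bias.  Tests passing on synthetic data
therefore validate the statistical machinery and the qualitative mechanism,
not quantitative agreement with any particular river survey — survey-scale
numbers (thousands of OTUs from millions of reads) are deliberately scaled
down to desk size (≈1500 OTUs, 7000 reads, tens of samples).

## Numerical and design choices

* All stochastic operations take an explicit seed; a run is reproducible
  bit-for-bit from its configuration, and the pipeline derives per-stage
  seeds from a single run seed.
* Sub-second degenerate inputs raise informative errors (empty networks,
  all-zero samples, single-taxon evenness, groups of size 1, constant
  predictors) rather than propagating NaNs.
* Regression on a constant response returns slope 0 with R² = 0 and p = 1.
* The pipeline writes results as TSV/JSON with a machine-readable manifest;
  logging goes to stderr, results never to stdout.

## Known limitations

* Networks must be strict trees; how real GIS products handle side-branches
  of a large river is outside scope, and such features must be resolved to
  a tree before import.
* The envfit implementation fits a single linear vector; factor fitting and
  surface fitting are not provided.
* No phylogeny-aware beta diversity (UniFrac) and no constrained
  ordination.
* Core-community membership at small sample numbers is sensitive to the
  ceil(q·n) threshold; with n = 10 mainstem samples, q = 0.90 means "present
  in at least 9".
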