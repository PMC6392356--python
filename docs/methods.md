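# Methods

This note records the models, conventions and design choices behind
`reefranges`, in the spirit of a statistical methods appendix.

## Range metric and response scale

Range size is the maximum linear distance: the largest great-circle
distance between any two occurrence records of a species, computed with
the haversine formula on a sphere of radius R = 6,371 km. The computation
is a deliberate O(n²) scan over record pairs — species record counts are
small and the brute force *is* the definition; any future shortcut must
match it exactly. A spherical rather than ellipsoidal Earth changes
distances by < 0.6%, immaterial at basin scale; the radius is a package
constant.

Because ranges are bounded by the attainable span of the study region,
the response is analysed on the logit scale:

    p = (range / d_ref) · (1 − 2ε) + ε,   y = log(p / (1 − p)).

`d_ref` is the reference span. The package default is the metric's own
supremum (half the Earth's circumference, ≈ 20,015 km); every analysis in
the examples and tests overrides it with the synthetic region's coastline
span (6,000 km), which is the span the generator draws ranges against —
using the generating span keeps the response scale linear in the
generator's coefficients. ε (default 0.001) squeezes the boundary so
point-range species remain finite; the squeeze perturbs mid-range logits
by < 1%.

## Mixed model and multimodel inference

The global model is a Gaussian LMM of y with fixed effects for log body
size, spawning mode (pelagic vs nonpelagic), adult mobility (low, medium,
high), circadian activity (diurnal, crepuscular, nocturnal), aggregation
behaviour (nonaggregative, temporarily aggregative, aggregative),
optionally PLD, and the spawning × mobility interaction; and random
intercepts for genus, family, order (nested — labels are globally
unique), ocean basin (endemic vs transpacific) and spatial structure
(coastline vs island).

Conventions, each a deliberate choice:

- **ML, never REML.** Likelihoods must be comparable across fixed-effect
  structures during all-subsets selection.
- **Standardization.** Continuous predictors are centred and divided by
  2 SD (slope of a 2-SD change, comparable with a binary contrast);
  two-level factors become centred 0/1; multi-level factors are
  dummy-coded against reference levels (nonpelagic, low mobility,
  nonaggregative, diurnal) and left unscaled.
- **Collinearity screen.** VIF per main-effect predictor; ≥ 2.5 is
  flagged (not fatal). The generator's independent trait draws keep VIFs
  near 1, matching the low collinearity of real trait tables.
- **Enumeration.** All fixed-term subsets obeying marginality (the
  interaction only alongside both mains): 2⁵ + 2³ = 40 models without
  PLD, 2⁶ + 2⁴ = 80 with. The random structure is held fixed; a random
  factor with < 2 observed levels in a subset is dropped from that fit
  with a logged note.
- **AICc weights and averaging.** AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1) with
  k counting fixed effects, variance components and the residual.
  Models with Akaike weight ≤ 0.001 are dropped and weights renormalized.
  Both averaging flavours are reported: the **full** average (a
  coefficient counts 0 in models excluding its term) as the headline
  effect size, and the **conditional** average (over models containing
  the term). Unconditional SEs combine within-model variance and
  between-model spread, √(Σ wᵢ(seᵢ² + (bᵢ − b̄)²)); p-values are
  two-sided normal on estimate/SE.
- **Which p calibrates?** Under the null, full-average estimates and
  z-scores are shrunk toward zero by the weight of models excluding the
  term, so full-average p-values are conservative (empirical type-I
  ≈ 0–3%). The conditional-average p is the approximately calibrated
  frequentist quantity (≈ 5%), and it is the one the calibration tests
  hold to the nominal band. Sensitivity comparisons use full-average
  p-values for consistency with the headline effect sizes.
- **Degenerate designs.** In a severely biased subset the interaction
  columns can be exactly collinear with the mains (e.g. every
  medium-mobility species pelagic). The interaction is then inestimable
  and is dropped with a warning, mirroring how `lmer` handles
  rank-deficient fixed-effect matrices.

### Fitting engine

Fits use a profiled-ML routine written for this package: with variance
ratios θ_k = σ²_k/σ², β and σ² have closed GLS forms, and each likelihood
evaluation costs O(q³) in the total number of random-effect levels q via
the Woodbury identity on precomputed cross-products (shared across all
submodels of a dataset, with warm-started variance ratios from the global
fit). This makes the resampling loops (thousands of 40-model selections)
run in minutes. The engine is verified in the test suite against
statsmodels' MixedLM (single and crossed variance components; identical
log-likelihoods and coefficients), against OLS for the no-random-effects
case, and against the closed-form Gaussian likelihood.

## Subset null model

The 13 compared characteristics are the number of families, mean body
size, and the level proportions of spawning mode (2), mobility (3),
aggregation (3) and circadian activity (3). Null subsets are uniform
draws of the focal size conditioned on every level of every modelled
categorical factor (the four behavioural factors plus basin and
structure; configurable) being represented — the same feasibility
constraint the mixed models need — implemented by batched rejection
sampling with a bounded retry count.

Significance: with n draws, a characteristic is flagged when at least
⌈0.975 n⌉ draws fall on one side of the focal value (9,750 of 10,000),
a two-sided test at α = 0.05. Ties count half to each side, which keeps
the test unbiased for discrete proportions; a degenerate null (zero SD,
e.g. focal = pool) is never significant. The standardized difference
reported for plotting is (null mean − observed)/null SD, so positive
values mean random subsets exceed the focal subset.

## Sensitivity analysis

The complete-data model (no PLD) is refitted on constrained random
subsets of focal size; replicate r draws its subset with seed `seed ⊕ r`,
so any execution order or partial rerun reproduces the same subsets.
Replicates whose fit fails are skipped and counted; more than 10%
failures aborts the run. Per coefficient the result holds the replicate
effect and p-value distributions, the modal significance class (binned
at p < 0.0001, < 0.001, < 0.05, ns) and the fraction of replicates with
p strictly below the focal subset's p.

## Synthetic study conditions

The generator emulates a Tropical-Eastern-Pacific-like assemblage and is
the fixed testbed for all calibration and acceptance checks:

- **Pool**: 497 species in 8 orders × 8 families × 2 genera each
  (64 families, ~125 observed genera — a regional pool's taxonomic
  granularity, enough for family-level concentration of a subset to be
  detectable). Traits are drawn independently per species (pelagic 0.55;
  mobility 0.45/0.35/0.20; diurnal 0.60/crepuscular 0.15/nocturnal 0.25;
  aggregation 0.40/0.30/0.30; endemic 0.80; coastline 0.85); body size
  is lognormal (median 25 cm, log-SD 0.8).
- **Effects** (logit scale): pelagic spawning +0.8, mobility +0.4/+0.7,
  log body size +0.35 per log-unit, nocturnal −0.5, crepuscular −0.1,
  aggregation +0.05/+0.1, PLD 0, spawning × mobility −0.3/−0.5 (mobility
  matters less for pelagic spawners); random-intercept SDs 0.35 (order),
  0.35 (family), 0.25 (genus), 0.7 (basin), 0.4 (structure); residual SD
  1.1; d_ref = 6,000 km. These magnitudes reproduce the qualitative
  pattern of the motivating system: strong spawning/mobility/body-size
  effects, a negative nocturnal effect, no aggregation effect.
- **Geometry**: an abstract meridian coastline arc spanning ~6,060 km
  plus island points; records are placed on the arc so the pairwise
  maximum equals the assigned range exactly. Only distances matter to
  the analysis; no map realism is attempted, and island points carried
  in the geometry are not used for record placement.
- **Availability bias**: inclusion weight inv_logit(γ·x) with trait-level
  log-odds shifts, sampled without replacement by exponential keys under
  the all-levels constraint. The default bias shifts availability toward
  pelagic, mobile, diurnal, aggregative species. The *headline* bias is
  deliberately severe — intercept −15 keeps all weights in the
  log-linear regime (so shifts act multiplicatively instead of
  saturating), pelagic +4.5 leaves only a handful of nonpelagic species
  in the subset, and a lognormal per-family multiplier (SD 1.0)
  concentrates measurement effort taxonomically. Its strength was set by
  a power calculation, not by observing range data: with ~3–7 nonpelagic
  species the spawning-contrast SE exceeds ~0.5, so a true effect of 0.8
  cannot reach significance, while balanced 148-species subsets have
  SE ≈ 0.2 and detect it easily.

What the generator does **not** emulate: trait–trait and trait–taxonomy
correlations (real traits are phylogenetically conserved; here taxonomy
enters only through random intercepts), measurement error in traits or
coordinates, spatially autocorrelated occurrence sampling, and any
larval-transport realism. Passing tests therefore demonstrate that the
*machinery* is correct and calibrated under known conditions, not that
real reef-fish data satisfy the model.

## Problem sizes in tests and the acceptance script

Resampling sizes are scaled to keep the default runs in the minutes
range while leaving the statistics interpretable: type-I calibration uses
200 simulated pools (99% binomial band 1.1–8.9% around the nominal 5%);
parameter recovery uses 20 pools of n = 2,000; null-model calibration
uses 400 experiments of 1,000 draws (band 2.1–7.9%) and the headline
null-model run uses the full 10,000 draws; the sensitivity loop uses
60–150 replicates in tests and the acceptance script (the pipeline
default remains 1,000). Monte-Carlo tolerances (3–4 SE, percentile
brackets) follow from these sizes.

## Known limitations

- p-values from normal z on averaged estimates (no Satterthwaite degrees
  of freedom); adequate at n ≈ 150+ but approximate for small subsets.
- Variance components for two-level factors (basin, structure) are
  weakly identified and often shrink to 0 in subsets; they are retained
  for faithfulness to the modelling structure.
- The weighted-sampling bias mask uses exponential-key sampling, whose
  inclusion probabilities are only proportional to the weights
  asymptotically; for the diagnostic purposes here the distinction is
  irrelevant.
- No multiplicity correction across the 13 null-model characteristics
  (deliberate: each characteristic is reported marginally).
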