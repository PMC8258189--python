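# Methods

This note documents the models, the synthetic data-generating process, the
numerical choices, and the limits of what the test suite demonstrates.

## Thermal performance curves

Performance is survivorship, a rate in [0, 1], as a function of water
temperature. The curve is anchored by three laboratory-derived traits per
life stage — CTmin, Topt (upper limit of the reported optimum range), CTmax
— and composed of a Gaussian rise below the optimum with width
`sigma_p = (Topt - CTmin) / 4` and a parabolic fall reaching zero exactly
at CTmax. The asymmetry encodes the standard physiology: biochemical rates
ramp up gradually with temperature, while protein damage and oxygen
limitation collapse performance quickly past the optimum.

Two numerical choices matter:

* **Clamping.** The Gaussian branch evaluates to `exp(-4) ≈ 0.018` at
  CTmin, not zero. By default performance is clamped to 0 outside
  [CTmin, CTmax], honouring the interpretation of the critical limits as
  survival bounds; `TPC.unclamped()` retains the tail for sensitivity
  analysis. Above CTmax the parabola is floored at 0 in both variants.
* **Skewness is conditional.** "Rise slower than fall" is often stated
  as `P(Topt - d) ≥ P(Topt + d)` whenever the rise width `Wr = Topt -
  CTmin` exceeds the fall width `Wf = CTmax - Topt`. For this functional
  form that is false in general: near the optimum the Gaussian loses
  `4d²/Wr²` while the parabola loses `d²/Wf²`, so the pointwise inequality
  requires `Wr ≥ 2·Wf` — and then holds for *every* d, via
  `exp(-u) ≥ 1-u`. The property tests assert exactly that conditional
  form, plus the unconditional relative-position asymmetry
  `exp(-4x²) ≤ 1-x²` (valid for x ≲ 0.99 of the branch width).

Trait finalisation collapses heterogeneous studies (ILT and CTM
methodologies, different acclimation regimes) by the narrowest-window rule:
final CTmin is the maximum of observed minima, final CTmax the minimum of
observed maxima, Topt the maximum observed optimum. The alternative
widest-envelope reading (`rule="widest"`) is available but not default.
No method-specific weighting is attempted.

## Synthetic world

The generator emulates the statistical structure the analysis needs, not
geography:

* **Network.** One random-attachment tree per region (node *i* attaches to
  a uniform earlier node) — branching, acyclic, dendritic. Regions occupy
  disjoint latitude bands alternating between hemispheres over 10–68° N/S,
  so hemisphere-aware code paths always run. Catchment areas are
  3000 km² + lognormal, matching the ingestion floor.
* **Temperature.** Monthly water temperature = latitude-dependent annual
  mean (25 °C at the equator, −0.30 °C per degree latitude) + a 6 °C
  seasonal sinusoid peaking in July (NH) or January (SH) + N(0, 0.5 °C)
  noise. The future period adds a uniform +2.2 °C, the global-mean warming
  of the RCP6.0 pathway; with zero noise the future equals baseline +
  offset exactly, which the tests exploit.
* **Covariates.** Altitude (negatively coupled to mean temperature),
  area-scaled winter discharge, and land-cover fractions; temperature-derived
  covariates (annual/autumn means, range, seasonality) are recomputed per
  period at feature-assembly time so future predictions carry the warming
  signal.
* **Niche and presences.** The annual-mean adult survivorship *v* under
  baseline temperatures passes through a logistic link centred at v = 0.5
  (steepness 25), rescaled so perfect habitat maps to the in-niche
  prevalence 0.95; each catchment is an independent Bernoulli draw. The
  steep, high-prevalence link makes occupancy near-deterministic given the
  environment — consistent with coarse catchment-scale mapping, where an
  unrecorded catchment is likely a true absence — and gives the world a
  *warm* and a *cold* range edge inside the sampled latitude span. With the
  default geometry the Bayes-optimal AUC of the generating process is
  ≈ 0.92; a shallower link (e.g. steepness 8, prevalence 0.45) caps any
  model near AUC 0.69, which is worth remembering when re-parameterising:
  label noise, not learner capacity, is the binding constraint.
* **Occurrence metadata.** Generated presences carry compliant record
  metadata (year ≥ 1985, uncertainty ≤ 5 km, "human observation"), so the
  ingestion filters run end-to-end without altering the sampled labels;
  filter rejection paths are unit-tested with hand-built records.

What the generator does **not** emulate: spatial autocorrelation of
residuals, observation effort gradients, covariate collinearity structures
beyond temperature coupling, flow direction, within-catchment habitat
heterogeneity, and biotic interactions. Passing tests on this world show
the machinery is correct and that a recoverable niche is recovered; they do
not certify performance on real survey data.

## SDM ensemble

* **Variable screen.** Candidates ordered by direction-free univariate AUC
  (`max(AUC, 1-AUC)`; names break ties deterministically); greedy retention
  requires AUC ≥ 0.65 *or* whitelist membership, and absolute Pearson
  correlation < 0.7 with everything already retained. The whitelist
  (literature-motivated variables) never bypasses the correlation cap.
* **Tuning.** Random search draws distinct configurations (budget 30 by
  default, capped with a warning at the enumerable space — the spline
  family has only 9 combinations); each is scored by mean AUC over five
  stratified folds of a stratified 80% partition, the winner refit on the
  partition, with the 20% holdout AUC reported for diagnostics.
* **Validation.** Repeated stratified 80/20 splits (default 100; the
  default-world acceptance run uses 20 to stay desk-scale). Thresholds are
  refit per split on calibration predictions — the only internally
  consistent choice when the threshold is part of the predictive procedure.
  TSS is computed as sensitivity + specificity − 1 per split, exactly.
* **Threshold rule.** Candidates are midpoints of consecutive sorted unique
  scores plus one candidate below the minimum and one above the maximum;
  minimise |sens − spec|, break ties by larger TSS, then larger threshold.
  Prediction uses score ≥ threshold.
* **Consensus.** Members are the learners with mean validation AUC > 0.85,
  refit on the full data; consensus probability is their arithmetic mean,
  averaged *before* thresholding; the final-map threshold is fit on
  full-data consensus probabilities (per-split thresholds remain
  calibration-only). If no learner clears the cutoff the run aborts with an
  explicit error rather than silently shipping a weak ensemble.
* **Absences.** All non-presence catchments are treated as true absences;
  no pseudo-absence sampling.

Seeds: one root seed; every stage, split and refit derives its own 31-bit
seed via `SeedSequence` on (root, CRC32 of stage keys). Reruns are
byte-identical, which the pipeline tests check file-by-file.

## Dispersal scenarios

Connectivity is undirected (dams block both directions; no up/downstream
distinction) and purely topological: a predicted presence survives if its
connected component contains a baseline presence. Paths may traverse
unsuitable catchments; a catchment that is both predicted and baseline
survives via the zero-length path. Regions are separate trees and are never
connected — marine routes between basins are out of scope. Nesting
(restricted ⊆ free ⊆ predicted) and equivalence with a plain BFS oracle are
property-tested on random dammed forests. Percent range change is rounded
half-away-from-zero to an integer.

## Performance assessment

Hemisphere is assigned by centroid latitude (≥ 0 → north). Seasons are the
NH month triplets; southern summaries keep the same month sets and label
them with the local season in brackets ("winter (summer)"). The spawning
season spans five months crossing the year boundary (Oct–Feb north,
Apr–Aug south) within a single climatological year; egg rates exist only
there. Seasonal/annual means weight every catchment × month cell equally,
which makes the balanced-design identity (annual = mean of seasonal means)
hold and testable. Latitudinal profiles average per-catchment annual means
in fixed-width bins; empty bins are omitted. The suitability–performance
correlation is Pearson's r with the t-based two-sided p-value, over
baseline-presence catchments only (occupied habitat is where the implicit
SDM assumption is meaningful); no multiple-testing adjustment, as each
stage is a single planned test.

## Problem sizes and defaults

The default world has 500 catchments in 6 regions, dam fraction 0.15, 5
trait observations per stage × trait at 0.5 °C noise. The acceptance run
and the parameter-recovery test use this world with 20 validation splits
and the default tuning budget of 30 draws; unit tests use 80–300 catchment
worlds and budgets of 2–10. The full acceptance computation completes in a
few minutes on one CPU.

## Known limitations

* Static TPCs: no acclimation, hardening, or oxygen-limitation terms.
* Survivorship is not propagated demographically; rates are habitat-quality
  indicators, not population projections.
* The learner set stands in for larger SDM model zoos (no neural networks,
  no presence-only maximum entropy); the consensus mechanics are the object
  of study, not the specific families.
* Net range change in the synthetic world is not calibrated to any
  particular decline figure; only the qualitative structure (summer
  performance loss without dispersal, partial recovery with it, further
  loss from dams) is asserted.
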