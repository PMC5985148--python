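# Methods

`canalize` tests whether the within-species variability of a meristic
(countable) skeletal trait declines over a clade's history — the
macroevolutionary signature of canalisation.  The worked system is the
crinoid arm: the number of primibrachial plates per arm, counted on
populations of fossil and Recent specimens from the Ordovician to the
present.  This note describes the statistical model, the defaults and the
choices made where the design was genuinely open.

## Data model

The unit record is a specimen with one primibrachial count per preserved
arm (`SpecimenRecord`).  Counts are positive integers — every arm carries
at least the first axillary plate — and arms are treated as an unordered
multiset within a specimen.  Species are assigned to exactly one of nine
geological periods (Ordovician … Cainozoic); a species observed in two
periods is a data error in strict mode and is otherwise split into
per-period pseudo-species `species@period`, since every downstream
statistic is computed within a period bin.

## Intraspecific variation

For each species the counts of all arms of all specimens are pooled and
summarized by the mean, the sample standard deviation (n−1 denominator),
the range (max − min) and the coefficient of variation CV = sd/mean.
Pooling at the arm level follows the definition of the species mean as
total plate count divided by total arm number.  Because counts are ≥ 1
the mean is ≥ 1 and the CV is always defined; CV = 0 exactly when the
species is invariant.  Whether the SD should instead be taken over
specimen means is not settled; pooled-arm SD is the default and the
package exposes the pieces (`pooled_counts`) to compute alternatives.

Species with fewer than five specimens are excluded from the
intraspecific analyses (`filter_min_individuals`, threshold
configurable); "individuals" means specimens, not arms.  The per-species
*range* used by the disparity analysis is deliberately computed on **all**
species, with no minimum-sample filter.

## Time binning

Bins are the nine periods, each represented by a mid-age in Ma.  Two
presets ship: `ics2012_midpoints` (arithmetic midpoints of the 2012
chronostratigraphic boundaries) and `paper_printed` (the same, with the
Carboniferous at 323 Ma and the Permian at 272 Ma, the values
conventionally quoted for this dataset); `paper_printed` is the default
for reproduction runs, and per-bin overrides are available.  Model
fitting uses elapsed time since the oldest retained bin, so the origin of
the series is the oldest bin and time increases toward the present.

Per bin the series carries the mean `m` of species CVs, their sample
variance `v` (n−1), the species count `n` and the sampling variance
`eps = v/n` of the bin mean.  Two degenerate cases need policy:

- **Single-species bins** (the Cretaceous in the reference composition):
  `v` is undefined.  Default: impute the df-weighted pooled variance of
  the other bins and flag the bin (`min_n_policy="impute"`);
  alternatively drop the bin.
- **All-invariant bins** (every species CV = 0, so `v = 0` and
  `eps = 0`): a zero sampling variance asserts the bin mean is known
  exactly, and the stasis likelihood then spikes degenerately at the
  variance floor (the optimum pins θ to that bin's mean).  The literal
  `v = 0` is kept by default (`zero_variance_policy="keep"`); the
  pipeline uses `"pool"`, which substitutes the pooled variance of the
  non-zero bins, mirroring the variance-pooling practice common in
  sampled-trait ML fitting.

## Trait-evolution models

Three models for the latent bin-mean trajectory are compared:

- **Stasis**: values fluctuate independently around an optimum θ with
  variance ω (CV², dimensionless).
- **URW** (unbiased random walk): Gaussian increments, mean 0, variance
  σ²ₛ per Ma.
- **GRW** (general/directional random walk): as URW with step mean μₛ
  (CV per Ma); μₛ < 0 on a variation series is the canalisation
  signature.

Two parameterizations are implemented, selectable everywhere:

- **joint** (default): the observed means are one multivariate-normal
  draw.  Random walks: mean `a + μₛ·tᵢ`, covariance
  `σ²ₛ·min(tᵢ,tⱼ) + δᵢⱼ·epsᵢ`.  Stasis: mean θ, diagonal covariance
  `ω + epsᵢ`.
- **ad** (ancestor–descendant): successive differences are independent
  normals `N(μₛ·Δt, σ²ₛ·Δt + epsᵢ + epsᵢ₊₁)`; stasis evaluates bins 2..B
  against `N(θ, ω + epsᵢ)`, the first sample conditioning the series.

Parameter counts K are 3/2/2 (GRW/URW/Stasis, joint) and 2/1/2 (ad);
N_obs is the number of bins (joint) or increments (ad), used consistently
in `AICc = −2logL + 2K + 2K(K+1)/(N−K−1)`.  Akaike weights
`exp(−Δᵢ/2)/Σexp(−Δ/2)` express proportional support; exact ties split
weight equally and the reporting order Stasis, URW, GRW breaks the
"winner" label.  Comparisons on fewer than five bins return a structured
insufficient-data result (this is what produces the dashes in per-clade
summary tables), as do series whose covariance is singular for every
parameter value (e.g. a zero-`eps` first bin under the joint random
walk).

### Numerical strategy

The mean parameters (a, μₛ, θ) enter linearly and are profiled out by
generalized least squares, reducing each fit to a one-dimensional
optimization over the log of the variance parameter, bounded below by a
floor of 1e-9.  The optimizer runs L-BFGS-B from the analytic start
(θ₀ = mean m, ω₀ = max(var m − mean eps, floor); σ²₀ = mean(d²/Δt)),
three seeded perturbed restarts and a floor-region start, followed by a
deterministic bounded scalar polish; the best optimum is kept
(convergence tolerance 1e-8 on logL).  Restart seeds derive from the run
seed, so fits are reproducible.

Profile-ML variance estimates carry the familiar downward O(q/N) bias
from the q profiled mean parameters; reported ω and σ²ₛ are therefore
rescaled by N/(N−q) — the same convention as the n−1 sample SD — unless
`correct_variance_bias=False`.  The reported logL and AICc are always the
uncorrected ML optimum, so model comparison is unaffected.

## Disparity

Interspecific variation is the mean pairwise distance (MPD) between
species within a bin, on a single character: the species' primibrachial
range.  With one character the Euclidean distance is the absolute
difference of ranges.  MPD averages the C(n,2) unordered distinct pairs
(diagonal excluded); bins with fewer than two species are flagged
undefined and excluded from the downstream correlation.

## Trends and the intra/inter correlation

The headline regression is OLS of species-level CV on bin mid-age
(species are the points, matching the scatter the method was designed to
summarize), with two-sided slope p on n−2 df.  Two prescribed subsets
re-run the regression: excluding invariant species (CV = 0) and excluding
the Carboniferous bin.  A LOESS smoother (tricube weights, span 0.75,
degree 2 — the classic defaults; validated against reference values from
an independent implementation) assesses the general shape;
pointwise standard errors come from the smoother's linear-operator rows
with σ² estimated as RSS/tr[(I−L)(I−L)ᵀ], and the reported band is
fitted ± 1.96·se.  Two sampling-artifact diagnostics regress species CV
on specimens per species, and bin mean CV on species per bin.

Correlating two autocorrelated, possibly trending series (mean CV per
bin vs MPD per bin) uses generalized differencing: each series is
OLS-detrended on time, the lag-1 autocorrelation ρ of the residuals e is
estimated as Σeᵢeᵢ₊₁/Σeᵢ², and the transformed series gdᵢ = eᵢ₊₁ − ρ·eᵢ
(length n−1) are correlated.  Spearman's rho is the default (Pearson via
config), with an exact permutation p-value when the transformed length is
≤ 9 and the t-approximation otherwise.  A perfectly linear input series
has no residual signal and is rejected with an explicit error.

## Synthetic data

`table1_template()` reproduces the nine-period composition of the
≥5-specimen subset of the reference compilation — 91 species and 1,018
specimens — with invariant fraction 0.70 and variant-species CV targets
drawn uniformly, capped at 0.6; the Carboniferous draws from the upper
tail (0.30–0.60), emulating its historical excess.  Variant species emit
per-arm counts from a two-point mixture {b, b+k} (k ≤ 4) tuned to the
drawn CV target; because primibrachial counts are small integers,
achievable CVs are discrete and high targets force small modal counts, so
the modal-count draw is restricted to feasible values.  A nominally
variant species that happens to draw identical counts everywhere has one
arm flipped, so the generator's invariance labels are exact.  Specimens
per species distribute a fixed per-period total (minimum five each,
remainder multinomial), and arms per specimen are uniform on 2–6.
Clade labels follow the coarse reality that post-Palaeozoic crinoids are
articulate pentacrinoids while Palaeozoic faunas mix camerates and
non-camerate pentacrinoids.

`simulate_cv_series` is the generative twin of the likelihoods: a latent
bin-mean path follows the chosen model on elapsed time, and each bin is
observed through `n_per_bin` species values with spread `within_bin_sd`,
from which m, v and eps are computed exactly as the analysis would.

What the generator does **not** emulate: phylogenetic correlation among
species, taphonomic loss, taxonomic error, and any real dependence of CV
on sample size.  Passing tests therefore demonstrate the correctness and
statistical calibration of the machinery on data satisfying the model
assumptions, not the empirical conclusions drawn from the museum
compilation.

## Verification batteries (sizes and thresholds)

- **Parameter recovery**: for each model at Stasis(θ=0.2, ω=0.01),
  URW(σ²ₛ=0.002), GRW(μₛ=−0.001, σ²ₛ=0.001), 200 replicates of a 50-bin
  series (10 Ma spacing, 20 species per bin, within-bin SD 0.05): the
  signed median relative error of each parameter stays below 10% and a
  sign test cannot reject a zero median bias at α = 0.05.  The signed
  median is the right bias summary here: the sampling error of μ̂ₛ
  (≈ √(σ²ₛ/T)) exceeds |μₛ| under these conditions, so absolute relative
  errors are dominated by irreducible sampling noise for any estimator.
- **Model selection**: under strong signal (25 bins), the generating
  model takes the top Akaike weight in ≥ 80% of 200 replicates per model.
- **Oracle equivalence**: MPD vs brute-force pair enumeration (1e-12);
  OLS vs normal equations (1e-10); joint stasis likelihood vs per-bin
  density product (1e-10); LOESS vs frozen independent reference values
  (1e-6).
- **Generalized differencing**: white-noise series (length 50, 500 reps)
  give a mean lag-1 autocorrelation of the transform within ±0.05 of 0;
  on AR(1) series with coefficient 0.6 the transform reduces |lag-1
  autocorrelation| in ≥ 95% of replicates.
- **Determinism**: identical seeds and inputs give byte-identical run
  reports apart from the timestamp.

These sizes keep the whole battery under a minute on one CPU while
leaving comfortable statistical margins.

## Known limitations

- The CV of a discrete count is bounded and lumpy; simulated CV targets
  are approximate, and Gaussian bin-mean models are an approximation for
  series of CVs (which are nonnegative).
- The joint random-walk likelihood requires a nonzero total variance in
  the first bin; fully invariant datasets are reported as degenerate
  rather than fitted.
- The generalized-differences routine fixes one of several published
  variants (OLS detrend, lag-1 correction, Spearman correlation); knobs
  expose the correlation flavour but not alternative detrending.
- No Ornstein–Uhlenbeck, punctuated or multi-regime models; no
  model-averaged parameter estimates; no stage-level binning or age
  uncertainty.
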