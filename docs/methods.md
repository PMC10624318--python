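# Methods

## The data and what is reconstructed

The packaged table (`callopt/data/treatments.csv`) holds the 33-treatment
factorial screen: doses of BAP, KIN, NAA and IBA in mg/L over [0, 2], with
the mean ± standard error of callus formation rate (CFR, %) and callus
fresh weight (CFW, g) per treatment. The design is one-factor-at-a-time in
structure: every non-control row has exactly one cytokinin (BAP xor KIN)
and at most one auxin (NAA xor IBA) non-zero, and the auxin level is paired
with the cytokinin level. The single hormone-free control formed no callus.

Per-vessel records are not published, so `synthetic.reconstruct_replicates`
emulates them:

- **CFR** is the percentage of 4 explants forming callus, so a vessel is
  drawn as `100·Binomial(4, mean/100)/4`. The binomial granularity — values
  on the 0/25/50/75/100 lattice — fixes the variance; the printed SE is not
  used for CFR. A single vessel therefore carries a noise SD of roughly
  `100·√(p(1−p)/4)` ≈ 20 percentage points at intermediate p.
- **CFW** is drawn from `Normal(mean, SE·√7)` (the SE of a mean of 7
  vessels), truncated at zero, and forced to exactly 0 for vessels in which
  no explant formed callus.
- Each treatment draws from its own substream
  (`SeedSequence(seed, spawn_key=(treatment_id,))`), so appending treatments
  never reshuffles earlier draws, and a fixed seed gives bit-identical
  tables.

What the generator does *not* emulate: vessel/position effects, time-course
growth, genotype dependence, or any correlation between CFR and CFW beyond
the zero-coupling rule. Passing tests on reconstructed data therefore show
that the pipeline recovers the screen's between-treatment structure, not
that it would generalise to a new petunia experiment.

`synthetic.simulate_surface` generates fully synthetic data from a Gaussian
bump with a known optimum (optionally rescaled to respond 0 at the
hormone-free origin), used wherever a test needs ground truth by
construction (model recovery, GA optimum recovery).

## Splitting and evaluation

The 231 vessels are split 80:20 by a seeded random permutation of records
(default), mirroring a random partition of the "231 data points". Metrics
(R², RMSE, MBE with predicted−observed sign) are computed per treatment:
predictions at a treatment's dose vector are compared against the mean of
its 7 reconstructed vessels, restricted to treatments represented in the
partition. Two facts force this choice:

- at the record level, the binomial vessel noise (variance ≈ 525 for CFR)
  is irreducible and caps attainable R² near 0.4 regardless of model
  quality, and any RMSE below ~18 pp is impossible;
- holding out whole treatments instead leaves the surrogates extrapolating
  across the sparse one-factor design, and test R² collapses below zero.

Treatment-mean evaluation has a noise floor of 525/7 = 75 (≈ 8.7 pp RMSE),
which is the regime the screen's reported accuracies occupy. Both
alternatives remain available (`split_level="treatment"`,
`metric_level="record"`) for leakage-safe or vessel-level analyses; their
numbers are not comparable to the defaults. k-fold utilities default to
k = 5.

Inputs are min-max normalised to [0, 1] inside each model so the four
hormones contribute equally to Euclidean distances; outputs stay on their
natural scales, and CFR and CFW are fitted as two independent single-output
models.

## The surrogates

**GRNN.** Nadaraya–Watson kernel regression: the prediction is the
Gaussian-weighted average of all stored training targets,
`ŷ(x) = Σ yᵢ·exp(−dᵢ²/2σ²) / Σ exp(−dᵢ²/2σ²)`. Weights are computed with a
max-shifted exponential so at least one weight is exactly 1: distant
queries never hit 0/0, and as σ→0 the prediction degenerates cleanly to the
nearest pattern's target. Predictions are convex combinations of training
targets and hence bounded by their range. The spread σ (normalised-input
units) is the only free parameter; it is chosen by 5-fold CV over a
geometric grid of 20 values in [0.02, 1.0], breaking ties toward the larger
(smoother) σ. On reconstructed data the selected spread sits near 0.1,
which is the bias–variance interior: small enough to resolve neighbouring
treatments, large enough to pool replicate noise.

**RBF network.** m Gaussian units (default `min(25, n/4)`) centred on
seeded k-means prototypes of the normalised inputs; each unit's width is
the mean distance to its two nearest sibling centres (floored at 1e-12).
Output weights and bias solve a ridge-regularised least-squares system
(λ = 1e-8, for conditioning under duplicated dose rows); an optional plain
gradient-descent refinement is available but off by default since the
closed-form solution is already the loss minimiser.

**MLP.** Fixed 4–128–1 architecture, numerically stable sigmoid hidden
layer, linear output, seeded uniform(−1/√fan_in, 1/√fan_in) init. Training
is minibatch SGD on the MSE with analytic backpropagated gradients
(verified against central finite differences). Targets are standardised
internally for conditioning and predictions returned on the natural scale.
Defaults: learning rate 0.05, 4000 epochs, full batch below 64 samples and
batch 32 otherwise. Smaller rates (e.g. 0.01) leave the network at the
mean-predictor loss on this data within any reasonable epoch budget; 0.05
reaches treatment-level R² ≈ 0.6–0.9 in a few seconds. Divergence
(non-finite loss) raises with advice to lower the rate rather than
returning garbage. An optional patience-based early stop is off by default
so runs are exactly reproducible from the seed.

## Sensitivity analysis

`sensitivity.compute_vsr` quantifies hormone importance for a trained
surrogate over the full dataset. Two schemes:

- **error_ratio** (default): RMSE with input i clamped to its dataset
  mean, divided by the intact RMSE. A hormone the model ignores scores
  exactly 1.0; informative hormones score above 1 (values 1.05–1.3 are
  typical here because replicate noise dominates the denominator). If
  clamping changes nothing the ratio is defined as exactly 1; for an
  exactly interpolated fit (zero base error) the denominator is floored so
  the ordering stays finite.
- **mean_slope**: mean of |Δoutput|/|Δinput| over dataset points and
  symmetric perturbation steps, with inputs perturbed on the normalised
  scale so different dose ranges are comparable.

Ranks are assigned by descending VSR with ties broken in input order
(BAP, KIN, NAA, IBA).

**Known limitation.** On data reconstructed from the printed means, every
scheme variant we measured (mean-clamp ratio, normalised slope,
leave-one-hormone-out refits, one-at-a-time profile sweeps; with GRNN and
MLP) ranks the cytokinins above the auxins for both outputs — clamping or
sweeping BAP/KIN moves points across the design's two cytokinin arms, and
that structural displacement dominates any within-arm auxin effect. An
auxin-first ranking is not recoverable from the printed table; per-vessel
data (not published) would be needed to settle it. The package reports what
it computes.

## Genetic algorithm

Real-valued individuals are dose 4-vectors in the box [0, 2]⁴ mg/L (the
screened range). Defaults: population 60, 200 generations, crossover rate
0.9 (per-gene arithmetic blend with α ~ U(0,1), so children stay in the
box by convexity), mutation rate 0.15 with N(0, 0.1 mg/L) perturbations
clipped to bounds, elitism 2. Roulette-wheel selection shifts fitnesses so
the minimum maps to a floor of 1e-9 of the range (handles ties and
negative values; an all-equal population is sampled uniformly). Termination
is the fixed generation budget, and the best individual ever evaluated is
returned; with elitism ≥ 1 the per-generation best is monotonically
non-decreasing.

When optimising a fitted surrogate through
`CallogenesisResults.optimize`, the screened dose combinations seed part of
the initial population. A small-spread GRNN surface is multimodal with
narrow basins; seeding known design points guarantees the search never
returns less than the best screened treatment's prediction while leaving
the rest of the population free to explore.

Two independent GA runs (CFR fitness, CFW fitness) produce the two
reported optima. A validation section in the pipeline report can compare a
GA prediction against externally supplied laboratory means (one-sample
two-sided t on mean ± SE); the lab numbers are inputs, never computed.

## Numerical and design notes

- Min-max scalers map constant features to 0 with a warning instead of
  dividing by zero; apply/invert round-trips to 1e-12.
- R² requires non-constant observations and at least 2 points; RMSE² always
  equals MBE² plus the residual variance.
- The dataset validators reject doses outside [0, 2] mg/L, CFR outside
  [0, 100], negative weights/SEs, duplicated dose rows, a non-zero
  hormone-free control, and (in granular mode) off-lattice vessel CFRs,
  naming the offending row.
- All randomness flows from integer seeds through `numpy` Generators; no
  global state. Pipeline reports embed the seed, package version and a
  config hash, and two runs with one seed are byte-identical.
- Problem sizes used in the shipped tests: 231 reconstructed vessels for
  study-level checks (10 seeds for medians), a 7⁴-point noiseless grid for
  surface-recovery checks, and 10⁴ replicates for the law-of-large-numbers
  check of the reconstruction law.
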