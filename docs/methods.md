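# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the known limitations of `ploidyml`.

## The task

Ploidy outcome (diploid / mixoploid / tetraploid) is modeled as a function
of two treatment variables: oryzalin concentration C (µM) and exposure time
t (h). The package (i) simulates explant-level outcomes over a 26-treatment
design, (ii) trains three classifiers on a balanced 72-row dataset,
(iii) compares them with macro-averaged criteria, and (iv) maximizes the
best probabilistic model's tetraploid posterior over the treatment
rectangle with a genetic algorithm.

## Synthetic dose–response generator

No public explant-level dataset exists for this design, so the generator is
a first-class, tested component, not a fixture. It emulates the qualitative
biology of oryzalin treatment:

- **Diploid escape.** A latent score
  `s(C, t) = β₀ + β₁ ln(1+C) + β₂ t + β₃ ln(1+C)·t` drives
  `P(diploid) = 1/(1 + e^{s/τ})`. Defaults β = (−21.74, 5.5, 0, 0.1),
  τ = 1: untreated and low-dose explants (≤ 5 µM, any exposure up to 48 h)
  stay diploid with probability ≥ 0.95, and escape grows with the
  dose × time interaction (log-dose, because membrane transport and
  microtubule binding saturate at high concentrations).
- **Tetraploid bump.** Conversion to a uniform tetraploid requires both
  enough dose and enough exposure near an optimum. The tetraploid share of
  the non-diploid mass is
  `B(C, t) = exp(−[(|C−33|/680)^½ + (|t−18|/w)^½])`, a stretched-exponential
  bump peaking at the planted optimum (33 µM, 18 h), with exposure scale
  w = 16 h on the short side and 1740 h on the long side. The strong
  short-side asymmetry encodes that brief pulses — even at extreme doses —
  convert only part of the meristem and yield chimeras; at 100 µM / 10 h
  the mixoploid class is modal.
- **Mixoploid remainder.** `P(tet) = (1 − P(dip))(1 − floor)·B` with
  chimera floor 0.02, and `P(mix)` takes the remainder, so the three
  probabilities sum to one exactly.

A separable *Gaussian* bump cannot express this response surface: the
calibration targets require the tetraploid probability to fall from ≥ 0.93
at the peak to ≤ 0.92 within 7 µM while staying ≥ 0.70 at a point 47 µM
away — a near/far decay ratio a quadratic exponent cannot produce (it
forces the far decay to be ≥ 45× the near decay). The stretched exponent
p = ½ decays fast near the peak and slowly far away, which satisfies every
calibration target with margin: tetraploid probability is 0.962 at
(33, 18), between 0.71 and 0.84 across the 40–80 µM × 24–36 h block, and
0.35 at (100, 10) where mixoploid (0.65) is modal.

Sampling is explant-level multinomial: each of 26 × 4 × 4 = 416 explants
draws its class independently from the analytic probabilities, so
per-treatment rates are multiples of 1/16 exactly as a real 4 × 4 design
would report them. The balanced dataset subsamples 24 records per class
(72 rows). What this generator does **not** emulate: replicate-level
random effects (explants within a replicate are exchangeable here),
explant mortality, flow-cytometry measurement noise, and genotype effects.
Tests passing on these data therefore certify the algorithms, not any
particular laboratory protocol.

## Preprocessing

- **Outlier screen**: features are standardized, rotated to principal
  components, and a row is removed when its squared Mahalanobis distance
  exceeds the χ² quantile at 1 − α (df = 2), α = 0.025 by default. The
  criterion is deliberately conservative; the default synthetic datasets
  contain no gross outliers and pass through unchanged.
- **Standardization** is fitted on the training partition only (population
  moments) and applied to test data with training statistics — asserted by
  a no-leakage test.
- **Split**: stratified 19 train / 5 test per class. A 70/30 split of 72
  rows cannot produce the observed accuracy denominators (every reported
  accuracy is an exact multiple of 1/57 or 1/15); 57/15 (79 %/21 %) can,
  so it is the default, and both counts are configurable.

## Classifiers

All three operate on standardized features and share the fixed class order
(diploid, mixoploid, tetraploid) for tie-breaking and confusion-matrix
axes.

**PNN.** The pattern layer is a Gaussian kernel; class sums are
*unweighted* (no 1/Nⱼ factor, no priors) — with balanced training sets the
argmax is identical to the classic Nⱼ-normalized formulation (asserted on
balanced fixtures). All kernel arithmetic runs in log space
(log-sum-exp), so σ → 0 degenerates exactly to 1-nearest-neighbor instead
of underflowing. σ is chosen from a geometric grid (0.05–2.0 in
standardized units, 25 points) by leave-one-out accuracy, ties toward the
larger (smoother) σ.

**SVC.** Each one-vs-one subproblem solves the soft-margin dual by
sequential minimal optimization (pairwise updates that preserve
Σαᵢyᵢ = 0 exactly; KKT tolerance 1e-3; sweep cap 10 000 with a
convergence error naming the subproblem). The kernel is the standard
`exp(−γ‖x−xᵢ‖²)`; a published variant typesets the exponent ambiguously as
`exp(−γ‖x−xᵢ‖)²`, which this package resolves to the standard form.
Defaults C = 1 and γ = 1/(2·mean per-feature variance) (= 0.5 on
standardized features). Multiclass prediction is majority vote over the
three subproblem signs; vote ties go to the class with the largest summed
absolute decision value, then to class order. Decision values were
validated against an independent constrained-QP solve of the dual and
against an external SVM implementation (≤ 2e-3 disagreement on the test
fixtures, tolerance 5e-2).

**KNN.** Cosine distance compares directions and is undefined at the
origin, but standardized features place mid-range treatments near the
origin. Inputs to KNN are therefore standardized and then shifted by +3
per coordinate — beyond the |z| < 3 range the bounded treatment designs
produce — keeping all vectors in the positive orthant where cosine
ordering is meaningful. The published description calls
`u·v/(‖u‖‖v‖)` itself a "distance"; as written that is a similarity, and
the package implements the universal convention distance = 1 − similarity.
Distance ties at the k-th rank resolve by stable training order; vote ties
resolve to the class of the single nearest neighbor. k is chosen from
{1, 3, 5, 7, 9} by leave-one-out accuracy, ties toward smaller k.

## Evaluation

One-vs-rest reduction per class gives TP/FP/FN/TN; accuracy is
trace/total × 100 (the only consistent multiclass reading of the binary
(TP+TN)/total formula) and error rate is its complement. Precision and
recall are macro averages; F1 is the harmonic mean *of the macro
averages*, not the macro average of per-class F1 — the convention that
reproduces five of the six published F1 entries exactly from their printed
precision/recall (the sixth, PNN-testing 0.91514, computes to 0.91455
under this convention; the discrepancy is asserted, not hidden).
Percentages are reported to 4 decimals, proportions to 5. A class never
predicted contributes precision 0 (and recall 0 if never observed).

## Genetic algorithm

Real-coded, box-bounded (defaults C ∈ [0, 100] µM, t ∈ [0, 36] h — the
experimental envelope), population 200, exactly 1000 generations (no early
stopping), elite count ⌈0.05·200⌉ = 10, crossover fraction 0.6.

- **Selection**: stochastic universal sampling (evenly spaced pointers,
  one random phase) over rank-scaled weights 1/rank (ties share average
  rank, so equal fitnesses select uniformly). Rank scaling makes selection
  order-dependent only; the harmonic profile concentrates parent mass on
  leaders, which the success-adaptive mutation needs to polish an optimum
  within a fixed generation budget. The flatter 1/√rank profile was
  measured to stall the quadratic benchmark an order of magnitude short of
  the 0.01 target.
- **Crossover**: scattered — each child gene comes from either parent by
  an independent fair coin.
- **Mutation**: per-gene Gaussian steps at rate 0.05, clipped to bounds.
  The step scale starts at 10 % of each gene's range, contracts by 0.95
  after a generation without best-fitness improvement and expands by
  1/0.95 (capped at the initial scale) after one with improvement. Inside
  `evolve`, every mutation child mutates at least one gene (a uniform gene
  is forced when all per-gene draws miss): without this, ~90 % of mutation
  offspring are clones, improvements become too rare, and the adaptive
  scale collapses before the population reaches the optimum basin. The
  operator keeps the literal per-gene semantics (rate 0 → identity) when
  called directly.
- **Fitness**: the PNN posterior probability of the tetraploid class at
  the standardized query point. Only the PNN yields a calibrated class
  probability, so the pipeline always couples the GA to the PNN even when
  the model ranking (by test accuracy) happens to favor KNN or SVC on a
  given dataset.

Elitism makes the best-so-far trace non-decreasing by construction; runs
are fully deterministic given (seed, config, fitness). On the quadratic
benchmark (pop 200, 200 generations) the optimizer recovers an interior
optimum to within 0.01 in 20/20 seeds, and on PNN surfaces its best
fitness matches an exhaustive grid argmax oracle.

## Problem sizes used by the test suite

The default study conditions are used throughout: 416 simulated explants,
72-row balanced datasets, 57/15 splits, GA at 200 × 1000. Monte-Carlo
calibration checks use 10 000 explants per treatment with 3-standard-error
bands; stochastic recovery checks use 20 seeds. The full suite runs in
about two minutes on one CPU.

## Known limitations

- **Posterior maximization rewards extrapolation.** A kernel classifier's
  posterior saturates toward 1.0 in regions far from all training data
  whenever the nearest class is the target class. The treatment design has
  large empty regions (no cells between 20 and 40 µM, none above 36 h), so
  the tetraploid-posterior surface often attains its maximum at a
  saturated plateau or at the search-rectangle corner rather than over the
  generator's true probability peak: with small LOO-selected σ the surface
  is a 0/1 Voronoi map (the argmax can land anywhere on a plateau), and
  with large σ the far-field is won by whichever class centroid is
  closest. Because the generator is also constrained to keep tetraploid
  probability ≥ 0.70 across the whole 40–80 µM × 24–36 h block, the honest
  interior posterior is nearly flat-high there (≈ 0.9 at best), and a
  saturated 1.0 elsewhere beats it. Consequently the GA reliably maximizes
  *its surface* (verified against the grid oracle) but recovers the
  generator's planted (33 µM, 18 h) peak only occasionally; the in-silico
  recovery test records this honestly. Practitioners applying
  posterior-maximizing optimization to kernel classifiers should constrain
  the search to the data hull or penalize low-density regions.
- The generator's class probabilities are explant-i.i.d.; real replicate
  structure would widen the Monte-Carlo bands.
- No survival/mortality modeling and no flow-cytometry signal simulation:
  ploidy labels are taken as observed inputs.
- SVC and KNN expose decision values and vote fractions, not calibrated
  probabilities; no probability calibration is attempted.
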