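# Methods

## The diagnostic model

`nirsaware` decides whether a two-run fNIRS session contains evidence of
command following. The decision statistic is the cross-validated accuracy of
an IMAGERY vs NO-IMAGERY decoder trained within the session itself; its
significance is assessed against a permutation null. Three feature sets are
tested (HbO, HbR, and the channel-doubled HbO & HbR), and the session is
labeled RESPONSIVE iff the minimum of the three empirical p-values is below
α = 0.05 (strict inequality; p = 0.05 exactly is not significant).

### Trial representation

A trial epoch X (channels × 84 samples) becomes an SPD matrix as follows.

1. **Prototypes.** P_A, P_B are the arithmetic means of the training trials
   of each class. They act as templates: the covariance between a trial and
   a template encodes how strongly the trial expresses the class-average
   spatiotemporal response, without assuming any canonical response shape.
2. **xDAWN spatial filters.** Per class, the f leading generalized
   eigenvectors of (evoked covariance, average signal covariance), i.e. the
   projections with maximal evoked-to-total power ratio. Solved in whitened
   coordinates (Cs^{-1/2}-conjugation, then a symmetric eigenproblem); rows
   are normalized to unit Euclidean norm. f ∈ {2, 4, 6} is a hyperparameter.
3. **Augmentation.** X̃ = [V_A P_A; V_B P_B; V X] with V = [V_A; V_B]; row
   order fixed (IMAGERY prototype, NO-IMAGERY prototype, trial), D = 4f
   rows.
4. **Covariance.** Rows of X̃ are mean-centred; the biased sample covariance
   (divide by the sample count) is shrunk with the closed-form OAS intensity
   toward (tr S / D)·I. The exact published formula (including its 2/p
   terms) is used; shrinkage preserves the trace and guarantees positive
   definiteness even when D exceeds the epoch length.

### Riemannian classification

Under the affine-invariant metric, the training covariances' Fréchet mean
serves as the tangent-space reference; each covariance C maps to the vector
of the upper triangle of log(M^{-1/2} C M^{-1/2}) with off-diagonal entries
scaled by √2 (so vector norms equal manifold distances). An L2-regularized
logistic regression (inverse regularization C ∈ {1, 10, 100, 1000})
separates the classes in this chart.

Cross-validation is stratified fivefold (per-class seeded shuffle, then
round-robin assignment: with 30 + 30 trials every test fold holds 6 + 6).
All twelve hyperparameter combinations are evaluated on one shared fold
assignment and the highest mean accuracy wins; exact ties resolve to the
smallest filter count, then the smallest C. Every data-dependent quantity —
prototypes, filters, whitener, covariances, reference, classifier — is
fitted on the training folds only (leak-freedom is asserted by checksum
tests).

### Permutation test

The null distribution is built by shuffling the trial labels N times
(default 250; the simulation studies use 99) and re-running, for each
shuffle, the *entire* search-and-fit procedure on the same folds; the null
statistic is thus the same best-of-12 accuracy as the observed one, and the
empirical p-value p = (1 + #{null ≥ observed}) / (1 + N) is valid under
exchangeability by construction.

This is the one place the implementation departs from its initial design,
which refit only the selected configuration inside the null. That variant
is severely anti-conservative: selection lifts the observed statistic by
roughly one null standard deviation even on pure noise, and in simulation
it produced a ~44% dataset-level false-positive rate at α = 0.05 (min-P
over three feature sets) on exchangeable null data. Re-selecting inside
each permutation removes the bias at about 2.5× the cost (not 12×: the
per-fold geometry is shared across the C grid, and the f-specific
covariances are submatrices of the max-f ones — see "Performance" below).
The fixed-configuration variant remains available via the `best` argument
of `permutation_pvalue` and is itself calibrated when its observed
statistic is also computed without selection.

### Class distinctiveness

`classDis(A, B) = d(X̄_A, X̄_B) / (½(σ_A + σ_B))` with Fréchet-mean class
centers and σ_K the mean distance of class-K matrices to their center
(dispersion exponent 1). It is used to compare covariance estimators and as
a monotonic readout of class separation; it plays no role in the diagnosis
itself.

## The paradigm simulator

The generator reproduces the block-design imagery experiment: 6.94 Hz
sampling; runs of 40-s baseline plus six blocks of five trials (1-s cue,
2-s task, 15-s rest), 580 s and 4025 samples per run; IMAGERY and
NO-IMAGERY alternating block-wise, 15 + 15 trials per run, two runs per
dataset with the starting block condition alternated across runs (60 trials
per dataset). The default montage is a left-hemisphere fronto-parietal cap
with nine sources and eight detectors forming 22 long channels at 3 cm and
one short channel at 1 cm; wavelengths default to 760/850 nm (a typical
pairing for this device class; the montage does not fix them) with a
bundled extinction-coefficient table.

**Evoked response.** In RESPONSIVE runs, IMAGERY trials add to ΔHbO a
canonical double-gamma impulse response (peak 6 s, undershoot 16 s, ratio
1/6) convolved with the 2-s task boxcar, normalized to unit peak and scaled
per channel by a smooth unimodal spatial profile with maximum
`evoked_amplitude_hbo`. ΔHbR mirrors ΔHbO scaled by −1/3 and lagged 1 s.
UNRESPONSIVE runs and NO-IMAGERY trials carry no evoked component, and the
short channel never does.

**Noise.** A shared systemic source enters every channel with
channel-specific log-normal gains: a Mayer wave (narrowband Gaussian noise
centred at 0.1 Hz, ±20% bandwidth), a cardiac oscillation (1.1 Hz ± 10%)
and a linear drift. Narrowband noise rather than pure sinusoids is
essential: at this paradigm's 18-s trial spacing a fixed-frequency 0.1-Hz
sinusoid is exactly phase-locked to the 90-s blocks and masquerades as task
structure. White measurement noise is added per channel (HbR at half the
HbO level; systemic coupling into HbR at 0.25), and the short channel's
noise is scaled by 0.3 — a 1-cm separation collects roughly an order of
magnitude more light than 3 cm, and a short channel as noisy as the long
channels would attenuate the regression coefficient and defeat the
systemic-noise removal it exists for. Concentrations map to raw intensities
through the Beer–Lambert forward model (the exact inverse of the analysis
MBLL), with multiplicative log-normal intensity noise (σ = 5 × 10⁻⁴ in OD
units).

**Defaults as study conditions.** `evoked_amplitude_hbo = 0.3 µM` is
calibrated once so that the grid-search CV accuracy on simulated RESPONSIVE
datasets is ≈ 0.80, the operating point at which the sensitivity claim is
evaluated; the remaining defaults (Mayer 0.4 µM, cardiac 0.15 µM, drift
0.002 µM/s, white noise 0.25 µM) are plausible magnitudes for band-passed
concentration data. What the generator does *not* model: optode-scalp
coupling, motion artifacts (beyond what TDDR tests inject), spatially
heterogeneous systemic physiology, inter-subject variability of the
hemodynamic response, or any nonstationarity across runs. Passing tests
therefore demonstrate the correctness and calibration of the *pipeline*
under controlled physics, not clinical performance on patients.

## Preprocessing details

* Optical density uses the natural logarithm of the mean-normalized
  intensity, making the chain invariant to source power.
* TDDR follows the published reference implementation exactly (verified
  bit-identical against the copy bundled with MNE): 0.5-Hz third-order
  low-pass split, Tukey-biweight (4.685) iterative reweighting of the
  low-frequency derivative to machine-precision convergence of the weighted
  mean, re-integration, re-centring. Two behaviours worth knowing: the
  repair removes the net linear drift of the slow component (a fractional
  sinusoid period reads as drift), and on *exactly* noise-free data the
  robust weights clip isolated evoked bumps because the derivative's median
  is near zero — with any realistic noise floor the evoked response passes
  through unharmed.
* Short-channel regression operates per wavelength in OD space before the
  MBLL, with intercept; the short channel is dropped afterwards. The step
  can be disabled by configuration when no short channel exists.
* The band-pass is [0.01, 0.4] Hz. The lower edge sits well below the
  1/18-Hz trial fundamental (a 0.1-Hz high-pass would remove the taskband)
  while still suppressing drift; applied forward-backward, so the effective
  order doubles and the phase is exactly zero.
* Epochs span [0, 12] s from cue onset: samples
  [round(onset·fs), round(onset·fs) + floor(12·fs)] inclusive, 84 samples at
  6.94 Hz. A least-squares line is removed per epoch and channel over the
  full window. Onsets whose window exceeds the recording are dropped with a
  warning.

## Numerical choices

* Matrix functions via symmetric eigendecomposition with an eigenvalue
  floor of 1e-12; SPD validation uses a 1e-10 relative symmetry tolerance.
* The Fréchet mean iterates the Karcher fixed point with an adaptive step
  (×1.05 on criterion decrease, ×0.5 on increase — the unit step converges
  slowly for widely spread sets), initialized at the arithmetic mean,
  default tolerance 1e-8 on the mean tangent norm, max 50 iterations,
  error with diagnostics on failure. Matrix exponentials of small steps
  (‖step‖ < 0.3) use a third-order Taylor expansion; the convergence test
  always uses exact logarithms.
* Inside the decoding pipeline the reference is a capped two-evaluation
  Karcher iteration (early exit at step norm 1e-3). The reference only
  anchors the tangent chart; on simulated data the capped and fully
  converged references change grid accuracies by at most one trial in 60.
  The identical procedure is applied to observed and permuted labels, so
  permutation comparisons are like-for-like.
* The logistic regression is solved by a damped Newton iteration in the
  representer parametrization w = Xᵀa (an (n+1)-dimensional solve per step
  regardless of feature dimension), gradient tolerance 1e-6·n, max 100
  iterations, backtracking line search; it reaches the same optimum as
  sklearn's solver (asserted in tests) at a fraction of the per-fit cost.
* Empirical p-values use the add-one formula; permutation label streams are
  drawn from a counter-derived seed sequence, so a master seed fixes the
  entire diagnosis bit-for-bit.

## Performance

The permutation layer re-runs the hyperparameter search hundreds of times,
so the grid evaluator caches everything label-independent (fold index sets,
each training fold's signal-covariance whitener) and exploits the grid's
nesting: the f-filter xDAWN basis is the leading rows of the 6-filter
basis, hence each trial's f-specific augmented sample covariance is a
submatrix of the 24-row one, computed once per fold; the classifier is
warm-started along the C path from a shared Gram matrix. A consistency test
asserts the fast path is numerically identical to evaluating each
configuration independently. One full diagnosis (three feature sets, grid
search, 99 permutations each) takes ≈ 35 s on one CPU.

The simulation studies in `scripts/acceptance.py` use 9 responsive
datasets, 13 null datasets for specificity, 20 null datasets for the
chance-level estimate, and 99 permutations throughout — sizes chosen so the
whole script completes in roughly a quarter of an hour on a single core.
The specificity estimate is the noisiest of the three (a binomial fraction
at this scale has a standard error of ~9 points); larger characterization
runs during development (32 null datasets) put it at 87.5%.

## Known limitations

* The diagnosis deliberately reuses CV accuracy as the evidence statistic
  (no nested CV): the goal is to detect decodable structure within a
  session, not to certify generalization. The permutation null accounts
  for the selection, but the accuracies themselves remain optimistic point
  estimates of decodability.
* The min-P combination over the three feature sets is not
  multiplicity-corrected: with valid per-test p-values its dataset-level
  false-positive rate lies between α and 1 − (1 − α)³ ≈ 14.3% at α = 0.05,
  the exact position depending on how correlated the three statistics are.
  Under the generator's conditions (independent measurement noise per
  chromophore) it realizes near the upper end — 12.5% over 32 simulated
  null datasets — so the expected specificity (~87–90%) brackets the level
  a nine-participant cohort can resolve. This matches the method's
  specification rather than a Bonferroni-style bound.
* SNIRF support covers continuous-wave amplitude data with one measurement
  per channel/wavelength; frequency- and time-domain variants are out of
  scope. Montage separations ride in a JSON sidecar (SNIRF stores optode
  coordinates, not calibrated separations); without the sidecar, 3-cm
  separations are assumed with a warning.
* The simulator's spatial structure is schematic (channel-index profile,
  not a head model), which suffices for spatial-filter tests but not for
  montage-design questions.
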