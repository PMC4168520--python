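# Methods

This note records the models implemented, the numerical choices behind
them, what the synthetic generators do and do not emulate, and the
design decisions taken where the method left room.

## MKL-SVM solver

The classifier minimises the SVM dual value J(d) over simplex-
constrained kernel weights d.  The implementation alternates an exact
inner dual solve with a reduced-gradient step:

* **Inner QP.** Sequential minimal optimisation over maximal-violating
  pairs with second-order selection of the second index, run to a KKT
  violation below 1e-8 (box 0 ≤ α ≤ C, equality Σα_i y_i = 0).  The bias
  b is the mean of −y∇ over free support vectors (0 < α < C), falling
  back to the violating-pair midpoint when none are free.  Warm starts
  from a feasible α are supported (used by the grid-search oracle).
* **Gradient and direction.** ∂J/∂d_m = −½ αᵀ diag(y) K_m diag(y) α.
  The descent direction zeroes coordinates at the boundary whose partial
  derivative would pull them negative, moves active coordinates along
  the negative reduced gradient relative to the largest weight μ
  (smallest index on ties), and gives μ the balancing component so the
  direction sums to zero.
* **Line search.** Backtracking from the maximal feasible step γ_max
  (the step that drives the first weight to the boundary), halving up to
  20 times until the objective decreases.  Hitting γ_max zeroes the
  boundary weight exactly; weights below 1e-8 are snapped to 0 and the
  rest renormalised, keeping the zero-weight branch of the direction
  formula well defined.
* **Termination.** Duality gap max_m αᵀG_mα − Σ d_m αᵀG_mα ≤ ε with
  ε = max(0.01 · combined quadratic form, 1e-4) by default; both
  tolerances, C (default 100), the iteration cap (200) and the seed are
  exposed in `SolverSettings`.  The method's source does not fix C, ε,
  the line-search rule or the initialisation; the defaults here
  (uniform d₀, the tolerances above) are this package's choices, not
  inherited ones.
* **Invariants maintained.** Σd = 1 and d ≥ 0 after every outer
  iteration; the recorded J sequence is non-increasing; `converged`
  implies gap ≤ ε.  On instances small enough to enumerate, the final J
  matches an exhaustive 0.01-step simplex grid search using the same
  inner QP (tested).

Kernel matters: each training Gram is scaled to unit mean diagonal
(trace/n = 1) by default so no kernel dominates through scale alone;
rectangular test blocks reuse the training constants.  Features are
z-scored with training-fold statistics before kernel evaluation.  Both
behaviours can be disabled.  The sigmoid kernel is implemented but
excluded from the default bank, which is the published 13-kernel set
(poly degrees 1–3, RBF widths 0.5–20).  Whether the original experiments
standardised features or normalised kernels is not recorded anywhere;
both toggles exist for that reason.

Prediction maps a zero score to the positive class.  One-versus-rest
ties go to the earlier class label; each binary problem learns its own
kernel weights (the literal reading of training K independent binary
machines), and weight summaries pool the K weight vectors.

## Wavelet-packet entropy

Signals are decomposed with a full db4 packet tree, 4 levels by default,
symmetric signal extension.  Band components are sums of single-node
reconstructions; nodes are indexed in natural (frequency) order.

Two band maps ship:

* **literal** (default): level-4 nodes 0/1/2 for delta/theta/alpha and
  {level-4 node 3, level-2 node 1} for beta — the published node
  selection.  At 250 Hz a level-4 node spans 7.8125 Hz, so these nodes
  do *not* coincide with the nominal 0–4/4–8/8–12/12–32 Hz edges (the
  "theta" node actually spans 7.8–15.6 Hz, and the level-2 node spans
  31.25–62.5 Hz).  The map is kept literally anyway: reproducing the
  published selection takes precedence, and the discrepancy is surfaced
  here rather than silently corrected.
* **edge-accurate** (`edge_band_map`): level-5 nodes grouped by the band
  containing each node's centre frequency, honouring the stated Hz edges
  as closely as the dyadic grid allows.  Band-selectivity properties
  (e.g. a 6 Hz tone landing in theta) hold under this map and are tested
  under it.

**Entropy.** The default is the literal form SE = −Σ_t f(t)² ln f(t)²
(natural log; 0·ln 0 := 0; all-zero component → 0).  A normalised mode
(p_t = f(t)²/Σf², SE = −Σ p_t ln p_t) exists behind a flag.  The
normalised form is the common "wavelet entropy" but it is scale-
invariant, which makes it blind to band power by construction — under it
two task classes differing only in alpha amplitude are provably
indistinguishable in the alpha feature, which defeats the purpose of the
feature path.  The literal form keeps the energy dependence and is also
the formula as printed; hence the default.  Entropies are computed per
trial (per-sub-window computation was left out; nothing in the source
material determines it).

**Parseval.** Coefficient energy equals signal energy only for the
non-expansive orthogonal transform: periodization mode on lengths
divisible by 2^levels.  Symmetric extension (the default, which keeps
perfect reconstruction at any length) is expansive and inflates
coefficient energy by a boundary-dependent few percent.  The energy
checks in the tests therefore use periodization on dyadic lengths.

## Granger causality

Bivariate, pairwise (unconditional) causality between region-averaged
signals, matching the two-variable VAR formulation; conditional or
multivariate extensions are out of scope.  Signals are demeaned per
trial; VAR coefficients come from per-equation least squares on the lag
design (rank-deficiency raises).  The time-domain measure compares the
restricted AR(p) of the target alone against the full bivariate VAR(p)
at the same order.

The spectral measure uses H(f) = (I − Σ_j A_j e^(−i2πfj/fs))⁻¹,
S = HΣH*, and I₂→₁(f) = −ln(1 − (Σ₂₂ − Σ₁₂²/Σ₁₁)|H₁₂(f)|²/S₁₁(f)).
S₁₁(f) is taken from the model spectrum HΣH* (the printed description
calls S "the power spectrum of X1"; the model spectrum is the standard
Geweke reading, noted).  The argument of the log is clipped away from
zero for numerical safety; an unstable VAR (companion spectral radius
≥ 1) raises.  Frequency grid: 0 to fs/2 in 0.5 Hz steps; the theta
feature is the arithmetic mean of I over grid points in [4, 8] Hz
inclusive.  Model order defaults to the BIC minimiser over 1..20 per
fit, with a fixed-p override used wherever determinism and speed matter
(feature extraction in the studies uses p = 5).

A caveat found and respected in the tests: the identity "mean of I over
frequency ≈ time-domain F" only holds when the restricted AR is rich
enough; with strong coupling the target's own-past representation is
long, and comparing at p = 2 inflates F by a factor ~3.  Consistency
checks run at p = 10–12.

Region map (18-channel montage): fronto-central {FP1, FP2, F7, F3, Fz,
F4, F8}, left sensorimotor {C3, P3}, central {Cz, Pz}, right
sensorimotor {C4, P4}, occipital {O1, O2}; EOG channels excluded.  The
two-sample t-test on mean connectivity between groups is a thin
reporting utility (standard statistic, not part of the method).

## Preprocessing (ICA + orthogonalized EMD)

Off by default: no published rule specifies which components were kept
or how they were recombined before the causality stage, and inventing a
selection rule would misrepresent the method.  When enabled, ICA
(fixed-point log-cosh contrast after whitening, seeded, max 500
iterations, tol 1e-6; scikit-learn's FastICA behind this surface)
retains the highest-variance components to a 99% explained-variance
threshold and back-projects.  EMD uses classical sifting: cubic-spline
envelopes through maxima/minima with mirrored end extrema, a normalised
SD stopping criterion (< 0.05), at most 10 sifts per IMF and 10 IMFs;
monotone signals yield no IMFs.  Orthogonalisation is sequential
Gram-Schmidt with the projection coefficients folded back as scale
factors, so the orthogonal set still sums to the original signal minus
the residual.

## Synthetic data

The generators emulate the *statistical structure each feature path
assumes*, nothing more:

* **Mental-task EEG**: per class, each channel is a sum over the four
  rhythm bands of band-limited Gaussian noise (4th-order zero-phase
  Butterworth on white noise; delta's lower edge at 0.5 Hz so the filter
  is well posed) scaled by class band power and channel gain, plus a
  broadband noise floor (0.25).   6 channels, 250 Hz, 10 s trials.
* **Coupled-VAR regions**: five channels from a VAR(2) whose diagonal is
  an AR(2) oscillator (poles at the resonance frequency, default 6 Hz)
  and whose lag-1 off-diagonal terms realise a directed coupling matrix.
  256 Hz.  Stability is screened (companion radius < 0.98 required).
  One numerical fact shapes the defaults: a low-relative-frequency AR(2)
  resonator has enormous DC gain, so bidirectional lag-1 feedback of 0.4
  is only stable for pole radius ≲ 0.36.  The two-group study spec
  (bidirectional fronto-central coupling plus a left→right sensorimotor
  link, i.e. the pairs reported disconnected in patients) therefore uses
  radius 0.35 — broadband damped oscillators — while the unidirectional
  theta-resonant pair used for spectral-peak properties uses radius
  0.95 (no feedback loop, block-triangular, stable for any strength).
  The "resonance per coupling" idea is realised as one resonance for the
  region oscillators; a genuinely per-edge resonance is not expressible
  in a plain VAR without per-edge filter states and was left out.
* **Two-group study**: 13 subjects per group (patients = controls with
  designated couplings halved), 4 trials of 4 s per subject, and
  subject-level lognormal amplitude jitter (σ = 0.1) so subjects are not
  bit-identical.  Per-channel gain does not alter Granger causality, so
  the jitter adds realism without touching the effect being studied.

What passing tests on these generators shows: the pipeline recovers the
structure it is designed to detect, at the stated effect sizes, with
correct nulls (label permutation at chance).  What it does not show:
performance on real EEG — the generators have no 1/f background, no
artifacts, no nonstationarity, no volume conduction, and inter-subject
variability reduced to an amplitude factor.  Published accuracies on the
real recordings are not reproducible from this repository because those
recordings cannot ship with it.

## Cross-validation and determinism

Stratified 5-fold CV (80/20 per fold), shuffled with the run seed.  When
subject ids exist, folds stratify and split *subjects*, so no subject
contributes to both train and test (the grouped design of the two-group
study makes pooled-trial CV leak identity information; subject-wise
folds are the defensible default).  Feature standardisation is fit on
training folds only, inside the model fit.  Label-permutation controls
shuffle at the subject level for grouped data, and chance confidence
intervals are computed on the number of independent units (subjects for
grouped data, trials otherwise).  Every entry point takes a seed; reruns
with the same config and seed are bit-identical.

## Problem sizes

The bundled studies run at desk scale, chosen once: solver-oracle
comparisons on n ≤ 20, M ≤ 3 instances (enumerable simplex); causality
recovery at n = 20000 with a 200-pair null at n = 2500; 40 trials/class
for the mental path; 13 + 13 subjects × 4 trials for the connectivity
path.

## Known limitations

* ℓ1 (simplex) MKL only; no ℓp>1 norms, no kernel alignment criteria.
* Pairwise GC can report indirect influence as direct; no conditional
  variant.
* EMD end effects are tamed by mirroring only; no ensemble EMD.
* The literal band map's node/Hz mismatch means "theta" features from it
  partially reflect 8–15 Hz activity at 250 Hz; use the edge-accurate
  map when physiological band fidelity matters more than replicating the
  published node selection.
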