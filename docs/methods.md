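# Methods

## Model

An EEM cube is a three-way array x (I samples × J emission × K excitation
wavelengths). Under dilute-solution conditions fluorescence is additive
and separable per fluorophore, so the cube follows the trilinear PARAFAC
model

    x_ijk = Σ_f a_if · b_jf · c_kf + e_ijk,

where a_if are per-sample component magnitudes ("scores", proportional to
relative fluorophore concentration) and b·f, c·f the emission and
excitation profiles ("loadings"). Given trilinearity and a correct
component number F, the decomposition is unique up to permutation and
scaling, so the loadings estimate real spectra rather than abstract
factors. All three factor matrices are constrained non-negative, which
both matches the physics (intensities, concentrations and spectra are
non-negative) and strengthens identifiability.

Canonical form: loading columns have unit Euclidean norm, the magnitude
sits entirely in the scores, and components are ordered by decreasing
score energy Σᵢ a²ᵢf with lexicographic tie-breaking on the emission
loading. This makes fits deterministic given (data, F, seed, number of
starts).

### Fitting

Alternating least squares: each factor matrix in turn is the exact
minimizer of the residual sum of squares with the other two fixed, subject
to non-negativity. The per-mode subproblem decomposes row-wise into small
NNLS problems sharing one F × F Gram matrix (the Hadamard product of the
other two factors' Gram matrices); rows whose unconstrained solution is
already non-negative are accepted directly (identical to the constrained
optimum), the rest are solved by an active-set method on the Gram system
(fast NNLS). Because every block update is an exact minimization, the SSE
trace is non-increasing — an invariant asserted in the tests.

Defaults: convergence when the relative SSE change drops below 1e-8,
at most 2000 sweeps, 10 starts — one deterministic start from the
magnitudes of the leading singular vectors of the emission/excitation
unfoldings, nine seeded random non-negative starts — keeping the
lowest-SSE solution. On the 144 × 71 × 26 default cube a full 10-start
fit takes well under a minute on one CPU.

### Diagnostics

* Explained variance: 100·(1 − SSE/ΣΣΣ x²), computed on the raw
  (uncentered) preprocessed cube.
* CORCONDIA: the least-squares Tucker core G for the fixed loadings
  (computed by contracting the cube with the factor pseudo-inverses) is
  compared with the F × F × F superidentity T:
  100·(1 − Σ(g − t)²/Σ t²). Values near 100 indicate appropriate
  trilinear structure; strongly negative values indicate overfactoring.
* Tucker congruence (cosine similarity of loading vectors) with exact
  Hungarian assignment is used wherever components from two models must
  be matched; greedy matching is never used.

## Acquisition grid and preprocessing

The protocol records emission 300–650 nm (5 nm steps) at excitation
250–500 nm (10 nm steps). For λex ≥ 290 nm acquisition starts at
λex + 20 nm; below 290 nm the full 300–650 nm range is measured. On this
grid 506 of the 71 × 26 cells are never measured (the triangular region
along the Rayleigh diagonal); the count is frozen as a regression
constant in the tests.

PARAFAC needs complete data, so the unmeasured region is filled before
fitting. Cells at or below the Rayleigh line (λem ≤ λex) are set to zero
— zero-Stokes-shift fluorescence is negligible and whatever the
instrument would see there is elastic scatter, not trilinear signal. For
the band between the Rayleigh line and the first measured point two
schemes are implemented:

* **ratio** (default): the cell (j, k) is estimated from the nearest
  excitation column k′ that measures emission row j, rescaled by the
  intensity ratio of the two columns at the first emission row column k
  measures: x̂[j,k] = x[j,k′]·x[m_k,k]/x[m_k,k′]. For locally rank-one
  data this is exact; in general it preserves trilinear structure far
  better than any fixed ramp shape, because the imputed band inherits the
  spectral shape of an adjacent measured column. Estimates with weak or
  unstable denominators fall back to the linear ramp.
* **linear**: a ramp from 0 on the Rayleigh line to the first measured
  intensity. Simple, monotone and bounded by the anchor, but it imposes a
  straight flank on what is physically a convex band edge; on synthetic
  trilinear data this injects enough non-trilinear structure (~0.2% of
  the total sum of squares) to visibly depress the explained variance
  and distort the recovery of overlapping UV components. It is retained
  as an option and for sensitivity analyses (`band_halfwidth` narrows
  the interpolated band).

Neither scheme touches a measured cell, and preprocessing records the
imputed cell list in the cube's provenance. Raman or second-order
Rayleigh features are not handled: the modelled instrument geometry shows
neither.

## Model-order selection

Two criteria jointly choose F:

* Residual scan, F = 1..8 by default: explained variance must still grow
  by more than 0.02 percentage points over F − 1 (the noise-floor
  tolerance; at the default noise level extra components beyond the true
  rank add ≪ 0.02 pp).
* Split-half validation: the cube is split into two halves (by cell line
  in the default design, matching the study layout; stratified random
  halves and explicit index sets are also supported), models are fitted
  independently on each half, components matched by joint
  emission × excitation congruence, and F passes when the minimum matched
  congruence is ≥ 0.95 in both spectral modes. 0.95 is the conventional
  "same loadings" bar; it is a parameter.

The chosen F is the largest candidate passing both. Scan fits use
lighter settings than a final fit (3 starts, tol 1e-7, ≤ 800 sweeps):
selection needs stable loadings, not machine-precision convergence, and
this keeps a full scan (8 full + 16 half fits) at roughly two to three
minutes. On the default synthetic cube the procedure selects F = 5: the
gain from the fifth component is ~0.18 pp, the gain from a sixth is
< 0.01 pp and the sixth component does not replicate across halves
(matched congruence ≈ 0).

## Viability calibration and statistics

Per cell line, MTT viability (% of control; each fluorescence sample is
assigned its dose group's MTT mean) is regressed on the F scores by OLS
with intercept. Leave-one-out cross-validation uses the closed-form
deleted residuals e_i/(1 − h_ii), which are algebraically identical to
per-fold refits (verified against explicit refits in the tests). LOO was
chosen over k-fold because the per-line sample counts are small and LOO
is deterministic. Predictions are not clipped to [0, 100]; out-of-range
values are flagged so the accordance analysis stays linear.

The accordance fit regresses predicted on reference dose-group means
(unweighted by default; 1/SD² weighting available) and reports slope and
intercept with 95% confidence intervals from the OLS t-distribution. The
two methods are "ideal-consistent" when the slope CI contains 1 and the
intercept CI contains 0.

Group comparisons use classical one-way ANOVA and equal-variance Tukey
HSD (studentized-range p-values; no Games–Howell variant) at α = 0.05
and 0.01, with the group sizes as given — MTT groups have 5 replicates,
fluorescence-derived groups 12; the module never resamples to equalize.
The disagreement list compares each source's significance verdicts with
the MTT reference pair by pair; the interesting direction is a pair the
MTT test discriminates that a fluorescence-derived source does not (or
vice versa).

## Synthetic study generator

The generator emulates the study design: cell lines A375 (doses 0, 5, 50,
250, 500, 1000 μM) and HaCaT (0, 5, 25, 100, 250, 500 μM), 12 replicates
each, 144 samples. Dose → viability follows a fixed map (A375:
100/90/80/60/10/10%; HaCaT: 100/90/70/65/50/10%).

Five fluorophore prototypes define the truth loadings, each a sum of
Gaussian bands evaluated on the grid, non-negative and unit-norm:

| component | excitation (nm) | emission (nm) | bands σ (nm) |
|---|---|---|---|
| 1 tryptophan-like | 290 | 330 | 13 / 18 |
| 2 tyrosine-like | 280 | 310 | 12 / 12 |
| 3 pyridoxine-like | 300 | 380 | 15 / 20 |
| 4 flavin/porphyrin-like | 390 & 440 | 520 & 590 (bimodal) | 20 |
| 5 NADH-like | 360 | 450 | 20 |

Two shape refinements matter and are deliberate:

* The small-Stokes-shift aromatic components (1–2) carry a sigmoid
  excitation red-edge cutoff and emission onset (5 nm edge width).
  Symmetric Gaussian tails would place appreciable intensity at
  λem ≤ λex — physically absent, and precisely the region the protocol
  never measures and the preprocessing zeroes. Without the edges the
  masked-and-refilled cube is measurably non-trilinear and both fit
  quality and component recovery degrade.
* Component magnitudes make the tryptophan-like signal dominant (scores
  ~5–20 vs. ~1–4 for the rest), matching the intensity landscape of
  cultured cells, whose UV protein fluorescence dwarfs the coenzyme and
  flavin signals.

Scores are linear in viability, score_if = baseline_f + slope_f·viab_i,
with positive slopes for components 1, 4, 5 (signal falls as cells die)
and negative for 2, 3 (signal rises), multiplicative Gaussian replicate
noise (CV 3%), truncation at zero, and optional effects that default to
off: a per-replicate drift term and an inner-filter-like attenuation of
component 3 at the lowest viabilities. Linearity in viability is a
modelling choice that makes MLR the correct calibration model — it
mirrors the approximate linearity a successful linear calibration
implies, nothing more.

Measurement noise is i.i.d. Gaussian with RMS equal to 0.1% of the
noise-free signal RMS, the regime in which the five-component fit of the
preprocessed cube explains ≥ 99.93% of the variance. The MTT reference
simulates 5 replicate absorbance ratios per group (CV 5%) normalized so
the control mean is exactly 100%.

What the generator does **not** emulate — hence what passing tests do not
show about instrument data: inner-filter distortion of strong absorbers
(beyond the optional flag), Raman and second-order scatter, wavelength-
dependent detector response, photobleaching over the 12 replicates,
non-Gaussian spike noise, and fluorophores beyond the five prototypes.
Real comp-2-type signals whose emission maximum lies inside the excluded
300–320 nm band can at best be recovered as truncated profiles.

## Numerical choices and degenerate inputs

* NNLS: active-set on the Gram system; tolerance 10·eps·max|ZtZ|·n;
  exact, not a clipped unconstrained solve. Rank-deficient designs raise
  unless an explicit ridge is enabled.
* ALS SSE is computed via the Gram identity per sweep (no full
  reconstruction), and convergence is declared on relative SSE change;
  SSE below 1e-14 of the total SS short-circuits (exact fits).
* Over-factored fits routinely collapse a component to zero; the
  resulting singular Gram matrices get a tiny ridge (1e-12·trace/F) and
  are logged at debug level.
* Explained variance on an all-zero cube, ANOVA on fully identical
  observations, accordance with < 3 groups, LOO with leverage 1 — all
  raise with explicit messages rather than returning NaN.
* Ties in component energy are broken lexicographically on the emission
  loading; split-half passes/fails are invariant to sample order within
  halves.

## Known limitations

* The ratio fill assumes neighbouring excitation columns have similar
  component mixtures; EEMs with spectrally isolated narrow excitation
  bands right at the mask edge would stress it (the linear-ramp fallback
  bounds the damage).
* Split-half supports a single two-way split per call, not multi-split
  (S4C4-style) schemes.
* No PARAFAC2 or Tucker3 modelling, no unimodality or orthogonality
  constraints, no weighted/missing-data ALS — completeness is guaranteed
  by preprocessing instead.
* Physical plausibility of loadings (peak assignments to specific
  fluorophores) is reported but never used as a selection criterion; the
  names attached to prototypes are mnemonic, not chemical claims.
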