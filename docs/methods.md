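# Methods

This note documents the modeling choices behind `lscpm`: what each stage
assumes, which parameters matter and why their defaults are what they are,
what the synthetic generator does and does not emulate, and the numerical
and design decisions taken where the protocol leaves room.

## Preprocessing model

The chain is drop-initial → nuisance regression → band-pass → scrub →
correlation, applied per subject.

- **Initial drop** removes ceil(10 s / TR) frames (14 at TR = 0.72 s) to
  discard pre-steady-state signal.
- **Nuisance regression** is a single OLS per ROI against 20 regressors:
  intercept, centered linear trend, 6 motion parameters, 3 tissue means,
  and backward-difference derivatives of the 9 signal regressors (first row
  zero). Linear detrending is folded into this model as the trend regressor
  rather than run as a separate pass; a rank-deficient design falls back to
  the pseudoinverse with a logged warning. Residuals are orthogonal to every
  regressor column to ~1e−8 of the data scale (tested).
- **Band-pass** is a 4th-order Butterworth at 0.008–0.1 Hz applied
  forward–backward (zero phase). The protocol names only the band; the
  Butterworth/filtfilt combination is the field convention. Measured
  response: gain 1.01 at 0.05 Hz, 0.002 at 0.3 Hz.
- **Framewise displacement** is the Power convention: sum of absolute
  frame-to-frame translation differences plus 50 mm times the sum of
  absolute rotation differences (rotations in radians; input files must
  declare units). FD at the first frame is 0.
- **Scrubbing** removes exactly the frames with FD strictly above 0.5 mm —
  no neighbor augmentation, boundary frames retained — and does not
  interpolate. A subject with fewer than `min_frames` (default 50)
  surviving frames is flagged and excluded, with the reason reported. The
  protocol quantifies neither the ordering of scrubbing relative to
  filtering nor a motion-exclusion criterion; we scrub after filtering and
  expose `min_frames` in place of the unquantified "excessive motion" rule.
- **Connectivity** is the Pearson correlation over retained frames,
  Fisher-transformed. |r| ≥ 1 − 1e−12 raises a degenerate-correlation error
  rather than emitting an infinite z; zero-variance ROIs are an error naming
  the ROI. The canonical edge ordering is the strict lower triangle in
  row-major order, k = i(i−1)/2 + j for i > j (0-based internally; atlas
  files are 1-based at the I/O boundary only).

## Prediction model

PCA is fit once on the full discovery matrix before the CV split, exactly
as the protocol diagrams it. This is unsupervised leakage-free with respect
to y, but it does couple the folds through the shared basis and centering;
a consequence worth knowing is that with K = n − 1 components the n score
vectors are linearly dependent (they sum to zero), which biases the
distribution of out-of-fold Pearson r — negatively on average across
cohorts (the familiar CV r bias), with a cohort-specific offset within one
cohort's permutation distribution. Neither bias affects validity: the
permutation null is built by the identical procedure, so observed and null
r share the bias and the test calibrates (measured rejection rate 0.08 at
α = 0.1 over 50 effect-free cohorts). Out-of-fold r should therefore not be
read as an unbiased effect size. A strictly nested variant (PCA refit per
fold) was deliberately not made the default, to match the protocol.

Ridge is solved in closed form with an unpenalized intercept on centered
scores. The inner CV (5 folds, seeded) eigendecomposes the training Gram
matrix once per inner fold and sweeps the whole λ grid through it, which is
what makes 5000-iteration permutation refits tractable. The grid defaults
to 13 log-spaced values 10⁻³…10³ (the protocol names no grid); MSE ties
break toward the larger λ, i.e. toward more regularization. PC scores enter
the ridge without further standardization — they are already centered, and
rescaling them would silently change what λ means. Fold assignment is a
seeded uniform shuffle into k groups with sizes differing by at most one,
no stratification. `k = n` is accepted as the leave-one-out reduction; all
other k require n ≥ 2k. A repeated-CV mode (`n_repeats`) averages
out-of-fold predictions over independent fold draws for users who read
"averaged predicted scores" as a discovery-side average; the default is a
single pass, with the averaging interpretation reserved for the
validation-side fold-model average.

## Permutation inference

Each iteration shuffles y, re-draws the outer folds, refits the full nested
CV on the fixed PC scores, and evaluates exactly as the observed statistic
was evaluated. PCA is reused across iterations — a y-shuffle cannot change
an unsupervised fit, so this is an exactness-preserving optimization. The
p-value is the add-one estimator, one-sided toward positive predictability
(the directional hypothesis of the protocol); a two-sided flag exists.
Per-iteration seeds are derived from the master seed up front, so results
are independent of execution order. If a degenerate null fit produces
constant predictions, that iteration's r is defined as 0; the public
`evaluate` stays strict and raises on constant input.

## Contribution and enrichment

Back-projection w_f = T β_f is exact, not approximate: the identity
b_f + w_fᵀ(x − center) = b_f + β_fᵀ s(x) holds to machine precision and is
enforced in tests at 1e−8. Intercepts are excluded — they carry no edge
information. The per-edge one-sample t-test uses df = folds − 1 and
two-sided p (the protocol does not state sidedness; the sign is taken from
the mean weight, matching its positive/negative split). Exactly-constant
fold weights are degenerate: p = 1 if the constant is zero, else p = 0 with
a logged degenerate flag.

Enrichment uses the hypergeometric upper tail P(X ≥ k) with population =
all E edges, successes = the network pair's K_c edges, draws = the tested
sign-specific set. The choice of population (all edges, not only
significant ones) follows the cited edge-overlap approach and is
configurable in spirit — the function takes the significant set and pair
map explicitly. α = 0.025 per sign family reflects splitting 0.05 over the
positive and negative tests, each further Bonferroni-corrected over 45
pairs.

## Synthetic cohorts

The generator's job is to produce data with the statistical structure the
analysis assumes, under known ground truth; it is not an fMRI simulator.

**Edge mode** draws z_ie = μ_e + γ_e·(LS_i − μ_LS)/σ_LS + ε_ie with
μ_e ~ N(0.2, 0.1) in Fisher-z units — a typical empirical connectivity
range whose back-transform stays well inside (−1, 1) — γ_e = `effect_size`
at the planted edges and 0 elsewhere, and ε ~ N(0, `edge_noise_sd`). LS is
N(54.5, 9.0), matching the discovery cohort's reported distribution.
Real connectome edge-value distributions are not publicly characterized;
these baselines are conventions, and nothing downstream depends on them
beyond plausibility.

**Time-series mode** realizes the same coupling through shared latent
sources: each planted edge (i, j) receives a common source with loading
√(ρ/(1−ρ)), ρ = clip(0.30 + δ_s + 0.15·effect_size·z_LS, 0.02, 0.9), so the
model-implied edge correlation rises linearly with standardized trait score
at slope 0.15·effect_size around a 0.30 baseline (δ_s is a small
per-subject offset, shared within sibling pairs when `family_pairs` > 0).
Tissue signals are smoothed noise mixed weakly into all ROIs (removed again
by nuisance regression); motion is a random walk (0.02 mm and 4·10⁻⁴ rad
steps) with Bernoulli(`motion_spike_rate`) spike frames receiving a
0.6–1.5 mm translation jump — guaranteed FD > 0.5 mm — plus a broadband
artifact across ROIs, so scrubbing is deterministically triggered and
visibly matters.

**Family structure** (edge mode) adds a pair-shared baseline offset
δ_e ~ N(0, 0.1) and within-pair noise correlation 0.5. This reproduces the
inflated within-family profile similarity that motivates unrelated-subject
selection; the pipeline itself does not model relatedness, mirroring the
protocol's subject-selection approach.

What the generator does **not** emulate: hemodynamics, spatial structure
within networks, autocorrelated BOLD noise, scanner drift beyond a linear
trend, distance-dependent motion artifacts, or realistic edge covariance
(edges are conditionally independent given the latent sources). Passing
tests therefore demonstrate that the *pipeline machinery* is correct and
calibrated under its own assumptions — not that the effect sizes it
recovers on real cohorts would match.

## Problem sizes

The test suite and acceptance script scale the studies to desk size as the
package's own choice of fixture: null calibration uses 50 effect-free
cohorts (n = 60, R = 30) with 99-permutation tests at α = 0.1; parameter
recovery uses 20 replicates of n = 100, R = 40, 30 planted edges at effect
0.5 and unit noise; the end-to-end smoke run uses 24 subjects, R = 20,
4 folds and 19 permutations. The protocol-scale defaults (R = 427, 10
folds, 5000 permutations) remain the `RunConfig` defaults for real runs.

## Known limitations

- Full-sample PCA (protocol-faithful) means discovery out-of-fold r is a
  biased effect-size estimate; rely on the permutation p, or use the nested
  variant for unbiased evaluation.
- Two-session concatenation, neighbor-frame scrubbing, and alternative
  filter families are not implemented; the preprocessing order is fixed
  (and logged) rather than configurable per stage.
- The enrichment population convention (all E edges) is one of two
  defensible readings; with very large significant sets the within/between
  base rates dominate either way.
- The CLI parallelizes nothing; permutations are sequential (the batched
  λ-grid solver keeps 5000 iterations tractable, but wall-clock scales
  linearly in `n_perm`).
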