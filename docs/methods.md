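# Methods

This note documents the model, the estimators, the synthetic-data
generator, and the numerical and design choices behind `circadiv`.

## Model and assumptions

Cells elongate exponentially, `dL/dt = ζ·α(t)·L`, with a mean rate
`α(t)` shared by the population and a per-cell amplitude
`ζ ~ Normal(1, σ_ζ)` truncated to positive values (the truncation is a
package choice; negative growth amplitudes are unphysical).  Division is
a point process with hazard

Γ(L, L0, ∂L/∂t, t) = S(Δ0) · G(τ(t)) · ζ·α(t)·L,  Δ0 = L − (1+a)·L0.

Assumptions inherited from this form:

* size control acts through the birth-length-independent added length
  Δ0 only — not through absolute length, age, or growth rate;
* the clock enters as a positive multiplier `G` that depends only on
  the time of day τ, with τ = 12 at dawn (entrainment convention shared
  by all modules);
* growth and division both stop in the dark, because `α = 0` implies
  `Γ = 0` (no divisions were ever observed in darkness).

**Hazard family.** `S` must be monotone non-decreasing for the thinning
bound to be valid; only that qualitative property is fixed by the
biology.  We use the Weibull form `S(Δ0) = (k/λ)(Δ0/λ)^(k−1)` for
Δ0 > 0: it nests the constant hazard at `k = 1`, rises roughly linearly
at `k ≈ 2` (as empirical hazard estimates do), and gives a closed-form
added-length distribution used throughout the tests.

**Truncation subtlety.** For sizer-like control (`a < 0`) a newborn is
already past the point Δ0 = 0: hazard accumulates from
Δ0(birth) = −a·L0 > 0, so Δ0 at division follows a *left-truncated*
Weibull whose truncation point moves with birth length.  Two
consequences are easy to miss: (i) the plain Weibull closed form is
exact only for `a ≥ 0` (the adder case is used for the exactness
checks; a probability-integral-transform test covers `a < 0`); (ii) the
marginal regression slope of added vs birth length is attenuated toward
zero relative to the generative `a`, because the truncation raises the
conditional mean of Δ0 for larger newborns.  The likelihood-based
estimator accounts for the truncation explicitly; the regression slope
is reported as the descriptive, attenuated quantity it is.

## Exact simulation

The thinning algorithm advances each cell over horizons of length
`dt_horizon` (default 0.75 h).  Growth within a horizon is integrated in
closed form (`∫α` has analytic antiderivatives for both the cosine
oscillation and the half-sine LD profile).  The dominating rate

B = S(L(t+Δt) − (1+a)L0) · Gmax · ζ · αmax · L(t+Δt)

bounds Γ throughout the horizon because length is non-decreasing, `S`
monotone, and `G`, `α` bounded (`Gmax` is taken as 1.5× the maximum of
the current `G` on a dense grid; `αmax` analogously in closed form).
Candidate times are drawn from an exponential clock at rate `B`,
evaluated with the exact state at the candidate time, and accepted with
probability Γ/B.  On division the length halves, the birth length
resets, and ζ is resampled.  A cross-validation simulator
(`circadiv.finestep`) implements the same process by brute force —
Bernoulli division with probability Γ·h on a fine grid (h = 10⁻³ h) —
sharing no code with the thinning path; the two agree in distribution
(Kolmogorov–Smirnov distance < 0.03 on added lengths and division
phases).

## Observation model and what the generator does (not) emulate

Lengths are sampled on a regular frame grid (`dt_acq`, default 0.75 h in
constant light and 1 h in LD, matching typical acquisition) with
additive Gaussian noise (default SD 0.03 µm, a realistic segmentation
error at 100× magnification).  For a division between frames f and f+1
the parent's division length is recorded at frame f and each daughter's
birth length at frame f+1, so recorded cycles are systematically short
by one frame in expectation.  Cells whose whole cycle falls between two
frames are unrecordable and dropped; cells alive at the end are emitted
censored.  The first, partially observed cycle of each lineage is
excluded, mirroring the unobservable history of experimental lineages.

The generator emulates: discrete noisy acquisition, lineage censoring,
the two strains (wild type vs `G ≡ 1`), constant-light and flux-matched
graded LD conditions at ~1,000–1,500 cells per condition.  It does not
emulate: segmentation/tracking failures, asymmetric division, spatial
crowding, cell death, photoinhibition, or clock re-entrainment
transients.  Passing tests therefore validate the estimators under the
model's own idealized observation process, not against every failure
mode of real microscopy data.

### Generator defaults (study conditions)

| parameter | default | rationale |
| --- | --- | --- |
| a | −0.35 | clock-deletion regression slope reported for constant light |
| k | 2 | roughly linearly rising hazard |
| λ | 4.5 µm | stationary birth length ≈ 3 µm, matching the 2.4–4.0 µm strata |
| σ_ζ | 0.15 | moderate cell-to-cell growth variability |
| ᾱ | 0.06 h⁻¹ | ≈ 11.5 h doubling at 15 µE·m⁻²·s⁻¹ |
| ε, phase | 0.2, 18 h | circadian elongation-rate oscillation in wild-type constant light; 0 for clock deletion |
| c | ᾱ/15 | light-tracking slope, so LD growth is flux-matched to constant light |
| G (wild type) | spline bump: basal 0.25, height 3, peak τ = 22 | low through subjective night/early day, sharp promotion at the end of subjective day; basal level chosen so that night-time divisions are suppressed strongly enough to produce the two subpopulations and the emergent slope steepening |

The wild-type coupling is an 8-knot periodic spline sampled from a
von-Mises-style bump whose center is adjusted (once, by bisection at
construction) so the spline's dense-grid argmax sits at the nominal peak
time.

## Size-control estimation

`empirical_hazard` is a life-table estimator in added length: within a
birth stratum, hazard(x) = events in [x, x+dx) / (dx · cells with added
length ≥ x), with 95% percentile bootstrap intervals resampling whole
cells (1,000 resamples) to respect within-cell dependence.

`SizeControlModel` maximizes a likelihood designed to be unbiased under
discrete, noisy acquisition; each ingredient was validated by parameter
recovery on synthetic data at experimental scale (~1,300 cells):

1. **Endpoint reconstruction.**  Each cell's frames are fit by OLS of
   log length on time; recorded birth and division lengths are replaced
   by the fitted line evaluated half a frame before the recorded birth
   and after the recorded division (the expected true event times).
   Slopes are shrunk empirical-Bayes toward the population mean rate —
   for 2–3-frame cells the raw slope error far exceeds the true
   cell-to-cell rate spread, and those short cycles carry most of the
   information about `a`.
2. **Noise-aware likelihood.**  The added length has a hard support
   edge at zero that does not move with `a`; the left-truncated Weibull
   density (in added-length space) is convolved with the Gaussian
   endpoint-estimate error, whose per-cell variance follows from the
   OLS prediction variance, the endpoint covariance, and the
   frame-timing jitter ((r·dt)²/12 in log length per endpoint).  The
   convolution uses 24-point Gauss–Legendre nodes that track the moving
   overlap of the noise window with the support, which avoids the
   spurious likelihood wiggles a fixed-node quadrature produces as the
   truncation boundary slides across nodes.
3. **Recordability conditioning.**  A cycle spanning fewer than two
   frames is never recorded; with a uniformly phased grid that happens
   with probability 1 − clip(D/dt − 1, 0, 1) for a cycle of duration D.
   Each recorded cell's density is conditioned on being recordable
   (normalization computed analytically outside the short-cycle window).
4. **Censored cells** contribute survival terms (their last observed
   frame comes from the trace table), which corrects the
   renewal-process inspection bias of complete-cycle sampling.

Optimization is a multi-start over `a` (Weibull fits of the transformed
added lengths as inner initializers) followed by Nelder–Mead; intervals
are profile-likelihood at the χ²₁ 95% cutoff.  With all four ingredients
the recovery bias of `a` is below 0.01 with SD ≈ 0.05 at n ≈ 1,300
(10 replicate datasets); removing any one of them reintroduces biases
of 0.05–0.3.  `correction="none"` deliberately skips ingredients 1–2
(raw endpoints, noise variance from trace residuals only), reproducing
the biased naive estimator.

## Coupling inference

Because `Γ dt = S(Δ0) G(τ) dL`, the total log-likelihood of all cells is

Σ_divisions log G(τ_div) − Σ_j w_j G(τ_j) + const,

with G-independent quadrature weights `w_j = S(Δ0(L_j)) ΔL_j` along the
piecewise-exponential reconstruction of each trace (3 subdivisions per
frame interval; midpoint rule, exact for the constant-hazard case).
Both sums are accumulated once onto a 192-bin time-of-day grid, making a
likelihood evaluation O(grid) regardless of data size.  Measurement
noise is *not* deconvolved in this likelihood (limitation; its effect on
G is second order because the weights integrate over many frames).  A
half-frame time correction (division times shifted +dt/2, histories
extrapolated half a frame at each end) mirrors the size-control
correction; without it the recovered peak shifts ~0.4 h early.

The prior is zero-mean Gaussian on the periodic second differences of
the knot log-values (scale 1.0 — only smooth/positive/periodic is
assumed) plus a weak Gaussian on the mean log level (scale 3.0) that
makes the prior proper.  Sampling uses the affine-invariant ensemble
sampler (emcee; 24 walkers × 1,200 steps by default, first half
discarded), seeded and with acceptance fraction and a minimum
effective-sample-size estimate reported; ESS < 100 triggers a warning.
The scale of G is anchored by fixing the size-control parameters from
clock-deletion data; the profile likelihood over a global G-scale is
strictly concave (tested).

Calibration, measured over 20 replicate wild-type datasets at ~1,000
cells: posterior-mean peak within 0.2 h of the true peak on average, and
aggregate knot-wise 95% credible coverage ≈ 88%.  Coverage is not
uniform across knots — at the sharp peak the smoothness prior and the
8-knot resolution shrink the posterior slightly below the truth — so the
coverage contract is stated as an aggregate across knots, not per knot.

The **division-time model** replaces Γ by `h(age)·G(τ)` with a Weibull
base hazard in cell age, inferred jointly (per-cell age grids, 0.25 h
steps).  `G` and `h` share an exact scale degeneracy, resolved by
anchoring G to geometric mean 1.  Its posterior bands are wider than the
trace-based model's at the coupling peak — the length history is what
sharpens the end-of-day peak.

## Population analyses

Subpopulations are found with a mixture of (von Mises in birth phase) ×
(Gaussian in standardized log cycle duration), fit by seeded multi-start
EM.  Two model-selection nulls are compared by BIC against the
two-component model: a single component, and a two-component *duration*
mixture whose components share a uniform phase distribution.  The second
null matters: cycle-duration marginals are right-skewed even without any
clock, and without it a mixture criterion reports spurious
subpopulations in clock-deletion data.  (A Gaussian mixture on the
(sin τ, cos τ, duration) embedding was tried first and rejected: the
unit-circle ring itself is bimodal to a Gaussian, so the null never
selects one component.)  The component with the smaller mean duration is
labeled *fast*.

Size-control classes follow the CI rule: adder-like if the 95% CI of
the added-vs-birth slope contains 0, otherwise sizer-like (negative) or
timer-like (positive) — sample-size aware, unlike a fixed slope
threshold.  Division-time windows are central quantile intervals of
division times in hours after the most recent dawn (dawn-to-dawn days
also define the same-day/next-day labels in LD).

## Numerical choices and degenerate inputs

* Times in hours, lengths in µm everywhere; columns suffixed `_h`/`_um`.
* Periodic splines built with `scipy` `CubicSpline(bc_type="periodic")`;
  positivity of G by construction (exponential parametrization).
* Empty strata are skipped with a warning; degenerate regressors raise;
  fewer than 4 coupling knots, k < 1, or non-positive lengths raise.
* Zero-cell coupling inference returns the (proper) prior.
* All stochastic components take explicit seeds; identical seeds give
  byte-identical outputs.

## Problem sizes

Simulated studies use ~1,000–1,500 cells per condition (120–160
lineages over 120 h), the scale of the experimental datasets.  The
exactness checks use 10⁴ cycles against the closed form and 5×10³
against the fine-step oracle; coupling calibration uses 20 replicate
datasets with a reduced sampler (24 walkers × 800 steps), which the
diagnostics show is ample for an 8-knot posterior.

## Known limitations

* Measurement noise enters the size-control likelihood but is not
  deconvolved in the coupling likelihood.
* The Weibull hazard family and the linear Δ0 law are parametric
  choices; the nonparametric hazard estimator provides the model check.
* Per-condition fits only: size-control parameters are re-estimated for
  each light condition rather than shared across conditions.
* The clock phase in LD is anchored at dawn (τ = 12); a
  `dawn_offset`/phase parameter exists but alternative entrainment
  conventions (e.g. midday-locked in long photoperiods) are not
  explored.
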