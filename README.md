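# circadiv

Stochastic modelling of circadian-clock-modulated cell size control in
the cyanobacterium *Synechococcus elongatus*.

Dividing cells must decide *when* and *at what size* to divide.  In
*S. elongatus* that decision integrates three signals: an intrinsic cell
size control, the 24-h circadian clock, and the ambient light that sets
the growth rate.  This package implements a phenomenological model of
that integration as a fully tested pipeline — an exact stochastic
simulator of growing and dividing lineages, estimators for the
size-control law and the clock coupling function, and the population
analyses that expose the clock's fingerprints (fast/slow subpopulations,
size-control slopes, division-time windows) under constant light and
graded light–dark (LD) cycles.

## The model

The instantaneous division rate of a cell of length `L` born at length
`L0` is the product

```
Γ(L, L0, ∂L/∂t, t) = S(L, L0) · G(t) · ∂L/∂t
```

* `S(L, L0) = S(Δ0)` — the size-control hazard, a rate per unit of added
  length that depends only on the birth-length-independent part of the
  added length, `Δ0 = L − (1 + a)·L0`.  This encodes the linear
  size-control law `Δ = a·L0 + Δ0`: `a = 0` is an adder, `a → −1` a
  sizer, `a > 0` timer-like.  `S` is Weibull-form with shape `k ≥ 1` and
  scale `λ` (µm), so `Δ0` at division follows a (left-truncated)
  Weibull(k, λ) distribution.
* `G(t)` — a positive, smooth, 24-h-periodic coupling function of the
  time of day imposed by the clock; `G ≡ 1` models clock-deletion
  (ΔkaiBC) cells.  Dawn corresponds to time of day τ = 12 h.
* `∂L/∂t = ζ·α(t)·L` — exponential elongation with mean rate `α(t)`
  (oscillatory in constant light, proportional to irradiance in LD
  cycles, hence zero in the dark) and a per-cell amplitude
  `ζ ~ Normal(1, σ)`.

Under LD cycles the time-dependent part of the rate is the *effective
coupling* `G(t)·α(t)`, which steers divisions away from dawn and dusk.

Lineages are simulated exactly by thinning: within a time horizon the
rate is dominated by `B = S(L(t+Δt) − (1+a)L0)·Gmax·ζ·αmax·L(t+Δt)`,
candidate division times arrive at rate `B` and are accepted with
probability `Γ/B`.  An observation model reproduces time-lapse
acquisition: lengths sampled on a frame grid with Gaussian noise,
division lengths recorded one frame early and birth lengths one frame
late.

`G(t)` is inferred by Bayesian MCMC from single-cell length traces via
the analytic division likelihood
`log p = log Γ(t_div) − ∫ Γ dt`, with `G` parametrized as the
exponential of a periodic cubic spline and a Gaussian smoothness prior
on its periodic second differences.

## Worked example

```python
from circadiv import CouplingModel, SizeControlModel
from circadiv.simulate import SimConfig, generate_dataset

# clock-deletion condition: constant light, no circadian gating (G = 1)
cfg = SimConfig(T=120.0, n_lineages=120, dt_acq=0.75, seed=42)
cells, traces = generate_dataset(cfg, "clockdel_constant")

fit = SizeControlModel(cells, dt_acq=0.75, traces=traces).fit()
print(fit.summary())

# wild type: same size control, now modulated by the clock coupling G(τ)
wt_cells, wt_traces = generate_dataset(cfg, "WT_constant")
post = CouplingModel(wt_cells, wt_traces, fit.to_size_control_params(),
                     dt_acq=0.75).fit(seed=0)
print(post.summary())
```

prints (992 completed cycles; generator defaults a = −0.35, k = 2,
λ = 4.5 µm):

```
Linear size-control model (Weibull hazard in Delta0)
  n cells: 992   correction: half_frame   logL: -1984.95
  param   estimate                  95% CI
  a        -0.2482      [-0.4426, -0.0860]
  k         1.9648      [1.7658, 2.1703]
  lam       4.2955      [3.8165, 4.8352]
Posterior over the circadian coupling function G(tau)
  knots: 8   draws: 14400   acceptance: 0.46   min ESS: 317
  posterior-mean peak at tau = 22.10 h
  tau_knot   G (MAP)                95% CI
       0.0     1.678     [1.390, 1.979]
       3.0     0.390     [0.299, 0.512]
       6.0     0.289     [0.205, 0.391]
       9.0     0.284     [0.214, 0.376]
      12.0     0.229     [0.176, 0.290]
      15.0     0.215     [0.172, 0.272]
      18.0     0.411     [0.349, 0.477]
      21.0     2.216     [1.934, 2.492]
```

The size-control fit recovers the generator's parameters within the
profile-likelihood intervals, and the inferred coupling reproduces the
wild-type pattern: repression through subjective night and early day
(τ ≈ 12–18, i.e. after dawn) and a sharp promotion of division at the
end of subjective day, peaking near τ = 22.

A command-line interface mirrors the library
(`circadiv simulate | fit-size-control | infer-coupling | analyze |
run-all`); see `circadiv --help`.

## Layout

| module | contents |
| --- | --- |
| `circadiv.light` | light profiles, flux-matched LD irradiance, elongation-rate models, time-of-day convention |
| `circadiv.core` | division-rate model: hazard, coupling function, effective coupling |
| `circadiv.simulate` | exact thinning simulator, observation model, named scenarios |
| `circadiv.finestep` | independent brute-force simulator used for cross-validation |
| `circadiv.sizecontrol` | nonparametric hazard estimates, size-control maximum likelihood |
| `circadiv.coupling` | Bayesian coupling inference from traces, and from division times only |
| `circadiv.population` | subpopulation clustering, size-control classes, division-time windows |
| `circadiv.io`, `circadiv.pipeline`, `circadiv.cli` | CSV/YAML I/O, pipeline driver, command line |
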