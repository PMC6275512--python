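"""Bayesian inference of the circadian coupling function G(t).

The division likelihood follows from the division rate: for a cell with
length history L(t) on [t_birth, t_div],

    log p = log Gamma(t_div) - int_{t_birth}^{t_div} Gamma(t) dt,

and a censored cell contributes only the survival integral.  Because
``Gamma dt = S(Delta0(L)) G(tau(t)) dL``, the integral becomes a line
integral in length along the reconstructed history (piecewise
exponential between observed frames), so the total log-likelihood is

    sum_divisions log G(tau_div)  -  sum_j w_j G(tau_j)  +  const,

with quadrature weights ``w_j = S(Delta0(L_j)) dL_j`` that do not depend
on G.  Both sums are accumulated once on a fine time-of-day grid, making
each likelihood evaluation O(grid size) regardless of the number of
cells.  G is parametrized as the exponential of a periodic cubic spline
at knots; the prior is a zero-mean Gaussian on the periodic second
differences of the knot log-values (smooth, positive, periodic — nothing
more is assumed).  Sampling uses an affine-invariant ensemble sampler
(emcee).

A simpler "division-time" model replaces Gamma by ``h(age) G(tau)`` with
a Weibull base hazard in cell age, requiring only birth and division
times; the base-hazard parameters are inferred jointly with G.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import emcee
import numpy as np
import pandas as pd
from scipy import optimize

from .core import CouplingFunction, SizeControlParams, size_hazard
from .light import PERIOD_H, time_of_day

__all__ = [
    "cycle_log_likelihood",
    "CouplingModel",
    "DivisionTimeModel",
    "CouplingPosterior",
    "infer_coupling",
    "infer_coupling_division_time",
    "default_knots",
]


def default_knots(n: int = 8) -> np.ndarray:
    return np.arange(n) * (PERIOD_H / n)


def _second_difference_matrix(n: int) -> np.ndarray:
    D = -2.0 * np.eye(n)
    for i in range(n):
        D[i, (i - 1) % n] += 1.0
        D[i, (i + 1) % n] += 1.0
    return D


# -- per-cell likelihood -----------------------------------------------------

def _segment_quadrature(times, lengths, L0_eff, a, params, dawn_offset, n_sub=3):
    """Quadrature nodes (tau_j, w_j) for int S(Delta0) dL along one history."""
    taus, ws = [], []
    for i in range(len(times) - 1):
        t1, t2 = times[i], times[i + 1]
        L1, L2 = lengths[i], lengths[i + 1]
        if t2 <= t1 or L2 <= 0 or L1 <= 0:
            continue
        ts = np.linspace(t1, t2, n_sub + 1)
        Ls = L1 * (L2 / L1) ** ((ts - t1) / (t2 - t1))
        mid_t = 0.5 * (ts[:-1] + ts[1:])
        mid_L = np.sqrt(Ls[:-1] * Ls[1:])
        dL = np.diff(Ls)
        S = size_hazard(mid_L - (1.0 + a) * L0_eff, params)
        taus.append(time_of_day(mid_t, dawn_offset))
        ws.append(S * dL)
    if not taus:
        return np.array([]), np.array([])
    return np.concatenate(taus), np.concatenate(ws)


def _prepare_history(trace_t, trace_L, censored, dt_acq, time_correction):
    """Optionally extrapolate half a frame beyond each end of the history.

    The observation convention records division one frame early and
    birth one frame late; extrapolating each cell's own exponential
    growth by half an acquisition interval at both ends re-centers the
    recorded cycle on the true one (division time shifts by +dt/2).
    """
    t = np.asarray(trace_t, float)
    L = np.asarray(trace_L, float)
    if time_correction == "none" or len(t) < 2 or dt_acq is None:
        return t, L, t[-1]
    half = 0.5 * dt_acq
    r0 = np.log(L[1] / L[0]) / (t[1] - t[0]) if L[1] > 0 and L[0] > 0 else 0.0
    t_new = [t[0] - half]
    L_new = [L[0] * np.exp(-r0 * half)]
    t_new.extend(t)
    L_new.extend(L)
    if not censored:
        r1 = np.log(L[-1] / L[-2]) / (t[-1] - t[-2]) if L[-1] > 0 and L[-2] > 0 else 0.0
        t_new.append(t[-1] + half)
        L_new.append(L[-1] * np.exp(r1 * half))
    return np.asarray(t_new), np.asarray(L_new), t_new[-1]


def cycle_log_likelihood(
    trace: pd.DataFrame,
    record: pd.Series,
    G: CouplingFunction,
    params: SizeControlParams,
    dawn_offset: float = 0.0,
    n_sub: int = 3,
    time_correction: str = "none",
    dt_acq: float | None = None,
) -> float:
    """Log-likelihood of one cell's length history under coupling G.

    For a divided cell: ``log Gamma(t_div) - int Gamma dt``; for a
    censored cell only the (negative) survival integral.  The integral
    uses the change of variables ``Gamma dt = S G dL`` along the
    piecewise-exponential reconstruction of the history.
    """
    tr = trace.sort_values("time_h")
    t = tr["time_h"].to_numpy(float)
    L = tr["length_um"].to_numpy(float)
    censored = bool(record["censored"])
    if len(t) == 0 or (not censored and len(t) < 2):
        raise ValueError(f"trace/record mismatch for cell {record.get('cell_id', '?')}")
    t, L, t_end = _prepare_history(t, L, censored, dt_acq, time_correction)
    L0_eff = L[0]
    taus, ws = _segment_quadrature(t, L, L0_eff, params.a, params, dawn_offset, n_sub)
    integral = float(np.sum(ws * G(taus))) if ws.size else 0.0
    if censored:
        return -integral
    # rate at division from the final segment of the history
    r = np.log(L[-1] / L[-2]) / (t[-1] - t[-2])
    gamma_div = (
        size_hazard(L[-1] - (1.0 + params.a) * L0_eff, params)
        * float(G(time_of_day(t_end, dawn_offset)))
        * r
        * L[-1]
    )
    if gamma_div <= 0:
        return -np.inf
    return float(np.log(gamma_div) - integral)


# -- results container -------------------------------------------------------

@dataclass
class CouplingPosterior:
    """Posterior over the coupling function's knot log-values.

    samples : array (n_draws, n_knots) of knot log-values (division-time
        model: base-hazard parameters removed).
    map_estimate : CouplingFunction at the posterior mode.
    ci_low, ci_high : 95% credible bounds on G at the knots.
    """

    knot_times: np.ndarray
    samples: np.ndarray
    map_estimate: CouplingFunction
    ci_low: np.ndarray
    ci_high: np.ndarray
    sampler_diagnostics: dict
    extra_samples: np.ndarray | None = None
    extra_names: tuple = ()

    def posterior_mean_curve(self, grid=None, max_draws: int = 400):
        """Posterior mean of G(tau) on a dense grid."""
        if grid is None:
            grid = np.linspace(0.0, PERIOD_H, 481)
        idx = np.linspace(0, len(self.samples) - 1, min(max_draws, len(self.samples))).astype(int)
        acc = np.zeros_like(grid, dtype=float)
        for i in idx:
            acc += CouplingFunction(self.knot_times, self.samples[i])(grid)
        return grid, acc / idx.size

    @property
    def peak_time(self) -> float:
        """Time of day at which the posterior-mean coupling peaks (h)."""
        grid, mean = self.posterior_mean_curve()
        return float(grid[np.argmax(mean)])

    def contains(self, value: float = 1.0) -> np.ndarray:
        """Which knots' 95% credible interval contains the given level."""
        return (self.ci_low <= value) & (value <= self.ci_high)

    def summary(self) -> str:
        d = self.sampler_diagnostics
        lines = [
            "Posterior over the circadian coupling function G(tau)",
            f"  knots: {len(self.knot_times)}   draws: {len(self.samples)}   "
            f"acceptance: {d.get('acceptance_fraction', float('nan')):.2f}   "
            f"min ESS: {d.get('ess_min', float('nan')):.0f}",
            f"  posterior-mean peak at tau = {self.peak_time:.2f} h",
            f"  {'tau_knot':>8}{'G (MAP)':>10}{'95% CI':>22}",
        ]
        gmap = self.map_estimate(self.knot_times)
        for i, kt in enumerate(self.knot_times):
            lines.append(
                f"  {kt:>8.1f}{gmap[i]:>10.3f}     [{self.ci_low[i]:.3f}, {self.ci_high[i]:.3f}]"
            )
        return "\n".join(lines)

    def plot(self, ax=None, **kwargs):  # pragma: no cover - thin plotting helper
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        grid, mean = self.posterior_mean_curve()
        ax.plot(grid, mean, label="posterior mean", **kwargs)
        ax.errorbar(
            self.knot_times,
            self.map_estimate(self.knot_times),
            yerr=[
                np.maximum(self.map_estimate(self.knot_times) - self.ci_low, 0),
                np.maximum(self.ci_high - self.map_estimate(self.knot_times), 0),
            ],
            fmt="o",
        )
        ax.set_xlabel("time of day (h)")
        ax.set_ylabel("G")
        return ax


# -- binned likelihood machinery --------------------------------------------

class _BinnedDivisionLikelihood:
    """Accumulates division counts and quadrature mass on a tau grid."""

    def __init__(self, n_bins: int = 192):
        self.n_bins = n_bins
        self.edges = np.linspace(0.0, PERIOD_H, n_bins + 1)
        self.centers = 0.5 * (self.edges[:-1] + self.edges[1:])
        self.div_counts = np.zeros(n_bins)
        self.weight = np.zeros(n_bins)
        self.n_divisions = 0

    def add_quadrature(self, taus: np.ndarray, ws: np.ndarray) -> None:
        if taus.size:
            idx = np.clip((taus / PERIOD_H * self.n_bins).astype(int), 0, self.n_bins - 1)
            np.add.at(self.weight, idx, ws)

    def add_division(self, tau: float) -> None:
        idx = min(int(tau / PERIOD_H * self.n_bins), self.n_bins - 1)
        self.div_counts[idx] += 1
        self.n_divisions += 1

    def loglike(self, G_at_centers: np.ndarray) -> float:
        with np.errstate(divide="ignore"):
            term = np.dot(self.div_counts, np.log(G_at_centers))
        return float(term - np.dot(self.weight, G_at_centers))


class _MCMCMixin:
    """Shared ensemble-sampling driver for the two coupling models."""

    def _run_sampler(self, log_post, ndim, x0, seed, nwalkers, nsteps, burn, progress):
        rng = np.random.default_rng(seed)
        nwalkers = max(nwalkers, 2 * ndim + 2)
        p0 = x0[None, :] + 0.05 * rng.standard_normal((nwalkers, ndim))
        sampler = emcee.EnsembleSampler(nwalkers, ndim, log_post)
        sampler.random_state = np.random.RandomState(seed % 2**31).get_state()
        sampler.run_mcmc(p0, nsteps, progress=progress)
        if burn is None:
            burn = nsteps // 2
        chain = sampler.get_chain(discard=burn, flat=True)
        acc = float(np.mean(sampler.acceptance_fraction))
        try:
            tau_int = sampler.get_autocorr_time(discard=burn, quiet=True)
            ess = float(np.min((nsteps - burn) * nwalkers / np.maximum(tau_int, 1.0)))
        except Exception:  # pragma: no cover
            ess = float("nan")
        diagnostics = {
            "acceptance_fraction": acc,
            "ess_min": ess,
            "n_draws": chain.shape[0],
            "nwalkers": nwalkers,
            "nsteps": nsteps,
        }
        if np.isfinite(ess) and ess < 100:
            warnings.warn(f"coupling sampler may not have mixed: min ESS = {ess:.0f}", stacklevel=3)
        return chain, diagnostics


class CouplingModel(_MCMCMixin):
    """Bayesian model for G(t) from single-cell length traces.

    The size-control parameters must be fixed beforehand (estimated from
    clock-deletion data), which anchors the overall scale of G.

    Parameters
    ----------
    cells, traces : DataFrames in the pipeline schemas.
    params_fixed : SizeControlParams from the clock-deletion fit.
    knot_times : knot grid over [0, 24); default 8 equispaced knots.
    prior_scale : SD of the Gaussian smoothness prior on periodic second
        differences of the knot log-values.
    dawn_offset : experiment time of first dawn (h).
    time_correction : 'half_frame' (default) re-centers the recorded
        cycle on the true one; 'none' uses recorded frames as-is.
    """

    def __init__(
        self,
        cells: pd.DataFrame,
        traces: pd.DataFrame,
        params_fixed: SizeControlParams,
        knot_times=None,
        prior_scale: float = 1.0,
        dawn_offset: float = 0.0,
        dt_acq: float | None = None,
        time_correction: str = "half_frame",
        n_bins: int = 192,
        n_sub: int = 3,
    ):
        self.knot_times = np.asarray(knot_times if knot_times is not None else default_knots(), float)
        self.params = params_fixed
        self.prior_scale = prior_scale
        self.level_scale = 3.0
        self.dawn_offset = dawn_offset
        self._D = _second_difference_matrix(len(self.knot_times))
        self.binned = _BinnedDivisionLikelihood(n_bins)
        if dt_acq is None and len(traces):
            diffs = traces.sort_values(["cell_id", "time_h"]).groupby("cell_id")["time_h"].diff()
            dt_acq = float(np.nanmedian(diffs)) if diffs.notna().any() else None
        self.dt_acq = dt_acq
        grouped = traces.groupby("cell_id") if len(traces) else {}
        self.n_cells = 0
        for _, rec in cells.iterrows():
            cid = rec["cell_id"]
            try:
                tr = grouped.get_group(cid)
            except (KeyError, AttributeError):
                continue
            tr = tr.sort_values("time_h")
            t = tr["time_h"].to_numpy(float)
            L = tr["length_um"].to_numpy(float)
            censored = bool(rec["censored"])
            if len(t) < 2:
                continue
            t, L, t_end = _prepare_history(t, L, censored, self.dt_acq, time_correction)
            taus, ws = _segment_quadrature(
                t, L, L[0], self.params.a, self.params, dawn_offset, n_sub
            )
            self.binned.add_quadrature(taus, ws)
            if not censored:
                self.binned.add_division(float(time_of_day(t_end, dawn_offset)))
            self.n_cells += 1

    # -- posterior -----------------------------------------------------------

    def log_prior(self, logv: np.ndarray) -> float:
        # smoothness on periodic second differences plus a weak proper
        # prior on the overall log-level (the smoothness part alone is
        # flat along constant shifts)
        d = self._D @ logv
        return float(
            -0.5 * np.dot(d, d) / self.prior_scale**2
            - 0.5 * (np.mean(logv) / self.level_scale) ** 2
        )

    def log_likelihood(self, logv: np.ndarray) -> float:
        if np.any(np.abs(logv) > 12):
            return -np.inf
        G = CouplingFunction(self.knot_times, logv, Gmax=1e9)
        return self.binned.loglike(G(self.binned.centers))

    def log_posterior(self, logv: np.ndarray) -> float:
        lp = self.log_prior(logv)
        return lp + self.log_likelihood(logv) if np.isfinite(lp) else -np.inf

    def fit(
        self,
        seed: int = 0,
        nwalkers: int = 24,
        nsteps: int = 1200,
        burn: int | None = None,
        progress: bool = False,
    ) -> CouplingPosterior:
        """Sample the posterior over knot log-values."""
        ndim = len(self.knot_times)
        x0 = optimize.minimize(
            lambda v: -self.log_posterior(v), np.zeros(ndim), method="Nelder-Mead",
            options={"maxiter": 3000, "xatol": 1e-4, "fatol": 1e-6},
        ).x
        chain, diagnostics = self._run_sampler(
            self.log_posterior, ndim, x0, seed, nwalkers, nsteps, burn, progress
        )
        return self._package(chain, diagnostics)

    def _package(self, chain, diagnostics) -> CouplingPosterior:
        lp = np.array([self.log_posterior(v) for v in chain[:: max(len(chain) // 512, 1)]])
        best = chain[:: max(len(chain) // 512, 1)][np.argmax(lp)]
        mode = optimize.minimize(
            lambda v: -self.log_posterior(v), best, method="Nelder-Mead",
            options={"maxiter": 2000},
        ).x
        g_samples = np.exp(chain)
        return CouplingPosterior(
            knot_times=self.knot_times,
            samples=chain,
            map_estimate=CouplingFunction(self.knot_times, mode),
            ci_low=np.percentile(g_samples, 2.5, axis=0),
            ci_high=np.percentile(g_samples, 97.5, axis=0),
            sampler_diagnostics=diagnostics,
        )


class DivisionTimeModel(_MCMCMixin):
    """Coupling inference from birth and division times only.

    The division rate is ``h(age) * G(tau)`` with a Weibull base hazard
    ``h(u) = (k/theta) (u/theta)^(k-1)`` in cell age, inferred jointly
    with the coupling.  Requires no length traces; the price is a wider
    posterior than the size-control model, especially at the peak.
    """

    def __init__(
        self,
        cells: pd.DataFrame,
        knot_times=None,
        prior_scale: float = 1.0,
        dawn_offset: float = 0.0,
        du: float = 0.25,
        dt_acq: float | None = None,
        time_correction: str = "half_frame",
    ):
        self.knot_times = np.asarray(knot_times if knot_times is not None else default_knots(), float)
        self._D = _second_difference_matrix(len(self.knot_times))
        self.prior_scale = prior_scale
        self.dawn_offset = dawn_offset
        shift = 0.5 * dt_acq if (time_correction == "half_frame" and dt_acq) else 0.0
        ages_list, taus_list, widx_list, cellw_list = [], [], [], []
        div_age, div_tau = [], []
        i_cell = 0
        for _, rec in cells.iterrows():
            tb = rec["birth_time_h"]
            censored = bool(rec["censored"])
            te = rec["division_time_h"] if not censored else rec.get("censor_time_h", np.nan)
            if not np.isfinite(te):
                if censored:
                    continue
                raise ValueError("division_time_h missing for uncensored cell")
            if not censored:
                te = te + shift
            age_end = te - tb
            if age_end <= 0:
                continue
            grid = np.arange(0.0, age_end + du, du)
            grid[-1] = age_end
            mids = 0.5 * (grid[:-1] + grid[1:])
            ages_list.append(mids)
            taus_list.append(time_of_day(tb + mids, dawn_offset))
            widx_list.append(np.full(mids.size, i_cell))
            cellw_list.append(np.diff(grid))
            if not censored:
                div_age.append(age_end)
                div_tau.append(float(time_of_day(te, dawn_offset)))
            i_cell += 1
        self.n_cells = i_cell
        self.ages = np.concatenate(ages_list) if ages_list else np.array([])
        self.taus = np.concatenate(taus_list) if ages_list else np.array([])
        self.du_w = np.concatenate(cellw_list) if ages_list else np.array([])
        self.div_age = np.asarray(div_age)
        self.div_tau = np.asarray(div_tau)

    @property
    def ndim(self) -> int:
        return 2 + len(self.knot_times)

    def log_posterior(self, theta: np.ndarray) -> float:
        log_k, log_th = theta[0], theta[1]
        logv = theta[2:]
        if abs(log_k) > 3 or abs(log_th) > 6 or np.any(np.abs(logv) > 12):
            return -np.inf
        k, th = np.exp(log_k), np.exp(log_th)
        # G and the base hazard share an exact scale degeneracy; G is
        # anchored to geometric mean 1 and the redundant direction pinned
        logv = logv - np.mean(logv)
        d = self._D @ logv
        lp = -0.5 * np.dot(d, d) / self.prior_scale**2 - 0.5 * (np.mean(theta[2:]) / 0.05) ** 2
        G = CouplingFunction(self.knot_times, logv, Gmax=1e9)
        with np.errstate(divide="ignore", invalid="ignore"):
            h_mid = (k / th) * np.maximum(self.ages / th, 1e-300) ** (k - 1.0)
        integral = float(np.sum(h_mid * G(self.taus) * self.du_w))
        if self.div_age.size:
            h_div = (k / th) * np.maximum(self.div_age / th, 1e-300) ** (k - 1.0)
            ll = float(np.sum(np.log(h_div)) + np.sum(np.log(G(self.div_tau)))) - integral
        else:
            ll = -integral
        return lp + ll if np.isfinite(ll) else -np.inf

    def fit(
        self,
        seed: int = 0,
        nwalkers: int = 32,
        nsteps: int = 1500,
        burn: int | None = None,
        progress: bool = False,
    ) -> CouplingPosterior:
        """Sample the joint posterior over base-hazard and coupling knots."""
        mean_age = float(np.mean(self.div_age)) if self.div_age.size else 10.0
        x0 = np.concatenate([[np.log(2.0), np.log(mean_age)], np.zeros(len(self.knot_times))])
        x0 = optimize.minimize(
            lambda v: -self.log_posterior(v), x0, method="Nelder-Mead",
            options={"maxiter": 5000, "xatol": 1e-4, "fatol": 1e-6},
        ).x
        chain, diagnostics = self._run_sampler(
            self.log_posterior, self.ndim, x0, seed, nwalkers, nsteps, burn, progress
        )
        lp_sub = chain[:: max(len(chain) // 512, 1)]
        lp = np.array([self.log_posterior(v) for v in lp_sub])
        mode = optimize.minimize(
            lambda v: -self.log_posterior(v), lp_sub[np.argmax(lp)], method="Nelder-Mead",
            options={"maxiter": 3000},
        ).x
        g_chain = chain[:, 2:] - chain[:, 2:].mean(axis=1, keepdims=True)
        g_samples = np.exp(g_chain)
        return CouplingPosterior(
            knot_times=self.knot_times,
            samples=g_chain,
            map_estimate=CouplingFunction(self.knot_times, mode[2:] - np.mean(mode[2:])),
            ci_low=np.percentile(g_samples, 2.5, axis=0),
            ci_high=np.percentile(g_samples, 97.5, axis=0),
            sampler_diagnostics=diagnostics,
            extra_samples=chain[:, :2],
            extra_names=("log_k_age", "log_theta_age"),
        )


def infer_coupling(
    cells: pd.DataFrame,
    traces: pd.DataFrame,
    params_fixed: SizeControlParams,
    seed: int = 0,
    **kwargs,
) -> CouplingPosterior:
    """Infer G(t) from length traces; see :class:`CouplingModel`."""
    fit_kw = {k: kwargs.pop(k) for k in ("nwalkers", "nsteps", "burn", "progress") if k in kwargs}
    return CouplingModel(cells, traces, params_fixed, **kwargs).fit(seed=seed, **fit_kw)


def infer_coupling_division_time(
    cells: pd.DataFrame,
    seed: int = 0,
    **kwargs,
) -> CouplingPosterior:
    """Infer G(t) from birth/division times only; see :class:`DivisionTimeModel`."""
    fit_kw = {k: kwargs.pop(k) for k in ("nwalkers", "nsteps", "burn", "progress") if k in kwargs}
    return DivisionTimeModel(cells, **kwargs).fit(seed=seed, **fit_kw)
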