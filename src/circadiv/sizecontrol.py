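"""Size-control estimation from cell tables (clock-deletion-style data).

The linear size-control model states that added length obeys
``Delta = a * L0 + Delta0`` with ``Delta0`` drawn from the distribution
implied by the hazard ``S``: ``p(Delta0) = S(Delta0) *
exp(-int_0^Delta0 S)``.  For the Weibull-form hazard this is the
Weibull(k, lam) density, so maximum likelihood over (a, k, lam) reduces,
at fixed ``a``, to a Weibull fit of the transformed added lengths.

Discrete acquisition biases naive estimates: the recorded division
length sits one frame early and the recorded birth length one frame
late, so observed added lengths are systematically short.  The
``half_frame`` correction extrapolates each cell's own exponential
growth by half an acquisition interval beyond the recorded division
frame and back from the recorded birth frame before forming Delta0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats

from .core import SizeControlParams

__all__ = [
    "HazardEstimate",
    "empirical_hazard",
    "SizeControlModel",
    "SizeControlResults",
    "fit_size_control",
    "regress_added_vs_birth",
    "RegressionSummary",
]

_CHI2_95_HALF = stats.chi2.ppf(0.95, df=1) / 2.0  # 1.9207


class EstimationError(RuntimeError):
    """Raised when the size-control fit cannot be completed."""


@dataclass
class HazardEstimate:
    """Life-table hazard estimate within one birth-length stratum."""

    grid: np.ndarray
    hazard: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    birth_bin: tuple
    n_at_risk: np.ndarray
    n_cells: int = 0

    @property
    def defined(self) -> np.ndarray:
        """Mask of bins with cells still at risk."""
        return self.n_at_risk > 0


def _per_cell_growth_fits(traces: pd.DataFrame | None) -> dict:
    """OLS of log length on time per cell.

    Returns cell_id -> (intercept, rate, n_points, t_mean, Sxx, rss);
    the design quantities feed the endpoint-prediction variances.
    """
    out = {}
    if traces is None or len(traces) == 0:
        return out
    for cid, grp in traces.groupby("cell_id"):
        t = grp["time_h"].to_numpy(float)
        y = np.log(np.maximum(grp["length_um"].to_numpy(float), 1e-9))
        if t.size < 2 or np.ptp(t) == 0:
            continue
        r, b0 = np.polyfit(t, y, 1)
        resid = y - (b0 + r * t)
        out[cid] = (b0, r, t.size, t.mean(), np.sum((t - t.mean()) ** 2), np.sum(resid**2))
    return out


def _pooled_log_residual_var(fits: dict) -> float:
    """Pooled residual variance of the per-cell log-growth fits.

    Estimates the (log-scale) measurement noise of a single frame;
    cells contribute n - 2 degrees of freedom each.
    """
    rss = sum(f[5] for f in fits.values() if f[2] >= 4)
    dof = sum(f[2] - 2 for f in fits.values() if f[2] >= 4)
    return rss / dof if dof > 0 else 0.0


def _rate_prior(fits: dict, s2_log: float) -> tuple[float, float]:
    """Population mean and between-cell variance of exponential growth rates.

    Uses cells with long traces (slope error small); the between-cell
    variance is the observed slope variance minus the mean slope-error
    variance, floored at a small positive value.
    """
    good = [f for f in fits.values() if f[2] >= 6]
    if not good:
        return 0.05, 1e-4
    rates = np.array([f[1] for f in good])
    v_err = np.array([s2_log / max(f[4], 1e-12) for f in good])
    v_pop = max(float(np.var(rates) - np.mean(v_err)), 1e-8)
    return float(np.mean(rates)), v_pop


def _trunc_weibull_pdf(x, lower, k: float, lam: float):
    """Weibull(k, lam) density left-truncated at ``lower`` (0 below it)."""
    pos = x > np.maximum(lower, 0.0)
    xs = np.where(pos, x, lam)  # dummy value where density is zero
    z = xs / lam
    dens = (k / lam) * z ** (k - 1.0) * np.exp(-(z**k - (np.maximum(lower, 0.0) / lam) ** k))
    return np.where(pos, dens, 0.0)


def _hazard_curve(x: np.ndarray, grid: np.ndarray, dx: float) -> tuple[np.ndarray, np.ndarray]:
    at_risk = (x[None, :] >= grid[:, None]).sum(axis=1)
    events = ((x[None, :] >= grid[:, None]) & (x[None, :] < (grid + dx)[:, None])).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        hz = np.where(at_risk > 0, events / (dx * at_risk), np.nan)
    return hz, at_risk


def empirical_hazard(
    cells: pd.DataFrame,
    birth_bins=None,
    dx: float = 0.4,
    a: float = 0.0,
    n_boot: int = 1000,
    seed: int = 0,
) -> list[HazardEstimate]:
    """Nonparametric hazard of division per unit added length, by birth stratum.

    Within each birth-length stratum the hazard at added length x is
    ``(# divisions in [x, x+dx)) / (dx * # cells with added length >= x)``.
    With ``a != 0`` the abscissa is the birth-length independent part
    ``Delta0 = L_div - (1+a) L_birth`` instead of the raw added length,
    under which strata collapse onto a single curve if the generating
    hazard depends on ``Delta0`` only.  Confidence intervals are 95%
    percentile bootstrap over cells.
    """
    if dx <= 0:
        raise ValueError("dx must be positive")
    obs = cells[cells["censored"] == 0]
    if len(obs) < 50:
        raise EstimationError(f"need >= 50 uncensored cells, got {len(obs)}")
    lb = obs["birth_length_um"].to_numpy(float)
    x_all = obs["division_length_um"].to_numpy(float) - (1.0 + a) * lb
    if birth_bins is None:
        qs = np.quantile(lb, [0.0, 0.25, 0.5, 0.75, 1.0])
        birth_bins = list(zip(qs[:-1], qs[1:]))
    rng = np.random.default_rng(seed)
    out: list[HazardEstimate] = []
    for lo, hi in birth_bins:
        sel = (lb >= lo) & (lb <= hi)
        x = x_all[sel]
        if x.size == 0:
            warnings.warn(f"empty birth stratum [{lo:.3g}, {hi:.3g}] skipped", stacklevel=2)
            continue
        grid = np.arange(0.0, np.max(x) + dx, dx)
        hz, at_risk = _hazard_curve(x, grid, dx)
        boot = np.empty((n_boot, grid.size))
        for b in range(n_boot):
            xb = x[rng.integers(0, x.size, x.size)]
            boot[b], _ = _hazard_curve(xb, grid, dx)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            lo_ci = np.nanpercentile(boot, 2.5, axis=0)
            hi_ci = np.nanpercentile(boot, 97.5, axis=0)
        out.append(
            HazardEstimate(
                grid=grid, hazard=hz, ci_low=lo_ci, ci_high=hi_ci,
                birth_bin=(float(lo), float(hi)), n_at_risk=at_risk, n_cells=int(x.size),
            )
        )
    return out


@dataclass
class RegressionSummary:
    """Slope/intercept of an OLS fit with 95% CI."""

    slope: float
    intercept: float
    ci_low: float
    ci_high: float
    n: int
    pvalue: float = np.nan


def regress_added_vs_birth(cells: pd.DataFrame) -> RegressionSummary:
    """OLS of added length (L_div - L_birth) on birth length.

    The slope classifies the size-control strategy: ~0 adder, negative
    sizer-like (toward -1, a pure sizer), positive timer-like.
    """
    obs = cells[cells["censored"] == 0]
    if len(obs) < 10:
        raise EstimationError(f"need >= 10 uncensored cells, got {len(obs)}")
    lb = obs["birth_length_um"].to_numpy(float)
    added = obs["division_length_um"].to_numpy(float) - lb
    if np.var(lb) == 0:
        raise EstimationError("degenerate birth-length variance")
    res = sm.OLS(added, sm.add_constant(lb)).fit()
    ci = res.conf_int(alpha=0.05)
    return RegressionSummary(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        ci_low=float(ci[1][0]),
        ci_high=float(ci[1][1]),
        n=len(obs),
        pvalue=float(res.pvalues[1]),
    )


class SizeControlModel:
    """Maximum-likelihood model for the linear size control (a, k, lam).

    Parameters
    ----------
    cells : DataFrame
        Cell table (pipeline schema).  Censored cells contribute survival
        terms when ``traces`` supplies their last observed frame;
        otherwise they are dropped with a warning.
    dt_acq : float, optional
        Acquisition interval (h); required for the half-frame correction.
    correction : {'half_frame', 'none'}
        Discretization correction applied to recorded lengths.
    traces : DataFrame, optional
        Trace table, used only for censored cells' last observations.

    Examples
    --------
    >>> res = SizeControlModel(cells, dt_acq=0.75).fit()   # doctest: +SKIP
    >>> res.params, res.conf_int()                         # doctest: +SKIP
    """

    def __init__(
        self,
        cells: pd.DataFrame,
        dt_acq: float | None = None,
        correction: str = "half_frame",
        traces: pd.DataFrame | None = None,
    ):
        if correction not in ("half_frame", "none"):
            raise ValueError("correction must be 'half_frame' or 'none'")
        if correction == "half_frame" and dt_acq is None:
            raise ValueError("half_frame correction requires dt_acq")
        obs = cells[cells["censored"] == 0].dropna(
            subset=["birth_length_um", "division_length_um", "birth_time_h", "division_time_h"]
        )
        if len(obs) < 100:
            raise EstimationError(f"need >= 100 uncensored cells, got {len(obs)}")
        lb = obs["birth_length_um"].to_numpy(float)
        ld = obs["division_length_um"].to_numpy(float)
        tb = obs["birth_time_h"].to_numpy(float)
        td = obs["division_time_h"].to_numpy(float)
        if np.any(td - tb <= 0):
            raise EstimationError("division before birth in input table")
        var_b = np.zeros_like(lb)
        var_d = np.zeros_like(ld)
        cov_bd = np.zeros_like(lb)
        rate = np.log(ld / lb) / (td - tb)
        fits = _per_cell_growth_fits(traces) if traces is not None else {}
        s2_log = _pooled_log_residual_var(fits)
        if correction == "half_frame":
            half = 0.5 * dt_acq
            r_bar, v_pop = _rate_prior(fits, s2_log)
            for i, cid in enumerate(obs["cell_id"]):
                if cid in fits:
                    # endpoints from the cell's fitted exponential growth
                    # line, with the slope shrunk toward the population
                    # mean rate: short traces (2-3 frames) have slope
                    # errors far larger than the true cell-to-cell rate
                    # spread, and they are exactly the cells that anchor
                    # the short-added-length edge of the likelihood
                    b0, r, n_pt, t_mean, sxx, _ = fits[cid]
                    v_r = s2_log / max(sxx, 1e-12)
                    w_shrink = v_pop / (v_pop + v_r)
                    r = r_bar + w_shrink * (r - r_bar)
                    v_r = w_shrink * v_r
                    b0 = b0 + (fits[cid][1] - r) * t_mean  # refit intercept at fixed slope
                    rate[i] = r
                    lb[i] = np.exp(b0 + r * (tb[i] - half))
                    ld[i] = np.exp(b0 + r * (td[i] + half))
                    jitter = (r * dt_acq) ** 2 / 12.0  # frame-timing jitter of the true endpoint
                    vb = s2_log / n_pt + v_r * (tb[i] - half - t_mean) ** 2
                    vd = s2_log / n_pt + v_r * (td[i] + half - t_mean) ** 2
                    var_b[i] = lb[i] ** 2 * (vb + jitter)
                    var_d[i] = ld[i] ** 2 * (vd + jitter)
                    cov_bd[i] = (
                        lb[i] * ld[i]
                        * (s2_log / n_pt + v_r * (tb[i] - half - t_mean) * (td[i] + half - t_mean))
                    )
                else:
                    r = rate[i]
                    lb[i] = lb[i] * np.exp(-r * half)
                    ld[i] = ld[i] * np.exp(r * half)
                    var_b[i] = lb[i] ** 2 * (s2_log + (r * dt_acq) ** 2 / 12.0)
                    var_d[i] = ld[i] ** 2 * (s2_log + (r * dt_acq) ** 2 / 12.0)
        elif s2_log > 0:
            var_b = lb**2 * s2_log
            var_d = ld**2 * s2_log
        self.lb, self.ld = lb, ld
        self.rate = np.maximum(rate, 1e-6)
        self.var_b, self.var_d = var_b, var_d
        self.cov_bd = cov_bd
        self._gh_x, self._gh_w = np.polynomial.hermite.hermgauss(21)
        self._gl_x, self._gl_w = np.polynomial.legendre.leggauss(24)
        self.nobs = len(obs)
        self.correction = correction
        self.dt_acq = dt_acq
        # censored cells: last observed (length, plus birth) -> survival term
        self.lb_c = np.array([])
        self.lend_c = np.array([])
        cens = cells[cells["censored"] == 1]
        if len(cens) and traces is not None:
            rows_lb, rows_lend = [], []
            last = traces.sort_values("time_h").groupby("cell_id").tail(1).set_index("cell_id")
            for _, row in cens.iterrows():
                cid = row["cell_id"]
                if cid in last.index and np.isfinite(row["birth_length_um"]):
                    rows_lb.append(float(row["birth_length_um"]))
                    rows_lend.append(float(last.loc[cid, "length_um"]))
            self.lb_c = np.asarray(rows_lb)
            self.lend_c = np.asarray(rows_lend)
        elif len(cens) and traces is None:
            warnings.warn(
                f"{len(cens)} censored cells dropped (no trace table for survival terms)",
                stacklevel=2,
            )

    # -- likelihood ----------------------------------------------------------

    def _observability(self, y):
        """Probability that a cycle with added length y was recorded.

        A cell is recorded only if its cycle spans at least two frames;
        for a cycle of duration D and a uniformly phased frame grid that
        probability is clip(D/dt - 1, 0, 1).  D follows from the cell's
        own exponential growth rate.  Without dt_acq no selection is
        modeled (weight 1).
        """
        if self.dt_acq is None:
            return np.ones_like(y)
        L_div = self.lb[:, None] + np.maximum(y, 0.0)
        D = np.log(L_div / self.lb[:, None]) / self.rate[:, None]
        return np.clip(D / self.dt_acq - 1.0, 0.0, 1.0)

    def loglike(self, a: float, k: float, lam: float) -> float:
        """Log-likelihood of (a, k, lam) given observed and censored cells.

        Three features make this estimate unbiased under discrete,
        noisy acquisition:

        * the hazard in Delta0 accumulates from its value at birth,
          Delta0_birth = -a * L0 (positive when a < 0), so the density is
          ``S(Delta0) * exp(-[Lam(Delta0) - Lam(Delta0_birth)])`` with
          ``Lam(x) = (max(x, 0)/lam)**k``;
        * the density is convolved with the Gaussian endpoint-estimate
          noise (Gauss-Hermite quadrature), whose per-cell variance
          follows from the trace residuals and frame-timing jitter;
        * each recorded cell is conditioned on being recordable at all
          (cycles shorter than the frame spacing are lost, and those
          short cycles are exactly the ones that pin down ``a``).
        """
        if k < 1 or lam <= 0:
            return -np.inf
        # work in added-length space y = L_div - L_birth, where the hard
        # support edge y > 0 does not move with a; Delta0 = y - a * L0
        y = self.ld - self.lb
        d0_birth = np.maximum(-a * self.lb, 0.0)
        sig2 = self.var_d + self.var_b - 2.0 * self.cov_bd
        if np.all(sig2 == 0):
            d0 = y - a * self.lb
            if np.any(d0 <= d0_birth):
                return -np.inf
            z = d0 / lam
            w = self._observability(y[:, None])[:, 0]
            num = np.log(k / lam) + (k - 1.0) * np.log(z) - (z**k - (d0_birth / lam) ** k)
            num = num + np.log(np.maximum(w, 1e-300))
        else:
            # exact convolution of the edge-truncated density with the
            # Gaussian added-length noise: Gauss-Legendre nodes track the
            # overlap of the noise window with the support y > 0
            sig = np.sqrt(np.maximum(sig2, 1e-12))
            lo = np.maximum(0.0, y - 6.0 * sig)[:, None]
            hi = np.maximum(y + 6.0 * sig, 1e-9)[:, None]
            mid = 0.5 * (hi + lo)
            halfw = 0.5 * (hi - lo)
            yq = mid + halfw * self._gl_x[None, :]
            dens = _trunc_weibull_pdf(yq - a * self.lb[:, None], d0_birth[:, None], k, lam)
            dens = dens * self._observability(yq)
            phi = np.exp(-0.5 * ((y[:, None] - yq) / sig[:, None]) ** 2) / (
                np.sqrt(2.0 * np.pi) * sig[:, None]
            )
            p = (self._gl_w[None, :] * dens * phi).sum(axis=1) * halfw[:, 0]
            num = np.log(np.maximum(p, 1e-300))
        if self.dt_acq is not None:
            # normalization Z = P(recordable) = 1 - int p * (1 - w); the
            # integrand is supported only on the short-cycle window
            # y in [0, y2] where the cycle spans < 2 frames
            y2 = self.lb * (np.exp(2.0 * self.dt_acq * self.rate) - 1.0)
            mid = 0.5 * y2[:, None]
            halfw = 0.5 * y2[:, None]
            yq = mid + halfw * self._gl_x[None, :]
            densq = _trunc_weibull_pdf(yq - a * self.lb[:, None], d0_birth[:, None], k, lam)
            lost = (self._gl_w[None, :] * densq * (1.0 - self._observability(yq))).sum(axis=1)
            Z = 1.0 - lost * halfw[:, 0]
            num = num - np.log(np.maximum(Z, 1e-300))
        ll = float(np.sum(num))
        if self.lend_c.size:
            d0c = self.lend_c - (1.0 + a) * self.lb_c
            dcb = np.maximum(-a * self.lb_c, 0.0)
            ll -= float(np.sum(np.maximum(np.maximum(d0c, 0.0) ** k - dcb**k, 0.0)) / lam**k)
        return ll

    def _profile_kl(self, a: float) -> tuple[float, float, float]:
        """Weibull MLE of (k, lam) at fixed a; returns (k, lam, loglik)."""
        d0 = self.ld - (1.0 + a) * self.lb
        pos = d0[d0 > 0]
        if pos.size < 0.5 * d0.size:
            return np.nan, np.nan, -np.inf
        if np.any(d0 <= 0) and np.all(self.var_d + self.var_b == 0):
            return np.nan, np.nan, -np.inf
        k0, _, lam0 = stats.weibull_min.fit(pos, floc=0)
        k0 = max(k0, 1.0)
        res = optimize.minimize(
            lambda p: -self.loglike(a, p[0], p[1]),
            x0=[k0, lam0],
            method="L-BFGS-B",
            bounds=[(1.0, 50.0), (1e-6, None)],
        )
        return float(res.x[0]), float(res.x[1]), float(-res.fun)

    def fit(self, a_grid=None) -> "SizeControlResults":
        """Maximize the likelihood with a multi-start over the birth coupling a."""
        if a_grid is None:
            a_grid = np.arange(-0.8, 0.41, 0.1)
        best = (np.nan, np.nan, np.nan, -np.inf)
        for a0 in a_grid:
            k0, lam0, ll0 = self._profile_kl(a0)
            if ll0 > best[3]:
                best = (a0, k0, lam0, ll0)
        if not np.isfinite(best[3]):
            raise EstimationError(
                "no feasible starting point: Delta0 <= 0 for some cell at every trial a"
            )
        res = optimize.minimize(
            lambda p: -self.loglike(*p),
            x0=list(best[:3]),
            method="Nelder-Mead",
            options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 4000},
        )
        if not res.success:
            raise EstimationError(f"size-control MLE did not converge: {res.message}")
        a_hat, k_hat, lam_hat = map(float, res.x)
        return SizeControlResults(self, a_hat, k_hat, lam_hat, float(-res.fun))


class SizeControlResults:
    """MLE of the linear size-control parameters with profile-likelihood CIs."""

    param_names = ("a", "k", "lam")

    def __init__(self, model: SizeControlModel, a: float, k: float, lam: float, llf: float):
        self.model = model
        self.params = pd.Series({"a": a, "k": k, "lam": lam})
        self.llf = llf
        self.nobs = model.nobs
        self._ci_cache: pd.DataFrame | None = None

    def to_size_control_params(self, sigma_zeta: float = 0.0) -> SizeControlParams:
        return SizeControlParams(
            a=self.params["a"], k=max(self.params["k"], 1.0), lam=self.params["lam"],
            sigma_zeta=sigma_zeta,
        )

    def _profile_ll(self, name: str, value: float) -> float:
        a, k, lam = self.params
        if name == "a":
            warm = optimize.minimize(
                lambda p: -self.model.loglike(value, max(p[0], 1.0), max(p[1], 1e-6)),
                x0=[k, lam],
                method="Nelder-Mead",
                options={"xatol": 1e-4, "fatol": 1e-6, "maxiter": 800},
            )
            return float(-warm.fun)
        free = {"k": ("a", "lam"), "lam": ("a", "k")}[name]
        x0 = [self.params[f] for f in free]
        bounds = {"a": (-0.99, 0.99), "k": (1.0, 50.0), "lam": (1e-6, None)}

        def neg(p):
            kw = dict(zip(free, p))
            kw[name] = value
            lo_k = bounds.get("k", (1.0, None))[0]
            if "k" in kw:
                kw["k"] = max(kw["k"], lo_k)
            if "lam" in kw:
                kw["lam"] = max(kw["lam"], 1e-6)
            return -self.model.loglike(kw["a"], kw["k"], kw["lam"])

        r = optimize.minimize(
            neg, x0=x0, method="Nelder-Mead",
            options={"xatol": 1e-4, "fatol": 1e-6, "maxiter": 800},
        )
        return float(-r.fun)

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        """Profile-likelihood confidence intervals for (a, k, lam)."""
        if alpha != 0.05 or self._ci_cache is None:
            cut = self.llf - stats.chi2.ppf(1 - alpha, df=1) / 2.0
            rows = {}
            hard_lo = {"a": -0.99, "k": 1.0, "lam": 1e-4}
            for name in self.param_names:
                mle = self.params[name]
                step = max(0.25 * abs(mle), 0.05)
                rows[name] = (
                    self._profile_bound(name, mle, -step, cut, hard_lo[name]),
                    self._profile_bound(name, mle, +step, cut, None),
                )
            ci = pd.DataFrame(rows, index=["lower", "upper"]).T
            if alpha == 0.05:
                self._ci_cache = ci
            return ci
        return self._ci_cache

    def _profile_bound(self, name, mle, step, cut, hard) -> float:
        lo, hi = mle, mle + step
        for _ in range(60):
            if hard is not None and hi <= hard:
                return hard
            if self._profile_ll(name, hi) < cut:
                break
            lo, hi = hi, hi + step
        else:
            return float(hi)
        f = lambda v: max(self._profile_ll(name, v), cut - 1e6) - cut
        try:
            return float(optimize.brentq(f, min(lo, hi), max(lo, hi), xtol=1e-4))
        except ValueError:
            return float(hi)

    def summary(self) -> str:
        ci = self.conf_int()
        lines = [
            "Linear size-control model (Weibull hazard in Delta0)",
            f"  n cells: {self.nobs}   correction: {self.model.correction}   logL: {self.llf:.2f}",
            f"  {'param':<6}{'estimate':>10}{'95% CI':>24}",
        ]
        for name in self.param_names:
            lines.append(
                f"  {name:<6}{self.params[name]:>10.4f}"
                f"      [{ci.loc[name, 'lower']:.4f}, {ci.loc[name, 'upper']:.4f}]"
            )
        return "\n".join(lines)

    def report(self) -> dict:
        """Machine-readable key-value report."""
        ci = self.conf_int()
        out = {"n_cells": self.nobs, "loglik": self.llf, "correction": self.model.correction}
        for name in self.param_names:
            out[name] = float(self.params[name])
            out[f"{name}_ci_low"] = float(ci.loc[name, "lower"])
            out[f"{name}_ci_high"] = float(ci.loc[name, "upper"])
        return out


def fit_size_control(
    cells: pd.DataFrame,
    correction: str = "half_frame",
    dt_acq: float | None = None,
    traces: pd.DataFrame | None = None,
) -> SizeControlResults:
    """Fit (a, k, lam) by maximum likelihood; see :class:`SizeControlModel`."""
    return SizeControlModel(cells, dt_acq=dt_acq, correction=correction, traces=traces).fit()
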