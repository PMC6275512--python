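"""Population-level analyses: subpopulations, size-control classes, division timing.

The clock splits cells into two dynamical subpopulations (fast/slow
cycles depending on birth time of day); a mixture of von Mises (birth
phase) x Gaussian (log cycle duration) components with BIC model
selection recovers them, treating the birth time of day as the circular
quantity it is.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import i0e, logsumexp

from .light import PERIOD_H, time_of_day
from .sizecontrol import EstimationError, RegressionSummary

__all__ = [
    "SubpopulationLabels",
    "SizeControlClassification",
    "cluster_subpopulations",
    "classify_size_control",
    "division_time_window",
    "added_vs_time_regression",
    "cycle_duration_histogram",
]


@dataclass
class SubpopulationLabels:
    """fast/slow labels with membership probabilities and the BIC report."""

    cell_id: np.ndarray
    label: np.ndarray  # 'fast' or 'slow'
    posterior_prob: np.ndarray  # probability of the assigned component
    n_components: int
    bic: dict
    component_means: pd.DataFrame

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"cell_id": self.cell_id, "label": self.label, "posterior_prob": self.posterior_prob}
        )


@dataclass
class SizeControlClassification:
    """Slope-based size-control category: sizer-like / adder-like / timer-like."""

    slope: float
    ci: tuple
    label: str


class _CircularMixture:
    """Mixture of (von Mises in birth phase) x (Gaussian in log duration).

    The birth time of day is an angle, so each component carries a von
    Mises circular density; a single component with low concentration
    degenerates to the uniform circle, which is the correct null for
    clock-deletion data (a Gaussian mixture on the (sin, cos) embedding
    has no such null: the unit-circle ring itself looks bimodal to it).
    """

    def __init__(
        self,
        n_components: int,
        seed: int = 0,
        n_init: int = 5,
        max_iter: int = 300,
        uniform_phase: bool = False,
    ):
        self.n_components = n_components
        self.seed = seed
        self.n_init = n_init
        self.max_iter = max_iter
        self.uniform_phase = uniform_phase

    @staticmethod
    def _kappa_from_rbar(rbar: float) -> float:
        # Best-Fisher approximation, capped for numerical stability
        rbar = min(rbar, 0.999)
        k = rbar * (2.0 - rbar**2) / max(1.0 - rbar**2, 1e-9)
        return float(np.clip(k, 1e-6, 100.0))

    def _log_density(self, theta, y, params):
        logp = np.empty((theta.size, self.n_components))
        for c in range(self.n_components):
            w, mu, kappa, m, s = params[c]
            log_vm = kappa * (np.cos(theta - mu) - 1.0) - np.log(2 * np.pi * i0e(kappa))
            log_norm = -0.5 * np.log(2 * np.pi * s**2) - 0.5 * ((y - m) / s) ** 2
            logp[:, c] = np.log(w) + log_vm + log_norm
        return logp

    def fit(self, theta, y):
        rng = np.random.default_rng(self.seed)
        best = None
        for _ in range(self.n_init):
            params = self._init(theta, y, rng)
            ll_prev = -np.inf
            for _ in range(self.max_iter):
                logp = self._log_density(theta, y, params)
                ll = float(logsumexp(logp, axis=1).sum())
                resp = np.exp(logp - logsumexp(logp, axis=1, keepdims=True))
                params = self._m_step(theta, y, resp)
                if abs(ll - ll_prev) < 1e-8 * max(abs(ll), 1.0):
                    break
                ll_prev = ll
            if best is None or ll > best[0]:
                best = (ll, params)
        self.loglik_, self.params_ = best
        per_comp = 2 if self.uniform_phase else 4
        n_par = self.n_components * per_comp + (self.n_components - 1)
        self.bic_ = -2.0 * self.loglik_ + n_par * np.log(theta.size)
        return self

    def predict_proba(self, theta, y):
        logp = self._log_density(theta, y, self.params_)
        return np.exp(logp - logsumexp(logp, axis=1, keepdims=True))

    def _init(self, theta, y, rng):
        n = theta.size
        params = []
        if self.n_components == 1:
            groups = [np.arange(n)]
        else:
            # split alternately by duration and by a random phase cut
            if rng.random() < 0.5:
                cut = np.median(y)
                groups = [np.flatnonzero(y <= cut), np.flatnonzero(y > cut)]
            else:
                phi = rng.uniform(0, 2 * np.pi)
                half = np.cos(theta - phi) > 0
                groups = [np.flatnonzero(half), np.flatnonzero(~half)]
            groups = [g if g.size >= 5 else rng.choice(n, max(5, n // 4)) for g in groups]
        for g in groups:
            params.append(self._component_stats(theta[g], y[g], np.ones(g.size), g.size / n))
        return params

    def _m_step(self, theta, y, resp):
        return [
            self._component_stats(
                theta, y, resp[:, c], resp[:, c].mean(), uniform_phase=self.uniform_phase
            )
            for c in range(self.n_components)
        ]

    @staticmethod
    def _component_stats(theta, y, r, weight, uniform_phase: bool = False):
        rs = max(r.sum(), 1e-9)
        if uniform_phase:
            mu, kappa = 0.0, 1e-9
        else:
            C = np.sum(r * np.cos(theta)) / rs
            S = np.sum(r * np.sin(theta)) / rs
            mu = np.arctan2(S, C)
            kappa = _CircularMixture._kappa_from_rbar(np.hypot(C, S))
        m = np.sum(r * y) / rs
        s = np.sqrt(max(np.sum(r * (y - m) ** 2) / rs, 1e-6))
        return (max(weight, 1e-6), mu, kappa, m, s)


def _features(cells: pd.DataFrame, dawn_offset: float):
    obs = cells[cells["censored"] == 0].dropna(subset=["birth_time_h", "division_time_h"])
    tau_b = np.asarray(time_of_day(obs["birth_time_h"].to_numpy(float), dawn_offset))
    dur = obs["division_time_h"].to_numpy(float) - obs["birth_time_h"].to_numpy(float)
    theta = 2 * np.pi * tau_b / PERIOD_H
    y = np.log(np.maximum(dur, 1e-3))
    y = (y - y.mean()) / max(y.std(), 1e-12)
    return theta, y, obs, dur, tau_b


def cluster_subpopulations(
    cells: pd.DataFrame, seed: int = 0, dawn_offset: float = 0.0
) -> SubpopulationLabels:
    """Cluster cells on (birth time of day, cycle duration); select 1 vs 2 by BIC.

    Fits one- and two-component mixtures of a von Mises density in birth
    phase times a Gaussian in standardized log cycle duration, and keeps
    the BIC winner.  The component with the smaller mean cycle duration
    is labeled ``fast``.  If one component is selected, all cells are
    labeled fast with probability 1 (no subpopulation structure).
    """
    theta, y, obs, dur, tau_b = _features(cells, dawn_offset)
    if len(obs) < 100:
        raise EstimationError(f"need >= 100 uncensored cells, got {len(obs)}")
    fits, bics = {}, {}
    for n in (1, 2):
        fits[n] = _CircularMixture(n, seed=seed).fit(theta, y)
        bics[n] = float(fits[n].bic_)
    # null for "two phase-linked subpopulations": a duration mixture whose
    # components share the same (uniform) birth-phase distribution; a
    # skewed duration marginal alone then no longer fakes subpopulations
    null2 = _CircularMixture(2, seed=seed, uniform_phase=True).fit(theta, y)
    bics["2_phase_free_null"] = float(null2.bic_)
    n_sel = 2 if bics[2] < min(bics[1], null2.bic_) else 1
    if n_sel == 1:
        label = np.full(len(obs), "fast", dtype=object)
        prob = np.ones(len(obs))
        comp_means = pd.DataFrame(
            {"mean_duration_h": [dur.mean()], "mean_birth_tau_h": [_circ_mean(tau_b)]},
            index=["fast"],
        )
    else:
        resp = fits[2].predict_proba(theta, y)
        hard = resp.argmax(axis=1)
        mean_dur = [dur[hard == c].mean() if (hard == c).any() else np.inf for c in (0, 1)]
        fast_c = int(np.argmin(mean_dur))
        label = np.where(hard == fast_c, "fast", "slow").astype(object)
        prob = resp[np.arange(len(obs)), hard]
        comp_means = pd.DataFrame(
            {
                "mean_duration_h": [dur[label == "fast"].mean(), dur[label == "slow"].mean()],
                "mean_birth_tau_h": [
                    _circ_mean(tau_b[label == "fast"]),
                    _circ_mean(tau_b[label == "slow"]),
                ],
            },
            index=["fast", "slow"],
        )
    return SubpopulationLabels(
        cell_id=obs["cell_id"].to_numpy(),
        label=label,
        posterior_prob=prob,
        n_components=n_sel,
        bic=bics,
        component_means=comp_means,
    )


def _circ_mean(tau: np.ndarray) -> float:
    ang = 2 * np.pi * tau / PERIOD_H
    return float(np.mod(np.arctan2(np.sin(ang).mean(), np.cos(ang).mean()), 2 * np.pi) / (2 * np.pi) * PERIOD_H)


def classify_size_control(slope: float, ci: tuple) -> SizeControlClassification:
    """Label a regression slope of added vs birth length.

    adder-like if the CI contains 0; otherwise sizer-like for negative
    slopes (toward -1, a pure sizer) and timer-like for positive ones.
    """
    lo, hi = ci
    if not (np.isfinite(slope) and np.isfinite(lo) and np.isfinite(hi)):
        raise ValueError("slope and CI must be finite")
    if lo <= 0.0 <= hi:
        label = "adder-like"
    elif slope < 0:
        label = "sizer-like"
    else:
        label = "timer-like"
    return SizeControlClassification(slope=slope, ci=(lo, hi), label=label)


def division_time_window(
    cells: pd.DataFrame, coverage: float = 0.9, dawn_offset: float = 0.0
) -> tuple[float, float]:
    """Central interval containing the given fraction of divisions, in hours after dawn."""
    if not 0 < coverage < 1:
        raise ValueError("coverage must be in (0, 1)")
    td = cells.loc[cells["censored"] == 0, "division_time_h"].dropna().to_numpy(float)
    if td.size == 0:
        raise EstimationError("no divisions in table")
    after_dawn = np.mod(td - dawn_offset, PERIOD_H)
    q = (1.0 - coverage) / 2.0
    return float(np.quantile(after_dawn, q)), float(np.quantile(after_dawn, 1.0 - q))


def added_vs_time_regression(
    cells: pd.DataFrame,
    labels: SubpopulationLabels | None = None,
    subset: str | None = None,
    dawn_offset: float = 0.0,
) -> RegressionSummary:
    """OLS of added length (um) on birth time of day (h) within a subpopulation.

    A negative slope in the fast subpopulation reflects cells born later
    having less time before the end-of-day division window.
    """
    obs = cells[cells["censored"] == 0].dropna(subset=["birth_length_um", "division_length_um"])
    if labels is not None and subset is not None:
        wanted = set(labels.cell_id[labels.label == subset])
        obs = obs[obs["cell_id"].isin(wanted)]
    if len(obs) < 10:
        raise EstimationError(f"need >= 10 cells in subset, got {len(obs)}")
    tau_b = np.asarray(time_of_day(obs["birth_time_h"].to_numpy(float), dawn_offset))
    added = obs["division_length_um"].to_numpy(float) - obs["birth_length_um"].to_numpy(float)
    if np.var(tau_b) == 0:
        raise EstimationError("degenerate birth-time variance")
    res = sm.OLS(added, sm.add_constant(tau_b)).fit()
    ci = res.conf_int(alpha=0.05)
    return RegressionSummary(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        ci_low=float(ci[1][0]),
        ci_high=float(ci[1][1]),
        n=len(obs),
        pvalue=float(res.pvalues[1]),
    )


def cycle_duration_histogram(
    cells: pd.DataFrame,
    bin_h: float = 1.0,
    dawn_offset: float = 0.0,
) -> dict:
    """Histogram of cycle durations plus same-day / next-day summaries.

    A cell divides "same-day" if birth and division fall in the same
    dawn-to-dawn calendar day, "next-day" otherwise (the two
    subpopulations of the LD conditions).
    """
    obs = cells[cells["censored"] == 0].dropna(subset=["birth_time_h", "division_time_h"])
    dur = obs["division_time_h"].to_numpy(float) - obs["birth_time_h"].to_numpy(float)
    edges = np.arange(0.0, dur.max() + bin_h, bin_h) if dur.size else np.array([0.0, bin_h])
    counts, edges = np.histogram(dur, bins=edges)
    day_birth = np.floor((obs["birth_time_h"].to_numpy(float) - dawn_offset) / PERIOD_H)
    day_div = np.floor((obs["division_time_h"].to_numpy(float) - dawn_offset) / PERIOD_H)
    same = day_birth == day_div
    summaries = pd.DataFrame(
        {
            "n": [int(same.sum()), int((~same).sum())],
            "mean_duration_h": [
                float(dur[same].mean()) if same.any() else np.nan,
                float(dur[~same].mean()) if (~same).any() else np.nan,
            ],
        },
        index=["same_day", "next_day"],
    )
    return {"counts": counts, "edges": edges, "day_class": same, "summaries": summaries}
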