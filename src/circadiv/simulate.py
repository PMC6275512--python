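"""Exact stochastic simulation of growing and dividing lineages.

Implements the thinning algorithm for the division rate
``Gamma = S(Delta0) * G(tau) * zeta * alpha(t) * L``: within each time
horizon ``dt_horizon`` the rate is dominated by the constant

    B = S(L(t + dt) - (1 + a) * L0) * Gmax * zeta * alpha_max * L(t + dt)

(valid because S is monotone non-decreasing for k >= 1, L is
non-decreasing, and G, alpha are bounded by Gmax, alpha_max).  Candidate
division times are drawn from an exponential clock at rate B and
accepted with probability Gamma/B evaluated at the exact state at the
candidate time.  On division the length halves, the birth length resets
and the growth amplitude zeta is resampled from Normal(1, sigma)
truncated to positive values.

An observation model mirrors the time-lapse acquisition: lengths are
sampled on a regular frame grid with additive Gaussian noise, and for a
division occurring between two frames the parent's division length is
recorded at the previous frame while each daughter's birth length is
recorded at the next frame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import CouplingFunction, SizeControlParams, bump_coupling, delta0, flat_coupling, size_hazard
from .light import ElongationModel, LightProfile, elongation_integral, mean_elongation_rate, time_of_day

__all__ = [
    "SimConfig",
    "DivisionEvent",
    "TrueCycle",
    "thinning_bound",
    "simulate_lineage",
    "observe_trace",
    "generate_dataset",
    "SCENARIOS",
]

CELL_COLUMNS = [
    "cell_id",
    "lineage_id",
    "parent_id",
    "condition",
    "birth_time_h",
    "division_time_h",
    "birth_length_um",
    "division_length_um",
    "censored",
]
TRACE_COLUMNS = ["cell_id", "time_h", "length_um"]


class UnsupportedHazardError(ValueError):
    """Raised when the thinning bound is invalid (non-monotone hazard)."""


@dataclass(frozen=True)
class SimConfig:
    """Simulation and observation settings.

    t0, T : simulation window (h).
    dt_horizon : thinning time horizon (h).
    dt_acq : acquisition (frame) interval (h).
    n_lineages : number of independent lineages followed.
    L0_mean, L0_sd : lognormal initial-length distribution (um).
    noise_sd : additive measurement noise SD on observed lengths (um).
    seed : RNG seed.
    mode : 'lineage' follows a single daughter per division; 'colony'
        follows both daughters up to max_cells per lineage tree.
    """

    t0: float = 0.0
    T: float = 120.0
    dt_horizon: float = 0.75
    dt_acq: float = 0.75
    n_lineages: int = 150
    L0_mean: float = 3.0
    L0_sd: float = 0.5
    noise_sd: float = 0.03
    seed: int = 0
    mode: str = "lineage"
    max_cells: int = 64

    def __post_init__(self) -> None:
        if self.t0 >= self.T:
            raise ValueError("t0 must precede T")
        if self.dt_horizon <= 0 or self.dt_acq <= 0:
            raise ValueError("time steps must be positive")
        if self.n_lineages < 1:
            raise ValueError("n_lineages must be >= 1")
        if self.mode not in ("lineage", "colony"):
            raise ValueError("mode must be 'lineage' or 'colony'")


@dataclass(frozen=True)
class DivisionEvent:
    """One division: time, pre-division length, and lineage linkage."""

    t_div: float
    L_div: float
    lineage_id: int
    parent_id: int


@dataclass
class TrueCycle:
    """One cell cycle of the continuous (noise-free) trajectory.

    Length at any time within the cycle is
    ``L0 * exp(zeta * int_{t_birth}^{t} alpha)``; ``t_div`` is None for
    cells still alive at the end of the simulation.
    """

    cell_id: int
    lineage_id: int
    parent_id: int
    t_birth: float
    L0: float
    zeta: float
    t_div: float | None = None
    L_div: float | None = None
    first_cycle: bool = False

    def length_at(self, t, model: ElongationModel, profile: LightProfile):
        t_arr = np.atleast_1d(np.asarray(t, dtype=float))
        out = np.array(
            [self.L0 * np.exp(self.zeta * elongation_integral(self.t_birth, ti, model, profile)) for ti in t_arr]
        )
        return out if np.ndim(t) else float(out[0])


def thinning_bound(
    L_end: float,
    L0: float,
    zeta: float,
    G: CouplingFunction,
    params: SizeControlParams,
    alpha_max: float,
) -> float:
    """Dominating rate B over a horizon ending with length ``L_end``.

    B = S(L_end - (1+a) L0) * Gmax * zeta * alpha_max * L_end, which
    bounds Gamma throughout the horizon because every factor is at its
    window maximum.
    """
    if params.k < 1:
        raise UnsupportedHazardError("thinning bound requires a monotone hazard (k >= 1)")
    if L_end < L0 * min(1.0, 1.0 + params.a) or L0 <= 0:
        raise ValueError("L_end must be reachable from a positive birth length")
    return float(size_hazard(delta0(L_end, L0, params.a), params) * G.Gmax * zeta * alpha_max * L_end)


def _draw_zeta(rng: np.random.Generator, sigma: float) -> float:
    """Normal(1, sigma) truncated to positive values."""
    if sigma == 0:
        return 1.0
    while True:
        z = rng.normal(1.0, sigma)
        if z > 0:
            return z


def _simulate_cycles(
    config: SimConfig,
    G: CouplingFunction,
    model: ElongationModel,
    profile: LightProfile,
    params: SizeControlParams,
    rng: np.random.Generator,
    lineage_id: int,
    next_id: int,
) -> tuple[list[TrueCycle], list[DivisionEvent], int]:
    """Run the thinning algorithm for one lineage tree."""
    alpha_max = model.alpha_max(profile)
    t_start = config.t0 + rng.uniform(0.0, config.dt_acq)
    L_init = float(rng.lognormal(np.log(config.L0_mean), config.L0_sd / config.L0_mean))
    root = TrueCycle(
        cell_id=next_id,
        lineage_id=lineage_id,
        parent_id=-1,
        t_birth=t_start,
        L0=L_init,
        zeta=_draw_zeta(rng, params.sigma_zeta),
        first_cycle=True,
    )
    next_id += 1
    cycles: list[TrueCycle] = []
    events: list[DivisionEvent] = []
    stack = [root]
    while stack:
        cell = stack.pop()
        t = cell.t_birth
        L = cell.L0
        divided = False
        while t < config.T:
            t_end = min(t + config.dt_horizon, config.T)
            growth = np.exp(cell.zeta * elongation_integral(t, t_end, model, profile))
            L_end = L * growth
            B = thinning_bound(L_end, cell.L0, cell.zeta, G, params, alpha_max)
            if B <= 0:
                t, L = t_end, L_end
                continue
            tau_wait = rng.exponential(1.0 / B)
            if tau_wait > t_end - t:
                t, L = t_end, L_end
                continue
            t_cand = t + tau_wait
            L_cand = L * np.exp(cell.zeta * elongation_integral(t, t_cand, model, profile))
            if not np.isfinite(L_cand):
                raise FloatingPointError("non-finite cell length in simulation")
            alpha_c = float(mean_elongation_rate(t_cand, model, profile))
            gamma = (
                size_hazard(delta0(L_cand, cell.L0, params.a), params)
                * G(time_of_day(t_cand, profile.dawn_offset))
                * cell.zeta
                * alpha_c
                * L_cand
            )
            u = rng.uniform()
            if gamma >= B * u:
                cell.t_div = float(t_cand)
                cell.L_div = float(L_cand)
                divided = True
                events.append(DivisionEvent(float(t_cand), float(L_cand), lineage_id, cell.cell_id))
                break
            t, L = t_cand, L_cand
        cycles.append(cell)
        if divided:
            n_daughters = 2 if config.mode == "colony" and next_id - root.cell_id < config.max_cells else 1
            for _ in range(n_daughters):
                daughter = TrueCycle(
                    cell_id=next_id,
                    lineage_id=lineage_id,
                    parent_id=cell.cell_id,
                    t_birth=cell.t_div,
                    L0=cell.L_div / 2.0,
                    zeta=_draw_zeta(rng, params.sigma_zeta),
                )
                next_id += 1
                stack.append(daughter)
    cycles.sort(key=lambda c: c.cell_id)
    return cycles, events, next_id


def simulate_lineage(
    config: SimConfig,
    G: CouplingFunction,
    model: ElongationModel,
    profile: LightProfile,
    params: SizeControlParams,
    rng: np.random.Generator | None = None,
) -> tuple[list[TrueCycle], list[DivisionEvent]]:
    """Simulate ``config.n_lineages`` independent lineage trees exactly.

    Returns the continuous trajectory (one :class:`TrueCycle` per cell,
    censored cells with ``t_div`` None) and the list of division events.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    all_cycles: list[TrueCycle] = []
    all_events: list[DivisionEvent] = []
    next_id = 0
    for lineage in range(config.n_lineages):
        cycles, events, next_id = _simulate_cycles(
            config, G, model, profile, params, rng, lineage, next_id
        )
        all_cycles.extend(cycles)
        all_events.extend(events)
    return all_cycles, all_events


def observe_trace(
    cycles: list[TrueCycle],
    config: SimConfig,
    model: ElongationModel,
    profile: LightProfile,
    rng: np.random.Generator | None = None,
    condition: str = "custom",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Discretize continuous trajectories onto the acquisition grid.

    For a division between frames f and f+1 the parent's recorded
    division length is the (noisy) length at frame f and each daughter's
    recorded birth length is its (noisy) length at frame f+1; recorded
    times are the frame times.  Cells alive at T are emitted censored.
    Cells whose full cycle falls between two frames are dropped.

    Returns (cell table, trace table) in the pipeline CSV schemas.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    n_frames = int(np.floor((config.T - config.t0) / config.dt_acq)) + 1
    grid = config.t0 + config.dt_acq * np.arange(n_frames)
    cell_rows = []
    trace_rows = []
    for cell in cycles:
        f_birth = int(np.ceil((cell.t_birth - config.t0) / config.dt_acq - 1e-12))
        if cell.parent_id >= 0:
            # birth recorded at the frame after the parent's division
            f_birth = int(np.floor((cell.t_birth - config.t0) / config.dt_acq + 1e-12)) + 1
        if cell.t_div is not None:
            f_div = int(np.floor((cell.t_div - config.t0) / config.dt_acq + 1e-12))
            censored = 0
        else:
            f_div = n_frames - 1
            censored = 1
        if f_birth >= f_div or f_birth >= n_frames:
            continue  # fewer than two frames observed, unusable record
        times = grid[f_birth : f_div + 1]
        lengths = cell.length_at(times, model, profile)
        if config.noise_sd > 0:
            lengths = lengths + rng.normal(0.0, config.noise_sd, size=lengths.shape)
        lengths = np.maximum(lengths, 1e-6)
        for ti, li in zip(times, lengths):
            trace_rows.append((cell.cell_id, float(ti), float(li)))
        cell_rows.append(
            {
                "cell_id": cell.cell_id,
                "lineage_id": cell.lineage_id,
                "parent_id": cell.parent_id,
                "condition": condition,
                "birth_time_h": float(times[0]),
                "division_time_h": float(times[-1]) if not censored else np.nan,
                "birth_length_um": float(lengths[0]),
                "division_length_um": float(lengths[-1]) if not censored else np.nan,
                "censored": censored,
                "first_cycle": int(cell.first_cycle),
            }
        )
    cells = pd.DataFrame(cell_rows)
    traces = pd.DataFrame(trace_rows, columns=TRACE_COLUMNS)
    return cells, traces


# -- scenarios ---------------------------------------------------------------

def _scenario_components(scenario: str, params: SizeControlParams):
    """Default (G, elongation model, light profile) for a named condition."""
    constant = LightProfile(mode="constant", A=15.0, dawn_offset=0.0)
    graded = LightProfile(mode="graded_LD", A=15.0, TL=12.0, dawn_offset=0.0)
    wt_G = bump_coupling()
    flat = flat_coupling(1.0)
    osc = ElongationModel(mode="constant_light_oscillatory", alpha_bar=0.06, epsilon=0.2, phase=18.0)
    flat_alpha = ElongationModel(mode="constant_light_oscillatory", alpha_bar=0.06, epsilon=0.0)
    tracking = ElongationModel(mode="light_tracking", c=0.06 / 15.0)
    table = {
        "WT_constant": (wt_G, osc, constant),
        "clockdel_constant": (flat, flat_alpha, constant),
        "WT_LD": (wt_G, tracking, graded),
        "clockdel_LD": (flat, tracking, graded),
    }
    if scenario not in table:
        raise KeyError(
            f"unknown scenario {scenario!r}; expected one of {sorted(table)} or 'custom'"
        )
    return table[scenario]


SCENARIOS = ("WT_constant", "clockdel_constant", "WT_LD", "clockdel_LD", "custom")


def generate_dataset(
    config: SimConfig,
    scenario: str = "clockdel_constant",
    params: SizeControlParams | None = None,
    G: CouplingFunction | None = None,
    model: ElongationModel | None = None,
    profile: LightProfile | None = None,
    keep_first_cycles: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a synthetic cell table and trace table for a named condition.

    Scenarios mirror the experimental conditions: wild type or clock
    deletion (G = 1), constant light or graded 12:12 LD.  ``custom``
    requires G, model and profile explicitly.  The first, partially
    observed cycle of each lineage is excluded (its birth was not
    observed as a division), mirroring unobservable history in
    experiments.  Reproducible given ``config.seed``.
    """
    if params is None:
        params = SizeControlParams()
    if scenario == "custom":
        if G is None or model is None or profile is None:
            raise KeyError("custom scenario requires explicit G, model and profile")
    else:
        G_s, model_s, profile_s = _scenario_components(scenario, params)
        G = G if G is not None else G_s
        model = model if model is not None else model_s
        profile = profile if profile is not None else profile_s
    rng = np.random.default_rng(config.seed)
    cycles, _events = simulate_lineage(config, G, model, profile, params, rng)
    cells, traces = observe_trace(cycles, config, model, profile, rng, condition=scenario)
    if not keep_first_cycles and len(cells):
        keep = cells["first_cycle"] == 0
        cells = cells.loc[keep].reset_index(drop=True)
        traces = traces[traces["cell_id"].isin(cells["cell_id"])].reset_index(drop=True)
    if len(cells):
        cells = cells.drop(columns=["first_cycle"])
    else:
        cells = pd.DataFrame(columns=CELL_COLUMNS)
    return cells, traces
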