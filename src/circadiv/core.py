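"""Division-rate model: size-control hazard, clock coupling, effective coupling.

The division rate of a cell of length ``L`` born at length ``L0`` is

    Gamma(L, L0, dL/dt, t) = S(L, L0) * G(t) * dL/dt

the product of a clock-independent size-control hazard ``S`` (rate per
unit length of triggering division), a positive periodic coupling
function ``G`` of the time of day imposed by the circadian clock, and
the instantaneous elongation rate ``dL/dt = zeta * alpha(t) * L`` of an
exponentially growing cell.

The size control depends on length only through the birth-length
independent part of the added length,

    Delta0 = L - (1 + a) * L0,

so added length at division satisfies the linear law
``Delta = a * L0 + Delta0`` with ``Delta0`` stochastic.  ``S(Delta0)`` is
taken Weibull-form in ``Delta0`` (shape ``k >= 1``, scale ``lam``): it is
monotonically increasing for ``k > 1``, nests a constant hazard at
``k = 1``, and makes the distribution of ``Delta0`` at division exactly
Weibull(k, lam), which the simulator tests exploit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline

from .light import (
    PERIOD_H,
    ElongationModel,
    LightProfile,
    mean_elongation_rate,
    time_of_day,
)

__all__ = [
    "SizeControlParams",
    "CouplingFunction",
    "CellState",
    "delta0",
    "size_hazard",
    "division_rate",
    "effective_coupling",
    "coupling_eval",
    "flat_coupling",
    "bump_coupling",
]


class InvalidStateError(ValueError):
    """Raised for physically impossible cell states (e.g. L0 <= 0)."""


class InvalidCouplingError(ValueError):
    """Raised when a coupling function is under-parametrized."""


@dataclass(frozen=True)
class SizeControlParams:
    """Parameters of the linear size-control model.

    a : birth-length coupling of added length (dimensionless).
        a = 0 is an adder, a -> -1 a sizer, a > 0 timer-like.
    k : Weibull hazard shape (dimensionless), k >= 1.
    lam : Weibull hazard scale (um).
    sigma_zeta : SD of the per-cell growth amplitude zeta (dimensionless).
    """

    a: float = -0.35
    k: float = 2.0
    lam: float = 4.5
    sigma_zeta: float = 0.15

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("hazard shape k must be >= 1 (monotone non-decreasing hazard)")
        if self.lam <= 0:
            raise ValueError("hazard scale lam must be positive")
        if self.sigma_zeta < 0:
            raise ValueError("sigma_zeta must be non-negative")


@dataclass(frozen=True)
class CellState:
    """Instantaneous state of one cell: length, birth length, growth amplitude, time."""

    L: float
    L0: float
    zeta: float = 1.0
    t: float = 0.0

    def __post_init__(self) -> None:
        if self.L0 <= 0 or self.L <= 0:
            raise InvalidStateError("cell lengths must be positive")
        if self.zeta <= 0:
            raise InvalidStateError("growth amplitude zeta must be positive")


def delta0(L, L0, a: float):
    """Birth-length independent part of added length, Delta0 = L - (1+a) L0.

    May be negative early in the cycle; the hazard is zero there.
    """
    L0 = np.asarray(L0, dtype=float)
    if np.any(L0 <= 0):
        raise InvalidStateError("birth length L0 must be positive")
    out = np.asarray(L, dtype=float) - (1.0 + a) * L0
    return out if out.ndim else float(out)


def size_hazard(d0, params: SizeControlParams):
    """Size-control hazard S(Delta0), rate per unit added length (1/um).

    Weibull form: S(d0) = (k/lam) * (d0/lam)**(k-1) for d0 > 0, else 0.
    Non-decreasing in d0 for k >= 1; constant 1/lam at k = 1.
    """
    d = np.asarray(d0, dtype=float)
    with np.errstate(invalid="ignore"):
        out = np.where(
            d > 0,
            (params.k / params.lam) * (np.maximum(d, 0.0) / params.lam) ** (params.k - 1.0),
            0.0,
        )
    return out if out.ndim else float(out)


class CouplingFunction:
    """Positive periodic coupling function G(tau) of the time of day.

    Parametrized as the exponential of a periodic cubic spline through
    ``log_values`` at ``knot_times`` (hours in [0, 24)), so positivity and
    24-h periodicity hold by construction.  ``G = 1`` everywhere models
    clock-deletion cells.

    Parameters
    ----------
    knot_times : array-like
        Strictly increasing knot locations in [0, 24); at least 4.
    log_values : array-like
        Log-coupling at the knots.
    Gmax : float, optional
        Upper bound used by the thinning simulator.  Defaults to 1.5x the
        maximum of G over a dense grid.
    """

    def __init__(self, knot_times, log_values, Gmax: float | None = None):
        kt = np.asarray(knot_times, dtype=float)
        lv = np.asarray(log_values, dtype=float)
        if kt.ndim != 1 or kt.size < 4:
            raise InvalidCouplingError("coupling needs at least 4 knots over [0, 24)")
        if kt.size != lv.size:
            raise InvalidCouplingError("knot_times and log_values must have equal length")
        if np.any(np.diff(kt) <= 0) or kt[0] < 0 or kt[-1] >= PERIOD_H:
            raise InvalidCouplingError("knots must be strictly increasing within [0, 24)")
        self.knot_times = kt
        self.log_values = lv
        x = np.concatenate([kt, [kt[0] + PERIOD_H]])
        y = np.concatenate([lv, [lv[0]]])
        self._spline = CubicSpline(x, y, bc_type="periodic")
        if Gmax is None:
            grid = np.linspace(0.0, PERIOD_H, 481)
            Gmax = 1.5 * float(np.max(self(grid)))
        if not np.isfinite(Gmax):
            raise InvalidCouplingError("Gmax must be finite")
        self.Gmax = float(Gmax)

    def __call__(self, tau):
        t = np.mod(np.asarray(tau, dtype=float) - self.knot_times[0], PERIOD_H) + self.knot_times[0]
        out = np.exp(self._spline(t))
        return out if out.ndim else float(out)

    def argmax(self, n_grid: int = 2401) -> float:
        """Time of day at which G peaks, from a dense grid."""
        grid = np.linspace(0.0, PERIOD_H, n_grid, endpoint=False)
        return float(grid[np.argmax(self(grid))])

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"CouplingFunction({self.knot_times.size} knots, "
            f"range [{np.exp(self.log_values.min()):.3g}, {np.exp(self.log_values.max()):.3g}])"
        )


def coupling_eval(tau, G: CouplingFunction):
    """Evaluate G at time of day tau (periodic, exact at knots)."""
    return G(tau)


def flat_coupling(value: float = 1.0, n_knots: int = 8) -> CouplingFunction:
    """Constant coupling G = value; value 1 models clock-deletion cells."""
    knots = np.arange(n_knots) * (PERIOD_H / n_knots)
    return CouplingFunction(knots, np.full(n_knots, np.log(value)))


def bump_coupling(
    peak_time: float = 22.0,
    height: float = 3.0,
    basal: float = 0.25,
    concentration: float = 5.0,
    n_knots: int = 8,
) -> CouplingFunction:
    """Smooth single-peaked coupling: basal level with a von-Mises-style bump.

    The spline knots sample ``basal + (height - basal) *
    exp(concentration * (cos(2*pi*(tau - center)/24) - 1))``, with the
    bump center adjusted so the resulting spline attains its maximum at
    ``peak_time``.  Mimics the inferred wild-type coupling: low through
    subjective night and early day, peaking near the end of subjective
    day (dawn at tau = 12).
    """
    if height <= 0 or basal <= 0:
        raise InvalidCouplingError("coupling levels must be positive")
    knots = np.arange(n_knots) * (PERIOD_H / n_knots)

    def build(center: float) -> CouplingFunction:
        g = basal + (height - basal) * np.exp(
            concentration * (np.cos(2.0 * np.pi * (knots - center) / PERIOD_H) - 1.0)
        )
        return CouplingFunction(knots, np.log(g))

    # The spline through sampled knots generally peaks slightly off the
    # analytic bump center; shift the center so the spline peak lands on
    # peak_time (circular bisection on the offset).
    center = peak_time
    for _ in range(25):
        shift = peak_time - build(center).argmax()
        shift = (shift + PERIOD_H / 2) % PERIOD_H - PERIOD_H / 2
        if abs(shift) < 5e-3:
            break
        center = (center + shift) % PERIOD_H
    return build(center)


def division_rate(
    state: CellState,
    G: CouplingFunction,
    alpha: float,
    params: SizeControlParams,
    dawn_offset: float = 0.0,
):
    """Instantaneous division rate Gamma (1/h) of a cell in the given state.

    Gamma = S(Delta0) * G(tau(t)) * zeta * alpha * L, with
    dL/dt = zeta * alpha * L (exponential growth).  Zero whenever
    alpha = 0 (dark) or Delta0 <= 0.
    """
    if alpha < 0:
        raise ValueError("elongation rate alpha must be non-negative")
    d0 = delta0(state.L, state.L0, params.a)
    tau = time_of_day(state.t, dawn_offset)
    return float(size_hazard(d0, params) * G(tau) * state.zeta * alpha * state.L)


def effective_coupling(texp, G: CouplingFunction, model: ElongationModel, profile: LightProfile):
    """Effective coupling G(tau(t)) * alpha(t): the time-dependent part of Gamma.

    Combines the clock's modulation with the environment's via growth;
    zero in the dark, and reduces to alpha(t) for clock-deletion cells
    (G = 1).
    """
    tau = time_of_day(texp, profile.dawn_offset)
    out = np.asarray(G(tau), dtype=float) * np.asarray(
        mean_elongation_rate(texp, model, profile), dtype=float
    )
    return out if out.ndim else float(out)
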