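"""Light environment and mean elongation-rate models.

Experiments on *S. elongatus* are run either under constant cool white
light or under graded light--dark (LD) cycles in which the irradiance
follows a half-sinusoid during the light period and is zero in the dark.
The graded profile is flux-matched to the constant-light reference: the
photon flux integrated over 24 h equals ``24 * A`` in both regimes, which
fixes the midday peak at ``Imax = 24 * A * pi / (2 * TL)``.

Time-of-day convention
----------------------
All modules share the entrainment convention that dawn (the end of the
last dark period of the entraining 12:12 LD cycle) maps to a time of day
of tau = 12 h.  ``dawn_offset`` is the experiment time of the first dawn,
so ``tau = mod(t_exp - dawn_offset + 12, 24)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "LightProfile",
    "ElongationModel",
    "peak_irradiance",
    "irradiance",
    "time_of_day",
    "mean_elongation_rate",
    "elongation_integral",
]

PERIOD_H = 24.0


class InvalidProfileError(ValueError):
    """Raised when a light profile is physically inconsistent."""


class InvalidModelError(ValueError):
    """Raised when an elongation model would produce a negative rate."""


def peak_irradiance(A: float, TL: float) -> float:
    """Midday peak of a graded LD profile flux-matched to constant light.

    Parameters
    ----------
    A : float
        Mean irradiance of the constant-light reference (uE m^-2 s^-1).
    TL : float
        Duration of the light period (h), in (0, 24].

    Returns
    -------
    float
        ``Imax = 24 * A * pi / (2 * TL)``, so that the daily photon flux
        per unit area equals that of constant light at level ``A``.
    """
    if A < 0:
        raise InvalidProfileError(f"irradiance must be non-negative, got A={A}")
    if not 0 < TL <= PERIOD_H:
        raise InvalidProfileError(f"light period must satisfy 0 < TL <= 24 h, got TL={TL}")
    return PERIOD_H * A * np.pi / (2.0 * TL)


@dataclass(frozen=True)
class LightProfile:
    """Ambient light condition descriptor.

    mode : ``"constant"`` or ``"graded_LD"``.
    A : mean irradiance over 24 h (uE m^-2 s^-1).
    TL : light-period duration (h); graded mode only.
    dawn_offset : experiment time of the first dawn (h).
    """

    mode: str = "constant"
    A: float = 15.0
    TL: float = 12.0
    dawn_offset: float = 0.0

    def __post_init__(self) -> None:
        if self.mode not in ("constant", "graded_LD"):
            raise InvalidProfileError(f"unknown light mode {self.mode!r}")
        if self.A < 0:
            raise InvalidProfileError("mean irradiance A must be non-negative")
        if self.mode == "graded_LD" and not 0 < self.TL <= PERIOD_H:
            raise InvalidProfileError("graded mode requires 0 < TL <= 24 h")

    @property
    def Imax(self) -> float:
        """Peak irradiance; equals A in constant mode."""
        if self.mode == "constant":
            return self.A
        return peak_irradiance(self.A, self.TL)


def time_of_day(texp, dawn_offset: float = 0.0):
    """Map experiment time to time of day tau in [0, 24), dawn at tau = 12."""
    return np.mod(np.asarray(texp, dtype=float) - dawn_offset + 12.0, PERIOD_H)


def irradiance(texp, profile: LightProfile):
    """Irradiance I(t_exp) under the given profile.

    Constant mode returns ``A`` everywhere.  Graded mode returns
    ``Imax * sin(2*pi*u / (2*TL))`` for ``u = mod(texp - dawn_offset, 24)``
    inside the light window ``0 <= u <= TL`` and 0 otherwise.
    """
    t = np.asarray(texp, dtype=float)
    if profile.mode == "constant":
        out = np.full_like(t, profile.A)
        return out if out.ndim else float(out)
    u = np.mod(t - profile.dawn_offset, PERIOD_H)
    imax = profile.Imax
    out = np.where(u <= profile.TL, imax * np.sin(np.pi * u / profile.TL), 0.0)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class ElongationModel:
    """Mean exponential elongation rate alpha(t).

    Two modes mirror the two experimental regimes:

    ``constant_light_oscillatory``
        alpha(t) = alpha_bar * (1 + epsilon * cos(2*pi*(tau - phase)/24)).
        Under constant light elongation rates oscillate with circadian
        period; ``epsilon = 0`` disables the oscillation (clock deletion).

    ``light_tracking``
        alpha(t) = c * I(t); elongation tracks ambient light, so growth
        (and hence division) stops in the dark.
    """

    mode: str = "constant_light_oscillatory"
    alpha_bar: float = 0.06
    epsilon: float = 0.0
    phase: float = 18.0
    c: float = 0.004

    def __post_init__(self) -> None:
        if self.mode not in ("constant_light_oscillatory", "light_tracking"):
            raise InvalidModelError(f"unknown elongation mode {self.mode!r}")
        if self.alpha_bar < 0 or self.c < 0:
            raise InvalidModelError("elongation rates must be non-negative")
        if not 0 <= self.epsilon < 1:
            raise InvalidModelError("relative oscillation amplitude must lie in [0, 1)")

    def alpha_max(self, profile: LightProfile) -> float:
        """Upper bound on alpha(t), required by the thinning simulator."""
        if self.mode == "constant_light_oscillatory":
            return self.alpha_bar * (1.0 + self.epsilon)
        return self.c * profile.Imax


def mean_elongation_rate(texp, model: ElongationModel, profile: LightProfile):
    """Evaluate alpha(t_exp) for the given elongation model and light profile."""
    t = np.asarray(texp, dtype=float)
    if model.mode == "constant_light_oscillatory":
        tau = time_of_day(t, profile.dawn_offset)
        out = model.alpha_bar * (
            1.0 + model.epsilon * np.cos(2.0 * np.pi * (tau - model.phase) / PERIOD_H)
        )
    else:
        out = model.c * np.asarray(irradiance(t, profile), dtype=float)
    return out if out.ndim else float(out)


def _cumulative_irradiance(t: float, profile: LightProfile) -> float:
    """Integral of I from the first dawn up to experiment time t (closed form)."""
    u = t - profile.dawn_offset
    days = np.floor(u / PERIOD_H)
    rem = u - PERIOD_H * days
    TL = profile.TL
    imax = profile.Imax
    per_day = imax * 2.0 * TL / np.pi  # = 24 * A by flux matching
    partial = imax * (TL / np.pi) * (1.0 - np.cos(np.pi * min(rem, TL) / TL))
    return days * per_day + partial


def elongation_integral(t1: float, t2: float, model: ElongationModel, profile: LightProfile) -> float:
    """Closed-form integral of alpha(t) over [t1, t2].

    This is the log growth factor per unit zeta: within a cell cycle
    L(t2) = L(t1) * exp(zeta * elongation_integral(t1, t2)).
    """
    if t2 < t1:
        raise ValueError("t2 must be >= t1")
    if model.mode == "constant_light_oscillatory":
        w = 2.0 * np.pi / PERIOD_H
        ph = profile.dawn_offset - 12.0 + model.phase
        osc = (np.sin(w * (t2 - ph)) - np.sin(w * (t1 - ph))) / w
        return model.alpha_bar * ((t2 - t1) + model.epsilon * osc)
    return model.c * (_cumulative_irradiance(t2, profile) - _cumulative_irradiance(t1, profile))
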