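"""Time-varying-elastance active fiber stress with length-dependent Ca2+ sensitivity.

Active contraction is modelled as a product of a calcium-sensitivity factor
and a cosine activation envelope:

    sigma_af(t, E_ff) = (T_max / 2) * Ca0^2 / (Ca0^2 + ECa50(E_ff)^2)
                        * (1 - cos omega(t, E_ff))

The half-maximal calcium concentration falls as the sarcomere lengthens
beyond the zero-tension length L_0 (the Frank–Starling effect):

    ECa50(E_ff) = Ca0_max / sqrt(exp(B (L(E_ff) - L_0)) - 1)

with the current sarcomere length obtained from the fiber Green–Lagrange
strain, L = L_r sqrt(2 E_ff + 1).  The activation phase omega ramps from 0
to pi over the time-to-peak t0, then from pi to 2*pi over a relaxation
duration that grows linearly with sarcomere length, t_r(L) = m L + b_relax.

Unit convention
---------------
Sarcomere lengths are accepted in micrometres at every API.  The printed
constants B = 4750 and m = 1048.9 are per millimetre of sarcomere length
(B mm^-1, m s/mm): only with lengths in millimetres do they yield a finite
length sensitivity (B*(L_r - L_0) = 1.2825 at baseline) and a physiological
relaxation time (t_r(1.85 um) = 0.511 s).  Lengths are therefore converted
um -> mm internally; times are seconds and stresses MPa throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ActiveParams",
    "ActivationState",
    "activation_state",
    "TwitchTrace",
    "BelowActivationThreshold",
    "sarcomere_length",
    "eca50",
    "relaxation_duration",
    "activation_phase",
    "active_fiber_stress",
    "peak_isometric_stress",
    "duration_of_contraction",
    "length_tension_curve",
]

_UM_TO_MM = 1e-3


class BelowActivationThreshold(ValueError):
    """The sarcomere is at or below the zero-tension length L_0."""


@dataclass(frozen=True)
class ActiveParams:
    """Active material constants of the time-varying-elastance law.

    T_max      maximum isometric tension (MPa)
    Ca0        peak intracellular calcium (arbitrary concentration units)
    Ca0_max    maximum calcium concentration (same units)
    B          length-sensitivity exponent (mm^-1)
    t0         time to peak tension (s)
    m          relaxation-duration slope (s/mm)
    b_relax    relaxation-duration intercept (s)
    L_r        unloaded reference sarcomere length (um)
    L_0        sarcomere length below which no active tension develops (um)
    """

    T_max: float = 0.1
    Ca0: float = 4.35
    Ca0_max: float = 4.35
    B: float = 4750.0
    t0: float = 0.1
    m: float = 1048.9
    b_relax: float = -1.429
    L_r: float = 1.85
    L_0: float = 1.58

    def __post_init__(self) -> None:
        if self.T_max <= 0:
            raise ValueError("T_max must be positive")
        if self.t0 <= 0:
            raise ValueError("t0 must be positive")
        if not (self.L_r > self.L_0 > 0):
            raise ValueError("need L_r > L_0 > 0")
        if relaxation_duration(self.L_r, self) <= 0:
            raise ValueError("relaxation duration t_r(L_r) must be positive")

    @property
    def sld(self) -> float:
        """Sarcomere length difference L_r - L_0 (um)."""
        return self.L_r - self.L_0


@dataclass(frozen=True)
class TwitchTrace:
    """Sampled isometric twitch: active fiber stress on a uniform time grid."""

    times: np.ndarray
    stresses: np.ndarray
    peak_stress: float
    peak_time: float
    duration_of_contraction: float

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"t_s": self.times, "sigma_af_MPa": self.stresses})


@dataclass(frozen=True)
class ActivationState:
    """All intermediate quantities of the active law at one (t, E_ff) point.

    Useful for inspecting a twitch: the current sarcomere length L (um),
    relaxation duration t_r (s), activation phase omega (rad), half-maximal
    calcium ECa50 (concentration units, inf below threshold), and the
    resulting active stress sigma_af (MPa).
    """

    t: float
    E_ff: float
    L: float
    t_r: float
    omega: float
    ECa50: float
    sigma_af: float


def activation_state(t: float, E_ff: float, params: ActiveParams) -> ActivationState:
    """Evaluate every intermediate of the active law at one point."""
    L = sarcomere_length(E_ff, params.L_r)
    try:
        e = eca50(E_ff, params)
    except BelowActivationThreshold:
        e = math.inf
    return ActivationState(
        t=t,
        E_ff=E_ff,
        L=L,
        t_r=relaxation_duration(L, params),
        omega=activation_phase(t, E_ff, params),
        ECa50=e,
        sigma_af=active_fiber_stress(t, E_ff, params),
    )


def sarcomere_length(E_ff: float, L_r: float) -> float:
    """Current sarcomere length (um) from fiber Green–Lagrange strain."""
    radicand = 2.0 * E_ff + 1.0
    if radicand <= 0:
        raise ValueError("2*E_ff + 1 must be positive (non-physical compression)")
    return L_r * math.sqrt(radicand)


def eca50(E_ff: float, params: ActiveParams) -> float:
    """Half-maximal calcium concentration at the current sarcomere length.

    Raises :class:`BelowActivationThreshold` when L <= L_0; callers that
    need a stress treat that state as producing zero active tension.
    """
    L = sarcomere_length(E_ff, params.L_r)
    if L <= params.L_0:
        raise BelowActivationThreshold(
            f"sarcomere length {L:.4f} um at or below L_0 = {params.L_0} um"
        )
    expm1 = math.expm1(params.B * (L - params.L_0) * _UM_TO_MM)
    return params.Ca0_max / math.sqrt(expm1)


def relaxation_duration(L: float, params: ActiveParams) -> float:
    """Length-dependent relaxation duration t_r = m L + b_relax (s), L in um."""
    if L <= 0:
        raise ValueError("sarcomere length must be positive")
    return params.m * L * _UM_TO_MM + params.b_relax


def activation_phase(t: float, E_ff: float, params: ActiveParams) -> float:
    """Activation phase omega(t, E_ff) in radians.

    Ramps 0 -> pi over [0, t0), pi -> 2*pi over the relaxation window
    [t0, t0 + t_r(L)), and is 0 afterwards, making 1 - cos(omega) a
    continuous twitch envelope.
    """
    if t < 0:
        raise ValueError("time must be non-negative")
    if t < params.t0:
        return math.pi * t / params.t0
    t_r = relaxation_duration(sarcomere_length(E_ff, params.L_r), params)
    if t_r > 0 and t < params.t0 + t_r:
        return math.pi * (t - params.t0 + t_r) / t_r
    return 0.0


def _sensitivity_factor(E_ff: float, params: ActiveParams) -> float:
    """Ca0^2 / (Ca0^2 + ECa50^2), the length-dependent fraction of T_max."""
    try:
        e = eca50(E_ff, params)
    except BelowActivationThreshold:
        return 0.0
    return params.Ca0**2 / (params.Ca0**2 + e**2)


def active_fiber_stress(t: float, E_ff: float, params: ActiveParams) -> float:
    """Active fiber Cauchy stress sigma_af(t, E_ff) in MPa.

    Zero below the activation threshold (L <= L_0) and outside the
    activation window; bounded above by T_max.
    """
    factor = _sensitivity_factor(E_ff, params)
    if factor == 0.0:
        return 0.0
    omega = activation_phase(t, E_ff, params)
    return 0.5 * params.T_max * factor * (1.0 - math.cos(omega))


def peak_isometric_stress(params: ActiveParams) -> float:
    """Peak stress of an isometric twitch at E_ff = 0 (MPa).

    Closed form T_max Ca0^2/(Ca0^2 + ECa50(0)^2); a function of the
    sarcomere length difference L_r - L_0 only.
    """
    return params.T_max * _sensitivity_factor(0.0, params)


def duration_of_contraction(params: ActiveParams) -> float:
    """Isometric duration of contraction t0 + t_r(L_r) (s); independent of L_0."""
    return params.t0 + relaxation_duration(params.L_r, params)


def length_tension_curve(
    L_grid, params: ActiveParams
) -> list[tuple[float, float]]:
    """Peak active tension as a function of sarcomere length (um).

    Each point evaluates the isometric peak T_max Ca0^2/(Ca0^2 + ECa50(L)^2)
    with the length held at L; zero at and below L_0.
    """
    out = []
    for L in L_grid:
        if L <= 0:
            raise ValueError("sarcomere lengths must be positive")
        if L <= params.L_0:
            out.append((float(L), 0.0))
            continue
        expm1 = math.expm1(params.B * (L - params.L_0) * _UM_TO_MM)
        e = params.Ca0_max / math.sqrt(expm1)
        out.append(
            (float(L), params.T_max * params.Ca0**2 / (params.Ca0**2 + e**2))
        )
    return out
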