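"""Holzapfel–Ogden passive myocardium under axis-aligned biaxial stretch.

The passive response of myocardial tissue is modelled by an orthotropic
hyperelastic strain-energy density split into an isotropic matrix term, two
exponential reinforcement terms along the fiber and sheet directions, a
fiber–sheet coupling term, and a volumetric penalty:

    psi_iso      = a/(2b)   * (exp(b (I1_bar - 3)) - 1)
    psi_fiber(i) = a_i/(2b_i) * (exp(b_i (I4i - 1)^2) - 1),  i in {f, s}
    psi_coupling = a_fs/(2b_fs) * (exp(b_fs I8fs^2) - 1)
    psi_vol      = (1/D) * ((J^2 - 1)/2 - ln J)

with deviatoric invariants I1_bar, I4f, I4s, I8fs of the right Cauchy–Green
tensor.  The anisotropic terms reinforce in tension only (they contribute
when I4 > 1), the standard convention for collagen-like fibers that cannot
support compression.

For a homogeneous, incompressible, axis-aligned biaxial stretch
(lambda_f, lambda_s prescribed, sheet-normal faces traction-free) the Cauchy
stresses have the closed forms

    sigma_ff = a exp(b (I1-3)) (lambda_f^2 - lambda_n^2)
               + 2 a_f (I4f - 1) exp(b_f (I4f - 1)^2) lambda_f^2
    sigma_ss = a exp(b (I1-3)) (lambda_s^2 - lambda_n^2)
               + 2 a_s (I4s - 1) exp(b_s (I4s - 1)^2) lambda_s^2

where the hydrostatic pressure has been eliminated through the
zero-traction condition in the sheet-normal direction and
lambda_n = 1/(lambda_f lambda_s) by incompressibility.

All stresses and energy densities are in MPa.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "PassiveParams",
    "KinematicState",
    "EnergyBreakdown",
    "StressPair",
    "sheet_normal_stretch",
    "kinematics_from_biaxial",
    "strain_energy",
    "cauchy_biaxial",
    "numeric_stress_oracle",
]


@dataclass(frozen=True)
class PassiveParams:
    """Passive material constants.

    Moduli ``a``, ``a_f``, ``a_s``, ``a_fs`` are stress-like (MPa); the
    ``b`` exponents are dimensionless; ``D`` is a volumetric compliance
    (MPa^-1, only relevant in the compressible mode).
    """

    a: float = 0.004
    b: float = 8.0
    a_f: float = 0.005
    b_f: float = 5.0
    a_s: float = 0.002
    b_s: float = 2.0
    a_fs: float = 0.0
    b_fs: float = 1.0
    D: float = 1e-3

    def __post_init__(self) -> None:
        for name in ("a", "a_f", "a_s", "a_fs"):
            if getattr(self, name) < 0:
                raise ValueError(f"modulus {name} must be >= 0")
        for name in ("b", "b_f", "b_s", "b_fs"):
            if getattr(self, name) <= 0:
                raise ValueError(f"exponent {name} must be > 0")
        if self.D <= 0:
            raise ValueError("volumetric compliance D must be > 0")


@dataclass(frozen=True)
class KinematicState:
    """Principal stretches and deviatoric invariants of one deformation state."""

    lambda_f: float
    lambda_s: float
    lambda_n: float
    J: float
    I1_bar: float
    I4f: float
    I4s: float
    I8fs: float

    def __post_init__(self) -> None:
        if min(self.lambda_f, self.lambda_s, self.lambda_n) <= 0:
            raise ValueError("principal stretches must be positive")
        if self.J <= 0:
            raise ValueError("volume ratio J must be positive")


@dataclass(frozen=True)
class EnergyBreakdown:
    """Strain-energy density split by physical origin (MPa)."""

    psi_iso: float
    psi_fiber: float
    psi_sheet: float
    psi_coupling: float
    psi_vol: float

    @property
    def psi_total(self) -> float:
        return (
            self.psi_iso
            + self.psi_fiber
            + self.psi_sheet
            + self.psi_coupling
            + self.psi_vol
        )


@dataclass(frozen=True)
class StressPair:
    """Cauchy stress components along the fiber and sheet axes (MPa)."""

    sigma_ff: float
    sigma_ss: float


def sheet_normal_stretch(lambda_f: float, lambda_s: float) -> float:
    """Sheet-normal stretch under incompressibility, 1/(lambda_f lambda_s)."""
    if lambda_f <= 0 or lambda_s <= 0:
        raise ValueError("stretches must be positive")
    return 1.0 / (lambda_f * lambda_s)


def kinematics_from_biaxial(lambda_f: float, lambda_s: float) -> KinematicState:
    """Assemble the invariant set for an incompressible axis-aligned biaxial state.

    The fiber and sheet directions coincide with the stretch axes, so
    I4f = lambda_f^2, I4s = lambda_s^2 and the coupling invariant I8fs
    vanishes; J = 1 makes the deviatoric invariants equal the plain ones.
    """
    lambda_n = sheet_normal_stretch(lambda_f, lambda_s)
    return KinematicState(
        lambda_f=lambda_f,
        lambda_s=lambda_s,
        lambda_n=lambda_n,
        J=1.0,
        I1_bar=lambda_f**2 + lambda_s**2 + lambda_n**2,
        I4f=lambda_f**2,
        I4s=lambda_s**2,
        I8fs=0.0,
    )


def _tension(I4: float) -> float:
    # Tension-only reinforcement: (I4 - 1) clipped at zero from below.
    return I4 - 1.0 if I4 > 1.0 else 0.0


def strain_energy(params: PassiveParams, state: KinematicState) -> EnergyBreakdown:
    """Evaluate the strain-energy decomposition at one kinematic state."""
    p = params
    e4f = _tension(state.I4f)
    e4s = _tension(state.I4s)
    psi_iso = p.a / (2.0 * p.b) * (math.exp(p.b * (state.I1_bar - 3.0)) - 1.0)
    psi_fiber = p.a_f / (2.0 * p.b_f) * (math.exp(p.b_f * e4f**2) - 1.0)
    psi_sheet = p.a_s / (2.0 * p.b_s) * (math.exp(p.b_s * e4s**2) - 1.0)
    psi_coupling = p.a_fs / (2.0 * p.b_fs) * (math.exp(p.b_fs * state.I8fs**2) - 1.0)
    psi_vol = (1.0 / p.D) * ((state.J**2 - 1.0) / 2.0 - math.log(state.J))
    return EnergyBreakdown(psi_iso, psi_fiber, psi_sheet, psi_coupling, psi_vol)


def cauchy_biaxial(
    params: PassiveParams, lambda_f: float, lambda_s: float
) -> StressPair:
    """Closed-form Cauchy stresses for the incompressible biaxial state.

    The incompressibility pressure is eliminated using the traction-free
    condition on the sheet-normal faces.
    """
    p = params
    state = kinematics_from_biaxial(lambda_f, lambda_s)
    iso = p.a * math.exp(p.b * (state.I1_bar - 3.0))
    e4f = _tension(state.I4f)
    e4s = _tension(state.I4s)
    sigma_ff = iso * (state.lambda_f**2 - state.lambda_n**2)
    sigma_ff += 2.0 * p.a_f * e4f * math.exp(p.b_f * e4f**2) * state.lambda_f**2
    sigma_ss = iso * (state.lambda_s**2 - state.lambda_n**2)
    sigma_ss += 2.0 * p.a_s * e4s * math.exp(p.b_s * e4s**2) * state.lambda_s**2
    return StressPair(sigma_ff=sigma_ff, sigma_ss=sigma_ss)


def _incompressible_energy(params: PassiveParams, lf: float, ls: float) -> float:
    return strain_energy(params, kinematics_from_biaxial(lf, ls)).psi_total


def numeric_stress_oracle(
    params: PassiveParams,
    lambda_f: float,
    lambda_s: float,
    h: float = 1e-6,
) -> StressPair:
    """Brute-force stresses by central differences of the constrained energy.

    Writing W_hat(lambda_f, lambda_s) for the strain energy with the
    incompressibility constraint lambda_n = 1/(lambda_f lambda_s) substituted,
    the derivative with respect to log-stretch gives the Cauchy stress net of
    the reaction pressure from the traction-free sheet-normal direction:

        sigma_ff = d W_hat / d ln(lambda_f),   sigma_ss = d W_hat / d ln(lambda_s)

    Central differences in ln(lambda) make the estimate second-order in ``h``.
    This path deliberately shares no code with :func:`cauchy_biaxial` beyond
    the energy density itself, so it serves as an independent check of the
    closed forms.
    """
    if h <= 0:
        raise ValueError("finite-difference step h must be positive")
    lf_p, lf_m = lambda_f * math.exp(h), lambda_f * math.exp(-h)
    ls_p, ls_m = lambda_s * math.exp(h), lambda_s * math.exp(-h)
    sigma_ff = (
        _incompressible_energy(params, lf_p, lambda_s)
        - _incompressible_energy(params, lf_m, lambda_s)
    ) / (2.0 * h)
    sigma_ss = (
        _incompressible_energy(params, lambda_f, ls_p)
        - _incompressible_energy(params, lambda_f, ls_m)
    ) / (2.0 * h)
    return StressPair(sigma_ff=sigma_ff, sigma_ss=sigma_ss)
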