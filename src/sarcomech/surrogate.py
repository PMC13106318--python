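"""Reduced 0D closed-loop left-heart surrogate.

The organ level is represented by four lumped compartments — a left
ventricle (LV) driven by the constitutive laws, a passive left atrium
(LA), and arterial and venous reservoirs — connected in a closed loop by
ideal-diode valves and linear resistances:

    LA --[mitral diode R_mv]--> LV --[aortic diode R_av]--> arterial
    arterial --[R_p]--> venous --[R_vr]--> LA

LV pressure follows from wall stress through a thick-walled-sphere
(Laplace-type) mapping: cavity and outer radii come from the cavity volume
and the (incompressible) wall volume, the midwall fiber stretch is
lambda = r_mid / r_mid,ref with the reference at the unloaded cavity
volume, and

    P_LV = 2 * (sigma_active(t, E_ff) + sigma_passive,ff(lambda))
             * ln(r_out / r_in)    [MPa -> mmHg]

with E_ff = (lambda^2 - 1)/2.  The fiber and sheet directions are treated
as equibiaxially stretched in the wall plane, so the passive fiber stress
is the closed-form biaxial sigma_ff at (lambda, lambda); below lambda = 1
the isotropic matrix term resists compression (elastic recoil producing
diastolic suction) while the tension-only fiber term drops out.  The active
twitch restarts at every cycle onset and feels the current stretch through
the length-dependent calcium sensitivity and relaxation duration, so a
scenario's (L_r, L_0) shapes both ejection and the late-systolic tension
that delays mitral opening.

This surrogate explores organ-level phenotypes *directionally*: it is an
independent design, not a reduction of any particular finite-element
model, and no absolute volume or pressure from it is a calibration target
beyond the baseline landing inside published normal ranges.

Integration is fixed-step explicit Euler; blood volume is conserved to
round-off by construction (each flow leaves one compartment and enters
another).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .active import ActiveParams, active_fiber_stress, activation_phase
from .active import _sensitivity_factor
from .passive import PassiveParams, cauchy_biaxial
from .scenarios import ScenarioSpec, build_scenario_table

__all__ = [
    "SurrogateParams",
    "BeatSeries",
    "IntegrationError",
    "lv_pressure_from_volume",
    "run_cycles",
    "scenario_response_table",
    "MMHG_PER_MPA",
]

MMHG_PER_MPA = 7500.616827

_FOUR_THIRDS_PI = 4.0 * math.pi / 3.0


def _active_stress(
    t: float, E_ff: float, active: ActiveParams, envelope_at_reference: bool
) -> float:
    """Active fiber stress; optionally time the envelope by the reference length.

    With ``envelope_at_reference`` the relaxation duration inside the
    activation phase is evaluated at the unloaded length L_r (E_ff = 0):
    the twitch keeps the isometric timing of its scenario while the
    calcium-sensitivity amplitude still tracks the instantaneous length.
    """
    if not envelope_at_reference:
        return active_fiber_stress(t, E_ff, active)
    factor = _sensitivity_factor(E_ff, active)
    if factor == 0.0:
        return 0.0
    omega = activation_phase(t, 0.0, active)
    return 0.5 * active.T_max * factor * (1.0 - math.cos(omega))


class IntegrationError(RuntimeError):
    """The closed-loop integration produced a non-finite state."""


@dataclass(frozen=True)
class SurrogateParams:
    """Calibrated circulation and geometry constants of the 0D left heart.

    Volumes in mL, pressures in mmHg, resistances in mmHg*s/mL,
    compliances in mL/mmHg, elastance in mmHg/mL, times in s.  The default
    values are the package's frozen calibration: they place the control
    scenario inside published normal ranges for EDV, ESV, SV, LVEF and CO
    at heart rate 60 and are not re-tuned per scenario.
    """

    V_wall: float = 90.0  # LV wall volume
    V_ref: float = 100.0  # unloaded LV cavity volume
    E_la: float = 1.0  # LA elastance
    V_la_ref: float = 0.0  # LA unstressed volume
    C_art: float = 1.5  # arterial compliance
    C_ven: float = 8.0  # venous compliance
    R_mv: float = 0.12  # mitral valve forward resistance
    R_av: float = 0.08  # aortic valve forward resistance
    R_p: float = 1.1  # peripheral resistance
    R_vr: float = 0.05  # venous-return resistance
    V_total: float = 830.0  # total blood volume in the loop
    cycle_length: float = 1.0
    beat_duration: float = 0.5
    V_lv_init: float = 120.0  # initial LV volume at the start of cycle 1
    #: include the compressive isotropic wall response below lambda = 1
    #: (elastic recoil / diastolic suction); if False the passive wall
    #: stress is clipped at zero in compression
    wall_recoil: bool = False
    #: if True, the activation envelope is timed by the unloaded reference
    #: sarcomere length (t_r evaluated at L_r) while the calcium-sensitivity
    #: factor still follows the instantaneous length; if False, both use the
    #: instantaneous length
    envelope_at_reference: bool = True

    def __post_init__(self) -> None:
        for name in (
            "V_wall",
            "V_ref",
            "E_la",
            "C_art",
            "C_ven",
            "R_mv",
            "R_av",
            "R_p",
            "R_vr",
            "V_total",
            "cycle_length",
            "beat_duration",
            "V_lv_init",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.beat_duration > self.cycle_length:
            raise ValueError("beat duration cannot exceed cycle length")


@dataclass
class BeatSeries:
    """Sampled closed-loop state plus per-cycle EDV/ESV summaries."""

    time: np.ndarray
    P_lv: np.ndarray
    P_la: np.ndarray
    P_art: np.ndarray
    P_ven: np.ndarray
    V_lv: np.ndarray
    V_la: np.ndarray
    V_art: np.ndarray
    V_ven: np.ndarray
    per_cycle: pd.DataFrame = field(default_factory=pd.DataFrame)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t_s": self.time,
                "P_lv_mmHg": self.P_lv,
                "P_la_mmHg": self.P_la,
                "P_art_mmHg": self.P_art,
                "P_ven_mmHg": self.P_ven,
                "V_lv_mL": self.V_lv,
                "V_la_mL": self.V_la,
                "V_art_mL": self.V_art,
                "V_ven_mL": self.V_ven,
            }
        )

    def pv_loop(self, cycle: int) -> pd.DataFrame:
        """(V_LV, P_LV) samples of one cycle (1-based index)."""
        t0 = (cycle - 1) * (self.time[-1] / len(self.per_cycle))
        t1 = t0 + self.time[-1] / len(self.per_cycle)
        mask = (self.time >= t0) & (self.time < t1)
        return pd.DataFrame({"V_lv_mL": self.V_lv[mask], "P_lv_mmHg": self.P_lv[mask]})


def _radii(V: float, V_wall: float) -> tuple[float, float, float]:
    r_in = (V / _FOUR_THIRDS_PI) ** (1.0 / 3.0)
    r_out = ((V + V_wall) / _FOUR_THIRDS_PI) ** (1.0 / 3.0)
    return r_in, r_out, 0.5 * (r_in + r_out)


def lv_pressure_from_volume(
    V: float,
    t_in_cycle: float,
    active: ActiveParams,
    passive: PassiveParams | None = None,
    params: SurrogateParams | None = None,
) -> float:
    """LV cavity pressure (mmHg) at volume V (mL) and cycle time t (s)."""
    params = params or SurrogateParams()
    passive = passive or PassiveParams()
    if V <= 0:
        raise ValueError("cavity volume must be positive")
    r_in, r_out, r_mid = _radii(V, params.V_wall)
    _, _, r_mid_ref = _radii(params.V_ref, params.V_wall)
    lam = r_mid / r_mid_ref
    E_ff = 0.5 * (lam * lam - 1.0)
    sigma = _active_stress(t_in_cycle, E_ff, active, params.envelope_at_reference)
    sigma_p = cauchy_biaxial(passive, lam, lam).sigma_ff
    sigma += sigma_p if params.wall_recoil else max(sigma_p, 0.0)
    return 2.0 * sigma * math.log(r_out / r_in) * MMHG_PER_MPA


def run_cycles(
    params: SurrogateParams | None = None,
    scenario: ScenarioSpec | ActiveParams | None = None,
    n_cycles: int = 5,
    dt: float = 1e-4,
    passive: PassiveParams | None = None,
    save_every: int = 10,
) -> BeatSeries:
    """Integrate the closed loop for ``n_cycles`` cycles of length 1 s.

    The loop starts from a common filled state (LV at ``V_lv_init``,
    reservoirs split so arterial pressure starts near 80 mmHg) and the
    activation twitch restarts at each cycle onset, mirroring a repeated
    beat protocol; per-cycle EDV is the LV volume at beat onset and ESV
    the minimum volume within the cycle.

    Raises :class:`IntegrationError` if any pressure becomes non-finite,
    naming the offending cycle.
    """
    params = params or SurrogateParams()
    passive = passive or PassiveParams()
    if isinstance(scenario, ScenarioSpec):
        active = scenario.active_params()
    elif isinstance(scenario, ActiveParams):
        active = scenario
    else:
        active = ActiveParams()
    if n_cycles < 1:
        raise ValueError("need at least one cycle")
    if dt <= 0:
        raise ValueError("dt must be positive")

    sp = params
    # initial distribution: LV filled, arterial reservoir charged to ~80 mmHg,
    # LA at a modest filling pressure, remainder in the venous pool
    V_lv = sp.V_lv_init
    V_art = sp.C_art * 80.0
    V_la = sp.V_la_ref + 8.0 / sp.E_la
    V_ven = sp.V_total - V_lv - V_art - V_la
    if V_ven <= 0:
        raise ValueError("V_total too small for the initial distribution")

    steps_per_cycle = int(round(sp.cycle_length / dt))
    n_steps = steps_per_cycle * n_cycles
    n_saved = n_steps // save_every + 1
    out = {
        k: np.empty(n_saved)
        for k in ("time", "P_lv", "P_la", "P_art", "P_ven", "V_lv", "V_la", "V_art", "V_ven")
    }
    cyc_records = []

    _, _, r_mid_ref = _radii(sp.V_ref, sp.V_wall)
    log_mmhg = 2.0 * MMHG_PER_MPA

    def lv_pressure(V: float, t_c: float) -> float:
        r_in, r_out, r_mid = _radii(V, sp.V_wall)
        lam = r_mid / r_mid_ref
        E_ff = 0.5 * (lam * lam - 1.0)
        sigma = _active_stress(t_c, E_ff, active, sp.envelope_at_reference)
        sigma_p = cauchy_biaxial(passive, lam, lam).sigma_ff
        sigma += sigma_p if sp.wall_recoil else max(sigma_p, 0.0)
        return sigma * log_mmhg * math.log(r_out / r_in)

    i_saved = 0
    for i in range(n_steps + 1):
        t = i * dt
        t_c = (i % steps_per_cycle) * dt
        cycle = i // steps_per_cycle + 1

        P_lv = lv_pressure(V_lv, t_c)
        P_la = sp.E_la * (V_la - sp.V_la_ref)
        P_art = V_art / sp.C_art
        P_ven = V_ven / sp.C_ven

        if i % steps_per_cycle == 0:
            if not all(map(math.isfinite, (P_lv, P_la, P_art, P_ven))):
                raise IntegrationError(
                    f"non-finite pressure at the start of cycle {cycle}"
                )
            if i < n_steps:
                cyc_records.append(
                    {"cycle": cycle, "EDV_mL": V_lv, "ESV_mL": V_lv}
                )

        if cyc_records:
            rec = cyc_records[-1]
            if V_lv < rec["ESV_mL"]:
                rec["ESV_mL"] = V_lv

        if i % save_every == 0 and i_saved < n_saved:
            out["time"][i_saved] = t
            out["P_lv"][i_saved] = P_lv
            out["P_la"][i_saved] = P_la
            out["P_art"][i_saved] = P_art
            out["P_ven"][i_saved] = P_ven
            out["V_lv"][i_saved] = V_lv
            out["V_la"][i_saved] = V_la
            out["V_art"][i_saved] = V_art
            out["V_ven"][i_saved] = V_ven
            i_saved += 1

        if i == n_steps:
            break

        q_mv = max(0.0, P_la - P_lv) / sp.R_mv
        q_av = max(0.0, P_lv - P_art) / sp.R_av
        q_p = (P_art - P_ven) / sp.R_p
        q_vr = (P_ven - P_la) / sp.R_vr

        V_lv += dt * (q_mv - q_av)
        V_art += dt * (q_av - q_p)
        V_ven += dt * (q_p - q_vr)
        V_la += dt * (q_vr - q_mv)

    per_cycle = pd.DataFrame(cyc_records)
    per_cycle["SV_mL"] = per_cycle["EDV_mL"] - per_cycle["ESV_mL"]
    for k in out:
        out[k] = out[k][:i_saved]
    return BeatSeries(
        time=out["time"],
        P_lv=out["P_lv"],
        P_la=out["P_la"],
        P_art=out["P_art"],
        P_ven=out["P_ven"],
        V_lv=out["V_lv"],
        V_la=out["V_la"],
        V_art=out["V_art"],
        V_ven=out["V_ven"],
        per_cycle=per_cycle,
    )


def scenario_response_table(
    params: SurrogateParams | None = None,
    scenario_table: list[ScenarioSpec] | None = None,
    n_cycles: int = 5,
    dt: float = 1e-4,
) -> pd.DataFrame:
    """Final-cycle EDV/ESV per scenario, ready for the metrics stage.

    Columns: id, series, EDV_mL, ESV_mL plus conservation and periodicity
    diagnostics (worst per-cycle relative drift of total blood volume and
    the relative EDV change from the penultimate to the final cycle).
    """
    params = params or SurrogateParams()
    scenario_table = (
        scenario_table if scenario_table is not None else build_scenario_table()
    )
    records = []
    for spec in scenario_table:
        series = run_cycles(params, spec, n_cycles=n_cycles, dt=dt)
        total = series.V_lv + series.V_la + series.V_art + series.V_ven
        conservation = float(np.max(np.abs(total - params.V_total)) / params.V_total)
        pc = series.per_cycle
        last = pc.iloc[-1]
        edv_drift = (
            abs(last.EDV_mL - pc.iloc[-2].EDV_mL) / pc.iloc[-2].EDV_mL
            if len(pc) > 1
            else float("nan")
        )
        records.append(
            {
                "id": spec.id,
                "series": spec.series,
                "EDV_mL": float(last.EDV_mL),
                "ESV_mL": float(last.ESV_mL),
                "volume_drift": conservation,
                "edv_periodicity": float(edv_drift),
            }
        )
    return pd.DataFrame(records)
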