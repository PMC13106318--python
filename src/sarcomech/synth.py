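"""Synthetic-data generators and parameter-recovery utilities.

Every analysis stage can be exercised without external data: the
generators emulate (a) noisy isometric twitch peak-stress measurements
under the active law, (b) scenario-by-metric tables with approximately
linear parameter dependence plus Gaussian noise, and (c) regional
average-peak-strain (APS) records with scenario-dependent shifts around
reference means/SDs.  A closed-form inversion recovers the sarcomere
length difference from peak-stress measurements.

All randomness flows through ``numpy.random.default_rng`` with an
explicit integer seed; there is no hidden global state.  Noise is
Gaussian throughout (truncation policies are stated per generator).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .active import ActiveParams, peak_isometric_stress
from .metrics import cardiac_metrics
from .scenarios import SERIES_PARAMETER, ScenarioSpec, build_scenario_table

__all__ = [
    "SynthConfig",
    "synth_metric_table",
    "synth_twitch_measurements",
    "recover_sld",
    "synth_aps_records",
    "APS_REGIONS",
]

_UM_TO_MM = 1e-3

#: regional APS layout: direction -> region list
APS_REGIONS = {
    "radial": ["basal", "equatorial", "apical"],
    "circumferential": ["basal", "equatorial", "apical"],
    "longitudinal": ["septal", "anterior", "lateral", "posterior"],
}


@dataclass(frozen=True)
class SynthConfig:
    """Generator settings: seed, per-quantity noise SDs, replicate count."""

    seed: int = 0
    noise_sd: float = 0.0
    n_replicates: int = 1
    effect_slopes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise SD must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")


def synth_metric_table(
    true_slopes: dict[str, float],
    baseline_metrics: dict[str, float],
    scenario_table: list[ScenarioSpec] | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Generate an EDV/ESV table with linear parameter dependence plus noise.

    EDV and ESV are baseline + slope * (parameter - baseline parameter) +
    Gaussian noise, where the parameter is the series' varied length (the
    control row gets no offset); SV, LVEF and CO are derived exactly.
    ``true_slopes`` maps "EDV_mL"/"ESV_mL" to mL-per-um slopes.  Draws
    producing non-positive volumes or ESV >= EDV raise, since they indicate
    a noise level incompatible with the generative model.
    """
    scenario_table = (
        scenario_table if scenario_table is not None else build_scenario_table()
    )
    rng = np.random.default_rng(seed)
    base = {s.id: s for s in scenario_table}["S00"]
    records = []
    for spec in scenario_table:
        parameter = SERIES_PARAMETER[spec.series]
        dp = getattr(spec, {"L_r": "L_r", "L_0": "L_0"}[parameter]) - getattr(
            base, {"L_r": "L_r", "L_0": "L_0"}[parameter]
        )
        edv = baseline_metrics["EDV_mL"] + true_slopes.get("EDV_mL", 0.0) * dp
        esv = baseline_metrics["ESV_mL"] + true_slopes.get("ESV_mL", 0.0) * dp
        if noise_sd > 0:
            edv += rng.normal(0.0, noise_sd)
            esv += rng.normal(0.0, noise_sd)
        if not (edv > esv > 0):
            raise ValueError(
                f"{spec.id}: generated volumes EDV={edv:.2f}, ESV={esv:.2f} "
                "are non-physical; lower the noise SD"
            )
        m = cardiac_metrics(edv, esv)
        records.append(
            {
                "id": spec.id,
                "series": spec.series,
                "EDV_mL": edv,
                "ESV_mL": esv,
                "SV_mL": m.SV,
                "LVEF_pct": m.LVEF,
                "CO_Lmin": m.CO,
            }
        )
    return pd.DataFrame(records)


def synth_twitch_measurements(
    params: ActiveParams | None = None,
    noise_sd: float = 0.0,
    n: int = 1,
    seed: int = 0,
) -> np.ndarray:
    """Noisy isometric peak-stress observations (MPa), truncated at zero."""
    if n < 1:
        raise ValueError("need at least one measurement")
    params = params or ActiveParams()
    peak = peak_isometric_stress(params)
    rng = np.random.default_rng(seed)
    draws = peak + rng.normal(0.0, noise_sd, size=n) if noise_sd > 0 else np.full(n, peak)
    return np.maximum(draws, 0.0)


def recover_sld(
    peak_measurements,
    params: ActiveParams | None = None,
) -> float:
    """Estimate the sarcomere length difference (um) from peak stresses.

    Inverts the closed-form peak, sigma = T_max Ca0^2/(Ca0^2 + ECa50^2)
    with ECa50 = Ca0_max / sqrt(exp(B*SLD) - 1):

        SLD = (1/B) ln(1 + Ca0_max^2 (T_max/sigma - 1)^{-1} ... )

    solved per measurement and averaged; exact for noiseless input and
    consistent (error shrinking with n) under zero-mean noise.
    Measurements outside (0, T_max) are rejected.
    """
    params = params or ActiveParams()
    sigma = np.asarray(peak_measurements, dtype=float)
    if sigma.size == 0:
        raise ValueError("need at least one measurement")
    if np.any(sigma <= 0) or np.any(sigma >= params.T_max):
        raise ValueError("peak stresses must lie strictly within (0, T_max)")
    # sigma/T_max = Ca0^2/(Ca0^2 + ECa50^2)  =>  ECa50^2 = Ca0^2 (T_max/sigma - 1)
    eca50_sq = params.Ca0**2 * (params.T_max / sigma - 1.0)
    # ECa50^2 = Ca0_max^2 / (exp(B*SLD) - 1)  =>  SLD = ln(1 + Ca0_max^2/ECa50^2)/B
    sld_mm = np.log1p(params.Ca0_max**2 / eca50_sq) / params.B
    return float(np.mean(sld_mm) / _UM_TO_MM)


def synth_aps_records(
    region_list: dict[str, list[str]] | None = None,
    reference_ranges: pd.DataFrame | None = None,
    scenario_shifts: dict[str, float] | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    scenario_table: list[ScenarioSpec] | None = None,
) -> pd.DataFrame:
    """Regional average-peak-strain records per scenario.

    Each (direction, region) has a reference mean and SD; a scenario's APS
    is mean + shift(scenario) * SD + Gaussian noise.  ``reference_ranges``
    carries columns (direction, region, mu, sigma); when omitted, a
    synthetic reference set is built with plausible magnitudes (radial
    thickening positive, circumferential/longitudinal shortening negative).
    ``scenario_shifts`` maps scenario id to a shift in SD units (default 0).
    """
    region_list = region_list if region_list is not None else APS_REGIONS
    scenario_table = (
        scenario_table if scenario_table is not None else build_scenario_table()
    )
    scenario_shifts = scenario_shifts or {}
    if reference_ranges is None:
        reference_ranges = default_aps_reference(region_list)
    for col in ("direction", "region", "mu", "sigma"):
        if col not in reference_ranges.columns:
            raise ValueError(f"reference table lacks column {col!r}")
    rng = np.random.default_rng(seed)
    records = []
    for spec in scenario_table:
        shift = scenario_shifts.get(spec.id, 0.0)
        for row in reference_ranges.itertuples():
            value = row.mu + shift * row.sigma
            if noise_sd > 0:
                value += rng.normal(0.0, noise_sd)
            records.append(
                {
                    "id": spec.id,
                    "direction": row.direction,
                    "region": row.region,
                    "aps": value,
                    "mu": row.mu,
                    "sigma": row.sigma,
                }
            )
    return pd.DataFrame(records)


def default_aps_reference(
    region_list: dict[str, list[str]] | None = None,
) -> pd.DataFrame:
    """A synthetic APS reference set (means and SDs of nominal strain).

    These are stand-in values with physiologically plausible magnitudes
    and signs, intended for exercising the deviation-score pipeline; they
    are not measurements.
    """
    region_list = region_list if region_list is not None else APS_REGIONS
    base = {"radial": (0.35, 0.08), "circumferential": (-0.19, 0.03), "longitudinal": (-0.15, 0.03)}
    rows = []
    for direction, regions in region_list.items():
        mu, sd = base[direction]
        for i, region in enumerate(regions):
            rows.append(
                {
                    "direction": direction,
                    "region": region,
                    # mild regional gradient so regions are distinguishable
                    "mu": mu * (1.0 + 0.05 * i),
                    "sigma": sd,
                }
            )
    return pd.DataFrame(rows)
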