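"""Cardiac-function metrics, sensitivity analysis, strain conversion, deviation scores.

This module holds the quantitative analytics layer: derived pump-function
metrics (SV, LVEF, CO) from end-diastolic and end-systolic volumes, percent
changes relative to a control case, ordinary-least-squares parameter
sensitivities with the normalised sensitivity

    S* = (p_base / Y_base) * dY/dp,

piecewise (segment-wise) sensitivities around the control, Green–Lagrange
to nominal strain conversion, and out-of-range deviation scores used to
rank scenarios against published normal values.

The packaged reference metric table (13 scenarios of a sarcomere-length
study, with published normal ranges) ships with the module and is the
canonical input for the sensitivity and deviation stages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from .scenarios import SERIES_PARAMETER, ScenarioSpec, build_scenario_table

__all__ = [
    "CardiacMetrics",
    "NormalRange",
    "SensitivityResult",
    "DeviationScore",
    "StrainValue",
    "METRIC_COLUMNS",
    "cardiac_metrics",
    "percent_change",
    "round_half_away",
    "recompute_metric_table",
    "percent_change_table",
    "ols_sensitivity",
    "series_sensitivity_table",
    "PIECEWISE_SEGMENTS",
    "piecewise_sensitivity",
    "aps_deviation",
    "range_deviation",
    "deviation_table",
    "rank_scenarios",
    "nominal_strain",
    "green_to_nominal",
    "load_printed_metric_table",
    "load_normal_ranges",
]

#: metric columns in canonical order (volumes mL, LVEF %, CO L/min)
METRIC_COLUMNS = ["EDV_mL", "ESV_mL", "SV_mL", "LVEF_pct", "CO_Lmin"]


# ---------------------------------------------------------------------------
# basic metric arithmetic


@dataclass(frozen=True)
class CardiacMetrics:
    """Global pump-function metrics of one scenario."""

    EDV: float
    ESV: float
    SV: float
    LVEF: float
    CO: float
    HR: float = 60.0


def cardiac_metrics(EDV: float, ESV: float, HR: float = 60.0) -> CardiacMetrics:
    """Derive SV (mL), LVEF (%), and CO (L/min) from EDV/ESV (mL) and HR (1/min)."""
    if not (EDV > ESV >= 0):
        raise ValueError("need EDV > ESV >= 0")
    if HR <= 0:
        raise ValueError("heart rate must be positive")
    SV = EDV - ESV
    return CardiacMetrics(
        EDV=EDV, ESV=ESV, SV=SV, LVEF=100.0 * SV / EDV, CO=SV * HR / 1000.0, HR=HR
    )


def percent_change(value: float, baseline: float) -> float:
    """Percent change of ``value`` relative to ``baseline``."""
    if baseline == 0:
        raise ValueError("baseline must be nonzero")
    return 100.0 * (value - baseline) / baseline


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (the convention of the reference tables)."""
    scale = 10.0**ndigits
    return math.floor(abs(x) * scale + 0.5) / scale * math.copysign(1.0, x)


def recompute_metric_table(
    table: pd.DataFrame, HR: float = 60.0, decimals: int | None = 3
) -> pd.DataFrame:
    """Recompute SV, LVEF, and CO from the EDV/ESV columns of a metric table.

    ``decimals`` rounds the derived columns to the table's display precision
    (pass ``None`` to keep full precision).  Input columns other than
    ``id``, ``EDV_mL``, ``ESV_mL`` are ignored.
    """
    out = table[["id", "EDV_mL", "ESV_mL"]].copy()
    derived = [cardiac_metrics(r.EDV_mL, r.ESV_mL, HR) for r in out.itertuples()]
    out["SV_mL"] = [m.SV for m in derived]
    out["LVEF_pct"] = [m.LVEF for m in derived]
    out["CO_Lmin"] = [m.CO for m in derived]
    if decimals is not None:
        for col in ("SV_mL", "LVEF_pct", "CO_Lmin"):
            out[col] = [round_half_away(v, decimals) for v in out[col]]
    return out


def percent_change_table(
    table: pd.DataFrame, baseline_id: str = "S00", decimals: int = 2
) -> pd.DataFrame:
    """Percent change of every metric column relative to the baseline row.

    Percent changes are computed from the table values as displayed (i.e.
    after any rounding applied upstream) and reported at ``decimals``
    places, rounding half away from zero — the convention under which the
    reference table's CO percent column is self-consistent.
    """
    base = table.loc[table["id"] == baseline_id]
    if base.empty:
        raise ValueError(f"baseline scenario {baseline_id!r} not in table")
    base = base.iloc[0]
    out = table[["id"]].copy()
    for col in METRIC_COLUMNS:
        out[col + "_pctchg"] = [
            round_half_away(percent_change(v, base[col]), decimals)
            for v in table[col]
        ]
    return out[out["id"] != baseline_id].reset_index(drop=True)


# ---------------------------------------------------------------------------
# sensitivity analysis


@dataclass(frozen=True)
class SensitivityResult:
    """OLS slope with normalised sensitivity for one segment and metric."""

    segment: str
    parameter: str
    metric: str
    slope: float
    p_base: float
    Y_base: float
    S_star: float
    r_squared: float

    def __post_init__(self) -> None:
        if not (-1e-12 <= self.r_squared <= 1.0 + 1e-12):
            raise ValueError("R^2 must lie in [0, 1]")


def ols_sensitivity(
    p_values,
    Y_values,
    p_base: float,
    Y_base: float,
    segment: str = "",
    parameter: str = "",
    metric: str = "",
) -> SensitivityResult:
    """Ordinary-least-squares slope dY/dp with S* = (p_base/Y_base) dY/dp.

    R^2 of a zero-variance response is defined as 0 (never NaN).
    """
    p = np.asarray(p_values, dtype=float)
    Y = np.asarray(Y_values, dtype=float)
    if p.size < 3:
        raise ValueError("need at least three points for a sensitivity fit")
    if np.ptp(p) == 0:
        raise ValueError("parameter values are degenerate (no spread)")
    if np.ptp(Y) == 0:
        slope, r2 = 0.0, 0.0
    else:
        fit = stats.linregress(p, Y)
        slope, r2 = float(fit.slope), float(fit.rvalue) ** 2
    return SensitivityResult(
        segment=segment,
        parameter=parameter,
        metric=metric,
        slope=slope,
        p_base=p_base,
        Y_base=Y_base,
        S_star=(p_base / Y_base) * slope,
        r_squared=r2,
    )


def _series_points(
    metric_table: pd.DataFrame,
    scenario_table: list[ScenarioSpec],
    ids: list[str],
    parameter: str,
):
    by_id = {s.id: s for s in scenario_table}
    missing = [i for i in ids if i not in set(metric_table["id"])]
    if missing:
        raise ValueError(f"metric table is missing scenario(s): {missing}")
    attr = {"L_r": "L_r", "L_0": "L_0"}[parameter]
    p = [getattr(by_id[i], attr) for i in ids]
    rows = metric_table.set_index("id").loc[ids]
    return np.array(p), rows


def series_sensitivity_table(
    metric_table: pd.DataFrame,
    scenario_table: list[ScenarioSpec] | None = None,
    baseline_id: str = "S00",
) -> pd.DataFrame:
    """Global five-point sensitivities per series and metric.

    For each series the five member scenarios are regressed against the
    series' varied parameter (L_r for the S0 and diagonal S2 series, L_0
    for the S1 series), with the baseline taken from the control row.
    """
    scenario_table = (
        scenario_table if scenario_table is not None else build_scenario_table()
    )
    by_id = {s.id: s for s in scenario_table}
    series_ids = {
        "S0": ["S01", "S02", "S00", "S03", "S04"],
        "S1": ["S11", "S12", "S00", "S13", "S14"],
        "S2": ["S21", "S22", "S00", "S23", "S24"],
    }
    base_row = metric_table.set_index("id").loc[baseline_id]
    records = []
    for series, ids in series_ids.items():
        parameter = SERIES_PARAMETER[series]
        p, rows = _series_points(metric_table, scenario_table, ids, parameter)
        p_base = getattr(by_id[baseline_id], {"L_r": "L_r", "L_0": "L_0"}[parameter])
        for metric in METRIC_COLUMNS:
            res = ols_sensitivity(
                p,
                rows[metric].to_numpy(),
                p_base,
                float(base_row[metric]),
                segment=series,
                parameter=parameter,
                metric=metric,
            )
            records.append(
                {
                    "series": series,
                    "parameter": parameter,
                    "metric": metric,
                    "slope": res.slope,
                    "S_star": res.S_star,
                    "R2": res.r_squared,
                }
            )
    return pd.DataFrame(records)


#: piecewise segments around the control: (label, member ids, regressor)
PIECEWISE_SEGMENTS = (
    ("S11-S12-S00", ["S11", "S12", "S00"], "L_0"),
    ("S00-S13-S14", ["S00", "S13", "S14"], "L_0"),
    ("S21-S22-S00", ["S21", "S22", "S00"], "L_r"),
    ("S00-S23-S24", ["S00", "S23", "S24"], "L_r"),
)


def piecewise_sensitivity(
    metric_table: pd.DataFrame,
    scenario_table: list[ScenarioSpec] | None = None,
    segments=PIECEWISE_SEGMENTS,
    baseline_id: str = "S00",
) -> pd.DataFrame:
    """Three-point sensitivities on the below/above-baseline segments.

    The diagonal (constant-SLD) segments are regressed against L_r along
    the path where L_r and L_0 increase together.
    """
    scenario_table = (
        scenario_table if scenario_table is not None else build_scenario_table()
    )
    by_id = {s.id: s for s in scenario_table}
    base_row = metric_table.set_index("id").loc[baseline_id]
    records = []
    for label, ids, parameter in segments:
        if len(ids) < 3:
            raise ValueError(f"segment {label}: need three scenarios")
        p, rows = _series_points(metric_table, scenario_table, ids, parameter)
        p_base = getattr(by_id[baseline_id], {"L_r": "L_r", "L_0": "L_0"}[parameter])
        for metric in METRIC_COLUMNS:
            res = ols_sensitivity(
                p,
                rows[metric].to_numpy(),
                p_base,
                float(base_row[metric]),
                segment=label,
                parameter=parameter,
                metric=metric,
            )
            records.append(
                {
                    "segment": label,
                    "parameter": parameter,
                    "metric": metric,
                    "slope": res.slope,
                    "S_star": res.S_star,
                    "R2": res.r_squared,
                }
            )
    return pd.DataFrame(records)


# ---------------------------------------------------------------------------
# deviation scoring


@dataclass(frozen=True)
class NormalRange:
    """Reference band for one metric: either [lower, upper] or mean +/- SD."""

    metric: str
    lower: float | None = None
    upper: float | None = None
    mu: float | None = None
    sigma: float | None = None

    def __post_init__(self) -> None:
        if self.lower is not None and self.upper is not None:
            if not self.upper > self.lower:
                raise ValueError("upper bound must exceed lower bound")
        if self.sigma is not None and self.sigma <= 0:
            raise ValueError("sigma must be positive")


@dataclass(frozen=True)
class DeviationScore:
    scenario_id: str
    per_metric: dict

    @property
    def total(self) -> float:
        return float(sum(self.per_metric.values()))


def aps_deviation(x: float, mu: float, sigma: float) -> float:
    """Outside-normal score against a mean +/- SD band: max(0, |x - mu|/sigma - 1)."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    return max(0.0, abs(x - mu) / sigma - 1.0)


def range_deviation(x: float, lower: float, upper: float) -> float:
    """Outside-normal score against [lower, upper], normalised by the width."""
    if upper <= lower:
        raise ValueError("upper bound must exceed lower bound")
    width = upper - lower
    return max(0.0, (lower - x) / width) + max(0.0, (x - upper) / width)


def deviation_table(
    metric_table: pd.DataFrame, ranges: dict[str, NormalRange] | None = None
) -> pd.DataFrame:
    """Per-metric and total out-of-range scores for every scenario row."""
    ranges = ranges if ranges is not None else load_normal_ranges()
    records = []
    for row in metric_table.itertuples():
        scores = {}
        for metric, nr in ranges.items():
            x = getattr(row, metric)
            scores[metric + "_score"] = range_deviation(x, nr.lower, nr.upper)
        total = sum(scores.values())
        records.append({"id": row.id, **scores, "total_score": total})
    return pd.DataFrame(records)


def rank_scenarios(score_table: pd.DataFrame) -> list[str]:
    """Scenario ids, most deviating first; ties broken lexicographically by id."""
    df = score_table.sort_values(
        ["total_score", "id"], ascending=[False, True], kind="mergesort"
    )
    return list(df["id"])


# ---------------------------------------------------------------------------
# strain conversion


@dataclass(frozen=True)
class StrainValue:
    """One deformation point in its three strain measures.

    stretch lambda, Green-Lagrange strain E = (lambda^2 - 1)/2, and nominal
    strain e = lambda - 1; the length measure l is optional context (the
    direction-specific length the strain was derived from).
    """

    stretch: float
    E: float
    e: float
    l: float | None = None

    @classmethod
    def from_stretch(cls, lam: float, l: float | None = None) -> "StrainValue":
        return cls(stretch=lam, E=0.5 * (lam * lam - 1.0), e=nominal_strain(lam), l=l)

    def __post_init__(self) -> None:
        if self.stretch <= 0:
            raise ValueError("stretch must be positive")
        if abs(self.e - (self.stretch - 1.0)) > 1e-9:
            raise ValueError("nominal strain inconsistent with stretch")
        if abs(self.E - 0.5 * (self.stretch**2 - 1.0)) > 1e-9:
            raise ValueError("Green-Lagrange strain inconsistent with stretch")


def nominal_strain(lam: float) -> float:
    """Nominal (engineering) strain from stretch: e = lambda - 1."""
    if lam <= 0:
        raise ValueError("stretch must be positive")
    return lam - 1.0


def green_to_nominal(E: float) -> float:
    """Nominal strain from a Green–Lagrange component: e = sqrt(2E + 1) - 1."""
    radicand = 2.0 * E + 1.0
    if radicand <= 0:
        raise ValueError("2E + 1 must be positive")
    return math.sqrt(radicand) - 1.0


# ---------------------------------------------------------------------------
# packaged reference data


def _data_path(name: str):
    return resources.files("sarcomech.data").joinpath(name)


def load_printed_metric_table() -> pd.DataFrame:
    """The packaged 13-scenario reference metric table (absolute values).

    Columns: id, series, EDV_mL, ESV_mL, SV_mL, LVEF_pct, CO_Lmin plus the
    published percent-change columns (blank for the control row).
    """
    with resources.as_file(_data_path("cardiac_metrics_printed.csv")) as p:
        return pd.read_csv(p)


def load_normal_ranges() -> dict[str, NormalRange]:
    """Published normal ranges for EDV, ESV, SV, LVEF, and CO."""
    with resources.as_file(_data_path("normal_ranges.csv")) as p:
        df = pd.read_csv(p)
    return {
        r.metric: NormalRange(metric=r.metric, lower=float(r.lower), upper=float(r.upper))
        for r in df.itertuples()
    }
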