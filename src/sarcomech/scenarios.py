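"""The 13-scenario sarcomere-length design and tissue-level sweeps.

Three series perturb the reference length L_r and the zero-tension length
L_0 around the control pair (1.85, 1.58) um:

* S0 series (S01, S02, S00, S03, S04): L_r varies over 1.75..1.95 um in
  0.05 um steps with L_0 fixed at 1.58 um.
* S1 series (S11, S12, S00, S13, S14): L_0 varies over 1.48..1.68 um with
  L_r fixed at 1.85 um.
* S2 series (S21, S22, S00, S23, S24): both vary together along the
  diagonal so the sarcomere length difference SLD = L_r - L_0 stays at
  0.27 um.

The control S00 is shared by all three series and appears once in the
table, carrying the series tag "S0".
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import pandas as pd

from .active import ActiveParams, duration_of_contraction, peak_isometric_stress

__all__ = [
    "ScenarioSpec",
    "TissueSummary",
    "build_scenario_table",
    "scenario_frame",
    "series_members",
    "tissue_sweep",
    "SERIES_PARAMETER",
]

#: regressor used when a series is analysed against a single parameter:
#: L_r for the S0 series, L_0 for the S1 series, and L_r along the diagonal
#: path for the constant-SLD S2 series.
SERIES_PARAMETER = {"S0": "L_r", "S1": "L_0", "S2": "L_r"}


@dataclass(frozen=True)
class ScenarioSpec:
    id: str
    series: str
    L_r: float
    L_0: float

    @property
    def sld(self) -> float:
        return self.L_r - self.L_0

    def __post_init__(self) -> None:
        if self.sld <= 0:
            raise ValueError(f"{self.id}: SLD = L_r - L_0 must be positive")

    def active_params(self, defaults: ActiveParams | None = None) -> ActiveParams:
        base = defaults or ActiveParams()
        return replace(base, L_r=self.L_r, L_0=self.L_0)


@dataclass(frozen=True)
class TissueSummary:
    scenario_id: str
    peak_stress: float
    doc: float

    def __post_init__(self) -> None:
        if not self.peak_stress > 0:
            raise ValueError("peak stress must be positive")
        if not self.doc > 0:
            raise ValueError("duration of contraction must be positive")


def build_scenario_table() -> list[ScenarioSpec]:
    """The 13 scenarios; S00 appears exactly once (series tag S0)."""
    table = [ScenarioSpec("S00", "S0", 1.85, 1.58)]
    lr_values = {"S01": 1.75, "S02": 1.80, "S03": 1.90, "S04": 1.95}
    for sid, lr in lr_values.items():
        table.append(ScenarioSpec(sid, "S0", lr, 1.58))
    l0_values = {"S11": 1.48, "S12": 1.53, "S13": 1.63, "S14": 1.68}
    for sid, l0 in l0_values.items():
        table.append(ScenarioSpec(sid, "S1", 1.85, l0))
    diag = {"S21": 1.75, "S22": 1.80, "S23": 1.90, "S24": 1.95}
    for sid, lr in diag.items():
        table.append(ScenarioSpec(sid, "S2", lr, lr - 0.27))
    return table


def scenario_frame(table: list[ScenarioSpec] | None = None) -> pd.DataFrame:
    """Scenario table as a DataFrame (id, series, Lr_um, L0_um, SLD_um)."""
    table = table if table is not None else build_scenario_table()
    return pd.DataFrame(
        {
            "id": [s.id for s in table],
            "series": [s.series for s in table],
            "Lr_um": [s.L_r for s in table],
            "L0_um": [s.L_0 for s in table],
            "SLD_um": [s.sld for s in table],
        }
    )


def series_members(
    series: str, table: list[ScenarioSpec] | None = None
) -> list[ScenarioSpec]:
    """Members of one series in increasing order of its varied parameter.

    The shared control S00 is aliased into every series.
    """
    table = table if table is not None else build_scenario_table()
    by_id = {s.id: s for s in table}
    members = [s for s in table if s.series == series and s.id != "S00"]
    control = by_id["S00"]
    if series != "S0":
        control = ScenarioSpec("S00", series, control.L_r, control.L_0)
    members.append(control)
    key = SERIES_PARAMETER[series]
    members.sort(key=lambda s: getattr(s, key))
    return members


def tissue_sweep(
    scenario_table: list[ScenarioSpec] | None = None,
    active_defaults: ActiveParams | None = None,
) -> list[TissueSummary]:
    """Peak isometric stress and duration of contraction per scenario.

    All active parameters other than (L_r, L_0) are held at the defaults.
    """
    scenario_table = (
        scenario_table if scenario_table is not None else build_scenario_table()
    )
    out = []
    for spec in scenario_table:
        params = spec.active_params(active_defaults)
        out.append(
            TissueSummary(
                scenario_id=spec.id,
                peak_stress=peak_isometric_stress(params),
                doc=duration_of_contraction(params),
            )
        )
    return out
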