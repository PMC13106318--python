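"""Unit-cube verification: passive biaxial closed forms and the isometric twitch.

Two benchmarks mirror how one would verify a constitutive implementation on
a single homogeneously deformed element:

* the passive closed-form Cauchy stresses are compared against a
  finite-difference energy oracle at prescribed biaxial stretches; and
* the active law is exercised as an isometric twitch (all strain held at
  zero) and its sampled peak and return-to-zero time are checked against
  the closed-form peak stress and duration of contraction.

Because the deformation is homogeneous, the point-wise constitutive
response *is* the element response, so no FEM solve is required.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .active import (
    ActiveParams,
    TwitchTrace,
    active_fiber_stress,
    duration_of_contraction,
)
from .passive import PassiveParams, cauchy_biaxial, numeric_stress_oracle

__all__ = [
    "VerificationReport",
    "passive_biaxial_report",
    "isometric_twitch",
    "DEFAULT_STRETCHES",
]

DEFAULT_STRETCHES = (1.10, 1.20, 1.30)

#: default pass tolerance: relative error, with an absolute floor for
#: near-zero stresses
REL_TOL = 1e-5
ABS_FLOOR = 1e-9


@dataclass
class VerificationReport:
    """Tabular comparison of analytic vs numeric values with PASS/FAIL status."""

    rows: pd.DataFrame = field(default_factory=pd.DataFrame)
    rel_tol: float = REL_TOL
    abs_floor: float = ABS_FLOOR

    @property
    def passed(self) -> bool:
        if self.rows.empty:
            return True
        ok = (self.rows["abs_error"] <= self.abs_floor) | (
            self.rows["rel_error"] <= self.rel_tol
        )
        return bool(ok.all())

    @property
    def failing_rows(self) -> pd.DataFrame:
        if self.rows.empty:
            return self.rows
        ok = (self.rows["abs_error"] <= self.abs_floor) | (
            self.rows["rel_error"] <= self.rel_tol
        )
        return self.rows[~ok]

    def to_csv(self, path) -> None:
        self.rows.to_csv(path, index=False, float_format="%.12g")


def _compare_row(label, lf, ls, component, analytic, numeric):
    abs_err = abs(analytic - numeric)
    denom = max(abs(analytic), abs(numeric))
    rel_err = abs_err / denom if denom > 0 else 0.0
    return {
        "case": label,
        "lambda_f": lf,
        "lambda_s": ls,
        "component": component,
        "analytic_MPa": analytic,
        "numeric_MPa": numeric,
        "abs_error": abs_err,
        "rel_error": rel_err,
    }


def passive_biaxial_report(
    params: PassiveParams | None = None,
    stretch_list=DEFAULT_STRETCHES,
    rel_tol: float = REL_TOL,
) -> VerificationReport:
    """Compare closed-form biaxial stresses with the energy-difference oracle.

    For each stretch, both an equibiaxial case (lambda, lambda) and a
    fiber-only case (lambda, 1.0) are evaluated for sigma_ff and sigma_ss.
    """
    params = params or PassiveParams()
    records = []
    for s in stretch_list:
        for label, lf, ls in (
            (f"equibiaxial_{s:g}", s, s),
            (f"fiber_only_{s:g}", s, 1.0),
        ):
            ana = cauchy_biaxial(params, lf, ls)
            num = numeric_stress_oracle(params, lf, ls)
            records.append(
                _compare_row(label, lf, ls, "sigma_ff", ana.sigma_ff, num.sigma_ff)
            )
            records.append(
                _compare_row(label, lf, ls, "sigma_ss", ana.sigma_ss, num.sigma_ss)
            )
    return VerificationReport(rows=pd.DataFrame(records), rel_tol=rel_tol)


def isometric_twitch(
    params: ActiveParams | None = None,
    t_end: float = 0.7,
    dt: float = 1e-4,
) -> TwitchTrace:
    """Sample the active stress of an isometric twitch (E_ff held at 0).

    The summary fields report the sampled peak, its time, and the first time
    after the peak at which the stress has returned to zero (the duration of
    contraction).  A window shorter than the analytic duration truncates the
    reported value and emits a warning.
    """
    params = params or ActiveParams()
    if dt <= 0:
        raise ValueError("dt must be positive")
    doc_analytic = duration_of_contraction(params)
    if t_end < doc_analytic:
        warnings.warn(
            f"t_end = {t_end} s is shorter than the duration of contraction "
            f"({doc_analytic:.4f} s); the reported duration is truncated",
            stacklevel=2,
        )
    times = np.arange(0.0, t_end + 0.5 * dt, dt)
    stresses = np.array(
        [active_fiber_stress(t, 0.0, params) for t in times]
    )
    i_peak = int(np.argmax(stresses))
    after_peak = np.nonzero((stresses == 0.0) & (times > times[i_peak]))[0]
    doc = float(times[after_peak[0]]) if after_peak.size else float(times[-1])
    return TwitchTrace(
        times=times,
        stresses=stresses,
        peak_stress=float(stresses[i_peak]),
        peak_time=float(times[i_peak]),
        duration_of_contraction=doc,
    )
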