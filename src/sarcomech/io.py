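"""Shared readers/writers and configuration handling.

CSV files are UTF-8 with '.' decimal separators; Unicode minus signs
(U+2212), which appear in typeset tables, are normalised to ASCII on
read.  Parameter sets live in a flat, commented key-value document with
one section per parameter block; the packaged default file mirrors the
constitutive parameter sets and the frozen surrogate calibration.
"""

from __future__ import annotations

import configparser
import io as _io
from dataclasses import fields
from importlib import resources
from pathlib import Path

import pandas as pd

from .active import ActiveParams
from .metrics import cardiac_metrics, round_half_away
from .passive import PassiveParams
from .surrogate import SurrogateParams

__all__ = [
    "read_metric_table",
    "write_table",
    "load_config",
    "default_config_path",
    "MetricTableError",
]

_MINUS = "−"

#: tolerance when cross-checking provided derived columns against EDV/ESV
DERIVED_TOL = 1e-3


class MetricTableError(ValueError):
    """A metric table failed validation; the message names the cell."""


def _normalise_minus(text: str) -> str:
    return text.replace(_MINUS, "-")


def read_metric_table(path) -> pd.DataFrame:
    """Read a metric-table CSV with header id, EDV_mL, ESV_mL[, derived...].

    Derived columns (SV_mL, LVEF_pct, CO_Lmin) are recomputed from EDV and
    ESV; when the file also provides them, each provided value is
    cross-checked against the recomputed one at a 0.001 tolerance and a
    :class:`MetricTableError` names any inconsistent cell.
    """
    raw = Path(path).read_text(encoding="utf-8")
    if not raw.strip():
        raise MetricTableError(f"{path}: empty metric table")
    df = pd.read_csv(_io.StringIO(_normalise_minus(raw)))
    for col in ("id", "EDV_mL", "ESV_mL"):
        if col not in df.columns:
            raise MetricTableError(f"{path}: missing required column {col!r}")
    derived = {
        "SV_mL": lambda m: m.SV,
        "LVEF_pct": lambda m: m.LVEF,
        "CO_Lmin": lambda m: m.CO,
    }
    out = df.copy()
    for row in df.itertuples():
        m = cardiac_metrics(row.EDV_mL, row.ESV_mL)
        for col, get in derived.items():
            value = get(m)
            if col in df.columns and pd.notna(getattr(row, col)):
                provided = float(getattr(row, col))
                # printed tables round to 3 decimals: compare at that precision
                if abs(round_half_away(value, 3) - provided) > DERIVED_TOL:
                    raise MetricTableError(
                        f"{path}: row {row.id}, column {col}: provided "
                        f"{provided} inconsistent with EDV-ESV ({value:.3f})"
                    )
            out.loc[row.Index, col] = value
    return out


def write_table(df: pd.DataFrame, path) -> None:
    """Write a table as UTF-8 CSV at full precision (lossless round-trip)."""
    df.to_csv(path, index=False, float_format="%.17g")


def default_config_path():
    return resources.files("sarcomech.data").joinpath("default_params.cfg")


def _build(cls, section, name):
    known = {f.name: f.type for f in fields(cls)}
    kwargs = {}
    for key, value in section.items():
        if key not in known:
            raise ValueError(f"unknown key {key!r} in section [{name}]")
        kwargs[key] = (
            value.strip().lower() in ("1", "true", "yes")
            if "bool" in str(known[key])
            else float(value)
        )
    return cls(**kwargs)


def load_config(path=None):
    """Load (PassiveParams, ActiveParams, SurrogateParams) from a config file.

    Unknown keys are rejected.  Sections may be omitted; missing sections
    fall back to the packaged defaults for that block.
    """
    cp = configparser.ConfigParser(inline_comment_prefixes=("#",))
    cp.optionxform = str  # keys are case-sensitive (D vs d, T_max ...)
    if path is None:
        with resources.as_file(default_config_path()) as p:
            cp.read(p, encoding="utf-8")
    else:
        if not cp.read(path, encoding="utf-8"):
            raise FileNotFoundError(path)
    passive = _build(PassiveParams, cp["passive"], "passive") if "passive" in cp else PassiveParams()
    active = _build(ActiveParams, cp["active"], "active") if "active" in cp else ActiveParams()
    surrogate = (
        _build(SurrogateParams, cp["surrogate"], "surrogate")
        if "surrogate" in cp
        else SurrogateParams()
    )
    return passive, active, surrogate
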