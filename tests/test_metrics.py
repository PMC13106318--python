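import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sarcomech.metrics import (
    NormalRange,
    aps_deviation,
    cardiac_metrics,
    deviation_table,
    green_to_nominal,
    nominal_strain,
    ols_sensitivity,
    percent_change,
    percent_change_table,
    piecewise_sensitivity,
    range_deviation,
    rank_scenarios,
    recompute_metric_table,
    round_half_away,
    series_sensitivity_table,
)


class TestCardiacMetrics:
    def test_published_baseline_row(self):
        m = cardiac_metrics(142.789, 65.248, 60)
        assert m.SV == pytest.approx(77.541, abs=5e-4)
        assert m.LVEF == pytest.approx(54.305, abs=5e-4)
        assert m.CO == pytest.approx(4.652, abs=5e-4)

    def test_published_high_reference_length_row(self):
        m = cardiac_metrics(136.392, 54.962, 60)
        assert m.SV == pytest.approx(81.430, abs=5e-4)
        assert m.CO == pytest.approx(4.886, abs=5e-4)

    def test_small_stroke_volume_limit(self):
        eps = 1e-6
        m = cardiac_metrics(100.0, 100.0 - eps, 60)
        assert m.SV == pytest.approx(eps, rel=1e-6)

    def test_inverted_volumes_rejected(self):
        with pytest.raises(ValueError):
            cardiac_metrics(80.0, 90.0)


class TestPercentChange:
    @pytest.mark.parametrize(
        "value, baseline, expected",
        [(67.998, 77.541, -12.31), (85.827, 142.789, -39.89), (5.0, 5.0, 0.0)],
    )
    def test_published_cells(self, value, baseline, expected):
        assert round_half_away(percent_change(value, baseline), 2) == expected

    def test_zero_baseline_rejected(self):
        with pytest.raises(ValueError):
            percent_change(1.0, 0.0)

    def test_rounding_half_away_from_zero(self):
        assert round_half_away(2.005, 2) == 2.01
        assert round_half_away(-2.005, 2) == -2.01


class TestOlsSensitivity:
    def test_reference_series_slope(self, printed_table):
        lr = np.array([1.75, 1.80, 1.85, 1.90, 1.95])
        edv = (
            printed_table.set_index("id")
            .loc[["S01", "S02", "S00", "S03", "S04"], "EDV_mL"]
            .to_numpy()
        )
        res = ols_sensitivity(lr, edv, 1.85, 142.789)
        assert res.slope == pytest.approx(-53.3, abs=0.05)
        assert res.S_star == pytest.approx(-0.691, abs=0.005)
        assert res.r_squared == pytest.approx(0.987, abs=0.001)

    def test_matches_independent_ols(self, printed_table):
        import statsmodels.api as sm

        lr = np.array([1.75, 1.80, 1.85, 1.90, 1.95])
        sv = (
            printed_table.set_index("id")
            .loc[["S01", "S02", "S00", "S03", "S04"], "SV_mL"]
            .to_numpy()
        )
        res = ols_sensitivity(lr, sv, 1.85, 77.541)
        fit = sm.OLS(sv, sm.add_constant(lr)).fit()
        assert res.slope == pytest.approx(fit.params[1], rel=1e-10)
        assert res.r_squared == pytest.approx(fit.rsquared, rel=1e-10)

    def test_constant_response_defined_as_zero(self):
        res = ols_sensitivity([1.0, 2.0, 3.0], [5.0, 5.0, 5.0], 2.0, 5.0)
        assert res.slope == 0.0 and res.S_star == 0.0 and res.r_squared == 0.0

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            ols_sensitivity([1.0, 1.0, 1.0], [1.0, 2.0, 3.0], 1.0, 1.0)
        with pytest.raises(ValueError):
            ols_sensitivity([1.0, 2.0], [1.0, 2.0], 1.0, 1.0)

    def test_s_star_identity(self):
        res = ols_sensitivity([1.0, 2.0, 3.0], [2.0, 4.0, 6.0], 2.0, 4.0)
        assert res.S_star == (res.p_base / res.Y_base) * res.slope


class TestPiecewiseSensitivity:
    def test_below_baseline_threshold_segment(self, printed_table):
        pw = piecewise_sensitivity(printed_table).set_index(["segment", "metric"])
        row = pw.loc[("S11-S12-S00", "EDV_mL")]
        assert row.slope == pytest.approx(569.6, abs=0.05)
        assert row.S_star == pytest.approx(6.303, abs=0.005)

    def test_diagonal_segment_uses_reference_length(self, printed_table):
        pw = piecewise_sensitivity(printed_table).set_index(["segment", "metric"])
        row = pw.loc[("S21-S22-S00", "SV_mL")]
        assert row.parameter == "L_r"
        assert row.slope == pytest.approx(486.2, abs=0.05)

    def test_missing_scenario_named(self, printed_table):
        broken = printed_table[printed_table["id"] != "S12"]
        with pytest.raises(ValueError, match="S12"):
            piecewise_sensitivity(broken)


class TestDeviationScores:
    @pytest.mark.parametrize(
        "x, mu, sigma, expected",
        [(1.0, 1.0, 0.1, 0.0), (1.2, 1.0, 0.1, 1.0), (0.95, 1.0, 0.1, 0.0)],
    )
    def test_band_score(self, x, mu, sigma, expected):
        assert aps_deviation(x, mu, sigma) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "x, lo, hi, expected", [(102.0, 102, 202, 0.0), (302.0, 102, 202, 1.0)]
    )
    def test_range_score(self, x, lo, hi, expected):
        assert range_deviation(x, lo, hi) == pytest.approx(expected)

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            aps_deviation(1.0, 0.0, 0.0)
        with pytest.raises(ValueError):
            range_deviation(1.0, 2.0, 2.0)

    def test_reference_low_threshold_scenario_scores(self, printed_table):
        # hand-computed from the published S11 row and normal ranges
        scores = deviation_table(printed_table).set_index("id").loc["S11"]
        assert scores["EDV_mL_score"] == pytest.approx(0.16173, abs=1e-5)
        assert scores["ESV_mL_score"] == 0.0
        assert scores["SV_mL_score"] == pytest.approx(0.23568, abs=1e-5)
        assert scores["LVEF_pct_score"] == pytest.approx(0.60833, abs=1e-5)
        assert scores["CO_Lmin_score"] == pytest.approx(0.47375, abs=1e-5)
        assert scores["total_score"] == pytest.approx(1.47949, abs=1e-5)

    @given(
        scale=st.floats(0.1, 10.0),
        offset=st.floats(-50.0, 50.0),
        x=st.floats(0.0, 300.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_range_score_invariant_under_affine_reunit(self, scale, offset, x):
        raw = range_deviation(x, 102.0, 202.0)
        rescaled = range_deviation(
            scale * x + offset, scale * 102.0 + offset, scale * 202.0 + offset
        )
        assert rescaled == pytest.approx(raw, abs=1e-9)


class TestRanking:
    def test_descending_by_total(self):
        scores = pd.DataFrame({"id": ["S00", "S11"], "total_score": [0.0, 1.479]})
        assert rank_scenarios(scores) == ["S11", "S00"]

    def test_lexicographic_tie_break(self):
        scores = pd.DataFrame(
            {"id": ["S03", "S01", "S02"], "total_score": [0.0, 0.0, 0.0]}
        )
        assert rank_scenarios(scores) == ["S01", "S02", "S03"]


class TestStrainConversion:
    def test_trivial_values(self):
        assert nominal_strain(1.0) == 0.0
        assert green_to_nominal(0.0) == 0.0

    def test_published_conversion_example(self):
        assert green_to_nominal(0.04) == pytest.approx(math.sqrt(1.08) - 1.0, rel=1e-12)

    @given(lam=st.floats(0.05, 2.0))
    @settings(max_examples=60, deadline=None)
    def test_round_trip_through_green_strain(self, lam):
        E = 0.5 * (lam**2 - 1.0)
        assert green_to_nominal(E) == pytest.approx(nominal_strain(lam), abs=1e-12)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            nominal_strain(0.0)
        with pytest.raises(ValueError):
            green_to_nominal(-0.6)


class TestTableRecompute:
    def test_derived_columns_match_printed(self, printed_table):
        rec = recompute_metric_table(printed_table)
        for col in ("SV_mL", "LVEF_pct", "CO_Lmin"):
            assert np.allclose(rec[col], printed_table[col], atol=1e-12)

    def test_percent_changes_match_printed(self, printed_table):
        rec = recompute_metric_table(printed_table)
        pct = percent_change_table(rec).set_index("id")
        printed = printed_table.set_index("id")
        mapping = {
            "EDV_mL_pctchg": "EDV_pct",
            "ESV_mL_pctchg": "ESV_pct",
            "SV_mL_pctchg": "SV_pct",
            "LVEF_pct_pctchg": "LVEF_pct_chg",
            "CO_Lmin_pctchg": "CO_pct",
        }
        for ours, theirs in mapping.items():
            got = pct[ours]
            want = printed.loc[got.index, theirs]
            assert np.allclose(got, want, atol=1e-12)

    def test_normal_range_invariants(self, normal_ranges):
        for nr in normal_ranges.values():
            assert nr.upper > nr.lower
        with pytest.raises(ValueError):
            NormalRange("x", lower=5.0, upper=5.0)


def test_strain_value_consistency():
    from sarcomech.metrics import StrainValue

    sv = StrainValue.from_stretch(1.1)
    assert sv.e == pytest.approx(0.1)
    assert sv.E == pytest.approx(0.105)
    with pytest.raises(ValueError):
        StrainValue(stretch=1.1, E=0.3, e=0.1)
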