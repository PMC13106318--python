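import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sarcomech.active import (
    ActiveParams,
    BelowActivationThreshold,
    activation_phase,
    active_fiber_stress,
    duration_of_contraction,
    eca50,
    length_tension_curve,
    peak_isometric_stress,
    relaxation_duration,
    sarcomere_length,
)


class TestSarcomereLength:
    @pytest.mark.parametrize(
        "E_ff, expected",
        [(0.0, 1.85), (0.105, 1.85 * math.sqrt(1.21)), (-0.095, 1.85 * math.sqrt(0.81))],
    )
    def test_length_from_green_strain(self, E_ff, expected):
        assert sarcomere_length(E_ff, 1.85) == pytest.approx(expected, rel=1e-12)

    def test_non_physical_compression_rejected(self):
        with pytest.raises(ValueError):
            sarcomere_length(-0.5, 1.85)


class TestCalciumSensitivity:
    def test_baseline_half_maximal_calcium(self, active_params):
        # B (L - L0) = 4750 mm^-1 * 0.27 um = 1.2825 under the mm convention
        assert eca50(0.0, active_params) == pytest.approx(
            4.35 / math.sqrt(math.expm1(1.2825)), rel=1e-12
        )
        assert eca50(0.0, active_params) == pytest.approx(2.6948, rel=1e-4)

    def test_smaller_sld_needs_more_calcium(self, active_params):
        short = replace(active_params, L_r=1.75)  # SLD 0.17 um
        assert eca50(0.0, short) == pytest.approx(3.9028, rel=1e-4)
        assert eca50(0.0, short) > eca50(0.0, active_params)

    def test_below_threshold_raises(self, active_params):
        # stretch that brings L below L_0 = 1.58 um
        lam = 1.57 / 1.85
        E_ff = 0.5 * (lam**2 - 1.0)
        with pytest.raises(BelowActivationThreshold):
            eca50(E_ff, active_params)
        assert active_fiber_stress(0.1, E_ff, active_params) == 0.0

    def test_diverges_as_length_approaches_threshold(self, active_params):
        lam = (1.58 + 1e-6) / 1.85
        E_ff = 0.5 * (lam**2 - 1.0)
        assert eca50(E_ff, active_params) > 1e2


class TestTiming:
    @pytest.mark.parametrize(
        "L, expected", [(1.85, 0.51147), (1.75, 0.40658), (1.95, 0.61636)]
    )
    def test_relaxation_duration_linear_in_length(self, L, expected, active_params):
        assert relaxation_duration(L, active_params) == pytest.approx(expected, abs=1e-5)

    def test_phase_piecewise_and_continuous(self, active_params):
        p = active_params
        assert activation_phase(0.0, 0.0, p) == 0.0
        assert activation_phase(p.t0 / 2, 0.0, p) == pytest.approx(math.pi / 2)
        assert activation_phase(p.t0, 0.0, p) == pytest.approx(math.pi)
        t_r = relaxation_duration(p.L_r, p)
        assert activation_phase(p.t0 + t_r, 0.0, p) == 0.0
        # left limit of (1 - cos omega) at the end of relaxation is 0
        omega_end = activation_phase(p.t0 + t_r - 1e-9, 0.0, p)
        assert 1.0 - math.cos(omega_end) == pytest.approx(0.0, abs=1e-12)

    def test_negative_time_rejected(self, active_params):
        with pytest.raises(ValueError):
            activation_phase(-0.1, 0.0, active_params)

    def test_doc_affine_in_reference_length(self, active_params):
        assert duration_of_contraction(active_params) == pytest.approx(0.61147, abs=1e-5)
        short = replace(active_params, L_r=1.75)
        long = replace(active_params, L_r=1.95)
        assert duration_of_contraction(short) == pytest.approx(0.50658, abs=1e-5)
        assert duration_of_contraction(long) == pytest.approx(0.71636, abs=1e-5)
        # the slope m (s/mm) converts to m*1e-3 seconds per um of L_r
        slope = (duration_of_contraction(long) - duration_of_contraction(short)) / 0.2
        assert slope == pytest.approx(1048.9e-3, rel=1e-12)

    def test_doc_independent_of_threshold_length(self, active_params):
        low = replace(active_params, L_0=1.48)
        high = replace(active_params, L_0=1.68)
        assert duration_of_contraction(low) == duration_of_contraction(high)


class TestActiveStress:
    def test_zero_at_onset_and_after_relaxation(self, active_params):
        assert active_fiber_stress(0.0, 0.0, active_params) == 0.0
        doc = duration_of_contraction(active_params)
        assert active_fiber_stress(doc + 1e-6, 0.0, active_params) == 0.0

    def test_peak_value_at_t0(self, active_params):
        sigma = active_fiber_stress(active_params.t0, 0.0, active_params)
        assert sigma == pytest.approx(0.072266, abs=1e-5)
        assert sigma == pytest.approx(peak_isometric_stress(active_params), rel=1e-12)

    @given(
        t=st.floats(0.0, 1.0),
        E_ff=st.floats(-0.3, 0.3),
        L_0=st.floats(1.48, 1.68),
    )
    @settings(max_examples=100, deadline=None)
    def test_stress_bounded_by_t_max(self, t, E_ff, L_0):
        p = ActiveParams(L_0=L_0)
        sigma = active_fiber_stress(t, E_ff, p)
        assert 0.0 <= sigma <= p.T_max


class TestPeakStressSldLaw:
    def test_peak_depends_on_sld_only(self):
        # same SLD, different absolute lengths -> identical peaks exactly
        pairs = [(1.75, 1.48), (1.80, 1.53), (1.85, 1.58), (1.90, 1.63), (1.95, 1.68)]
        peaks = [peak_isometric_stress(ActiveParams(L_r=lr, L_0=l0)) for lr, l0 in pairs]
        assert max(peaks) - min(peaks) < 1e-15

    @pytest.mark.parametrize(
        "L_r, expected", [(1.75, 0.05540), (1.85, 0.07227), (1.95, 0.08275)]
    )
    def test_peak_values_across_sld(self, L_r, expected):
        assert peak_isometric_stress(ActiveParams(L_r=L_r)) == pytest.approx(
            expected, abs=2e-5
        )

    @given(sld=st.floats(0.05, 0.5))
    @settings(max_examples=40, deadline=None)
    def test_peak_increasing_in_sld(self, sld):
        lo = peak_isometric_stress(ActiveParams(L_r=1.5 + sld, L_0=1.5))
        hi = peak_isometric_stress(ActiveParams(L_r=1.5 + sld + 0.01, L_0=1.5))
        assert hi > lo


class TestLengthTensionCurve:
    def test_zero_at_and_below_threshold(self, active_params):
        curve = dict(length_tension_curve([1.4, 1.58], active_params))
        assert curve[1.4] == 0.0 and curve[1.58] == 0.0

    def test_consistent_with_isometric_peak(self, active_params):
        curve = dict(length_tension_curve([1.85], active_params))
        assert curve[1.85] == pytest.approx(
            peak_isometric_stress(active_params), rel=1e-12
        )

    def test_lower_threshold_shifts_curve_up(self, active_params):
        grid = np.linspace(1.6, 2.2, 13)
        low = dict(length_tension_curve(grid, replace(active_params, L_0=1.48)))
        base = dict(length_tension_curve(grid, active_params))
        assert all(low[L] >= base[L] for L in low)

    def test_monotone_non_decreasing(self, active_params):
        grid = np.linspace(1.4, 2.3, 40)
        values = [v for _, v in length_tension_curve(grid, active_params)]
        assert all(b >= a for a, b in zip(values, values[1:]))


def test_parameter_validation():
    with pytest.raises(ValueError):
        ActiveParams(T_max=0.0)
    with pytest.raises(ValueError):
        ActiveParams(L_r=1.5, L_0=1.58)  # L_r must exceed L_0
    with pytest.raises(ValueError):
        ActiveParams(b_relax=-10.0)  # t_r(L_r) would be negative


def test_activation_state_bundles_intermediates(active_params):
    from sarcomech.active import activation_state

    st_ = activation_state(active_params.t0, 0.0, active_params)
    assert st_.L == active_params.L_r
    assert st_.sigma_af == pytest.approx(peak_isometric_stress(active_params))
    assert st_.omega == pytest.approx(math.pi)
    below = activation_state(0.05, -0.2, active_params)
    assert below.ECa50 == math.inf and below.sigma_af == 0.0
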