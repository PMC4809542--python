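"""Single-cell model: vector field, bifurcation structure, waveforms."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import brentq

from uteromag.cell_dynamics import (
    CellState,
    FHNParams,
    StimulusWaveform,
    bifurcation_diagram,
    bifurcation_result,
    classify_stimulus,
    discriminants,
    equilibrium_potential,
    equilibrium_stimulus,
    fhn_rhs,
    hopf_frequency,
    jacobian,
    limit_cycle_range,
    resting_potential,
    resting_state,
    simulate_cell,
    spike_frequency,
    spike_times,
)


class TestVectorField:
    def test_zero_at_equilibrium(self, params):
        """The nullcline-constructed state is an exact fixed point."""
        for vm_star in (-0.055, -0.04, -0.03):
            nu = equilibrium_stimulus(vm_star, params)
            w = (params.beta * vm_star + params.delta) / params.gamma
            stim = StimulusWaveform(kind="constant", amplitude=nu)
            dv, dw = fhn_rhs(CellState(vm_star, w), 0.0, params, stim)
            assert abs(dv) < 1e-12 and abs(dw) < 1e-12

    def test_cubic_root_kills_voltage_term(self, params):
        dv, _ = fhn_rhs(CellState(params.v1, 0.0), 0.0, params, None)
        assert dv == 0.0

    def test_hand_evaluated_cubic(self, params):
        # k (v-v1)(v2-v)(v-v3) / (eps1 c_m) at v = -0.03:
        # 7000 * (-0.01)(-0.01)(0.035) / (10 * 0.01) = 0.245 V/s
        dv, _ = fhn_rhs(CellState(-0.03, 0.0), 0.0, params, None)
        assert dv == pytest.approx(0.245, rel=1e-12)

    def test_nonfinite_state_rejected(self, params):
        with pytest.raises(Exception):
            fhn_rhs([float("nan"), 0.0], 0.0, params, None)


class TestEquilibria:
    def test_pure_cubic_root_gives_zero_stimulus(self):
        p = FHNParams(beta=1e-12, delta=0.0)
        # with negligible recovery coupling the cubic root v2 is equilibrium
        assert equilibrium_stimulus(p.v2, p) == pytest.approx(0.0, abs=1e-10)

    def test_consistency_with_bisection_oracle(self, params):
        """equilibrium_potential inverts the nu(v) map found by bisection."""
        for nu in (0.0, 0.05, 0.1, 0.18, 0.25):
            v_root = brentq(
                lambda v: equilibrium_stimulus(v, params) - nu, -0.2, 0.1,
                xtol=1e-14,
            )
            assert equilibrium_potential(nu, params) == pytest.approx(
                v_root, abs=1e-10
            )

    def test_resting_potential_near_minus_56mV(self, params):
        assert resting_potential(params) == pytest.approx(-0.0556, abs=1e-4)

    def test_translation_covariance(self, params):
        """Shifting all cubic roots shifts the rest potential identically."""
        c = 0.013
        shifted = FHNParams(
            c_m=params.c_m, eps1=params.eps1, eps2=params.eps2,
            v1=params.v1 + c, v2=params.v2 + c, v3=params.v3 + c,
            k=params.k, beta=params.beta, gamma=params.gamma,
            delta=params.delta - params.beta * c,
        )
        assert resting_potential(shifted) == pytest.approx(
            resting_potential(params) + c, abs=1e-12
        )

    def test_rest_stimulus_is_zero(self, params):
        assert abs(equilibrium_stimulus(resting_potential(params), params)) < 1e-12


class TestBifurcation:
    def test_discriminant_values(self, params):
        """Hand-evaluated polynomial expressions for the published set."""
        d1, d2 = discriminants(params)
        assert d1 == pytest.approx(-2.7607e-3, rel=1e-4)
        assert d2 == pytest.approx(1.4821e-3, rel=1e-4)
        assert d1 < 0 < d2

    def test_equality_boundary(self):
        p = FHNParams(beta=10.0 * 10.0 * 0.01 * 0.1**2)  # beta = e1 e2 c_m gamma^2
        d1, d2 = discriminants(p)
        assert d1 == pytest.approx(d2, rel=1e-12)

    def test_published_window(self, params):
        lo, hi = limit_cycle_range(params)
        assert lo == pytest.approx(0.012, abs=1e-3)
        assert hi == pytest.approx(0.207, abs=1e-3)

    def test_window_empty_when_timescales_too_fast(self, params):
        slow = params.with_scales(eps1=200.0, eps2=100.0)
        assert limit_cycle_range(slow) is None

    def test_window_edges_are_hopf_points(self, params):
        """Jacobian trace vanishes at the window-edge equilibria."""
        res = bifurcation_result(params)
        for vm in (res.vm_star_low, res.vm_star_high):
            assert np.trace(jacobian(vm, params)) == pytest.approx(0.0, abs=1e-8)

    def test_classification(self, params):
        assert classify_stimulus(0.15, params) == "limit_cycle"
        assert classify_stimulus(0.0, params) == "stable_equilibrium"
        lo, hi = limit_cycle_range(params)
        eps = 1e-4
        assert classify_stimulus(lo - eps, params) == "stable_equilibrium"
        assert classify_stimulus(lo + eps, params) == "limit_cycle"
        assert classify_stimulus(hi + eps, params) == "stable_equilibrium"

    def test_classification_matches_long_integration(self, params):
        """Attractor type from integration agrees with the eigenvalue test."""
        for nu in np.linspace(0.0, 0.25, 21):
            stim = StimulusWaveform(kind="constant", amplitude=float(nu))
            rest = resting_state(params)
            trace = simulate_cell(
                params, stim, 80.0, initial=CellState(rest.v_m + 5e-3, rest.w),
                sample_rate=200.0,
            )
            tail = trace.v_m[trace.t > 60.0]
            oscillating = tail.max() - tail.min() > 1e-4
            expected = classify_stimulus(float(nu), params) == "limit_cycle"
            assert oscillating == expected, f"nu={nu}"

    def test_diagram_instability_inside_window(self, params):
        rows = bifurcation_diagram(
            params, [0.0, 0.05, 0.15, 0.25], settle=40.0, window=20.0
        )
        stable = {r["nu"]: r["stable"] for r in rows}
        assert stable[0.0] and stable[0.25]
        assert not stable[0.05] and not stable[0.15]
        r15 = next(r for r in rows if r["nu"] == 0.15)
        assert r15["cycle_min"] < r15["vm_eq"] < r15["cycle_max"]

    def test_multiple_equilibria_rejected(self):
        # tiny beta -> delta1 > 0 -> the analysis must refuse
        p = FHNParams(beta=1e-4)
        assert discriminants(p)[0] > 0
        with pytest.raises(ValueError):
            limit_cycle_range(p)


class TestHopfFrequency:
    def test_exact_timescale_scaling(self, params):
        w0 = hopf_frequency(params, 0.1)
        assert hopf_frequency(params.with_scales(40.0, 10.0), 0.1) == pytest.approx(
            w0 / 2, rel=1e-12
        )
        assert hopf_frequency(params.with_scales(10.0, 40.0), 0.1) == pytest.approx(
            2 * w0, rel=1e-12
        )

    def test_matches_quadratic_formula_oracle(self, params):
        """sqrt(det J) equals the eigenvalue-pair modulus near the Hopf edge."""
        lo, _ = limit_cycle_range(params)
        nu = lo + 1e-3  # just inside the window: trace ~ 0, complex pair
        vm = equilibrium_potential(nu, params)
        J = jacobian(vm, params)
        lam = np.roots([1.0, -np.trace(J), np.linalg.det(J)])
        assert lam[0].imag != 0  # genuinely oscillatory here
        assert hopf_frequency(params, nu) == pytest.approx(
            abs(lam[0]), rel=1e-10
        )

    def test_defined_throughout_the_window(self, params):
        """det J > 0 wherever the equilibrium is unique, so the natural
        frequency exists for every stimulus amplitude."""
        for nu in np.linspace(0.0, 0.25, 11):
            assert hopf_frequency(params, float(nu)) > 0


class TestWaveforms:
    def test_plateau_returns_to_rest(self, params):
        rest = resting_state(params)
        trace = simulate_cell(
            params,
            StimulusWaveform(kind="none"),
            30.0,
            initial=CellState(-0.030, rest.w),
        )
        assert trace.v_m[-1] == pytest.approx(rest.v_m, abs=1e-4)
        assert trace.v_m.max() > -0.030  # an excursion happened first

    def test_constant_stimulus_spikes_persist(self, params):
        trace = simulate_cell(
            params, StimulusWaveform(kind="constant", amplitude=0.15), 60.0
        )
        late = spike_times(trace, discard_fraction=0.5)
        assert len(late) >= 10
        assert late[-1] > 55.0  # still firing at the end

    def test_quiescent_trace_has_zero_rate(self, params):
        trace = simulate_cell(params, StimulusWaveform(kind="none"), 5.0)
        assert spike_frequency(trace) == 0.0

    def test_spike_rate_on_synthetic_train(self):
        """Known-rate synthetic spike train recovered exactly."""
        t = np.linspace(0.0, 100.0, 20001)
        v = np.where((t % 2.5) < 0.4, -0.01, -0.055)  # 0.4 Hz square spikes
        from uteromag.cell_dynamics import CellTrace

        trace = CellTrace(t, v, np.zeros_like(t))
        assert spike_frequency(trace) == pytest.approx(0.4, rel=1e-3)

    def test_stimulus_validation(self):
        with pytest.raises(ValueError):
            StimulusWaveform(kind="wiggle")
        with pytest.raises(ValueError):
            StimulusWaveform(kind="periodic_heaviside", period=10.0, duration=11.0)

    def test_sinusoid_and_heaviside_values(self):
        s = StimulusWaveform(kind="periodic_heaviside", amplitude=0.11,
                             period=420.0, duration=60.0)
        assert s(10.0) == 0.11 and s(100.0) == 0.0 and s(430.0) == 0.11
        sin = StimulusWaveform(kind="sinusoid", amplitude=0.11, period=20.0)
        assert sin(5.0) == pytest.approx(0.11)


# -- property tests ----------------------------------------------------------

valid_params = st.builds(
    FHNParams,
    eps1=st.floats(1.0, 50.0),
    eps2=st.floats(1.0, 50.0),
    k=st.floats(2000.0, 20000.0),
    beta=st.floats(0.5, 2.0),
    gamma=st.floats(0.05, 0.5),
    delta=st.floats(0.02, 0.08),
)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(p=valid_params, vm_star=st.floats(-0.09, 0.0))
def test_equilibrium_consistency_property(p, vm_star):
    """For any parameters, the inverted stimulus makes (vm*, w*) a fixed point."""
    nu = equilibrium_stimulus(vm_star, p)
    w = (p.beta * vm_star + p.delta) / p.gamma
    stim = StimulusWaveform(kind="constant", amplitude=nu)
    dv, dw = fhn_rhs(CellState(vm_star, w), 0.0, p, stim)
    scale = abs(nu) / (p.eps1 * p.c_m) + 1.0
    assert abs(dv) <= 1e-9 * scale and abs(dw) < 1e-10
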