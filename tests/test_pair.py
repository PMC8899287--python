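"""Cell-pair simulation: Mg2+ flux, Vj modulation, joint trapping, summaries."""

import numpy as np
import pytest

from cx36mg import (
    VARIANT_PARAMS,
    PairState,
    Protocol,
    VjModulation,
    VjPulse,
    asymmetric_protocol,
    mg_flux_rhs,
    modulate_rates,
    simulate_pair,
    simulate_pair_joint_trap,
    symmetric_protocol,
    trace_summary,
    vj_pulse_protocol,
    vj_ramp_experiment,
)
from cx36mg.pair import TraceSet


def _pair(mg1, mg2):
    return PairState(
        hc1=np.array([1.0, 0.0, 0.0]), hc2=np.array([1.0, 0.0, 0.0]),
        mg1=mg1, mg2=mg2,
    )


class TestMgFlux:
    def test_donor_clamped_flux_into_recipient(self, wt):
        protocol = asymmetric_protocol(10.0)
        d1, d2 = mg_flux_rhs(_pair(0.0, 10.0), wt, 1.0, protocol)
        assert d1 == pytest.approx(0.0135 * 10.0)  # +P*gj*(mg2-mg1)
        assert d2 == 0.0  # clamped donor

    def test_closed_junction_has_no_flux(self, wt):
        protocol = Protocol(duration=5.0, pipette_mg=(0.0, 10.0), clamp=(False, False))
        d1, d2 = mg_flux_rhs(_pair(0.0, 10.0), wt, 0.0, protocol)
        assert d1 == 0.0 and d2 == 0.0

    def test_equal_concentrations_in_equilibrium(self, wt):
        protocol = Protocol(duration=5.0, pipette_mg=(3.0, 3.0), clamp=(False, False))
        d1, d2 = mg_flux_rhs(_pair(3.0, 3.0), wt, 0.5, protocol)
        assert d1 == 0.0 and d2 == 0.0

    def test_leak_drains_recipient(self, wt):
        params = wt.replace(p_leak=0.1)
        protocol = asymmetric_protocol(10.0)
        d1, _ = mg_flux_rhs(_pair(2.0, 10.0), params, 0.0, protocol)
        assert d1 == pytest.approx(-0.2)


class TestVjModulation:
    def test_zero_voltage_is_identity(self, wt):
        mod = VjModulation(z_open=0.07, z_close=0.04)
        assert modulate_rates(wt, 0.0, mod) == (wt.k1, wt.k2)

    def test_zero_slopes_insensitive(self, wt):
        mod = VjModulation(z_open=0.0, z_close=0.0)
        assert modulate_rates(wt, 83.0, mod) == (wt.k1, wt.k2)

    def test_exponential_scaling(self):
        from cx36mg import RateParams

        params = RateParams(k1=5.35, k2=100.0, k3=1.0, k4=1.0)
        mod = VjModulation(z_open=0.05, z_close=0.0)
        k1, k2 = modulate_rates(params, 60.0, mod, polarity=1.0)
        assert k1 == pytest.approx(5.35 * np.exp(3.0), rel=1e-12)
        assert k2 == pytest.approx(100.0)


class TestSimulatePair:
    def test_impermeable_junction_keeps_recipient_mg_constant(self, wt, model5_hill):
        params = wt.replace(p=0.0)
        trace = simulate_pair(model5_hill, params, asymmetric_protocol(10.0))
        assert np.max(np.abs(trace.mg1 - trace.mg1[0])) < 1e-9

    def test_wt_symmetric_5mm_decreases_monotonically(self, wt, model5_hill):
        trace = simulate_pair(model5_hill, wt, symmetric_protocol(5.0))
        assert trace.gj_norm[0] == 1.0
        assert np.all(np.diff(trace.gj_norm) <= 1e-12)
        assert trace.gj_norm[-1] < 1.0

    def test_a13k_symmetric_5mm_barely_responds(self, a13k, model5_hill):
        trace = simulate_pair(model5_hill, a13k, symmetric_protocol(5.0))
        assert trace.gj_norm[-1] >= 0.95

    def test_asymmetric_fluorescence_rises_with_recipient_mg(self, wt, model5_hill):
        trace = simulate_pair(model5_hill, wt, asymmetric_protocol(10.0))
        assert trace.mg1[-1] > trace.mg1[0]
        assert trace.fi_norm[0] == 1.0
        assert trace.fi_norm[-1] == pytest.approx(1.0 + trace.mg1[-1] - trace.mg1[0])

    def test_mg_mass_conserved_in_closed_system(self, wt, model5_hill):
        protocol = Protocol(
            duration=10.0,
            pipette_mg=(0.0, 8.0),
            clamp=(False, False),
            initial_mg=(0.0, 8.0),
        )
        trace = simulate_pair(model5_hill, wt, protocol)
        total = trace.mg1 + trace.mg2
        assert np.max(np.abs(total - total[0])) < 1e-6

    def test_swapping_cell_labels_transposes_solution(self, wt, model5_hill):
        fwd = simulate_pair(
            model5_hill, wt,
            Protocol(duration=5.0, pipette_mg=(0.0, 10.0), clamp=(False, True)),
        )
        rev = simulate_pair(
            model5_hill, wt,
            Protocol(duration=5.0, pipette_mg=(10.0, 0.0), clamp=(True, False)),
        )
        assert np.allclose(fwd.gj_norm, rev.gj_norm, atol=1e-9)
        assert np.allclose(fwd.mg1, rev.mg2, atol=1e-9)
        assert np.allclose(fwd.mg2, rev.mg1, atol=1e-9)

    @pytest.mark.parametrize("variant", sorted(VARIANT_PARAMS))
    def test_euler_agrees_with_reference_solution(self, variant, model5_hill):
        """Fixed-step Euler at 1e-3 min tracks the exact clamped-system
        solution to <1e-4 in normalised conductance over 30 min."""
        params = VARIANT_PARAMS[variant]
        protocol = symmetric_protocol(5.0, duration=30.0, sample_interval=0.5)
        exact = simulate_pair(model5_hill, params, protocol)
        euler = simulate_pair(model5_hill, params, protocol, method="euler",
                              euler_step=1e-3)
        assert np.max(np.abs(exact.gj_norm - euler.gj_norm)) < 1e-4

    def test_euler_agrees_with_adaptive_on_coupled_flux(self, wt, model5_hill):
        protocol = asymmetric_protocol(10.0)
        adaptive = simulate_pair(model5_hill, wt, protocol)
        euler = simulate_pair(model5_hill, wt, protocol, method="euler",
                              euler_step=1e-3)
        assert np.max(np.abs(adaptive.gj_norm - euler.gj_norm)) < 1e-4
        assert np.max(np.abs(adaptive.mg1 - euler.mg1)) < 1e-4


class TestJointTrap:
    def test_unit_trap_factor_reproduces_independent_marginals(self, wt, model5_hill):
        protocol = symmetric_protocol(1.0, duration=30.0)
        joint = simulate_pair_joint_trap(model5_hill, wt, protocol, eps=1.0)
        independent = simulate_pair(model5_hill, wt, protocol)
        jp = joint.extras["joint_p"].reshape(-1, 3, 3)
        assert np.max(np.abs(jp.sum(axis=2) - independent.states[:, 0:3])) < 1e-8
        assert np.max(np.abs(jp.sum(axis=1) - independent.states[:, 3:6])) < 1e-8

    def test_no_binding_means_no_double_closed_state(self, wt, model5_hill):
        params = wt.replace(k3=0.0)
        joint = simulate_pair_joint_trap(
            model5_hill, params, symmetric_protocol(5.0), eps=0.0
        )
        assert np.max(joint.extras["p_double_closed"]) < 1e-12

    def test_absorbing_trap_accumulates_double_closed(self, wt, model5_hill):
        protocol = symmetric_protocol(1.0, duration=180.0, sample_interval=1.0)
        joint = simulate_pair_joint_trap(model5_hill, wt, protocol, eps=0.0)
        p_dc = joint.extras["p_double_closed"]
        assert np.all(np.diff(p_dc) >= -1e-12)
        assert p_dc[-1] > 0.9

    def test_non_terminal_binding_scheme_unsupported(self, wt):
        from cx36mg import get_scheme

        with pytest.raises(ValueError, match="Model 5"):
            simulate_pair_joint_trap(
                get_scheme("Model 1"), wt, symmetric_protocol(1.0)
            )


class TestVjRamp:
    def test_zero_amplitude_matches_unperturbed_simulation(self, wt, model5_hill):
        protocol = Protocol(
            duration=5.0, pipette_mg=(5.0, 5.0),
            vj_waveform=VjPulse(2.0, 2.5, 0.0), protocol_id="zero",
        )
        ramped = vj_ramp_experiment(model5_hill, wt, protocol, VjModulation())
        plain = simulate_pair(model5_hill, wt, symmetric_protocol(5.0))
        assert np.max(np.abs(ramped.gj_norm - plain.gj_norm)) < 1e-6

    def test_a13k_recovers_fully_and_h18k_plateaus(self, a13k, h18k, model5_hill):
        """Vj-induced closure recovers rapidly without Mg2+ binding (A13K)
        but is impeded when binding stabilises the closed state (H18K)."""
        protocol = vj_pulse_protocol(5.0)
        mod = VjModulation()
        recoveries = {}
        for label, params in (("A13K", a13k), ("H18K", h18k)):
            trace = vj_ramp_experiment(model5_hill, params, protocol, mod)
            pre = trace.gj_norm[trace.time <= 5.0][-1]
            window = (trace.time >= 5.2) & (trace.time <= 10.2)
            recoveries[label] = float(np.max(trace.gj_norm[window]) / pre)
        assert recoveries["A13K"] >= 0.95
        assert recoveries["H18K"] < recoveries["A13K"]

    def test_baseline_counterfactual_has_no_pulse_dip(self, h18k, model5_hill):
        protocol = vj_pulse_protocol(5.0)
        ramped, baseline = vj_ramp_experiment(
            model5_hill, h18k, protocol, VjModulation(), with_baseline=True
        )
        in_pulse = (ramped.time >= 5.0) & (ramped.time <= 5.1)
        assert ramped.gj_norm[in_pulse].min() < baseline.gj_norm[in_pulse].min()
        assert np.all(np.diff(baseline.gj_norm) <= 1e-12)


class TestTraceSummary:
    def test_constant_trace_all_ratios_one(self):
        trace = TraceSet(time=np.arange(4.0), gj_norm=np.ones(4),
                         fi_norm=np.ones(4))
        summary = trace_summary(trace)
        assert summary == {
            "gj_ss_over_init": 1.0,
            "gj_final_over_init": 1.0,
            "fi_final_over_init": 1.0,
        }

    def test_final_over_init_is_last_over_first(self):
        trace = TraceSet(time=np.arange(4.0), gj_norm=np.array([1.0, 0.8, 0.5, 0.5]))
        assert trace_summary(trace)["gj_final_over_init"] == pytest.approx(0.5)

    def test_consistent_with_simulator_endpoint(self, wt, model5_hill):
        trace = simulate_pair(model5_hill, wt, symmetric_protocol(5.0))
        summary = trace_summary(trace)
        assert summary["gj_final_over_init"] == pytest.approx(
            trace.gj_norm[-1] / trace.gj_norm[0]
        )

    def test_zero_initial_value_raises(self):
        trace = TraceSet(time=np.arange(3.0), gj_norm=np.array([0.0, 0.5, 0.5]))
        with pytest.raises(ZeroDivisionError):
            trace_summary(trace)
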