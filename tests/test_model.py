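"""Plasticity model: LIF dynamics, kernels, eligibility, rule sign structure."""

import numpy as np
import pytest

from rstdp import (EligibilityState, LifNeuron, Network, PlasticityRuleParams,
                   PlasticityRule, ProtocolSpec, apply_reinforcement,
                   reference_rule, run_action_discovery, run_protocol,
                   simulate_lif, update_eligibility, weight_change_surface)
from rstdp.model import SignalKernel
from rstdp.pipeline import protocol_conditions


class TestLif:
    def test_zero_input_stays_at_rest(self):
        n = LifNeuron()
        spikes, v = simulate_lif(n, np.zeros(1000), dt=0.001)
        assert spikes.size == 0 and np.allclose(v, 0.0)

    def test_subthreshold_constant_input_never_fires(self):
        n = LifNeuron(v_thresh=1.0)
        spikes, v = simulate_lif(n, np.full(5000, 0.8), dt=0.001)
        assert spikes.size == 0
        assert v[-1] == pytest.approx(0.8, abs=1e-6)

    def test_suprathreshold_isi_matches_closed_form(self):
        n = LifNeuron(tau_m=0.02, v_thresh=1.0, v_reset=0.0, refractory_s=0.002)
        dt = 0.0005
        spikes, _ = simulate_lif(n, np.full(40000, 1.5), dt=dt)
        isi = np.diff(spikes)
        assert isi.std() < 1e-9
        assert isi.mean() == pytest.approx(n.isi_constant_input(1.5), abs=2 * dt)

    def test_too_large_dt_raises(self):
        with pytest.raises(ValueError, match="dt"):
            simulate_lif(LifNeuron(tau_m=0.02), np.zeros(10), dt=0.01)


class TestKernels:
    def test_causality(self):
        k = SignalKernel("dopamine", 0.05, 0.30, onset_delay_s=1.0)
        t = np.linspace(0, 0.999, 50)
        assert np.all(k(t) == 0.0)

    def test_peak_time_and_height_match_closed_form(self):
        k = SignalKernel("dopamine", 0.05, 0.30)
        tp = np.log(0.30 / 0.05) / (1 / 0.05 - 1 / 0.30)
        assert k.peak_time_s == pytest.approx(tp)
        t = np.linspace(0, 3, 300001)
        y = k(t)
        assert t[np.argmax(y)] == pytest.approx(tp, abs=1e-4)
        assert y.max() == pytest.approx(1.0, abs=1e-9)

    def test_integral_matches_quadrature(self):
        k = SignalKernel("thalamic", 0.03, 0.20)
        t = np.linspace(0, 10, 200001)
        assert np.trapezoid(k(t), t) == pytest.approx(k.analytic_integral(), rel=1e-4)

    def test_equal_time_constants_alpha_limit(self):
        k = SignalKernel("dopamine", 0.1, 0.1)
        assert k.peak_time_s == pytest.approx(0.1)
        assert k(np.array([0.1]))[0] == pytest.approx(1.0)

    def test_rise_slower_than_decay_required(self):
        with pytest.raises(ValueError):
            SignalKernel("dopamine", 0.4, 0.3)


class TestEligibility:
    def test_positive_pairing_seeds_potentiation_only(self):
        s = EligibilityState(n_synapses=3)
        update_eligibility(0.0, 0.010, s, synapses=[0, 1])
        assert len(s.seeds_pot) == 1 and len(s.seeds_dep) == 0
        assert list(s.pot_seeded) == [True, True, False]

    def test_negative_pairing_seeds_depression_only(self):
        s = EligibilityState(n_synapses=2)
        update_eligibility(0.010, 0.0, s)
        assert len(s.seeds_dep) == 1 and len(s.seeds_pot) == 0

    def test_out_of_window_pairing_is_noop(self):
        s = EligibilityState(n_synapses=2)
        update_eligibility(0.0, 0.200, s)
        assert not s.seeds_pot and not s.seeds_dep

    def test_waveform_peaks_at_tau_r_and_decays_below_one_percent(self):
        s = EligibilityState(n_synapses=1)
        assert s.waveform(s.tau_r_s) == pytest.approx(1.0)
        assert s.waveform(3.0) < 0.01

    def test_traces_superpose_additively(self):
        s = EligibilityState(n_synapses=1)
        update_eligibility(0.0, 0.010, s)
        update_eligibility(0.1, 0.110, s)
        t = np.array([1.0])
        single1 = s.waveform(t - 0.010)
        single2 = s.waveform(t - 0.110)
        assert s.e_pot(t)[0, 0] == pytest.approx((single1 + single2)[0])


class TestReinforcementRule:
    def _dw(self, rule, pairing_dt_ms, da_onsets, th_onsets):
        t = rule.time_grid()
        s = EligibilityState(1, k=rule.params.k, tau_r_s=rule.params.tau_r_s)
        update_eligibility(0.0, pairing_dt_ms / 1000.0, s)
        da = sum((rule.da_kernel(o)(t) for o in da_onsets), np.zeros_like(t))
        th = sum((rule.th_kernel(o)(t) for o in th_onsets), np.zeros_like(t))
        return apply_reinforcement(s, t, da, th, rule)[0]

    def test_positive_pairing_with_conjunction_at_1s_potentiates(self, rule):
        assert self._dw(rule, +10.0, [1.0], [1.0]) > 0

    def test_positive_pairing_with_dopamine_only_at_2s_depresses(self, rule):
        assert self._dw(rule, +10.0, [2.0], []) < 0

    def test_negative_pairing_with_conjunction_depresses(self, rule):
        assert self._dw(rule, -10.0, [1.0], [1.0]) < 0

    def test_unreinforced_negative_pairing_no_drift(self, rule):
        assert self._dw(rule, -10.0, [], []) == 0.0


class TestProtocols:
    def test_zero_learning_rates_fixed_point(self):
        rule = reference_rule(eta_pot=0.0, eta_dep=0.0, kappa_baseline=0.0)
        res = run_protocol(protocol_conditions(10)["reinforced"], rule)
        assert np.all(res.mean_weights == res.mean_weights[0])

    def test_weights_stay_in_bounds_under_aggressive_rates(self):
        rule = reference_rule(eta_pot=0.5, eta_dep=0.5, kappa_baseline=0.2)
        net_states = []
        for proto in protocol_conditions(30).values():
            res = run_protocol(proto, rule)
            net_states.append(res.mean_weights)
        w = np.concatenate(net_states)
        assert w.min() >= rule.params.w_min and w.max() <= rule.params.w_max

    def test_surface_agrees_with_protocol_in_single_event_limit(self, rule):
        """One positive pairing with light-evoked DA+Th at delay d must give
        the same weight change as the surface entry at (d, d)."""
        d = 0.8
        proto = ProtocolSpec(n_events=1, pairing_dt_ms=10.0, light_on=True,
                             bsr_on=False, light_delay_s=d, baseline_s=10.0,
                             test_s=10.0)
        res = run_protocol(proto, rule)
        dw_syn = weight_change_surface([d], [d], rule)[0, 0]
        # nine of the eleven inputs to SPN 1 are pairing-active
        expected = dw_syn * 9 / 11 / rule.params.w_init * 100.0
        assert res.percent_change == pytest.approx(expected, rel=1e-6)

    def test_surface_has_single_positive_region_and_late_delay_depresses(self, rule):
        grid = np.arange(0.0, 3.01, 0.25)
        surf = weight_change_surface(grid, grid, rule)
        d = np.diag(surf)
        pos = d > 0
        # contiguous positive block along the diagonal
        assert pos.any()
        first, last = np.argmax(pos), len(pos) - 1 - np.argmax(pos[::-1])
        assert pos[first:last + 1].all()
        assert surf[np.searchsorted(grid, 2.5), np.searchsorted(grid, 2.5)] < 0

    def test_dopamine_without_thalamic_signal_never_potentiates(self, rule):
        t = rule.time_grid()
        s = EligibilityState(1, k=rule.params.k, tau_r_s=rule.params.tau_r_s)
        update_eligibility(0.0, 0.010, s)
        da = rule.da_kernel(0.7)(t)
        assert apply_reinforcement(s, t, da, np.zeros_like(t), rule)[0] <= 0

    def test_negative_delay_grid_rejected(self, rule):
        with pytest.raises(ValueError, match="support"):
            weight_change_surface([-0.1, 0.5], [0.5], rule)


class TestNetwork:
    def test_wiring_counts(self):
        net = Network()
        assert net.n_synapses == 22
        assert len(net.synapses_onto(0)) == 11
        assert len(net.synapses_from_program_to(0, 0)) == 9
        assert len(net.synapses_from_program_to(0, 1)) == 2

    def test_quorum_gates_spn_firing(self):
        net = Network()
        assert net.spn_spike_time(net.program_cells(0), 0) is not None
        # crossover alone (two cells) must stay subthreshold
        cross = net.program_cells(0)[-2:]
        assert net.spn_spike_time(cross, 1) is None


class TestActionDiscovery:
    def test_flat_with_zero_rates(self):
        rule = reference_rule(eta_pot=0.0, eta_dep=0.0, kappa_baseline=0.0)
        traj = run_action_discovery(200.0, rule, switch_time_s=100.0, seed=0)
        assert np.all(traj["mean_w_spn1"] == traj["mean_w_spn1"][0])
        assert np.all(traj["mean_w_spn2"] == traj["mean_w_spn2"][0])

    def test_relabeling_swaps_trajectories_exactly(self, rule):
        a = run_action_discovery(400.0, rule, switch_time_s=200.0, seed=4,
                                 program_order=(0, 1))
        b = run_action_discovery(400.0, rule, switch_time_s=200.0, seed=4,
                                 program_order=(1, 0))
        assert np.array_equal(a["mean_w_spn1"], b["mean_w_spn2"])
        assert np.array_equal(a["mean_w_spn2"], b["mean_w_spn1"])

    def test_delayed_reinforcement_fails_to_build_weights(self, rule):
        """Reinforcement at 2.5 s falls outside the eligibility window, so
        the rewarded program's weights do not rise."""
        traj = run_action_discovery(400.0, rule, switch_time_s=399.0, seed=2,
                                    reinforcement_delay_s=2.5)
        assert traj["mean_w_spn1"][-1] <= rule.params.w_init
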