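"""PSP pipeline: exclusion rule, sliding-window slope, binning, cell QC."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rstdp import (ProtocolSpec, QcCriteria, SynthParams,
                   exclude_outlier_traces, generate_recording,
                   normalize_and_bin, psp_slope, qc_cell_health)

FS = 20000.0


def _sweeps(n, length=0.3, base=-80.0, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    t = np.arange(int(length * FS)) / FS
    vm = np.full((n, t.size), base) + rng.normal(0, noise, (n, t.size))
    return t, vm


class TestExclusion:
    def test_identical_trials_all_retained(self):
        t, vm = _sweeps(10)
        inc, frac = exclude_outlier_traces(vm, t, 0.045, 0.25)
        assert inc.all() and frac == 0.0

    def test_single_offset_trial_excluded(self):
        t, vm = _sweeps(12, noise=0.2, seed=1)
        vm[4] += 10 * vm.std()
        inc, frac = exclude_outlier_traces(vm, t, 0.045, 0.25)
        assert not inc[4]
        assert inc.sum() == 11

    def test_checkpoint_outside_trace_raises(self):
        t, vm = _sweeps(5)
        with pytest.raises(ValueError, match="outside"):
            exclude_outlier_traces(vm, t, -1.0, 0.25)

    def test_idempotent_with_frozen_statistics(self):
        """Re-running the rule on the retained set with the original group
        mean/SD excludes nothing further."""
        from rstdp.psp import checkpoint_stats
        t, vm = _sweeps(40, noise=0.5, seed=3)
        vm[[2, 9]] += 12.0
        cps = (0.045, 0.25)
        stats = checkpoint_stats(vm, t, cps)
        inc, _ = exclude_outlier_traces(vm, t, *cps, stats=stats)
        inc2, frac2 = exclude_outlier_traces(vm[inc], t, *cps, stats=stats)
        assert inc2.all() and frac2 == 0.0

    def test_requires_three_trials(self):
        t, vm = _sweeps(2)
        with pytest.raises(ValueError):
            exclude_outlier_traces(vm, t, 0.045, 0.25)


class TestSlope:
    def test_pure_ramp_exact(self):
        t = np.arange(int(0.05 * FS)) / FS
        vm = -80 + 2.0 * np.clip(t - 0.01, 0, None) * 1000
        r = psp_slope(vm, FS, 0.009)
        assert r.ok and r.slope_mv_per_ms == pytest.approx(2.0, rel=1e-6)

    def test_piecewise_ramp_takes_max_window(self):
        """Two-slope rising phase (1 then 3 mV/ms): the sliding-window max
        must report the steeper section."""
        t = np.arange(int(0.05 * FS)) / FS
        vm = -80 + np.where(t < 0.012, np.clip(t - 0.010, 0, None) * 1000,
                            2.0 + 3.0 * (t - 0.012) * 1000)
        r = psp_slope(vm, FS, 0.009, search_limit_ms=8.0)
        assert r.slope_mv_per_ms == pytest.approx(3.0, rel=1e-6)

    def test_first_component_truncation(self):
        """A later, steeper second component beyond the first local maximum
        must not be measured."""
        t = np.arange(int(0.06 * FS)) / FS
        first = np.clip(t - 0.010, 0, 0.003) * 1000.0          # 1 mV/ms, peak 3 mV
        dip = -np.clip(t - 0.013, 0, 0.002) * 500.0            # decay after peak
        second = np.clip(t - 0.020, 0, 0.004) * 5000.0         # 5 mV/ms later comp.
        vm = -80 + first + dip + second
        r = psp_slope(vm, FS, 0.009, search_limit_ms=30.0)
        assert r.slope_mv_per_ms == pytest.approx(1.0, rel=0.05)

    def test_no_depolarization_is_flagged(self):
        t, vm = _sweeps(1, noise=0.05, seed=2)
        r = psp_slope(vm[0], FS, 0.05)
        assert not r.ok and np.isnan(r.slope_mv_per_ms)

    @settings(max_examples=20, deadline=None)
    @given(offset=st.floats(-30, 30), scale=st.floats(0.5, 3))
    def test_offset_invariance_and_linear_scaling(self, offset, scale):
        """Adding a constant leaves the slope unchanged; scaling the trace
        scales the slope linearly."""
        t = np.arange(int(0.04 * FS)) / FS
        vm = -80 + 1.7 * np.clip(t - 0.01, 0, 0.004) * 1000
        base = psp_slope(vm, FS, 0.009).slope_mv_per_ms
        shifted = psp_slope(vm + offset, FS, 0.009).slope_mv_per_ms
        scaled = psp_slope((vm + 80) * scale - 80, FS, 0.009).slope_mv_per_ms
        assert shifted == pytest.approx(base, rel=1e-9)
        assert scaled == pytest.approx(base * scale, rel=1e-6)


class TestNormalizeAndBin:
    @staticmethod
    def _series(slopes_test, slope_base=2.0, n_base=10):
        return pd.DataFrame({
            "trial_time_s": np.arange(n_base + len(slopes_test)) * 10.0,
            "slope_mv_per_ms": np.r_[np.full(n_base, slope_base), slopes_test],
            "included": True,
            "phase": ["baseline"] * n_base + ["test"] * len(slopes_test),
        })

    def test_constant_slopes_give_zero_percent(self):
        out = normalize_and_bin(self._series(np.full(60, 2.0)))
        assert np.allclose(out["mean"], 0.0)

    def test_uniform_factor_gives_uniform_percent(self):
        out = normalize_and_bin(self._series(np.full(60, 2.4)))
        assert np.allclose(out["mean"], 20.0)
        assert len(out) == 2  # 600 s of test trials in 300 s bins

    def test_baseline_mean_percent_change_is_zero(self):
        """The baseline trials' own mean maps to 0% by construction."""
        rng = np.random.default_rng(0)
        base = 2.0 + rng.normal(0, 0.1, 10)
        df = self._series(np.full(6, base.mean()))
        df.loc[df["phase"] == "baseline", "slope_mv_per_ms"] = base
        out = normalize_and_bin(df)
        assert out["mean"].iloc[0] == pytest.approx(0.0, abs=1e-9)

    def test_empty_baseline_raises(self):
        df = self._series(np.full(6, 2.0))
        df.loc[df["phase"] == "baseline", "included"] = False
        with pytest.raises(ValueError, match="baseline"):
            normalize_and_bin(df)


class TestCellHealth:
    @staticmethod
    def _recording(down=-80.0, up=-65.0, with_spike=True):
        proto = ProtocolSpec(n_events=3, event_rate_hz=0.25, pairing_dt_ms=10.0,
                             light_on=False, bsr_on=False, baseline_s=0.0,
                             test_s=0.0)
        p = SynthParams(noise_sd_mv=0.3, dwell_cv=0.0, down_mean_mv=down,
                        up_mean_mv=up, sampling_rate_hz=2000.0, seed=7)
        rec = generate_recording(p, proto)
        if not with_spike:
            rec.events = [(t, k) for t, k in rec.events if k != "spike"]
        return rec

    def test_healthy_recording_passes(self):
        rep = qc_cell_health(self._recording(), input_resistance=[50, 51, 49.5])
        assert rep["overall"] and rep["down_state"] == "pass"

    def test_depolarized_down_state_fails(self):
        rep = qc_cell_health(self._recording(down=-70.0, up=-60.0))
        assert rep["down_state"] == "fail"

    def test_input_resistance_drift_fails(self):
        rep = qc_cell_health(self._recording(), input_resistance=[50, 54, 57.5])
        assert rep["input_resistance"] == "fail"

    def test_missing_spikes_not_evaluable(self):
        rep = qc_cell_health(self._recording(with_spike=False))
        assert rep["action_potential"] == "not_evaluable"
        assert not rep["overall"]

    def test_nonfinite_criteria_rejected(self):
        with pytest.raises(ValueError):
            QcCriteria(down_state_max_mv=np.nan)
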