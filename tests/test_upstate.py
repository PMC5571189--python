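"""Up-state analysis: thresholds, latency extraction, fits, excess probability."""

import numpy as np
import pytest

from rstdp import (SynthParams, estimate_thresholds, excess_probability,
                   extract_latencies, fit_distribution, frozen,
                   generate_recording, sample_latency_pairs,
                   select_distribution)

from conftest import light_only_protocol


class TestThresholds:
    def test_bimodal_equal_occupancy(self):
        vm = np.r_[np.full(1000, -80.0), np.full(1000, -60.0)]
        thr = estimate_thresholds(vm)
        assert (thr.down_level_mv, thr.up_level_mv) == (-80.0, -60.0)
        assert thr.transition_level_mv == -70.0

    def test_uniform_segment_analytic_percentiles(self):
        vm = np.linspace(-80.0, -60.0, 100001)
        thr = estimate_thresholds(vm)
        assert thr.down_level_mv == pytest.approx(-76.0, abs=1e-3)
        assert thr.up_level_mv == pytest.approx(-64.0, abs=1e-3)
        assert thr.transition_level_mv == pytest.approx(-70.0, abs=1e-3)

    def test_constant_segment_raises(self):
        with pytest.raises(ValueError, match="degenerate"):
            estimate_thresholds(np.full(1000, -75.0))

    def test_synthetic_transition_between_state_means(self, noiseless_params,
                                                      quiet_protocol):
        rec = generate_recording(noiseless_params, quiet_protocol)
        thr = estimate_thresholds(rec.vm_mv[:4000])
        assert (noiseless_params.down_mean_mv < thr.transition_level_mv
                < noiseless_params.up_mean_mv)


class TestExtraction:
    def test_degenerate_generator_exact_latencies(self):
        """Light always evokes a transition at 100 ms: every measured light
        latency is 0.100 s to within one sample period."""
        proto = light_only_protocol(30)
        p = SynthParams(noise_sd_mv=0.0, dwell_cv=0.0, osc_freq_hz=0.5,
                        light_evoke_prob=1.0, sampling_rate_hz=2000.0,
                        light_latency_dist=("point", {"value": 0.1}), seed=5)
        ds = extract_latencies(generate_recording(p, proto), seed=0)
        assert ds.n_light >= 10
        assert ds.light_latencies_s == pytest.approx(0.1, abs=2 / 2000)

    def test_up_state_lights_excluded(self):
        """At ~50% duty cycle roughly half the light events fall in the up
        state and are excluded from the dataset."""
        proto = light_only_protocol(80, rate_hz=0.2)
        p = SynthParams(noise_sd_mv=1.5, dwell_cv=0.3, osc_freq_hz=1.0,
                        light_evoke_prob=0.5, sampling_rate_hz=2000.0, seed=6)
        ds = extract_latencies(generate_recording(p, proto), seed=1)
        assert 0 < ds.n_light < 80
        assert 0.25 <= ds.n_light / 80 <= 0.75

    def test_no_qualifying_events_gives_empty_dataset(self, noiseless_params):
        """A recording without light annotations yields an empty, flagged
        dataset rather than an error."""
        rec = generate_recording(noiseless_params, light_only_protocol(3))
        rec.events = [(t, k) for t, k in rec.events if k != "light"]
        ds = extract_latencies(rec, seed=0)
        assert ds.empty and ds.n_light == 0


class TestFitting:
    def test_bic_matches_definition_and_ranking_ties(self):
        x = frozen("exponential", {"scale": 0.3}).rvs(
            size=500, random_state=np.random.default_rng(0))
        fit = fit_distribution(x, "exponential")
        assert fit.bic == pytest.approx(1 * np.log(500) - 2 * fit.loglik)

    def test_nested_family_identity_prefers_fewer_params(self):
        """Weibull with shape 1 is the exponential; at large n the log-lik
        difference vanishes and BIC prefers the 1-parameter family."""
        x = frozen("exponential", {"scale": 0.25}).rvs(
            size=2000, random_state=np.random.default_rng(1))
        fe = fit_distribution(x, "exponential")
        fw = fit_distribution(x, "weibull")
        assert abs(fw.loglik - fe.loglik) < 5.0
        assert fe.bic < fw.bic
        ranked = select_distribution(x, ("exponential", "weibull"))
        assert ranked[0].family == "exponential"

    def test_loglogistic_ranked_first_on_loglogistic_data(self):
        x = frozen("loglogistic", {"shape": 3.0, "scale": 0.12}).rvs(
            size=2000, random_state=np.random.default_rng(2))
        ranked = select_distribution(x)
        assert ranked[0].family == "loglogistic"

    def test_too_few_or_nonpositive_latencies_raise(self):
        with pytest.raises(ValueError):
            fit_distribution([0.1, 0.2, 0.3], "weibull")
        with pytest.raises(ValueError):
            fit_distribution([0.1, 0.2, 0.3, -0.1, 0.5], "weibull")


class TestExcessProbability:
    def test_identical_fits_give_zero(self):
        f = frozen("weibull", {"shape": 1.5, "scale": 0.4})
        assert excess_probability(f, f) == 0.0

    def test_point_mass_bounds(self):
        inside = frozen("point", {"value": 0.1})
        outside = frozen("point", {"value": 0.5})
        assert excess_probability(inside, outside) == 1.0
        assert excess_probability(outside, inside) == -1.0

    def test_antisymmetric_under_swap(self):
        a = frozen("loglogistic", {"shape": 2.5, "scale": 0.19})
        b = frozen("weibull", {"shape": 1.5, "scale": 0.40})
        assert excess_probability(a, b) == pytest.approx(
            -excess_probability(b, a))

    def test_invalid_window_raises(self):
        f = frozen("weibull", {"shape": 1.5, "scale": 0.4})
        with pytest.raises(ValueError):
            excess_probability(f, f, window=(0.2, 0.1))

    def test_sampled_estimate_tracks_analytic_value(self):
        """Fitting n=177 sampled pairs recovers the analytic CDF excess of
        the generating distributions."""
        light = ("loglogistic", {"shape": 2.5, "scale": 0.19})
        rand = ("weibull", {"shape": 1.5, "scale": 0.40})
        truth = excess_probability(frozen(*light), frozen(*rand))
        ds = sample_latency_pairs(light, rand, 177, seed=3)
        est = excess_probability(fit_distribution(ds.light_latencies_s, "loglogistic"),
                                 fit_distribution(ds.random_latencies_s, "weibull"))
        assert est == pytest.approx(truth, abs=0.08)
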