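"""Synthetic intracellular recordings with the statistics the analyses assume.

Striatal spiny projection neurons (SPNs) under urethane anesthesia alternate
slowly (0.5-2 Hz) between a hyperpolarized *down state* (below about -75 mV)
and a depolarized *up state*.  Cortical stimulation evokes a PSP of >= 5 mV
rising ~5 ms after the stimulus; a reward-conditioned light flash delivered
during a down state can trigger an early transition to the up state.  This
module generates membrane-potential time series with exactly those features,
plus per-trial PSP sweeps with controllable slope drift (the "plasticity"),
so that every downstream pipeline stage can be tested against known ground
truth.

The generator is deliberately stylized:

* the up/down alternation is a two-state semi-Markov process with gamma dwell
  times (mean 1/(2 f) per state, coefficient of variation ``dwell_cv``);
  state transitions are instantaneous steps;
* a light flash falling in a down state triggers, with probability
  ``light_evoke_prob``, an up transition at a latency drawn from a named
  distribution; the forced transition *replaces* the next spontaneous one;
* spikes are 2 ms triangles of ~60 mV, used only by QC checks;
* noise is additive white Gaussian.

Setting ``noise_sd_mv = 0`` and ``dwell_cv = 0`` gives the exact noiseless
limit in which every generated quantity equals its configured value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np

from .distributions import frozen
from .protocols import Event, ProtocolSpec
from .upstate import LatencyDataset

__all__ = [
    "MembraneRecording",
    "SynthParams",
    "PspTrialSet",
    "generate_recording",
    "generate_psp_trial_set",
    "sample_latency_pairs",
]


@dataclass
class MembraneRecording:
    """Annotated membrane-potential time series.

    ``time_s`` is uniform (default 20 kHz sampling), ``vm_mv`` is in
    millivolts, and ``events`` carries the protocol annotations
    (cortical_stim, light, bsr, spike, trial_start).  ``truth`` holds
    generator-only ground truth (state segments, which light events evoked a
    transition) and is not part of the serialized record.
    """

    time_s: np.ndarray
    vm_mv: np.ndarray
    events: List[Event]
    sampling_rate_hz: float
    duration_s: float
    seed: Optional[int] = None
    truth: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.vm_mv = np.asarray(self.vm_mv, dtype=float)
        if self.time_s.ndim != 1 or self.time_s.shape != self.vm_mv.shape:
            raise ValueError("time_s and vm_mv must be 1-D arrays of equal length")
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        steps = np.diff(self.time_s)
        if len(steps) and (steps.min() <= 0 or not np.allclose(
                steps, 1.0 / self.sampling_rate_hz, rtol=1e-6, atol=1e-12)):
            raise ValueError("time axis must be strictly increasing and uniform")
        if not np.all(np.isfinite(self.vm_mv)):
            raise ValueError("vm contains non-finite values")
        for t, kind in self.events:
            if not (0.0 <= t <= self.duration_s + 1e-9):
                raise ValueError(f"event ({t}, {kind}) outside [0, duration]")

    @property
    def meta(self) -> dict:
        return {
            "sampling_rate_hz": self.sampling_rate_hz,
            "duration_s": self.duration_s,
            "seed": self.seed,
        }

    def event_times(self, kind: str) -> np.ndarray:
        return np.array([t for t, k in self.events if k == kind], dtype=float)

    def sample_index(self, t: float) -> int:
        return int(round(t * self.sampling_rate_hz))


@dataclass
class SynthParams:
    """Generator configuration; defaults emulate the recording conditions."""

    osc_freq_hz: float = 1.0
    down_mean_mv: float = -80.0
    up_mean_mv: float = -65.0
    noise_sd_mv: float = 1.0
    dwell_cv: float = 0.2
    psp_amp_mv: float = 6.0
    psp_latency_ms: float = 5.2
    psp_slope_mv_per_ms: float = 1.7
    psp_decay_ms: float = 30.0
    light_evoke_prob: float = 0.5
    light_latency_dist: Tuple[str, dict] = ("loglogistic", None)
    plasticity_drift: Union[float, Sequence[float]] = 1.0
    spike_amp_mv: float = 60.0
    spike_width_ms: float = 2.0
    sampling_rate_hz: float = 20000.0
    seed: int = 0

    def __post_init__(self):
        if self.light_latency_dist[1] is None:
            self.light_latency_dist = ("loglogistic", {"shape": 3.0, "scale": 0.12})
        if not (0.5 <= self.osc_freq_hz <= 2.0):
            raise ValueError("osc_freq_hz must lie in [0.5, 2] Hz")
        if self.down_mean_mv >= self.up_mean_mv:
            raise ValueError("down_mean_mv must be below up_mean_mv")
        if not (0.0 <= self.light_evoke_prob <= 1.0):
            raise ValueError("light_evoke_prob must lie in [0, 1]")
        if self.psp_amp_mv <= 0:
            raise ValueError("psp_amp_mv must be positive")
        if self.psp_slope_mv_per_ms <= 0:
            raise ValueError("psp_slope_mv_per_ms must be positive")
        if self.noise_sd_mv < 0 or self.dwell_cv < 0:
            raise ValueError("noise_sd_mv and dwell_cv must be >= 0")
        # fail fast on an unknown latency distribution name
        frozen(*self.light_latency_dist)


def _dwell(rng: np.random.Generator, mean: float, cv: float) -> float:
    """One gamma dwell time with the requested mean and CV (CV=0: exact)."""
    if cv == 0:
        return mean
    shape = 1.0 / cv**2
    return float(rng.gamma(shape, mean / shape))


def _state_segments(params: SynthParams, duration_s: float,
                    light_times: np.ndarray, rng: np.random.Generator):
    """Build the up/down timeline, letting light events force transitions.

    Returns (segments, evoked) where segments is a list of
    (state, t_start, t_end) with state in {"down", "up"} and evoked is the
    list of (light_time, forced_transition_time) pairs.
    """
    mean_dwell = 0.5 / params.osc_freq_hz
    latency_dist = frozen(*params.light_latency_dist)
    segments: List[Tuple[str, float, float]] = []
    evoked: List[Tuple[float, float]] = []
    lights = list(np.sort(light_times))
    li = 0
    t, state = 0.0, "down"
    while t < duration_s:
        end = t + _dwell(rng, mean_dwell, params.dwell_cv)
        if state == "down":
            # lights landing in this down segment may force its end
            forced = None
            while li < len(lights) and lights[li] < min(end, duration_s):
                lt = lights[li]
                if forced is not None and lt >= forced:
                    break  # light falls after the forced transition: next segment
                li += 1
                if rng.random() < params.light_evoke_prob:
                    lat = float(latency_dist.rvs(random_state=rng))
                    cand = lt + lat
                    if forced is None or cand < forced:
                        forced = cand
                        evoked.append((lt, cand))
            if forced is not None:
                end = forced  # overrides the next spontaneous transition
        else:
            while li < len(lights) and lights[li] < min(end, duration_s):
                li += 1  # light in up state: no effect
        segments.append((state, t, min(end, duration_s)))
        t = end
        state = "up" if state == "down" else "down"
    return segments, evoked


def _add_psp(vm: np.ndarray, fs: float, onset_s: float, amp: float,
             slope_mv_per_ms: float, decay_ms: float):
    """Add a ramp-then-exponential PSP starting at onset_s (in place)."""
    i0 = int(round(onset_s * fs))
    if i0 >= len(vm):
        return
    rise_s = (amp / slope_mv_per_ms) / 1000.0
    n_rise = max(1, int(round(rise_s * fs)))
    t = np.arange(len(vm) - i0) / fs
    wave = np.where(
        t <= rise_s,
        slope_mv_per_ms * t * 1000.0,
        amp * np.exp(-(t - rise_s) / (decay_ms / 1000.0)),
    )
    # keep the ramp exact up to the configured amplitude
    wave[: n_rise + 1] = np.minimum(wave[: n_rise + 1], amp)
    vm[i0:] += wave


def _add_spike(vm: np.ndarray, fs: float, t_s: float, amp: float, width_ms: float):
    i0 = int(round(t_s * fs))
    half = max(1, int(round(width_ms / 2000.0 * fs)))
    for j in range(-half, half + 1):
        i = i0 + j
        if 0 <= i < len(vm):
            vm[i] += amp * (1.0 - abs(j) / half)


def generate_recording(params: SynthParams, protocol: ProtocolSpec) -> MembraneRecording:
    """Generate one annotated membrane-potential recording.

    The protocol's event schedule is embedded in the trace: each
    ``cortical_stim`` is followed by a PSP of the configured slope/amplitude
    at ``psp_latency_ms``; each ``light`` falling in a down state triggers,
    with probability ``light_evoke_prob``, an up transition at a latency
    drawn from ``light_latency_dist``; ``spike`` events add stylized action
    potentials.  Identical (params, protocol) including the seed give
    bit-identical output.

    Raises
    ------
    ValueError
        If any protocol event lies beyond the protocol duration, or the
        latency distribution name is unknown.
    """
    events = protocol.events()
    duration = float(protocol.duration_s)
    late = [ev for ev in events if ev[0] > duration]
    if late:
        raise ValueError(
            f"duration {duration} s too short for protocol: event at {late[0][0]} s")

    fs = params.sampling_rate_hz
    rng = np.random.default_rng(params.seed)
    n = int(round(duration * fs)) + 1
    time = np.arange(n) / fs

    light_times = np.array([t for t, k in events if k == "light"], dtype=float)
    segments, evoked = _state_segments(params, duration, light_times, rng)

    vm = np.full(n, params.down_mean_mv)
    for state, t0, t1 in segments:
        if state == "up":
            vm[int(round(t0 * fs)): int(round(t1 * fs)) + 1] = params.up_mean_mv

    drift = params.plasticity_drift
    stim_times = [t for t, k in events if k == "cortical_stim"]
    for k_trial, ts in enumerate(stim_times):
        d = drift if np.isscalar(drift) else drift[min(k_trial, len(drift) - 1)]
        _add_psp(vm, fs, ts + params.psp_latency_ms / 1000.0,
                 params.psp_amp_mv * d, params.psp_slope_mv_per_ms * d,
                 params.psp_decay_ms)
    for t, k in events:
        if k == "spike":
            _add_spike(vm, fs, t, params.spike_amp_mv, params.spike_width_ms)

    if params.noise_sd_mv > 0:
        vm = vm + rng.normal(0.0, params.noise_sd_mv, size=n)

    return MembraneRecording(
        time_s=time, vm_mv=vm, events=events,
        sampling_rate_hz=fs, duration_s=duration, seed=params.seed,
        truth={"segments": segments, "evoked_lights": evoked},
    )


@dataclass
class PspTrialSet:
    """Per-trial PSP sweeps with generator ground truth."""

    time_s: np.ndarray          # shared time axis, one sweep
    traces: np.ndarray          # (n_trials, n_samples) vm in mV
    stim_time_s: float
    true_slopes: np.ndarray     # configured maximal initial slope per trial
    artifact: np.ndarray        # bool: trial carries an injected baseline shift

    @property
    def n_trials(self) -> int:
        return self.traces.shape[0]


def generate_psp_trial_set(params: SynthParams, n_trials: int,
                           drift: Sequence[float],
                           artifact_fraction: float = 0.0,
                           artifact_amp_mv: float = 10.0,
                           trial_duration_s: float = 0.30,
                           stim_time_s: float = 0.05) -> PspTrialSet:
    """Generate a set of single-trial PSP sweeps.

    Trial ``k`` carries a PSP whose maximal initial slope is
    ``psp_slope_mv_per_ms * drift[k]`` (exact in the noiseless case).  A
    Bernoulli(``artifact_fraction``) subset of trials is contaminated with a
    whole-sweep baseline shift of ``+/- artifact_amp_mv`` emulating
    spontaneous membrane fluctuations, which the exclusion stage should
    remove.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    drift = np.asarray(drift, dtype=float)
    if drift.shape != (n_trials,):
        raise ValueError("drift must have length n_trials")
    if np.any(drift * params.psp_slope_mv_per_ms < 0) or np.any(drift < 0):
        raise ValueError("negative PSP slope requested")
    if not (0.0 <= artifact_fraction <= 1.0):
        raise ValueError("artifact_fraction must lie in [0, 1]")

    fs = params.sampling_rate_hz
    rng = np.random.default_rng(params.seed)
    n = int(round(trial_duration_s * fs)) + 1
    time = np.arange(n) / fs

    traces = np.full((n_trials, n), params.down_mean_mv)
    artifact = rng.random(n_trials) < artifact_fraction
    signs = np.where(rng.random(n_trials) < 0.5, -1.0, 1.0)
    for k in range(n_trials):
        _add_psp(traces[k], fs, stim_time_s + params.psp_latency_ms / 1000.0,
                 params.psp_amp_mv * drift[k],
                 params.psp_slope_mv_per_ms * drift[k], params.psp_decay_ms)
        if artifact[k]:
            traces[k] += signs[k] * artifact_amp_mv
    if params.noise_sd_mv > 0:
        traces = traces + rng.normal(0.0, params.noise_sd_mv, size=traces.shape)

    return PspTrialSet(time_s=time, traces=traces, stim_time_s=stim_time_s,
                       true_slopes=params.psp_slope_mv_per_ms * drift,
                       artifact=artifact)


def sample_latency_pairs(light_dist: Tuple[str, dict], random_dist: Tuple[str, dict],
                         n: int, seed: int = 0) -> LatencyDataset:
    """Draw paired light-evoked and random-control latency samples.

    ``n`` i.i.d. latencies from each named positive-support distribution,
    reproducible under ``seed``.  This bypasses the trace-level generator and
    samples the latency distributions directly, for tests of the fitting,
    Kuiper and excess-probability machinery.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    light = np.asarray(frozen(*light_dist).rvs(size=n, random_state=rng), dtype=float)
    rand = np.asarray(frozen(*random_dist).rvs(size=n, random_state=rng), dtype=float)
    return LatencyDataset(light_latencies_s=light, random_latencies_s=rand, paired=True)
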