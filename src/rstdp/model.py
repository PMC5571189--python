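"""Spiking corticostriatal model with reward-modulated eligibility-trace STDP.

Two populations of 11 cortical cells, each encoding a motor program, project
onto two striatal spiny projection neurons (SPNs): program A to SPN 1 and
program B to SPN 2, with a crossover of two cells from each population to
the other SPN.  A synchronous program activation that drives its SPN to fire
within ~10 ms constitutes a positive STDP pairing and seeds a *potentiation
eligibility trace* on the active synapses; a post-before-pre pairing seeds a
*depression trace*.  The trace waveform is

    e(t) = (t / tau_r)**k * exp(k * (1 - t / tau_r)),   t >= 0,

a smooth bump peaking at 1 at t = tau_r and decayed to well under 1% of peak
by 3 s.  Delayed reinforcement consists of a dopamine transient and a
depolarizing thalamic transient, each modeled as the response of a pair of
chained leaky integrators (peak-normalized difference of exponentials).
Weight change for one pairing integrates the trace against the *conjunction*
(pointwise minimum) of the two reinforcement signals:

    dw = eta_pot * a2a * integral(e_pot * min(DA, Th))
       - eta_dep *        integral(e_dep * min(DA, Th))
       - kappa   * 1[potentiation trace seeded and conjunction ~ absent]

so potentiation requires *both* signals inside the eligibility window;
dopamine or thalamic input alone, absent reinforcement, or reinforcement
arriving too late all leave the kappa drift, matching the minor depression
seen with unreinforced positive pairings.  A conditioned light evokes both
signals, scaled by a habituation factor that decays when the light is
presented without subsequent primary reward (BSR) and resets when the
pairing is restored; BSR itself evokes dopamine only.

Reference constants live in ``rstdp/data/reference.yaml``.  The eligibility
shape (k = 12, tau_r = 0.90 s) was fixed by a calibration scan of the
equal-delay weight-change surface so that the half-maximum potentiation
window spans ~0.4 to ~1.1 s of reinforcement delay
(``analysis/04_surface_calibration.py`` reproduces the scan).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import yaml

from .protocols import ProtocolSpec

__all__ = [
    "LifNeuron",
    "SignalKernel",
    "EligibilityState",
    "PlasticityRuleParams",
    "PlasticityRule",
    "Network",
    "ProtocolResult",
    "simulate_lif",
    "reinforcement_kernel",
    "update_eligibility",
    "apply_reinforcement",
    "run_protocol",
    "weight_change_surface",
    "diagonal_half_max",
    "run_action_discovery",
    "reference_rule",
    "reference_network",
    "load_reference_config",
]


# ---------------------------------------------------------------------------
# leaky integrate-and-fire neuron
# ---------------------------------------------------------------------------

@dataclass
class LifNeuron:
    """LIF unit in dimensionless membrane units (rest = 0)."""

    tau_m: float = 0.02
    v_thresh: float = 1.0
    v_reset: float = 0.0
    refractory_s: float = 0.005

    def __post_init__(self):
        if self.tau_m <= 0:
            raise ValueError("tau_m must be positive")
        if self.v_reset >= self.v_thresh:
            raise ValueError("v_reset must be below v_thresh")

    def isi_constant_input(self, i_const: float) -> float:
        """Closed-form inter-spike interval for constant suprathreshold input."""
        if i_const <= self.v_thresh:
            return np.inf
        return self.refractory_s + self.tau_m * np.log(
            (i_const - self.v_reset) / (i_const - self.v_thresh))


def simulate_lif(neuron: LifNeuron, current: np.ndarray, dt: float,
                 v0: Optional[float] = None) -> Tuple[np.ndarray, np.ndarray]:
    """Integrate a LIF neuron driven by an input-current series.

    Exponential-Euler update (exact for piecewise-constant input); a spike
    is emitted at threshold crossing, the potential resets and the
    refractory period is honored.  Returns ``(spike_times, v_trajectory)``.
    """
    if dt > neuron.tau_m / 10:
        raise ValueError("dt must be <= tau_m / 10 for a faithful trajectory")
    current = np.asarray(current, dtype=float)
    decay = np.exp(-dt / neuron.tau_m)
    v = neuron.v_reset if v0 is None else float(v0)
    refr_steps = int(round(neuron.refractory_s / dt))
    refr = 0
    traj = np.empty_like(current)
    spikes = []
    for i, inp in enumerate(current):
        if refr > 0:
            refr -= 1
            v = neuron.v_reset
        else:
            v = inp + (v - inp) * decay
            if v >= neuron.v_thresh:
                spikes.append(i * dt)
                v = neuron.v_reset
                refr = refr_steps
        traj[i] = v
    return np.array(spikes), traj


# ---------------------------------------------------------------------------
# reinforcement signal kernels
# ---------------------------------------------------------------------------

@dataclass
class SignalKernel:
    """Chained-leaky-integrator response: peak-normalized rise/decay bump."""

    kind: str = "dopamine"
    tau_rise_s: float = 0.05
    tau_decay_s: float = 0.30
    amplitude: float = 1.0
    onset_delay_s: float = 0.0

    def __post_init__(self):
        if self.tau_rise_s > self.tau_decay_s:
            raise ValueError("tau_rise must be <= tau_decay")

    @property
    def peak_time_s(self) -> float:
        """Time of the kernel maximum after onset (closed form)."""
        tr, td = self.tau_rise_s, self.tau_decay_s
        if np.isclose(tr, td):
            return tr  # alpha-function limit
        return np.log(td / tr) / (1.0 / tr - 1.0 / td)

    def _peak_value_unnormalized(self) -> float:
        tr, td = self.tau_rise_s, self.tau_decay_s
        tp = self.peak_time_s
        if np.isclose(tr, td):
            return 1.0  # alpha form below is already peak-normalized
        return np.exp(-tp / td) - np.exp(-tp / tr)

    def __call__(self, t) -> np.ndarray:
        """Kernel value at times ``t`` (zero before onset, peak = amplitude)."""
        t = np.asarray(t, dtype=float) - self.onset_delay_s
        tr, td = self.tau_rise_s, self.tau_decay_s
        tp = np.clip(t, 0.0, None)
        if np.isclose(tr, td):
            out = (tp / tr) * np.exp(1.0 - tp / tr)
        else:
            out = (np.exp(-tp / td) - np.exp(-tp / tr)) / self._peak_value_unnormalized()
        return self.amplitude * np.where(t >= 0, out, 0.0)

    def analytic_integral(self) -> float:
        """Closed-form integral of the kernel over [onset, infinity)."""
        tr, td = self.tau_rise_s, self.tau_decay_s
        if np.isclose(tr, td):
            return self.amplitude * np.e * tr  # integral of (t/tau) e^(1-t/tau)
        return self.amplitude * (td - tr) / self._peak_value_unnormalized()


def reinforcement_kernel(kind: str, t_event: float, params: "PlasticityRuleParams",
                         t_grid: np.ndarray, amplitude: float = 1.0) -> np.ndarray:
    """Evaluate the dopamine or thalamic kernel with onset at ``t_event``."""
    if kind == "dopamine":
        k = SignalKernel("dopamine", params.da_tau_rise_s, params.da_tau_decay_s,
                         amplitude, t_event)
    elif kind == "thalamic":
        k = SignalKernel("thalamic", params.th_tau_rise_s, params.th_tau_decay_s,
                         amplitude, t_event)
    else:
        raise ValueError(f"unknown kernel kind {kind!r}")
    return k(t_grid)


# ---------------------------------------------------------------------------
# eligibility traces
# ---------------------------------------------------------------------------

@dataclass
class EligibilityState:
    """Per-synapse potentiation/depression eligibility traces.

    Each registered pairing seeds a copy of the trace waveform on the
    synapses it involves; waveforms from multiple pairings superpose
    additively.  Traces are dimensionless with unit peak per pairing.
    """

    n_synapses: int
    k: float = 12.0
    tau_r_s: float = 0.90
    pairing_window_ms: float = 30.0
    seeds_pot: List[Tuple[float, np.ndarray]] = field(default_factory=list)
    seeds_dep: List[Tuple[float, np.ndarray]] = field(default_factory=list)

    def waveform(self, t) -> np.ndarray:
        t = np.clip(np.asarray(t, dtype=float), 0.0, None)
        x = t / self.tau_r_s
        return x**self.k * np.exp(self.k * (1.0 - x))

    def _trace(self, seeds, t_grid) -> np.ndarray:
        out = np.zeros((self.n_synapses, len(t_grid)))
        for t_seed, amps in seeds:
            out += amps[:, None] * self.waveform(np.asarray(t_grid) - t_seed)[None, :]
        return out

    def e_pot(self, t_grid) -> np.ndarray:
        return self._trace(self.seeds_pot, t_grid)

    def e_dep(self, t_grid) -> np.ndarray:
        return self._trace(self.seeds_dep, t_grid)

    @property
    def pot_seeded(self) -> np.ndarray:
        mask = np.zeros(self.n_synapses, dtype=bool)
        for _, amps in self.seeds_pot:
            mask |= amps > 0
        return mask


def update_eligibility(t_pre: float, t_post: float, state: EligibilityState,
                       synapses: Optional[Sequence[int]] = None,
                       amplitude: float = 1.0) -> EligibilityState:
    """Register one pre/post spike pairing on the given synapses.

    Pre-before-post within the pairing window (0 < dt <= 30 ms) seeds the
    potentiation trace; post-before-pre seeds the depression trace with the
    same waveform.  Pairs outside the window are no-ops.  The trace starts
    at the later spike of the pair.
    """
    dt_ms = (t_post - t_pre) * 1000.0
    amps = np.zeros(state.n_synapses)
    idx = np.arange(state.n_synapses) if synapses is None else np.asarray(synapses)
    amps[idx] = amplitude
    t_seed = max(t_pre, t_post)
    if 0.0 < dt_ms <= state.pairing_window_ms:
        state.seeds_pot.append((t_seed, amps))
    elif -state.pairing_window_ms <= dt_ms < 0.0:
        state.seeds_dep.append((t_seed, amps))
    return state


# ---------------------------------------------------------------------------
# plasticity rule
# ---------------------------------------------------------------------------

@dataclass
class PlasticityRuleParams:
    """Reference parameterization of the reinforcement-modulated rule.

    The YAML file ``rstdp/data/reference.yaml`` is the authoritative copy of
    these constants; :func:`reference_rule` loads it.
    """

    k: float = 12.0
    tau_r_s: float = 0.90
    pairing_window_ms: float = 30.0
    da_tau_rise_s: float = 0.05
    da_tau_decay_s: float = 0.30
    th_tau_rise_s: float = 0.03
    th_tau_decay_s: float = 0.20
    eta_pot: float = 0.0028
    eta_dep: float = 0.0037
    kappa_baseline: float = 0.0006
    theta_conj: float = 0.10
    habituation_tau_events: float = 8.0
    novelty_da_events: int = 5
    da_block_scale: float = 1.0
    a2a_block_scale: float = 1.0
    w_min: float = 0.0
    w_max: float = 1.0
    w_init: float = 0.5
    dt_integral_s: float = 0.010
    horizon_s: float = 6.0

    def __post_init__(self):
        for name in ("eta_pot", "eta_dep", "kappa_baseline"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("da_block_scale", "a2a_block_scale"):
            if not (0.0 <= getattr(self, name) <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.w_min >= self.w_max:
            raise ValueError("w_min must be below w_max")


class PlasticityRule:
    """Rule engine: kernels, eligibility waveform, and weight updates.

    Conjunction integrals are normalized by the peak of the equal-delay
    conjunction curve (cached once per instance), so ``eta_pot`` is the
    weight change per pairing at the optimal reinforcement delay.
    """

    def __init__(self, params: PlasticityRuleParams):
        self.params = params
        self._c_ref: Optional[float] = None

    def da_kernel(self, onset: float = 0.0, amplitude: float = 1.0) -> SignalKernel:
        p = self.params
        return SignalKernel("dopamine", p.da_tau_rise_s, p.da_tau_decay_s,
                            amplitude, onset)

    def th_kernel(self, onset: float = 0.0, amplitude: float = 1.0) -> SignalKernel:
        p = self.params
        return SignalKernel("thalamic", p.th_tau_rise_s, p.th_tau_decay_s,
                            amplitude, onset)

    def time_grid(self) -> np.ndarray:
        p = self.params
        return np.arange(0.0, p.horizon_s + p.dt_integral_s / 2, p.dt_integral_s)

    def _new_state(self, n_synapses: int = 1) -> EligibilityState:
        p = self.params
        return EligibilityState(n_synapses=n_synapses, k=p.k, tau_r_s=p.tau_r_s,
                                pairing_window_ms=p.pairing_window_ms)

    def conjunction_integral(self, d_da: float, d_th: float,
                             amp_da: float = 1.0, amp_th: float = 1.0,
                             t_pair: float = 0.0) -> float:
        """Raw integral of the eligibility trace against min(DA, Th)."""
        t = self.time_grid()
        e = self._new_state(1).waveform(t - t_pair)
        conj = np.minimum(self.da_kernel(d_da, amp_da)(t),
                          self.th_kernel(d_th, amp_th)(t))
        return float(np.trapezoid(e * conj, t))

    @property
    def c_ref(self) -> float:
        """Peak of the equal-delay conjunction curve (normalization)."""
        if self._c_ref is None:
            d = np.arange(0.0, 3.0001, 0.02)
            self._c_ref = max(self.conjunction_integral(x, x) for x in d)
        return self._c_ref


def apply_reinforcement(state: EligibilityState, t_grid: np.ndarray,
                        da_series: np.ndarray, th_series: np.ndarray,
                        rule: PlasticityRule) -> np.ndarray:
    """Per-synapse weight change for one inter-event interval.

    Integrates each synapse's potentiation and depression traces against
    the conjunction min(DA, Th) of the reinforcement series, and applies the
    baseline drift ``kappa`` to synapses whose potentiation trace was seeded
    but whose conjunction drive stayed below ``theta_conj`` of the optimal
    drive (reinforcement absent, individual, or outside the window).
    """
    p = rule.params
    conj = np.minimum(np.asarray(da_series, dtype=float),
                      np.asarray(th_series, dtype=float))
    drive_pot = np.trapezoid(state.e_pot(t_grid) * conj[None, :], t_grid, axis=1)
    drive_dep = np.trapezoid(state.e_dep(t_grid) * conj[None, :], t_grid, axis=1)
    cn_pot = drive_pot / rule.c_ref
    cn_dep = drive_dep / rule.c_ref
    failed = state.pot_seeded & (cn_pot < p.theta_conj)
    dw = (p.eta_pot * p.a2a_block_scale * cn_pot
          - p.eta_dep * cn_dep
          - p.kappa_baseline * failed)
    return dw


# ---------------------------------------------------------------------------
# network
# ---------------------------------------------------------------------------

@dataclass
class Network:
    """Two cortical programs of 11 cells onto two SPNs with 2-cell crossover.

    Synapse ``s`` connects cortical cell ``pre_cell[s]`` to SPN
    ``post_spn[s]``.  Cells 0..10 form program A, 11..21 program B; the last
    ``n_crossover`` cells of each program project to the other SPN.
    """

    n_per_program: int = 11
    n_crossover: int = 2
    w_init: float = 0.5
    w_min: float = 0.0
    w_max: float = 1.0
    spn: LifNeuron = field(default_factory=LifNeuron)
    syn_tau_s: float = 0.005
    quorum_sum_w: float = 2.0

    def __post_init__(self):
        npp, nx = self.n_per_program, self.n_crossover
        pre, post = [], []
        for prog, spn_own in ((0, 0), (1, 1)):
            for c in range(npp):
                cell = prog * npp + c
                pre.append(cell)
                post.append(spn_own if c < npp - nx else 1 - spn_own)
        self.pre_cell = np.array(pre)
        self.post_spn = np.array(post)
        self.weights = np.full(len(pre), float(self.w_init))

    @property
    def n_synapses(self) -> int:
        return len(self.weights)

    def program_cells(self, program: int) -> np.ndarray:
        npp = self.n_per_program
        return np.arange(program * npp, (program + 1) * npp)

    def synapses_onto(self, spn: int) -> np.ndarray:
        return np.nonzero(self.post_spn == spn)[0]

    def synapses_from_program_to(self, program: int, spn: int) -> np.ndarray:
        cells = set(self.program_cells(program))
        return np.nonzero([(self.pre_cell[s] in cells) and self.post_spn[s] == spn
                           for s in range(self.n_synapses)])[0]

    def mean_weight(self, spn: int) -> float:
        # canonical (sorted) summation order so that relabeling the programs
        # with the same seed swaps the two means bit-exactly
        w = np.sort(self.weights[self.synapses_onto(spn)])
        return float(w.sum() / w.size)

    def apply_dw(self, dw: np.ndarray):
        self.weights = np.clip(self.weights + dw, self.w_min, self.w_max)

    def spn_drive(self, active_cells: np.ndarray, spn: int) -> float:
        """Summed synaptic weight from the active cells onto one SPN."""
        mask = np.isin(self.pre_cell, active_cells) & (self.post_spn == spn)
        return float(self.weights[mask].sum())

    def spn_spike_time(self, active_cells: np.ndarray, spn: int,
                       dt: float = 0.001, t_max: float = 0.05) -> Optional[float]:
        """Simulate the SPN's LIF response to a synchronous volley.

        The volley injects an exponentially decaying current whose gain is
        set so the neuron reaches threshold iff the summed active weight
        exceeds ``quorum_sum_w`` (crossover inputs alone stay subthreshold).
        Returns the spike time after the volley, or None.
        """
        drive = self.spn_drive(active_cells, spn)
        t = np.arange(0.0, t_max, dt)
        unit = np.exp(-t / self.syn_tau_s)
        # peak subthreshold response per unit drive (filtered by the membrane)
        _, v_unit = simulate_lif(replace(self.spn, v_thresh=np.inf), unit, dt)
        gain = self.spn.v_thresh / (np.max(v_unit) * self.quorum_sum_w)
        spikes, _ = simulate_lif(self.spn, gain * drive * unit, dt)
        return float(spikes[0]) if spikes.size else None


# ---------------------------------------------------------------------------
# protocol simulation
# ---------------------------------------------------------------------------

@dataclass
class ProtocolResult:
    """Weight trajectory and phase summary for one protocol condition."""

    times_s: np.ndarray
    mean_weights: np.ndarray         # mean weight of inputs to the recorded SPN
    phase: List[str]                 # phase label per sample
    baseline_mean: float
    test_mean: float
    peak_pairing: float

    @property
    def percent_change(self) -> float:
        return 100.0 * (self.test_mean - self.baseline_mean) / self.baseline_mean

    @property
    def peak_percent_change(self) -> float:
        return 100.0 * (self.peak_pairing - self.baseline_mean) / self.baseline_mean


def _light_amplitudes(event_idx: int, h: float, p: PlasticityRuleParams,
                      lesioned: bool) -> Tuple[float, float]:
    """DA and thalamic amplitudes evoked by one light flash."""
    da = 1.0 if event_idx < p.novelty_da_events else h
    th = 0.0 if lesioned else h
    return p.da_block_scale * da, th


def run_protocol(protocol: ProtocolSpec, rule: PlasticityRule,
                 network: Optional[Network] = None) -> ProtocolResult:
    """Execute one plasticity-protocol condition and track mean weight.

    Baseline phase: PSP test pulses only, no pairing or reward (weights
    constant).  Pairing phase: ``n_events`` trials; each seeds an
    eligibility trace via the configured +/-10 ms pairing and receives the
    condition's reinforcement components (light-evoked DA + thalamic input,
    BSR-evoked DA) with habituation of the light when unpaired with BSR.
    Test phase: weights constant again.  The recorded quantity is the mean
    synaptic weight of inputs to SPN 1.
    """
    p = rule.params
    net = network if network is not None else Network(
        w_init=p.w_init, w_min=p.w_min, w_max=p.w_max)
    t_grid = rule.time_grid()
    shift = protocol.reinforcement_delay_shift_s

    # pairing-active synapses: program A cells onto the recorded SPN 1 (index 0)
    active_cells = net.program_cells(0)
    seeded_synapses = net.synapses_from_program_to(0, 0)

    times, weights, phases = [0.0], [net.mean_weight(0)], ["baseline"]
    h = 1.0
    peak = net.mean_weight(0)
    for idx, t_ev in enumerate(protocol.trial_times()):
        state = rule._new_state(net.n_synapses)
        if protocol.pairing_dt_ms:
            update_eligibility(0.0, protocol.pairing_dt_ms / 1000.0, state,
                               synapses=seeded_synapses)
        da = np.zeros_like(t_grid)
        th = np.zeros_like(t_grid)
        if protocol.light_on:
            amp_da, amp_th = _light_amplitudes(idx, h, p, protocol.thalamus_lesioned)
            onset = protocol.light_delay_s + shift
            da += rule.da_kernel(onset, amp_da)(t_grid)
            th += rule.th_kernel(onset, amp_th)(t_grid)
            h = 1.0 if protocol.bsr_on else h * np.exp(-1.0 / p.habituation_tau_events)
        if protocol.bsr_on:
            da += rule.da_kernel(protocol.bsr_delay_s + shift, p.da_block_scale)(t_grid)
        net.apply_dw(apply_reinforcement(state, t_grid, da, th, rule))
        w = net.mean_weight(0)
        peak = max(peak, w)
        times.append(t_ev + protocol.pairing_period_s)
        weights.append(w)
        phases.append("pairing")
    times.append(protocol.duration_s)
    weights.append(net.mean_weight(0))
    phases.append("test")

    return ProtocolResult(
        times_s=np.array(times), mean_weights=np.array(weights), phase=phases,
        baseline_mean=weights[0], test_mean=weights[-1], peak_pairing=peak)


# ---------------------------------------------------------------------------
# weight-change surface (single positive pairing)
# ---------------------------------------------------------------------------

def weight_change_surface(t_da: np.ndarray, t_th: np.ndarray,
                          rule: PlasticityRule,
                          pairing_dt_s: float = 0.010) -> np.ndarray:
    """Weight change for a single +10 ms pairing on a DA x Th delay grid.

    Entry [i, j] is the predicted dw when dopamine arrives at delay
    ``t_da[i]`` and the thalamic signal at ``t_th[j]`` after the pairing.
    The eligibility trace starts at the postsynaptic spike
    (``pairing_dt_s`` after the pairing onset the delays are measured
    from), exactly as in :func:`run_protocol`.
    """
    t_da = np.asarray(t_da, dtype=float)
    t_th = np.asarray(t_th, dtype=float)
    p = rule.params
    if np.any(t_da < 0) or np.any(t_th < 0):
        raise ValueError("delay grid outside kernel support (delays must be >= 0)")
    if t_da.max() > p.horizon_s or t_th.max() > p.horizon_s:
        raise ValueError("delay grid exceeds the integration horizon")
    out = np.empty((len(t_da), len(t_th)))
    for i, d1 in enumerate(t_da):
        for j, d2 in enumerate(t_th):
            cn = rule.conjunction_integral(d1, d2, t_pair=pairing_dt_s) / rule.c_ref
            dw = p.eta_pot * p.a2a_block_scale * cn
            if cn < p.theta_conj:
                dw -= p.kappa_baseline
            out[i, j] = dw
    return out


def diagonal_half_max(rule: PlasticityRule, d_max: float = 3.0,
                      step: float = 0.01,
                      pairing_dt_s: float = 0.010) -> Tuple[float, float]:
    """Half-maximum edges of potentiation along the equal-delay diagonal.

    Scans dw for a single positive pairing with both reinforcement signals
    at the same delay d in [0, d_max]; returns the smallest and largest d at
    which dw is at least half its maximum.
    """
    d = np.arange(0.0, d_max + step / 2, step)
    p = rule.params
    cn = np.array([rule.conjunction_integral(x, x, t_pair=pairing_dt_s)
                   for x in d]) / rule.c_ref
    dw = p.eta_pot * p.a2a_block_scale * cn - p.kappa_baseline * (cn < p.theta_conj)
    half = 0.5 * dw.max()
    sel = np.nonzero(dw >= half)[0]
    return float(d[sel[0]]), float(d[sel[-1]])


# ---------------------------------------------------------------------------
# action discovery
# ---------------------------------------------------------------------------

def run_action_discovery(duration_s: float, rule: PlasticityRule,
                         switch_time_s: float = 300.0, seed: int = 0,
                         network: Optional[Network] = None,
                         program_order: Tuple[int, int] = (0, 1),
                         reinforcement_delay_s: float = 1.0) -> Dict[str, np.ndarray]:
    """Two-program action-discovery experiment with a mid-run reward switch.

    Programs activate at random intervals (uniform 5-20 s), each activation
    a synchronous spike volley.  An activation that drives its SPN to fire
    seeds eligibility on the active synapses; reinforcement (dopamine +
    thalamic input at 1 s) is delivered only when the activated program is
    the currently rewarded one: ``program_order[0]`` before the switch,
    ``program_order[1]`` after.  Passing ``program_order=(1, 0)`` relabels
    the programs and, with the same seed, swaps the two trajectories
    exactly.

    Returns event times, the activated program and per-event mean weights
    onto both SPNs.
    """
    if duration_s <= switch_time_s:
        raise ValueError("duration must exceed switch_time")
    p = rule.params
    net = network if network is not None else Network(
        w_init=p.w_init, w_min=p.w_min, w_max=p.w_max)
    rng = np.random.default_rng(seed)
    t_grid = rule.time_grid()

    times, programs = [], []
    w1, w2 = [], []
    t = 0.0
    while True:
        t += rng.uniform(5.0, 20.0)
        if t >= duration_s:
            break
        prog = program_order[0] if rng.random() < 0.5 else program_order[1]
        rewarded = program_order[0] if t < switch_time_s else program_order[1]

        active = net.program_cells(prog)
        state = rule._new_state(net.n_synapses)
        for spn in (0, 1):
            t_spike = net.spn_spike_time(active, spn)
            if t_spike is not None:
                syn = np.nonzero(np.isin(net.pre_cell, active)
                                 & (net.post_spn == spn))[0]
                update_eligibility(0.0, t_spike, state, synapses=syn)
        da = np.zeros_like(t_grid)
        th = np.zeros_like(t_grid)
        if prog == rewarded:
            da = rule.da_kernel(reinforcement_delay_s, p.da_block_scale)(t_grid)
            th = rule.th_kernel(reinforcement_delay_s)(t_grid)
        net.apply_dw(apply_reinforcement(state, t_grid, da, th, rule))

        times.append(t)
        programs.append(prog)
        w1.append(net.mean_weight(0))
        w2.append(net.mean_weight(1))

    return {
        "time_s": np.array(times),
        "program": np.array(programs),
        "mean_w_spn1": np.array(w1),
        "mean_w_spn2": np.array(w2),
        "switch_time_s": switch_time_s,
    }


# ---------------------------------------------------------------------------
# reference configuration
# ---------------------------------------------------------------------------

def load_reference_config() -> dict:
    """Load the packaged reference constants (rule + network)."""
    ref = importlib.resources.files("rstdp").joinpath("data/reference.yaml")
    return yaml.safe_load(ref.read_text())


def reference_rule(**overrides) -> PlasticityRule:
    """The reference rule parameterization, optionally overridden."""
    cfg = load_reference_config()["rule"]
    cfg.update(overrides)
    return PlasticityRule(PlasticityRuleParams(**cfg))


def reference_network(rule: Optional[PlasticityRule] = None, **overrides) -> Network:
    """The reference two-program network."""
    cfg = load_reference_config()["network"]
    cfg.update(overrides)
    spn = LifNeuron(**cfg.pop("spn"))
    p = rule.params if rule is not None else PlasticityRuleParams()
    return Network(spn=spn, w_init=p.w_init, w_min=p.w_min, w_max=p.w_max, **cfg)
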