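# Methods

## The plasticity rule

The model treats one corticostriatal pairing event and its delayed
reinforcement as follows.

**Eligibility trace.** A pre→post pairing with 0 < Δt ≤ 30 ms seeds a
potentiation trace on the active synapses; a post→pre pairing within the
same window seeds a depression trace.  Both use the waveform

    e(t) = (t / τ_r)^k · exp(k · (1 − t / τ_r)),   t ≥ 0,

a dimensionless bump with unit peak at t = τ_r that is below 1% of peak by
3 s.  The trace starts at the later spike of the pair, and traces from
multiple pairings superpose additively.  Reference values: k = 12,
τ_r = 0.90 s (see *Calibration* below).

**Reinforcement kernels.** Dopamine and thalamic responses are each the
output of two chained leaky integrators — a peak-normalized difference of
exponentials with (τ_rise, τ_decay) = (0.05, 0.30) s for dopamine and
(0.03, 0.20) s for the thalamic signal.  The peak time is
ln(τ_d/τ_r)/(1/τ_r − 1/τ_d) after onset; equal time constants degrade
gracefully to the alpha function (t/τ)e^(1−t/τ).

**Weight update.** For each inter-event interval,

    Δw = η⁺ · s_A2A · ∫ e_pot(t) · min(DA(t), Th(t)) dt / C*
       − η⁻ ·         ∫ e_dep(t) · min(DA(t), Th(t)) dt / C*
       − κ · 𝟙[e_pot seeded ∧ normalized conjunction drive < θ]

with weights clipped to [w_min, w_max] after every update.  C* is the peak
of the equal-delay conjunction curve, so η⁺ is the weight change per
pairing at the optimal reinforcement delay.  The pointwise minimum
implements the requirement that *both* signals be present: dopamine alone,
thalamic input alone, or reinforcement outside the eligibility window all
leave the conjunction integral near zero, in which case a seeded
potentiation trace decays un-reinforced and the synapse takes the small κ
drift — matching the minor depression observed for unreinforced positive
pairings, while unreinforced negative pairings change nothing.

**Conditioned light and habituation.** A light flash evokes both a
dopamine and a thalamic transient, scaled by a habituation state h that
decays by exp(−1/τ_hab) each time the light occurs without subsequent
primary reward (BSR) and resets to 1 when the light–BSR pairing is
restored; the first `novelty_da_events` presentations evoke dopamine
regardless (novelty response).  BSR evokes dopamine only.  Drug conditions
enter solely as scalar attenuations: `da_block_scale` multiplies all
dopamine amplitudes (D1-receptor blockade) and `a2a_block_scale`
multiplies the potentiation pathway (adenosine A2A blockade); no receptor
biophysics is modeled.

**Network.** Two populations of 11 cortical cells project to two SPNs
(program A → SPN 1, program B → SPN 2) with a crossover of two cells from
each population to the other SPN.  SPNs are leaky integrate-and-fire units
(τ_m = 20 ms, unit threshold, 5 ms refractory; exponential-Euler
integration at 1 ms, which errs on the side of the closed-form constant-
input firing period by less than one step).  A synchronous program volley
injects an exponentially decaying current whose gain is normalized so the
SPN fires iff the summed active weight exceeds a quorum (reference: 2.0,
i.e. the two crossover synapses alone are subthreshold).  The reported
variable is the mean synaptic weight of the 11 inputs to each SPN; means
use a sorted summation order so program relabeling is bit-exact.

### Parameters (reference values, `src/rstdp/data/reference.yaml`)

| parameter | value | meaning |
|---|---|---|
| k, τ_r | 12, 0.90 s | eligibility bump sharpness and peak time |
| DA kernel | 0.05 / 0.30 s | dopamine rise/decay |
| Th kernel | 0.03 / 0.20 s | thalamic rise/decay |
| η⁺, η⁻ | 0.0028, 0.0037 | per-pairing learning rates at optimal delay |
| κ | 0.0006 | drift for unreinforced potentiation traces |
| θ | 0.10 | conjunction-failure threshold (fraction of optimum) |
| τ_hab, novelty | 8 events, 5 events | light habituation and novelty dopamine |
| w bounds, w₀ | [0, 1], 0.5 | synaptic weight range and initial value |
| dt (integral), horizon | 10 ms, 6 s | reinforcement-integral numerics |

η⁺, η⁻ and κ were set so that 60-event protocols produce weight changes
of the order seen in vivo (reinforced positive pairings ≈ +10–20% of the
mean input weight, reinforced negative pairings ≈ −20%, unreinforced
positive pairings ≈ −6%); only their ratios matter for every sign-level
result, and κ/η⁺ ≈ 0.2 guarantees that a habituating light-only protocol
ends below baseline within 60 events.  Halving the 10 ms integration step
changes the conjunction integrals by < 0.1%.

### Calibration of the eligibility window

With the kernel time constants and min-conjunction fixed, (k, τ_r) were
scanned so that the half-maximum potentiation window along the equal-delay
diagonal of the single-pairing weight-change surface spans ≈ 0.4–1.1 s —
the delay range over which reinforcement is behaviorally effective.
k = 12, τ_r = 0.90 s gives edges at 0.41 s and 1.09 s (10 ms diagonal
resolution); smaller k values make the bump too broad and left-shifted
(k = 5, τ_r = 0.68 s gives 0.17–0.95 s).  The scan is reproducible with
`analysis/04_surface_calibration.py --scan`.  The surface and the protocol
simulator share one code path (`apply_reinforcement`), and a test pins
their equivalence in the single-event limit.

## Analysis pipelines

**PSP slopes.** Sweeps are excluded when their potential deviates from the
single-pass group mean by more than 1.5 group SDs at either of two
standardized checkpoints (defaults: 5 ms pre-stimulus and 200 ms
post-stimulus, when the potential should have returned to baseline; the
checkpoint positions are declared defaults, not estimates).  The PSP
measure is the maximal least-squares slope of a 1 ms window slid over the
initial depolarizing phase, after a 1 ms stimulus-artifact blank, with the
search truncated at the first local maximum of the lightly smoothed
(0.5 ms) trace so that only the first, putatively monosynaptic, component
is measured; slopes are computed on the smoothed trace, which leaves ramp
slopes exact while shrinking the max-over-windows selection bias under
noise.  Traces with no depolarization above 4 baseline SDs are flagged,
never silently zero.  Slopes are expressed as percent change from the
included-baseline mean and averaged in 5-min bins of the test period.

**Up-state latencies.** Per light event, state levels come from the
membrane-potential histogram of a 2 s window around the event: down = 20th
percentile, up = 80th, transition = their mean.  An event qualifies if the
smoothed (5 ms) potential at event time is on the down side of the
transition level; the percentile level itself cannot serve as the
membership test because it sits below the down-state mean whenever
down-state occupancy exceeds 20%.  The latency is the time to the first
upward crossing of the transition level; a seeded random control point is
drawn uniformly in the portion of the same sub-transition-level segment
preceding the event, and pairs without a crossing within 1 s (a declared
cap) are dropped from both samples.  Light latencies are fitted with a
log-logistic and random latencies with a Weibull distribution by maximum
likelihood (location pinned at 0); five positive-support families
(log-logistic, Weibull, lognormal, gamma, exponential) can be ranked by
BIC = k·ln n − 2·logL, ties breaking toward fewer parameters then a fixed
family order.  Kuiper's V = D⁺ + D⁻ compares the empirical light sample
against the fitted random CDF, with the Stephens-scaled asymptotic series
for p (Monte-Carlo calibration below n = 30, where the series is least
accurate).  The headline effect statistic is the CDF excess
[F_light(0.14) − F_light(0.06)] − [F_random(0.14) − F_random(0.06)].

## Synthetic data: what it emulates and what it does not

The generator produces: two-state semi-Markov up/down alternation (gamma
dwell times, mean 1/(2f) per state, CV 0.2 by default) between −80 and
−65 mV; additive white Gaussian noise; ramp-then-exponential PSPs of
≥ 5 mV with 5.2 ms onset latency and configurable per-trial slope drift;
light flashes that, with a configurable probability, force the next up
transition at a latency drawn from a named distribution (replacing, not
adding to, the next spontaneous transition); stylized 2 ms triangular
spikes used only by QC; and whole-sweep baseline-shift artifacts for the
exclusion stage.  Setting the noise SD and dwell CV to zero yields an
exact noiseless limit in which every generated quantity equals its
configured value, which the trivial-limit tests rely on.

It does **not** emulate: correlated (1/f or oscillatory) membrane noise,
gradual state transitions, anesthesia-depth drift, realistic spike
waveforms, conductance interactions between the PSP and the state
transitions, or any dependence of up-state duration on its trigger.
Passing round-trip tests therefore show that the pipelines recover effects
embedded under the stated statistical assumptions — not that those
assumptions hold for any particular recording.  The dwell-time family is a
documented placeholder, not a claim about data.

## Numerical choices and degenerate cases

- Exclusion statistics are computed once over all sweeps (single pass,
  order-independent); a zero checkpoint-SD retains all trials.
- Percentile thresholds on an effectively constant window raise rather
  than fabricating levels.
- Latency extraction is exact to one sample period on the degenerate
  (point-mass) generator.
- Non-converged distribution fits are flagged and excluded from BIC
  ranking, never silently ranked.
- The Kuiper statistic is validated against a brute-force ECDF enumeration
  oracle; the asymptotic p-value's true type-I error at n = 100 is ≈ 0.048
  at α = 0.05.
- Protocol simulations treat events independently (traces decay to < 1%
  of peak well inside the ≥ 10 s inter-event interval), which makes
  60-event runs effectively instantaneous without changing any result.

## Known limitations

- The rule is phenomenological: conjunction-by-minimum and the κ indicator
  are declared reference choices, not mechanistic claims; cholinergic and
  endocannabinoid contributions are out of scope.
- Drug conditions are scalar attenuations only.
- The analysis pipeline exports tidy per-trial tables; mixed-effects
  inference on the binned data is intentionally left to external
  statistical tools.
- Printed in vivo effect sizes (e.g. excess probabilities of +0.13/+0.18)
  depend on the original recordings and are emulated here only as
  configurable study conditions, not reproduced.
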