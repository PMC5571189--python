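# Reference parameterization of the reinforcement-modulated plasticity rule
# and the two-program corticostriatal network.  The eligibility shape
# (k, tau_r_s) was fixed by a calibration scan of the equal-delay
# weight-change surface so the half-maximum potentiation window spans
# ~0.4-1.1 s of reinforcement delay (see analysis/04_surface_calibration.py).

rule:
  # eligibility trace e(t) = (t/tau_r)^k * exp(k * (1 - t/tau_r))
  k: 12.0
  tau_r_s: 0.90
  pairing_window_ms: 30.0
  # reinforcement kernels: chained leaky integrators (difference of
  # exponentials, peak-normalized)
  da_tau_rise_s: 0.05
  da_tau_decay_s: 0.30
  th_tau_rise_s: 0.03
  th_tau_decay_s: 0.20
  # learning rates (weight change per pairing at optimal reinforcement delay)
  eta_pot: 0.0028
  eta_dep: 0.0037
  # baseline drift applied to unreinforced potentiation traces
  kappa_baseline: 0.0006
  # conjunction drive (relative to optimum) below which reinforcement counts
  # as absent and the kappa drift applies
  theta_conj: 0.10
  # conditioned-light habituation when presented without BSR
  habituation_tau_events: 8.0
  novelty_da_events: 5
  # drug conditions: scalar attenuation of dopamine / the potentiation pathway
  da_block_scale: 1.0
  a2a_block_scale: 1.0
  # synaptic weight bounds and initial value
  w_min: 0.0
  w_max: 1.0
  w_init: 0.5
  # numerics
  dt_integral_s: 0.010
  horizon_s: 6.0

network:
  n_per_program: 11
  n_crossover: 2
  spn:
    tau_m: 0.02
    v_thresh: 1.0
    v_reset: 0.0
    refractory_s: 0.005
  syn_tau_s: 0.005
  quorum_sum_w: 2.0
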