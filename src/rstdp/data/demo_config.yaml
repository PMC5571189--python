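# Demo end-to-end run: synthetic recording -> up-state latency analysis,
# plus the six model protocol conditions.  Sized to finish in seconds.
stages: [generate, upstate, model_protocols]
params:
  generate:
    protocol:
      n_events: 40
      event_rate_hz: 0.2
      stim_on: false
      bsr_on: false
      light_delay_s: 0.4
      baseline_s: 0.0
      test_s: 2.0
    synth:
      sampling_rate_hz: 2000.0
      dwell_cv: 0.3
      light_evoke_prob: 0.6
    write: false
  model_protocols:
    n_events: 60
seed: 0
out_dir: results
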