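#!/usr/bin/env python
"""Generate the synthetic intracellular recordings used by the analyses.

Produces one annotated membrane-potential recording under the full
plasticity protocol (pairing + light + BSR events) and one light-only
recording for the up-state latency analysis, and writes both to
``results/`` as HDF5.  The recording emulates slow (here 1 Hz) up/down
alternation around -80/-65 mV, >=5 mV PSPs with a 5.2 ms onset latency and
light flashes that can trigger early up-state transitions.
"""

import argparse
from pathlib import Path

from rstdp import ProtocolSpec, SynthParams, generate_recording
from rstdp.io import write_recording


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    full = ProtocolSpec(n_events=30, pairing_dt_ms=10.0, baseline_s=30.0, test_s=30.0)
    rec = generate_recording(SynthParams(seed=args.seed, sampling_rate_hz=5000.0), full)
    path = write_recording(rec, args.out / "protocol_recording.h5")
    print(f"full protocol recording: {rec.duration_s:.0f} s, "
          f"{len(rec.vm_mv)} samples, {len(rec.events)} events -> {path}")

    lights = ProtocolSpec(n_events=60, event_rate_hz=0.2, stim_on=False,
                          bsr_on=False, light_delay_s=0.4, baseline_s=0.0,
                          test_s=2.0)
    rec2 = generate_recording(
        SynthParams(seed=args.seed + 1, sampling_rate_hz=5000.0, dwell_cv=0.3,
                    light_evoke_prob=0.6), lights)
    path2 = write_recording(rec2, args.out / "light_recording.h5")
    n_evoked = len(rec2.truth["evoked_lights"])
    print(f"light-only recording: {len(rec2.event_times('light'))} flashes, "
          f"{n_evoked} evoked up transitions -> {path2}")


if __name__ == "__main__":
    main()
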