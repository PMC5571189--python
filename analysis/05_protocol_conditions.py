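#!/usr/bin/env python
"""Model recreation of the six positive-pairing protocol conditions.

Runs 60-event protocols (0.1 Hz pairings) for: pairings alone, pairings
with light + BSR reinforcement, BSR only, light only (habituating),
reinforcement delayed by 2 s, and thalamic input lesioned.  Prints the
final percent weight change per condition and checks the expected sign
pattern (-, +, -, rise-then-fall-to--, -, -).
"""

import argparse
from pathlib import Path

import numpy as np

from rstdp.pipeline import EXPECTED_SIGNS, stage_model_protocols


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    rep = stage_model_protocols({}, args.seed, args.out, {})
    ok = True
    for name, r in rep.items():
        expected = EXPECTED_SIGNS[name]
        match = np.sign(r["percent_change"]) == expected
        ok &= match
        print(f"{name:20s} final {r['percent_change']:+7.2f}%  "
              f"peak {r['peak_percent_change']:+7.2f}%  "
              f"expected sign {expected:+d}  {'ok' if match else 'MISMATCH'}")
    print("sign pattern " + ("matches" if ok else "DOES NOT match")
          + " the in vivo outcomes")
    print(f"details: {args.out / 'protocol_conditions.json'}")


if __name__ == "__main__":
    main()
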