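#!/usr/bin/env python
"""Weight-change surface and the calibration of the eligibility waveform.

For a single positive pairing, computes the predicted synaptic weight
change as a function of dopamine and thalamic signal delay on a 0-3 s
grid, and reports the half-maximum potentiation window along the
equal-delay diagonal (the "eligibility window").

Also reproduces the calibration scan that fixed the reference eligibility
shape: with the dopamine (0.05/0.30 s) and thalamic (0.03/0.20 s) kernels
and the min-conjunction held fixed, the bump sharpness k and rise scale
tau_r were scanned so the diagonal half-max window lands at ~0.4-1.1 s;
k=12, tau_r=0.90 s is the frozen reference.
"""

import argparse
from pathlib import Path

import numpy as np

from rstdp import diagonal_half_max, reference_rule, weight_change_surface


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=Path("results"))
    ap.add_argument("--scan", action="store_true",
                    help="rerun the (k, tau_r) calibration scan")
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    rule = reference_rule()
    step = 0.025
    grid = np.arange(0.0, 3.0 + step / 2, step)
    surface = weight_change_surface(grid, grid, rule)
    np.savetxt(args.out / "weight_change_surface.csv", surface, delimiter=",")
    lo, hi = diagonal_half_max(rule, step=0.01)
    print(f"reference rule (k={rule.params.k:g}, tau_r={rule.params.tau_r_s:g} s): "
          f"half-max potentiation window [{lo:.2f}, {hi:.2f}] s")
    print(f"surface ({len(grid)}x{len(grid)}, {step * 1000:.0f} ms grid) -> "
          f"{args.out / 'weight_change_surface.csv'}")

    if args.scan:
        print("\ncalibration scan (lower/upper half-max edges in s):")
        for k in (5, 8, 12, 16):
            for tau_r in (0.68, 0.80, 0.90, 1.00):
                r = reference_rule(k=float(k), tau_r_s=tau_r)
                lo_s, hi_s = diagonal_half_max(r, step=0.02)
                print(f"  k={k:<3d} tau_r={tau_r:.2f} -> [{lo_s:.2f}, {hi_s:.2f}]")


if __name__ == "__main__":
    main()
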