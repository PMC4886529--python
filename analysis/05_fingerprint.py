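#!/usr/bin/env python
"""Assemble the five-parameter migratory fingerprint and render it.

Combines the motility parameters (03) and barrier parameters (04) into the
signature {v_run, tau_run, tau_rest, P_turn(8), P_turn(0)} and draws the
radar chart.  As an illustration of condition comparison, a second,
less motile condition is included with slower runs, shorter run
persistence and more frequent reversals."""

import argparse
import json
from pathlib import Path

from ringmig import compute_fingerprint, radar_chart


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()

    motility = json.loads((args.out_dir / "motility_parameters.json").read_text())
    barrier = json.loads((args.out_dir / "barrier_parameters.json").read_text())
    ref = compute_fingerprint(motility, barrier, label="reference")

    # an illustrative slower phenotype for the comparison chart
    slow_mot = dict(motility, v_run=motility["v_run"] * 0.55,
                    tau_run=motility["tau_run"] * 0.5,
                    tau_rest=motility["tau_rest"] * 1.4)
    slow_bar = dict(barrier, p_turn_8=min(1.0, barrier["p_turn_8"] * 1.3))
    slow = compute_fingerprint(slow_mot, slow_bar, label="slow-phenotype")

    (args.out_dir / "fingerprint.json").write_text(
        json.dumps({"reference": ref.to_dict(), "slow-phenotype": slow.to_dict()},
                   indent=1) + "\n"
    )
    vertices = radar_chart([ref, slow], path=args.out_dir / "fingerprint.svg")
    print("fingerprint (reference):")
    for axis, vals in vertices["reference"].items():
        print(f"  {axis:9s} value={vals['value']:7.2f} radius={vals['radius']:.2f}")
    print(f"-> {args.out_dir / 'fingerprint.svg'} (+ .json vertex data)")


if __name__ == "__main__":
    main()
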