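#!/usr/bin/env python
"""Search for filter/hidden configurations matching the published 17,972
trainable-parameter total, and verify the shipped default is the winner.

Prints every exact solution (filter ladder F1..F4, hidden width, attention
key width) and the selection the package uses as its default configuration.

Usage:
    python scripts/calibrate_params.py [--target N]
"""

import argparse


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--target", type=int, default=None,
                        help="parameter total to match (default: the published count)")
    args = parser.parse_args()

    from midecoder.calibration import TARGET_PARAMS, calibrated_default, search

    target = args.target if args.target is not None else TARGET_PARAMS
    solutions = search(target)
    if not solutions:
        raise SystemExit(f"no configuration found totalling {target} parameters")

    print(f"exact solutions for a {target}-parameter model "
          f"(F1 F2 F3 F4 | hidden | key width):")
    for s in solutions:
        print(f"  {s.f1:3d} {s.f2:3d} {s.f3:3d} {s.f4:3d} | {s.hidden_size:3d} "
              f"| {s.key_dim:3d}  -> {s.total}")
    if target == TARGET_PARAMS:
        best = calibrated_default()
        print(f"selected default: F=({best.f1},{best.f2},{best.f3},{best.f4}), "
              f"hidden={best.hidden_size}, key_dim={best.key_dim} "
              f"(verified against a built model: {best.total} parameters)")


if __name__ == "__main__":
    main()
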