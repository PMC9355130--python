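#!/usr/bin/env python
"""Calibrate the synthetic family-history severity scales.

Solves for the two CohortConfig severity scales (fh_breast_scale,
fh_adjacent_scale) so that among simulated carriers the base testing
criteria detect ~33% and the adjusted criteria ~53%.  The printed values
are the ones frozen as CohortConfig defaults; re-run after changing the
family-history model.

Usage:
    python scripts/calibrate_fh.py [--n-probands 4000] [--seed 20180]
"""

from __future__ import annotations

import argparse
import json

from genofirst.calibrate import calibrate_fh_severity


def main() -> int:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--target-base", type=float, default=0.33)
    parser.add_argument("--target-adjusted", type=float, default=0.53)
    parser.add_argument("--n-probands", type=int, default=4000)
    parser.add_argument("--seed", type=int, default=20180)
    args = parser.parse_args()

    result = calibrate_fh_severity(
        target_base=args.target_base,
        target_adjusted=args.target_adjusted,
        n_probands=args.n_probands,
        seed=args.seed,
    )
    print(json.dumps(result, indent=2))
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
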