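#!/usr/bin/env python
"""Generate the synthetic parameterization-trial datasets.

Writes the four trial tables the fitting stage consumes: feeding sessions
(consumption vs. prey density), factorial growth trials, reaction-distance
trials, and the paired gradient-vs-homogeneous growth trial.
"""

import argparse
from pathlib import Path

from daphnia_ifd.generate import (
    default_consumption_spec,
    default_growth_spec,
    default_paired_growth_spec,
    default_rd_spec,
    gen_consumption,
    gen_growth,
    gen_paired_growth,
    gen_rd,
)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results/data"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    datasets = {
        "consumption_trials.csv": gen_consumption(
            default_consumption_spec(args.seed)
        ),
        "growth_trials.csv": gen_growth(default_growth_spec(args.seed + 1)),
        "rd_trials.csv": gen_rd(default_rd_spec(args.seed + 2)),
        "paired_growth_trials.csv": gen_paired_growth(
            default_paired_growth_spec(args.seed + 3)
        ),
    }
    for name, frame in datasets.items():
        frame.to_csv(args.out / name, index=False)
        print(f"{name}: {len(frame)} rows")


if __name__ == "__main__":
    main()
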