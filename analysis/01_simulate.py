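#!/usr/bin/env python
"""Generate the synthetic report database used by the downstream analyses.

Writes DEMO/DRUG/REAC CSVs plus the generator's ground truth to
results/synthetic_db/. The default configuration mimics the study
conditions: combination-pattern prevalences and odds multipliers echo the
real database's combination table, and per-pattern onset distributions are
early-failure Weibulls.
"""

import argparse
import dataclasses

from triplewhammy.synthetic import SimulationConfig, emit_fixture


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--n", type=int, default=50_000)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--out-dir", default="results/synthetic_db")
    args = parser.parse_args()

    config = dataclasses.replace(SimulationConfig(), n_cases=args.n, seed=args.seed)
    paths = emit_fixture(config, args.out_dir)
    print(f"wrote {args.n} synthetic cases:")
    for name, path in paths.items():
        print(f"  {name}: {path}")


if __name__ == "__main__":
    main()
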