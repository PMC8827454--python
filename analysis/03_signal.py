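#!/usr/bin/env python
"""Disproportionality analysis: reporting odds ratios by combination pattern.

Reads the annotation table from results/cohort/, builds the pattern-level
signal table (crude and covariate-adjusted RORs vs the no-TW-drug stratum),
and the AKI-vs-other characteristics comparison with chi-square tests.
Writes both to results/signal/ and prints the signal table.
"""

import argparse
from pathlib import Path

import pandas as pd

from triplewhammy.disproportionality import ror_table
from triplewhammy.pipeline import aki_vs_other_characteristics


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--annotations", default="results/cohort/annotations.csv")
    parser.add_argument("--out-dir", default="results/signal")
    args = parser.parse_args()

    frame = pd.read_csv(args.annotations)
    for col in ("is_aki", "sex_male", "elderly_70", "uses_aki_risk",
                "uses_rasi", "uses_diuretic", "uses_nsaid"):
        frame[col] = frame[col].astype(bool)

    signal = ror_table(frame)
    characteristics = aki_vs_other_characteristics(frame)

    out = Path(args.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    signal.to_csv(out / "signal_table.csv", index=False, lineterminator="\n")
    characteristics.to_csv(out / "characteristics.csv", index=False, lineterminator="\n")

    show = signal[["row", "aki_n", "other_n", "crude_ror", "adjusted_ror", "signal"]]
    print(show.to_string(index=False, float_format=lambda v: f"{v:.2f}"))
    n_signals = int(signal["signal"].sum())
    print(f"\n{n_signals} of {len(signal)} rows meet the signal rule (CI lower bound > 1)")


if __name__ == "__main__":
    main()
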