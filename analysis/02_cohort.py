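#!/usr/bin/env python
"""Build the analysis cohort from the simulated database.

Reads results/synthetic_db/, applies the inclusion flow (known sex and age,
age >= 20), flags AKI cases, classifies Triple Whammy exposures, and writes
the flow counts and the case-level annotation table to results/cohort/.
"""

import argparse
from pathlib import Path

import pandas as pd

from triplewhammy.cohort import (
    DrugLists,
    annotate_cases,
    annotations_frame,
    filter_population,
)
from triplewhammy.defaults import DEFAULT_AKI_PTS
from triplewhammy.jader_io import join_cases, read_table


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--in-dir", default="results/synthetic_db")
    parser.add_argument("--out-dir", default="results/cohort")
    args = parser.parse_args()

    src = Path(args.in_dir)
    cases, orphans = join_cases(
        read_table(src / "demo.csv", "demo"),
        read_table(src / "drug.csv", "drug"),
        read_table(src / "reac.csv", "reac"),
    )
    kept, flow = filter_population(cases)
    frame = annotations_frame(annotate_cases(kept, DrugLists.default(), DEFAULT_AKI_PTS))

    out = Path(args.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    csv = frame.copy()
    for col in ("is_aki", "sex_male", "elderly_70", "uses_aki_risk",
                "uses_rasi", "uses_diuretic", "uses_nsaid"):
        csv[col] = csv[col].astype(int)
    csv.to_csv(out / "annotations.csv", index=False, lineterminator="\n")
    pd.DataFrame([flow.as_dict()]).to_csv(out / "flow.csv", index=False, lineterminator="\n")

    n_aki = int(frame["is_aki"].sum())
    n_tw = int((frame["pattern"].astype(str) != "NONE").sum())
    print(f"{flow.total} cases read, {flow.after_demographic_exclusion} kept after "
          f"demographic exclusion; {n_aki} AKI cases, {n_tw} with TW drugs")


if __name__ == "__main__":
    main()
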