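"""End-to-end orchestration: ingest (or simulate) -> cohort -> signal -> onset.

:func:`run_pipeline` produces a deterministic bundle of diffable CSV tables —
the inclusion-flow counts, the signal table (combination patterns with crude
and adjusted RORs), target-case characteristics, the Weibull shape table,
Kaplan-Meier medians and step coordinates, and pairwise generalized-Wilcoxon
matrices — plus a machine-readable run manifest (config hash, package
version, seed). Identical config and seed give identical outputs; no stage
reads the clock or machine identity.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__, defaults
from .cohort import (
    DrugLists,
    annotate_cases,
    annotations_frame,
    filter_population,
    summarize_cohort,
)
from .disproportionality import ContingencyTable2x2, chi_square_2x2, ror_table
from .errors import ConfigurationError, DegenerateTableError
from .jader_io import TableDialect, join_cases, read_table
from .onset import (
    OnsetRecord,
    build_onset_records,
    curve_table,
    median_table,
    onset_groups,
    pairwise_onset_comparison,
    weibull_table,
)
from .synthetic import SimulationConfig, simulate_reports

logger = logging.getLogger("triplewhammy")


@dataclass(frozen=True)
class RunConfig:
    """Everything one pipeline run depends on.

    Either ``input_paths`` (demo/drug/reac files) or ``simulation`` must be
    set. Membership lists default to the package defaults; supply a YAML via
    :func:`triplewhammy.defaults.load_lists_yaml` to override.
    """

    input_paths: Mapping[str, str] | None = None  # keys: demo, drug, reac
    simulation: SimulationConfig | None = None
    dialect: TableDialect = field(default_factory=TableDialect)
    pt_list: frozenset[str] = defaults.DEFAULT_AKI_PTS
    lists: DrugLists = field(default_factory=DrugLists.default)
    convention: Literal["day0", "day1"] = "day0"
    zero_policy: Literal["offset_half", "exclude", "shift_all_plus1"] = "offset_half"
    alpha: float = 0.05
    out_dir: str = "results/run"
    seed: int = 0

    def validate(self) -> None:
        if (self.input_paths is None) == (self.simulation is None):
            raise ConfigurationError(
                "exactly one of input_paths or simulation must be set"
            )
        if not 0.0 < self.alpha < 1.0:
            raise ConfigurationError(f"alpha={self.alpha} outside (0, 1)")
        if self.input_paths is not None:
            missing = [
                f"{k}: {v}"
                for k, v in self.input_paths.items()
                if not Path(v).exists()
            ]
            if missing:
                raise ConfigurationError(f"input files not found: {missing}")


def _config_hash(config: RunConfig) -> str:
    def default(o):
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        if isinstance(o, frozenset):
            return sorted(o)
        if isinstance(o, tuple):
            return list(o)
        return str(o)

    fields = dataclasses.asdict(config)
    fields.pop("out_dir", None)  # where the bundle lands is not analytic config
    doc = json.dumps(fields, sort_keys=True, default=default)
    return hashlib.sha256(doc.encode()).hexdigest()


def _fmt_est(value: float, lo: float, hi: float) -> str:
    if not np.isfinite(value):
        return ""
    return f"{value:.2f} [{lo:.2f}-{hi:.2f}]"


def aki_vs_other_characteristics(frame: pd.DataFrame) -> pd.DataFrame:
    """Case-characteristics comparison between AKI and other-event reports,
    with a Pearson chi-square test per factor."""
    n_aki = int(frame["is_aki"].sum())
    n_other = int((~frame["is_aki"]).sum())
    factors = {
        "Males": frame["sex_male"],
        "Elderly (age >= 70)": frame["elderly_70"],
        "RASIs": frame["uses_rasi"],
        "Diuretics": frame["uses_diuretic"],
        "NSAIDs": frame["uses_nsaid"],
        "any Triple Whammy drugs": frame["pattern"].astype(str) != "NONE",
        "any AKI risk drugs": frame["uses_aki_risk"],
    }
    rows = []
    for label, flag in factors.items():
        a = int((flag & frame["is_aki"]).sum())
        b = int((flag & ~frame["is_aki"]).sum())
        table = ContingencyTable2x2(a, n_aki - a, b, n_other - b)
        try:
            stat, p = chi_square_2x2(table)
        except DegenerateTableError:
            stat, p = np.nan, np.nan
        rows.append(
            {
                "factor": label,
                "aki_n": a,
                "aki_pct": 100.0 * a / n_aki if n_aki else np.nan,
                "other_n": b,
                "other_pct": 100.0 * b / n_other if n_other else np.nan,
                "chi_square": stat,
                "p_value": p,
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig, write: bool = True) -> dict:
    """Run every stage and (optionally) write the report bundle to
    ``config.out_dir``. Returns the bundle as a dict of DataFrames plus the
    flow counts and manifest."""
    config.validate()

    # --- ingest ---------------------------------------------------------
    if config.simulation is not None:
        demo_f, drug_f, reac_f, truth = simulate_reports(
            config.simulation, seed=config.seed
        )
        from .jader_io import frame_to_records

        demo = frame_to_records(demo_f, "demo", config.dialect)
        drug = frame_to_records(drug_f, "drug", config.dialect)
        reac = frame_to_records(reac_f, "reac", config.dialect)
    else:
        truth = None
        demo = read_table(config.input_paths["demo"], "demo", config.dialect)
        drug = read_table(config.input_paths["drug"], "drug", config.dialect)
        reac = read_table(config.input_paths["reac"], "reac", config.dialect)
    cases, orphans = join_cases(demo, drug, reac)
    if not orphans.empty:
        logger.info(
            "orphan rows: %d drug, %d reac",
            len(orphans.drug_case_ids),
            len(orphans.reac_case_ids),
        )

    # --- cohort ---------------------------------------------------------
    kept, flow = filter_population(cases)
    logger.info(
        "population filter: %d -> %d cases", flow.total, flow.after_demographic_exclusion
    )
    annotations = annotate_cases(kept, config.lists, config.pt_list)
    frame = annotations_frame(annotations)
    flow.aki_cases = int(frame["is_aki"].sum())
    flow.tw_cases = int((frame["pattern"].astype(str) != "NONE").sum())
    flow.aki_tw_cases = int(
        (frame["is_aki"] & (frame["pattern"].astype(str) != "NONE")).sum()
    )

    # --- disproportionality ----------------------------------------------
    signal = ror_table(frame, alpha=config.alpha)
    signal["crude_fmt"] = [
        _fmt_est(r.crude_ror, r.crude_ci_low, r.crude_ci_high)
        for r in signal.itertuples()
    ]
    signal["adjusted_fmt"] = [
        _fmt_est(r.adjusted_ror, r.adjusted_ci_low, r.adjusted_ci_high)
        for r in signal.itertuples()
    ]
    characteristics = aki_vs_other_characteristics(frame)

    # --- onset -----------------------------------------------------------
    records, exclusions = build_onset_records(
        kept, annotations, config.lists, config.pt_list, convention=config.convention
    )
    flow.target_with_dates = len(records)
    logger.info("onset exclusions: %s", exclusions)
    target_ids = {r.case_id for r in records}
    target_ann = [a for a in annotations if a.case_id in target_ids]
    target_cases = [c for c in kept if c.case_id in target_ids]
    target_summary = summarize_cohort(
        target_ann, cases=target_cases, lists=config.lists, pt_list=config.pt_list
    )

    weibull = weibull_table(records, zero_policy=config.zero_policy, alpha=config.alpha)
    weibull["beta_fmt"] = [
        _fmt_est(r.beta, r.beta_ci_low, r.beta_ci_high) for r in weibull.itertuples()
    ]
    medians = median_table(records)
    curves = curve_table(records)
    groups = onset_groups(records)
    pairwise = {}
    for strat, inner in groups.items():
        nonempty = {k: v for k, v in inner.items() if len(v) > 0}
        if len(nonempty) >= 2:
            pairwise[strat] = pairwise_onset_comparison(nonempty, alpha=config.alpha)
        else:
            pairwise[strat] = pd.DataFrame()

    manifest = {
        "package_version": __version__,
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "convention": config.convention,
        "zero_policy": config.zero_policy,
        "alpha": config.alpha,
        "flow": flow.as_dict(),
        "onset_exclusions": exclusions,
        "orphan_rows": {
            "drug": len(orphans.drug_case_ids),
            "reac": len(orphans.reac_case_ids),
        },
    }

    bundle = {
        "flow": pd.DataFrame([flow.as_dict()]),
        "signal_table": signal,
        "characteristics": characteristics,
        "target_characteristics": target_summary["characteristics"],
        "target_patterns": target_summary["patterns"],
        "target_outcomes": target_summary.get("outcomes", pd.DataFrame()),
        "weibull_table": weibull,
        "median_table": medians,
        "curve_table": curves,
        "pairwise": pairwise,
        "manifest": manifest,
        "records": records,
        "annotations_frame": frame,
        "ground_truth": truth,
    }

    if write:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name in (
            "flow",
            "signal_table",
            "characteristics",
            "target_characteristics",
            "target_patterns",
            "target_outcomes",
            "weibull_table",
            "median_table",
            "curve_table",
        ):
            bundle[name].to_csv(out / f"{name}.csv", index=False, lineterminator="\n")
        for strat, table in pairwise.items():
            table.to_csv(out / f"pairwise_{strat}.csv", index=False, lineterminator="\n")
        with open(out / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        logger.info("bundle written to %s", out)
    return bundle


def records_from_duration_table(
    table: pd.DataFrame, duration_shift: float = 0.0
) -> list[OnsetRecord]:
    """Adapt a deposited per-case duration dataset to :class:`OnsetRecord`.

    ``table`` is the output of :func:`triplewhammy.jader_io.load_onset_dataset`.
    Pattern labels are matched leniently ("RDN", "R+D+N", names of the drug
    classes). ``duration_shift`` converts between day-counting conventions
    (use -1 if the deposited durations count the start day as day 1 and the
    analysis should run on a day-0 scale). Durations are clipped at 0.
    """
    records: list[OnsetRecord] = []
    for row in table.itertuples():
        if not np.isfinite(row.duration_days):
            continue
        raw = str(row.pattern).lower()
        letters = ""
        if set(str(row.pattern).upper()) <= set("RDN+ ") and str(row.pattern).strip():
            letters = "".join(c for c in str(row.pattern).upper() if c in "RDN")
        else:
            letters += "R" if ("rasi" in raw or "ras " in raw) else ""
            letters += "D" if "diuretic" in raw else ""
            letters += "N" if "nsaid" in raw else ""
        pattern = "".join(c for c in "RDN" if c in letters) or "NONE"
        order_raw = str(row.order).lower()
        simultaneous = "sim" in order_raw
        last_class = None
        if not simultaneous:
            if "->" in str(row.order):
                tail = str(row.order).split("->")[-1].strip().upper()
                letters = {"RASIS": "R", "DIURETICS": "D", "NSAIDS": "N"}
                last_class = letters.get(tail, tail if tail in {"R", "D", "N"} else None)
            elif "last" in order_raw:
                for token, cls in (("rasi", "R"), ("diuretic", "D"), ("nsaid", "N")):
                    if token in order_raw:
                        last_class = cls
                        break
        records.append(
            OnsetRecord(
                case_id=str(row.case_id),
                pattern=pattern,
                order={},
                order_key=str(row.order),
                last_class=last_class,
                simultaneous=simultaneous,
                duration_days=max(0.0, float(row.duration_days) + duration_shift),
            )
        )
    return records


__all__ = [
    "RunConfig",
    "run_pipeline",
    "aki_vs_other_characteristics",
    "records_from_duration_table",
]
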