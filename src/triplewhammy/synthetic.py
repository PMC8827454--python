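"""Synthetic spontaneous-report databases with known ground truth.

Every pipeline stage is testable without access to a real release: this
module draws JADER-shaped DEMO/DRUG/REAC tables from a fully specified
generative model and returns the ground truth alongside, so recovery of
reporting odds ratios, covariate effects and onset-time distributions can be
checked against configured values.

Generative model per case:

* demographics — sex, a decade age band, a reporting year; a small fraction
  of rows get unknown sex/age or an under-20 band to exercise the inclusion
  flow;
* exposure — one Triple Whammy combination pattern drawn from a prevalence
  vector over {NONE, R, D, N, RD, RN, DN, RDN}, plus an independent AKI-risk
  drug indicator; drug rows carry names sampled from the configured class
  lists, involvement categories and start dates;
* outcome — the AKI indicator follows a logistic model: baseline log-odds
  plus the pattern's log odds multiplier plus covariate effects (male,
  age >= 70, AKI-risk drug, linear year trend). The configured multiplier is
  therefore the true covariate-conditional odds ratio versus NONE;
* onset — AKI cases in TW patterns get an onset date equal to the last TW
  start plus a per-pattern Weibull draw rounded down to whole days (dates are
  daily-resolution); start-date ties ("simultaneous starts") and missing
  dates are injected at configured rates.

The default configuration mimics the published study conditions: pattern
prevalences and adjusted odds multipliers echo the real database's
combination table, and per-pattern Weibull shapes/medians echo the published
shape-parameter table. It is synthetic demonstration data, not the study's
data.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import defaults
from .cohort import PATTERN_CLASSES, PATTERNS
from .errors import ConfigurationError

_BANDS = ("20s", "30s", "40s", "50s", "60s", "70s", "80s", "90s")

#: prevalences echoing the real database's combination distribution
DEFAULT_PREVALENCE: dict[str, float] = {
    "NONE": 0.740, "R": 0.071, "D": 0.037, "N": 0.095,
    "RD": 0.031, "RN": 0.014, "DN": 0.007, "RDN": 0.005,
}

#: true covariate-conditional odds ratios vs NONE (demonstration values)
DEFAULT_PATTERN_ODDS: dict[str, float] = {
    "NONE": 1.0, "R": 1.43, "D": 1.76, "N": 1.18,
    "RD": 2.41, "RN": 1.55, "DN": 1.70, "RDN": 2.44,
}

#: per-pattern onset model as (Weibull shape, median days); scale is derived
DEFAULT_ONSET: dict[str, tuple[float, float]] = {
    "R": (0.57, 63.0), "D": (0.49, 30.0), "N": (0.49, 9.0),
    "RD": (0.62, 120.0), "RN": (0.49, 9.0), "DN": (0.48, 8.0),
    "RDN": (0.51, 8.0),
}


def _scale_from_median(shape: float, median: float) -> float:
    return median / np.log(2.0) ** (1.0 / shape)


@dataclass(frozen=True)
class SimulationConfig:
    n_cases: int = 2000
    seed: int = 0
    male_probability: float = 0.55
    age_band_probs: Mapping[str, float] = field(
        default_factory=lambda: dict(
            zip(_BANDS, (0.05, 0.07, 0.09, 0.12, 0.17, 0.24, 0.18, 0.08))
        )
    )
    unknown_demo_probability: float = 0.02  # unknown sex or age band
    under20_probability: float = 0.01
    year_range: tuple[int, int] = (2005, 2020)
    pattern_prevalence: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PREVALENCE)
    )
    baseline_aki_probability: float = 0.03
    pattern_odds: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PATTERN_ODDS)
    )
    male_log_odds: float = 0.25
    elderly_log_odds: float = 0.45
    aki_risk_log_odds: float = 0.65
    year_log_odds: float = 0.01  # per year, centred on the window midpoint
    aki_risk_probability: float = 0.30
    onset_weibull: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            p: (shape, _scale_from_median(shape, med))
            for p, (shape, med) in DEFAULT_ONSET.items()
        }
    )  # pattern -> (shape, scale days)
    start_window: tuple[str, str] = ("2006-01-01", "2019-06-30")
    date_missingness: float = 0.35  # matches the low completeness of real reports
    simultaneous_start_probability: float = 0.10

    def validate(self) -> None:
        bad: list[str] = []
        if self.n_cases <= 0:
            bad.append("n_cases must be positive")
        for name in (
            "male_probability",
            "unknown_demo_probability",
            "under20_probability",
            "baseline_aki_probability",
            "aki_risk_probability",
            "date_missingness",
            "simultaneous_start_probability",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                bad.append(f"{name}={v} outside [0, 1]")
        prev = [self.pattern_prevalence.get(p, 0.0) for p in PATTERNS]
        if any(p < 0 for p in prev) or abs(sum(prev) - 1.0) > 1e-9:
            bad.append("pattern_prevalence must be non-negative and sum to 1")
        for p, odds in self.pattern_odds.items():
            if odds <= 0:
                bad.append(f"pattern_odds[{p}]={odds} must be positive")
        for p, (shape, scale) in self.onset_weibull.items():
            if shape <= 0 or scale <= 0:
                bad.append(f"onset_weibull[{p}]=({shape}, {scale}) must be positive")
        if dt.date.fromisoformat(self.start_window[0]) >= dt.date.fromisoformat(
            self.start_window[1]
        ):
            bad.append("start_window must be an increasing date pair")
        if bad:
            raise ConfigurationError("; ".join(bad))


@dataclass(frozen=True)
class GroundTruth:
    """What the generator actually used, for recovery tests."""

    odds_ratio: Mapping[str, float]  # pattern -> true conditional OR vs NONE
    weibull: Mapping[str, tuple[float, float]]  # pattern -> (shape, scale)
    median_days: Mapping[str, float]  # analytic scale * ln(2)^(1/shape)

    @classmethod
    def from_config(cls, config: SimulationConfig) -> "GroundTruth":
        medians = {
            p: float(scale * np.log(2.0) ** (1.0 / shape))
            for p, (shape, scale) in config.onset_weibull.items()
        }
        return cls(
            odds_ratio=dict(config.pattern_odds),
            weibull=dict(config.onset_weibull),
            median_days=medians,
        )


def _sorted(names) -> tuple[str, ...]:
    return tuple(sorted(names))


def simulate_reports(
    config: SimulationConfig | None = None, seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Draw one synthetic report database.

    Returns raw DEMO/DRUG/REAC tables (string-valued DataFrames readable by
    :mod:`triplewhammy.jader_io` with the default dialect) plus the
    :class:`GroundTruth`. Fully reproducible: the same config and seed give
    byte-identical tables. ``seed`` overrides ``config.seed`` when given.
    """
    config = config or SimulationConfig()
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_cases

    class_names = {
        "R": _sorted(defaults.DEFAULT_RASI),
        "D": _sorted(defaults.DEFAULT_DIURETIC),
        "N": _sorted(defaults.DEFAULT_NSAID),
    }
    risk_names = _sorted(defaults.DEFAULT_AKI_RISK)
    filler_names = defaults.FILLER_DRUGS
    aki_pts = _sorted(defaults.DEFAULT_AKI_PTS)
    decoy_pts = defaults.DECOY_PTS
    outcomes = defaults.OUTCOME_CATEGORIES
    outcome_probs = np.array([0.45, 0.10, 0.18, 0.07, 0.05, 0.15])
    involvements = ("suspect drug", "concomitant drug", "interaction")
    involvement_probs = np.array([0.70, 0.25, 0.05])

    bands = list(config.age_band_probs)
    band_probs = np.array([config.age_band_probs[b] for b in bands], dtype=float)
    band_probs = band_probs / band_probs.sum()

    # --- vectorized per-case draws -------------------------------------
    sex_male = rng.random(n) < config.male_probability
    band_idx = rng.choice(len(bands), size=n, p=band_probs)
    age_band = np.array(bands, dtype=object)[band_idx]
    under20 = rng.random(n) < config.under20_probability
    age_band[under20] = "10s"
    unknown_demo = rng.random(n) < config.unknown_demo_probability
    unknown_kind = rng.random(n) < 0.5  # True: blank sex, False: blank age
    year = rng.integers(config.year_range[0], config.year_range[1] + 1, size=n)

    prev = np.array([config.pattern_prevalence.get(p, 0.0) for p in PATTERNS])
    pattern_idx = rng.choice(len(PATTERNS), size=n, p=prev / prev.sum())
    patterns = np.array(PATTERNS, dtype=object)[pattern_idx]
    uses_risk = rng.random(n) < config.aki_risk_probability

    elderly = np.array([b in {"70s", "80s", "90s", "100s"} for b in age_band])
    base = config.baseline_aki_probability
    logit = np.log(base / (1.0 - base)) + np.log(
        np.array([config.pattern_odds.get(p, 1.0) for p in patterns])
    )
    logit += config.male_log_odds * sex_male
    logit += config.elderly_log_odds * elderly
    logit += config.aki_risk_log_odds * uses_risk
    mid_year = 0.5 * (config.year_range[0] + config.year_range[1])
    logit += config.year_log_odds * (year - mid_year)
    p_aki = 1.0 / (1.0 + np.exp(-logit))
    is_aki = rng.random(n) < p_aki

    start_lo = dt.date.fromisoformat(config.start_window[0]).toordinal()
    start_hi = dt.date.fromisoformat(config.start_window[1]).toordinal()
    last_start = rng.integers(start_lo, start_hi + 1, size=n)
    simultaneous = rng.random(n) < config.simultaneous_start_probability
    # earlier-class offsets: distinct day counts before the last start
    offsets = rng.integers(1, 366, size=(n, 2))
    offsets[:, 1] = offsets[:, 0] + 1 + rng.integers(0, 200, size=n)

    shapes = np.array(
        [config.onset_weibull.get(p, (1.0, 30.0))[0] for p in patterns]
    )
    scales = np.array(
        [config.onset_weibull.get(p, (1.0, 30.0))[1] for p in patterns]
    )
    durations = np.floor(rng.weibull(shapes) * scales).astype(int)
    decoy_durations = np.floor(rng.weibull(1.0, size=n) * 30.0).astype(int)

    name_pick = rng.random((n, 3))
    involvement_pick = rng.choice(len(involvements), size=(n, 4), p=involvement_probs)
    drug_missing = rng.random((n, 5)) < config.date_missingness
    onset_missing = rng.random(n) < config.date_missingness
    pt_pick = rng.integers(0, 10**9, size=n)
    outcome_idx = rng.choice(len(outcomes), size=n, p=outcome_probs)
    risk_pick = rng.integers(0, len(risk_names), size=n)
    filler_pick = rng.integers(0, len(filler_names), size=n)
    order_perm = rng.random((n, 3))

    # --- assemble rows --------------------------------------------------
    demo_rows = []
    drug_rows = []
    reac_rows = []
    for i in range(n):
        cid = f"C{i + 1:07d}"
        sex = "male" if sex_male[i] else "female"
        band = str(age_band[i])
        if unknown_demo[i]:
            if unknown_kind[i]:
                sex = ""
            else:
                band = ""
        demo_rows.append((cid, sex, band, str(year[i])))

        classes = PATTERN_CLASSES[str(patterns[i])]
        # start order: permute the involved classes; the last one starts last
        if classes:
            order = [c for _, c in sorted(zip(order_perm[i, : len(classes)], classes))]
            class_start: dict[str, int] = {}
            if len(classes) == 1 or simultaneous[i]:
                for c in classes:
                    class_start[c] = int(last_start[i])
            else:
                class_start[order[-1]] = int(last_start[i])
                for j, c in enumerate(order[:-1]):
                    class_start[c] = int(last_start[i]) - int(offsets[i, len(order) - 2 - j])
            for j, c in enumerate(classes):
                names = class_names[c]
                name = names[int(name_pick[i, j] * len(names))]
                start = (
                    ""
                    if drug_missing[i, j]
                    else dt.date.fromordinal(class_start[c]).strftime("%Y%m%d")
                )
                drug_rows.append(
                    (cid, name, involvements[involvement_pick[i, j]], "systemic", start)
                )
        else:
            start = (
                ""
                if drug_missing[i, 3]
                else dt.date.fromordinal(int(last_start[i])).strftime("%Y%m%d")
            )
            drug_rows.append(
                (cid, filler_names[filler_pick[i]], "suspect drug", "systemic", start)
            )
        if uses_risk[i]:
            start = (
                ""
                if drug_missing[i, 4]
                else dt.date.fromordinal(int(last_start[i]) - 30).strftime("%Y%m%d")
            )
            drug_rows.append(
                (cid, risk_names[risk_pick[i]], involvements[involvement_pick[i, 3]],
                 "systemic", start)
            )

        if is_aki[i]:
            pt = aki_pts[pt_pick[i] % len(aki_pts)]
            dur = int(durations[i]) if classes else int(decoy_durations[i])
        else:
            pt = decoy_pts[pt_pick[i] % len(decoy_pts)]
            dur = int(decoy_durations[i])
        onset = (
            ""
            if onset_missing[i]
            else dt.date.fromordinal(int(last_start[i]) + dur).strftime("%Y%m%d")
        )
        reac_rows.append((cid, pt, onset, outcomes[outcome_idx[i]]))

    demo = pd.DataFrame(demo_rows, columns=["case_id", "sex", "age", "report_year"])
    drug = pd.DataFrame(
        drug_rows, columns=["case_id", "drug_name", "involvement", "route", "start_date"]
    )
    reac = pd.DataFrame(reac_rows, columns=["case_id", "pt", "onset_date", "outcome"])
    return demo, drug, reac, GroundTruth.from_config(config)


def emit_fixture(
    config: SimulationConfig | None = None,
    out_dir: str | Path = ".",
    seed: int | None = None,
) -> dict[str, Path]:
    """Write demo/drug/reac CSVs plus a ground-truth YAML to ``out_dir``.

    The CSVs are readable by :func:`triplewhammy.jader_io.read_table` with the
    default dialect. Returns the written paths.
    """
    config = config or SimulationConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    demo, drug, reac, truth = simulate_reports(config, seed=seed)
    paths = {
        "demo": out / "demo.csv",
        "drug": out / "drug.csv",
        "reac": out / "reac.csv",
        "truth": out / "ground_truth.yaml",
    }
    demo.to_csv(paths["demo"], index=False, lineterminator="\n")
    drug.to_csv(paths["drug"], index=False, lineterminator="\n")
    reac.to_csv(paths["reac"], index=False, lineterminator="\n")
    truth_doc = {
        "synthetic": True,
        "odds_ratio": {k: float(v) for k, v in truth.odds_ratio.items()},
        "weibull": {k: [float(a), float(b)] for k, (a, b) in truth.weibull.items()},
        "median_days": {k: float(v) for k, v in truth.median_days.items()},
    }
    with open(paths["truth"], "w", encoding="utf-8") as fh:
        yaml.safe_dump(truth_doc, fh, sort_keys=True)
    return paths


__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "DEFAULT_PREVALENCE",
    "DEFAULT_PATTERN_ODDS",
    "DEFAULT_ONSET",
    "simulate_reports",
    "emit_fixture",
    "replace",
]
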