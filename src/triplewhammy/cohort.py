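"""Cohort construction: inclusion flow, AKI flagging, exposure classification.

The analysis population is built in two demographic stages — drop cases with
unknown sex or age band, then drop patients younger than 20 (NSAIDs are not
generally given to children in the source population) — and each case is then
annotated with:

* ``is_aki`` — any reaction PT in the configured AKI PT list;
* the three Triple Whammy exposure booleans (RASI, diuretic, NSAID) and the
  derived combination ``pattern`` in {NONE, R, D, N, RD, RN, DN, RDN};
* covariates used by the adjusted disproportionality model: male sex,
  age ≥ 70 (band lower bound), any AKI-risk drug, reporting year.

Exposure rules: all involvement categories (suspect / concomitant /
interaction) count; aspirin never counts as an NSAID; a case whose only NSAID
exposures are topical is NSAID-naive (unknown route counts as systemic).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from . import defaults
from .defaults import normalize_name, normalize_set
from .errors import ConfigurationError
from .jader_io import ReportCase

#: combination patterns in canonical order (R = RASI, D = diuretic, N = NSAID)
PATTERNS: tuple[str, ...] = ("NONE", "R", "D", "N", "RD", "RN", "DN", "RDN")

#: pattern -> number of TW classes involved
PATTERN_SIZE: dict[str, int] = {
    "NONE": 0, "R": 1, "D": 1, "N": 1, "RD": 2, "RN": 2, "DN": 2, "RDN": 3,
}

#: pattern -> involved class letters
PATTERN_CLASSES: dict[str, tuple[str, ...]] = {
    "NONE": (), "R": ("R",), "D": ("D",), "N": ("N",),
    "RD": ("R", "D"), "RN": ("R", "N"), "DN": ("D", "N"), "RDN": ("R", "D", "N"),
}


def pattern_from_flags(rasi: bool, diuretic: bool, nsaid: bool) -> str:
    """The combination pattern is a pure function of the three class flags."""
    letters = ("R" if rasi else "") + ("D" if diuretic else "") + ("N" if nsaid else "")
    return letters or "NONE"


@dataclass(frozen=True)
class DrugLists:
    """Normalized membership sets for the TW classes and AKI-risk drugs.

    Construction removes aspirin names from the effective NSAID set, so the
    aspirin rule cannot be bypassed by listing aspirin under NSAIDs.
    """

    rasi: frozenset[str]
    diuretic: frozenset[str]
    nsaid: frozenset[str]
    aki_risk: frozenset[str]
    aspirin_names: frozenset[str]
    aki_risk_groups: Mapping[str, frozenset[str]] = field(default_factory=dict)

    @classmethod
    def from_names(
        cls,
        rasi: Iterable[str] = defaults.DEFAULT_RASI,
        diuretic: Iterable[str] = defaults.DEFAULT_DIURETIC,
        nsaid: Iterable[str] = defaults.DEFAULT_NSAID,
        aki_risk: Iterable[str] = defaults.DEFAULT_AKI_RISK,
        aspirin_names: Iterable[str] = defaults.DEFAULT_ASPIRIN,
        aki_risk_groups: Mapping[str, Iterable[str]] | None = None,
    ) -> "DrugLists":
        aspirin = normalize_set(aspirin_names)
        groups = aki_risk_groups
        if groups is None:
            groups = defaults.DEFAULT_AKI_RISK_GROUPS
        return cls(
            rasi=normalize_set(rasi),
            diuretic=normalize_set(diuretic),
            nsaid=normalize_set(nsaid) - aspirin,
            aki_risk=normalize_set(aki_risk),
            aspirin_names=aspirin,
            aki_risk_groups={k: normalize_set(v) for k, v in groups.items()},
        )

    @classmethod
    def default(cls) -> "DrugLists":
        return cls.from_names()


@dataclass(frozen=True)
class CaseAnnotation:
    case_id: str
    is_aki: bool = False
    uses_rasi: bool = False
    uses_diuretic: bool = False
    uses_nsaid: bool = False
    uses_aki_risk: bool = False
    pattern: str = "NONE"
    sex_male: bool = False
    elderly_70: bool = False
    report_year: int | None = None


@dataclass
class FlowReport:
    """Counts along the inclusion/exclusion flow; later stages are filled as
    the pipeline reaches them. Each chained stage is non-increasing."""

    total: int = 0
    after_demographic_exclusion: int = 0
    aki_cases: int | None = None
    tw_cases: int | None = None
    aki_tw_cases: int | None = None
    target_with_dates: int | None = None

    def as_dict(self) -> dict[str, int | None]:
        return {
            "total": self.total,
            "after_demographic_exclusion": self.after_demographic_exclusion,
            "aki_cases": self.aki_cases,
            "tw_cases": self.tw_cases,
            "aki_tw_cases": self.aki_tw_cases,
            "target_with_dates": self.target_with_dates,
        }


_AGE_BAND_RE = re.compile(r"^(\d{1,3})\s*(?:s|'s|歳代|代)?$")


def parse_age_band(label: str) -> int | None:
    """Lower bound in years of a decade band label ("20s" -> 20), or None."""
    m = _AGE_BAND_RE.match(label.strip())
    if m is None:
        return None
    return int(m.group(1))


def filter_population(cases: Sequence[ReportCase]) -> tuple[list[ReportCase], FlowReport]:
    """Keep cases with known sex, known age band, and age lower bound >= 20."""
    known = [
        c
        for c in cases
        if c.demo.sex in {"male", "female"} and parse_age_band(c.demo.age_band) is not None
    ]
    kept = [c for c in known if parse_age_band(c.demo.age_band) >= 20]
    report = FlowReport(total=len(cases), after_demographic_exclusion=len(kept))
    return kept, report


def flag_aki(case: ReportCase, pt_list: Iterable[str]) -> bool:
    """True iff any reaction PT is in the AKI PT list (normalized exact match)."""
    pts = normalize_set(pt_list)
    if not pts:
        raise ConfigurationError("AKI PT list is empty")
    return any(normalize_name(r.pt) in pts for r in case.reactions)


def classify_exposures(
    case: ReportCase, lists: DrugLists, pt_list: Iterable[str] | None = None
) -> CaseAnnotation:
    """Annotate one case with TW exposures, pattern and covariates.

    The result is order-independent in the case's drug list: each flag is an
    any-match over rows. If ``pt_list`` is given the AKI flag is set too.
    """
    uses_rasi = uses_diuretic = uses_nsaid = uses_risk = False
    for drug in case.drugs:
        name = normalize_name(drug.drug_name)
        if name in lists.rasi:
            uses_rasi = True
        if name in lists.diuretic:
            uses_diuretic = True
        # aspirin is excluded from the NSAID set at construction; topical-only
        # NSAID use must not set the flag (unknown route counts as systemic)
        if name in lists.nsaid and drug.route != "topical":
            uses_nsaid = True
        if name in lists.aki_risk:
            uses_risk = True
    lower = parse_age_band(case.demo.age_band)
    return CaseAnnotation(
        case_id=case.case_id,
        is_aki=flag_aki(case, pt_list) if pt_list is not None else False,
        uses_rasi=uses_rasi,
        uses_diuretic=uses_diuretic,
        uses_nsaid=uses_nsaid,
        uses_aki_risk=uses_risk,
        pattern=pattern_from_flags(uses_rasi, uses_diuretic, uses_nsaid),
        sex_male=case.demo.sex == "male",
        elderly_70=lower is not None and lower >= 70,
        report_year=case.demo.report_year,
    )


def annotate_cases(
    cases: Sequence[ReportCase], lists: DrugLists, pt_list: Iterable[str]
) -> list[CaseAnnotation]:
    return [classify_exposures(c, lists, pt_list=pt_list) for c in cases]


def annotations_frame(annotations: Sequence[CaseAnnotation]) -> pd.DataFrame:
    """Case-level annotation table used by the regression and summary ops."""
    return pd.DataFrame(
        {
            "case_id": [a.case_id for a in annotations],
            "is_aki": [a.is_aki for a in annotations],
            "uses_rasi": [a.uses_rasi for a in annotations],
            "uses_diuretic": [a.uses_diuretic for a in annotations],
            "uses_nsaid": [a.uses_nsaid for a in annotations],
            "uses_aki_risk": [a.uses_aki_risk for a in annotations],
            "pattern": pd.Categorical(
                [a.pattern for a in annotations], categories=list(PATTERNS)
            ),
            "sex_male": [a.sex_male for a in annotations],
            "elderly_70": [a.elderly_70 for a in annotations],
            "report_year": [a.report_year for a in annotations],
        }
    )


def _fmt_count(n: int, denom: int) -> str:
    if denom == 0:
        return f"{n} ()"
    return f"{n} ({100.0 * n / denom:.1f})"


def summarize_cohort(
    annotations: Sequence[CaseAnnotation],
    cases: Sequence[ReportCase] | None = None,
    lists: DrugLists | None = None,
    pt_list: Iterable[str] | None = None,
) -> dict[str, pd.DataFrame]:
    """Cross-tabulations of the annotated cohort.

    Returns a dict of DataFrames: ``characteristics`` (sex, elderly, TW class
    use, AKI-risk drug use — per group when ``cases`` are supplied — with
    counts and percentages of the cohort), ``patterns`` (counts per combination
    pattern grouped single/double/triple), and, when ``cases`` and ``pt_list``
    are supplied, ``outcomes`` (AKI outcome category by pattern).
    """
    n = len(annotations)
    rows = [
        ("Males", sum(a.sex_male for a in annotations)),
        ("Elderly (age >= 70)", sum(a.elderly_70 for a in annotations)),
        ("RASIs", sum(a.uses_rasi for a in annotations)),
        ("Diuretics", sum(a.uses_diuretic for a in annotations)),
        ("NSAIDs", sum(a.uses_nsaid for a in annotations)),
        ("any Triple Whammy drugs", sum(a.pattern != "NONE" for a in annotations)),
    ]
    if cases is not None and lists is not None and lists.aki_risk_groups:
        by_id = {c.case_id: c for c in cases}
        for group, names in lists.aki_risk_groups.items():
            count = sum(
                1
                for a in annotations
                if a.case_id in by_id
                and any(
                    normalize_name(d.drug_name) in names for d in by_id[a.case_id].drugs
                )
            )
            rows.append((group, count))
    rows.append(("any AKI risk drugs", sum(a.uses_aki_risk for a in annotations)))
    characteristics = pd.DataFrame(
        {
            "item": [r[0] for r in rows],
            "n": [r[1] for r in rows],
            "pct": [100.0 * r[1] / n if n else float("nan") for r in rows],
            "formatted": [_fmt_count(r[1], n) for r in rows],
        }
    )

    pat_counts = {p: sum(a.pattern == p for a in annotations) for p in PATTERNS}
    pat_rows = []
    for p in PATTERNS:
        pat_rows.append(
            {
                "pattern": p,
                "group": ("none", "single", "double", "triple")[PATTERN_SIZE[p]],
                "n": pat_counts[p],
                "pct": 100.0 * pat_counts[p] / n if n else float("nan"),
            }
        )
    patterns = pd.DataFrame(pat_rows)

    out = {"characteristics": characteristics, "patterns": patterns}

    if cases is not None and pt_list is not None:
        pts = normalize_set(pt_list)
        by_id = {c.case_id: c for c in cases}
        outcome_rows = []
        for a in annotations:
            if not a.is_aki or a.case_id not in by_id:
                continue
            case = by_id[a.case_id]
            aki_outcomes = {
                r.outcome for r in case.reactions if normalize_name(r.pt) in pts
            }
            # one AKI case contributes its worst-reported outcome once
            order = ["Death", "With sequelae", "Unrecovered", "Remission", "Recovered", "unknown"]
            outcome = next((o for o in order if o in aki_outcomes), "unknown")
            outcome_rows.append({"pattern": a.pattern, "outcome": outcome})
        if outcome_rows:
            frame = pd.DataFrame(outcome_rows)
            table = (
                frame.groupby(["pattern", "outcome"], observed=True)
                .size()
                .unstack(fill_value=0)
                .reindex(index=[p for p in PATTERNS if p in frame["pattern"].unique()])
            )
        else:
            table = pd.DataFrame()
        out["outcomes"] = table
    return out


__all__ = [
    "PATTERNS",
    "PATTERN_SIZE",
    "PATTERN_CLASSES",
    "pattern_from_flags",
    "DrugLists",
    "CaseAnnotation",
    "FlowReport",
    "parse_age_band",
    "filter_population",
    "flag_aki",
    "classify_exposures",
    "annotate_cases",
    "annotations_frame",
    "summarize_cohort",
]
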