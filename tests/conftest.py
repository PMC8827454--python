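"""Shared builders for case-level test data."""

from __future__ import annotations

import datetime as dt

import pytest

from triplewhammy.jader_io import DemoRecord, DrugRecord, ReacRecord, ReportCase


def drug(
    name: str,
    case_id: str = "A",
    route: str = "systemic",
    start: str | None = None,
    involvement: str = "suspect",
    incomplete: bool = False,
) -> DrugRecord:
    return DrugRecord(
        case_id=case_id,
        drug_name=name,
        involvement=involvement,
        route=route,
        start_date=dt.date.fromisoformat(start) if start else None,
        start_date_incomplete=incomplete,
    )


def reac(
    pt: str,
    case_id: str = "A",
    onset: str | None = None,
    outcome: str = "Recovered",
) -> ReacRecord:
    return ReacRecord(
        case_id=case_id,
        pt=pt,
        onset_date=dt.date.fromisoformat(onset) if onset else None,
        outcome=outcome,
    )


def case(
    case_id: str = "A",
    sex: str = "male",
    age: str = "50s",
    year: int = 2015,
    drugs: tuple[DrugRecord, ...] = (),
    reactions: tuple[ReacRecord, ...] = (),
) -> ReportCase:
    return ReportCase(
        demo=DemoRecord(case_id=case_id, sex=sex, age_band=age, report_year=year),
        drugs=tuple(d if d.case_id == case_id else DrugRecord(**{**d.__dict__, "case_id": case_id}) for d in drugs),
        reactions=tuple(r if r.case_id == case_id else ReacRecord(**{**r.__dict__, "case_id": case_id}) for r in reactions),
    )


@pytest.fixture(scope="session")
def default_lists():
    from triplewhammy.cohort import DrugLists

    return DrugLists.default()
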