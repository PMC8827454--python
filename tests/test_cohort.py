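"""Cohort construction: inclusion flow, AKI flagging, exposure rules."""

from __future__ import annotations

import dataclasses
import random

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from triplewhammy.cohort import (
    PATTERNS,
    DrugLists,
    annotate_cases,
    classify_exposures,
    filter_population,
    flag_aki,
    parse_age_band,
    pattern_from_flags,
    summarize_cohort,
)
from triplewhammy.errors import ConfigurationError

from .conftest import case, drug, reac

AKI_PTS = {"Acute kidney injury", "Renal failure"}


class TestAgeBand:
    @pytest.mark.parametrize(
        "label, expected",
        [("20s", 20), ("70s", 70), ("100s", 100), ("", None), ("adult", None), ("30歳代", 30)],
    )
    def test_lower_bound(self, label, expected):
        assert parse_age_band(label) == expected


class TestFilterPopulation:
    def test_under_20_excluded(self):
        kept, flow = filter_population([case("A", age="10s")])
        assert kept == [] and flow.total == 1 and flow.after_demographic_exclusion == 0

    def test_unknown_sex_or_age_excluded(self):
        cases = [case("A", sex="unknown"), case("B", age="unknown"), case("C")]
        kept, flow = filter_population(cases)
        assert [c.case_id for c in kept] == ["C"]

    def test_all_valid_identity(self):
        cases = [case(str(i)) for i in range(4)]
        kept, flow = filter_population(cases)
        assert len(kept) == flow.after_demographic_exclusion == flow.total == 4


class TestFlagAki:
    def test_listed_pt_flags(self):
        assert flag_aki(case(reactions=(reac("Acute kidney injury"),)), AKI_PTS)

    def test_unlisted_pt_does_not_flag(self):
        assert not flag_aki(case(reactions=(reac("Nausea"),)), AKI_PTS)

    def test_any_match_suffices(self):
        c = case(reactions=(reac("Nausea"), reac("Renal failure")))
        assert flag_aki(c, AKI_PTS)

    def test_empty_pt_list_is_a_configuration_error(self):
        with pytest.raises(ConfigurationError):
            flag_aki(case(), set())


class TestClassifyExposures:
    def test_aspirin_never_counts_as_nsaid(self, default_lists):
        ann = classify_exposures(case(drugs=(drug("aspirin"),)), default_lists)
        assert not ann.uses_nsaid and ann.pattern == "NONE"

    def test_topical_only_nsaid_is_naive(self, default_lists):
        ann = classify_exposures(
            case(drugs=(drug("diclofenac", route="topical"),)), default_lists
        )
        assert not ann.uses_nsaid

    def test_unknown_route_counts_as_systemic(self, default_lists):
        ann = classify_exposures(
            case(drugs=(drug("diclofenac", route="unknown"),)), default_lists
        )
        assert ann.uses_nsaid and ann.pattern == "N"

    def test_topical_plus_systemic_nsaid_counts(self, default_lists):
        ann = classify_exposures(
            case(drugs=(drug("diclofenac", route="topical"), drug("ibuprofen"))),
            default_lists,
        )
        assert ann.uses_nsaid

    def test_triple_combination_pattern(self, default_lists):
        ann = classify_exposures(
            case(drugs=(drug("enalapril"), drug("furosemide"), drug("loxoprofen"))),
            default_lists,
        )
        assert ann.pattern == "RDN"

    def test_all_involvement_categories_count(self, default_lists):
        ann = classify_exposures(
            case(drugs=(drug("enalapril", involvement="concomitant"),)), default_lists
        )
        assert ann.uses_rasi and ann.pattern == "R"

    def test_elderly_from_band_lower_bound(self, default_lists):
        assert classify_exposures(case(age="70s"), default_lists).elderly_70
        assert not classify_exposures(case(age="60s"), default_lists).elderly_70

    def test_aspirin_listed_under_nsaids_is_still_removed(self):
        lists = DrugLists.from_names(nsaid={"ibuprofen", "aspirin"})
        assert "aspirin" not in lists.nsaid


@settings(max_examples=50, deadline=None)
@given(seed=st.integers(0, 10**6))
def test_annotation_is_drug_order_independent(seed, default_lists):
    """Shuffling a case's drug list never changes its annotation."""
    rng = random.Random(seed)
    pool = [
        drug("enalapril"), drug("furosemide"), drug("diclofenac", route="topical"),
        drug("loxoprofen"), drug("aspirin"), drug("famotidine"),
    ]
    drugs = [rng.choice(pool) for _ in range(rng.randint(0, 6))]
    base = classify_exposures(case(drugs=tuple(drugs)), default_lists)
    rng.shuffle(drugs)
    assert classify_exposures(case(drugs=tuple(drugs)), default_lists) == base


@settings(max_examples=30, deadline=None)
@given(flags=st.tuples(st.booleans(), st.booleans(), st.booleans()))
def test_pattern_is_pure_function_of_flags(flags):
    pattern = pattern_from_flags(*flags)
    assert pattern in PATTERNS
    assert (pattern != "NONE") == any(flags)


def test_pattern_partition_sums_to_cohort_size(default_lists):
    rng = random.Random(7)
    names = ["enalapril", "furosemide", "loxoprofen", "aspirin", "acetaminophen"]
    cases = [
        case(str(i), drugs=tuple(drug(rng.choice(names)) for _ in range(rng.randint(0, 4))))
        for i in range(200)
    ]
    annotations = annotate_cases(cases, default_lists, AKI_PTS)
    counts = {p: sum(a.pattern == p for a in annotations) for p in PATTERNS}
    assert sum(counts.values()) == 200


class TestSummarize:
    def test_formatted_percentages(self, default_lists):
        cases = [case(str(i), sex="male" if i < 59 else "female") for i in range(100)]
        annotations = annotate_cases(cases, default_lists, AKI_PTS)
        table = summarize_cohort(annotations)["characteristics"]
        males = table[table["item"] == "Males"].iloc[0]
        assert males["formatted"] == "59 (59.0)"

    def test_empty_cohort_has_blank_percentages(self):
        table = summarize_cohort([])["characteristics"]
        assert (table["n"] == 0).all()
        assert table["formatted"].str.endswith("()").all()

    def test_generator_prevalences_recovered_within_3_binomial_sd(self):
        """Simulate with a uniform 4-pattern prevalence and check the observed
        pattern proportions against binomial sampling error."""
        from triplewhammy.defaults import DEFAULT_AKI_PTS
        from triplewhammy.jader_io import frame_to_records, join_cases
        from triplewhammy.synthetic import SimulationConfig, simulate_reports

        prevalence = {p: 0.0 for p in PATTERNS}
        for p in ("NONE", "R", "DN", "RDN"):
            prevalence[p] = 0.25
        config = dataclasses.replace(
            SimulationConfig(),
            n_cases=10_000,
            seed=11,
            pattern_prevalence=prevalence,
            unknown_demo_probability=0.0,
            under20_probability=0.0,
        )
        demo, drug_f, reac_f, _ = simulate_reports(config)
        cases, _ = join_cases(
            frame_to_records(demo, "demo"),
            frame_to_records(drug_f, "drug"),
            frame_to_records(reac_f, "reac"),
        )
        annotations = annotate_cases(cases, DrugLists.default(), DEFAULT_AKI_PTS)
        n = len(annotations)
        sd = np.sqrt(0.25 * 0.75 / n)
        for p in ("NONE", "R", "DN", "RDN"):
            observed = sum(a.pattern == p for a in annotations) / n
            assert abs(observed - 0.25) < 3 * sd, f"pattern {p}: {observed}"
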