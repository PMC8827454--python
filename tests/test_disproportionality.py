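"""Reporting odds ratios: crude, chi-square, covariate-adjusted."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from triplewhammy.cohort import annotations_frame
from triplewhammy.disproportionality import (
    ContingencyTable2x2,
    adjusted_ror,
    chi_square_2x2,
    crude_ror,
    pattern_table,
    ror_table,
)
from triplewhammy.errors import ConvergenceError, DegenerateTableError


def _annotations(seed, n, odds, prevalence=None, **config_kwargs):
    """Annotation frame from the synthetic generator via the full ingest path."""
    from triplewhammy.cohort import DrugLists, annotate_cases
    from triplewhammy.defaults import DEFAULT_AKI_PTS
    from triplewhammy.jader_io import frame_to_records, join_cases
    from triplewhammy.synthetic import SimulationConfig, simulate_reports

    config = dataclasses.replace(
        SimulationConfig(),
        n_cases=n,
        seed=seed,
        pattern_odds=odds,
        pattern_prevalence=prevalence or SimulationConfig().pattern_prevalence,
        **config_kwargs,
    )
    demo, drug, reac, truth = simulate_reports(config)
    cases, _ = join_cases(
        frame_to_records(demo, "demo"),
        frame_to_records(drug, "drug"),
        frame_to_records(reac, "reac"),
    )
    annotations = annotate_cases(cases, DrugLists.default(), DEFAULT_AKI_PTS)
    return annotations_frame(annotations), truth


class TestCrudeRor:
    def test_published_triple_vs_control_counts(self):
        # cross-product oracle: ROR = (a*d)/(b*c)
        table = ContingencyTable2x2(a=275, b=2727, c=10949, d=391559)
        oracle = (275 * 391559) / (2727 * 10949)
        result = crude_ror(table)
        assert result.ror == pytest.approx(oracle, abs=5e-13)
        assert result.signal and result.ci_low > 1

    def test_equal_odds_is_one_without_signal(self):
        result = crude_ror(ContingencyTable2x2(10, 10, 10, 10))
        assert result.ror == pytest.approx(1.0)
        assert not result.signal

    def test_zero_cell_errors_by_default(self):
        with pytest.raises(DegenerateTableError):
            crude_ror(ContingencyTable2x2(0, 5, 5, 5))

    def test_haldane_adds_half_to_every_cell(self):
        result = crude_ror(ContingencyTable2x2(0, 5, 5, 5), zero_policy="haldane")
        assert result.correction_applied
        assert result.ror == pytest.approx((0.5 / 5.5) / (5.5 / 5.5))

    def test_wald_interval_hand_computed(self):
        # exp(ln ROR +/- 1.959964 * sqrt(1/a+1/b+1/c+1/d))
        a, b, c, d = 20, 80, 50, 850
        se = np.sqrt(1 / 20 + 1 / 80 + 1 / 50 + 1 / 850)
        ror = (20 / 80) / (50 / 850)
        result = crude_ror(ContingencyTable2x2(a, b, c, d))
        assert result.ci_low == pytest.approx(ror * np.exp(-1.959964 * se), rel=1e-6)
        assert result.ci_high == pytest.approx(ror * np.exp(1.959964 * se), rel=1e-6)

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable2x2(-1, 2, 3, 4)


positive_cells = st.integers(min_value=1, max_value=5000)


@settings(max_examples=100, deadline=None)
@given(a=positive_cells, b=positive_cells, c=positive_cells, d=positive_cells)
def test_ror_invariants(a, b, c, d):
    """Scaling invariance, inversion symmetry, and the signal rule."""
    base = crude_ror(ContingencyTable2x2(a, b, c, d))
    scaled = crude_ror(ContingencyTable2x2(a, 3 * b, c, 3 * d))
    assert scaled.ror == pytest.approx(base.ror, rel=1e-12)
    inverted = crude_ror(ContingencyTable2x2(c, d, a, b))
    assert inverted.ror == pytest.approx(1 / base.ror, rel=1e-12)
    assert inverted.ci_low == pytest.approx(1 / base.ci_high, rel=1e-9)
    assert inverted.ci_high == pytest.approx(1 / base.ci_low, rel=1e-9)
    assert base.signal == (base.ci_low > 1)


class TestChiSquare:
    def test_independence_gives_zero(self):
        stat, p = chi_square_2x2(ContingencyTable2x2(10, 10, 10, 10))
        assert stat == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_matches_expected_count_oracle(self):
        table = ContingencyTable2x2(275, 2727, 10949, 391559)
        observed = np.array([[275, 2727], [10949, 391559]], dtype=float)
        total = observed.sum()
        expected = np.outer(observed.sum(axis=1), observed.sum(axis=0)) / total
        oracle = ((observed - expected) ** 2 / expected).sum()
        stat, p = chi_square_2x2(table)
        assert stat == pytest.approx(oracle, rel=1e-12)
        assert 0 <= p <= 1

    def test_transposition_symmetry(self):
        s1, _ = chi_square_2x2(ContingencyTable2x2(20, 10, 5, 40))
        s2, _ = chi_square_2x2(ContingencyTable2x2(20, 5, 10, 40))
        assert s1 == pytest.approx(s2)

    def test_zero_margin_is_undefined(self):
        with pytest.raises(DegenerateTableError):
            chi_square_2x2(ContingencyTable2x2(0, 0, 5, 5))


class TestAdjustedRor:
    def test_constant_outcome_is_degenerate(self):
        frame, _ = _annotations(5, 500, {p: 1.0 for p in ["NONE", "R", "D", "N", "RD", "RN", "DN", "RDN"]})
        frame["is_aki"] = False
        with pytest.raises(ConvergenceError):
            adjusted_ror(frame)

    def test_noise_covariates_leave_adjusted_near_crude(self):
        """With covariates generated independently of outcome and exposure and
        a rare outcome, the adjusted ROR collapses to the crude ROR."""
        odds = {p: 1.0 for p in ["NONE", "R", "D", "N", "RD", "RN", "DN", "RDN"]}
        odds["RDN"] = 1.8
        prevalence = {p: 0.0 for p in odds}
        prevalence.update(NONE=0.7, RDN=0.3)
        frame, _ = _annotations(
            21, 40_000, odds, prevalence=prevalence,
            male_log_odds=0.0, elderly_log_odds=0.0,
            aki_risk_log_odds=0.0, year_log_odds=0.0,
        )
        crude = crude_ror(pattern_table(frame, "RDN"))
        fit = adjusted_ror(frame)
        assert fit.adjusted["RDN"].ror == pytest.approx(crude.ror, rel=0.05)

    def test_loglik_is_a_maximum_against_perturbations(self):
        """The reported optimum beats 100 random perturbations of the params
        and has a near-zero analytic gradient."""
        import statsmodels.api as sm

        frame, _ = _annotations(9, 4000, {p: 2.0 if p != "NONE" else 1.0
                                          for p in ["NONE", "R", "D", "N", "RD", "RN", "DN", "RDN"]})
        fit = adjusted_ror(frame)
        assert fit.gradient_norm < 1e-4 * fit.n

        # rebuild the same design to evaluate the likelihood surface
        X = np.column_stack(
            [np.ones(len(frame))]
            + [
                (frame["pattern"].astype(str) == p).astype(float)
                for p in ["R", "D", "N", "RD", "RN", "DN", "RDN"]
            ]
            + [
                frame[c].astype(float)
                for c in ("sex_male", "elderly_70", "uses_aki_risk")
            ]
            + [(frame["report_year"] - frame["report_year"].mean()).to_numpy()]
        )
        model = sm.Logit(frame["is_aki"].astype(float).to_numpy(), X)
        theta = np.array(list(fit.params.values()))
        ll_hat = model.loglike(theta)
        rng = np.random.default_rng(0)
        for _ in range(100):
            assert model.loglike(theta + rng.normal(0, 0.05, theta.size)) <= ll_hat + 1e-9

    def test_ror_table_has_pattern_and_pooled_rows(self):
        frame, _ = _annotations(3, 8000, {p: 2.0 if p != "NONE" else 1.0
                                          for p in ["NONE", "R", "D", "N", "RD", "RN", "DN", "RDN"]})
        table = ror_table(frame)
        assert set(table["row"]) == {"R", "D", "N", "RD", "RN", "DN", "RDN",
                                     "single", "double", "triple"}
        by_row = table.set_index("row")
        assert (
            by_row.loc["single", "aki_n"]
            == by_row.loc[["R", "D", "N"], "aki_n"].sum()
        )
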