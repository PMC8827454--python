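"""Reporting odds ratio (ROR) signal detection.

In a spontaneous-report database the reporting odds ratio compares the odds of
the target event (here AKI) among reports in an index exposure group against
the same odds among reference reports:

    ROR = (a/b) / (c/d)

for a 2x2 table with ``a`` AKI and ``b`` other-event reports in the index
group, ``c`` and ``d`` in the reference group. The 95% CI is a Wald interval
on the log scale, exp(ln ROR +/- z * sqrt(1/a + 1/b + 1/c + 1/d)); a signal is
declared when the CI lower bound exceeds 1. Covariate-adjusted RORs come from
a binomial logistic regression of the AKI indicator on pattern indicators plus
male sex, age >= 70, any AKI-risk drug and reporting year, with the no-TW-drug
stratum as reference; the adjusted ROR for a pattern is exp of its
coefficient, with a Wald CI.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .cohort import PATTERNS, PATTERN_SIZE
from .errors import ConvergenceError, DegenerateTableError, SeparationError

ZeroPolicy = Literal["error", "haldane"]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """AKI vs other-event counts for an index/reference split.

    a: AKI in index; b: other events in index; c: AKI in reference;
    d: other events in reference.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        cells = (self.a, self.b, self.c, self.d)
        if any(int(x) != x or x < 0 for x in cells):
            raise ValueError(f"cell counts must be non-negative integers, got {cells}")
        if sum(cells) <= 0:
            raise ValueError("contingency table is empty")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class RorResult:
    ror: float
    ci_low: float
    ci_high: float
    alpha: float
    signal: bool
    correction_applied: bool = False


def crude_ror(
    table: ContingencyTable2x2,
    alpha: float = 0.05,
    zero_policy: ZeroPolicy = "error",
) -> RorResult:
    """Crude ROR with Wald CI on the log scale and the lower-bound signal rule.

    With ``zero_policy="haldane"`` 0.5 is added to every cell when any cell is
    zero (Haldane–Anscombe); with ``"error"`` a zero cell raises
    :class:`DegenerateTableError`.
    """
    cells = [float(table.a), float(table.b), float(table.c), float(table.d)]
    corrected = False
    if any(x == 0 for x in cells):
        if zero_policy == "haldane":
            cells = [x + 0.5 for x in cells]
            corrected = True
        else:
            raise DegenerateTableError(
                f"zero cell in table {cells}; use zero_policy='haldane' to correct"
            )
    a, b, c, d = cells
    ror = (a / b) / (c / d)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = stats.norm.ppf(1 - alpha / 2)
    lo = float(np.exp(np.log(ror) - z * se))
    hi = float(np.exp(np.log(ror) + z * se))
    return RorResult(
        ror=float(ror),
        ci_low=lo,
        ci_high=hi,
        alpha=alpha,
        signal=lo > 1.0,
        correction_applied=corrected,
    )


def chi_square_2x2(
    table: ContingencyTable2x2, correction: bool = False
) -> tuple[float, float]:
    """Pearson chi-square (1 df) for a 2x2 table; Yates correction optional."""
    arr = np.array([[table.a, table.b], [table.c, table.d]], dtype=float)
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise DegenerateTableError("a zero row or column margin makes the test undefined")
    stat, p, _, _ = stats.chi2_contingency(arr, correction=correction)
    return float(stat), float(p)


def pattern_table(
    frame: pd.DataFrame, index_pattern: str | Sequence[str], reference: str = "NONE"
) -> ContingencyTable2x2:
    """Build the AKI-vs-other 2x2 table for one pattern (or pooled patterns)
    against the reference stratum from an annotation frame."""
    index_set = {index_pattern} if isinstance(index_pattern, str) else set(index_pattern)
    pat = frame["pattern"].astype(str)
    idx = pat.isin(index_set)
    ref = pat == reference
    return ContingencyTable2x2(
        a=int((idx & frame["is_aki"]).sum()),
        b=int((idx & ~frame["is_aki"]).sum()),
        c=int((ref & frame["is_aki"]).sum()),
        d=int((ref & ~frame["is_aki"]).sum()),
    )


@dataclass(frozen=True)
class LogisticFit:
    """A converged maximum-likelihood logistic fit with per-pattern adjusted RORs."""

    params: Mapping[str, float]
    bse: Mapping[str, float]
    adjusted: Mapping[str, RorResult]
    log_likelihood: float
    iterations: int
    gradient_norm: float
    alpha: float
    n: int


_COVARIATES = ("sex_male", "elderly_70", "uses_aki_risk")
_SEPARATION_COEF = 15.0  # |log-OR| beyond this is numerically a separated fit


def adjusted_ror(
    frame: pd.DataFrame,
    reference: str = "NONE",
    alpha: float = 0.05,
    terms: Literal["pattern", "group"] = "pattern",
    year_encoding: Literal["continuous", "categorical"] = "continuous",
    maxiter: int = 100,
    gtol: float = 1e-6,
) -> LogisticFit:
    """Covariate-adjusted RORs by maximum-likelihood logistic regression.

    ``frame`` is a case-level annotation table (see
    :func:`triplewhammy.cohort.annotations_frame`) with the AKI indicator as
    outcome. ``terms="pattern"`` fits the seven combination indicators jointly;
    ``terms="group"`` pools them into single/double/triple indicators. The
    reporting year enters centred as a continuous covariate by default, or
    one-hot per year.

    Raises :class:`ConvergenceError` if Newton iterations do not reach the
    gradient tolerance and :class:`SeparationError` on (quasi-)complete
    separation.
    """
    y = frame["is_aki"].astype(float).to_numpy()
    if len(np.unique(y)) < 2:
        raise ConvergenceError("outcome is constant; logistic model is degenerate")

    X = pd.DataFrame(index=frame.index)
    pat = frame["pattern"].astype(str)
    if terms == "pattern":
        exposure_terms = [p for p in PATTERNS if p != reference]
        for p in exposure_terms:
            X[f"pattern_{p}"] = (pat == p).astype(float)
        term_of = {p: f"pattern_{p}" for p in exposure_terms}
    else:
        groups = {"single": 1, "double": 2, "triple": 3}
        for name, size in groups.items():
            X[f"group_{name}"] = pat.map(lambda s: PATTERN_SIZE[s] == size).astype(float)
        term_of = {name: f"group_{name}" for name in groups}
    # drop exposure columns absent from the data (keeps the design full rank)
    for label, col in list(term_of.items()):
        if X[col].sum() == 0:
            X = X.drop(columns=[col])
            del term_of[label]

    for cov in _COVARIATES:
        X[cov] = frame[cov].astype(float)
    year = pd.to_numeric(frame["report_year"], errors="coerce")
    if year_encoding == "continuous":
        X["report_year"] = (year - year.mean()).fillna(0.0)
    else:
        filled = year.fillna(-1).astype(int)
        for yv in sorted(filled.unique())[1:]:  # first level is the reference
            X[f"year_{yv}"] = (filled == yv).astype(float)
    X = sm.add_constant(X, prepend=True)

    model = sm.Logit(y, X.to_numpy())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            result = model.fit(method="newton", maxiter=maxiter, tol=gtol, disp=0)
        except (np.linalg.LinAlgError, sm.tools.sm_exceptions.PerfectSeparationError) as exc:
            raise SeparationError(f"logistic fit failed: {exc}") from exc

    params = dict(zip(X.columns, result.params))
    bse = dict(zip(X.columns, result.bse))
    grad_norm = float(np.max(np.abs(model.score(result.params))))
    if not result.mle_retvals.get("converged", False) and grad_norm > 1e-4 * len(y):
        raise ConvergenceError(
            f"Newton iterations did not converge (gradient norm {grad_norm:.3g})"
        )
    if any(abs(params[c]) > _SEPARATION_COEF for c in term_of.values()):
        raise SeparationError("diverging exposure coefficient indicates separation")

    z = stats.norm.ppf(1 - alpha / 2)
    adjusted = {}
    for label, col in term_of.items():
        coef, se = params[col], bse[col]
        lo, hi = np.exp(coef - z * se), np.exp(coef + z * se)
        adjusted[label] = RorResult(
            ror=float(np.exp(coef)),
            ci_low=float(lo),
            ci_high=float(hi),
            alpha=alpha,
            signal=lo > 1.0,
        )
    return LogisticFit(
        params=params,
        bse=bse,
        adjusted=adjusted,
        log_likelihood=float(result.llf),
        iterations=int(result.mle_retvals.get("iterations", -1)),
        gradient_norm=grad_norm,
        alpha=alpha,
        n=len(y),
    )


def ror_table(
    frame: pd.DataFrame,
    reference: str = "NONE",
    alpha: float = 0.05,
    zero_policy: ZeroPolicy = "haldane",
) -> pd.DataFrame:
    """Signal table shaped like the published comparison of TW combinations.

    One row per combination pattern plus pooled single/double/triple rows:
    AKI and other-event counts with percentages, crude ROR with CI and signal
    flag, and the covariate-adjusted ROR with CI. Adjusted columns are NaN for
    rows whose model did not converge.
    """
    n_aki = int(frame["is_aki"].sum())
    n_other = int((~frame["is_aki"]).sum())

    fits: dict[str, RorResult] = {}
    try:
        fits.update(adjusted_ror(frame, reference=reference, alpha=alpha, terms="pattern").adjusted)
    except (ConvergenceError, SeparationError):
        pass
    try:
        fits.update(adjusted_ror(frame, reference=reference, alpha=alpha, terms="group").adjusted)
    except (ConvergenceError, SeparationError):
        pass

    row_specs: list[tuple[str, str | list[str]]] = [(p, p) for p in PATTERNS if p != reference]
    for group, size in (("single", 1), ("double", 2), ("triple", 3)):
        pooled = [p for p in PATTERNS if PATTERN_SIZE[p] == size]
        row_specs.append((group, pooled))

    rows = []
    for label, spec in row_specs:
        table = pattern_table(frame, spec, reference=reference)
        try:
            crude = crude_ror(table, alpha=alpha, zero_policy=zero_policy)
            crude_vals = (crude.ror, crude.ci_low, crude.ci_high, crude.signal)
        except DegenerateTableError:
            crude_vals = (np.nan, np.nan, np.nan, False)
        adj = fits.get(label)
        rows.append(
            {
                "row": label,
                "aki_n": table.a,
                "aki_pct": 100.0 * table.a / n_aki if n_aki else np.nan,
                "other_n": table.b,
                "other_pct": 100.0 * table.b / n_other if n_other else np.nan,
                "crude_ror": crude_vals[0],
                "crude_ci_low": crude_vals[1],
                "crude_ci_high": crude_vals[2],
                "signal": crude_vals[3],
                "adjusted_ror": adj.ror if adj else np.nan,
                "adjusted_ci_low": adj.ci_low if adj else np.nan,
                "adjusted_ci_high": adj.ci_high if adj else np.nan,
            }
        )
    return pd.DataFrame(rows)


__all__ = [
    "ContingencyTable2x2",
    "RorResult",
    "LogisticFit",
    "crude_ror",
    "chi_square_2x2",
    "pattern_table",
    "adjusted_ror",
    "ror_table",
]
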