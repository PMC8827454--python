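"""Time-to-onset analysis: durations, Weibull shape test, cumulative incidence,
generalized Wilcoxon comparisons.

For each AKI case exposed to Triple Whammy drugs with complete dates, the
duration is the number of days between the start of the *last* TW drug class
and AKI onset (0 days when onset falls on the start day; an optional
convention counts the start day as day 1). Cases whose TW classes started on
the same day cannot be ordered and are excluded from order-stratified
analyses, though they still contribute to pattern-level totals.

The hazard trend over time is summarized by the two-parameter Weibull shape
parameter beta fitted by maximum likelihood: beta < 1 means early failure
(decreasing hazard — events cluster shortly after exposure), beta = 1 random
failure (constant hazard, exponential), beta > 1 wear-out failure. The MLE
solves the one-dimensional profile score equation

    1/beta + mean(ln x) - sum(x^beta ln x) / sum(x^beta) = 0

by bracketed root finding; the scale is then closed-form,
eta = mean(x^beta)^(1/beta). The CI for beta is a Wald interval on log beta
from the observed information.

With no censoring (every record is an event) the Kaplan-Meier cumulative
incidence reduces to the empirical CDF, and the group median is the first
event time at which it reaches 50%. Groups are compared with the
Gehan-Breslow generalized Wilcoxon test: W = sum over cross-pairs of
sign(b_j - a_i), with the permutation variance conditional on the pooled
sample, or an exhaustive permutation p-value for small samples.
"""

from __future__ import annotations

import datetime as dt
import itertools
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

from .cohort import (
    PATTERN_CLASSES,
    PATTERN_SIZE,
    PATTERNS,
    CaseAnnotation,
    DrugLists,
)
from .defaults import normalize_name, normalize_set
from .errors import ConvergenceError, FitError, ImplausibleSequenceError
from .jader_io import ReportCase

Convention = Literal["day0", "day1"]
ZeroPolicy = Literal["offset_half", "exclude", "shift_all_plus1"]

_RANK_LABELS = ("1st", "2nd", "3rd")


def compute_duration(
    last_start: dt.date, onset: dt.date, convention: Convention = "day0"
) -> int:
    """Days from the last TW drug start to AKI onset.

    ``day0``: onset on the start day is 0 days. ``day1``: the start day counts
    as day 1, so the same-day duration is 1. Onset before the start raises
    :class:`ImplausibleSequenceError` (the caller excludes and logs the case).
    """
    delta = (onset - last_start).days
    if delta < 0:
        raise ImplausibleSequenceError(
            f"onset {onset} precedes last drug start {last_start}"
        )
    return delta + (1 if convention == "day1" else 0)


@dataclass(frozen=True)
class OrderResult:
    """Start order of the TW classes involved in one case."""

    ranks: Mapping[str, int]  # class letter -> 1-based rank (ties share a rank)
    labels: Mapping[str, str]  # class letter -> "1st"/"2nd"/"3rd" or "simultaneous"
    last_class: str | None  # unique latest-started class, if any
    simultaneous: bool  # any tie among the class start dates
    order_key: str  # e.g. "R->N"; "simultaneous" when tied


def order_strata(class_starts: Mapping[str, dt.date]) -> OrderResult:
    """Rank TW classes by their (earliest) start date within one case.

    Any tie among the class start dates marks the case simultaneous: it cannot
    be placed in the "which drug came last" strata.
    """
    items = sorted(class_starts.items(), key=lambda kv: (kv[1], kv[0]))
    dates = [d for _, d in items]
    simultaneous = len(set(dates)) < len(dates)
    if simultaneous:
        ranks = {cls: sorted(dates).index(d) + 1 for cls, d in class_starts.items()}
        labels = {cls: "simultaneous" for cls in class_starts}
        return OrderResult(ranks, labels, None, True, "simultaneous")
    ranks = {cls: i + 1 for i, (cls, _) in enumerate(items)}
    labels = {cls: _RANK_LABELS[r - 1] for cls, r in ranks.items()}
    return OrderResult(
        ranks,
        labels,
        last_class=items[-1][0],
        simultaneous=False,
        order_key="->".join(cls for cls, _ in items),
    )


@dataclass(frozen=True)
class OnsetRecord:
    case_id: str
    pattern: str
    order: Mapping[str, str]  # class letter -> rank label or "simultaneous"
    order_key: str
    last_class: str | None
    simultaneous: bool
    duration_days: float


def build_onset_records(
    cases: Sequence[ReportCase],
    annotations: Sequence[CaseAnnotation],
    lists: DrugLists,
    pt_list: Iterable[str],
    convention: Convention = "day0",
) -> tuple[list[OnsetRecord], dict[str, int]]:
    """Derive one :class:`OnsetRecord` per analyzable AKI+TW case.

    A case is analyzable when every involved TW class has at least one
    complete start date and an AKI reaction has a complete onset date. The per
    class start is the earliest complete start among its drugs (a re-started
    drug keeps its first start). Exclusion counts are returned by reason.
    """
    pts = normalize_set(pt_list)
    by_id = {c.case_id: c for c in cases}
    exclusions = {"missing_start_date": 0, "missing_onset_date": 0, "implausible_sequence": 0}
    records: list[OnsetRecord] = []
    for ann in annotations:
        if not ann.is_aki or ann.pattern == "NONE" or ann.case_id not in by_id:
            continue
        case = by_id[ann.case_id]
        class_starts: dict[str, dt.date] = {}
        complete = True
        for cls in PATTERN_CLASSES[ann.pattern]:
            starts = [
                d.start_date
                for d in case.drugs
                if d.start_date is not None and _in_class(d, cls, lists)
            ]
            if not starts:
                complete = False
                break
            class_starts[cls] = min(starts)
        if not complete:
            exclusions["missing_start_date"] += 1
            continue
        onsets = [
            r.onset_date
            for r in case.reactions
            if r.onset_date is not None and normalize_name(r.pt) in pts
        ]
        if not onsets:
            exclusions["missing_onset_date"] += 1
            continue
        last_start = max(class_starts.values())
        try:
            duration = compute_duration(last_start, min(onsets), convention)
        except ImplausibleSequenceError:
            exclusions["implausible_sequence"] += 1
            continue
        order = order_strata(class_starts)
        records.append(
            OnsetRecord(
                case_id=ann.case_id,
                pattern=ann.pattern,
                order=order.labels,
                order_key=order.order_key,
                last_class=order.last_class,
                simultaneous=order.simultaneous,
                duration_days=float(duration),
            )
        )
    return records, exclusions


def _in_class(drug, cls: str, lists: DrugLists) -> bool:
    name = normalize_name(drug.drug_name)
    if cls == "R":
        return name in lists.rasi
    if cls == "D":
        return name in lists.diuretic
    return name in lists.nsaid and drug.route != "topical"


# ---------------------------------------------------------------------------
# Weibull shape-parameter test


@dataclass(frozen=True)
class WeibullFit:
    shape_beta: float
    scale: float
    beta_ci_low: float
    beta_ci_high: float
    n: int
    log_likelihood: float
    failure_type: str  # early | random | wear_out
    zero_policy: str = "offset_half"

    @property
    def median(self) -> float:
        """Analytic distribution median, scale * ln(2)^(1/shape)."""
        return float(self.scale * np.log(2.0) ** (1.0 / self.shape_beta))


def _profile_score(k: float, log_x: np.ndarray) -> float:
    # 1/k + mean(ln x) - sum(x^k ln x)/sum(x^k), computed via shifted exps
    w = k * log_x
    w = w - w.max()
    e = np.exp(w)
    return 1.0 / k + log_x.mean() - float((e * log_x).sum() / e.sum())


def _weibull_loglik(k: float, lam: float, x: np.ndarray) -> float:
    n = x.size
    return float(
        n * np.log(k)
        - n * k * np.log(lam)
        + (k - 1.0) * np.log(x).sum()
        - ((x / lam) ** k).sum()
    )


def _apply_zero_policy(durations: np.ndarray, policy: ZeroPolicy) -> np.ndarray:
    """Weibull support is strictly positive; day-resolution data contain exact
    zeros (onset on the start day), handled by the configured policy."""
    if policy == "offset_half":
        return np.where(durations == 0.0, 0.5, durations)
    if policy == "exclude":
        return durations[durations > 0.0]
    if policy == "shift_all_plus1":
        return durations + 1.0
    raise ValueError(f"unknown zero policy {policy!r}")


def fit_weibull(
    durations: Sequence[float],
    zero_policy: ZeroPolicy = "offset_half",
    alpha: float = 0.05,
    ci_mode: Literal["ci", "strict"] = "ci",
) -> WeibullFit:
    """Two-parameter Weibull MLE with a Wald CI for the shape on the log scale.

    The shape is found by bracketed root-solving of the profile score; the
    scale is closed-form given the shape. The shape CI uses the observed
    information of the log-parameterized likelihood, so it is always positive.
    """
    x = np.asarray(list(durations), dtype=float)
    if np.any(x < 0) or np.any(~np.isfinite(x)):
        raise FitError("durations must be finite and non-negative")
    x = _apply_zero_policy(x, zero_policy)
    if x.size < 3:
        raise FitError(f"need at least 3 positive durations, have {x.size}")
    if np.ptp(x) == 0.0:
        raise FitError("durations have zero spread; Weibull fit is degenerate")

    log_x = np.log(x)
    lo, hi = 1e-3, 2.0
    while _profile_score(hi, log_x) > 0.0:
        hi *= 2.0
        if hi > 1e4:
            raise ConvergenceError(
                f"profile score has no root in (0, {hi:g}]; bracket search failed"
            )
    if _profile_score(lo, log_x) < 0.0:
        raise ConvergenceError("profile score negative at the lower bracket 1e-3")
    shape = float(optimize.brentq(_profile_score, lo, hi, args=(log_x,), xtol=1e-12))
    w = shape * log_x
    shift = w.max()
    scale = float(np.exp((np.log(np.exp(w - shift).mean()) + shift) / shape))
    ll = _weibull_loglik(shape, scale, x)

    # observed information on (log shape, log scale) by central differences
    t0, t1 = np.log(shape), np.log(scale)
    h = 1e-4

    def f(u0: float, u1: float) -> float:
        return _weibull_loglik(np.exp(u0), np.exp(u1), x)

    h00 = (f(t0 + h, t1) - 2 * ll + f(t0 - h, t1)) / h**2
    h11 = (f(t0, t1 + h) - 2 * ll + f(t0, t1 - h)) / h**2
    h01 = (
        f(t0 + h, t1 + h) - f(t0 + h, t1 - h) - f(t0 - h, t1 + h) + f(t0 - h, t1 - h)
    ) / (4 * h**2)
    info = -np.array([[h00, h01], [h01, h11]])
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError as exc:
        raise ConvergenceError(f"singular observed information: {exc}") from exc
    var_logk = cov[0, 0]
    if var_logk <= 0:
        raise ConvergenceError("non-positive variance for log shape")
    z = stats.norm.ppf(1 - alpha / 2)
    ci_low = float(np.exp(t0 - z * np.sqrt(var_logk)))
    ci_high = float(np.exp(t0 + z * np.sqrt(var_logk)))

    fit = WeibullFit(
        shape_beta=shape,
        scale=scale,
        beta_ci_low=ci_low,
        beta_ci_high=ci_high,
        n=int(x.size),
        log_likelihood=ll,
        failure_type="",
        zero_policy=zero_policy,
    )
    return WeibullFit(**{**fit.__dict__, "failure_type": classify_failure(fit, mode=ci_mode)})


def classify_failure(fit: WeibullFit, mode: Literal["ci", "strict"] = "ci") -> str:
    """Hazard-trend classification from the fitted shape.

    ``strict`` compares the point estimate to 1. The default ``ci`` mode only
    declares early/wear-out failure when the whole CI is on one side of 1;
    otherwise random failure is not excluded.
    """
    if mode == "strict":
        if fit.shape_beta < 1.0:
            return "early"
        if fit.shape_beta > 1.0:
            return "wear_out"
        return "random"
    if fit.beta_ci_high < 1.0:
        return "early"
    if fit.beta_ci_low > 1.0:
        return "wear_out"
    return "random"


# ---------------------------------------------------------------------------
# Cumulative incidence (uncensored Kaplan-Meier = empirical CDF)


@dataclass(frozen=True)
class IncidenceCurve:
    times: tuple[float, ...]  # sorted unique event times
    incidence: tuple[float, ...]  # cumulative incidence at each time
    n: int


def incidence_curve(durations: Sequence[float]) -> IncidenceCurve:
    """Cumulative incidence over time; with every record an event this is the
    empirical CDF, with tied times merged into one step."""
    x = np.asarray(list(durations), dtype=float)
    if x.size == 0:
        raise ValueError("cannot build an incidence curve from an empty sample")
    times, counts = np.unique(x, return_counts=True)
    cum = np.cumsum(counts) / x.size
    return IncidenceCurve(tuple(float(t) for t in times), tuple(float(c) for c in cum), int(x.size))


def median_onset(curve: IncidenceCurve) -> float:
    """Smallest event time at which cumulative incidence reaches 50%."""
    for t, c in zip(curve.times, curve.incidence):
        if c >= 0.5:
            return t
    return curve.times[-1]  # unreachable when the curve ends at 1


# ---------------------------------------------------------------------------
# Gehan-Breslow generalized Wilcoxon test


@dataclass(frozen=True)
class GehanResult:
    statistic: float  # W = sum over cross-pairs of sign(b_j - a_i)
    variance: float
    z: float
    p_value: float
    method: str  # normal_approx | exact_permutation
    #: For the exact method, the Lancaster mid-p (half weight on the observed
    #: atom) — the quantity a continuous approximation of a discrete null
    #: distribution estimates. Equals p_value for the normal approximation.
    mid_p_value: float = float("nan")


def _gehan_scores(pooled: np.ndarray) -> np.ndarray:
    # h_k = #(obs < x_k) - #(obs > x_k) over the pooled sample
    order = np.argsort(pooled, kind="mergesort")
    sorted_x = pooled[order]
    less = np.searchsorted(sorted_x, pooled, side="left")
    greater = pooled.size - np.searchsorted(sorted_x, pooled, side="right")
    return (less - greater).astype(float)


def gehan_wilcoxon(
    a: Sequence[float],
    b: Sequence[float],
    method: Literal["normal_approx", "exact_permutation", "auto"] = "auto",
    exact_limit: int = 12,
) -> GehanResult:
    """Two-sample Gehan-Breslow test on uncensored event times.

    W sums sign(b_j - a_i) over all cross-pairs (ties score 0); equivalently
    W is the sum of pooled Gehan scores over group b. The normal approximation
    uses the permutation variance m*n/(N(N-1)) * sum(h^2); exact permutation
    enumerates all group-b assignments (feasible for small pooled samples, by
    default n <= 12 as "auto").
    """
    xa = np.asarray(list(a), dtype=float)
    xb = np.asarray(list(b), dtype=float)
    if xa.size == 0 or xb.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([xa, xb])
    m, n, N = xa.size, xb.size, pooled.size
    h = _gehan_scores(pooled)
    w_obs = float(h[m:].sum())
    variance = m * n / (N * (N - 1.0)) * float((h**2).sum())

    if method == "auto":
        method = "exact_permutation" if N <= exact_limit else "normal_approx"

    if method == "exact_permutation":
        greater = equal = total = 0
        for subset in itertools.combinations(range(N), n):
            w = abs(float(h[list(subset)].sum()))
            total += 1
            if w > abs(w_obs) + 1e-12:
                greater += 1
            elif w >= abs(w_obs) - 1e-12:
                equal += 1
        p = (greater + equal) / total
        mid_p = (greater + 0.5 * equal) / total
        z = 0.0 if variance == 0 else w_obs / np.sqrt(variance)
        return GehanResult(
            w_obs, variance, float(z), float(p), "exact_permutation", float(mid_p)
        )

    if variance == 0.0:
        return GehanResult(w_obs, 0.0, 0.0, 1.0, "normal_approx", 1.0)
    z = w_obs / np.sqrt(variance)
    p = float(min(2.0 * stats.norm.sf(abs(z)), 1.0))
    return GehanResult(w_obs, variance, float(z), p, "normal_approx", p)


def pairwise_onset_comparison(
    groups: Mapping[str, Sequence[float]],
    adjust: Literal["none", "holm"] = "none",
    method: Literal["normal_approx", "exact_permutation", "auto"] = "normal_approx",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """All unordered pairwise Gehan tests among labeled duration groups."""
    labels = [k for k, v in groups.items() if len(v) > 0]
    if len(labels) < 2:
        raise ValueError("need at least two non-empty groups")
    rows = []
    for ga, gb in itertools.combinations(labels, 2):
        res = gehan_wilcoxon(groups[ga], groups[gb], method=method)
        rows.append(
            {
                "group_a": ga,
                "group_b": gb,
                "n_a": len(groups[ga]),
                "n_b": len(groups[gb]),
                "statistic": res.statistic,
                "z": res.z,
                "p_value": res.p_value,
            }
        )
    frame = pd.DataFrame(rows)
    if adjust == "holm":
        frame["p_adjusted"] = multipletests(frame["p_value"], method="holm")[1]
    else:
        frame["p_adjusted"] = frame["p_value"]
    frame["significant"] = frame["p_adjusted"] < alpha
    return frame


# ---------------------------------------------------------------------------
# Stratified summary tables


def onset_groups(records: Sequence[OnsetRecord]) -> dict[str, dict[str, list[float]]]:
    """Duration groups for the published stratifications.

    ``by_count``: single/double/triple; ``single``: R/D/N; ``double_order``:
    the six ordered double combinations (e.g. "R->N" is an NSAID added to a
    RASI); ``triple_last``: triple cases by which class came last.
    Simultaneous-start cases are excluded from every stratification that
    depends on order (all but the pattern-level totals).
    """
    by_count: dict[str, list[float]] = {"single": [], "double": [], "triple": []}
    single: dict[str, list[float]] = {"R": [], "D": [], "N": []}
    double_order: dict[str, list[float]] = {}
    triple_last: dict[str, list[float]] = {"R": [], "D": [], "N": []}
    for rec in records:
        size = PATTERN_SIZE[rec.pattern]
        if size == 1:
            by_count["single"].append(rec.duration_days)
            single[rec.pattern].append(rec.duration_days)
        elif rec.simultaneous:
            continue
        elif size == 2:
            by_count["double"].append(rec.duration_days)
            double_order.setdefault(rec.order_key, []).append(rec.duration_days)
        else:
            by_count["triple"].append(rec.duration_days)
            triple_last[rec.last_class].append(rec.duration_days)
    return {
        "by_count": by_count,
        "single": single,
        "double_order": double_order,
        "triple_last": triple_last,
    }


def weibull_table(
    records: Sequence[OnsetRecord],
    zero_policy: ZeroPolicy = "offset_half",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Shape-parameter table by combination pattern and start order.

    Pattern-level rows (and single/double/triple totals) include
    simultaneous-start cases; order-stratified sub-rows exclude them. Rows
    whose stratum is too small for a fit carry NaN estimates.
    """
    rows: list[dict] = []

    def add_row(label: str, durations: Sequence[float]) -> None:
        row: dict = {"row": label, "n": len(durations)}
        try:
            fit = fit_weibull(durations, zero_policy=zero_policy, alpha=alpha)
            row.update(
                beta=fit.shape_beta,
                beta_ci_low=fit.beta_ci_low,
                beta_ci_high=fit.beta_ci_high,
                scale=fit.scale,
                failure_type=fit.failure_type,
            )
        except (FitError, ConvergenceError):
            row.update(
                beta=np.nan, beta_ci_low=np.nan, beta_ci_high=np.nan,
                scale=np.nan, failure_type="",
            )
        rows.append(row)

    def durations_of(pred) -> list[float]:
        return [r.duration_days for r in records if pred(r)]

    for p in ("R", "D", "N"):
        add_row(p, durations_of(lambda r, p=p: r.pattern == p))
    add_row("single total", durations_of(lambda r: PATTERN_SIZE[r.pattern] == 1))
    for p in ("RD", "RN", "DN"):
        add_row(p, durations_of(lambda r, p=p: r.pattern == p))
        ordered = sorted(
            {r.order_key for r in records if r.pattern == p and not r.simultaneous}
        )
        for key in ordered:
            add_row(
                f"{p} {key}",
                durations_of(lambda r, p=p, k=key: r.pattern == p and r.order_key == k),
            )
    add_row("double total", durations_of(lambda r: PATTERN_SIZE[r.pattern] == 2))
    for cls in ("R", "D", "N"):
        add_row(
            f"RDN last={cls}",
            durations_of(
                lambda r, c=cls: r.pattern == "RDN" and not r.simultaneous and r.last_class == c
            ),
        )
    add_row("triple total", durations_of(lambda r: r.pattern == "RDN"))
    return pd.DataFrame(rows)


def median_table(records: Sequence[OnsetRecord]) -> pd.DataFrame:
    """Kaplan-Meier medians (first time the incidence reaches 50%) for every
    stratification group; simultaneous-start cases excluded from ordered ones."""
    groups = onset_groups(records)
    rows = []
    for strat, inner in groups.items():
        for label, durations in sorted(inner.items()):
            if not durations:
                continue
            curve = incidence_curve(durations)
            rows.append(
                {
                    "stratification": strat,
                    "group": label,
                    "n": len(durations),
                    "median_days": median_onset(curve),
                }
            )
    return pd.DataFrame(rows)


def curve_table(records: Sequence[OnsetRecord]) -> pd.DataFrame:
    """Step-function coordinates of every group's cumulative incidence curve
    (long format, ready for plotting)."""
    groups = onset_groups(records)
    rows = []
    for strat, inner in groups.items():
        for label, durations in sorted(inner.items()):
            if not durations:
                continue
            curve = incidence_curve(durations)
            for t, c in zip(curve.times, curve.incidence):
                rows.append(
                    {
                        "stratification": strat,
                        "group": label,
                        "time_days": t,
                        "cumulative_incidence": c,
                    }
                )
    return pd.DataFrame(rows)


__all__ = [
    "compute_duration",
    "OrderResult",
    "order_strata",
    "OnsetRecord",
    "build_onset_records",
    "WeibullFit",
    "fit_weibull",
    "classify_failure",
    "IncidenceCurve",
    "incidence_curve",
    "median_onset",
    "GehanResult",
    "gehan_wilcoxon",
    "pairwise_onset_comparison",
    "onset_groups",
    "weibull_table",
    "median_table",
    "curve_table",
]
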