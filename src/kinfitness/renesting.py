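"""Renesting-decision timing and the opportunity cost of helping.

After a nest fails, a pair either renests or terminates breeding for the
year; the probability of renesting declines logistically with failure date.
The day at which it crosses 50% — the termination date — is estimated per
year from annual logistic regressions, failure dates are standardized as
``failure date − termination date + 100``, and the renesting-vs-relative-date
logistic is refit for males that eventually became helpers and males that did
not. If helpers gave up breeding earlier than non-helpers (a lower
inflection), helping would carry an opportunity cost of foregone renesting;
coincident inflections mean no such cost.

Small annual samples make complete separation of the renest/terminate
outcomes likely, so fits fall back to a Jeffreys-prior (Firth) penalized
logistic when the unpenalized likelihood diverges.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

RELATIVE_DATE_OFFSET = 100.0


class RenestingAnalysisError(ValueError):
    pass


@dataclass
class InflectionEstimate:
    """A 50%-renesting point from a logistic fit of outcome on date."""

    date: float
    se: float
    intercept: float
    slope: float
    n: int
    method: str  # 'ml' or 'firth'

    def as_dict(self) -> dict:
        return {
            "date": self.date,
            "se": self.se,
            "intercept": self.intercept,
            "slope": self.slope,
            "n": self.n,
            "method": self.method,
        }


def _firth_logistic(y: np.ndarray, X: np.ndarray, max_iter: int = 100):
    """Firth (Jeffreys-prior) penalized logistic regression by modified
    scoring; keeps estimates finite under complete separation."""
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-np.clip(eta, -30, 30)))
        w = p * (1.0 - p)
        XtWX = X.T @ (X * w[:, None])
        try:
            info_inv = np.linalg.inv(XtWX)
        except np.linalg.LinAlgError:
            raise RenestingAnalysisError("singular information matrix") from None
        # hat values of the weighted design
        WX = X * np.sqrt(w)[:, None]
        h = np.einsum("ij,jk,ik->i", WX, info_inv, WX)
        score = X.T @ (y - p + h * (0.5 - p))
        step = info_inv @ score
        beta = beta + step
        if np.max(np.abs(step)) < 1e-10:
            break
    eta = X @ beta
    p = 1.0 / (1.0 + np.exp(-np.clip(eta, -30, 30)))
    w = p * (1.0 - p)
    cov = np.linalg.inv(X.T @ (X * w[:, None]))
    return beta, cov


def _fit_renesting_logistic(
    renest: np.ndarray, date: np.ndarray
) -> tuple[np.ndarray, np.ndarray, str]:
    """Logistic fit of renest (1) / terminate (0) on date, with the Firth
    fallback under separation. Returns (params, cov, method)."""
    if len(np.unique(renest)) < 2:
        raise RenestingAnalysisError(
            "outcome is constant (all renested or all terminated)"
        )
    X = np.column_stack([np.ones(len(date)), date])
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GLM(renest, X, family=sm.families.Binomial()).fit()
        params = np.asarray(res.params)
        cov = np.asarray(res.cov_params())
        if np.abs(params[1]) > 5.0 or not np.isfinite(cov).all():
            raise PerfectSeparationError("separated")
        return params, cov, "ml"
    except (PerfectSeparationError, np.linalg.LinAlgError, ValueError):
        params, cov = _firth_logistic(renest, X)
        return params, cov, "firth"


def _inflection_from_fit(
    params: np.ndarray, cov: np.ndarray, n: int, method: str
) -> InflectionEstimate:
    a, b = params
    if b == 0:
        raise RenestingAnalysisError("zero slope: no date dependence to invert")
    if b > 0:
        warnings.warn(
            "renesting probability increases with failure date; "
            "the fitted relationship is biologically inverted"
        )
    date = -a / b
    grad = np.array([-1.0 / b, a / b**2])
    var = float(grad @ cov @ grad)
    se = math.sqrt(var) if var > 0 else float("nan")
    return InflectionEstimate(
        date=float(date), se=se, intercept=float(a), slope=float(b), n=n, method=method
    )


def annual_termination_date(attempts: pd.DataFrame) -> InflectionEstimate:
    """Termination date for one year: the failure date at which the fitted
    probability of renesting is 50%, with a delta-method standard error.

    Attempts failing before the year's median first-attempt lay date
    (``year_median_lay`` column, if present) are excluded: such very early
    failures are replaced almost deterministically and carry no information
    about season end.
    """
    df = attempts
    if "year_median_lay" in df.columns:
        df = df[df["failure_date"] >= df["year_median_lay"]]
    if df.empty:
        raise RenestingAnalysisError("no attempts after the median lay date")
    renest = (df["outcome"] == "renested").to_numpy(dtype=float)
    date = df["failure_date"].to_numpy(dtype=float)
    params, cov, method = _fit_renesting_logistic(renest, date)
    return _inflection_from_fit(params, cov, len(df), method)


def termination_dates_by_year(attempts: pd.DataFrame) -> dict[int, InflectionEstimate]:
    """Per-year termination dates from annual logistic regressions."""
    out: dict[int, InflectionEstimate] = {}
    for year, group in attempts.groupby("year"):
        out[int(year)] = annual_termination_date(group)
    return out


def relative_failure_dates(
    attempts: pd.DataFrame,
    terminations: dict[int, InflectionEstimate] | dict[int, float],
    offset: float = RELATIVE_DATE_OFFSET,
) -> pd.DataFrame:
    """Standardize failure dates across years: relative date = failure date
    − that year's termination date + ``offset`` (the offset removes negative
    values). All other columns are preserved."""
    t: dict[int, float] = {
        int(y): (v.date if isinstance(v, InflectionEstimate) else float(v))
        for y, v in terminations.items()
    }
    missing = set(int(y) for y in attempts["year"].unique()) - set(t)
    if missing:
        raise RenestingAnalysisError(
            f"no termination date for year(s) {sorted(missing)}"
        )
    out = attempts.copy()
    out["relative_failure_date"] = [
        fd - t[int(y)] + offset
        for fd, y in zip(attempts["failure_date"], attempts["year"])
    ]
    return out


def renesting_inflection(
    standardized: pd.DataFrame, group: str = "all"
) -> InflectionEstimate:
    """50%-renesting point on the relative-date scale for ``group`` in
    {'all', 'helpers', 'non_helpers'}."""
    if group == "helpers":
        df = standardized[standardized["became_helper"]]
    elif group == "non_helpers":
        df = standardized[~standardized["became_helper"].astype(bool)]
    elif group == "all":
        df = standardized
    else:
        raise RenestingAnalysisError("group must be 'all', 'helpers' or 'non_helpers'")
    if df.empty:
        raise RenestingAnalysisError(f"group {group!r} is empty")
    renest = (df["outcome"] == "renested").to_numpy(dtype=float)
    date = df["relative_failure_date"].to_numpy(dtype=float)
    params, cov, method = _fit_renesting_logistic(renest, date)
    return _inflection_from_fit(params, cov, len(df), method)


@dataclass
class OpportunityCostReport:
    """Comparison of renesting inflections for helpers vs non-helpers."""

    helpers: InflectionEstimate
    non_helpers: InflectionEstimate
    difference: float
    se: float
    z: float
    ci_low: float
    ci_high: float
    cost_detected: bool
    verdict: str

    def as_dict(self) -> dict:
        return {
            "helpers": self.helpers.as_dict(),
            "non_helpers": self.non_helpers.as_dict(),
            "difference": self.difference,
            "se": self.se,
            "z": self.z,
            "ci": [self.ci_low, self.ci_high],
            "cost_detected": self.cost_detected,
            "verdict": self.verdict,
        }


def opportunity_cost_test(
    helpers: InflectionEstimate, non_helpers: InflectionEstimate
) -> OpportunityCostReport:
    """Test whether males that became helpers abandoned breeding earlier
    than males that did not (which would be an opportunity cost of helping).

    A helper inflection below the non-helper inflection with a 95% CI
    excluding zero flags a cost; a CI covering zero is 'no opportunity cost
    detected'.
    """
    diff = helpers.date - non_helpers.date
    se = math.sqrt(helpers.se**2 + non_helpers.se**2)
    z = diff / se if se > 0 else float("inf")
    lo, hi = diff - 1.96 * se, diff + 1.96 * se
    detected = not (lo <= 0.0 <= hi) and diff < 0
    verdict = (
        "opportunity cost: helpers terminate breeding earlier than non-helpers"
        if detected
        else "no opportunity cost detected"
    )
    return OpportunityCostReport(
        helpers=helpers,
        non_helpers=non_helpers,
        difference=diff,
        se=se,
        z=z,
        ci_low=lo,
        ci_high=hi,
        cost_detected=detected,
        verdict=verdict,
    )


def analyze_attempts(attempts: pd.DataFrame) -> dict:
    """Full renesting analysis: per-year termination dates, standardized
    dates, overall and per-group inflections, and the opportunity-cost test.

    Years whose termination date cannot be estimated (constant outcome,
    e.g. every pair renested) are dropped from the standardized comparison
    with a warning; their attempts carry no information about the decision
    threshold.
    """
    terminations: dict[int, InflectionEstimate] = {}
    dropped: list[int] = []
    for year, group in attempts.groupby("year"):
        try:
            terminations[int(year)] = annual_termination_date(group)
        except RenestingAnalysisError as exc:
            dropped.append(int(year))
            warnings.warn(f"year {year}: {exc}; excluded from the analysis")
    if not terminations:
        raise RenestingAnalysisError("no year has an estimable termination date")
    attempts = attempts[~attempts["year"].astype(int).isin(dropped)]
    standardized = relative_failure_dates(attempts, terminations)
    if "year_median_lay" in standardized.columns:
        standardized = standardized[
            standardized["failure_date"] >= standardized["year_median_lay"]
        ]
    overall = renesting_inflection(standardized, "all")
    helpers = renesting_inflection(standardized, "helpers")
    non_helpers = renesting_inflection(standardized, "non_helpers")
    report = opportunity_cost_test(helpers, non_helpers)
    return {
        "termination_dates": {y: t.as_dict() for y, t in terminations.items()},
        "dropped_years": dropped,
        "overall_inflection": overall.as_dict(),
        "opportunity_cost": report.as_dict(),
    }
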