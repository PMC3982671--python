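"""Fledgling recruitment: multilevel logistic model and helper marginal effects.

The model is a logit-link binomial regression of recruitment (a fledgling
entering the breeding population the next year) on sex and the number of
helpers that provisioned it, with crossed random intercepts for year and
natal nest:

    logit P(recruit) = β₀ + β_f·female + β_h·helpers + u_year + u_nest

The per-helper marginal effect on recruitment probability is the derivative
of the inverse-logit at a covariate point, β_h·p(1−p), with a confidence
interval from simulating the (approximate) sampling distribution of the
fixed coefficients. The effect is converted to male-recruit equivalents per
helper by multiplying by mean brood size and the male sex ratio.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit
import statsmodels.api as sm
from statsmodels.genmod.bayes_mixed_glm import BinomialBayesMixedGLM
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .config import PopulationConstants

_FIXED_NAMES = ("intercept", "female", "helpers")


class RecruitmentModelError(ValueError):
    pass


class SeparationError(RecruitmentModelError):
    """The likelihood is maximized at an infinite coefficient."""


@dataclass
class LogisticFit:
    """Fitted recruitment model.

    ``coefficients`` are (intercept, female, helpers) on the logit scale;
    ``cov`` is their (approximate) covariance. ``year_re_sd`` and
    ``nest_re_sd`` are the estimated random-intercept standard deviations
    (zero for the fixed-effects fallback). ``method`` records whether the
    crossed-random-intercept variational fit or the fixed-effects fallback
    produced the coefficients.
    """

    coefficients: np.ndarray
    cov: np.ndarray
    year_re_sd: float
    nest_re_sd: float
    n: int
    n_years: int
    n_nests: int
    method: str
    converged: bool
    fallback: bool = False

    @property
    def intercept(self) -> float:
        return float(self.coefficients[0])

    @property
    def female_effect(self) -> float:
        return float(self.coefficients[1])

    @property
    def helper_effect(self) -> float:
        return float(self.coefficients[2])

    def as_dict(self) -> dict:
        return {
            "coefficients": dict(zip(_FIXED_NAMES, map(float, self.coefficients))),
            "cov": self.cov.tolist(),
            "year_re_sd": self.year_re_sd,
            "nest_re_sd": self.nest_re_sd,
            "n": self.n,
            "n_years": self.n_years,
            "n_nests": self.n_nests,
            "method": self.method,
            "converged": self.converged,
            "fallback": self.fallback,
        }


def _design(obs: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    required = {"female", "helpers", "year", "nest_id", "recruited"}
    missing = required - set(obs.columns)
    if missing:
        raise RecruitmentModelError(f"observations lack columns {sorted(missing)}")
    y = obs["recruited"].to_numpy(dtype=float)
    X = np.column_stack(
        [
            np.ones(len(obs)),
            obs["female"].to_numpy(dtype=float),
            obs["helpers"].to_numpy(dtype=float),
        ]
    )
    return y, X


def _check_outcome(y: np.ndarray) -> None:
    if len(np.unique(y)) < 2:
        raise RecruitmentModelError("outcome is constant; the model is unidentifiable")


def _check_separation(params: np.ndarray) -> None:
    big = np.abs(params) > 15.0
    if big.any():
        name = _FIXED_NAMES[int(np.argmax(np.abs(params)))]
        raise SeparationError(
            f"coefficient for {name!r} diverged (separation in the data)"
        )


def _fit_fixed(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray, bool]:
    model = sm.GLM(y, X, family=sm.families.Binomial())
    try:
        res = model.fit()
    except PerfectSeparationError as exc:
        raise SeparationError(str(exc)) from exc
    _check_separation(res.params)
    return np.asarray(res.params), np.asarray(res.cov_params()), bool(res.converged)


def fit_recruitment_model(
    obs: pd.DataFrame, method: str = "auto"
) -> LogisticFit:
    """Fit the recruitment model.

    ``method='mixed'`` fits the crossed random intercepts for year and nest
    by a variational Bayes approximation; ``'fixed'`` fits a plain logistic
    regression; ``'auto'`` (default) tries the mixed fit and falls back,
    flagged, to the fixed-effects fit if it does not converge. The mixed
    fit's fixed-coefficient covariance is the variational posterior
    covariance (diagonal), which slightly understates between-coefficient
    correlation.
    """
    if method not in ("auto", "mixed", "fixed"):
        raise RecruitmentModelError("method must be 'auto', 'mixed' or 'fixed'")
    y, X = _design(obs)
    _check_outcome(y)
    years = pd.Categorical(obs["year"])
    nests = pd.Categorical(obs["nest_id"])
    n_years, n_nests = len(years.categories), len(nests.categories)
    if n_years < 2 or n_nests < 2:
        raise RecruitmentModelError(
            "need at least 2 year groups and 2 nest groups for random intercepts"
        )

    if method in ("auto", "mixed"):
        try:
            from scipy import sparse

            z_year = sparse.csr_matrix(
                (np.ones(len(obs)), (np.arange(len(obs)), years.codes)),
                shape=(len(obs), n_years),
            )
            z_nest = sparse.csr_matrix(
                (np.ones(len(obs)), (np.arange(len(obs)), nests.codes)),
                shape=(len(obs), n_nests),
            )
            exog_vc = sparse.hstack([z_year, z_nest]).tocsr()
            ident = np.concatenate(
                [np.zeros(n_years, dtype=int), np.ones(n_nests, dtype=int)]
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                glmm = BinomialBayesMixedGLM(y, X, exog_vc, ident, vcp_p=2.0, fe_p=2.0)
                res = glmm.fit_vb()
            params = np.asarray(res.fe_mean)
            _check_separation(params)
            cov = np.diag(np.asarray(res.fe_sd) ** 2)
            re_sds = np.exp(np.asarray(res.vcp_mean))
            return LogisticFit(
                coefficients=params,
                cov=cov,
                year_re_sd=float(re_sds[0]),
                nest_re_sd=float(re_sds[1]),
                n=len(obs),
                n_years=n_years,
                n_nests=n_nests,
                method="mixed_vb",
                converged=True,
            )
        except SeparationError:
            raise
        except Exception:
            if method == "mixed":
                raise
            # fall through to the flagged fixed-effects fit

    params, cov, converged = _fit_fixed(y, X)
    return LogisticFit(
        coefficients=params,
        cov=cov,
        year_re_sd=0.0,
        nest_re_sd=0.0,
        n=len(obs),
        n_years=n_years,
        n_nests=n_nests,
        method="fixed",
        converged=converged,
        fallback=(method == "auto"),
    )


def predict_recruitment(fit: LogisticFit, female: int, helpers: float) -> float:
    """Fitted recruitment probability at the covariates, random effects at
    zero: logit⁻¹(β₀ + β_f·female + β_h·helpers)."""
    if not fit.converged:
        raise RecruitmentModelError("fit did not converge")
    eta = fit.intercept + fit.female_effect * female + fit.helper_effect * helpers
    return float(expit(eta))


@dataclass
class MarginalEffect:
    """Per-helper change in recruitment probability with a simulation CI."""

    estimate: float
    ci_low: float
    ci_high: float
    scheme: str
    female: int | None
    helpers: float | None
    n_draws: int
    seed: int

    def as_dict(self) -> dict:
        return {
            "estimate": self.estimate,
            "ci": [self.ci_low, self.ci_high],
            "scheme": self.scheme,
            "female": self.female,
            "helpers": self.helpers,
            "n_draws": self.n_draws,
            "seed": self.seed,
        }


def _point_effect(beta: np.ndarray, scheme_X: np.ndarray) -> float | np.ndarray:
    """β_h·p(1−p), possibly averaged over rows of the evaluation design."""
    eta = scheme_X @ beta
    p = expit(eta)
    return float(np.mean(beta[2] * p * (1.0 - p)))


def marginal_effect(
    fit: LogisticFit,
    scheme: str = "at",
    female: int = 0,
    helpers: float = 1.8,
    obs: pd.DataFrame | None = None,
    n_draws: int = 10_000,
    seed: int = 0,
) -> MarginalEffect:
    """Marginal effect of one additional helper on recruitment probability.

    ``scheme='at'`` evaluates β_h·p(1−p) at the given covariates (default:
    a male fledgling at the mean helper number of helped nests, 1.8);
    ``scheme='average'`` averages the derivative over the observed
    covariates, which requires ``obs``. The 95% CI is the 2.5/97.5
    percentile of the same quantity over ``n_draws`` multivariate-normal
    draws of the fixed coefficients; it is deterministic given ``seed``.
    """
    if n_draws < 100:
        raise RecruitmentModelError("n_draws < 100 gives unstable percentiles")
    if scheme == "at":
        scheme_X = np.array([[1.0, float(female), float(helpers)]])
    elif scheme == "average":
        if obs is None:
            raise RecruitmentModelError("scheme='average' requires the observations")
        _, scheme_X = _design(obs)
        female = None
        helpers = None
    else:
        raise RecruitmentModelError("scheme must be 'at' or 'average'")

    beta = fit.coefficients
    point = _point_effect(beta, scheme_X)
    rng = np.random.default_rng(seed)
    draws = rng.multivariate_normal(beta, fit.cov, size=n_draws)
    eta = scheme_X @ draws.T  # (n_eval, n_draws)
    p = expit(eta)
    effects = np.mean(draws[:, 2] * p * (1.0 - p), axis=0)
    lo, hi = np.percentile(effects, [2.5, 97.5])
    return MarginalEffect(
        estimate=float(point),
        ci_low=float(lo),
        ci_high=float(hi),
        scheme=scheme,
        female=female,
        helpers=helpers,
        n_draws=n_draws,
        seed=seed,
    )


@dataclass
class RecruitsPerHelper:
    """Marginal effect of a helper expressed as male recruits."""

    estimate: float
    ci_low: float | None
    ci_high: float | None
    mean_brood_size: float
    male_sex_ratio: float

    def as_dict(self) -> dict:
        return {
            "estimate": self.estimate,
            "ci": None if self.ci_low is None else [self.ci_low, self.ci_high],
            "mean_brood_size": self.mean_brood_size,
            "male_sex_ratio": self.male_sex_ratio,
        }


def recruits_per_helper(
    marginal: MarginalEffect | float,
    consts: PopulationConstants = PopulationConstants(),
) -> RecruitsPerHelper:
    """Convert a per-fledgling recruitment effect into male recruits per
    helper: brood size × male sex ratio × marginal effect. CI endpoints are
    transformed identically when present."""
    factor = consts.mean_brood_size * consts.male_sex_ratio
    if isinstance(marginal, MarginalEffect):
        return RecruitsPerHelper(
            estimate=factor * marginal.estimate,
            ci_low=factor * marginal.ci_low,
            ci_high=factor * marginal.ci_high,
            mean_brood_size=consts.mean_brood_size,
            male_sex_ratio=consts.male_sex_ratio,
        )
    return RecruitsPerHelper(
        estimate=factor * float(marginal),
        ci_low=None,
        ci_high=None,
        mean_brood_size=consts.mean_brood_size,
        male_sex_ratio=consts.male_sex_ratio,
    )
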