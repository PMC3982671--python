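"""Survival effects of helping: load-lightening benefit and helping cost.

Two quantities feed the Hamilton accounting. The benefit side is
load-lightening: helped male breeders provision less and survive better, and
the survival difference divided by the mean number of helpers gives a
per-helper survival effect. The cost side needs a latent-quality
decomposition, because failed breeders self-select into helping: birds that
decline an opportunity to help are disproportionately low-quality, so the raw
helper/non-helper comparison hides the cost. Treating no-opportunity birds as
the same two-class quality mixture as opportunity birds, the high-quality
survival rate solves

    s_overall = p_low·s_low + (1 − p_low)·s_high,

and the helping cost is the difference between helper survival and the
inferred high-quality non-helper survival. Survival deltas are converted to
male genetic equivalents by chaining the annual probability that a pair
produces a male recruit and the breeder-to-own-brood relatedness.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import PopulationConstants

CATEGORIES = ("helped", "opportunity_not_helped", "no_opportunity")


class SurvivalAnalysisError(ValueError):
    pass


class InconsistentMixtureError(SurvivalAnalysisError):
    """The implied high-quality survival falls outside [0, 1]."""


def _check_prob(name: str, p: float) -> None:
    if not 0.0 <= p <= 1.0:
        raise SurvivalAnalysisError(f"{name} must be in [0, 1], got {p}")


def per_helper_survival_benefit(
    s_with: float, s_without: float, mean_helpers: float
) -> float:
    """Per-helper effect on breeder survival: (s_with − s_without) / mean
    helpers at helped nests."""
    _check_prob("s_with", s_with)
    _check_prob("s_without", s_without)
    if mean_helpers <= 0:
        raise SurvivalAnalysisError("mean_helpers must be positive")
    return (s_with - s_without) / mean_helpers


@dataclass
class GeneticEquivalents:
    """A survival delta chained into male recruits and genetic equivalents."""

    survival_delta: float
    annual_male_recruit_prob: float
    breeder_brood_relatedness: float
    male_recruits: float
    genetic_equivalents: float

    def as_dict(self) -> dict:
        return {
            "survival_delta": self.survival_delta,
            "annual_male_recruit_prob": self.annual_male_recruit_prob,
            "breeder_brood_relatedness": self.breeder_brood_relatedness,
            "male_recruits": self.male_recruits,
            "genetic_equivalents": self.genetic_equivalents,
        }


def to_genetic_equivalents(
    survival_delta: float, consts: PopulationConstants = PopulationConstants()
) -> GeneticEquivalents:
    """Chain a survival delta into future-reproduction currency:
    delta × P(male recruit) → male recruits, × breeder-brood relatedness →
    male genetic equivalents. The sign of the delta is preserved."""
    recruits = survival_delta * consts.annual_male_recruit_prob
    return GeneticEquivalents(
        survival_delta=survival_delta,
        annual_male_recruit_prob=consts.annual_male_recruit_prob,
        breeder_brood_relatedness=consts.breeder_brood_relatedness,
        male_recruits=recruits,
        genetic_equivalents=recruits * consts.breeder_brood_relatedness,
    )


def solve_quality_mixture(s_overall: float, p_low: float, s_low: float) -> float:
    """High-quality survival implied by a two-class mixture:
    s_high = (s_overall − p_low·s_low) / (1 − p_low)."""
    _check_prob("s_overall", s_overall)
    _check_prob("s_low", s_low)
    if not 0.0 < p_low < 1.0:
        raise SurvivalAnalysisError("p_low must lie strictly between 0 and 1")
    if s_low > s_overall:
        raise SurvivalAnalysisError(
            "s_low exceeds s_overall; the low-quality class cannot outlive the mixture"
        )
    s_high = (s_overall - p_low * s_low) / (1.0 - p_low)
    if not 0.0 <= s_high <= 1.0:
        raise InconsistentMixtureError(
            f"implied high-quality survival {s_high:.4f} outside [0, 1]"
        )
    return s_high


def helping_cost(s_helper: float, s_high_nonhelper: float) -> float:
    """Survival cost of helping: helper survival minus the survival of
    high-quality birds that did not help (negative when helping is costly)."""
    _check_prob("s_helper", s_helper)
    _check_prob("s_high_nonhelper", s_high_nonhelper)
    return s_helper - s_high_nonhelper


@dataclass
class QualityMixture:
    """Latent two-class decomposition of failed-breeder survival."""

    p_low: float
    s_low: float
    s_overall: float
    s_helper: float
    s_high: float
    cost: float

    def as_dict(self) -> dict:
        return {
            "p_low": self.p_low,
            "s_low": self.s_low,
            "s_overall": self.s_overall,
            "s_helper": self.s_helper,
            "s_high": self.s_high,
            "cost": self.cost,
            # Stated model assumption, carried in the report rather than
            # left implicit: no-opportunity birds share the quality
            # composition of opportunity birds.
            "assumption": "no-opportunity birds share the opportunity birds' quality mix",
        }


@dataclass
class ConsistencyReport:
    """Comparison of the survival cost:benefit ratio with the provisioning
    feed ratio (how many feeds a helper contributes per feed a breeder saves
    through load-lightening)."""

    survival_ratio: float
    feed_ratio: float
    difference: float

    def as_dict(self) -> dict:
        return {
            "survival_ratio": self.survival_ratio,
            "feed_ratio": self.feed_ratio,
            "difference": self.difference,
        }


def feed_ratio_consistency(
    feed_ratio: float, cost: float, benefit: float
) -> ConsistencyReport:
    """Check that the helper-cost : breeder-benefit survival ratio is on the
    same scale as the provisioning feed ratio."""
    if benefit == 0:
        raise SurvivalAnalysisError("benefit must be non-zero")
    ratio = abs(cost) / abs(benefit)
    return ConsistencyReport(
        survival_ratio=ratio,
        feed_ratio=feed_ratio,
        difference=abs(ratio - feed_ratio),
    )


@dataclass
class CategorySurvival:
    """Observed survival proportion of one failed-breeder category."""

    rate: float
    se: float
    n: int


def estimate_category_survival(
    table: pd.DataFrame,
) -> dict[str, CategorySurvival]:
    """Per-category survival proportions with binomial standard errors.

    The table needs columns ``category`` (one of ``helped``,
    ``opportunity_not_helped``, ``no_opportunity``) and binary ``survived``.
    """
    required = {"category", "survived"}
    if not required.issubset(table.columns):
        raise SurvivalAnalysisError(f"survival table must have columns {sorted(required)}")
    unknown = set(table["category"]) - set(CATEGORIES)
    if unknown:
        raise SurvivalAnalysisError(f"unknown survival categories: {sorted(unknown)}")
    out: dict[str, CategorySurvival] = {}
    for cat in CATEGORIES:
        sub = table[table["category"] == cat]
        if sub.empty:
            raise SurvivalAnalysisError(f"survival category {cat!r} is empty")
        n = len(sub)
        rate = float(sub["survived"].mean())
        out[cat] = CategorySurvival(
            rate=rate, se=math.sqrt(rate * (1.0 - rate) / n), n=n
        )
    return out


@dataclass
class SurvivalReport:
    """Full cost-side analysis of a failed-breeder survival table."""

    categories: dict[str, CategorySurvival]
    mixture: QualityMixture
    cost_equivalents: GeneticEquivalents
    non_altruistic: bool

    def as_dict(self) -> dict:
        return {
            "categories": {
                k: {"rate": v.rate, "se": v.se, "n": v.n}
                for k, v in self.categories.items()
            },
            "mixture": self.mixture.as_dict(),
            "cost_equivalents": self.cost_equivalents.as_dict(),
            "non_altruistic": self.non_altruistic,
        }


def analyze_survival_table(
    table: pd.DataFrame,
    consts: PopulationConstants = PopulationConstants(),
    p_low: float | None = None,
) -> SurvivalReport:
    """End-to-end cost estimation from a failed-breeder survival table.

    The low-quality fraction defaults to the observed proportion of
    opportunity birds that declined to help (self-selection makes decliners
    the low-quality class); pass ``p_low`` to override. The no-opportunity
    category supplies the mixture's overall survival, the decliners its
    low-quality survival, and the helpers the helper survival.
    """
    cats = estimate_category_survival(table)
    if p_low is None:
        n_opp = cats["helped"].n + cats["opportunity_not_helped"].n
        p_low = cats["opportunity_not_helped"].n / n_opp
    s_low = cats["opportunity_not_helped"].rate
    s_overall = cats["no_opportunity"].rate
    s_helper = cats["helped"].rate
    s_high = solve_quality_mixture(s_overall, p_low, s_low)
    cost = helping_cost(s_helper, s_high)
    mixture = QualityMixture(
        p_low=p_low,
        s_low=s_low,
        s_overall=s_overall,
        s_helper=s_helper,
        s_high=s_high,
        cost=cost,
    )
    return SurvivalReport(
        categories=cats,
        mixture=mixture,
        cost_equivalents=to_genetic_equivalents(cost, consts),
        non_altruistic=cost > 0,
    )


@dataclass
class LoadLightening:
    """Benefit-side summary: breeder survival with and without helpers."""

    s_with: float
    s_without: float
    mean_helpers: float
    delta: float
    per_helper: float
    benefit_equivalents: GeneticEquivalents

    def as_dict(self) -> dict:
        return {
            "s_with": self.s_with,
            "s_without": self.s_without,
            "mean_helpers": self.mean_helpers,
            "delta": self.delta,
            "per_helper": self.per_helper,
            "benefit_equivalents": self.benefit_equivalents.as_dict(),
        }


def load_lightening_benefit(
    s_with: float = 0.52,
    s_without: float = 0.43,
    consts: PopulationConstants = PopulationConstants(),
) -> LoadLightening:
    """Benefit chain from breeder survival with/without helpers to male
    genetic equivalents per helper. Defaults are the study's modal-brood
    male survival rates."""
    delta = s_with - s_without
    per_helper = per_helper_survival_benefit(s_with, s_without, consts.mean_helpers)
    return LoadLightening(
        s_with=s_with,
        s_without=s_without,
        mean_helpers=consts.mean_helpers,
        delta=delta,
        per_helper=per_helper,
        benefit_equivalents=to_genetic_equivalents(per_helper, consts),
    )
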