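"""Configuration objects for the synthetic population and the analyses.

The study-level constants (mean brood size, brood sex ratio, mean number of
helpers at helped nests, annual probability that a pair produces a male
recruit, breeder-to-own-brood relatedness) are inputs to the accounting, not
code constants: they live in :class:`PopulationConstants` with the long-tailed
tit field-study defaults and can be overridden from YAML.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml


class ConfigurationError(ValueError):
    """Raised when a configuration violates its invariants."""


def _check_prob(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ConfigurationError(f"{name} must be a probability in [0, 1], got {value}")


@dataclass(frozen=True)
class PopulationConstants:
    """Study-level constants used to convert marginal effects into
    male-genetic-equivalent units.

    Attributes
    ----------
    mean_brood_size:
        Mean number of fledglings per successful brood.
    male_sex_ratio:
        Proportion of fledglings that are male.
    mean_helpers:
        Mean number of helpers at helped nests.
    annual_male_recruit_prob:
        Annual probability that a breeding pair produces a male recruit.
    breeder_brood_relatedness:
        Relatedness of a male breeder to the young in his own nest
        (below 0.5 because of extra-pair paternity).
    """

    mean_brood_size: float = 8.9
    male_sex_ratio: float = 0.53
    mean_helpers: float = 1.8
    annual_male_recruit_prob: float = 0.26
    breeder_brood_relatedness: float = 0.48

    def __post_init__(self) -> None:
        if self.mean_brood_size <= 0:
            raise ConfigurationError("mean_brood_size must be positive")
        if self.mean_helpers <= 0:
            raise ConfigurationError("mean_helpers must be positive")
        _check_prob("male_sex_ratio", self.male_sex_ratio)
        _check_prob("annual_male_recruit_prob", self.annual_male_recruit_prob)
        _check_prob("breeder_brood_relatedness", self.breeder_brood_relatedness)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic cooperatively-breeding population.

    Defaults reproduce the statistical structure of the study population:
    a 72% nest failure rate, broods of ~8.9 fledglings at a 0.53 male sex
    ratio, recruitment logistic in helper number with coefficients
    (-1.57, -0.99, +0.32) on the logit scale, a latent two-class quality
    mixture in failed-breeder survival (42% low-quality surviving at 0.24,
    58% high-quality at 0.79) with a 0.23 survival cost of helping, and
    per-year 50%-renesting termination dates.
    """

    n_years: int = 15
    n_pairs_per_year: int = 50
    n_loci: int = 19
    alleles_per_locus: int = 8
    allele_freq_concentration: float = 1.0
    genotype_missing_rate: float = 0.0
    nest_failure_rate: float = 0.72
    mean_brood_size: float = 8.9
    max_brood_size: int = 12
    male_sex_ratio: float = 0.53
    helper_kin_preference: float = 25.0
    helper_male_fraction: float = 0.85
    single_visit_fraction: float = 0.1
    recruit_coefficients: tuple[float, float, float] = (-1.57, -0.99, 0.32)
    year_re_sd: float = 0.3
    nest_re_sd: float = 0.3
    quality_low_fraction: float = 0.42
    survival_low: float = 0.24
    survival_high: float = 0.79
    helping_cost: float = 0.23
    adult_survival: float = 0.55
    philopatric_recruit_rate: float = 0.30
    immigrant_female_fraction: float = 0.5
    mean_lay_date: float = 30.0
    lay_date_sd: float = 8.0
    season_length: int = 120
    termination_slope: float = 0.15
    termination_date_by_year: tuple[float, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_years", "n_pairs_per_year", "n_loci", "alleles_per_locus"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        for name in (
            "nest_failure_rate",
            "male_sex_ratio",
            "helper_male_fraction",
            "single_visit_fraction",
            "quality_low_fraction",
            "survival_low",
            "survival_high",
            "adult_survival",
            "philopatric_recruit_rate",
            "immigrant_female_fraction",
            "genotype_missing_rate",
        ):
            _check_prob(name, getattr(self, name))
        if self.mean_brood_size <= 0:
            raise ConfigurationError("mean_brood_size must be positive")
        if self.survival_low > self.survival_high:
            raise ConfigurationError("survival_low must not exceed survival_high")
        if self.helping_cost > self.survival_high:
            raise ConfigurationError("helping_cost must not exceed survival_high")
        if self.helper_kin_preference < 0:
            raise ConfigurationError("helper_kin_preference must be non-negative")

    def termination_dates(self) -> tuple[float, ...]:
        """Per-year 50%-renesting dates (day-of-season, day 1 = 1 March)."""
        if self.termination_date_by_year is not None:
            if len(self.termination_date_by_year) != self.n_years:
                raise ConfigurationError(
                    "termination_date_by_year must have one entry per year"
                )
            return tuple(float(d) for d in self.termination_date_by_year)
        # Year-to-year variation in season end mimics weather-driven
        # variation; the base sits mid-season so both outcomes occur.
        base = self.mean_lay_date + 22.0
        return tuple(base + 2.0 * ((y * 7) % 5 - 2) for y in range(self.n_years))


def _from_mapping(cls, data: Mapping):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigurationError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    kwargs = dict(data)
    for key in ("recruit_coefficients", "termination_date_by_year"):
        if key in kwargs and kwargs[key] is not None:
            kwargs[key] = tuple(kwargs[key])
    return cls(**kwargs)


def load_simulation_config(path: str | Path) -> SimulationConfig:
    """Read a :class:`SimulationConfig` from a YAML (or flat key: value) file."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, Mapping):
        raise ConfigurationError(f"{path}: expected a mapping of config keys")
    return _from_mapping(SimulationConfig, data)


def load_population_constants(path: str | Path) -> PopulationConstants:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, Mapping):
        raise ConfigurationError(f"{path}: expected a mapping of config keys")
    return _from_mapping(PopulationConstants, data)
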