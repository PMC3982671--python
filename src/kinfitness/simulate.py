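"""Synthetic cooperatively-breeding population generator.

Emulates the structure of a long-tailed tit study population: socially
monogamous pairs breed once per season, most nests are depredated, and
late-failing breeders may redirect care to another pair's brood, with a
preference for nests belonging to first-order kin. The generator produces
the six tables consumed by the downstream analyses (pedigree/genotypes,
nests, helper assignments, fledgling recruitment, failed-breeder survival,
breeding attempts with renesting outcomes) together with the generating
parameters, so every estimator in the package has parameter-recovery tests
without any field data.

Randomness is drawn from a hierarchical seed: one global integer spawns one
independent stream per stage (pedigree, genotypes, helping, recruitment,
survival), so a stage can be regenerated on its own without disturbing the
others.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import poisson

from .config import ConfigurationError, SimulationConfig
from .genotypes import MISSING, GenotypeTable

_STAGES = ("pedigree", "genotypes", "helping", "recruitment", "survival")


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Independent per-stage random stream spawned from the global seed."""
    if stage not in _STAGES:
        raise ValueError(f"unknown stage {stage!r}; expected one of {_STAGES}")
    root = np.random.SeedSequence(seed)
    children = root.spawn(len(_STAGES))
    return np.random.default_rng(children[_STAGES.index(stage)])


@dataclass
class SyntheticDataset:
    """The complete simulated dataset plus the parameters that generated it."""

    pedigree: pd.DataFrame
    genotypes: GenotypeTable
    nests: pd.DataFrame
    helpers: pd.DataFrame
    recruitment: pd.DataFrame
    survival: pd.DataFrame
    attempts: pd.DataFrame
    truth: SimulationConfig

    def tables(self) -> Mapping[str, pd.DataFrame]:
        return {
            "pedigree": self.pedigree,
            "nests": self.nests,
            "helpers": self.helpers,
            "recruitment": self.recruitment,
            "survival": self.survival,
            "attempts": self.attempts,
        }


# ------------------------------------------------------------------ pedigree


def _truncated_poisson(rng, mean: float, low: int, high: int, size: int) -> np.ndarray:
    """Poisson draws conditioned on ``low <= k <= high`` (brood sizes)."""
    ks = np.arange(low, high + 1)
    pmf = poisson.pmf(ks, mean)
    pmf = pmf / pmf.sum()
    return rng.choice(ks, size=size, p=pmf)


class _Registry:
    """Running pedigree state during simulation."""

    def __init__(self) -> None:
        self.rows: list[dict] = []
        self.parents: dict[str, tuple[str | None, str | None]] = {}
        self.sex: dict[str, str] = {}
        self.counter = 0

    def new_individual(
        self,
        sex: str,
        birth_year: int,
        sire: str | None = None,
        dam: str | None = None,
        natal_nest: str | None = None,
    ) -> str:
        self.counter += 1
        ind = f"ind{self.counter:05d}"
        self.rows.append(
            {
                "id": ind,
                "sire": sire,
                "dam": dam,
                "birth_year": birth_year,
                "sex": sex,
                "natal_nest": natal_nest,
            }
        )
        self.parents[ind] = (sire, dam)
        self.sex[ind] = sex
        return ind

    def first_order_kin(self, a: str, b: str) -> bool:
        """Parent-offspring or sibling (sharing at least one parent)."""
        pa, pb = self.parents.get(a, (None, None)), self.parents.get(b, (None, None))
        if a in pb or b in pa:
            return True
        return any(p is not None and p in pb for p in pa)


def pedigree_kinship(parents: Mapping[str, tuple[str | None, str | None]]):
    """Memoized pedigree kinship coefficient φ; relatedness is 2φ.

    ``parents`` maps individual -> (sire, dam) with None for founders.
    The recursion always descends through the individual of greater
    generational depth, which is never an ancestor of the other.
    """
    cache: dict[tuple[str, str], float] = {}
    depth_cache: dict[str, int] = {}

    def depth(x: str) -> int:
        if x in depth_cache:
            return depth_cache[x]
        f, m = parents.get(x, (None, None))
        d = 0 if f is None and m is None else 1 + max(
            depth(p) for p in (f, m) if p is not None
        )
        depth_cache[x] = d
        return d

    def phi(a: str | None, b: str | None) -> float:
        if a is None or b is None:
            return 0.0
        if a == b:
            fa, ma = parents.get(a, (None, None))
            return 0.5 * (1.0 + phi(fa, ma))
        key = (a, b) if a < b else (b, a)
        if key in cache:
            return cache[key]
        deeper, other = (a, b) if depth(a) >= depth(b) else (b, a)
        fy, my = parents.get(deeper, (None, None))
        val = 0.5 * (phi(fy, other) + phi(my, other))
        cache[key] = val
        return val

    def relatedness(a: str, b: str) -> float:
        return 2.0 * phi(a, b) if a != b else 1.0

    return relatedness


def simulate_pedigree(
    config: SimulationConfig, seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the pedigree and the per-year nest table.

    Each year exactly ``n_pairs_per_year`` socially monogamous pairs breed
    once; a nest fails with probability ``nest_failure_rate`` (failure date
    drawn during the exposure period), otherwise it fledges a brood drawn
    around ``mean_brood_size`` with sex ratio ``male_sex_ratio``. Philopatric
    male fledglings recruit into the next year's breeding pool with
    probability ``philopatric_recruit_rate``; surviving adults return with
    probability ``adult_survival``; immigrant founders (unrelated birds,
    mostly females, emulating female-biased dispersal) fill the pool.

    Returns ``(pedigree, nests)``. Pedigree columns: id, sire, dam,
    birth_year, sex, natal_nest. Nest columns: nest_id, year, male_id,
    female_id, lay_date, failed, failure_date, n_fledged.
    """
    if seed is None:
        seed = config.seed
    rng = stage_rng(seed, "pedigree")
    reg = _Registry()
    pool_m: list[str] = []
    pool_f: list[str] = []
    nest_rows: list[dict] = []

    for year in range(config.n_years):
        # survivors carried over from last year; immigrant founders top the
        # pool up to exactly n_pairs_per_year pairs. Female turnover is kept
        # at or above the configured immigrant fraction (female-biased
        # dispersal) by capping how many local females return.
        max_local_f = int(
            round((1 - config.immigrant_female_fraction) * config.n_pairs_per_year)
        )
        pool_f = pool_f[:max_local_f]
        while len(pool_f) < config.n_pairs_per_year:
            pool_f.append(reg.new_individual("F", year - 1))
        while len(pool_m) < config.n_pairs_per_year:
            pool_m.append(reg.new_individual("M", year - 1))
        pool_m = pool_m[: config.n_pairs_per_year]
        pool_f = pool_f[: config.n_pairs_per_year]

        males = list(pool_m)
        females = list(pool_f)
        rng.shuffle(males)
        rng.shuffle(females)
        pairs: list[tuple[str, str]] = []
        for male in males:
            # inbreeding avoidance: skip first-order kin where possible
            pick = next(
                (k for k, f in enumerate(females) if not reg.first_order_kin(male, f)),
                0,
            )
            pairs.append((male, females.pop(pick)))

        lay_dates = rng.normal(config.mean_lay_date, config.lay_date_sd, len(pairs))
        fails = rng.random(len(pairs)) < config.nest_failure_rate
        recruits_m: list[str] = []
        recruits_f: list[str] = []
        for k, (male, female) in enumerate(pairs):
            nest_id = f"Y{year:02d}N{k:03d}"
            lay = float(lay_dates[k])
            row = {
                "nest_id": nest_id,
                "year": year,
                "male_id": male,
                "female_id": female,
                "lay_date": round(lay, 1),
                "failed": bool(fails[k]),
                "failure_date": np.nan,
                "n_fledged": 0,
            }
            if fails[k]:
                # predation anywhere in the ~33-day incubation+nestling window
                row["failure_date"] = round(lay + rng.uniform(5.0, 38.0), 1)
            else:
                size = int(
                    _truncated_poisson(
                        rng, config.mean_brood_size, 1, config.max_brood_size, 1
                    )[0]
                )
                row["n_fledged"] = size
                sexes = np.where(
                    rng.random(size) < config.male_sex_ratio, "M", "F"
                )
                for sex in sexes:
                    child = reg.new_individual(
                        sex, year, sire=male, dam=female, natal_nest=nest_id
                    )
                    if sex == "M":
                        if rng.random() < config.philopatric_recruit_rate:
                            recruits_m.append(child)
                    else:
                        # most juvenile females disperse out of the population
                        if rng.random() < config.philopatric_recruit_rate / 3.0:
                            recruits_f.append(child)
            nest_rows.append(row)

        survive_m = [m for m in pool_m if rng.random() < config.adult_survival]
        survive_f = [f for f in pool_f if rng.random() < config.adult_survival]
        pool_m = survive_m + recruits_m
        pool_f = survive_f + recruits_f

    pedigree = pd.DataFrame(reg.rows)
    nests = pd.DataFrame(nest_rows)
    return pedigree, nests


# ----------------------------------------------------------------- genotypes


def draw_allele_frequencies(
    config: SimulationConfig, rng: np.random.Generator
) -> list[np.ndarray]:
    """Per-locus allele frequencies from a symmetric Dirichlet."""
    conc = config.allele_freq_concentration
    return [
        rng.dirichlet(np.full(config.alleles_per_locus, conc))
        for _ in range(config.n_loci)
    ]


def simulate_genotypes(
    pedigree: pd.DataFrame,
    config: SimulationConfig,
    seed: int | None = None,
    allele_freqs: list[np.ndarray] | None = None,
) -> GenotypeTable:
    """Drop genotypes down the pedigree.

    Founders (rows with no recorded parents) draw two alleles per locus from
    the locus allele frequencies; every other bird inherits one uniformly
    chosen allele from each parent per locus, independently across loci.
    Optional per-call missingness at ``genotype_missing_rate``.
    """
    if seed is None:
        seed = config.seed
    rng = stage_rng(seed, "genotypes")
    if allele_freqs is None:
        allele_freqs = draw_allele_frequencies(config, rng)
    if len(allele_freqs) != config.n_loci:
        raise ConfigurationError("allele_freqs must have one entry per locus")

    ids = list(pedigree["id"])
    order = pedigree.sort_values("birth_year", kind="stable")
    index = {ind: i for i, ind in enumerate(ids)}
    n, L = len(ids), config.n_loci
    alleles = np.zeros((n, L, 2), dtype=np.int32)
    done = np.zeros(n, dtype=bool)

    for row in order.itertuples():
        i = index[row.id]
        sire, dam = row.sire, row.dam
        for parent in (sire, dam):
            if parent is not None and not pd.isna(parent):
                j = index.get(parent)
                if j is None:
                    raise ConfigurationError(f"parent {parent!r} missing from pedigree")
                if not done[j]:
                    raise ConfigurationError(
                        "pedigree is not ancestor-ordered (cycle or bad birth years)"
                    )
        founder = (sire is None or pd.isna(sire)) and (dam is None or pd.isna(dam))
        if founder:
            for locus in range(L):
                freqs = allele_freqs[locus]
                alleles[i, locus] = rng.choice(len(freqs), size=2, p=freqs) + 1
        else:
            for k, parent in enumerate((sire, dam)):
                j = index[parent]
                picks = rng.integers(0, 2, size=L)
                alleles[i, :, k] = alleles[j, np.arange(L), picks]
        done[i] = True

    if config.genotype_missing_rate > 0:
        drop = rng.random((n, L)) < config.genotype_missing_rate
        alleles[drop] = MISSING

    pops = [f"cohort{by}" for by in pedigree["birth_year"]]
    loci = [f"loc{j + 1:02d}" for j in range(L)]
    return GenotypeTable(ids, loci, alleles[[index[i] for i in ids]], pops)


# ------------------------------------------------------------------- helping


def simulate_helping(
    nests: pd.DataFrame,
    pedigree: pd.DataFrame,
    config: SimulationConfig,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assign helpers to broods and classify failed breeders.

    One member of each late-failing pair (failure in the final
    ``late_window`` days before the year's termination date) becomes a
    candidate redirected carer: the male with probability
    ``helper_male_fraction``, matching the male bias of helping. Candidates
    carry a latent quality class (low with probability
    ``quality_low_fraction``); high-quality candidates with an active
    first-order-kin brood help, choosing among all active broods with odds
    multiplied by ``helper_kin_preference`` for kin nests. Low-quality birds
    spurn the opportunity, which is what makes helping self-selected for
    quality in the survival analysis.

    Returns ``(helpers, candidates)``: the helper-assignment table
    (helper_id, nest_id, visits) and the failed-breeder candidate table
    (id, year, sex, quality, has_opportunity, helped, helped_nest).
    """
    if seed is None:
        seed = config.seed
    rng = stage_rng(seed, "helping")
    parents = {
        r.id: (
            None if pd.isna(r.sire) else r.sire,
            None if pd.isna(r.dam) else r.dam,
        )
        for r in pedigree.itertuples()
    }
    relatedness = pedigree_kinship(parents)
    kin_threshold = 0.125  # kin up to second order count as an opportunity
    terminations = config.termination_dates()
    late_window = 40.0  # failures this close to season end can yield helpers

    helper_rows: list[dict] = []
    cand_rows: list[dict] = []
    for year, year_nests in nests.groupby("year"):
        t_year = terminations[int(year)]
        active = year_nests[~year_nests["failed"]]
        failed = year_nests[year_nests["failed"]]
        if active.empty:
            continue
        active_ids = list(active["nest_id"])
        breeders = {
            r.nest_id: (r.male_id, r.female_id) for r in active.itertuples()
        }
        for r in failed.itertuples():
            if r.failure_date < t_year - late_window:
                continue  # early failures renest instead of redirecting care
            is_male = rng.random() < config.helper_male_fraction
            cand = r.male_id if is_male else r.female_id
            quality = "low" if rng.random() < config.quality_low_fraction else "high"
            # the pair shares one social neighbourhood: the kin network that
            # creates a helping opportunity is the pair's (in practice mostly
            # the male's, since most females are immigrants)
            kin_mask = np.array(
                [
                    max(
                        relatedness(member, b)
                        for member in (r.male_id, r.female_id)
                        for b in breeders[nid]
                    )
                    >= kin_threshold
                    for nid in active_ids
                ]
            )
            has_opportunity = bool(kin_mask.any())
            helped = has_opportunity and quality == "high"
            helped_nest = None
            if helped:
                weights = np.where(kin_mask, config.helper_kin_preference, 1.0)
                if not np.isfinite(weights).all():
                    weights = kin_mask.astype(float)
                if weights.sum() == 0:
                    weights = np.ones(len(active_ids))
                helped_nest = rng.choice(active_ids, p=weights / weights.sum())
                if rng.random() < config.single_visit_fraction:
                    visits = 1  # seen at the nest once only; filtered downstream
                else:
                    visits = 2 + int(rng.poisson(15))
                helper_rows.append(
                    {"helper_id": cand, "nest_id": helped_nest, "visits": visits}
                )
            cand_rows.append(
                {
                    "id": cand,
                    "year": int(year),
                    "sex": "M" if is_male else "F",
                    "quality": quality,
                    "has_opportunity": has_opportunity,
                    "helped": helped,
                    "helped_nest": helped_nest,
                }
            )
    helpers = pd.DataFrame(helper_rows, columns=["helper_id", "nest_id", "visits"])
    candidates = pd.DataFrame(
        cand_rows,
        columns=["id", "year", "sex", "quality", "has_opportunity", "helped", "helped_nest"],
    )
    return helpers, candidates


# --------------------------------------------------------------- recruitment


def _helper_counts(helpers: pd.DataFrame, min_visits: int = 2) -> pd.Series:
    if helpers.empty:
        return pd.Series(dtype=int)
    real = helpers[helpers["visits"] >= min_visits]
    return real.groupby("nest_id").size()


def simulate_recruitment(
    nests: pd.DataFrame,
    helpers: pd.DataFrame,
    pedigree: pd.DataFrame,
    config: SimulationConfig,
    seed: int | None = None,
) -> pd.DataFrame:
    """Draw fledgling recruitment outcomes.

    Each fledgling recruits with probability
    ``logit⁻¹(β₀ + β_f·female + β_h·helpers + u_year + u_nest)`` where the
    random intercepts are Gaussian with the configured standard deviations,
    shared within year and nest. Helper count is the number of genuine
    (≥2-visit) helpers at the natal nest.
    """
    if seed is None:
        seed = config.seed
    rng = stage_rng(seed, "recruitment")
    b0, bf, bh = config.recruit_coefficients
    counts = _helper_counts(helpers)
    fledglings = pedigree[pedigree["natal_nest"].notna()]
    nest_year = dict(zip(nests["nest_id"], nests["year"]))

    years = sorted(set(nests["year"]))
    u_year = {y: rng.normal(0.0, config.year_re_sd) for y in years}
    u_nest = {n: rng.normal(0.0, config.nest_re_sd) for n in nests["nest_id"]}

    rows = []
    for r in fledglings.itertuples():
        nest = r.natal_nest
        female = 1 if r.sex == "F" else 0
        n_help = int(counts.get(nest, 0))
        year = nest_year[nest]
        eta = b0 + bf * female + bh * n_help + u_year[year] + u_nest[nest]
        rows.append(
            {
                "fledgling_id": r.id,
                "female": female,
                "helpers": n_help,
                "year": year,
                "nest_id": nest,
                "recruited": int(rng.random() < expit(eta)),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["fledgling_id", "female", "helpers", "year", "nest_id", "recruited"],
    )


# ------------------------------------------------- survival & renesting


def simulate_survival_and_renesting(
    attempts: pd.DataFrame,
    candidates: pd.DataFrame,
    config: SimulationConfig,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw renesting outcomes for failed attempts and survival for failed
    breeders.

    Renesting probability follows the year-specific logistic
    ``logit⁻¹(slope·(T_year − failure_date))`` — identical for eventual
    helpers and non-helpers, so any synchrony the renesting analysis detects
    is genuine. Survival is drawn from the latent quality class:
    low-quality birds survive at ``survival_low``; high-quality birds at
    ``survival_high``, minus ``helping_cost`` if they helped.
    """
    if seed is None:
        seed = config.seed
    rng = stage_rng(seed, "survival")
    terminations = config.termination_dates()

    attempts = attempts.copy()
    t = np.array([terminations[int(y)] for y in attempts["year"]])
    p_renest = expit(config.termination_slope * (t - attempts["failure_date"].to_numpy()))
    attempts["outcome"] = np.where(
        rng.random(len(attempts)) < p_renest, "renested", "terminated"
    )
    helper_years = {
        (r.id, r.year) for r in candidates.itertuples() if r.helped and r.sex == "M"
    }
    attempts["became_helper"] = [
        (m, y) in helper_years
        for m, y in zip(attempts["male_id"], attempts["year"])
    ]

    surv_rows = []
    for r in candidates.itertuples():
        if r.quality == "low":
            p = config.survival_low
        else:
            p = config.survival_high - (config.helping_cost if r.helped else 0.0)
        if p < 0:
            warnings.warn("survival after helping cost < 0; clamped to 0")
            p = 0.0
        if r.helped:
            category = "helped"
        elif r.has_opportunity:
            category = "opportunity_not_helped"
        else:
            category = "no_opportunity"
        surv_rows.append(
            {
                "id": r.id,
                "year": r.year,
                "category": category,
                "survived": int(rng.random() < p),
            }
        )
    survival = pd.DataFrame(surv_rows, columns=["id", "year", "category", "survived"])
    return survival, attempts


def attempts_from_nests(nests: pd.DataFrame) -> pd.DataFrame:
    """Failed nests as male breeding attempts, with the year's median
    first-attempt lay date recorded for the early-failure exclusion."""
    failed = nests[nests["failed"]].copy()
    median_lay = nests.groupby("year")["lay_date"].median()
    out = pd.DataFrame(
        {
            "male_id": failed["male_id"],
            "year": failed["year"],
            "failure_date": failed["failure_date"],
            "year_median_lay": [median_lay[y] for y in failed["year"]],
        }
    )
    return out.reset_index(drop=True)


# -------------------------------------------------------------- orchestrator


def simulate_dataset(config: SimulationConfig, seed: int | None = None) -> SyntheticDataset:
    """Run all generator stages in dependency order."""
    if seed is None:
        seed = config.seed
    config = replace(config, seed=seed)
    pedigree, nests = simulate_pedigree(config, seed)
    genotypes = simulate_genotypes(pedigree, config, seed)
    helpers, candidates = simulate_helping(nests, pedigree, config, seed)
    recruitment = simulate_recruitment(nests, helpers, pedigree, config, seed)
    attempts = attempts_from_nests(nests)
    survival, attempts = simulate_survival_and_renesting(
        attempts, candidates, config, seed
    )
    return SyntheticDataset(
        pedigree=pedigree,
        genotypes=genotypes,
        nests=nests,
        helpers=helpers,
        recruitment=recruitment,
        survival=survival,
        attempts=attempts,
        truth=config,
    )


# --------------------------------------- targeted parameter-recovery draws


def simulate_dyads(
    n: int,
    relationship: str,
    config: SimulationConfig,
    seed: int = 0,
) -> tuple[GenotypeTable, list[tuple[str, str]]]:
    """Genotype pairs of known pedigree relationship for estimator calibration.

    ``relationship`` is one of ``unrelated``, ``parent_offspring``,
    ``full_sib``, ``half_sib`` (expected relatedness 0, 0.5, 0.5, 0.25).
    Returns the genotype table (founder parents included, so allele
    frequencies can be estimated from a large sample) and the focal pairs.
    """
    expected = {"unrelated", "parent_offspring", "full_sib", "half_sib"}
    if relationship not in expected:
        raise ValueError(f"relationship must be one of {sorted(expected)}")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    freqs = draw_allele_frequencies(config, rng)
    L = config.n_loci

    def founder() -> np.ndarray:
        g = np.empty((L, 2), dtype=np.int32)
        for locus in range(L):
            g[locus] = rng.choice(len(freqs[locus]), size=2, p=freqs[locus]) + 1
        return g

    def child(sire: np.ndarray, dam: np.ndarray) -> np.ndarray:
        picks = rng.integers(0, 2, size=(L, 2))
        g = np.empty((L, 2), dtype=np.int32)
        g[:, 0] = sire[np.arange(L), picks[:, 0]]
        g[:, 1] = dam[np.arange(L), picks[:, 1]]
        return g

    ids: list[str] = []
    rows: list[np.ndarray] = []
    pairs: list[tuple[str, str]] = []

    def add(g: np.ndarray, tag: str) -> str:
        ids.append(tag)
        rows.append(g)
        return tag

    for k in range(n):
        if relationship == "unrelated":
            a = add(founder(), f"u{k}a")
            b = add(founder(), f"u{k}b")
        elif relationship == "parent_offspring":
            sire, dam = founder(), founder()
            a = add(sire, f"po{k}p")
            add(dam, f"po{k}m")
            b = add(child(sire, dam), f"po{k}c")
        elif relationship == "full_sib":
            sire, dam = founder(), founder()
            add(sire, f"fs{k}p")
            add(dam, f"fs{k}m")
            a = add(child(sire, dam), f"fs{k}c1")
            b = add(child(sire, dam), f"fs{k}c2")
        else:  # half_sib: shared sire, different dams
            sire, dam1, dam2 = founder(), founder(), founder()
            add(sire, f"hs{k}p")
            add(dam1, f"hs{k}m1")
            add(dam2, f"hs{k}m2")
            a = add(child(sire, dam1), f"hs{k}c1")
            b = add(child(sire, dam2), f"hs{k}c2")
        pairs.append((a, b))

    loci = [f"loc{j + 1:02d}" for j in range(L)]
    table = GenotypeTable(ids, loci, np.stack(rows))
    return table, pairs


def simulate_recruitment_table(
    n_nests: int,
    config: SimulationConfig,
    seed: int = 0,
    n_years: int | None = None,
    helper_dist: tuple[float, ...] = (0.45, 0.25, 0.17, 0.08, 0.05),
) -> pd.DataFrame:
    """Recruitment observations drawn directly from the generating logistic,
    without the full pedigree machinery — the harness for model-recovery
    tests at arbitrary sample size.

    ``helper_dist`` is the probability distribution of helper counts
    (0, 1, 2, ...) across nests.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    b0, bf, bh = config.recruit_coefficients
    if n_years is None:
        n_years = config.n_years
    helper_dist = np.asarray(helper_dist, dtype=float)
    helper_dist = helper_dist / helper_dist.sum()

    years = rng.integers(0, n_years, size=n_nests)
    u_year = rng.normal(0.0, config.year_re_sd, size=n_years)
    rows = []
    for k in range(n_nests):
        n_help = int(rng.choice(len(helper_dist), p=helper_dist))
        size = int(
            _truncated_poisson(rng, config.mean_brood_size, 1, config.max_brood_size, 1)[0]
        )
        u_n = rng.normal(0.0, config.nest_re_sd)
        females = rng.random(size) >= config.male_sex_ratio
        eta = b0 + bf * females + bh * n_help + u_year[years[k]] + u_n
        recruited = rng.random(size) < expit(eta)
        for i in range(size):
            rows.append(
                {
                    "fledgling_id": f"n{k}f{i}",
                    "female": int(females[i]),
                    "helpers": n_help,
                    "year": int(years[k]),
                    "nest_id": f"n{k}",
                    "recruited": int(recruited[i]),
                }
            )
    return pd.DataFrame(rows)


def simulate_survival_table(
    n_per_category: int, config: SimulationConfig, seed: int = 0
) -> pd.DataFrame:
    """Failed-breeder survival table with equal-sized categories at the
    configured quality-mixture truth, for mixture/cost recovery tests.

    Opportunity birds split by latent quality exactly as in the full
    generator: the ``helped`` category is all high quality (survival
    ``survival_high − helping_cost``), ``opportunity_not_helped`` all low
    quality (``survival_low``), and ``no_opportunity`` is the
    ``quality_low_fraction`` mixture of both classes. To keep the printed
    42% spurn rate, opportunity categories are sized accordingly.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    p_low = config.quality_low_fraction
    n_opp = n_per_category
    n_not_helped = int(round(p_low * n_opp / (1 - p_low)))
    rows = []
    helper_survival = max(config.survival_high - config.helping_cost, 0.0)
    for k in range(n_opp):
        rows.append(
            {
                "id": f"h{k}",
                "year": 0,
                "category": "helped",
                "survived": int(rng.random() < helper_survival),
            }
        )
    for k in range(n_not_helped):
        rows.append(
            {
                "id": f"o{k}",
                "year": 0,
                "category": "opportunity_not_helped",
                "survived": int(rng.random() < config.survival_low),
            }
        )
    for k in range(n_per_category):
        low = rng.random() < p_low
        p = config.survival_low if low else config.survival_high
        rows.append(
            {
                "id": f"n{k}",
                "year": 0,
                "category": "no_opportunity",
                "survived": int(rng.random() < p),
            }
        )
    return pd.DataFrame(rows)


def simulate_attempts_table(
    n_per_year: int,
    termination_dates: tuple[float, ...],
    config: SimulationConfig,
    seed: int = 0,
    helper_shift: float = 0.0,
) -> pd.DataFrame:
    """Breeding attempts with renest/terminate outcomes from known per-year
    termination dates, for inflection-recovery tests.

    Failure dates are spread around each year's termination date so the
    logistic is well identified. ``helper_shift`` moves the inflection for
    eventual helpers by that many days (0 = the no-opportunity-cost null).
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    rows = []
    for year, t_year in enumerate(termination_dates):
        dates = rng.normal(t_year, 15.0, size=n_per_year)
        helper = rng.random(n_per_year) < 0.5
        infl = np.where(helper, t_year + helper_shift, t_year)
        p = expit(config.termination_slope * (infl - dates))
        renest = rng.random(n_per_year) < p
        for k in range(n_per_year):
            rows.append(
                {
                    "male_id": f"y{year}m{k}",
                    "year": year,
                    "failure_date": round(float(dates[k]), 1),
                    "year_median_lay": t_year - 40.0,
                    "outcome": "renested" if renest[k] else "terminated",
                    "became_helper": bool(helper[k]),
                }
            )
    return pd.DataFrame(rows)
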