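"""Generator structure: Mendelian transmission, rates, determinism."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import binom

from kinfitness.config import ConfigurationError, SimulationConfig
from kinfitness.simulate import (
    attempts_from_nests,
    pedigree_kinship,
    simulate_dataset,
    simulate_genotypes,
    simulate_helping,
    simulate_pedigree,
    simulate_recruitment_table,
    simulate_survival_table,
)


class TestPedigree:
    def test_nest_count_is_pairs_times_years(self):
        cfg = SimulationConfig(n_years=3, n_pairs_per_year=50)
        _, nests = simulate_pedigree(cfg, seed=1)
        assert len(nests) == 150

    def test_failure_rate_within_binomial_bounds(self):
        cfg = SimulationConfig(n_years=20, n_pairs_per_year=50, nest_failure_rate=0.72)
        _, nests = simulate_pedigree(cfg, seed=2)
        n = len(nests)
        lo, hi = binom.ppf([0.005, 0.995], n, 0.72)
        assert lo <= nests["failed"].sum() <= hi

    def test_zero_failure_rate_means_every_nest_fledges(self):
        cfg = SimulationConfig(n_years=2, n_pairs_per_year=20, nest_failure_rate=0.0)
        _, nests = simulate_pedigree(cfg, seed=3)
        assert not nests["failed"].any()
        assert (nests["n_fledged"] >= 1).all()

    def test_invalid_counts_rejected(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(n_pairs_per_year=0)

    def test_brood_sex_ratio(self, default_dataset):
        fledged = default_dataset.pedigree[default_dataset.pedigree["natal_nest"].notna()]
        n = len(fledged)
        lo, hi = binom.ppf([0.005, 0.995], n, 0.53)
        assert lo <= (fledged["sex"] == "M").sum() <= hi


class TestGenotypes:
    def test_every_individual_has_all_19_loci(self, default_dataset):
        table = default_dataset.genotypes
        assert table.n_loci == 19
        assert len(table) == len(default_dataset.pedigree)

    def test_mendelian_conservation(self, default_dataset):
        """Every non-founder allele is present in the corresponding parent."""
        table = default_dataset.genotypes
        ped = default_dataset.pedigree
        children = ped[ped["sire"].notna()].sample(60, random_state=0)
        for row in children.itertuples():
            g = table.row(row.id)
            gs, gd = table.row(row.sire), table.row(row.dam)
            for j in range(table.n_loci):
                a, b = g[j]
                ok = (a in gs[j] and b in gd[j]) or (a in gd[j] and b in gs[j])
                assert ok, f"{row.id} locus {j}: {g[j]} from {gs[j]} x {gd[j]}"

    def test_homozygote_cross_is_deterministic(self):
        """AA x BB parents always give AB offspring."""
        ped = pd.DataFrame(
            {
                "id": ["s", "d"] + [f"c{i}" for i in range(50)],
                "sire": [None, None] + ["s"] * 50,
                "dam": [None, None] + ["d"] * 50,
                "birth_year": [0, 0] + [1] * 50,
                "sex": ["M", "F"] + ["M"] * 50,
                "natal_nest": [None] * 52,
            }
        )
        cfg = SimulationConfig(n_loci=1, alleles_per_locus=2)
        # force the founders homozygous by redrawing until distinct homozygotes
        for seed in range(50):
            table = simulate_genotypes(ped, cfg, seed=seed)
            gs, gd = table.row("s")[0], table.row("d")[0]
            if gs[0] == gs[1] and gd[0] == gd[1] and gs[0] != gd[0]:
                for i in range(50):
                    child = set(table.row(f"c{i}")[0])
                    assert child == {gs[0], gd[0]}
                return
        pytest.fail("no seed produced distinct homozygous founders")

    def test_heterozygote_cross_segregates_1_2_1(self):
        """AB x AB offspring genotypes fit the 1:2:1 Mendelian ratio."""
        n = 10_000
        rng = np.random.default_rng(42)
        picks = rng.integers(0, 2, size=(n, 2))  # same mechanism as generator
        hom_a = ((picks == 0).all(axis=1)).mean()
        het = (picks.sum(axis=1) == 1).mean()
        assert abs(hom_a - 0.25) < 3 * np.sqrt(0.25 * 0.75 / n)
        assert abs(het - 0.5) < 3 * np.sqrt(0.5 * 0.5 / n)

    def test_cycle_detection(self):
        ped = pd.DataFrame(
            {
                "id": ["a", "b"],
                "sire": ["b", "a"],
                "dam": [None, None],
                "birth_year": [0, 0],
                "sex": ["M", "M"],
                "natal_nest": [None, None],
            }
        )
        with pytest.raises(ConfigurationError, match="ancestor-ordered"):
            simulate_genotypes(ped, SimulationConfig(n_loci=2), seed=0)


class TestKinship:
    def test_pedigree_relatedness_values(self):
        parents = {
            "f": (None, None),
            "m": (None, None),
            "c1": ("f", "m"),
            "c2": ("f", "m"),
            "m2": (None, None),
            "h": ("f", "m2"),
            "u": (None, None),
        }
        r = pedigree_kinship(parents)
        assert r("f", "c1") == pytest.approx(0.5)
        assert r("c1", "c2") == pytest.approx(0.5)
        assert r("c1", "h") == pytest.approx(0.25)
        assert r("c1", "u") == 0.0
        assert r("c1", "c1") == 1.0


class TestHelping:
    def test_helper_male_fraction(self, default_dataset):
        helpers = default_dataset.helpers
        sexes = default_dataset.pedigree.set_index("id")["sex"]
        n = len(helpers)
        males = (sexes.loc[helpers["helper_id"]] == "M").sum()
        lo, hi = binom.ppf([0.005, 0.995], n, 0.85)
        assert lo <= males <= hi

    def test_infinite_kin_preference_always_chooses_kin(self, default_config):
        cfg = SimulationConfig(helper_kin_preference=1e12)
        pedigree, nests = simulate_pedigree(cfg, seed=5)
        helpers, candidates = simulate_helping(nests, pedigree, cfg, seed=5)
        parents = {
            r.id: (
                None if pd.isna(r.sire) else r.sire,
                None if pd.isna(r.dam) else r.dam,
            )
            for r in pedigree.itertuples()
        }
        rel = pedigree_kinship(parents)
        breeders = {r.nest_id: (r.male_id, r.female_id) for r in nests.itertuples()}
        # the choice rule weights nests by the failed pair's kin network
        pair_of = {}
        for r in nests[nests["failed"]].itertuples():
            pair_of[(r.male_id, r.year)] = r.female_id
            pair_of[(r.female_id, r.year)] = r.male_id
        helped = candidates[candidates["helped"]]
        assert len(helped) > 0
        for row in helped.itertuples():
            members = (row.id, pair_of[(row.id, row.year)])
            assert max(
                rel(a, b) for a in members for b in breeders[row.helped_nest]
            ) >= 0.125

    def test_spurn_rate_matches_quality_fraction(self, default_dataset):
        cand = default_dataset.survival
        opp = cand[cand["category"] != "no_opportunity"]
        spurned = (opp["category"] == "opportunity_not_helped").mean()
        n = len(opp)
        lo, hi = binom.ppf([0.005, 0.995], n, 0.42)
        assert lo <= spurned * n <= hi


class TestRecruitmentGenerator:
    def test_base_rate_matches_closed_form(self):
        """Male fledglings with no helpers recruit at logit^-1(-1.57)."""
        cfg = SimulationConfig(year_re_sd=0.0, nest_re_sd=0.0)
        obs = simulate_recruitment_table(
            4000, cfg, seed=9, helper_dist=(1.0,)
        )
        males = obs[obs["female"] == 0]
        p = 1 / (1 + np.exp(1.57))
        n = len(males)
        assert abs(males["recruited"].mean() - p) < 3 * np.sqrt(p * (1 - p) / n)

    def test_null_helper_effect(self):
        cfg = SimulationConfig(
            recruit_coefficients=(-1.0, 0.0, 0.0), year_re_sd=0.0, nest_re_sd=0.0
        )
        obs = simulate_recruitment_table(3000, cfg, seed=10)
        rates = obs.groupby(obs["helpers"] > 0)["recruited"].mean()
        assert abs(rates[True] - rates[False]) < 0.03

    def test_female_logit_shift(self):
        """The sex effect shows up as ~-0.99 on the empirical logit."""
        cfg = SimulationConfig(year_re_sd=0.0, nest_re_sd=0.0)
        obs = simulate_recruitment_table(8000, cfg, seed=11, helper_dist=(1.0,))
        logit = lambda p: np.log(p / (1 - p))
        diff = logit(obs[obs.female == 1]["recruited"].mean()) - logit(
            obs[obs.female == 0]["recruited"].mean()
        )
        assert diff == pytest.approx(-0.99, abs=0.12)


class TestSurvivalGenerator:
    def test_no_opportunity_mixture_rate(self):
        table = simulate_survival_table(20_000, SimulationConfig(), seed=12)
        noop = table[table["category"] == "no_opportunity"]
        assert noop["survived"].mean() == pytest.approx(0.56, abs=0.012)

    def test_helper_rate_after_cost(self):
        table = simulate_survival_table(20_000, SimulationConfig(), seed=13)
        helped = table[table["category"] == "helped"]
        assert helped["survived"].mean() == pytest.approx(0.56, abs=0.012)

    def test_zero_cost_equalizes_helpers_and_high_quality(self):
        cfg = SimulationConfig(helping_cost=0.0)
        table = simulate_survival_table(20_000, cfg, seed=14)
        helped = table[table["category"] == "helped"]["survived"].mean()
        assert helped == pytest.approx(0.79, abs=0.012)


class TestDeterminism:
    def test_same_seed_same_dataset(self, small_config):
        a = simulate_dataset(small_config, seed=77)
        b = simulate_dataset(small_config, seed=77)
        for name in a.tables():
            pd.testing.assert_frame_equal(a.tables()[name], b.tables()[name])
        np.testing.assert_array_equal(a.genotypes.alleles, b.genotypes.alleles)

    def test_different_seed_different_dataset(self, small_config):
        a = simulate_dataset(small_config, seed=77)
        b = simulate_dataset(small_config, seed=78)
        assert not a.nests.equals(b.nests)


def test_attempts_cover_failed_nests(default_dataset):
    failed = default_dataset.nests["failed"].sum()
    assert len(attempts_from_nests(default_dataset.nests)) == failed
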