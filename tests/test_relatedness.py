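"""Queller-Goodnight estimator: hand-derived values, invariances, calibration."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from kinfitness.config import SimulationConfig
from kinfitness.genotypes import MISSING, GenotypeTable
from kinfitness.relatedness import (
    AlleleFrequencies,
    RelatednessError,
    UndefinedRelatednessError,
    estimate_allele_frequencies,
    helper_relatedness_summary,
    jackknife_se_over_loci,
    queller_goodnight,
)
from kinfitness.simulate import simulate_dataset, simulate_dyads


def table_from(rows: dict[str, list[tuple[int, int]]], loci=None) -> GenotypeTable:
    ids = list(rows)
    n_loci = len(next(iter(rows.values())))
    loci = loci or [f"L{j}" for j in range(n_loci)]
    alleles = np.array([[list(pair) for pair in rows[i]] for i in ids])
    return GenotypeTable(ids, loci, alleles)


class TestAlleleFrequencies:
    def test_direct_counts(self):
        table = table_from({"a": [(1, 1)], "b": [(1, 2)]})
        freqs = estimate_allele_frequencies(table).freqs[0]
        assert freqs == {1: 0.75, 2: 0.25}

    def test_monomorphic_locus(self):
        table = table_from({"a": [(3, 3)], "b": [(3, 3)]})
        assert estimate_allele_frequencies(table).freqs[0] == {3: 1.0}

    def test_missing_calls_skipped(self):
        table = table_from({"a": [(1, 2)], "b": [(MISSING, MISSING)]})
        f = estimate_allele_frequencies(table)
        assert f.n_individuals == [1]
        assert f.freqs[0] == {1: 0.5, 2: 0.5}

    def test_all_missing_locus_excluded(self):
        table = table_from({"a": [(1, 1), (0, 0)], "b": [(1, 2), (0, 0)]})
        with pytest.warns(UserWarning, match="excluded"):
            f = estimate_allele_frequencies(table)
        assert f.loci == ["L0"]

    def test_known_frequencies_recovered(self):
        truth = {1: 0.5, 2: 0.3, 3: 0.2}
        rng = np.random.default_rng(21)
        n = 5000
        draws = rng.choice(list(truth), size=(n, 2), p=list(truth.values()))
        table = GenotypeTable(
            [f"i{k}" for k in range(n)], ["L0"], draws[:, None, :]
        )
        est = estimate_allele_frequencies(table).freqs[0]
        for allele, p in truth.items():
            se = np.sqrt(p * (1 - p) / (2 * n))
            assert abs(est[allele] - p) < 3 * se


class TestQuellerGoodnight:
    def test_four_distinct_alleles_equal_frequencies(self):
        """x=(A,B), y=(C,D), all p=0.25: both directed ratios are -1."""
        table = table_from({"x": [(1, 2)], "y": [(3, 4)]})
        freqs = AlleleFrequencies(["L0"], [{1: 1, 2: 1, 3: 1, 4: 1}], [2])
        assert queller_goodnight(table, "x", "y", freqs) == pytest.approx(-1.0)

    def test_identical_genotypes_give_one(self):
        table = table_from(
            {"x": [(1, 2), (3, 3)], "y": [(1, 2), (3, 3)], "z": [(2, 2), (1, 3)]}
        )
        freqs = estimate_allele_frequencies(table)
        assert queller_goodnight(table, "x", "y", freqs) == pytest.approx(1.0)
        assert queller_goodnight(table, "x", "x", freqs) == pytest.approx(1.0)

    def test_symmetry(self):
        rng = np.random.default_rng(3)
        rows = {
            f"i{k}": [tuple(rng.integers(1, 6, 2)) for _ in range(8)] for k in range(12)
        }
        table = table_from(rows)
        freqs = estimate_allele_frequencies(table)
        for a, b in [("i0", "i1"), ("i2", "i9"), ("i4", "i7")]:
            assert queller_goodnight(table, a, b, freqs) == pytest.approx(
                queller_goodnight(table, b, a, freqs), abs=1e-12
            )

    def test_missing_locus_invariance(self):
        """A locus missing in either member leaves the estimate unchanged."""
        base = {"x": [(1, 2), (2, 3)], "y": [(1, 3), (2, 2)], "z": [(3, 3), (1, 1)]}
        with_extra = {
            "x": base["x"] + [(0, 0)],
            "y": base["y"] + [(1, 2)],
            "z": base["z"] + [(2, 3)],
        }
        t1, t2 = table_from(base), table_from(with_extra)
        f1, f2 = estimate_allele_frequencies(t1), estimate_allele_frequencies(t2)
        assert queller_goodnight(t1, "x", "y", f1) == pytest.approx(
            queller_goodnight(t2, "x", "y", f2), abs=1e-12
        )

    def test_no_shared_locus_raises(self):
        table = table_from({"x": [(1, 2), (0, 0)], "y": [(0, 0), (1, 2)]})
        freqs = estimate_allele_frequencies(table)
        with pytest.raises(RelatednessError, match="no co-typed locus"):
            queller_goodnight(table, "x", "y", freqs)

    def test_unknown_allele_raises(self):
        table = table_from({"x": [(1, 2)], "y": [(1, 9)]})
        freqs = AlleleFrequencies(["L0"], [{1: 2, 2: 2}], [2])
        with pytest.raises(RelatednessError, match="absent"):
            queller_goodnight(table, "x", "y", freqs)

    @pytest.mark.parametrize(
        "relationship,expected",
        [("unrelated", 0.0), ("half_sib", 0.25), ("parent_offspring", 0.5)],
    )
    def test_pedigree_calibration(self, relationship, expected):
        """Mean estimate over simulated dyads matches pedigree expectation."""
        cfg = SimulationConfig()
        table, pairs = simulate_dyads(1500, relationship, cfg, seed=31)
        freqs = estimate_allele_frequencies(table)
        vals = [queller_goodnight(table, a, b, freqs) for a, b in pairs]
        assert np.mean(vals) == pytest.approx(expected, abs=0.02)


class TestHelperSummary:
    def test_single_visit_helpers_filtered_to_empty_summary(self, small_dataset):
        helpers = small_dataset.helpers.copy()
        helpers["visits"] = 1
        from kinfitness.relatedness import brood_membership_from_pedigree

        summary = helper_relatedness_summary(
            helpers,
            small_dataset.nests,
            small_dataset.genotypes,
            brood_membership_from_pedigree(small_dataset.pedigree),
        )
        assert summary.helper_to_male.n == 0
        assert summary.n_excluded_single_visit == len(helpers)

    def test_empty_helper_table_raises(self, small_dataset):
        with pytest.raises(RelatednessError, match="empty"):
            helper_relatedness_summary(
                small_dataset.helpers.iloc[0:0],
                small_dataset.nests,
                small_dataset.genotypes,
                {},
            )

    def test_neutral_choice_without_kin_structure_gives_zero_means(self):
        """No kin structure + neutral choice: all three means are ~0."""
        cfg = SimulationConfig(
            n_years=6,
            n_pairs_per_year=60,
            helper_kin_preference=1.0,
            philopatric_recruit_rate=0.0,
            immigrant_female_fraction=1.0,
        )
        ds = simulate_dataset(cfg, seed=41)
        from kinfitness.relatedness import brood_membership_from_pedigree

        # without kin nobody has an "opportunity"; let every candidate help
        # by marking opportunity irrelevant: rebuild helpers from candidates
        # is unnecessary -- with no kin structure nobody helps, so instead
        # assign helpers at random to exercise the estimator neutrally.
        rng = np.random.default_rng(5)
        fledged = ds.nests[~ds.nests["failed"]]
        adults = ds.pedigree[ds.pedigree["natal_nest"].isna()]["id"]
        helpers = pd.DataFrame(
            {
                "helper_id": rng.choice(adults, 150),
                "nest_id": rng.choice(fledged["nest_id"], 150),
                "visits": 5,
            }
        )
        summary = helper_relatedness_summary(
            helpers,
            ds.nests,
            ds.genotypes,
            brood_membership_from_pedigree(ds.pedigree),
        )
        for comp in (
            summary.helper_to_male,
            summary.helper_to_female,
            summary.helper_to_brood,
        ):
            assert abs(comp.mean) <= 3 * comp.se

    def test_kin_preference_elevates_relatedness(self, default_dataset):
        from kinfitness.relatedness import brood_membership_from_pedigree

        summary = helper_relatedness_summary(
            default_dataset.helpers,
            default_dataset.nests,
            default_dataset.genotypes,
            brood_membership_from_pedigree(default_dataset.pedigree),
        )
        assert summary.helper_to_male.mean > 0.08
        assert summary.helper_to_brood.mean > 0.05


def test_jackknife_se_positive():
    cfg = SimulationConfig(n_loci=6)
    table, pairs = simulate_dyads(40, "full_sib", cfg, seed=51)
    mean, se = jackknife_se_over_loci(table, pairs)
    assert mean == pytest.approx(0.5, abs=0.15)
    assert se > 0
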