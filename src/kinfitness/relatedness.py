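"""Pairwise genetic relatedness from codominant markers.

Implements the moment-based Queller & Goodnight regression estimator for
diploid multilocus genotypes. For a focal individual *x* with alleles
``(a, b)`` and a partner *y* with ``(c, d)`` at one locus, with population
allele frequencies ``p``:

    numerator   = ½(S_ac + S_ad + S_bc + S_bd) − p_a − p_b
    denominator = 1 + S_ab − p_a − p_b

where ``S`` is allelic identity (1 if the labels match, else 0). The
multilocus estimate is the ratio of summed numerators to summed denominators
(so low-information loci are weighted by the information they carry), and the
reported value is the average of the two directed ratios (x as focal, y as
focal), which makes the estimator symmetric in its arguments. Loci missing
in either individual are skipped.

The module also summarizes helper-to-recipient relatedness (to the male
breeder, the female breeder, and the helped brood) over a helper-assignment
table, excluding helpers observed provisioning only once.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeTable


class RelatednessError(ValueError):
    pass


class UndefinedRelatednessError(RelatednessError):
    """Both directed denominators are zero: the pair carries no information."""


@dataclass
class AlleleFrequencies:
    """Per-locus allele frequencies with the counts they were derived from."""

    loci: list[str]
    counts: list[dict[int, int]]  # allele label -> observed allele count
    n_individuals: list[int]  # individuals with a complete call at the locus

    @property
    def freqs(self) -> list[dict[int, float]]:
        out = []
        for c in self.counts:
            total = sum(c.values())
            out.append({a: k / total for a, k in c.items()})
        return out

    def excluding(self, table: GenotypeTable, individuals: Sequence[str]) -> "AlleleFrequencies":
        """Frequencies with the named individuals' alleles removed (the
        exclude-pair bias correction)."""
        counts = [dict(c) for c in self.counts]
        n_ind = list(self.n_individuals)
        for ind in individuals:
            row = table.row(ind)
            for j in range(len(self.loci)):
                a, b = int(row[j, 0]), int(row[j, 1])
                if a == MISSING:
                    continue
                counts[j][a] -= 1
                counts[j][b] -= 1
                n_ind[j] -= 1
                if counts[j][a] == 0:
                    del counts[j][a]
                if b != a and counts[j].get(b) == 0:
                    del counts[j][b]
        return AlleleFrequencies(self.loci, counts, n_ind)


def estimate_allele_frequencies(table: GenotypeTable) -> AlleleFrequencies:
    """Count-based allele frequencies over all non-missing calls.

    A locus with no complete calls is excluded with a warning; a locus typed
    in fewer than two individuals is unreliable for the estimator and is
    kept but warned about.
    """
    loci: list[str] = []
    counts: list[dict[int, int]] = []
    n_ind: list[int] = []
    for j, locus in enumerate(table.loci):
        calls = table.alleles[:, j, :]
        ok = calls[:, 0] != MISSING
        if not ok.any():
            warnings.warn(f"locus {locus!r} has no complete calls; excluded")
            continue
        vals, cnt = np.unique(calls[ok].ravel(), return_counts=True)
        loci.append(locus)
        counts.append({int(v): int(c) for v, c in zip(vals, cnt)})
        n_ind.append(int(ok.sum()))
        if ok.sum() < 2:
            warnings.warn(f"locus {locus!r} typed in fewer than 2 individuals")
    if not loci:
        raise RelatednessError("no locus has any complete genotype call")
    return AlleleFrequencies(loci, counts, n_ind)


def _directed_sums(
    focal: np.ndarray,
    partner: np.ndarray,
    freqs: Sequence[Mapping[int, float]],
    locus_idx: Sequence[int],
) -> tuple[float, float]:
    num = 0.0
    den = 0.0
    for j, f in zip(locus_idx, freqs):
        a, b = int(focal[j, 0]), int(focal[j, 1])
        c, d = int(partner[j, 0]), int(partner[j, 1])
        try:
            pa, pb = f[a], f[b]
        except KeyError as exc:
            raise RelatednessError(
                f"allele {exc.args[0]} absent from reference frequencies"
            ) from None
        s = 0.5 * ((a == c) + (a == d) + (b == c) + (b == d))
        num += s - pa - pb
        den += 1.0 + (a == b) - pa - pb
    return num, den


def queller_goodnight(
    table: GenotypeTable,
    x: str,
    y: str,
    frequencies: AlleleFrequencies,
) -> float:
    """Symmetrized multilocus Queller & Goodnight relatedness of ``x`` and
    ``y`` under the given reference allele frequencies.

    Raises
    ------
    RelatednessError
        If the pair shares no co-typed locus or carries an allele absent
        from the reference frequencies.
    UndefinedRelatednessError
        If both directed denominators are zero.
    """
    gx, gy = table.row(x), table.row(y)
    locus_pos = {locus: k for k, locus in enumerate(table.loci)}
    idx = [locus_pos[l] for l in frequencies.loci]
    shared = [
        (j, f)
        for j, f in zip(idx, frequencies.freqs)
        if gx[j, 0] != MISSING and gy[j, 0] != MISSING
    ]
    if not shared:
        raise RelatednessError(f"pair ({x!r}, {y!r}) shares no co-typed locus")
    js = [j for j, _ in shared]
    fs = [f for _, f in shared]
    num_xy, den_xy = _directed_sums(gx, gy, fs, js)
    num_yx, den_yx = _directed_sums(gy, gx, fs, js)
    ratios = []
    for num, den in ((num_xy, den_xy), (num_yx, den_yx)):
        if den != 0.0:
            ratios.append(num / den)
    if not ratios:
        raise UndefinedRelatednessError(
            f"pair ({x!r}, {y!r}): zero denominator in both directions"
        )
    return float(np.mean(ratios))


@dataclass
class ComponentSummary:
    """Mean relatedness of helpers to one class of recipient."""

    mean: float
    se: float
    n: int
    values: list[float] = field(default_factory=list)


@dataclass
class RelatednessSummary:
    """Helper relatedness to male breeders, female breeders and broods."""

    helper_to_male: ComponentSummary
    helper_to_female: ComponentSummary
    helper_to_brood: ComponentSummary
    n_assignments: int
    n_excluded_single_visit: int

    def as_dict(self) -> dict:
        def comp(c: ComponentSummary) -> dict:
            return {"mean": c.mean, "se": c.se, "n": c.n}

        return {
            "r_helper_male": comp(self.helper_to_male),
            "r_helper_female": comp(self.helper_to_female),
            "r_helper_brood": comp(self.helper_to_brood),
            "n_assignments": self.n_assignments,
            "n_excluded_single_visit": self.n_excluded_single_visit,
        }


def _summarize(values: list[float]) -> ComponentSummary:
    if not values:
        return ComponentSummary(mean=float("nan"), se=float("nan"), n=0)
    arr = np.asarray(values, dtype=float)
    se = float(arr.std(ddof=1) / np.sqrt(len(arr))) if len(arr) > 1 else float("nan")
    return ComponentSummary(mean=float(arr.mean()), se=se, n=len(arr), values=values)


def brood_membership_from_pedigree(pedigree: pd.DataFrame) -> dict[str, list[str]]:
    """Map nest ID to the fledglings raised in it (pedigree ``natal_nest``)."""
    fledged = pedigree[pedigree["natal_nest"].notna()]
    return {
        nest: list(group["id"]) for nest, group in fledged.groupby("natal_nest")
    }


def helper_relatedness_summary(
    helpers: pd.DataFrame,
    nests: pd.DataFrame,
    table: GenotypeTable,
    brood_membership: Mapping[str, Sequence[str]],
    min_visits: int = 2,
    frequencies: AlleleFrequencies | None = None,
    exclude_pair: bool = False,
) -> RelatednessSummary:
    """Mean (± s.e.) relatedness of helpers to the recipients of their care.

    Helpers observed provisioning a nest only once (visit count below
    ``min_visits``) are excluded. Relatedness to the brood is the mean of
    pairwise values over genotyped brood members. Pairs with missing
    genotypes are dropped per component, so the attained n may differ
    between the male-breeder, female-breeder and brood summaries.

    ``exclude_pair=True`` recomputes the reference allele frequencies with
    each focal pair's alleles removed (a small-sample bias correction);
    the default uses whole-sample frequencies.
    """
    required = {"helper_id", "nest_id", "visits"}
    if not required.issubset(helpers.columns):
        raise RelatednessError(f"helper table must have columns {sorted(required)}")
    if helpers.empty:
        raise RelatednessError("helper table is empty; nothing to summarize")
    eligible = helpers[helpers["visits"] >= min_visits]
    n_excluded = len(helpers) - len(eligible)
    if frequencies is None:
        frequencies = estimate_allele_frequencies(table)
    breeders = {r.nest_id: (r.male_id, r.female_id) for r in nests.itertuples()}

    def r_or_none(a: str, b: str) -> float | None:
        if a not in table or b not in table:
            return None
        freqs = (
            frequencies.excluding(table, [a, b]) if exclude_pair else frequencies
        )
        try:
            return queller_goodnight(table, a, b, freqs)
        except RelatednessError:
            return None

    to_male: list[float] = []
    to_female: list[float] = []
    to_brood: list[float] = []
    for row in eligible.itertuples():
        if row.nest_id not in breeders:
            raise RelatednessError(f"helper assignment to unknown nest {row.nest_id!r}")
        male, female = breeders[row.nest_id]
        rm = r_or_none(row.helper_id, male)
        if rm is not None:
            to_male.append(rm)
        rf = r_or_none(row.helper_id, female)
        if rf is not None:
            to_female.append(rf)
        brood = [
            b
            for b in brood_membership.get(row.nest_id, [])
            if b in table and b != row.helper_id
        ]
        vals = [r for b in brood if (r := r_or_none(row.helper_id, b)) is not None]
        if vals:
            to_brood.append(float(np.mean(vals)))

    # all assignments filtered out (e.g. every helper seen only once) is a
    # legitimate outcome: the summary simply attains n = 0 per component
    return RelatednessSummary(
        helper_to_male=_summarize(to_male),
        helper_to_female=_summarize(to_female),
        helper_to_brood=_summarize(to_brood),
        n_assignments=len(eligible),
        n_excluded_single_visit=n_excluded,
    )


def jackknife_se_over_loci(
    table: GenotypeTable,
    pairs: Sequence[tuple[str, str]],
    frequencies: AlleleFrequencies | None = None,
) -> tuple[float, float]:
    """Delete-one-locus jackknife mean and s.e. of the mean pairwise
    relatedness over ``pairs`` (an alternative to the plain over-pairs s.e.)."""
    if frequencies is None:
        frequencies = estimate_allele_frequencies(table)
    loci = list(frequencies.loci)
    if len(loci) < 2:
        raise RelatednessError("jackknife needs at least two loci")

    def mean_r(freqs: AlleleFrequencies) -> float:
        vals = [queller_goodnight(table, a, b, freqs) for a, b in pairs]
        return float(np.mean(vals))

    full = mean_r(frequencies)
    leave_out = []
    for drop in range(len(loci)):
        sub = AlleleFrequencies(
            [l for k, l in enumerate(loci) if k != drop],
            [c for k, c in enumerate(frequencies.counts) if k != drop],
            [n for k, n in enumerate(frequencies.n_individuals) if k != drop],
        )
        leave_out.append(mean_r(sub))
    lo = np.asarray(leave_out)
    m = len(loci)
    se = float(np.sqrt((m - 1) / m * ((lo - lo.mean()) ** 2).sum()))
    return full, se
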