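"""Diploid multilocus genotype container and file round-trips.

Genotypes are held as an integer array of shape ``(n_individuals, n_loci, 2)``
with allele label 0 meaning "missing"; a locus call is either a complete pair
of positive labels or wholly missing (0, 0). Two on-disk dialects are
supported: a wide CSV (``id`` column then ``<locus>_1``/``<locus>_2`` pairs,
0 or blank = missing) and GenePop (digit-pair allele coding, ``pop`` blocks),
read through Bio.PopGen.GenePop.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.PopGen import GenePop as _GenePop

MISSING = 0


class GenotypeError(ValueError):
    pass


@dataclass
class GenotypeTable:
    """Individual-by-locus diploid allele calls.

    Parameters
    ----------
    ids:
        Individual identifiers, one per row of ``alleles``.
    loci:
        Locus names.
    alleles:
        Integer array ``(n, n_loci, 2)``; 0 encodes a missing call and both
        slots of a locus must be missing together.
    populations:
        Optional population/cohort label per individual (used for GenePop
        ``pop`` blocks).
    """

    ids: list[str]
    loci: list[str]
    alleles: np.ndarray
    populations: list[str] | None = None
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int32)
        if self.alleles.shape != (len(self.ids), len(self.loci), 2):
            raise GenotypeError(
                f"allele array shape {self.alleles.shape} does not match "
                f"{len(self.ids)} individuals x {len(self.loci)} loci"
            )
        if (self.alleles < 0).any():
            raise GenotypeError("allele labels must be non-negative integers")
        half = (self.alleles == MISSING).sum(axis=2) == 1
        if half.any():
            i, j = np.argwhere(half)[0]
            raise GenotypeError(
                f"individual {self.ids[i]!r} locus {self.loci[j]!r}: "
                "a locus call must be a complete pair or wholly missing"
            )
        if self.populations is not None and len(self.populations) != len(self.ids):
            raise GenotypeError("populations must have one label per individual")
        self._index = {ind: i for i, ind in enumerate(self.ids)}

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def row(self, individual: str) -> np.ndarray:
        """Allele pairs ``(n_loci, 2)`` for one individual."""
        try:
            return self.alleles[self._index[individual]]
        except KeyError:
            raise KeyError(f"individual {individual!r} not genotyped") from None

    def __contains__(self, individual: str) -> bool:
        return individual in self._index

    def subset(self, individuals: Sequence[str]) -> "GenotypeTable":
        idx = [self._index[i] for i in individuals]
        pops = [self.populations[i] for i in idx] if self.populations else None
        return GenotypeTable(list(individuals), list(self.loci), self.alleles[idx], pops)

    # ---------------------------------------------------------------- CSV

    def to_frame(self) -> pd.DataFrame:
        data: dict[str, object] = {"id": self.ids}
        for j, locus in enumerate(self.loci):
            data[f"{locus}_1"] = self.alleles[:, j, 0]
            data[f"{locus}_2"] = self.alleles[:, j, 1]
        return pd.DataFrame(data)

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "GenotypeTable":
        if "id" not in frame.columns:
            raise GenotypeError("genotype CSV must have an 'id' column")
        suffixed = [c for c in frame.columns if c.endswith("_1")]
        loci = [c[:-2] for c in suffixed if f"{c[:-2]}_2" in frame.columns]
        if not loci:
            raise GenotypeError("no <locus>_1/<locus>_2 column pairs found")
        n = len(frame)
        alleles = np.zeros((n, len(loci), 2), dtype=np.int32)
        for j, locus in enumerate(loci):
            for k in (0, 1):
                col = frame[f"{locus}_{k + 1}"]
                vals = pd.to_numeric(col, errors="coerce").fillna(MISSING)
                alleles[:, j, k] = vals.astype(np.int32)
        # a half-missing pair on disk is a recording error we surface loudly
        return cls([str(i) for i in frame["id"]], loci, alleles)

    @classmethod
    def read_csv(cls, path: str | Path) -> "GenotypeTable":
        return cls.from_frame(pd.read_csv(path))

    # ------------------------------------------------------------ GenePop

    def to_genepop(self, title: str = "kinfitness genotypes", digits: int = 2) -> str:
        """Render as GenePop text, one ``pop`` block per population label
        (cohort year), allele labels zero-padded to ``digits`` digits."""
        if digits not in (2, 3):
            raise GenotypeError("GenePop allele coding must use 2 or 3 digits")
        if int(self.alleles.max(initial=0)) >= 10**digits:
            raise GenotypeError(f"allele labels too large for {digits}-digit coding")
        pops = self.populations or ["pop1"] * len(self.ids)
        lines = [title]
        lines.extend(self.loci)
        order = sorted(set(pops), key=str)
        for pop in order:
            lines.append("pop")
            for i, ind in enumerate(self.ids):
                if pops[i] != pop:
                    continue
                calls = "".join(
                    " %0*d%0*d" % (digits, a, digits, b)
                    for a, b in self.alleles[i]
                )
                lines.append(f"{ind} ,{calls}")
        return "\n".join(lines) + "\n"

    def write_genepop(self, path: str | Path, **kwargs) -> None:
        Path(path).write_text(self.to_genepop(**kwargs))

    @classmethod
    def from_genepop(cls, text: str) -> "GenotypeTable":
        record = _GenePop.read(io.StringIO(text))
        ids: list[str] = []
        pops: list[str] = []
        rows: list[list[tuple[int, int]]] = []
        for p, population in enumerate(record.populations):
            for name, calls in population:
                ids.append(name.strip().rstrip(",").strip())
                pops.append(f"pop{p + 1}")
                rows.append(
                    [
                        (MISSING, MISSING) if a is None or b is None else (a, b)
                        for a, b in calls
                    ]
                )
        alleles = np.array(rows, dtype=np.int32) if rows else np.zeros(
            (0, len(record.loci_list), 2), dtype=np.int32
        )
        return cls(ids, list(record.loci_list), alleles, pops)

    @classmethod
    def read_genepop(cls, path: str | Path) -> "GenotypeTable":
        return cls.from_genepop(Path(path).read_text())
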