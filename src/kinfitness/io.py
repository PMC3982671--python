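"""Table readers/writers and schema validation for the six pipeline tables.

All tables travel as tab-separated text with a header row; genotypes
additionally round-trip through a wide CSV and GenePop (see
:mod:`kinfitness.genotypes`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeTable

TABLE_COLUMNS: dict[str, list[str]] = {
    "pedigree": ["id", "sire", "dam", "birth_year", "sex", "natal_nest"],
    "nests": [
        "nest_id",
        "year",
        "male_id",
        "female_id",
        "lay_date",
        "failed",
        "failure_date",
        "n_fledged",
    ],
    "helpers": ["helper_id", "nest_id", "visits"],
    "recruitment": ["fledgling_id", "female", "helpers", "year", "nest_id", "recruited"],
    "survival": ["id", "year", "category", "survived"],
    "attempts": [
        "male_id",
        "year",
        "failure_date",
        "year_median_lay",
        "outcome",
        "became_helper",
    ],
}


class TableIOError(ValueError):
    pass


def write_table(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, sep="\t", index=False)


def read_table(path: str | Path, name: str) -> pd.DataFrame:
    if name not in TABLE_COLUMNS:
        raise TableIOError(f"unknown table {name!r}")
    try:
        frame = pd.read_csv(path, sep="\t")
    except OSError as exc:
        raise TableIOError(f"cannot read {name} table: {exc}") from exc
    missing = set(TABLE_COLUMNS[name]) - set(frame.columns)
    if missing:
        raise TableIOError(f"{path}: {name} table lacks columns {sorted(missing)}")
    if name == "attempts" and frame["became_helper"].dtype == object:
        frame["became_helper"] = frame["became_helper"].astype(str).str.lower().isin(
            ("true", "1", "yes")
        )
    return frame


def write_dataset_tables(tables: Mapping[str, pd.DataFrame], outdir: str | Path) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, frame in tables.items():
        path = outdir / f"{name}.tsv"
        write_table(frame, path)
        paths[name] = path
    return paths


@dataclass
class Issue:
    table: str
    row: int | None
    column: str | None
    message: str

    def __str__(self) -> str:
        loc = self.table
        if self.row is not None:
            loc += f" row {self.row}"
        if self.column is not None:
            loc += f" column {self.column!r}"
        return f"{loc}: {self.message}"


@dataclass
class ValidationReport:
    issues: list[Issue] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.issues

    def add(self, table: str, message: str, row: int | None = None, column: str | None = None) -> None:
        self.issues.append(Issue(table, row, column, message))

    def as_dict(self) -> dict:
        return {
            "ok": self.ok,
            "issues": [
                {"table": i.table, "row": i.row, "column": i.column, "message": i.message}
                for i in self.issues
            ],
        }


def validate_tables(
    tables: Mapping[str, pd.DataFrame],
    genotypes: GenotypeTable | None = None,
) -> ValidationReport:
    """Schema and cross-reference checks over the in-memory tables.

    Verifies required columns, binary outcome coding, ID cross-references
    (helpers and breeders exist in the pedigree, helped nests exist in the
    nest table) and, when genotypes are supplied, that every locus call is
    a complete pair or wholly missing (the container enforces this on
    construction; re-checked here for externally built arrays).
    """
    report = ValidationReport()
    for name, frame in tables.items():
        if name not in TABLE_COLUMNS:
            report.add(name, "unknown table name")
            continue
        for col in TABLE_COLUMNS[name]:
            if col not in frame.columns:
                report.add(name, "missing required column", column=col)

    def col_ok(name: str, col: str) -> bool:
        return name in tables and col in tables[name].columns

    ids: set[str] = set()
    if col_ok("pedigree", "id"):
        ids = set(tables["pedigree"]["id"].astype(str))
        dup = tables["pedigree"]["id"][tables["pedigree"]["id"].duplicated()]
        for r in dup.index:
            report.add("pedigree", f"duplicate individual {tables['pedigree']['id'][r]!r}", row=int(r), column="id")
    nest_ids: set[str] = set()
    if col_ok("nests", "nest_id"):
        nest_ids = set(tables["nests"]["nest_id"].astype(str))
        if ids:
            for col in ("male_id", "female_id"):
                if col_ok("nests", col):
                    bad = ~tables["nests"][col].astype(str).isin(ids)
                    for r in tables["nests"].index[bad]:
                        report.add("nests", "breeder not in pedigree", row=int(r), column=col)
    if col_ok("helpers", "nest_id"):
        bad = ~tables["helpers"]["nest_id"].astype(str).isin(nest_ids)
        for r in tables["helpers"].index[bad]:
            report.add("helpers", "reference to unknown nest", row=int(r), column="nest_id")
    if col_ok("helpers", "helper_id") and ids:
        bad = ~tables["helpers"]["helper_id"].astype(str).isin(ids)
        for r in tables["helpers"].index[bad]:
            report.add("helpers", "helper not in pedigree", row=int(r), column="helper_id")
    for name, col in (("recruitment", "recruited"), ("survival", "survived")):
        if col_ok(name, col):
            vals = set(pd.unique(tables[name][col]))
            if not vals <= {0, 1}:
                report.add(name, "outcome must be coded 0/1", column=col)
    if col_ok("attempts", "outcome"):
        vals = set(pd.unique(tables["attempts"]["outcome"]))
        if not vals <= {"renested", "terminated"}:
            report.add("attempts", "outcome must be 'renested' or 'terminated'", column="outcome")
    if col_ok("survival", "category"):
        from .survival import CATEGORIES

        vals = set(pd.unique(tables["survival"]["category"]))
        if not vals <= set(CATEGORIES):
            report.add("survival", f"categories must be among {CATEGORIES}", column="category")

    if genotypes is not None:
        half = (genotypes.alleles == MISSING).sum(axis=2) == 1
        for i, j in np.argwhere(half):
            report.add(
                "genotypes",
                f"individual {genotypes.ids[i]!r}: one allele present, one missing",
                row=int(i),
                column=genotypes.loci[j],
            )
        if ids:
            absent = [g for g in genotypes.ids if g not in ids]
            for g in absent:
                report.add("genotypes", f"genotyped individual {g!r} not in pedigree")
    return report


def validate_table_files(paths: Mapping[str, str | Path]) -> ValidationReport:
    """Read and validate tables from disk; unreadable or malformed files
    become issues naming the offending table."""
    tables: dict[str, pd.DataFrame] = {}
    report = ValidationReport()
    for name, path in paths.items():
        if name == "genotypes":
            continue
        try:
            tables[name] = read_table(path, name)
        except (TableIOError, OSError) as exc:
            report.add(name, str(exc))
    genotypes = None
    if "genotypes" in paths:
        p = Path(paths["genotypes"])
        try:
            genotypes = (
                GenotypeTable.read_csv(p)
                if p.suffix.lower() == ".csv"
                else GenotypeTable.read_genepop(p)
            )
        except Exception as exc:
            report.add("genotypes", str(exc))
    inner = validate_tables(tables, genotypes)
    report.issues.extend(inner.issues)
    return report
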