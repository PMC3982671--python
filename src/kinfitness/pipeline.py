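"""End-to-end orchestration: data in, Hamilton's-rule report out.

Stages run in dependency order — simulate or load the six tables, estimate
helper relatedness, fit the recruitment model and its marginal effect,
derive the survival benefit and cost, run the renesting opportunity-cost
test, and assemble the relatedness-weighted accounting. Any stage failure
aborts with the stage name; the report carries provenance (seed, inputs,
version) and per-stage filter counts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import __version__
from .config import PopulationConstants, SimulationConfig
from .genotypes import GenotypeTable
from .hamilton import build_table1, evaluate_hamilton
from .io import read_table, validate_tables, write_dataset_tables
from .recruitment import fit_recruitment_model, marginal_effect, recruits_per_helper
from .relatedness import brood_membership_from_pedigree, helper_relatedness_summary
from .renesting import analyze_attempts
from .simulate import SyntheticDataset, simulate_dataset
from .survival import analyze_survival_table, load_lightening_benefit

logger = logging.getLogger("kinfitness")


class PipelineError(RuntimeError):
    pass


@dataclass
class AnalysisOptions:
    """Knobs of the analysis stages (not of the data-generating process)."""

    min_visits: int = 2
    model_method: str = "auto"
    marginal_scheme: str = "at"
    marginal_female: int = 0
    marginal_helpers: float = 1.8
    n_draws: int = 10_000
    seed: int = 0
    precision: str = "full"
    breeder_survival_with: float = 0.52
    breeder_survival_without: float = 0.43
    feed_ratio: float = 2.45
    p_low: float | None = None


@dataclass
class PipelineConfig:
    mode: str = "simulate"  # or "load"
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    constants: PopulationConstants = field(default_factory=PopulationConstants)
    options: AnalysisOptions = field(default_factory=AnalysisOptions)
    paths: Mapping[str, str | Path] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "load"):
            raise PipelineError("mode must be 'simulate' or 'load'")
        if self.mode == "load":
            needed = {
                "pedigree",
                "nests",
                "helpers",
                "recruitment",
                "survival",
                "attempts",
                "genotypes",
            }
            if self.paths is None or not needed <= set(self.paths):
                missing = sorted(needed - set(self.paths or {}))
                raise PipelineError(f"load mode needs paths for: {missing}")


def _load_tables(paths: Mapping[str, str | Path]) -> SyntheticDataset:
    for name, path in paths.items():
        if not Path(path).exists():
            raise PipelineError(f"missing table file for {name!r}: {path}")
    gp = Path(paths["genotypes"])
    genotypes = (
        GenotypeTable.read_csv(gp)
        if gp.suffix.lower() == ".csv"
        else GenotypeTable.read_genepop(gp)
    )
    return SyntheticDataset(
        pedigree=read_table(paths["pedigree"], "pedigree"),
        genotypes=genotypes,
        nests=read_table(paths["nests"], "nests"),
        helpers=read_table(paths["helpers"], "helpers"),
        recruitment=read_table(paths["recruitment"], "recruitment"),
        survival=read_table(paths["survival"], "survival"),
        attempts=read_table(paths["attempts"], "attempts"),
        truth=SimulationConfig(),
    )


def _hash_frame(frame: pd.DataFrame) -> str:
    return hashlib.sha256(
        frame.to_csv(index=False).encode("utf-8")
    ).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages and return the JSON-serializable run report."""
    opts = config.options
    warnings_log: list[str] = []

    if config.mode == "simulate":
        data = simulate_dataset(config.sim, seed=config.seed)
    else:
        data = _load_tables(config.paths)
        issues = validate_tables(data.tables(), data.genotypes)
        if not issues.ok:
            raise PipelineError(
                "input validation failed: " + "; ".join(str(i) for i in issues.issues)
            )

    def stage(name: str, fn):
        logger.info("stage %s: start", name)
        try:
            return fn()
        except Exception as exc:
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc

    membership = brood_membership_from_pedigree(data.pedigree)
    rel = stage(
        "relatedness",
        lambda: helper_relatedness_summary(
            data.helpers,
            data.nests,
            data.genotypes,
            membership,
            min_visits=opts.min_visits,
        ),
    )
    logger.info(
        "relatedness: %d assignments kept, %d removed by the >=%d-visit rule",
        rel.n_assignments,
        rel.n_excluded_single_visit,
        opts.min_visits,
    )

    fit = stage(
        "recruitment_fit",
        lambda: fit_recruitment_model(data.recruitment, method=opts.model_method),
    )
    me = stage(
        "marginal_effect",
        lambda: marginal_effect(
            fit,
            scheme=opts.marginal_scheme,
            female=opts.marginal_female,
            helpers=opts.marginal_helpers,
            obs=data.recruitment,
            n_draws=opts.n_draws,
            seed=opts.seed,
        ),
    )
    rph = recruits_per_helper(me, config.constants)

    surv = stage(
        "survival",
        lambda: analyze_survival_table(
            data.survival, config.constants, p_low=opts.p_low
        ),
    )
    benefit = load_lightening_benefit(
        opts.breeder_survival_with, opts.breeder_survival_without, config.constants
    )

    renest = stage("renesting", lambda: analyze_attempts(data.attempts))

    terms, rendered = stage(
        "hamilton",
        lambda: build_table1(
            r_brood=rel.helper_to_brood.mean,
            r_male_breeder=rel.helper_to_male.mean,
            recruits_per_helper=rph.estimate,
            breeder_benefit=benefit.benefit_equivalents,
            cost=surv.cost_equivalents,
            r_female_breeder=rel.helper_to_female.mean,
            provenance={
                "r": "estimated from genotypes",
                "b_brood": "recruitment model marginal effect",
                "b_breeder": "load-lightening constants",
                "c": "quality-mixture decomposition",
            },
        ),
    )
    result = evaluate_hamilton(terms, precision=opts.precision)

    report = {
        "version": __version__,
        "mode": config.mode,
        "seed": config.seed,
        "provenance": {
            "table_hashes": {k: _hash_frame(v) for k, v in data.tables().items()},
        },
        "relatedness": rel.as_dict(),
        "recruitment": {
            "fit": fit.as_dict(),
            "marginal_effect": me.as_dict(),
            "recruits_per_helper": rph.as_dict(),
        },
        "survival": {
            "report": surv.as_dict(),
            "load_lightening": benefit.as_dict(),
        },
        "renesting": renest,
        "hamilton": result.as_dict(),
        "table1": rendered,
        "warnings": warnings_log,
    }
    return report


# Minimal structural schema for the run report; checked without external
# validators so reports stay verifiable offline.
REPORT_SCHEMA: dict[str, type | dict] = {
    "version": str,
    "mode": str,
    "seed": int,
    "provenance": dict,
    "relatedness": dict,
    "recruitment": {"fit": dict, "marginal_effect": dict, "recruits_per_helper": dict},
    "survival": {"report": dict, "load_lightening": dict},
    "renesting": dict,
    "hamilton": dict,
    "table1": str,
    "warnings": list,
}


def validate_report(report: Mapping) -> list[str]:
    """Structural check of a run report against :data:`REPORT_SCHEMA`;
    returns a list of problems (empty = valid)."""
    problems: list[str] = []

    def walk(schema: Mapping, node: Mapping, prefix: str) -> None:
        for key, expected in schema.items():
            if key not in node:
                problems.append(f"missing key {prefix}{key}")
                continue
            if isinstance(expected, dict):
                if not isinstance(node[key], Mapping):
                    problems.append(f"{prefix}{key} should be a mapping")
                else:
                    walk(expected, node[key], f"{prefix}{key}.")
            elif not isinstance(node[key], expected):
                problems.append(
                    f"{prefix}{key} should be {expected.__name__}, "
                    f"got {type(node[key]).__name__}"
                )

    walk(REPORT_SCHEMA, report, "")
    return problems


def write_report(report: Mapping, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, default=float) + "\n")


def simulate_to_dir(config: SimulationConfig, seed: int, outdir: str | Path) -> dict[str, Path]:
    """Generate a dataset and write the six tables plus genotype files."""
    data = simulate_dataset(config, seed=seed)
    paths = write_dataset_tables(data.tables(), outdir)
    outdir = Path(outdir)
    data.genotypes.write_csv(outdir / "genotypes.csv")
    data.genotypes.write_genepop(outdir / "genotypes.gen")
    paths["genotypes"] = outdir / "genotypes.csv"
    return paths
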