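"""Top-level analysis objects: configure once, fit, inspect results.

`MineaAnalysis` bundles a normalised model, a set of metabolic tasks and
one or more condition-pair gene-call tables; `fit()` runs the whole
procedure — task formulation, MILP enumeration of alternative minimal
networks, reaction-regulation assignment, and enrichment scoring — and
returns a `MineaResults` holding the enumerations and the report tables.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import enrichment, min_enum
from .gem_io import MetabolicModel, split_reversible
from .min_enum import AlternativeSet
from .regulation import RegulationAssignment
from .tasks import DEFAULT_YIELD_FRACTION, MetabolicTask, TaskInfeasibleError


@dataclass
class MineaAnalysis:
    """Minimal network enrichment analysis of one model.

    Parameters
    ----------
    model:
        A validated metabolic model; it is split into irreversible
        reactions on construction if any reversible reactions remain.
    tasks:
        The metabolic tasks (target-metabolite syntheses) to enumerate.
    gene_calls:
        Mapping of condition-pair label → {gene id: "up"/"down"}.
    c:
        Yield floor as a fraction of each task's maximum yield.
    max_rank, cap:
        Enumeration depth beyond the minimum size, and a hard cap on the
        number of alternatives per task.
    alpha_gene, alpha_reaction:
        Raw significance thresholds for the gene-mode and reaction-mode
        tests.
    """

    model: MetabolicModel
    tasks: list[MetabolicTask]
    gene_calls: dict[str, dict[str, str]] = field(default_factory=dict)
    c: float = DEFAULT_YIELD_FRACTION
    max_rank: int = min_enum.DEFAULT_MAX_RANK
    cap: int = min_enum.DEFAULT_CAP
    alpha_gene: float = enrichment.DEFAULT_ALPHA_GENE
    alpha_reaction: float = enrichment.DEFAULT_ALPHA_REACTION
    gene_universe: str = "model"

    def __post_init__(self):
        if not (0 < self.c <= 1):
            raise ValueError("c must be in (0, 1]")
        if any(r.lower < 0 for r in self.model.reactions):
            self.model = split_reversible(self.model)

    def fit(self) -> "MineaResults":
        sets: list[AlternativeSet] = []
        skipped: list[str] = []
        for task in self.tasks:
            task.c = self.c
            try:
                sets.append(
                    min_enum.enumerate_alternatives(
                        self.model, task, max_rank=self.max_rank, cap=self.cap
                    )
                )
            except TaskInfeasibleError:
                skipped.append(task.name)
        regulations = [
            RegulationAssignment.from_calls(self.model, calls, condition_pair=pair)
            for pair, calls in self.gene_calls.items()
        ]
        report = (
            enrichment.build_report(
                sets, self.model, regulations,
                alpha_gene=self.alpha_gene,
                alpha_reaction=self.alpha_reaction,
                gene_universe=self.gene_universe,
            )
            if regulations
            else {"networks": pd.DataFrame(), "aminf": pd.DataFrame(),
                  "hfr_regulation": pd.DataFrame()}
        )
        return MineaResults(
            analysis=self, alternative_sets=sets, regulations=regulations,
            skipped_tasks=skipped, **report,
        )


@dataclass
class MineaResults:
    """Fitted results: enumerations, per-network statistics, AMiNF tables."""

    analysis: MineaAnalysis
    alternative_sets: list[AlternativeSet]
    regulations: list[RegulationAssignment]
    networks: pd.DataFrame
    aminf: pd.DataFrame
    hfr_regulation: pd.DataFrame
    skipped_tasks: list[str] = field(default_factory=list)

    def alternative_set(self, task: str) -> AlternativeSet:
        for s in self.alternative_sets:
            if s.task == task:
                return s
        raise KeyError(f"no enumeration for task {task!r}")

    def enumeration_summary(self) -> pd.DataFrame:
        """One row per task: size, alternatives, HFR counts and percentages."""
        phen_hfrs = {}
        by_phen: dict[str, list[AlternativeSet]] = {}
        for s in self.alternative_sets:
            by_phen.setdefault(s.phenotype, []).append(s)
        for phen, group in by_phen.items():
            phen_hfrs[phen] = len(min_enum.phenotypic_hfrs(group))
        return pd.DataFrame(
            [
                {
                    "task": s.task,
                    "phenotype": s.phenotype,
                    "msize": s.msize,
                    "n_alternatives": s.n_alternatives,
                    "n_hfrs": len(s.hfrs),
                    "pct_hfrs": round(s.hfr_fraction, 1),
                    "n_phenotypic_hfrs": phen_hfrs[s.phenotype],
                    "truncated": s.truncated,
                }
                for s in self.alternative_sets
            ]
        )

    def summary(self) -> str:
        """Human-readable account of the fit."""
        lines = [
            "Minimal network enrichment analysis",
            f"  model: {self.analysis.model.model_id} "
            f"({len(self.analysis.model.parent_ids())} reactions, "
            f"{len(self.analysis.model.genes)} genes)",
            f"  yield floor c = {self.analysis.c}",
            "",
            "Enumeration (per task):",
            self.enumeration_summary().to_string(index=False),
        ]
        if self.skipped_tasks:
            lines.append(f"  infeasible tasks skipped: {', '.join(self.skipped_tasks)}")
        if not self.aminf.empty:
            lines += [
                "",
                f"AMiNF (alpha_gene={self.analysis.alpha_gene}, "
                f"alpha_reaction={self.analysis.alpha_reaction}):",
                self.aminf.to_string(index=False),
            ]
        return "\n".join(lines)

    def save(self, outdir: str | Path) -> None:
        """Write per-task enumeration JSON plus the report TSVs."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for s in self.alternative_sets:
            doc = {
                "task": s.task,
                "phenotype": s.phenotype,
                "msize": s.msize,
                "truncated": s.truncated,
                "hfrs": sorted(s.hfrs),
                "networks": [
                    {
                        "active_reactions": sorted(n.active_reactions),
                        "size": n.size,
                        "objective_rank": n.objective_rank,
                        "flux_witness": {
                            k: round(v, 9) for k, v in sorted(n.flux_witness.items())
                        },
                    }
                    for n in s.networks
                ],
            }
            with open(outdir / f"minea_networks_{s.task}.json", "w") as fh:
                json.dump(doc, fh, indent=1, sort_keys=True)
        self.enumeration_summary().to_csv(
            outdir / "minea_summary.tsv", sep="\t", index=False
        )
        self.networks.to_csv(outdir / "minea_networks.tsv", sep="\t", index=False)
        self.aminf.to_csv(outdir / "minea_aminf.tsv", sep="\t", index=False)
        self.hfr_regulation.to_csv(
            outdir / "minea_hfr_regulation.tsv", sep="\t", index=False
        )
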