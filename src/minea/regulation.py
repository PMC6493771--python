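"""Differential-expression calls and the reaction-regulation metric.

Gene-level calls (up / down) come from an upstream differential-expression
analysis and are consumed here as a plain table.  A reaction inherits a
state from the calls on its GPR genes: *upregulated* if every called gene
among its associated genes is up, *downregulated* if every one is down, and
*unregulated* when the evidence is mixed or absent.  Association is set
membership in the GPR rule — the AND/OR structure is ignored, which keeps
the metric conservative under rule uncertainty.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gem_io import MetabolicModel, ReactionRecord, genes_of

UP, DOWN, UNREGULATED = "up", "down", "unregulated"

DEFAULT_FDR = 0.05


def load_deg_table(path: str, fdr: float = DEFAULT_FDR) -> dict[str, str]:
    """Read gene-level calls from a TSV with ``gene_id`` plus either a
    ``direction`` column (up/down) or a signed ``logFC`` column (direction
    inferred from the sign, rows with ``fdr`` above the threshold dropped
    when an ``fdr`` column is present).
    """
    table = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    if "gene_id" not in table.columns:
        raise ValueError(f"DEG table {path} lacks a gene_id column")
    if "direction" in table.columns:
        dirs = table["direction"].astype(str).str.lower()
        bad = sorted(set(dirs) - {UP, DOWN})
        if bad:
            raise ValueError(f"DEG table {path}: bad direction values {bad}")
    elif "logFC" in table.columns:
        if "fdr" in table.columns:
            table = table[table["fdr"] <= fdr]
        lfc = table["logFC"].astype(float)
        table = table[lfc != 0]
        dirs = np.where(table["logFC"].astype(float) > 0, UP, DOWN)
        dirs = pd.Series(dirs, index=table.index)
    else:
        raise ValueError(f"DEG table {path} needs a direction or logFC column")

    calls: dict[str, str] = {}
    for gene, direction in zip(table["gene_id"], dirs):
        if gene in calls and calls[gene] != direction:
            raise ValueError(f"gene {gene!r} listed as both up and down in {path}")
        calls[gene] = direction
    return calls


def reaction_state(reaction: ReactionRecord, gene_calls: dict[str, str]) -> str:
    """Regulation state of one reaction under the gene calls."""
    states = {gene_calls[g] for g in genes_of(reaction) if g in gene_calls}
    if states == {UP}:
        return UP
    if states == {DOWN}:
        return DOWN
    return UNREGULATED


def census(reaction_states: dict[str, str]) -> tuple[int, int, int, int]:
    """Partition a set of reaction states into (R, R_up, R_down, R_no)."""
    r_up = sum(1 for s in reaction_states.values() if s == UP)
    r_down = sum(1 for s in reaction_states.values() if s == DOWN)
    r = len(reaction_states)
    return r, r_up, r_down, r - r_up - r_down


@dataclass
class RegulationAssignment:
    """Per-gene calls and the derived per-parent-reaction states for a model.

    The census runs over parent reactions (both split directions inherit
    the parent's state) and excludes demand scaffolding.
    """

    condition_pair: str
    gene_calls: dict[str, str]
    reaction_states: dict[str, str]
    flagged_genes: frozenset[str] = frozenset()

    @property
    def census(self) -> tuple[int, int, int, int]:
        return census(self.reaction_states)

    @property
    def deregulated_genes(self) -> frozenset[str]:
        return frozenset(self.gene_calls) - self.flagged_genes

    @classmethod
    def from_calls(
        cls,
        model: MetabolicModel,
        gene_calls: dict[str, str],
        condition_pair: str = "",
    ) -> "RegulationAssignment":
        """Derive parent-reaction states from gene calls on a model.

        Genes absent from the model are retained in ``gene_calls`` but
        flagged; they never influence reaction states (and by default not
        the gene universe either).
        """
        flagged = frozenset(g for g in gene_calls if g not in model.genes)
        states: dict[str, str] = {}
        for parent in model.parent_ids():
            rec = model.directions_of(parent)[0]
            states[parent] = reaction_state(rec, gene_calls)
        return cls(
            condition_pair=condition_pair,
            gene_calls=dict(gene_calls),
            reaction_states=states,
            flagged_genes=flagged,
        )
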