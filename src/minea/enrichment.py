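"""Deregulation statistics for minimal networks.

Two complementary significance tests are applied to each alternative
minimal network (MiN):

* a **gene-based** test — the number of deregulated genes k among the K
  genes of the MiN, against n deregulated genes in a universe of N model
  genes, is scored with the upper tail P(X ≥ k) of the hypergeometric law
  with density C(K,k)·C(N−K, n−k)/C(N,n);

* a **reaction-based** test — with the model's reactions partitioned into
  R_up upregulated, R_down downregulated and R_no unregulated (R in
  total), a MiN of T reactions showing (T_up, T_down) is scored with the
  multivariate hypergeometric tail over outcomes at least as extreme:
  at least T_up upregulated *and* at most T_down downregulated reactions,

      p_up = Σ_{i=T_up}^{min(R_up,T)} Σ_{j=0}^{T_down, i+j≤T}
             C(R_up,i)·C(R_down,j)·C(R_no,T−i−j) / C(R,T) ,

  and symmetrically for the downregulated test with up and down swapped.

All tails are computed as exact rational sums (no normal approximation).
Descriptive companions: DRP (fraction of a MiN's genes deregulated), UPR /
DnRP (fraction of its reactions up- / downregulated), and AMiNF — the
fraction of a task's alternative MiNs significant at the chosen threshold,
which grades how consistently the task's alternatives are deregulated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction

import pandas as pd

from .gem_io import MetabolicModel, genes_of
from .min_enum import AlternativeSet, MinimalNetwork
from .regulation import DOWN, UP, RegulationAssignment, census

#: Raw per-test significance thresholds; no multiple-testing correction is
#: applied when labelling (BH-adjusted columns are emitted for reference).
DEFAULT_ALPHA_GENE = 0.05
DEFAULT_ALPHA_REACTION = 0.005


# ---------------------------------------------------------------------------
# Exact tails
# ---------------------------------------------------------------------------

def _gene_tail(k: int, K: int, n: int, N: int) -> Fraction:
    denom = math.comb(N, n)
    total = 0
    for i in range(k, min(K, n) + 1):
        total += math.comb(K, i) * math.comb(N - K, n - i)
    return Fraction(total, denom)


def gene_pvalue(k: int, K: int, n: int, N: int, exact: bool = False):
    """Upper-tail hypergeometric p-value P(X ≥ k) for gene over-representation.

    k of the MiN's K genes are deregulated; n of the N genes of the whole
    network are.  ``exact=True`` returns the rational value.
    """
    if not (0 <= k <= K <= N and 0 <= n <= N and k <= n):
        raise ValueError(f"invalid hypergeometric bounds k={k} K={K} n={n} N={N}")
    p = _gene_tail(k, K, n, N)
    return p if exact else float(p)


def _reaction_tail(
    R: int, R_up: int, R_down: int, R_no: int, T: int, T_up: int, T_down: int
) -> Fraction:
    if R != R_up + R_down + R_no:
        raise ValueError("model census does not satisfy R = R_up + R_down + R_no")
    if not (0 <= T <= R and 0 <= T_up and 0 <= T_down and T_up + T_down <= T):
        raise ValueError("network census inconsistent with its size")
    denom = math.comb(R, T)
    total = 0
    for i in range(T_up, min(R_up, T) + 1):
        for j in range(0, min(T_down, R_down, T - i) + 1):
            rest = T - i - j
            if rest > R_no:
                continue
            total += math.comb(R_up, i) * math.comb(R_down, j) * math.comb(R_no, rest)
    return Fraction(total, denom)


def up_pvalue(model_census, network_census, exact: bool = False):
    """Multivariate hypergeometric tail for an upregulated MiN.

    ``model_census`` is ``(R, R_up, R_down, R_no)``; ``network_census`` is
    ``(T, T_up, T_down)``.  An outcome counts as at least as extreme when,
    drawing T reactions without replacement, it shows ≥ T_up upregulated
    and ≤ T_down downregulated reactions.
    """
    R, R_up, R_down, R_no = model_census
    T, T_up, T_down = network_census
    p = _reaction_tail(R, R_up, R_down, R_no, T, T_up, T_down)
    return p if exact else float(p)


def down_pvalue(model_census, network_census, exact: bool = False):
    """Mirror of :func:`up_pvalue` with the roles of up and down exchanged."""
    R, R_up, R_down, R_no = model_census
    T, T_up, T_down = network_census
    p = _reaction_tail(R, R_down, R_up, R_no, T, T_down, T_up)
    return p if exact else float(p)


# ---------------------------------------------------------------------------
# Descriptive fractions
# ---------------------------------------------------------------------------

def drp(k: int, K: int) -> float:
    """Deregulated percentage: fraction k/K of a MiN's genes deregulated.

    Undefined (NaN) for a MiN without GPR genes.
    """
    if not (0 <= k <= K):
        raise ValueError(f"need 0 <= k <= K, got k={k} K={K}")
    return k / K if K > 0 else float("nan")


def aminf(pvalues, alpha: float) -> float:
    """Alternative minimal network frequency: fraction of MiNs with p < alpha.

    1 when every alternative is significantly deregulated, 0 when none is.
    Requires the complete (non-truncated) list of alternatives for a task.
    """
    pvalues = list(pvalues)
    if not pvalues:
        raise ValueError("aminf needs at least one alternative")
    return sum(1 for p in pvalues if p < alpha) / len(pvalues)


# ---------------------------------------------------------------------------
# Per-network scoring and report assembly
# ---------------------------------------------------------------------------

@dataclass
class MinCensus:
    """Reaction and gene counts within one MiN."""

    T: int
    T_up: int
    T_down: int
    K: int
    k: int

    @property
    def T_no(self) -> int:
        return self.T - self.T_up - self.T_down


def network_census(
    network: MinimalNetwork, model: MetabolicModel, regulation: RegulationAssignment
) -> MinCensus:
    """Count regulated reactions and deregulated genes inside one network."""
    states = [regulation.reaction_states[p] for p in network.active_reactions]
    genes: set[str] = set()
    for parent in network.active_reactions:
        genes |= genes_of(model.directions_of(parent)[0])
    deregulated = genes & regulation.deregulated_genes
    return MinCensus(
        T=len(states),
        T_up=sum(1 for s in states if s == UP),
        T_down=sum(1 for s in states if s == DOWN),
        K=len(genes),
        k=len(deregulated),
    )


def score_networks(
    sets: list[AlternativeSet],
    model: MetabolicModel,
    regulation: RegulationAssignment,
    gene_universe: str = "model",
) -> pd.DataFrame:
    """Per-MiN statistics table for one condition pair.

    ``gene_universe`` selects N of the gene test: ``"model"`` (all model
    genes; deregulated genes outside the model ignored) or ``"union"``
    (model genes plus called genes absent from the model).
    """
    if gene_universe == "model":
        N = len(model.genes)
        n = len(regulation.deregulated_genes)
    elif gene_universe == "union":
        N = len(model.genes | set(regulation.gene_calls))
        n = len(regulation.gene_calls)
    else:
        raise ValueError(f"unknown gene universe {gene_universe!r}")
    model_cen = regulation.census

    rows = []
    for alt in sets:
        for idx, net in enumerate(alt.networks):
            cen = network_census(net, model, regulation)
            rows.append(
                {
                    "condition_pair": regulation.condition_pair,
                    "task": alt.task,
                    "network_index": idx,
                    "size": net.size,
                    "objective_rank": net.objective_rank,
                    "T_up": cen.T_up,
                    "T_down": cen.T_down,
                    "K_genes": cen.K,
                    "k_deregulated": cen.k,
                    "p_gene": gene_pvalue(cen.k, cen.K, n, N),
                    "p_up": up_pvalue(model_cen, (cen.T, cen.T_up, cen.T_down)),
                    "p_down": down_pvalue(model_cen, (cen.T, cen.T_up, cen.T_down)),
                    "drp": drp(cen.k, cen.K) if cen.K else float("nan"),
                    "urp": cen.T_up / cen.T,
                    "dnrp": cen.T_down / cen.T,
                }
            )
    return pd.DataFrame(rows)


def _bh_adjust(p: pd.Series) -> pd.Series:
    from statsmodels.stats.multitest import multipletests

    if p.empty:
        return p
    return pd.Series(multipletests(p.values, method="fdr_bh")[1], index=p.index)


def aminf_table(
    network_table: pd.DataFrame,
    alpha_gene: float = DEFAULT_ALPHA_GENE,
    alpha_reaction: float = DEFAULT_ALPHA_REACTION,
) -> pd.DataFrame:
    """Per-task AMiNF in the three modes (gene, up, down)."""
    rows = []
    for (pair, task), grp in network_table.groupby(["condition_pair", "task"], sort=True):
        rows.append(
            {
                "condition_pair": pair,
                "task": task,
                "n_alternatives": len(grp),
                "aminf_gene": aminf(grp["p_gene"], alpha_gene),
                "aminf_up": aminf(grp["p_up"], alpha_reaction),
                "aminf_down": aminf(grp["p_down"], alpha_reaction),
            }
        )
    return pd.DataFrame(rows)


def hfr_regulation_table(
    sets: list[AlternativeSet], regulation: RegulationAssignment
) -> pd.DataFrame:
    """Counts of up- and downregulated HFRs per phenotype and per task."""
    rows = []
    for alt in sets:
        states = [regulation.reaction_states[r] for r in alt.hfrs]
        rows.append(
            {
                "condition_pair": regulation.condition_pair,
                "phenotype": alt.phenotype,
                "task": alt.task,
                "n_hfrs": len(alt.hfrs),
                "hfrs_up": sum(1 for s in states if s == UP),
                "hfrs_down": sum(1 for s in states if s == DOWN),
            }
        )
    return pd.DataFrame(rows)


def build_report(
    sets: list[AlternativeSet],
    model: MetabolicModel,
    regulations: list[RegulationAssignment],
    alpha_gene: float = DEFAULT_ALPHA_GENE,
    alpha_reaction: float = DEFAULT_ALPHA_REACTION,
    gene_universe: str = "model",
) -> dict[str, pd.DataFrame]:
    """Assemble the full enrichment report across condition pairs.

    Returns ``{"networks": per-MiN table, "aminf": per-task AMiNF table,
    "hfr_regulation": HFR regulation counts}``.  The per-MiN table carries
    significance flags at the raw thresholds plus Benjamini-Hochberg
    adjusted companions (reported, never used for AMiNF), and an up/down
    network label from whichever reaction-mode p-value clears its
    threshold (the smaller wins if both do; exact ties labelled "both").
    """
    nets = pd.concat(
        [score_networks(sets, model, reg, gene_universe) for reg in regulations],
        ignore_index=True,
    )
    if not nets.empty:
        nets["significant_gene"] = nets["p_gene"] < alpha_gene
        nets["significant_up"] = nets["p_up"] < alpha_reaction
        nets["significant_down"] = nets["p_down"] < alpha_reaction
        for col in ("p_gene", "p_up", "p_down"):
            nets[col + "_bh"] = nets.groupby("condition_pair")[col].transform(_bh_adjust)

        def label(row):
            up_ok, down_ok = row["significant_up"], row["significant_down"]
            if up_ok and down_ok:
                if row["p_up"] == row["p_down"]:
                    return "both"
                return "up" if row["p_up"] < row["p_down"] else "down"
            if up_ok:
                return "up"
            if down_ok:
                return "down"
            return ""

        nets["regulation_label"] = nets.apply(label, axis=1)

    aminfs = aminf_table(nets, alpha_gene, alpha_reaction) if not nets.empty else pd.DataFrame()
    hfr = pd.concat(
        [hfr_regulation_table(sets, reg) for reg in regulations], ignore_index=True
    )
    return {"networks": nets, "aminf": aminfs, "hfr_regulation": hfr}
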