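"""Synthetic fixtures with known ground truth, and brute-force oracles.

The generator builds small multi-compartment-style stoichiometric models
shaped as source → staged parallel branches → target: each stage offers a
set of stoichiometrically interchangeable branches, so the number of
alternative minimal networks is the product of the branch counts over the
stages, and the high-frequency reactions are exactly the shared backbone.
Decoy routes (one reaction longer than a branch) are flux-capable but never
minimal.  Optionally a stage's branches can be coupled to a shared cofactor
pair whose regeneration reaction then joins every minimal network — the
mass-balance effect that pathway-map enrichment cannot represent.

The oracles here re-derive every statistic by exhaustive enumeration and
are deliberately independent of the MILP and of the rational tail sums
they are used to check.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy.optimize import linprog

from .gem_io import GprNode, MetabolicModel, Metabolite, ReactionRecord
from .min_enum import ACTIVITY_TOL, YIELD_TOL, AlternativeSet, MinimalNetwork
from .regulation import DOWN, UP
from .tasks import DEFAULT_YIELD_FRACTION, MetabolicTask, formulate_task

ORACLE_MAX_REACTIONS = 14
ORACLE_MAX_R = 15


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one parallel-route fixture.

    ``branches_per_stage`` gives the number of interchangeable branches in
    each of ``n_stages`` stages (an entry of 0 degenerates to a single
    direct route).  ``n_decoy_reactions`` counts decoy routes, each one
    reaction longer than a branch.  ``gpr_genes_per_reaction`` is an
    inclusive ``(lo, hi)`` range sampled per reaction.  The expected number
    of alternative minimal networks is the product of the (clamped) branch
    counts.
    """

    n_stages: int = 1
    branches_per_stage: tuple[int, ...] = (2,)
    branch_length: int = 1
    n_decoy_reactions: int = 0
    gpr_genes_per_reaction: tuple[int, int] = (1, 2)
    seed: int = 0
    cofactor_stages: tuple[int, ...] = ()

    def __post_init__(self):
        if len(self.branches_per_stage) != self.n_stages:
            raise ValueError("branches_per_stage must have n_stages entries")
        lo, hi = self.gpr_genes_per_reaction
        if not (0 <= lo <= hi):
            raise ValueError("bad gpr_genes_per_reaction range")

    @property
    def expected_alternatives(self) -> int:
        return math.prod(max(1, b) for b in self.branches_per_stage)


def _gpr_for(rxn_id: str, rng, lo: int, hi: int) -> GprNode | None:
    n = int(rng.integers(lo, hi + 1)) if hi > lo else lo
    if n == 0:
        return None
    leaves = tuple(GprNode(gene=f"G_{rxn_id}_{i}") for i in range(n))
    return leaves[0] if n == 1 else GprNode(op="and", children=leaves)


def make_parallel_gem(spec: FixtureSpec):
    """Build the fixture model, its task, and the ground-truth alternatives.

    Returns ``(model, task, truth)`` where ``truth`` is an
    :class:`AlternativeSet` whose networks are derived by construction (one
    branch chosen per stage plus the backbone), with flux witnesses of 1
    unit along the chosen route.  Deterministic under ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.gpr_genes_per_reaction

    metabolites = [Metabolite(f"M{s}", "c") for s in range(spec.n_stages + 1)]
    metabolites.append(Metabolite("TGT", "c"))
    reactions: list[ReactionRecord] = []
    stoich: dict[tuple[str, str], float] = {}

    def add_rxn(rid: str, coeffs: dict[str, float], subsystem: str) -> None:
        reactions.append(
            ReactionRecord(
                id=rid, lower=0.0, upper=100.0,
                gpr=_gpr_for(rid, rng, lo, hi), subsystem=subsystem,
            )
        )
        for met, c in coeffs.items():
            stoich[(met, rid)] = c

    def add_chain(prefix: str, src: str, dst: str, length: int,
                  subsystem: str, extra_first: dict[str, float]) -> list[str]:
        ids = []
        prev = src
        for step in range(length):
            nxt = dst if step == length - 1 else f"X_{prefix}_{step}"
            if nxt != dst:
                metabolites.append(Metabolite(nxt, "c"))
            coeffs = {prev: -1.0, nxt: 1.0}
            if step == 0:
                coeffs.update(extra_first)
            rid = f"R_{prefix}_{step}"
            add_rxn(rid, coeffs, subsystem)
            ids.append(rid)
            prev = nxt
        return ids

    add_rxn("R_src", {"M0": 1.0}, "uptake")
    backbone = ["R_src", "R_fin"]
    branch_ids: dict[tuple[int, int], list[str]] = {}
    cofactor_used = False
    for s in range(1, spec.n_stages + 1):
        n_branches = max(1, spec.branches_per_stage[s - 1])
        coupled = s in spec.cofactor_stages
        if coupled and not cofactor_used:
            metabolites.append(Metabolite("COF_ox", "c"))
            metabolites.append(Metabolite("COF_red", "c"))
            add_rxn("R_cof", {"COF_red": -1.0, "COF_ox": 1.0}, "cofactor")
            backbone.append("R_cof")
            cofactor_used = True
        extra = {"COF_ox": -1.0, "COF_red": 1.0} if coupled else {}
        for b in range(n_branches):
            branch_ids[(s, b)] = add_chain(
                f"s{s}b{b}", f"M{s-1}", f"M{s}", spec.branch_length,
                f"stage_{s}", extra,
            )
    add_rxn("R_fin", {f"M{spec.n_stages}": -1.0, "TGT": 1.0}, "secretion")

    # decoy routes: one reaction longer than a branch, round-robin by stage
    for d in range(spec.n_decoy_reactions):
        s = 1 + d % spec.n_stages
        add_chain(f"decoy{d}", f"M{s-1}", f"M{s}", spec.branch_length + 1, "decoy", {})

    genes: set[str] = set()
    for r in reactions:
        if r.gpr is not None:
            genes |= r.gpr.leaves()
    model = MetabolicModel(
        model_id=f"parallel_{spec.seed}",
        metabolites=metabolites,
        reactions=reactions,
        stoichiometry=stoich,
        genes=genes,
    )
    model.validate()

    task = MetabolicTask(name="TGT_synthesis", target_metabolite="TGT",
                         phenotype="synthetic", c=DEFAULT_YIELD_FRACTION)

    # ground truth by construction
    networks = []
    choices = [range(max(1, b)) for b in spec.branches_per_stage]
    for combo in itertools.product(*choices):
        active = list(backbone)
        for s, b in enumerate(combo, start=1):
            active += branch_ids[(s, b)]
        witness = {rid: 100.0 for rid in active}
        witness["DM_TGT"] = 100.0
        networks.append(
            MinimalNetwork(task=task.name, active_reactions=frozenset(active),
                           flux_witness=witness)
        )
    networks.sort(key=lambda n: (n.size, sorted(n.active_reactions)))
    truth = AlternativeSet(
        task=task.name, networks=networks, msize=networks[0].size,
        phenotype=task.phenotype,
    )
    return model, task, truth


def plant_regulation(
    model: MetabolicModel,
    target_branch: str,
    direction: str,
    background_rate: float = 0.0,
    seed: int = 0,
) -> dict[str, str]:
    """Gene calls with one branch fully regulated in ``direction``.

    ``target_branch`` is a reaction-id prefix (e.g. ``"R_s1b2"``); every
    gene of every reaction on that branch is called in the given direction.
    All other model genes are independently called with probability
    ``background_rate``, direction uniform.  Deterministic under ``seed``.
    """
    if direction not in (UP, DOWN):
        raise ValueError(f"direction must be 'up' or 'down', got {direction!r}")
    branch_rxns = [r for r in model.reactions if r.id.startswith(target_branch)]
    if not branch_rxns:
        raise KeyError(f"no reactions match branch prefix {target_branch!r}")
    branch_genes: set[str] = set()
    for r in branch_rxns:
        if r.gpr is not None:
            branch_genes |= r.gpr.leaves()

    rng = np.random.default_rng(seed)
    calls: dict[str, str] = {}
    for g in sorted(model.genes - branch_genes):
        if rng.random() < background_rate:
            calls[g] = UP if rng.random() < 0.5 else DOWN
    for g in sorted(branch_genes):
        calls[g] = direction
    return calls


# ---------------------------------------------------------------------------
# Oracles
# ---------------------------------------------------------------------------

def oracle_enumerate(model: MetabolicModel, task: MetabolicTask) -> AlternativeSet:
    """Exhaustive minimal-network enumeration on a tiny model.

    Tests every subset of the (≤ 14) non-demand parent reactions in
    ascending cardinality for LP feasibility of the yield floor restricted
    to that subset; all minimum-cardinality feasible subsets are returned.
    An infeasible task yields an empty set with msize 0 (undefined).
    """
    if not task.demand_reaction_id:
        model, task = formulate_task(model, task)
    parents = model.parent_ids()
    if len(parents) > ORACLE_MAX_REACTIONS:
        raise ValueError(
            f"oracle refuses models with more than {ORACLE_MAX_REACTIONS} "
            f"reactions (got {len(parents)})"
        )
    S, lb, ub = model.to_arrays()
    lb = np.maximum(lb, 0.0)
    n = len(model.reactions)
    demand_j = model.reaction_ids.index(task.demand_reaction_id)
    floor = task.c * task.v_mt_max
    cost = np.zeros(n)
    cost[demand_j] = -1.0
    dirs_of = {p: [j for j, r in enumerate(model.reactions) if r.parent_id == p
                   and not r.is_demand] for p in parents}

    def feasible(subset) -> dict[str, float] | None:
        mask_ub = ub.copy()
        allowed = set().union(*(dirs_of[p] for p in subset)) if subset else set()
        for j, r in enumerate(model.reactions):
            if not r.is_demand and j not in allowed:
                mask_ub[j] = 0.0
        res = linprog(cost, A_eq=S, b_eq=np.zeros(S.shape[0]),
                      bounds=list(zip(lb, mask_ub)), method="highs")
        if res.success and -res.fun >= floor - YIELD_TOL:
            return {
                model.reactions[j].id: float(res.x[j])
                for j in range(n) if abs(res.x[j]) > ACTIVITY_TOL
            }
        return None

    if not (task.v_mt_max > 0):
        return AlternativeSet(task=task.name, networks=[], msize=0,
                              phenotype=task.phenotype)

    for size in range(1, len(parents) + 1):
        found = []
        for subset in itertools.combinations(parents, size):
            witness = feasible(subset)
            if witness is not None:
                found.append(
                    MinimalNetwork(task=task.name,
                                   active_reactions=frozenset(subset),
                                   flux_witness=witness)
                )
        if found:
            found.sort(key=lambda net: sorted(net.active_reactions))
            return AlternativeSet(task=task.name, networks=found, msize=size,
                                  phenotype=task.phenotype)
    return AlternativeSet(task=task.name, networks=[], msize=0,
                          phenotype=task.phenotype)


def oracle_multivariate_tail(model_census, network_census, mode: str) -> Fraction:
    """Exact reaction-mode tail probability by full subset enumeration.

    Labels the R ≤ 15 model reactions up/down/no per the census, walks all
    C(R, T) subsets, and counts those at least as extreme as the observed
    ``(T_up, T_down)`` pair: for ``mode="up"`` at least T_up ups and at
    most T_down downs, mirrored for ``mode="down"``.
    """
    R, R_up, R_down, R_no = model_census
    T, T_up, T_down = network_census
    if R != R_up + R_down + R_no:
        raise ValueError("census does not partition R")
    if R > ORACLE_MAX_R:
        raise ValueError(f"oracle refuses R > {ORACLE_MAX_R} (got {R})")
    if mode not in ("up", "down"):
        raise ValueError(f"mode must be 'up' or 'down', got {mode!r}")

    labels = [UP] * R_up + [DOWN] * R_down + [None] * R_no
    hits = 0
    total = 0
    for subset in itertools.combinations(range(R), T):
        ups = sum(1 for i in subset if labels[i] == UP)
        downs = sum(1 for i in subset if labels[i] == DOWN)
        total += 1
        if mode == "up":
            if ups >= T_up and downs <= T_down:
                hits += 1
        else:
            if downs >= T_down and ups <= T_up:
                hits += 1
    return Fraction(hits, total)
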