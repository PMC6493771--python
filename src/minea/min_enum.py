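"""Minimal active network MILP and integer-cut enumeration.

For one metabolic task the problem is: among all steady-state flux
distributions (S·v = 0, 0 ≤ v ≤ vmax) that deliver at least ``c·V_MT,max``
through the task's demand reaction, find a support of minimum cardinality.
With a binary activity indicator z_i per reaction and the big-M coupling
``v_i ≤ vmax_i · z_i`` this is

    minimise  Σ_i z_i
    s.t.      S·v = 0,  0 ≤ v_i ≤ vmax_i · z_i,  v_MT ≥ c · V_MT,max .

Alternative optima are enumerated by re-solving after adding one integer
cut per found network, ``Σ_{i∈A} z_i ≤ |A| − 1``, until the objective
exceeds ``msize + max_rank`` — so networks appear in non-decreasing size
order and every reported network is subset-minimal.

Sizes, cuts and reported reaction sets are all expressed at the *parent*
reaction level: the two directions of a split reversible reaction count
once, may not be active simultaneously (z_fwd + z_rev ≤ 1), and the demand
reaction is scaffolding, excluded from the count.

Reactions that overlap between all alternative networks of a task are the
task's high-frequency reactions (HFRs); intersecting further across all
tasks of a phenotype gives the phenotypic HFRs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, linprog, milp

from .gem_io import MetabolicModel
from .tasks import MetabolicTask, TaskInfeasibleError, formulate_task

logger = logging.getLogger(__name__)

#: Flux magnitude below which a reaction is considered inactive in a witness.
ACTIVITY_TOL = 1e-6
#: Feasibility slack allowed on the yield floor during witness verification.
YIELD_TOL = 1e-6

DEFAULT_MAX_RANK = 0
DEFAULT_CAP = 10_000


@dataclass
class MinimalNetwork:
    """One enumerated minimal active network with its flux witness."""

    task: str
    active_reactions: frozenset[str]
    flux_witness: dict[str, float]
    objective_rank: int = 0

    @property
    def size(self) -> int:
        return len(self.active_reactions)


@dataclass
class AlternativeSet:
    """All alternative minimal networks of one task, plus HFRs."""

    task: str
    networks: list[MinimalNetwork]
    msize: int
    truncated: bool = False
    phenotype: str = ""

    @property
    def hfrs(self) -> frozenset[str]:
        """Reactions present in every alternative network."""
        sets = [n.active_reactions for n in self.networks]
        return frozenset.intersection(*sets) if sets else frozenset()

    @property
    def hfr_fraction(self) -> float:
        """HFR count as a percentage of the minimal network size."""
        return 100.0 * len(self.hfrs) / self.msize if self.msize else float("nan")

    @property
    def n_alternatives(self) -> int:
        return len(self.networks)


class _TaskMilp:
    """MILP state for one (split model, formulated task) pair."""

    def __init__(self, model: MetabolicModel, task: MetabolicTask):
        if not task.demand_reaction_id:
            raise ValueError("task must be formulated (no demand reaction id)")
        if not (task.v_mt_max > 0):
            raise TaskInfeasibleError(
                f"task {task.name}: maximum yield is {task.v_mt_max}; nothing to enumerate"
            )
        self.model = model
        self.task = task
        self.S, self.lb, self.ub = model.to_arrays()
        self.n_rxn = len(model.reactions)
        self.demand_j = model.reaction_ids.index(task.demand_reaction_id)
        self.yield_floor = task.c * task.v_mt_max

        # binaries only for non-demand reactions with positive capacity
        self.bin_rxns = [
            j for j, r in enumerate(model.reactions)
            if not r.is_demand and self.ub[j] > 0
        ]
        self.parents = model.parent_ids()
        self._parent_of = {r.id: r.parent_id for r in model.reactions}
        self.cuts: list[frozenset[str]] = []

    # -- constraint assembly ---------------------------------------------
    def _build(self):
        n, m = self.n_rxn, len(self.bin_rxns)
        nv = n + m
        cons = []

        # mass balance S v = 0
        A_eq = sparse.hstack([self.S, sparse.csr_matrix((self.S.shape[0], m))])
        cons.append(LinearConstraint(A_eq, 0.0, 0.0))

        # big-M coupling v_j - ub_j z_j <= 0
        rows = sparse.lil_matrix((m, nv))
        for k, j in enumerate(self.bin_rxns):
            rows[k, j] = 1.0
            rows[k, n + k] = -self.ub[j]
        cons.append(LinearConstraint(rows.tocsr(), -np.inf, 0.0))

        # one direction per split pair
        bin_pos = {j: n + k for k, j in enumerate(self.bin_rxns)}
        by_parent: dict[str, list[int]] = {}
        for j in self.bin_rxns:
            by_parent.setdefault(self._parent_of[self.model.reactions[j].id], []).append(j)
        pair_rows = []
        for parent, js in by_parent.items():
            if len(js) > 1:
                row = np.zeros(nv)
                for j in js:
                    row[bin_pos[j]] = 1.0
                pair_rows.append(row)
        if pair_rows:
            cons.append(LinearConstraint(np.array(pair_rows), -np.inf, 1.0))

        # integer cuts over parent-level active sets
        for cut in self.cuts:
            row = np.zeros(nv)
            for j in self.bin_rxns:
                if self._parent_of[self.model.reactions[j].id] in cut:
                    row[bin_pos[j]] = 1.0
            cons.append(LinearConstraint(row, -np.inf, len(cut) - 1))

        lb = np.concatenate([np.maximum(self.lb, 0.0), np.zeros(m)])
        ub = np.concatenate([self.ub, np.ones(m)])
        lb[self.demand_j] = self.yield_floor
        integrality = np.concatenate([np.zeros(n), np.ones(m)])

        cost = np.zeros(nv)
        cost[n:] = 1.0
        return cost, cons, Bounds(lb, ub), integrality

    def solve_next(self) -> MinimalNetwork | None:
        """Solve under the current cuts; returns None when exhausted."""
        cost, cons, bounds, integrality = self._build()
        res = milp(
            c=cost,
            constraints=cons,
            bounds=bounds,
            integrality=integrality,
            options={"mip_rel_gap": 0.0, "presolve": True},
        )
        if res.status == 2:  # infeasible: all alternatives exhausted
            return None
        if not res.success:
            raise RuntimeError(
                f"MILP failed for task {self.task.name}: {res.message}"
            )
        z = res.x[self.n_rxn:]
        active = frozenset(
            self._parent_of[self.model.reactions[j].id]
            for k, j in enumerate(self.bin_rxns)
            if z[k] > 0.5
        )
        witness = self._verify(active)
        net = MinimalNetwork(
            task=self.task.name, active_reactions=active, flux_witness=witness
        )
        self.cuts.append(active)
        return net

    def _verify(self, active: frozenset[str]) -> dict[str, float]:
        """Re-derive a flux witness by an LP restricted to the active set.

        Independent of the MILP solution values: all reactions outside the
        active set (demand excepted) are closed and the demand flux is
        maximised.  Fails loudly if the yield floor cannot be met.
        """
        ub = self.ub.copy()
        for j, r in enumerate(self.model.reactions):
            if not r.is_demand and r.parent_id not in active:
                ub[j] = 0.0
        cost = np.zeros(self.n_rxn)
        cost[self.demand_j] = -1.0
        res = linprog(
            cost,
            A_eq=self.S,
            b_eq=np.zeros(self.S.shape[0]),
            bounds=list(zip(np.maximum(self.lb, 0.0), ub)),
            method="highs",
        )
        if not res.success or -res.fun < self.yield_floor - YIELD_TOL:
            raise RuntimeError(
                f"witness LP refutes MILP solution for task {self.task.name}: "
                f"active set {sorted(active)}"
            )
        v = res.x
        balance = np.abs(self.S @ v)
        if balance.max(initial=0.0) > 1e-6:
            raise RuntimeError("witness violates mass balance")
        return {
            r.id: float(v[j])
            for j, r in enumerate(self.model.reactions)
            if abs(v[j]) > ACTIVITY_TOL
        }


def prepare(model: MetabolicModel, task: MetabolicTask):
    """Formulate the task on a split model; returns (model, task, solver state)."""
    model, task = formulate_task(model, task)
    return model, task, _TaskMilp(model, task)


def solve_min_network(model: MetabolicModel, task: MetabolicTask) -> MinimalNetwork:
    """One provably minimum-cardinality active network for the task.

    ``model`` must already be split (all lower bounds ≥ 0); the task's
    demand reaction is added here if the task is not yet formulated.
    """
    if not task.demand_reaction_id:
        model, task, state = prepare(model, task)
    else:
        state = _TaskMilp(model, task)
    net = state.solve_next()
    if net is None:
        raise TaskInfeasibleError(f"task {task.name} is infeasible")
    return net


def enumerate_alternatives(
    model: MetabolicModel,
    task: MetabolicTask,
    max_rank: int = DEFAULT_MAX_RANK,
    cap: int = DEFAULT_CAP,
) -> AlternativeSet:
    """All alternative minimal networks of the task up to ``msize + max_rank``.

    Networks are found in non-decreasing size order by integer-cut
    re-solves; ``objective_rank`` records the excess over ``msize``.  If
    ``cap`` networks are found before the size bound is passed the result
    is flagged truncated (its HFRs then only describe the enumerated
    subset).  The returned list is sorted lexicographically by active-set
    ids, so the result is a deterministic function of the inputs.
    """
    if not task.demand_reaction_id:
        model, task, state = prepare(model, task)
    else:
        state = _TaskMilp(model, task)

    networks: list[MinimalNetwork] = []
    msize: int | None = None
    truncated = False
    while True:
        net = state.solve_next()
        if net is None:
            break
        if msize is None:
            msize = net.size
        if net.size > msize + max_rank:
            break
        net.objective_rank = net.size - msize
        networks.append(net)
        if len(networks) >= cap:
            truncated = True
            logger.warning(
                "task %s: enumeration capped at %d networks; HFRs describe "
                "the enumerated subset only", task.name, cap,
            )
            break
    if msize is None:
        raise TaskInfeasibleError(f"task {task.name} is infeasible")
    networks.sort(key=lambda n: (n.size, sorted(n.active_reactions)))
    return AlternativeSet(
        task=task.name,
        networks=networks,
        msize=msize,
        truncated=truncated,
        phenotype=task.phenotype,
    )


def phenotypic_hfrs(sets: list[AlternativeSet]) -> frozenset[str]:
    """Reactions shared by every alternative of every task in a phenotype."""
    if not sets:
        raise ValueError("phenotypic_hfrs needs at least one alternative set")
    if any(s.truncated for s in sets):
        logger.warning(
            "phenotypic HFRs computed from truncated enumerations; result is "
            "approximate"
        )
    members = [n.active_reactions for s in sets for n in s.networks]
    return frozenset.intersection(*members)


def subsystem_summary(active, model: MetabolicModel) -> pd.DataFrame:
    """Per-subsystem census of a reaction set against the whole model.

    ``active`` is any iterable of parent reaction ids (a network's active
    set, an HFR set...).  Reactions without a subsystem label are grouped
    under ``"unassigned"``.
    """
    active = set(active)
    rows: dict[str, dict[str, int]] = {}
    for parent in model.parent_ids():
        sub = next(
            (r.subsystem for r in model.directions_of(parent) if r.subsystem),
            "",
        ) or "unassigned"
        entry = rows.setdefault(sub, {"active": 0, "total": 0})
        entry["total"] += 1
        if parent in active:
            entry["active"] += 1
    out = pd.DataFrame(
        [(k, v["active"], v["total"]) for k, v in sorted(rows.items())],
        columns=["subsystem", "active", "total"],
    )
    return out
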