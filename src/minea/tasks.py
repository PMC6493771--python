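"""Metabolic tasks: demand reactions and yield ceilings.

A metabolic task (MT) asks the network to synthesise one target metabolite.
It is realised as an irreversible *demand* reaction consuming one unit of
the target; the task is then the constraint that the demand flux reach at
least a fraction ``c`` of its linear-programming maximum ``V_MT,max``
(default ``c = 0.8``, i.e. at least 80% of the maximum yield).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .gem_io import DEFAULT_VMAX, MetabolicModel, ReactionRecord

DEMAND_PREFIX = "DM_"

#: Fraction of the maximum yield the network must still attain inside a
#: minimal network.
DEFAULT_YIELD_FRACTION = 0.8


class TaskInfeasibleError(RuntimeError):
    """The task's target cannot be produced at a positive rate."""


@dataclass
class MetabolicTask:
    """One target-metabolite synthesis task.

    ``target_metabolite`` must name the metabolite in its compartment as it
    appears in the model (no compartment guessing is performed).
    ``v_mt_max`` and ``demand_reaction_id`` are filled in by
    :func:`formulate_task`; a task is usable only when ``v_mt_max > 0``.
    """

    name: str
    target_metabolite: str
    phenotype: str = ""
    c: float = DEFAULT_YIELD_FRACTION
    v_mt_max: float = field(default=float("nan"))
    demand_reaction_id: str = ""

    def __post_init__(self):
        if not (0 < self.c <= 1):
            raise ValueError(f"yield fraction c must be in (0, 1], got {self.c}")


def add_demand(model: MetabolicModel, target: str, vmax: float = DEFAULT_VMAX):
    """Append a demand reaction consuming one unit of ``target``.

    Returns ``(model, demand_reaction_id)``.  Idempotent: a second call for
    the same target returns the existing demand reaction.
    """
    if not model.has_metabolite(target):
        raise KeyError(f"unknown metabolite {target!r}")
    demand_id = DEMAND_PREFIX + target
    if model.has_reaction(demand_id):
        return model, demand_id
    out = model.copy()
    out.reactions.append(
        ReactionRecord(id=demand_id, lower=0.0, upper=vmax, is_demand=True)
    )
    out.stoichiometry[(target, demand_id)] = -1.0
    out._reindex()
    return out, demand_id


def compute_max_yield(model: MetabolicModel, demand_id: str) -> float:
    """LP maximum of the demand flux subject to S·v = 0 and the bounds."""
    if not model.has_reaction(demand_id):
        raise KeyError(f"unknown reaction {demand_id!r}")
    S, lb, ub = model.to_arrays()
    j = model.reaction_ids.index(demand_id)
    cost = np.zeros(S.shape[1])
    cost[j] = -1.0
    res = linprog(
        cost,
        A_eq=S,
        b_eq=np.zeros(S.shape[0]),
        bounds=list(zip(lb, ub)),
        method="highs",
    )
    if not res.success:
        raise RuntimeError(f"max-yield LP failed for {demand_id}: {res.message}")
    return max(0.0, float(-res.fun))


def formulate_task(
    model: MetabolicModel, task: MetabolicTask, vmax: float = DEFAULT_VMAX
):
    """Attach the task's demand reaction and compute its maximum yield.

    Returns ``(model_with_demand, task)`` where the task carries
    ``demand_reaction_id`` and ``v_mt_max``.
    """
    model, demand_id = add_demand(model, task.target_metabolite, vmax=vmax)
    v_max = compute_max_yield(model, demand_id)
    return model, replace(task, v_mt_max=v_max, demand_reaction_id=demand_id)


def load_tasks(
    path: str,
    model: MetabolicModel | None = None,
    c: float = DEFAULT_YIELD_FRACTION,
) -> list[MetabolicTask]:
    """Read a task table (TSV: task_name, metabolite_id, compartment, phenotype).

    ``metabolite_id`` may already include the compartment suffix, in which
    case the compartment column may be empty; otherwise the target is
    ``<metabolite_id>_<compartment>``.  When a model is given, each target
    is checked against it and a missing metabolite is an error naming the
    offending row.
    """
    table = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"task_name", "metabolite_id"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"task table {path} lacks columns: {sorted(missing)}")
    if table["task_name"].duplicated().any():
        dupes = sorted(table.loc[table["task_name"].duplicated(), "task_name"])
        raise ValueError(f"duplicate task names in {path}: {dupes}")

    tasks: list[MetabolicTask] = []
    for i, row in table.iterrows():
        met = row["metabolite_id"]
        comp = row.get("compartment", "")
        target = f"{met}_{comp}" if comp and not met.endswith(f"_{comp}") else met
        if model is not None and not model.has_metabolite(target):
            raise KeyError(
                f"task table row {i} ({row['task_name']}): metabolite "
                f"{target!r} not in model {model.model_id}"
            )
        tasks.append(
            MetabolicTask(
                name=row["task_name"],
                target_metabolite=target,
                phenotype=row.get("phenotype", ""),
                c=c,
            )
        )
    return tasks
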