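"""Genome-scale metabolic model (GEM) containers and normalisation.

A GEM is held as an explicit stoichiometric structure: metabolites with
compartments, reactions with flux bounds and gene-protein-reaction (GPR)
rules, and a sparse (metabolite, reaction) -> coefficient mapping.  Before
any minimal-network computation the model is *normalised*: every reversible
reaction is split into two irreversible forward reactions so that all fluxes
are non-negative and a single binary activity indicator per direction is
meaningful in the MILP.

Parsing of the standard on-disk formats (SBML Level 3 with the fbc package,
COBRA-style JSON) is delegated to cobrapy; this module only converts the
parsed structure into the containers above and validates it.
"""

from __future__ import annotations

import json
import logging
import math
import re
from dataclasses import dataclass, field, replace

logger = logging.getLogger(__name__)

#: Default cap for unbounded fluxes, in model flux units.  Keeps the MILP
#: big-M coefficients finite; standard COBRA convention.
DEFAULT_VMAX = 1000.0

FWD_SUFFIX = "_fwd"
REV_SUFFIX = "_rev"


class ModelValidationError(ValueError):
    """Raised when a model file parses but violates structural invariants."""


# ---------------------------------------------------------------------------
# GPR expression trees
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GprNode:
    """Node of a boolean gene-protein-reaction expression.

    ``op`` is ``"and"`` or ``"or"`` for internal nodes (with ``children``),
    or ``None`` for a leaf, in which case ``gene`` holds the gene id.
    """

    op: str | None = None
    gene: str | None = None
    children: tuple["GprNode", ...] = ()

    def leaves(self) -> set[str]:
        if self.op is None:
            return {self.gene} if self.gene is not None else set()
        out: set[str] = set()
        for child in self.children:
            out |= child.leaves()
        return out

    def to_string(self) -> str:
        if self.op is None:
            return self.gene or ""
        sep = f" {self.op} "
        return "(" + sep.join(c.to_string() for c in self.children) + ")"


_GPR_TOKEN = re.compile(r"\(|\)|[^\s()]+")


def parse_gpr(rule: str) -> GprNode | None:
    """Parse a GPR rule string into an expression tree.

    Accepts both ``and``/``or`` and ``&``/``|`` (also ``&&``/``||``)
    spellings, case-insensitively, with parentheses; ``and`` binds tighter
    than ``or``.  Returns ``None`` for an empty rule.  Raises ``ValueError``
    on malformed input (the caller decides whether to warn-and-drop).
    """
    if rule is None or not rule.strip():
        return None
    tokens = _GPR_TOKEN.findall(rule)
    pos = 0

    def peek() -> str | None:
        return tokens[pos] if pos < len(tokens) else None

    def classify(tok: str) -> str:
        low = tok.lower()
        if low in ("and", "&", "&&"):
            return "and"
        if low in ("or", "|", "||"):
            return "or"
        return "gene"

    def parse_or() -> GprNode:
        nonlocal pos
        terms = [parse_and()]
        while peek() is not None and classify(peek()) == "or":
            pos += 1
            terms.append(parse_and())
        return terms[0] if len(terms) == 1 else GprNode(op="or", children=tuple(terms))

    def parse_and() -> GprNode:
        nonlocal pos
        terms = [parse_atom()]
        while peek() is not None and classify(peek()) == "and":
            pos += 1
            terms.append(parse_atom())
        return terms[0] if len(terms) == 1 else GprNode(op="and", children=tuple(terms))

    def parse_atom() -> GprNode:
        nonlocal pos
        tok = peek()
        if tok is None:
            raise ValueError(f"GPR rule ended unexpectedly: {rule!r}")
        if tok == "(":
            pos += 1
            node = parse_or()
            if peek() != ")":
                raise ValueError(f"unbalanced parentheses in GPR rule: {rule!r}")
            pos += 1
            return node
        if classify(tok) != "gene" or tok == ")":
            raise ValueError(f"unexpected token {tok!r} in GPR rule: {rule!r}")
        pos += 1
        return GprNode(gene=tok)

    node = parse_or()
    if pos != len(tokens):
        raise ValueError(f"trailing tokens in GPR rule: {rule!r}")
    return node


# ---------------------------------------------------------------------------
# Model containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Metabolite:
    id: str
    compartment: str = ""


@dataclass(frozen=True)
class ReactionRecord:
    """One reaction: bounds, GPR tree, subsystem, and split bookkeeping.

    ``parent_id`` names the original reaction when this record is one
    direction of a split reversible reaction; for unsplit reactions it
    equals ``id``.  ``is_demand`` marks task scaffolding (demand reactions
    added by the tasks layer) which is excluded from network size counts
    and regulation censuses.
    """

    id: str
    lower: float
    upper: float
    gpr: GprNode | None = None
    subsystem: str = ""
    parent_id: str = ""
    is_demand: bool = False

    def __post_init__(self):
        if not self.parent_id:
            object.__setattr__(self, "parent_id", self.id)

    @property
    def reversible(self) -> bool:
        return self.lower < 0


def genes_of(reaction: ReactionRecord) -> set[str]:
    """All gene ids appearing anywhere in the reaction's GPR rule.

    Gene-to-reaction association for regulation purposes is pure set
    membership in the rule — the AND/OR structure is deliberately ignored.
    """
    return reaction.gpr.leaves() if reaction.gpr is not None else set()


@dataclass
class MetabolicModel:
    """A validated stoichiometric model.

    ``stoichiometry`` maps ``(metabolite_id, reaction_id)`` to the (signed)
    stoichiometric coefficient; absent pairs are zero.
    """

    model_id: str
    metabolites: list[Metabolite]
    reactions: list[ReactionRecord]
    stoichiometry: dict[tuple[str, str], float]
    genes: set[str] = field(default_factory=set)

    def __post_init__(self):
        self._reindex()

    def _reindex(self) -> None:
        self._met_index = {m.id: i for i, m in enumerate(self.metabolites)}
        self._rxn_index = {r.id: i for i, r in enumerate(self.reactions)}

    # -- lookups ----------------------------------------------------------
    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def reaction(self, rxn_id: str) -> ReactionRecord:
        return self.reactions[self._rxn_index[rxn_id]]

    def has_metabolite(self, met_id: str) -> bool:
        return met_id in self._met_index

    def has_reaction(self, rxn_id: str) -> bool:
        return rxn_id in self._rxn_index

    def reaction_stoichiometry(self, rxn_id: str) -> dict[str, float]:
        return {m: c for (m, r), c in self.stoichiometry.items() if r == rxn_id}

    def parent_ids(self, include_demand: bool = False) -> list[str]:
        """Distinct parent reaction ids in first-appearance order."""
        seen: dict[str, None] = {}
        for r in self.reactions:
            if r.is_demand and not include_demand:
                continue
            seen.setdefault(r.parent_id)
        return list(seen)

    def directions_of(self, parent_id: str) -> list[ReactionRecord]:
        return [r for r in self.reactions if r.parent_id == parent_id]

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        ids = [r.id for r in self.reactions]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ModelValidationError(f"duplicate reaction ids: {dupes}")
        mids = [m.id for m in self.metabolites]
        if len(mids) != len(set(mids)):
            dupes = sorted({i for i in mids if mids.count(i) > 1})
            raise ModelValidationError(f"duplicate metabolite ids: {dupes}")
        rxn_with_stoich = set()
        for (met, rxn), coeff in self.stoichiometry.items():
            if met not in self._met_index:
                raise ModelValidationError(
                    f"stoichiometry references unknown metabolite {met!r}"
                )
            if rxn not in self._rxn_index:
                raise ModelValidationError(
                    f"stoichiometry references unknown reaction {rxn!r}"
                )
            if coeff != 0:
                rxn_with_stoich.add(rxn)
        for r in self.reactions:
            if r.id not in rxn_with_stoich:
                raise ModelValidationError(
                    f"reaction {r.id!r} has no stoichiometry"
                )
            for g in genes_of(r):
                if g not in self.genes:
                    raise ModelValidationError(
                        f"reaction {r.id!r} GPR references unknown gene {g!r}"
                    )

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            model_id=self.model_id,
            metabolites=list(self.metabolites),
            reactions=list(self.reactions),
            stoichiometry=dict(self.stoichiometry),
            genes=set(self.genes),
        )

    def to_arrays(self):
        """Dense CSR stoichiometric matrix plus bound vectors (scipy sparse)."""
        import numpy as np
        from scipy import sparse

        rows, cols, data = [], [], []
        for (met, rxn), coeff in self.stoichiometry.items():
            rows.append(self._met_index[met])
            cols.append(self._rxn_index[rxn])
            data.append(coeff)
        S = sparse.csr_matrix(
            (data, (rows, cols)),
            shape=(len(self.metabolites), len(self.reactions)),
        )
        lb = np.array([r.lower for r in self.reactions], dtype=float)
        ub = np.array([r.upper for r in self.reactions], dtype=float)
        return S, lb, ub


# ---------------------------------------------------------------------------
# Loading / writing
# ---------------------------------------------------------------------------

def _clip_bound(x: float, vmax: float) -> float:
    if x is None or math.isinf(x):
        return math.copysign(vmax, x if x is not None else 1.0)
    return max(-vmax, min(vmax, x))


def _from_cobra(cb_model, vmax: float) -> MetabolicModel:
    metabolites = [Metabolite(m.id, m.compartment or "") for m in cb_model.metabolites]
    reactions: list[ReactionRecord] = []
    stoich: dict[tuple[str, str], float] = {}
    genes: set[str] = set()
    for rxn in cb_model.reactions:
        rule = rxn.gene_reaction_rule or ""
        try:
            gpr = parse_gpr(rule)
        except ValueError as exc:
            logger.warning("unparseable GPR for %s (%s); treating as empty", rxn.id, exc)
            gpr = None
        if gpr is not None:
            genes |= gpr.leaves()
        reactions.append(
            ReactionRecord(
                id=rxn.id,
                lower=_clip_bound(rxn.lower_bound, vmax),
                upper=_clip_bound(rxn.upper_bound, vmax),
                gpr=gpr,
                subsystem=rxn.subsystem or "",
            )
        )
        if not rxn.metabolites:
            raise ModelValidationError(f"reaction {rxn.id!r} has no stoichiometry")
        for met, coeff in rxn.metabolites.items():
            stoich[(met.id, rxn.id)] = float(coeff)
    model = MetabolicModel(
        model_id=cb_model.id or "model",
        metabolites=metabolites,
        reactions=reactions,
        stoichiometry=stoich,
        genes=genes,
    )
    model.validate()
    return model


def load_model(path: str, format: str | None = None, vmax: float = DEFAULT_VMAX) -> MetabolicModel:
    """Load and validate a GEM from SBML (fbc) or COBRA-style JSON.

    ``format`` is ``"sbml"`` or ``"cobra-json"``; when omitted it is inferred
    from the file extension.  Unbounded or infinite flux bounds are clipped
    to ``±vmax``.  Unparseable GPR strings are logged and treated as empty.
    """
    path = str(path)
    if format is None:
        format = "cobra-json" if path.endswith(".json") else "sbml"
    if format not in ("sbml", "cobra-json"):
        raise ValueError(f"unknown model format {format!r}")

    import cobra.io

    if format == "cobra-json":
        with open(path) as fh:
            raw = json.load(fh)
        ids = [r.get("id") for r in raw.get("reactions", [])]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ModelValidationError(f"duplicate reaction ids in {path}: {dupes}")
        cb_model = cobra.io.load_json_model(path)
    else:
        cb_model = cobra.io.read_sbml_model(path)
    return _from_cobra(cb_model, vmax)


def write_model_json(model: MetabolicModel, path: str) -> None:
    """Write a COBRA-style JSON file that round-trips through load_model."""
    doc = {
        "id": model.model_id,
        "version": "1",
        "compartments": {m.compartment: m.compartment for m in model.metabolites if m.compartment},
        "metabolites": [
            {"id": m.id, "compartment": m.compartment, "name": m.id}
            for m in model.metabolites
        ],
        "genes": [{"id": g, "name": g} for g in sorted(model.genes)],
        "reactions": [
            {
                "id": r.id,
                "name": r.id,
                "metabolites": model.reaction_stoichiometry(r.id),
                "lower_bound": r.lower,
                "upper_bound": r.upper,
                "gene_reaction_rule": r.gpr.to_string() if r.gpr else "",
                "subsystem": r.subsystem,
            }
            for r in model.reactions
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# Normalisation
# ---------------------------------------------------------------------------

def split_reversible(model: MetabolicModel, vmax: float = DEFAULT_VMAX) -> MetabolicModel:
    """Split every reversible reaction into two irreversible forward copies.

    A reaction with ``lower < 0 < upper`` becomes ``<id>_fwd`` (original
    stoichiometry, bounds ``[0, upper]``) and ``<id>_rev`` (negated
    stoichiometry, bounds ``[0, -lower]``), both carrying ``parent_id = id``.
    A purely backward reaction (``upper <= 0``) is canonicalised into a
    single ``_rev`` copy.  Irreversible reactions are kept, with bounds
    clipped into ``[0, vmax]``.  Idempotent: a second application is a no-op.

    The operation preserves the feasible flux cone — any pre-split flux
    vector maps to a post-split one with identical net fluxes and back.
    """
    reactions: list[ReactionRecord] = []
    stoich: dict[tuple[str, str], float] = {}

    def put(rec: ReactionRecord, coeffs: dict[str, float]) -> None:
        reactions.append(rec)
        for met, c in coeffs.items():
            stoich[(met, rec.id)] = c

    for rxn in model.reactions:
        coeffs = model.reaction_stoichiometry(rxn.id)
        lower = _clip_bound(rxn.lower, vmax)
        upper = _clip_bound(rxn.upper, vmax)
        if lower >= 0:
            put(replace(rxn, lower=max(0.0, lower), upper=max(0.0, upper)), coeffs)
        elif upper <= 0:
            put(
                replace(
                    rxn,
                    id=rxn.id + REV_SUFFIX,
                    parent_id=rxn.parent_id,
                    lower=max(0.0, -upper),
                    upper=-lower,
                ),
                {m: -c for m, c in coeffs.items()},
            )
        else:
            put(
                replace(rxn, id=rxn.id + FWD_SUFFIX, parent_id=rxn.parent_id,
                        lower=0.0, upper=upper),
                coeffs,
            )
            put(
                replace(rxn, id=rxn.id + REV_SUFFIX, parent_id=rxn.parent_id,
                        lower=0.0, upper=-lower),
                {m: -c for m, c in coeffs.items()},
            )
    out = MetabolicModel(
        model_id=model.model_id,
        metabolites=list(model.metabolites),
        reactions=reactions,
        stoichiometry=stoich,
        genes=set(model.genes),
    )
    out.validate()
    return out


def apply_directionality(model: MetabolicModel, restrictions) -> MetabolicModel:
    """Restrict reaction directionality from an external table.

    ``restrictions`` is an iterable of ``(reaction_id, direction)`` rows (or
    a pandas DataFrame with columns ``reaction_id``/``direction``) with
    direction in ``{"forward", "reverse", "both"}``.  These bounds stand in
    for upstream thermodynamic pre-processing: the forbidden direction of
    each listed reaction gets upper bound 0.  Ids may be parent ids of split
    pairs or concrete (post-split) reaction ids.
    """
    try:
        rows = [(str(r.reaction_id), str(r.direction)) for r in restrictions.itertuples()]
    except AttributeError:
        rows = [(str(a), str(b)) for a, b in restrictions]

    out = model.copy()
    known_parents = {r.parent_id for r in out.reactions}
    unknown = [rid for rid, _ in rows if not out.has_reaction(rid) and rid not in known_parents]
    if unknown:
        raise KeyError(f"directionality table lists unknown reaction ids: {sorted(set(unknown))}")

    new_reactions = list(out.reactions)
    for rid, direction in rows:
        if direction not in ("forward", "reverse", "both"):
            raise ValueError(f"bad direction {direction!r} for {rid!r}")
        if direction == "both":
            continue
        for i, rxn in enumerate(new_reactions):
            if rxn.id != rid and rxn.parent_id != rid:
                continue
            is_rev_copy = rxn.id.endswith(REV_SUFFIX)
            if rxn.id == rid and not rxn.id.endswith((FWD_SUFFIX, REV_SUFFIX)):
                # unsplit reaction: adjust bounds in place
                if direction == "forward":
                    new_reactions[i] = replace(rxn, lower=max(0.0, rxn.lower))
                else:
                    new_reactions[i] = replace(rxn, upper=min(0.0, rxn.upper))
            elif (direction == "forward" and is_rev_copy) or (
                direction == "reverse" and not is_rev_copy
            ):
                new_reactions[i] = replace(rxn, upper=0.0, lower=0.0)
    out.reactions = new_reactions
    out._reindex()
    return out
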