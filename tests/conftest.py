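"""Shared toy-model builders for the test suite."""

import pytest

from minea.gem_io import MetabolicModel, Metabolite, ReactionRecord, parse_gpr


def make_model(rxns: dict, model_id: str = "toy", compartment: str = "c") -> MetabolicModel:
    """Build a validated model from {rxn_id: spec} where spec holds
    ``stoich`` (metabolite -> coefficient) and optional ``lb``, ``ub``,
    ``gpr`` (rule string), ``subsystem``.
    """
    met_ids: dict[str, None] = {}
    reactions, stoich, genes = [], {}, set()
    for rid, spec in rxns.items():
        for met in spec["stoich"]:
            met_ids.setdefault(met)
        gpr = parse_gpr(spec.get("gpr", ""))
        if gpr is not None:
            genes |= gpr.leaves()
        reactions.append(
            ReactionRecord(
                id=rid,
                lower=spec.get("lb", 0.0),
                upper=spec.get("ub", 100.0),
                gpr=gpr,
                subsystem=spec.get("subsystem", ""),
            )
        )
        for met, c in spec["stoich"].items():
            stoich[(met, rid)] = float(c)
    model = MetabolicModel(
        model_id=model_id,
        metabolites=[Metabolite(m, compartment) for m in met_ids],
        reactions=reactions,
        stoichiometry=stoich,
        genes=genes,
    )
    model.validate()
    return model


@pytest.fixture
def parallel_toy():
    """Source feeding two interchangeable routes to B: R1 →A, R2/R3 A→B."""
    return make_model(
        {
            "R1": {"stoich": {"A": 1.0}, "gpr": "g1"},
            "R2": {"stoich": {"A": -1.0, "B": 1.0}, "gpr": "g2 and g3"},
            "R3": {"stoich": {"A": -1.0, "B": 1.0}, "gpr": "g4"},
        }
    )


@pytest.fixture
def chain_toy():
    """A single linear route of five reactions; no alternatives exist."""
    mets = ["A", "B", "C", "D", "E"]
    rxns = {"R0": {"stoich": {"A": 1.0}, "gpr": "g0"}}
    for i in range(4):
        rxns[f"R{i+1}"] = {
            "stoich": {mets[i]: -1.0, mets[i + 1]: 1.0},
            "gpr": f"g{i+1}",
        }
    return make_model(rxns)


@pytest.fixture
def reversible_toy():
    """One reversible interconversion plus an uptake and a drain."""
    return make_model(
        {
            "R_in": {"stoich": {"A": 1.0}},
            "R_ab": {"stoich": {"A": -1.0, "B": 1.0}, "lb": -100.0},
            "R_out": {"stoich": {"B": -1.0}},
        }
    )
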