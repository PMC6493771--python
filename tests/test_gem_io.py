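"""Model container, GPR parsing, splitting and directionality."""

import json

import numpy as np
import pytest
from scipy.optimize import linprog

from minea.gem_io import (
    ModelValidationError,
    apply_directionality,
    genes_of,
    load_model,
    parse_gpr,
    split_reversible,
    write_model_json,
)

from conftest import make_model


class TestGprParsing:
    @pytest.mark.parametrize(
        "rule, leaves",
        [
            ("(g1 and g2) or g3", {"g1", "g2", "g3"}),
            ("g1 & g2 | g3", {"g1", "g2", "g3"}),
            ("G1 AND (G2 OR G3)", {"G1", "G2", "G3"}),
            ("g1 || (g1 && g2)", {"g1", "g2"}),  # deduplicated leaf set
            ("g1", {"g1"}),
            ("((g1))", {"g1"}),
        ],
    )
    def test_leaf_sets(self, rule, leaves):
        assert parse_gpr(rule).leaves() == leaves

    def test_empty_rule_is_none(self):
        assert parse_gpr("") is None
        assert parse_gpr("   ") is None

    @pytest.mark.parametrize("rule", ["g1 and", "(g1 or g2", "g1 g2", "and g1"])
    def test_malformed_rules_raise(self, rule):
        with pytest.raises(ValueError):
            parse_gpr(rule)

    def test_and_binds_tighter_than_or(self):
        tree = parse_gpr("g1 or g2 and g3")
        assert tree.op == "or"
        assert {c.op for c in tree.children} == {None, "and"}

    def test_genes_of_invariant_under_equivalent_rewrites(self, parallel_toy):
        # same leaf set under distributivity / duplication of terms
        rxn = parallel_toy.reaction("R2")
        rewritten = rxn.__class__(
            id="R2b", lower=0, upper=100,
            gpr=parse_gpr("(g2 or g2) and (g3 or g2)"),
        )
        assert genes_of(rxn) == {"g2", "g3"}
        assert genes_of(rewritten) == {"g2", "g3"}

    def test_genes_of_empty_gpr(self, reversible_toy):
        assert genes_of(reversible_toy.reaction("R_in")) == set()


class TestValidation:
    def test_missing_stoichiometry_rejected(self):
        with pytest.raises(ModelValidationError, match="no stoichiometry"):
            make_model({"R1": {"stoich": {}}})

    def test_duplicate_reaction_ids_rejected_on_load(self, tmp_path):
        doc = {
            "id": "dup", "metabolites": [{"id": "A", "compartment": "c"}],
            "genes": [],
            "reactions": [
                {"id": "R1", "metabolites": {"A": 1.0}, "lower_bound": 0,
                 "upper_bound": 10, "gene_reaction_rule": ""},
                {"id": "R1", "metabolites": {"A": -1.0}, "lower_bound": 0,
                 "upper_bound": 10, "gene_reaction_rule": ""},
            ],
        }
        path = tmp_path / "dup.json"
        path.write_text(json.dumps(doc))
        with pytest.raises(ModelValidationError, match="duplicate"):
            load_model(path, format="cobra-json")


class TestLoadRoundTrip:
    def test_json_round_trip_preserves_structure(self, parallel_toy, tmp_path):
        path = tmp_path / "model.json"
        write_model_json(parallel_toy, path)
        loaded = load_model(path)
        assert loaded.reaction_ids == parallel_toy.reaction_ids
        assert loaded.genes == parallel_toy.genes
        for rid in parallel_toy.reaction_ids:
            a, b = parallel_toy.reaction(rid), loaded.reaction(rid)
            assert (a.lower, a.upper) == (b.lower, b.upper)
            assert genes_of(a) == genes_of(b)
            assert parallel_toy.reaction_stoichiometry(rid) == loaded.reaction_stoichiometry(rid)

    def test_toy_fixture_counts(self, parallel_toy, tmp_path):
        path = tmp_path / "model.json"
        write_model_json(parallel_toy, path)
        loaded = load_model(path)
        assert len(loaded.reactions) == 3
        assert len(loaded.metabolites) == 2

    def test_unbounded_bounds_clipped_to_vmax(self, tmp_path):
        doc = {
            "id": "m", "metabolites": [{"id": "A", "compartment": "c"}],
            "genes": [],
            "reactions": [{"id": "R1", "metabolites": {"A": 1.0},
                           "lower_bound": -1e9, "upper_bound": 1e9,
                           "gene_reaction_rule": ""}],
        }
        path = tmp_path / "m.json"
        path.write_text(json.dumps(doc))
        m = load_model(path, vmax=1000.0)
        assert m.reaction("R1").lower == -1000.0
        assert m.reaction("R1").upper == 1000.0


def _max_net_flux(model, objective_rxns):
    """LP maximum of a net flux, summing signed split copies."""
    S, lb, ub = model.to_arrays()
    cost = np.zeros(len(model.reactions))
    for rid, sign in objective_rxns.items():
        cost[model.reaction_ids.index(rid)] = -sign
    res = linprog(cost, A_eq=S, b_eq=np.zeros(S.shape[0]),
                  bounds=list(zip(lb, ub)), method="highs")
    assert res.success
    return -res.fun


class TestSplitReversible:
    def test_reversible_becomes_two_forward_copies(self, reversible_toy):
        split = split_reversible(reversible_toy)
        ids = set(split.reaction_ids)
        assert {"R_ab_fwd", "R_ab_rev"} <= ids
        assert "R_ab" not in ids
        fwd, rev = split.reaction("R_ab_fwd"), split.reaction("R_ab_rev")
        assert (fwd.lower, fwd.upper) == (0.0, 100.0)
        assert (rev.lower, rev.upper) == (0.0, 100.0)
        assert fwd.parent_id == rev.parent_id == "R_ab"
        assert split.reaction_stoichiometry("R_ab_rev") == {"A": 1.0, "B": -1.0}

    def test_counts_and_lower_bounds(self):
        rxns = {f"R{i}": {"stoich": {"A": 1.0}} for i in range(3)}
        rxns["Rr1"] = {"stoich": {"A": -1.0, "B": 1.0}, "lb": -50.0}
        rxns["Rr2"] = {"stoich": {"B": -1.0}, "lb": -50.0}
        split = split_reversible(make_model(rxns))
        assert len(split.reactions) == 7
        assert all(r.lower >= 0 for r in split.reactions)

    def test_irreversible_unchanged(self, chain_toy):
        split = split_reversible(chain_toy)
        assert split.reaction_ids == chain_toy.reaction_ids

    def test_idempotent(self, reversible_toy):
        once = split_reversible(reversible_toy)
        twice = split_reversible(once)
        assert twice.reaction_ids == once.reaction_ids

    def test_flux_cone_preserved(self, reversible_toy):
        # max A->B throughput identical before and after splitting
        before = _max_net_flux(reversible_toy, {"R_out": 1.0})
        split = split_reversible(reversible_toy)
        after = _max_net_flux(split, {"R_out": 1.0})
        assert after == pytest.approx(before)
        # and the reverse direction is reachable post-split too
        assert _max_net_flux(split, {"R_ab_rev": 1.0}) == pytest.approx(100.0)


class TestDirectionality:
    def test_forbidden_direction_closed(self, reversible_toy):
        split = split_reversible(reversible_toy)
        restricted = apply_directionality(split, [("R_ab", "forward")])
        assert restricted.reaction("R_ab_rev").upper == 0.0
        assert restricted.reaction("R_ab_fwd").upper == 100.0

    def test_empty_table_is_identity(self, reversible_toy):
        split = split_reversible(reversible_toy)
        same = apply_directionality(split, [])
        assert [(r.id, r.lower, r.upper) for r in same.reactions] == [
            (r.id, r.lower, r.upper) for r in split.reactions
        ]

    def test_unknown_id_rejected(self, reversible_toy):
        with pytest.raises(KeyError, match="NOPE"):
            apply_directionality(split_reversible(reversible_toy), [("NOPE", "forward")])

    def test_restricting_only_route_kills_yield(self):
        from minea.tasks import add_demand, compute_max_yield

        model = make_model(
            {
                "R_in": {"stoich": {"A": 1.0}},
                "R_ab": {"stoich": {"A": -1.0, "B": 1.0}, "lb": -100.0},
            }
        )
        split = split_reversible(model)
        restricted = apply_directionality(split, [("R_ab", "reverse")])
        with_dm, dm = add_demand(restricted, "B")
        assert compute_max_yield(with_dm, dm) == pytest.approx(0.0)
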