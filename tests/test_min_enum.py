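"""MILP minimal networks, integer-cut enumeration, HFRs."""

import pytest

from minea.min_enum import (
    enumerate_alternatives,
    phenotypic_hfrs,
    solve_min_network,
    subsystem_summary,
)
from minea.synth import FixtureSpec, make_parallel_gem, oracle_enumerate
from minea.tasks import MetabolicTask, TaskInfeasibleError, formulate_task

from conftest import make_model


def _task(target="B", name="toy"):
    return MetabolicTask(name=name, target_metabolite=target)


class TestSolveMinNetwork:
    def test_parallel_toy_size_two(self, parallel_toy):
        net = solve_min_network(parallel_toy, _task())
        # demand scaffolding excluded: {R1, one of R2/R3}
        assert net.size == 2
        assert "R1" in net.active_reactions
        assert net.active_reactions & {"R2", "R3"}

    def test_chain_is_unique_network(self, chain_toy):
        net = solve_min_network(chain_toy, _task(target="E", name="chain"))
        assert net.active_reactions == frozenset(f"R{i}" for i in range(5))

    def test_witness_satisfies_yield_floor(self, parallel_toy):
        net = solve_min_network(parallel_toy, _task())
        assert net.flux_witness["DM_B"] >= 0.8 * 100.0 - 1e-6
        # witness fluxes only on active reactions (plus demand)
        for rid in net.flux_witness:
            assert rid == "DM_B" or rid in net.active_reactions

    def test_infeasible_task_raises(self):
        model = make_model({"R1": {"stoich": {"A": 1.0}}, "Rx": {"stoich": {"A": -1.0, "B": -1.0}}})
        with pytest.raises(TaskInfeasibleError):
            solve_min_network(model, _task(target="B"))


class TestEnumeration:
    def test_parallel_toy_two_alternatives(self, parallel_toy):
        alt = enumerate_alternatives(parallel_toy, _task())
        assert alt.n_alternatives == 2
        assert {n.active_reactions for n in alt.networks} == {
            frozenset({"R1", "R2"}), frozenset({"R1", "R3"})
        }
        assert alt.hfrs == frozenset({"R1"})
        assert alt.msize == 2

    def test_chain_single_alternative_full_hfr(self, chain_toy):
        alt = enumerate_alternatives(chain_toy, _task(target="E", name="chain"))
        assert alt.n_alternatives == 1
        assert alt.hfrs == alt.networks[0].active_reactions
        assert alt.hfr_fraction == pytest.approx(100.0)

    def test_networks_pairwise_distinct_and_size_ordered(self):
        spec = FixtureSpec(n_stages=2, branches_per_stage=(2, 3), branch_length=1,
                           n_decoy_reactions=1, seed=3)
        model, task, truth = make_parallel_gem(spec)
        alt = enumerate_alternatives(model, task)
        sets = [n.active_reactions for n in alt.networks]
        assert len(sets) == len(set(sets)) == truth.n_alternatives
        assert all(n.size == alt.msize for n in alt.networks)

    def test_max_rank_extends_to_larger_networks(self):
        # one short branch plus a decoy route one reaction longer: the decoy
        # network only appears once near-minimal networks are requested
        spec = FixtureSpec(n_stages=1, branches_per_stage=(1,), branch_length=1,
                           n_decoy_reactions=1, seed=5)
        model, task, _ = make_parallel_gem(spec)
        strict = enumerate_alternatives(model, task)
        assert strict.n_alternatives == 1
        relaxed = enumerate_alternatives(model, task, max_rank=1)
        assert {n.objective_rank for n in relaxed.networks} == {0, 1}
        bigger = [n for n in relaxed.networks if n.objective_rank == 1]
        assert all(n.size == relaxed.msize + 1 for n in bigger)
        assert any("decoy" in rid for n in bigger for rid in n.active_reactions)

    def test_cap_flags_truncation(self, parallel_toy):
        alt = enumerate_alternatives(parallel_toy, _task(), cap=1)
        assert alt.truncated
        assert alt.n_alternatives == 1

    def test_deterministic_network_set(self):
        spec = FixtureSpec(n_stages=1, branches_per_stage=(3,), branch_length=2,
                           n_decoy_reactions=2, seed=11)
        model, task, _ = make_parallel_gem(spec)
        a = enumerate_alternatives(model, task)
        b = enumerate_alternatives(model, task)
        assert [n.active_reactions for n in a.networks] == [
            n.active_reactions for n in b.networks
        ]

    def test_split_pair_never_both_active(self, reversible_toy):
        # a futile 2-cycle through R_ab_fwd/R_ab_rev must not appear
        from minea.gem_io import split_reversible

        split = split_reversible(reversible_toy)
        alt = enumerate_alternatives(split, _task(target="B", name="rev"))
        for net in alt.networks:
            fwd = net.flux_witness.get("R_ab_fwd", 0.0)
            rev = net.flux_witness.get("R_ab_rev", 0.0)
            assert not (fwd > 1e-6 and rev > 1e-6)

    def test_minimality_no_redundant_reaction(self, parallel_toy):
        # within each network, removing any single active reaction (all other
        # model reactions stay closed) breaks the yield floor
        from dataclasses import replace
        from minea.tasks import formulate_task, compute_max_yield

        model, task = formulate_task(parallel_toy, _task())
        alt = enumerate_alternatives(model, task)
        for net in alt.networks:
            for removed in net.active_reactions:
                allowed = net.active_reactions - {removed}
                pruned = model.copy()
                pruned.reactions = [
                    r if (r.is_demand or r.parent_id in allowed)
                    else replace(r, lower=0.0, upper=0.0)
                    for r in pruned.reactions
                ]
                pruned._reindex()
                assert compute_max_yield(pruned, task.demand_reaction_id) < 0.8 * 100.0


class TestOracleAgreement:
    @pytest.mark.parametrize("spec", [
        FixtureSpec(n_stages=1, branches_per_stage=(2,), branch_length=1, seed=0),
        FixtureSpec(n_stages=1, branches_per_stage=(3,), branch_length=2,
                    n_decoy_reactions=1, seed=1),
        FixtureSpec(n_stages=2, branches_per_stage=(2, 2), branch_length=1,
                    n_decoy_reactions=1, seed=2),
        FixtureSpec(n_stages=1, branches_per_stage=(2,), branch_length=2,
                    cofactor_stages=(1,), seed=3),
    ])
    def test_matches_exhaustive_search(self, spec):
        model, task, truth = make_parallel_gem(spec)
        milp = enumerate_alternatives(model, task)
        oracle = oracle_enumerate(model, task)
        assert milp.msize == oracle.msize == truth.msize
        assert {n.active_reactions for n in milp.networks} == \
               {n.active_reactions for n in oracle.networks} == \
               {n.active_reactions for n in truth.networks}
        assert milp.hfrs == oracle.hfrs == truth.hfrs


class TestPhenotypicHfrs:
    def test_single_task_equals_own_hfrs(self, parallel_toy):
        alt = enumerate_alternatives(parallel_toy, _task())
        assert phenotypic_hfrs([alt]) == alt.hfrs

    def test_shared_backbone_across_tasks(self):
        # two targets branching off the same uptake route
        model = make_model(
            {
                "R_in": {"stoich": {"A": 1.0}},
                "R_ab": {"stoich": {"A": -1.0, "B": 1.0}},
                "R_t1": {"stoich": {"B": -1.0, "T1": 1.0}},
                "R_t2": {"stoich": {"B": -1.0, "T2": 1.0}},
            }
        )
        alt1 = enumerate_alternatives(model, _task(target="T1", name="t1"))
        alt2 = enumerate_alternatives(model, _task(target="T2", name="t2"))
        assert phenotypic_hfrs([alt1, alt2]) == frozenset({"R_in", "R_ab"})

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            phenotypic_hfrs([])


class TestSubsystemSummary:
    def test_counts(self):
        model = make_model(
            {
                "R1": {"stoich": {"A": 1.0}, "subsystem": "uptake"},
                "R2": {"stoich": {"A": -1.0, "B": 1.0}, "subsystem": "core"},
                "R3": {"stoich": {"A": -1.0, "B": 1.0}, "subsystem": "core"},
                "R4": {"stoich": {"B": -1.0}},
            }
        )
        table = subsystem_summary({"R1", "R2"}, model)
        by_sub = table.set_index("subsystem")
        assert by_sub.loc["core", "active"] == 1
        assert by_sub.loc["core", "total"] == 2
        assert by_sub.loc["uptake", "active"] == 1
        assert by_sub.loc["unassigned", "total"] == 1

    def test_empty_set_all_zero(self, chain_toy):
        table = subsystem_summary(set(), chain_toy)
        assert (table["active"] == 0).all()
        assert table["total"].sum() == 5
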