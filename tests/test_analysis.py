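"""Recovery/accuracy scoring, connectivity curves, frequency tables, baselines."""

import pytest

from cfpath import (
    CFPQuery,
    CFPResultSet,
    FluxPath,
    ReferencePathway,
    accuracy_rate,
    apply_strategy,
    best_accuracy,
    connectivity_curve,
    connectivity_weights,
    enumerate_k_shortest,
    frequency_table,
    path_supportable,
    recovery_rate,
    stoichiometric_recovery_rate,
)


def _path(nodes):
    arcs = list(zip(nodes[:-1], nodes[1:]))
    return FluxPath(list(nodes), arcs, set(), {})


def _result(paths, source="S", target="T", k=None):
    query = CFPQuery(source, target, k=k or max(1, len(paths)))
    return CFPResultSet(query=query, paths=paths)


class TestRecovery:
    def test_exact_match_at_first_rank(self):
        ref = ReferencePathway("p", (("S", "a"), ("a", "T")))
        res = _result([_path(["S", "a", "T"])])
        rr = recovery_rate(res, ref)
        assert (rr.recovered, rr.rank, rr.accuracy) == (1, 1, 1.0)

    def test_no_match_among_many(self):
        ref = ReferencePathway("p", (("S", "zz"), ("zz", "T")))
        paths = [_path(["S", f"n{i}", "T"]) for i in range(100)]
        rr = recovery_rate(_result(paths), ref)
        assert rr.recovered == 0 and rr.rank is None

    def test_match_planted_at_rank_37(self):
        paths = [_path(["S", f"n{i}", "T"]) for i in range(100)]
        paths[36] = _path(["S", "hit", "T"])
        ref = ReferencePathway("p", (("S", "hit"), ("hit", "T")))
        rr = recovery_rate(_result(paths), ref)
        assert rr.recovered == 1 and rr.rank == 37

    def test_recovery_is_monotone_in_k(self):
        paths = [_path(["S", f"n{i}", "T"]) for i in range(10)]
        paths[4] = _path(["S", "hit", "T"])
        ref = ReferencePathway("p", (("S", "hit"), ("hit", "T")))
        for k in range(5, 11):
            assert recovery_rate(_result(paths[:k]), ref).recovered == 1


class TestStoichiometricRecovery:
    def test_correct_exclusion_of_infeasible_reference_scores_one(self):
        ref = ReferencePathway("tca", (("S", "x"), ("x", "T")))
        absent = _result([_path(["S", "y", "T"])])
        assert stoichiometric_recovery_rate(absent, ref, feasible=False) == 1

    def test_incorrect_recovery_of_infeasible_reference_scores_zero(self):
        ref = ReferencePathway("tca", (("S", "x"), ("x", "T")))
        present = _result([_path(["S", "x", "T"])])
        assert stoichiometric_recovery_rate(present, ref, feasible=True) == 1
        assert stoichiometric_recovery_rate(present, ref, feasible=False) == 0

    def test_feasibility_decided_by_per_path_check_on_figure2(self, fig2, config):
        bundle, net, graph = fig2
        ref = ReferencePathway(
            "route", (("A", "B"), ("B", "C"), ("C", "E"), ("E", "F"))
        )
        result = enumerate_k_shortest(
            graph, net, bundle.medium, CFPQuery("A", "F", k=5), config
        )
        feasible = (
            path_supportable(list(ref.arcs), graph, net, bundle.medium, config)
            is not None
        )
        assert stoichiometric_recovery_rate(result, ref, feasible) == 1
        # starved medium: reference infeasible AND absent -> correct exclusion
        starved = bundle.medium.without("D_ext")
        starved_result = enumerate_k_shortest(
            graph, net, starved, CFPQuery("A", "F", k=5), config
        )
        feasible = (
            path_supportable(list(ref.arcs), graph, net, starved, config) is not None
        )
        assert feasible is False
        assert stoichiometric_recovery_rate(starved_result, ref, feasible) == 1


class TestAccuracy:
    def test_identical_disjoint_and_partial_overlap(self):
        ref = ReferencePathway(
            "p", (("S", "a"), ("a", "b"), ("b", "c"), ("c", "T"))
        )
        assert accuracy_rate(_path(["S", "a", "b", "c", "T"]), ref) == 1.0
        assert accuracy_rate(_path(["S", "x", "y", "T"]), ref) == 0.0
        # shares 3 of 4 reference arcs
        shared = FluxPath(
            ["S", "a", "b", "c", "Z"],
            [("S", "a"), ("a", "b"), ("b", "c"), ("c", "Z")],
            set(),
            {},
        )
        assert accuracy_rate(shared, ref) == 0.75

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            accuracy_rate(_path(["S", "T"]), ReferencePathway("p", ()))

    def test_best_accuracy_is_one_whenever_recovered(self):
        ref = ReferencePathway("p", (("S", "a"), ("a", "T")))
        res = _result([_path(["S", "x", "T"]), _path(["S", "a", "T"])])
        assert recovery_rate(res, ref).recovered == 1
        assert best_accuracy(res, ref) == 1.0


class TestConnectivityCurve:
    def test_figure2_curve_from_source_a(self, fig2, config):
        bundle, net, graph = fig2
        curve = connectivity_curve("A", graph, net, bundle.medium, True, config)
        assert curve.counts == {1: 1, 2: 2, 3: 3, 4: 4, 5: 5}
        assert curve.total_reachable == 5
        assert set(curve.shortest_lengths) == {"B", "C", "E", "F", "F_ext"}

    def test_figure2_curve_identical_without_stoichiometry(self, fig2, config):
        bundle, net, graph = fig2
        on = connectivity_curve("A", graph, net, bundle.medium, True, config)
        off = connectivity_curve("A", graph, net, bundle.medium, False, config)
        assert on.shortest_lengths == off.shortest_lengths

    def test_stoichiometry_curve_dominated_pointwise(self, fig5_shunt, config):
        bundle, net, graph = fig5_shunt
        on = connectivity_curve("AcCoA", graph, net, bundle.medium, True, config)
        off = connectivity_curve("AcCoA", graph, net, bundle.medium, False, config)
        horizon = max([*on.shortest_lengths.values(), *off.shortest_lengths.values()], default=0)
        for n in range(1, horizon + 1):
            assert on.count_at(n) <= off.count_at(n)
        assert on.total_reachable <= off.total_reachable


class TestFrequencyTable:
    def test_single_path_counts(self):
        table = frequency_table(_result([_path(["A", "B", "C"])]))
        assert table.arc_frequency == {("A", "B"): 1, ("B", "C"): 1}
        assert table.metabolite_frequency == {"A": 1, "B": 1, "C": 1}

    def test_empty_result_set(self):
        table = frequency_table(_result([], k=1))
        assert table.arc_frequency == {} and table.metabolite_frequency == {}

    def test_planted_shared_arc_counted_seven_times(self):
        paths = [_path(["S", "mid", f"e{i}", "T"]) for i in range(7)]
        paths += [_path(["S", f"o{i}", "T"]) for i in range(3)]
        table = frequency_table(_result(paths))
        assert table.arc_frequency[("S", "mid")] == 7
        assert table.metabolite_frequency["S"] == 10


class TestStrategies:
    def test_topology_is_identity(self, fig2):
        _, net, graph = fig2
        graph2, weights = apply_strategy(graph, net, "topology")
        assert graph2 is graph
        assert set(weights.values()) == {1.0}

    def test_hub_removal_strips_touching_arcs(self, fig2):
        _, net, graph = fig2
        graph2, _ = apply_strategy(graph, net, "hubs", hub_list=["E"])
        assert set(graph2.arcs) == set(graph.arcs) - {("C", "E"), ("D", "E"), ("E", "F")}

    def test_unknown_hub_warns_and_is_skipped(self, fig2):
        _, net, graph = fig2
        with pytest.warns(UserWarning, match="ghost"):
            graph2, _ = apply_strategy(graph, net, "hubs", hub_list=["ghost"])
        assert set(graph2.arcs) == set(graph.arcs)

    def test_connectivity_weights_count_reactions_per_metabolite(self, fig2):
        _, net, graph = fig2
        _, weights = apply_strategy(graph, net, "connectivity_weighted")
        for m in "ABCDEF":
            assert weights[m] == 2.0
        assert weights["A_ext"] == 1.0

    def test_weighted_objective_prefers_low_connectivity_route(self, fig2, config):
        # sanity: on the toy network the unique route is returned either way
        bundle, net, graph = fig2
        graph2, weights = apply_strategy(graph, net, "connectivity_weighted")
        from cfpath import solve_shortest_cfp

        path = solve_shortest_cfp(
            graph2,
            net,
            bundle.medium,
            CFPQuery("A", "F", objective_mode="connectivity_weighted"),
            config,
            node_weights=weights,
        )
        assert path.node_sequence == ["A", "B", "C", "E", "F"]

    def test_connectivity_weights_computed_from_reaction_incidence(self, fig5_shunt):
        _, net, _ = fig5_shunt
        weights = connectivity_weights(net)
        # acetyl-CoA: beta-oxidation, citrate synthase, PDH, malate synthase
        assert weights["AcCoA"] == 4.0
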