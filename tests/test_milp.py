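"""CFP program construction, solving, enumeration and verification."""

import networkx as nx
import pytest

from cfpath import (
    CFPQuery,
    SolverConfig,
    brute_force_oracle,
    build_cfp_program,
    enumerate_k_shortest,
    path_supportable,
    solve_shortest_cfp,
    verify_solution,
)


class TestProgramStructure:
    def test_figure2_variable_and_linking_counts(self, fig2, config):
        _, net, graph = fig2
        program = build_cfp_program(
            graph, net, fig2[0].medium, CFPQuery("A", "F"), config
        )
        assert len(program.u_vars) == 8
        assert len(program.z_vars) == 7
        assert len(program.v_vars) == 7
        # one arc-covering constraint per graph arc
        assert program.problem.num_variables == 8 + 7 + 7

    def test_stoichiometry_free_mode_keeps_activity_and_covering(self, fig2, config):
        bundle, net, graph = fig2
        with_st = build_cfp_program(
            graph, net, bundle.medium, CFPQuery("A", "F", use_stoichiometry=True), config
        )
        without = build_cfp_program(
            graph, net, bundle.medium, CFPQuery("A", "F", use_stoichiometry=False), config
        )
        # dropping the balances removes exactly the per-metabolite constraints
        # (internal balances plus no-uptake bounds on non-medium externals)
        n_balance = len(
            [
                m
                for m in net.metabolites
                if any(m.id in r.stoichiometry for r in net.reactions)
                and (m.is_internal or m.id not in bundle.medium.consumable)
            ]
        )
        assert with_st.problem.num_constraints - without.problem.num_constraints == n_balance
        # z/v still exist: arc covering needs them
        assert len(without.z_vars) == len(net.reactions)

    def test_no_reverse_pairs_means_no_exclusion_constraints(self, fig2, glcat, config):
        bundle2, net2, graph2 = fig2
        bundleg, netg, graphg = glcat
        assert net2.reverse_pairs == set()
        base = build_cfp_program(
            graphg, netg, bundleg.medium, CFPQuery("DGlc", "Prod"), config
        )
        no_cut = build_cfp_program(
            graphg,
            netg,
            bundleg.medium,
            CFPQuery("DGlc", "Prod", forbid_reverse_pairs=False),
            config,
        )
        assert base.problem.num_constraints - no_cut.problem.num_constraints == len(
            netg.reverse_pairs
        )

    def test_bad_endpoints_rejected(self, fig2, config):
        bundle, net, graph = fig2
        with pytest.raises(ValueError):
            CFPQuery("A", "A")
        with pytest.raises(ValueError, match="unreachable endpoint"):
            build_cfp_program(graph, net, bundle.medium, CFPQuery("A", "nope"), config)


class TestSolveFigure2:
    def test_unique_path_with_all_reactions_active(self, fig2, config):
        bundle, net, graph = fig2
        path = solve_shortest_cfp(graph, net, bundle.medium, CFPQuery("A", "F"), config)
        assert path is not None
        assert path.node_sequence == ["A", "B", "C", "E", "F"]
        assert path.arcs == [("A", "B"), ("B", "C"), ("C", "E"), ("E", "F")]
        assert path.length == 4
        assert path.active_reactions == {f"r{i}" for i in range(1, 8)}
        assert verify_solution(path, graph, net, bundle.medium, config).ok

    def test_off_path_balancing_needs_exactly_three_reactions(self, fig2, config):
        bundle, net, graph = fig2
        path = solve_shortest_cfp(graph, net, bundle.medium, CFPQuery("A", "F"), config)
        assert path.off_path_reactions(graph) == {"r1", "r6", "r7"}

    def test_medium_knockout_destroys_flux_path_but_not_graph_path(self, fig2, config):
        bundle, net, graph = fig2
        starved = bundle.medium.without("D_ext")
        assert solve_shortest_cfp(graph, net, starved, CFPQuery("A", "F"), config) is None
        assert nx.has_path(graph.to_networkx(), "A", "F")

    def test_enumeration_exhausts_after_the_single_path(self, fig2, config):
        bundle, net, graph = fig2
        result = enumerate_k_shortest(
            graph, net, bundle.medium, CFPQuery("A", "F", k=5), config
        )
        assert len(result.paths) == 1
        assert result.exhausted
        assert result.paths[0].node_sequence == ["A", "B", "C", "E", "F"]

    def test_k1_enumeration_matches_single_solve(self, fig5_shunt, config):
        bundle, net, graph = fig5_shunt
        q = CFPQuery(bundle.source, bundle.target, k=1)
        single = solve_shortest_cfp(graph, net, bundle.medium, q, config)
        result = enumerate_k_shortest(graph, net, bundle.medium, q, config)
        assert [p.arc_set for p in result.paths] == [single.arc_set]
        assert not result.exhausted


class TestVerifier:
    def test_tampered_flux_fails_the_internal_balance(self, fig2, config):
        bundle, net, graph = fig2
        path = solve_shortest_cfp(graph, net, bundle.medium, CFPQuery("A", "F"), config)
        path.fluxes["r1"] = 0.0
        path.active_reactions.discard("r1")
        verdict = verify_solution(path, graph, net, bundle.medium, config)
        assert not verdict.ok
        assert any("balance: internal A" in f for f in verdict.failures)

    def test_forward_backward_pair_fails_reversibility_check(self, glcat, config):
        bundle, net, graph = glcat
        result = enumerate_k_shortest(
            graph,
            net,
            bundle.medium,
            CFPQuery("DGlc", "Prod", k=3, forbid_reverse_pairs=False),
            config,
        )
        pathological = next(
            p
            for p in result.paths
            if any(pair <= p.active_reactions for pair in net.reverse_pairs)
        )
        verdict = verify_solution(
            pathological, graph, net, bundle.medium, config, forbid_reverse_pairs=True
        )
        assert not verdict.ok
        assert any("reverse_pair" in f for f in verdict.failures)

    def test_verifier_rejects_arc_without_active_support(self, fig2, config):
        bundle, net, graph = fig2
        path = solve_shortest_cfp(graph, net, bundle.medium, CFPQuery("A", "F"), config)
        path.active_reactions.discard("r3")
        verdict = verify_solution(path, graph, net, bundle.medium, config)
        assert any("cover: arc B->C" in f for f in verdict.failures)


class TestOracle:
    def test_figure2_oracle_finds_exactly_the_one_path(self, fig2, config):
        bundle, net, graph = fig2
        result = brute_force_oracle(
            graph, net, bundle.medium, CFPQuery("A", "F", k=10), config
        )
        assert [p.node_sequence for p in result.paths] == [["A", "B", "C", "E", "F"]]
        assert result.exhausted

    def test_oracle_excludes_graph_path_without_medium_support(self, fig2, config):
        bundle, net, graph = fig2
        starved = bundle.medium.without("D_ext")
        result = brute_force_oracle(
            graph, net, starved, CFPQuery("A", "F", k=10), config
        )
        assert result.paths == []
        assert (
            sum(1 for _ in nx.all_simple_paths(graph.to_networkx(), "A", "F")) == 1
        )

    def test_oracle_refuses_oversized_graphs(self, fig5_shunt, config):
        bundle, net, graph = fig5_shunt
        with pytest.raises(ValueError, match="budget"):
            brute_force_oracle(
                graph, net, bundle.medium, CFPQuery("AcCoA", "G6P"), config, max_nodes=10
            )

    def test_reference_path_supportability_check(self, fig2, config):
        bundle, net, graph = fig2
        arcs = [("A", "B"), ("B", "C"), ("C", "E"), ("E", "F")]
        assert path_supportable(arcs, graph, net, bundle.medium, config) is not None
        assert (
            path_supportable(arcs, graph, net, bundle.medium.without("D_ext"), config)
            is None
        )


class TestSolverConfig:
    def test_inconsistent_big_m_rejected(self):
        with pytest.raises(ValueError):
            SolverConfig(big_M=0.5)

    def test_scaling_big_m_does_not_change_solutions(self, fig5_shunt):
        bundle, net, graph = fig5_shunt
        q = CFPQuery("AcCoA", "G6P", k=5)
        base = enumerate_k_shortest(graph, net, bundle.medium, q, SolverConfig())
        scaled = enumerate_k_shortest(
            graph, net, bundle.medium, q, SolverConfig(big_M=10000.0)
        )
        assert sorted(tuple(sorted(p.arc_set)) for p in base.paths) == sorted(
            tuple(sorted(p.arc_set)) for p in scaled.paths
        )
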