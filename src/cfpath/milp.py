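"""Carbon-flux-path MILP: build, solve, enumerate, verify.

A carbon flux path (CFP) from a source metabolite ``alpha`` to a target
``beta`` is a simple directed path in the carbon-exchange metabolite
graph that can operate inside a steady-state flux distribution of the
whole network.  The decision problem is a mixed-integer linear program:

* binary ``u_ij`` — arc i->j is on the path;
* binary ``z_r`` — reaction r carries non-zero flux;
* continuous ``v_r`` in [0, M] — the flux through r (fluxes are scaled
  so the minimum non-zero flux is 1 and the maximum is M).

Path structure: exactly one arc leaves the source and one enters the
target; no arc enters the source or leaves the target; flow is conserved
at every other node; in-degree is at most one everywhere (no node
revisited).  Steady state: internal metabolites balance exactly,
external metabolites outside the growth medium may only be net
produced.  Activity coupling: ``z_r <= v_r <= M z_r``.  A split
reversible pair may not be co-active.  Each path arc must be covered by
at least one active reaction supporting it in carbon exchange — active
reactions need not lie on the path, which is how off-path balancing
(producing the source, draining the target, supplying co-substrates)
enters the model.

The objective minimizes the number of arcs (or their node weights, for
the connectivity-weighted baseline).  K-shortest enumeration re-solves
after adding, for each found path with arc set A and length L, the
integer cut ``sum_{(i,j) in A} u_ij <= L - 1``, which also excludes
strict supersets of found paths (so no path-plus-detached-cycle
solutions survive enumeration).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

from .network import MetabolicNetwork, Medium, MetaboliteGraph
from .solver import MilpProblem, Solution, Status

__all__ = [
    "CFPQuery",
    "SolverConfig",
    "FluxPath",
    "CFPResultSet",
    "CFPProgram",
    "Verdict",
    "UnsolvedError",
    "build_cfp_program",
    "solve_shortest_cfp",
    "enumerate_k_shortest",
    "verify_solution",
    "path_supportable",
    "brute_force_oracle",
]


class UnsolvedError(RuntimeError):
    """The solver hit a limit; feasibility is undecided (never 'no CFP')."""


@dataclass(frozen=True)
class CFPQuery:
    """A source/target/K query over the metabolite graph.

    ``use_stoichiometry`` toggles the steady-state balance constraints
    (the stoichiometry-free comparison mode drops exactly those two
    constraint families; activity coupling and arc covering remain).
    ``forbid_reverse_pairs`` toggles the reversible-pair exclusion, kept
    switchable to demonstrate the forward/backward-cycle pathology.
    """

    source: str
    target: str
    k: int = 1
    use_stoichiometry: bool = True
    objective_mode: str = "unit"  # or "connectivity_weighted"
    forbid_reverse_pairs: bool = True

    def __post_init__(self) -> None:
        if self.source == self.target:
            raise ValueError("source and target must differ")
        if self.k < 1:
            raise ValueError("k must be a positive integer")
        if self.objective_mode not in ("unit", "connectivity_weighted"):
            raise ValueError(f"unknown objective_mode {self.objective_mode!r}")


@dataclass(frozen=True)
class SolverConfig:
    """Numerical configuration.

    ``big_M`` caps fluxes after scaling the minimum non-zero flux to
    ``min_flux`` (fixed at 1); any steady state needing a flux ratio
    beyond M:1 is thereby infeasible, so M is exposed.  Tolerances sit
    above the HiGHS default feasibility tolerances.  ``random_seed`` is
    accepted for reproducibility bookkeeping; the HiGHS backend is
    deterministic for a fixed problem.
    """

    big_M: float = 1000.0
    min_flux: float = 1.0
    int_tolerance: float = 1e-6
    flux_tolerance: float = 1e-6
    time_limit_seconds: float | None = None
    solver_name: str = "highs"
    random_seed: int | None = None

    def __post_init__(self) -> None:
        if not (self.big_M > self.min_flux >= self.flux_tolerance):
            raise ValueError("require big_M > min_flux >= flux_tolerance")


@dataclass
class FluxPath:
    """A solved CFP: the path plus its supporting flux distribution."""

    node_sequence: list[str]
    arcs: list[tuple[str, str]]
    active_reactions: set[str]
    fluxes: dict[str, float]

    @property
    def length(self) -> int:
        return len(self.arcs)

    @property
    def arc_set(self) -> frozenset[tuple[str, str]]:
        return frozenset(self.arcs)

    def off_path_reactions(self, graph: MetaboliteGraph) -> set[str]:
        """Active reactions not supporting any arc of the path."""
        on_path: set[str] = set()
        for i, j in self.arcs:
            on_path |= graph.support(i, j) & self.active_reactions
        return self.active_reactions - on_path

    def to_dict(self) -> dict:
        return {
            "node_sequence": list(self.node_sequence),
            "arcs": [list(a) for a in self.arcs],
            "active_reactions": sorted(self.active_reactions),
            "fluxes": {r: self.fluxes[r] for r in sorted(self.fluxes)},
            "length": self.length,
        }


@dataclass
class CFPResultSet:
    query: CFPQuery
    paths: list[FluxPath] = field(default_factory=list)
    exhausted: bool = False

    def arc_set_family(self) -> list[frozenset[tuple[str, str]]]:
        return [p.arc_set for p in self.paths]

    def to_dict(self) -> dict:
        return {
            "query": {
                "source": self.query.source,
                "target": self.query.target,
                "k": self.query.k,
                "use_stoichiometry": self.query.use_stoichiometry,
                "objective_mode": self.query.objective_mode,
            },
            "paths": [p.to_dict() for p in self.paths],
            "exhausted": self.exhausted,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


@dataclass
class CFPProgram:
    """A built program with its variable-name maps."""

    problem: MilpProblem
    u_vars: dict[tuple[str, str], str]
    z_vars: dict[str, str]
    v_vars: dict[str, str]


def build_cfp_program(
    graph: MetaboliteGraph,
    network: MetabolicNetwork,
    medium: Medium,
    query: CFPQuery,
    config: SolverConfig = SolverConfig(),
    node_weights: dict[str, float] | None = None,
) -> CFPProgram:
    """Assemble the CFP MILP for one query.

    ``node_weights`` is required for ``connectivity_weighted`` objective
    mode and ignored otherwise.
    """
    alpha, beta = query.source, query.target
    for endpoint in (alpha, beta):
        if endpoint not in graph.nodes:
            raise ValueError(f"unreachable endpoint: {endpoint!r} not in graph")
    medium.validate(network)

    prob = MilpProblem()
    u_vars = {arc: prob.add_binary(f"u[{arc[0]}->{arc[1]}]") for arc in sorted(graph.arcs)}
    # z/v exist regardless of use_stoichiometry: arc covering still links
    # arcs to reactions, and activity coupling gives covered arcs flux.
    z_vars = {r.id: prob.add_binary(f"z[{r.id}]") for r in network.reactions}
    v_vars = {
        r.id: prob.add_continuous(f"v[{r.id}]", 0.0, config.big_M)
        for r in network.reactions
    }

    out_arcs: dict[str, list[tuple[str, str]]] = {}
    in_arcs: dict[str, list[tuple[str, str]]] = {}
    for i, j in graph.arcs:
        out_arcs.setdefault(i, []).append((i, j))
        in_arcs.setdefault(j, []).append((i, j))

    def degree_expr(arcs: list[tuple[str, str]]) -> dict[str, float]:
        return {u_vars[a]: 1.0 for a in arcs}

    # source/target degrees: one arc leaves alpha, one enters beta;
    # none enters alpha, none leaves beta.
    prob.add_constraint(degree_expr(out_arcs.get(alpha, [])), 1.0, 1.0, "src_out")
    prob.add_constraint(degree_expr(in_arcs.get(beta, [])), 1.0, 1.0, "tgt_in")
    prob.add_constraint(degree_expr(in_arcs.get(alpha, [])), 0.0, 0.0, "src_in")
    prob.add_constraint(degree_expr(out_arcs.get(beta, [])), 0.0, 0.0, "tgt_out")

    for node in sorted(graph.nodes):
        if node in (alpha, beta):
            continue
        expr = {u_vars[a]: 1.0 for a in in_arcs.get(node, [])}
        for a in out_arcs.get(node, []):
            expr[u_vars[a]] = expr.get(u_vars[a], 0.0) - 1.0
        if expr:
            prob.add_constraint(expr, 0.0, 0.0, f"flow[{node}]")
        ins = in_arcs.get(node, [])
        if ins:
            prob.add_constraint(degree_expr(ins), ub=1.0, name=f"visit[{node}]")

    if query.use_stoichiometry:
        consumable = medium.consumable
        for met in network.metabolites:
            expr = {}
            for r in network.reactions:
                coeff = r.stoichiometry.get(met.id)
                if coeff:
                    expr[v_vars[r.id]] = coeff
            if not expr:
                continue
            if met.is_internal:
                prob.add_constraint(expr, 0.0, 0.0, f"balance[{met.id}]")
            elif met.id not in consumable:
                prob.add_constraint(expr, lb=0.0, name=f"no_uptake[{met.id}]")

    for r in network.reactions:
        # min_flux * z_r <= v_r <= M * z_r
        prob.add_constraint(
            {v_vars[r.id]: 1.0, z_vars[r.id]: -config.min_flux},
            lb=0.0,
            name=f"act_lo[{r.id}]",
        )
        prob.add_constraint(
            {v_vars[r.id]: 1.0, z_vars[r.id]: -config.big_M},
            ub=0.0,
            name=f"act_hi[{r.id}]",
        )

    if query.forbid_reverse_pairs:
        for pair in sorted(map(sorted, network.reverse_pairs)):
            lam, mu = pair
            prob.add_constraint(
                {z_vars[lam]: 1.0, z_vars[mu]: 1.0}, ub=1.0, name=f"rev[{lam}]"
            )

    for arc in sorted(graph.arcs):
        expr = {u_vars[arc]: 1.0}
        for r in sorted(graph.support(*arc)):
            expr[z_vars[r]] = -1.0
        prob.add_constraint(expr, ub=0.0, name=f"cover[{arc[0]}->{arc[1]}]")

    if query.objective_mode == "connectivity_weighted":
        if node_weights is None:
            raise ValueError("connectivity_weighted objective requires node_weights")
        prob.set_objective(
            {u_vars[(i, j)]: float(node_weights.get(j, 1.0)) for (i, j) in graph.arcs}
        )
    else:
        prob.set_objective({name: 1.0 for name in u_vars.values()})

    return CFPProgram(prob, u_vars, z_vars, v_vars)


def _extract_path(
    graph: MetaboliteGraph,
    query: CFPQuery,
    program: CFPProgram,
    solution: Solution,
    config: SolverConfig,
) -> FluxPath:
    tol = config.int_tolerance
    chosen = {
        arc for arc, name in program.u_vars.items() if solution.values[name] > 1.0 - tol
    }
    succ = {i: j for (i, j) in chosen}
    seq = [query.source]
    while seq[-1] != query.target:
        nxt = succ.get(seq[-1])
        if nxt is None or nxt in seq:
            raise RuntimeError("solver returned a non-path arc set")
        seq.append(nxt)
    arcs = list(zip(seq[:-1], seq[1:]))
    if set(arcs) != chosen:
        raise RuntimeError("solver arc set contains arcs off the extracted path")
    active = {
        r for r, name in program.z_vars.items() if solution.values[name] > 1.0 - tol
    }
    fluxes = {r: max(0.0, solution.values[name]) for r, name in program.v_vars.items()}
    return FluxPath(seq, arcs, active, fluxes)


def solve_shortest_cfp(
    graph: MetaboliteGraph,
    network: MetabolicNetwork,
    medium: Medium,
    query: CFPQuery,
    config: SolverConfig = SolverConfig(),
    node_weights: dict[str, float] | None = None,
) -> FluxPath | None:
    """Shortest CFP for the query, or ``None`` if no CFP exists."""
    program = build_cfp_program(graph, network, medium, query, config, node_weights)
    sol = program.problem.solve(time_limit=config.time_limit_seconds)
    if sol.status is Status.OPTIMAL:
        return _extract_path(graph, query, program, sol, config)
    if sol.status is Status.INFEASIBLE:
        return None
    raise UnsolvedError(f"solver returned status {sol.status.value}")


def enumerate_k_shortest(
    graph: MetaboliteGraph,
    network: MetabolicNetwork,
    medium: Medium,
    query: CFPQuery,
    config: SolverConfig = SolverConfig(),
    node_weights: dict[str, float] | None = None,
) -> CFPResultSet:
    """K-shortest CFPs via iterated integer cuts.

    Stops at K paths or at the first infeasible iteration (``exhausted``
    is then true: fewer than K CFPs exist).
    """
    result = CFPResultSet(query=query)
    cuts: list[FluxPath] = []
    for iteration in range(query.k):
        program = build_cfp_program(graph, network, medium, query, config, node_weights)
        for path in cuts:
            program.problem.add_constraint(
                {program.u_vars[a]: 1.0 for a in path.arcs},
                ub=path.length - 1,
                name=f"cut[{len(cuts)}]",
            )
        sol = program.problem.solve(time_limit=config.time_limit_seconds)
        if sol.status is Status.INFEASIBLE:
            result.exhausted = True
            break
        if sol.status is not Status.OPTIMAL:
            raise UnsolvedError(
                f"iteration {iteration + 1}: solver status {sol.status.value}"
            )
        path = _extract_path(graph, query, program, sol, config)
        result.paths.append(path)
        cuts.append(path)
    return result


# -- verification --------------------------------------------------------


@dataclass
class Verdict:
    ok: bool
    failures: list[str]

    def __bool__(self) -> bool:
        return self.ok

    @property
    def first_failure(self) -> str | None:
        return self.failures[0] if self.failures else None


def verify_solution(
    path: FluxPath,
    graph: MetaboliteGraph,
    network: MetabolicNetwork,
    medium: Medium,
    config: SolverConfig = SolverConfig(),
    use_stoichiometry: bool = True,
    forbid_reverse_pairs: bool = True,
) -> Verdict:
    """Independent numerical/combinatorial re-check of a solved path.

    Checks, in order: simple-path structure; internal balances; external
    non-medium net production; flux/activity coupling; reverse-pair
    exclusion; arc covering by active supporting reactions.  Always
    returns a verdict (never raises), naming every violated constraint.
    """
    failures: list[str] = []
    tol = config.flux_tolerance
    seq, arcs = path.node_sequence, path.arcs

    if len(set(seq)) != len(seq):
        failures.append("path: node revisited")
    if arcs != list(zip(seq[:-1], seq[1:])) or path.length != len(seq) - 1:
        failures.append("path: arc list inconsistent with node sequence")
    for a in arcs:
        if a not in graph.arcs:
            failures.append(f"path: arc {a[0]}->{a[1]} not in metabolite graph")

    if use_stoichiometry:
        for met in network.metabolites:
            net = sum(
                r.stoichiometry.get(met.id, 0.0) * path.fluxes.get(r.id, 0.0)
                for r in network.reactions
            )
            if met.is_internal:
                if abs(net) > tol:
                    failures.append(f"balance: internal {met.id} net {net:.3g}")
            elif met.id not in medium.consumable and net < -tol:
                failures.append(f"no_uptake: external {met.id} consumed ({net:.3g})")

    for r in network.reactions:
        v = path.fluxes.get(r.id, 0.0)
        if r.id in path.active_reactions:
            if v < config.min_flux - tol:
                failures.append(f"activity: {r.id} active but flux {v:.3g} < 1")
        elif v > tol:
            failures.append(f"activity: {r.id} inactive but flux {v:.3g} > 0")

    if forbid_reverse_pairs:
        for pair in network.reverse_pairs:
            if pair <= path.active_reactions:
                lam, mu = sorted(pair)
                failures.append(f"reverse_pair: {lam} and {mu} co-active")

    for i, j in arcs:
        if not (graph.support(i, j) & path.active_reactions):
            failures.append(f"cover: arc {i}->{j} has no active supporting reaction")

    return Verdict(not failures, failures)


# -- brute-force oracle --------------------------------------------------


def path_supportable(
    arcs: list[tuple[str, str]],
    graph: MetaboliteGraph,
    network: MetabolicNetwork,
    medium: Medium,
    config: SolverConfig = SolverConfig(),
    use_stoichiometry: bool = True,
    forbid_reverse_pairs: bool = True,
) -> FluxPath | None:
    """Feasibility check for one given simple path.

    Solves a small program over reaction variables only (the path arcs
    are fixed): steady-state balances, activity coupling, reverse-pair
    exclusion, and at-least-one active supporting reaction per path arc.
    Returns the path with a witnessing flux distribution, or ``None``.
    """
    prob = MilpProblem()
    z = {r.id: prob.add_binary(f"z[{r.id}]") for r in network.reactions}
    v = {
        r.id: prob.add_continuous(f"v[{r.id}]", 0.0, config.big_M)
        for r in network.reactions
    }
    if use_stoichiometry:
        for met in network.metabolites:
            expr = {
                v[r.id]: r.stoichiometry[met.id]
                for r in network.reactions
                if met.id in r.stoichiometry
            }
            if not expr:
                continue
            if met.is_internal:
                prob.add_constraint(expr, 0.0, 0.0)
            elif met.id not in medium.consumable:
                prob.add_constraint(expr, lb=0.0)
    for r in network.reactions:
        prob.add_constraint({v[r.id]: 1.0, z[r.id]: -config.min_flux}, lb=0.0)
        prob.add_constraint({v[r.id]: 1.0, z[r.id]: -config.big_M}, ub=0.0)
    if forbid_reverse_pairs:
        for pair in network.reverse_pairs:
            lam, mu = sorted(pair)
            prob.add_constraint({z[lam]: 1.0, z[mu]: 1.0}, ub=1.0)
    for i, j in arcs:
        support = graph.support(i, j)
        if not support:
            return None
        prob.add_constraint({z[r]: 1.0 for r in sorted(support)}, lb=1.0)
    prob.set_objective({})
    sol = prob.solve(time_limit=config.time_limit_seconds)
    if sol.status is Status.INFEASIBLE:
        return None
    if sol.status is not Status.OPTIMAL:
        raise UnsolvedError(f"per-path feasibility: status {sol.status.value}")
    active = {r for r, name in z.items() if sol.values[name] > 1.0 - config.int_tolerance}
    fluxes = {r: max(0.0, sol.values[name]) for r, name in v.items()}
    seq = [arcs[0][0]] + [j for _, j in arcs] if arcs else []
    return FluxPath(seq, list(arcs), active, fluxes)


def brute_force_oracle(
    graph: MetaboliteGraph,
    network: MetabolicNetwork,
    medium: Medium,
    query: CFPQuery,
    config: SolverConfig = SolverConfig(),
    max_nodes: int = 15,
) -> CFPResultSet:
    """Ground truth by exhaustive enumeration (small graphs only).

    Enumerates every simple directed path source->target by depth-first
    search, keeps those that pass the per-path feasibility check, and
    returns the first K sorted by length.  Exponential in graph size; a
    node budget guards against misuse.
    """
    if len(graph.nodes) > max_nodes:
        raise ValueError(
            f"oracle refused: {len(graph.nodes)} nodes exceeds budget {max_nodes}"
        )
    import networkx as nx

    g = graph.to_networkx()
    if query.source not in g or query.target not in g:
        raise ValueError("query endpoint not in graph")
    supported: list[FluxPath] = []
    for seq in nx.all_simple_paths(g, query.source, query.target):
        arcs = list(zip(seq[:-1], seq[1:]))
        fp = path_supportable(
            arcs,
            graph,
            network,
            medium,
            config,
            use_stoichiometry=query.use_stoichiometry,
            forbid_reverse_pairs=query.forbid_reverse_pairs,
        )
        if fp is not None:
            supported.append(fp)
    supported.sort(key=lambda p: (p.length, p.node_sequence))
    exhausted = len(supported) < query.k
    return CFPResultSet(query=query, paths=supported[: query.k], exhausted=exhausted)
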