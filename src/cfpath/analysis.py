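"""Downstream analyses over CFP result sets.

Recovery and accuracy against reference pathways, connectivity curves
with and without stoichiometric constraints, arc/metabolite frequency
tables over K solutions, and the baseline graph strategies (unadjusted
topology, hub removal, connectivity weighting) that path-finding
methods use in place of stoichiometry.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

from .milp import (
    CFPQuery,
    CFPResultSet,
    FluxPath,
    SolverConfig,
    UnsolvedError,
    solve_shortest_cfp,
)
from .network import MetabolicNetwork, Medium, MetaboliteGraph

__all__ = [
    "ReferencePathway",
    "RecoveryResult",
    "ConnectivityCurve",
    "FrequencyTable",
    "recovery_rate",
    "stoichiometric_recovery_rate",
    "accuracy_rate",
    "best_accuracy",
    "connectivity_curve",
    "frequency_table",
    "apply_strategy",
    "connectivity_weights",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ReferencePathway:
    """A canonical route given as an ordered arc list."""

    id: str
    arcs: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        arcs = tuple(tuple(a) for a in self.arcs)
        object.__setattr__(self, "arcs", arcs)
        for (_, j1), (i2, _) in zip(arcs[:-1], arcs[1:]):
            if j1 != i2:
                raise ValueError(f"reference {self.id!r}: arcs are not consecutive")
        nodes = [arcs[0][0]] + [j for _, j in arcs] if arcs else []
        if len(set(nodes)) != len(nodes):
            raise ValueError(f"reference {self.id!r}: not a simple path")

    @property
    def arc_set(self) -> frozenset[tuple[str, str]]:
        return frozenset(self.arcs)


@dataclass
class RecoveryResult:
    pathway_id: str
    recovered: int
    rank: int | None
    accuracy: float


def recovery_rate(result: CFPResultSet, reference: ReferencePathway) -> RecoveryResult:
    """Binary exact-match recovery: 1 iff some returned path equals the
    reference arc-for-arc; rank is the first matching position (1-based)."""
    ref = list(reference.arcs)
    rank = None
    for k, path in enumerate(result.paths, start=1):
        if path.arcs == ref:
            rank = k
            break
    acc = best_accuracy(result, reference)
    return RecoveryResult(reference.id, int(rank is not None), rank, acc)


def stoichiometric_recovery_rate(
    result: CFPResultSet, reference: ReferencePathway, feasible: bool
) -> int:
    """Recovery under a growth medium, crediting correct exclusions.

    1 if a steady-state-feasible reference was matched by some returned
    path, or an infeasible reference was (correctly) absent from all of
    them; 0 otherwise.  ``feasible`` is whether the reference pathway
    itself is steady-state supportable in the medium (decide with
    :func:`cfpath.milp.path_supportable` on the reference arcs).
    """
    matched = recovery_rate(result, reference).recovered == 1
    return int(matched if feasible else not matched)


def accuracy_rate(path: FluxPath, reference: ReferencePathway) -> float:
    """Fraction of the reference's arcs present in the path."""
    if not reference.arcs:
        raise ValueError(f"reference {reference.id!r} is empty")
    return len(path.arc_set & reference.arc_set) / len(reference.arc_set)


def best_accuracy(result: CFPResultSet, reference: ReferencePathway) -> float:
    """Best per-path accuracy over a result set (0 if the set is empty)."""
    if not result.paths:
        return 0.0
    return max(accuracy_rate(p, reference) for p in result.paths)


@dataclass
class ConnectivityCurve:
    """Cumulative reachability: metabolites whose shortest CFP from the
    source has at most n steps, for each n."""

    source: str
    shortest_lengths: dict[str, int] = field(default_factory=dict)

    @property
    def counts(self) -> dict[int, int]:
        if not self.shortest_lengths:
            return {}
        horizon = max(self.shortest_lengths.values())
        lengths = sorted(self.shortest_lengths.values())
        return {n: sum(1 for ln in lengths if ln <= n) for n in range(1, horizon + 1)}

    @property
    def total_reachable(self) -> int:
        return len(self.shortest_lengths)

    def count_at(self, n: int) -> int:
        return sum(1 for ln in self.shortest_lengths.values() if ln <= n)


def connectivity_curve(
    source: str,
    graph: MetaboliteGraph,
    network: MetabolicNetwork,
    medium: Medium,
    use_stoichiometry: bool = True,
    config: SolverConfig = SolverConfig(),
) -> ConnectivityCurve:
    """Shortest-CFP length from ``source`` to every other graph node.

    Targets whose program is infeasible are unreachable and excluded;
    solver limit hits are logged and excluded from the curve but never
    silently counted as unreachable (they raise a warning).  Per-target
    queries are independent, so execution order cannot affect results.
    """
    curve = ConnectivityCurve(source)
    for target in sorted(graph.nodes):
        if target == source:
            continue
        query = CFPQuery(source, target, k=1, use_stoichiometry=use_stoichiometry)
        try:
            path = solve_shortest_cfp(graph, network, medium, query, config)
        except UnsolvedError as exc:
            logger.warning("connectivity %s->%s: %s", source, target, exc)
            warnings.warn(f"connectivity {source}->{target}: solver limit; excluded")
            continue
        if path is not None:
            curve.shortest_lengths[target] = path.length
    return curve


@dataclass
class FrequencyTable:
    arc_frequency: dict[tuple[str, str], int] = field(default_factory=dict)
    metabolite_frequency: dict[str, int] = field(default_factory=dict)


def frequency_table(result: CFPResultSet) -> FrequencyTable:
    """How often each arc and metabolite appears among the K paths."""
    table = FrequencyTable()
    for path in result.paths:
        for arc in path.arcs:
            table.arc_frequency[arc] = table.arc_frequency.get(arc, 0) + 1
        for met in path.node_sequence:
            table.metabolite_frequency[met] = table.metabolite_frequency.get(met, 0) + 1
    return table


def connectivity_weights(network: MetabolicNetwork) -> dict[str, float]:
    """Node weight = number of reactions involving the metabolite."""
    weights: dict[str, float] = {m.id: 0.0 for m in network.metabolites}
    for r in network.reactions:
        for met in r.stoichiometry:
            weights[met] += 1.0
    return weights


def apply_strategy(
    graph: MetaboliteGraph,
    network: MetabolicNetwork,
    strategy: str,
    hub_list: list[str] | None = None,
) -> tuple[MetaboliteGraph, dict[str, float]]:
    """Baseline graph adjustments used by stoichiometry-free methods.

    ``topology``: graph unchanged, unit weights.  ``hubs``: every arc
    touching a listed highly connected metabolite is removed, unit
    weights.  ``connectivity_weighted``: graph unchanged, node weights
    equal to the metabolite's reaction count; shortest becomes lightest.
    """
    unit = {m.id: 1.0 for m in network.metabolites}
    if strategy == "topology":
        return graph, unit
    if strategy == "hubs":
        if hub_list is None:
            raise ValueError("hubs strategy requires a hub list")
        kept = []
        for hub in hub_list:
            if network.has_metabolite(hub):
                kept.append(hub)
            else:
                warnings.warn(f"hub {hub!r} not in network; skipped")
        return graph.subgraph_without_node_arcs(set(kept)), unit
    if strategy == "connectivity_weighted":
        return graph, connectivity_weights(network)
    raise ValueError(f"unknown strategy {strategy!r}")
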