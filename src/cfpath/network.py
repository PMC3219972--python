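"""Metabolic network data model and the carbon-exchange metabolite graph.

A metabolic network is a set of metabolites partitioned into internal
(inside the system boundary, stoichiometrically balanced at steady state)
and external (boundary) metabolites, together with reactions whose signed
stoichiometric coefficients follow the usual convention: negative for
inputs, positive for outputs.

Reversible reactions are split into two irreversible copies so every flux
is non-negative; the split pairs are remembered so that a reaction and its
reverse can be barred from co-operating in one flux distribution.

The directed *metabolite graph* restricted to effective carbon exchange
has metabolites as nodes and an arc i->j for every reaction in which input
metabolite i passes carbon atoms to output metabolite j.  Which (i, j,
reaction) triples count as effective carbon exchange is curated knowledge,
supplied as a :class:`CarbonExchangeTable`; a formula-based heuristic
fallback is provided for networks without a curated table.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

__all__ = [
    "Metabolite",
    "Reaction",
    "MetabolicNetwork",
    "CarbonExchangeTable",
    "Medium",
    "MetaboliteGraph",
    "split_reversible",
    "build_metabolite_graph",
    "infer_carbon_arcs_from_formulas",
    "carbon_count",
    "FWD_SUFFIX",
    "REV_SUFFIX",
]

#: Comparison tolerance for stoichiometric sign tests (coefficients are
#: small rationals; anything below this magnitude is treated as zero).
COEFF_TOL = 1e-9

#: Deterministic id suffixes for the two directions of a split reversible
#: reaction, so the reverse-pair set is reconstructible from ids alone.
FWD_SUFFIX = "__fwd"
REV_SUFFIX = "__rev"


@dataclass(frozen=True)
class Metabolite:
    """A chemical species; ``is_internal`` selects the balanced set."""

    id: str
    name: str = ""
    is_internal: bool = True
    formula: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("metabolite id must be non-empty")


@dataclass(frozen=True)
class Reaction:
    """A (possibly reversible) reaction.

    ``stoichiometry`` maps metabolite id to a signed coefficient:
    negative for inputs, positive for outputs.  ``reversible`` marks an
    unsplit bidirectional reaction; after :func:`split_reversible` no
    reaction carries the flag and ``reverse_of`` links split pairs.
    """

    id: str
    stoichiometry: dict[str, float]
    reversible: bool = False
    reverse_of: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("reaction id must be non-empty")
        for met, coeff in self.stoichiometry.items():
            if abs(coeff) <= COEFF_TOL:
                raise ValueError(
                    f"reaction {self.id!r}: metabolite {met!r} has zero coefficient"
                )

    @property
    def inputs(self) -> list[str]:
        return [m for m, c in self.stoichiometry.items() if c < -COEFF_TOL]

    @property
    def outputs(self) -> list[str]:
        return [m for m, c in self.stoichiometry.items() if c > COEFF_TOL]

    def reversed(self, new_id: str, reverse_of: str) -> "Reaction":
        return Reaction(
            id=new_id,
            stoichiometry={m: -c for m, c in self.stoichiometry.items()},
            reversible=False,
            reverse_of=reverse_of,
        )


class MetabolicNetwork:
    """An ordered collection of metabolites and reactions.

    Parameters
    ----------
    metabolites, reactions:
        Iterables of :class:`Metabolite` and :class:`Reaction`.  Every
        metabolite referenced by a reaction must be declared.
    """

    def __init__(self, metabolites, reactions) -> None:
        self.metabolites: list[Metabolite] = list(metabolites)
        self.reactions: list[Reaction] = list(reactions)
        self._met_index = {m.id: m for m in self.metabolites}
        if len(self._met_index) != len(self.metabolites):
            raise ValueError("duplicate metabolite ids")
        self._rxn_index = {r.id: r for r in self.reactions}
        if len(self._rxn_index) != len(self.reactions):
            raise ValueError("duplicate reaction ids")
        for r in self.reactions:
            for m in r.stoichiometry:
                if m not in self._met_index:
                    raise ValueError(
                        f"reaction {r.id!r} references unknown metabolite {m!r}"
                    )
        # symmetry check on reverse_of links
        for r in self.reactions:
            if r.reverse_of is not None:
                partner = self._rxn_index.get(r.reverse_of)
                if partner is None or partner.reverse_of != r.id:
                    raise ValueError(
                        f"reaction {r.id!r}: reverse_of link is not symmetric"
                    )

    # -- lookups ---------------------------------------------------------
    def metabolite(self, met_id: str) -> Metabolite:
        return self._met_index[met_id]

    def reaction(self, rxn_id: str) -> Reaction:
        return self._rxn_index[rxn_id]

    def has_metabolite(self, met_id: str) -> bool:
        return met_id in self._met_index

    def has_reaction(self, rxn_id: str) -> bool:
        return rxn_id in self._rxn_index

    @property
    def internal_ids(self) -> list[str]:
        return [m.id for m in self.metabolites if m.is_internal]

    @property
    def external_ids(self) -> list[str]:
        return [m.id for m in self.metabolites if not m.is_internal]

    @property
    def reverse_pairs(self) -> set[frozenset[str]]:
        """Unordered id pairs of reactions that are reverses of each other."""
        pairs = set()
        for r in self.reactions:
            if r.reverse_of is not None:
                pairs.add(frozenset((r.id, r.reverse_of)))
        return pairs

    def coefficient(self, met_id: str, rxn_id: str) -> float:
        return self._rxn_index[rxn_id].stoichiometry.get(met_id, 0.0)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"MetabolicNetwork({len(self.metabolites)} metabolites, "
            f"{len(self.reactions)} reactions)"
        )


def split_reversible(network: MetabolicNetwork) -> MetabolicNetwork:
    """Split every reversible reaction into paired irreversible copies.

    A reversible reaction ``r`` becomes ``r__fwd`` (original
    stoichiometry) and ``r__rev`` (negated), linked through
    ``reverse_of``.  Irreversible reactions pass through unchanged and
    the metabolite set is untouched, so re-merging the pairs recovers the
    original reaction count.
    """
    out: list[Reaction] = []
    for r in network.reactions:
        if not r.reversible:
            out.append(r)
            continue
        if not r.stoichiometry:
            raise ValueError(f"reversible reaction {r.id!r} has empty stoichiometry")
        fwd_id, rev_id = r.id + FWD_SUFFIX, r.id + REV_SUFFIX
        fwd = replace(r, id=fwd_id, reversible=False, reverse_of=rev_id)
        out.append(fwd)
        out.append(r.reversed(rev_id, reverse_of=fwd_id))
    return MetabolicNetwork(network.metabolites, out)


@dataclass
class CarbonExchangeTable:
    """Set of (input metabolite, output metabolite, reaction) triples.

    Membership of ``(i, j, r)`` states that reaction ``r`` passes carbon
    atoms from its input ``i`` to its output ``j``; absence states it
    does not.  ``provenance`` records whether the table was curated or
    produced by the formula heuristic.
    """

    entries: set[tuple[str, str, str]] = field(default_factory=set)
    provenance: str = "curated"

    def resolve(self, network: MetabolicNetwork) -> "CarbonExchangeTable":
        """Validate against a (split) network, expanding reversible references.

        An entry naming an unsplit reversible reaction id applies to both
        split directions, with input/output swapped for the reverse copy.
        Entries whose metabolite is not an input/output of the named
        reaction are rejected.
        """
        resolved: set[tuple[str, str, str]] = set()
        for i, j, r in sorted(self.entries):
            if network.has_reaction(r):
                _check_entry(network, i, j, r)
                resolved.add((i, j, r))
            elif network.has_reaction(r + FWD_SUFFIX):
                fwd, rev = r + FWD_SUFFIX, r + REV_SUFFIX
                _check_entry(network, i, j, fwd)
                resolved.add((i, j, fwd))
                resolved.add((j, i, rev))
            else:
                raise ValueError(
                    f"carbon-exchange entry ({i!r}, {j!r}, {r!r}) "
                    f"references unknown reaction {r!r}"
                )
        return CarbonExchangeTable(resolved, provenance=self.provenance)

    def supporting_reactions(self, i: str, j: str) -> set[str]:
        return {r for (a, b, r) in self.entries if a == i and b == j}


def _check_entry(network: MetabolicNetwork, i: str, j: str, r: str) -> None:
    if not network.has_metabolite(i) or not network.has_metabolite(j):
        missing = i if not network.has_metabolite(i) else j
        raise ValueError(
            f"carbon-exchange entry ({i!r}, {j!r}, {r!r}) "
            f"references unknown metabolite {missing!r}"
        )
    rxn = network.reaction(r)
    if not rxn.stoichiometry.get(i, 0.0) < -COEFF_TOL:
        raise ValueError(
            f"carbon-exchange entry ({i!r}, {j!r}, {r!r}): "
            f"{i!r} is not an input of {r!r}"
        )
    if not rxn.stoichiometry.get(j, 0.0) > COEFF_TOL:
        raise ValueError(
            f"carbon-exchange entry ({i!r}, {j!r}, {r!r}): "
            f"{j!r} is not an output of {r!r}"
        )


@dataclass(frozen=True)
class Medium:
    """The growth medium: external metabolites allowed to be net-consumed.

    External metabolites outside the medium may be produced but never
    consumed at steady state.
    """

    consumable: frozenset[str] = frozenset()

    def __init__(self, consumable=()) -> None:
        object.__setattr__(self, "consumable", frozenset(consumable))

    def validate(self, network: MetabolicNetwork) -> None:
        for m in self.consumable:
            if not network.has_metabolite(m):
                raise ValueError(f"medium metabolite {m!r} not in network")
            if network.metabolite(m).is_internal:
                raise ValueError(f"medium metabolite {m!r} is internal")

    def without(self, *met_ids: str) -> "Medium":
        return Medium(self.consumable - set(met_ids))

    def with_(self, *met_ids: str) -> "Medium":
        return Medium(self.consumable | set(met_ids))


class MetaboliteGraph:
    """Directed metabolite graph restricted to effective carbon exchange.

    Arcs carry the non-empty set of reactions supporting them; self-arcs
    are dropped (a simple path never revisits a node).
    """

    def __init__(self, arcs: dict[tuple[str, str], set[str]], extra_nodes=()) -> None:
        self.arcs: dict[tuple[str, str], set[str]] = {
            a: set(rs) for a, rs in arcs.items() if rs and a[0] != a[1]
        }
        nodes = set(extra_nodes)
        for i, j in self.arcs:
            nodes.add(i)
            nodes.add(j)
        self.nodes: set[str] = nodes
        self._succ: dict[str, set[str]] = {}
        self._pred: dict[str, set[str]] = {}
        for i, j in self.arcs:
            self._succ.setdefault(i, set()).add(j)
            self._pred.setdefault(j, set()).add(i)

    def successors(self, node: str) -> set[str]:
        return self._succ.get(node, set())

    def predecessors(self, node: str) -> set[str]:
        return self._pred.get(node, set())

    def support(self, i: str, j: str) -> set[str]:
        return self.arcs.get((i, j), set())

    def subgraph_without_node_arcs(self, banned: set[str]) -> "MetaboliteGraph":
        """Remove every arc touching a banned node (hubs baseline)."""
        kept = {
            (i, j): rs
            for (i, j), rs in self.arcs.items()
            if i not in banned and j not in banned
        }
        return MetaboliteGraph(kept, extra_nodes=self.nodes)

    def to_networkx(self):
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from(sorted(self.nodes))
        for (i, j), rs in self.arcs.items():
            g.add_edge(i, j, reactions=sorted(rs))
        return g

    def __len__(self) -> int:
        return len(self.arcs)

    def __repr__(self) -> str:  # pragma: no cover
        return f"MetaboliteGraph({len(self.nodes)} nodes, {len(self.arcs)} arcs)"


def build_metabolite_graph(
    network: MetabolicNetwork, carbon: CarbonExchangeTable
) -> MetaboliteGraph:
    """Aggregate a validated carbon-exchange table into the arc map."""
    carbon = carbon.resolve(network)
    arcs: dict[tuple[str, str], set[str]] = {}
    for i, j, r in carbon.entries:
        if i == j:
            continue
        arcs.setdefault((i, j), set()).add(r)
    return MetaboliteGraph(arcs, extra_nodes=[m.id for m in network.metabolites])


# -- formula heuristic ---------------------------------------------------

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def carbon_count(formula: str) -> int:
    """Number of carbon atoms in an elemental formula such as ``C6H12O6``."""
    if not formula or not re.fullmatch(r"(?:[A-Z][a-z]?\d*)+", formula):
        raise ValueError(f"unparseable formula {formula!r}")
    total = 0
    for element, count in _FORMULA_TOKEN.findall(formula):
        if element == "C":
            total += int(count) if count else 1
    return total


def infer_carbon_arcs_from_formulas(network: MetabolicNetwork) -> CarbonExchangeTable:
    """Heuristic carbon-exchange table from elemental formulas.

    Emits (i, j, r) for every input-output pair of every reaction in
    which both metabolites contain at least one carbon atom.  This
    over-approximates true atom transfer (a carbon-bearing input and a
    carbon-bearing output need not share any atom), so the result is
    flagged ``heuristic`` and a curated table should be preferred.
    """
    counts: dict[str, int] = {}
    for m in network.metabolites:
        if m.formula is None:
            raise ValueError(f"metabolite {m.id!r} has no formula")
        try:
            counts[m.id] = carbon_count(m.formula)
        except ValueError as exc:
            raise ValueError(f"metabolite {m.id!r}: {exc}") from exc
    entries = set()
    for r in network.reactions:
        for i in r.inputs:
            if counts[i] == 0:
                continue
            for j in r.outputs:
                if counts[j] > 0:
                    entries.add((i, j, r.id))
    return CarbonExchangeTable(entries, provenance="heuristic")
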