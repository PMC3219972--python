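"""Packaged example networks and a seeded random-network generator.

Three hand-reconstructed networks ship with the package so every other
module is testable without downloads:

* a seven-reaction toy network whose single source-to-target route
  illustrates how off-path reactions balance a flux path;
* a simplified central-carbon network for the fatty-acid-to-sugar
  question, where net gluconeogenesis from acetyl-CoA is
  stoichiometrically possible if and only if the glyoxylate shunt
  (isocitrate lyase + malate synthase) is present;
* a small network around the reversible D-glucose O-acetyltransferase
  reaction, whose forward/backward pair produces a meaningless
  two-step cycle unless reverse pairs are barred from co-operating.

The random generator emits small connected networks with a guaranteed
supportable chain from a designated source to a designated target, plus
random extra reactions that may or may not be steady-state supportable —
exactly the regime where exhaustive ground truth is still computable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import (
    CarbonExchangeTable,
    MetabolicNetwork,
    Metabolite,
    Medium,
    MetaboliteGraph,
    Reaction,
    build_metabolite_graph,
    split_reversible,
)

__all__ = [
    "FixtureBundle",
    "figure2_network",
    "figueiredo_network",
    "glcat_network",
    "random_network",
    "data_path",
]


def data_path(filename: str):
    """Path to an on-disk copy of a packaged fixture file."""
    from importlib.resources import files

    return files("cfpath") / "data" / filename


@dataclass
class FixtureBundle:
    """A network with its carbon table, medium and default query endpoints."""

    network: MetabolicNetwork
    carbon: CarbonExchangeTable
    medium: Medium
    provenance: str = ""
    source: str | None = None
    target: str | None = None

    def split(self) -> MetabolicNetwork:
        return split_reversible(self.network)

    def prepare(self) -> tuple[MetabolicNetwork, MetaboliteGraph]:
        """Split reversibles and build the carbon-exchange graph."""
        net = self.split()
        return net, build_metabolite_graph(net, self.carbon)


def _mets(internal: list[str], external: list[str], formulas=None) -> list[Metabolite]:
    formulas = formulas or {}
    out = [Metabolite(m, is_internal=True, formula=formulas.get(m)) for m in internal]
    out += [Metabolite(m, is_internal=False, formula=formulas.get(m)) for m in external]
    return out


def _all_pair_table(network: MetabolicNetwork) -> CarbonExchangeTable:
    entries = set()
    for r in network.reactions:
        for i in r.inputs:
            for j in r.outputs:
                entries.add((i, j, r.id))
    return CarbonExchangeTable(entries, provenance="all input-output pairs")


def figure2_network() -> FixtureBundle:
    """Toy network: one source-to-target route needing off-path balancing.

    Nine metabolites (six internal: A..F; three external: A_ext, D_ext,
    F_ext) and seven reactions: an importer for A, the chain A->B->C, a
    condensation C + D -> E, E -> F, an importer for D and an exporter
    for F.  The unique route A->B->C->E->F can only carry steady-state
    flux when the importers and the exporter run off-path; removing the
    D importer's substrate from the medium destroys feasibility while
    the graph-level path survives.

    Coefficients are all unit; the carbon table lists every input-output
    pair.  Default medium: both importable externals.
    """
    mets = _mets(
        ["A", "B", "C", "D", "E", "F"],
        ["A_ext", "D_ext", "F_ext"],
        formulas={m: "C2H4O2" for m in "ABCDEF"}
        | {"A_ext": "C2H4O2", "D_ext": "C2H4O2", "F_ext": "C2H4O2"},
    )
    rxns = [
        Reaction("r1", {"A_ext": -1, "A": 1}),
        Reaction("r2", {"A": -1, "B": 1}),
        Reaction("r3", {"B": -1, "C": 1}),
        Reaction("r4", {"C": -1, "D": -1, "E": 1}),
        Reaction("r5", {"E": -1, "F": 1}),
        Reaction("r6", {"D_ext": -1, "D": 1}),
        Reaction("r7", {"F": -1, "F_ext": 1}),
    ]
    net = MetabolicNetwork(mets, rxns)
    return FixtureBundle(
        network=net,
        carbon=_all_pair_table(net),
        medium=Medium({"A_ext", "D_ext"}),
        provenance=(
            "Hand reconstruction of a published toy example; the drawing itself "
            "is not machine readable, so this is the minimal unit-coefficient "
            "network consistent with every textual property (unique route "
            "A->B->C->E->F; off-path balancing by r1, r6, r7; feasibility lost "
            "when D_ext leaves the medium)."
        ),
        source="A",
        target="F",
    )


def figueiredo_network(with_glyoxylate_shunt: bool = True) -> FixtureBundle:
    """Simplified fatty-acid-to-sugar network around the TCA cycle.

    Textbook stoichiometries; cofactors (NAD(H), NADP(H), CoA, ATP/ADP,
    CoQ/CoQH2) are internal and balanced, with an O2-dependent quinol
    oxidase so respiration-dependent steps need oxygen in the medium.
    Acetyl-CoA enters by lumped beta-oxidation of an external fatty
    acid; glucose 6-phosphate drains through a phosphatase and a glucose
    exporter.  Gluconeogenesis from phosphoenolpyruvate is lumped into
    one reaction (2 PEP -> G6P).

    Without isocitrate lyase + malate synthase every route from AcCoA
    loses both acetyl carbons as CO2 before reaching a C4 acid, so no
    steady-state route to G6P exists even though the graph still
    contains one; with the shunt, 4 AcCoA -> G6P closes.
    """
    internal = [
        "AcCoA", "CoA", "Cit", "ICit", "AKG", "SUCCoA", "SUCC", "Fum",
        "L-Mal", "OAA", "Glx", "Pyr", "PEP", "G6P", "D-Glc",
        "NAD", "NADH", "NADP", "NADPH", "ATP", "ADP", "CoQ", "CoQH2",
    ]
    external = ["FA_ext", "O2_ext", "CO2_ext", "Glc_ext"]
    rxns = [
        Reaction("FAO", {"FA_ext": -1, "CoA": -1, "NAD": -1, "AcCoA": 1, "NADH": 1}),
        Reaction("CS", {"AcCoA": -1, "OAA": -1, "Cit": 1, "CoA": 1}),
        Reaction("ACONT", {"Cit": -1, "ICit": 1}, reversible=True),
        Reaction(
            "ICDHyr",
            {"ICit": -1, "NADP": -1, "AKG": 1, "CO2_ext": 1, "NADPH": 1},
            reversible=True,
        ),
        Reaction(
            "AKGDH",
            {"AKG": -1, "NAD": -1, "CoA": -1, "SUCCoA": 1, "CO2_ext": 1, "NADH": 1},
        ),
        Reaction(
            "SUCOAS",
            {"SUCCoA": -1, "ADP": -1, "SUCC": 1, "CoA": 1, "ATP": 1},
            reversible=True,
        ),
        Reaction("SUCDi", {"SUCC": -1, "CoQ": -1, "Fum": 1, "CoQH2": 1}),
        Reaction("FUM", {"Fum": -1, "L-Mal": 1}, reversible=True),
        Reaction(
            "MDH", {"L-Mal": -1, "NAD": -1, "OAA": 1, "NADH": 1}, reversible=True
        ),
        Reaction(
            "PDH", {"Pyr": -1, "CoA": -1, "NAD": -1, "AcCoA": 1, "CO2_ext": 1, "NADH": 1}
        ),
        Reaction("PYK", {"PEP": -1, "ADP": -1, "Pyr": 1, "ATP": 1}),
        Reaction("PC", {"Pyr": -1, "CO2_ext": -1, "ATP": -1, "OAA": 1, "ADP": 1}),
        Reaction("PCK1", {"OAA": -1, "ATP": -1, "PEP": 1, "CO2_ext": 1, "ADP": 1}),
        Reaction(
            "ME1", {"L-Mal": -1, "NAD": -1, "Pyr": 1, "CO2_ext": 1, "NADH": 1}
        ),
        Reaction(
            "GNEO",
            {"PEP": -2, "ATP": -2, "NADH": -2, "G6P": 1, "ADP": 2, "NAD": 2},
        ),
        Reaction("G6PP", {"G6P": -1, "D-Glc": 1}),
        Reaction("GLCex", {"D-Glc": -1, "Glc_ext": 1}),
        Reaction("NADHOX", {"NADH": -1, "CoQ": -1, "NAD": 1, "CoQH2": 1}),
        Reaction("QOX", {"CoQH2": -1, "O2_ext": -0.5, "CoQ": 1}),
        Reaction("ATPS", {"ADP": -1, "ATP": 1}),
        Reaction("THD", {"NADPH": -1, "NAD": -1, "NADP": 1, "NADH": 1}),
    ]
    if with_glyoxylate_shunt:
        rxns.append(Reaction("ICL", {"ICit": -1, "SUCC": 1, "Glx": 1}))
        rxns.append(Reaction("MALS", {"Glx": -1, "AcCoA": -1, "L-Mal": 1, "CoA": 1}))
    net = MetabolicNetwork(_mets(internal, external), rxns)
    entries = {
        ("FA_ext", "AcCoA", "FAO"),
        ("AcCoA", "Cit", "CS"),
        ("OAA", "Cit", "CS"),
        ("Cit", "ICit", "ACONT"),
        ("ICit", "AKG", "ICDHyr"),
        ("AKG", "SUCCoA", "AKGDH"),
        ("SUCCoA", "SUCC", "SUCOAS"),
        ("SUCC", "Fum", "SUCDi"),
        ("Fum", "L-Mal", "FUM"),
        ("L-Mal", "OAA", "MDH"),
        ("Pyr", "AcCoA", "PDH"),
        ("PEP", "Pyr", "PYK"),
        ("Pyr", "OAA", "PC"),
        ("OAA", "PEP", "PCK1"),
        ("L-Mal", "Pyr", "ME1"),
        ("PEP", "G6P", "GNEO"),
        ("G6P", "D-Glc", "G6PP"),
        ("D-Glc", "Glc_ext", "GLCex"),
    }
    if with_glyoxylate_shunt:
        entries |= {
            ("ICit", "SUCC", "ICL"),
            ("ICit", "Glx", "ICL"),
            ("Glx", "L-Mal", "MALS"),
            ("AcCoA", "L-Mal", "MALS"),
        }
    return FixtureBundle(
        network=net,
        carbon=CarbonExchangeTable(entries, provenance="curated skeleton-carbon pairs"),
        medium=Medium({"FA_ext", "O2_ext", "CO2_ext"}),
        provenance=(
            "Standard-biochemistry reconstruction of a published simplified "
            "fatty-acid-to-sugar network; the figure itself is not machine "
            "readable, so reactions follow the enzyme list in its legend with "
            "textbook stoichiometries, including the two decarboxylating TCA "
            "steps, lumped beta-oxidation and gluconeogenesis, and internal "
            "balanced cofactors with O2-dependent quinol reoxidation."
        ),
        source="AcCoA",
        target="G6P",
    )


def glcat_network() -> FixtureBundle:
    """Reversible-acetyltransferase toy for the forward/backward pathology.

    The reversible reaction DGlc + AcCoA <-> AcGlcD + CoA carries carbon
    from glucose into the acetylated sugar and back; without the
    reverse-pair exclusion the shortest route from glucose to the
    product runs DGlc -> AcGlcD -> AcCoA through both directions of the
    same reaction, a biochemically meaningless two-step cycle.
    """
    mets = _mets(
        ["DGlc", "AcGlcD", "AcCoA", "CoA", "Prod"],
        ["Glc_ext", "Ac_ext", "P_ext"],
    )
    rxns = [
        Reaction("GLCIN", {"Glc_ext": -1, "DGlc": 1}),
        Reaction(
            "GLCATr",
            {"DGlc": -1, "AcCoA": -1, "AcGlcD": 1, "CoA": 1},
            reversible=True,
        ),
        Reaction("ACS", {"Ac_ext": -1, "CoA": -1, "AcCoA": 1}),
        Reaction("USE", {"AcCoA": -1, "Prod": 1, "CoA": 1}),
        Reaction("EXP", {"Prod": -1, "P_ext": 1}),
    ]
    net = MetabolicNetwork(mets, rxns)
    entries = {
        ("Glc_ext", "DGlc", "GLCIN"),
        ("DGlc", "AcGlcD", "GLCATr"),
        ("AcCoA", "AcGlcD", "GLCATr"),
        ("AcCoA", "CoA", "GLCATr"),
        ("Ac_ext", "AcCoA", "ACS"),
        ("CoA", "AcCoA", "ACS"),
        ("AcCoA", "Prod", "USE"),
        ("Prod", "P_ext", "EXP"),
    }
    return FixtureBundle(
        network=net,
        carbon=CarbonExchangeTable(entries, provenance="curated acetyl-transfer pairs"),
        medium=Medium({"Glc_ext", "Ac_ext"}),
        provenance=(
            "Minimal network around the reversible D-glucose "
            "O-acetyltransferase reaction, built to exhibit the "
            "forward-plus-backward path pathology."
        ),
        source="DGlc",
        target="Prod",
    )


def random_network(
    seed: int,
    n_internal: int = 8,
    n_reactions: int = 11,
    p_reversible: float = 0.2,
    max_retries: int = 20,
) -> FixtureBundle:
    """Seeded small random network with a guaranteed supportable route.

    Internal metabolites m1..mn carry a chain of unit conversions
    m1 -> m2 -> ... -> mn; the first quarter of metabolites (source
    tier) each get an importer from a private external, the last
    quarter (sink tier) an exporter, so the chain (importers and
    exporter off-path) is always a steady-state route from m1 to mn.
    The remaining ``n_reactions - (n_internal - 1)`` reactions draw
    random internal substrates and products and are reversible with
    probability ``p_reversible``; whether routes through them are
    supportable is instance-specific.  Carbon table: all input-output
    pairs.  Fully determined by ``seed``.
    """
    if n_internal > 15:
        raise ValueError("keep n_internal <= 15 so exhaustive ground truth is viable")
    n_extra = n_reactions - (n_internal - 1)
    if n_extra < 0:
        raise ValueError("n_reactions must be at least n_internal - 1")
    rng = np.random.default_rng(seed)
    internal = [f"m{i}" for i in range(1, n_internal + 1)]
    tier = max(1, n_internal // 4)
    src_tier, sink_tier = internal[:tier], internal[-tier:]
    external = [f"x_in_{m}" for m in src_tier] + [f"x_out_{m}" for m in sink_tier]

    for attempt in range(max_retries):
        rxns = [
            Reaction(f"chain{i}", {internal[i - 1]: -1, internal[i]: 1})
            for i in range(1, n_internal)
        ]
        rxns += [Reaction(f"imp_{m}", {f"x_in_{m}": -1, m: 1}) for m in src_tier]
        rxns += [Reaction(f"exp_{m}", {m: -1, f"x_out_{m}": 1}) for m in sink_tier]
        for e in range(n_extra):
            n_in = int(rng.integers(1, 3))
            n_out = int(rng.integers(1, 3))
            picks = rng.choice(n_internal, size=n_in + n_out, replace=False)
            stoich = {internal[p]: -1.0 for p in picks[:n_in]}
            stoich |= {internal[p]: 1.0 for p in picks[n_in:]}
            rev = bool(rng.random() < p_reversible)
            rxns.append(Reaction(f"extra{e}", stoich, reversible=rev))
        net = MetabolicNetwork(_mets(internal, external), rxns)
        carbon = _all_pair_table(net)
        split = split_reversible(net)
        graph = build_metabolite_graph(split, carbon)
        import networkx as nx

        if nx.is_weakly_connected(graph.to_networkx()):
            return FixtureBundle(
                network=net,
                carbon=carbon,
                medium=Medium(f"x_in_{m}" for m in src_tier),
                provenance=f"seeded random network (seed={seed}, attempt={attempt})",
                source=internal[0],
                target=internal[-1],
            )
    raise ValueError(
        f"could not generate a connected network in {max_retries} attempts"
    )
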