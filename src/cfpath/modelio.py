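"""Readers and writers for models, carbon-arc tables, media and results.

Formats
-------
* JSON model dialect mirroring the domain types one-to-one
  (``{"metabolites": [...], "reactions": [...]}``); read/write.
* SBML Level 2/3 (read only): species with ``boundaryCondition`` true,
  or living in a caller-supplied external compartment list, map to
  external metabolites; the ``reversible`` flag is taken from the
  reaction element.  Splitting is never applied at read time.
* Carbon-arc TSV: three tab-separated columns
  ``input_metabolite<TAB>output_metabolite<TAB>reaction``, one triple
  per line, ``#`` comments allowed.
* Medium file: one external metabolite id per line, ``#`` comments.
* Reference pathways: JSON list of ``{"id": ..., "arcs": [[i, j], ...]}``.
* Results: paths.tsv / fluxes.tsv / summary.json and an optional
  Graphviz DOT rendering with frequency-scaled attributes.

All tabular output is tab-separated with ``.`` decimals, independent of
locale.
"""

from __future__ import annotations

import json
from pathlib import Path

from .analysis import ReferencePathway, frequency_table
from .milp import CFPResultSet
from .network import (
    CarbonExchangeTable,
    MetabolicNetwork,
    Metabolite,
    Medium,
    Reaction,
)

__all__ = [
    "read_model",
    "read_model_json",
    "read_model_sbml",
    "write_model_json",
    "read_carbon_tsv",
    "write_carbon_tsv",
    "read_medium",
    "write_medium",
    "read_reference_pathways",
    "write_reference_pathways",
    "write_results",
    "result_set_to_dot",
]


# -- model JSON ----------------------------------------------------------

def network_to_dict(network: MetabolicNetwork) -> dict:
    return {
        "metabolites": [
            {
                "id": m.id,
                "name": m.name,
                "is_internal": m.is_internal,
                **({"formula": m.formula} if m.formula else {}),
            }
            for m in network.metabolites
        ],
        "reactions": [
            {
                "id": r.id,
                "stoichiometry": dict(r.stoichiometry),
                "reversible": r.reversible,
                **({"reverse_of": r.reverse_of} if r.reverse_of else {}),
            }
            for r in network.reactions
        ],
    }


def network_from_dict(payload: dict) -> MetabolicNetwork:
    try:
        mets = [
            Metabolite(
                id=m["id"],
                name=m.get("name", ""),
                is_internal=bool(m.get("is_internal", True)),
                formula=m.get("formula"),
            )
            for m in payload["metabolites"]
        ]
        rxns = [
            Reaction(
                id=r["id"],
                stoichiometry={k: float(v) for k, v in r["stoichiometry"].items()},
                reversible=bool(r.get("reversible", False)),
                reverse_of=r.get("reverse_of"),
            )
            for r in payload["reactions"]
        ]
    except KeyError as exc:
        raise ValueError(f"model JSON missing required field {exc}") from exc
    return MetabolicNetwork(mets, rxns)


def read_model_json(path) -> MetabolicNetwork:
    with open(path) as fh:
        return network_from_dict(json.load(fh))


def write_model_json(network: MetabolicNetwork, path) -> None:
    with open(path, "w") as fh:
        json.dump(network_to_dict(network), fh, indent=1, sort_keys=False)
        fh.write("\n")


def read_model_sbml(path, external_compartments: set[str] | None = None) -> MetabolicNetwork:
    """Read an SBML file; boundary species and species in any listed
    external compartment become external metabolites."""
    import libsbml

    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise ValueError(
            f"SBML parse error at line {err.getLine()}: {err.getMessage()}"
        )
    model = doc.getModel()
    if model is None:
        raise ValueError(f"{path}: no SBML model element")
    external_compartments = external_compartments or set()
    mets = []
    for s in model.getListOfSpecies():
        external = s.getBoundaryCondition() or s.getCompartment() in external_compartments
        mets.append(
            Metabolite(
                id=s.getId(), name=s.getName() or "", is_internal=not external
            )
        )
    rxns = []
    for r in model.getListOfReactions():
        stoich: dict[str, float] = {}
        for ref in r.getListOfReactants():
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) - ref.getStoichiometry()
        for ref in r.getListOfProducts():
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) + ref.getStoichiometry()
        stoich = {k: v for k, v in stoich.items() if v != 0.0}
        rxns.append(Reaction(id=r.getId(), stoichiometry=stoich, reversible=r.getReversible()))
    return MetabolicNetwork(mets, rxns)


def read_model(path, fmt: str | None = None, **kwargs) -> MetabolicNetwork:
    """Dispatch on declared format, or on file extension if omitted."""
    if fmt is None:
        fmt = "sbml" if str(path).endswith((".xml", ".sbml")) else "json"
    if fmt == "json":
        return read_model_json(path)
    if fmt == "sbml":
        return read_model_sbml(path, **kwargs)
    raise ValueError(f"unknown model format {fmt!r}")


# -- carbon TSV / medium -------------------------------------------------

def read_carbon_tsv(path, provenance: str = "curated") -> CarbonExchangeTable:
    entries = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(
                    f"{path}:{lineno}: expected 3 tab-separated columns, got {len(parts)}"
                )
            entries.add(tuple(parts))
    return CarbonExchangeTable(entries, provenance=provenance)


def write_carbon_tsv(table: CarbonExchangeTable, path) -> None:
    with open(path, "w") as fh:
        fh.write("# input_metabolite\toutput_metabolite\treaction\n")
        for i, j, r in sorted(table.entries):
            fh.write(f"{i}\t{j}\t{r}\n")


def read_medium(path) -> Medium:
    ids = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                ids.append(line)
    return Medium(ids)


def write_medium(medium: Medium, path) -> None:
    with open(path, "w") as fh:
        for m in sorted(medium.consumable):
            fh.write(m + "\n")


# -- reference pathways --------------------------------------------------

def read_reference_pathways(path) -> list[ReferencePathway]:
    with open(path) as fh:
        payload = json.load(fh)
    return [
        ReferencePathway(id=p["id"], arcs=tuple(tuple(a) for a in p["arcs"]))
        for p in payload
    ]


def write_reference_pathways(pathways: list[ReferencePathway], path) -> None:
    with open(path, "w") as fh:
        json.dump(
            [{"id": p.id, "arcs": [list(a) for a in p.arcs]} for p in pathways],
            fh,
            indent=1,
        )
        fh.write("\n")


# -- results -------------------------------------------------------------

def write_results(result: CFPResultSet, out_dir, dot: bool = False) -> list[Path]:
    """Emit paths.tsv, fluxes.tsv, summary.json (and optionally graph.dot)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    paths_tsv = out / "paths.tsv"
    with open(paths_tsv, "w") as fh:
        fh.write("k\tlength\tnode_sequence\tactive_reactions\n")
        for k, p in enumerate(result.paths, start=1):
            fh.write(
                f"{k}\t{p.length}\t{'->'.join(p.node_sequence)}\t"
                f"{','.join(sorted(p.active_reactions))}\n"
            )
    written.append(paths_tsv)

    fluxes_tsv = out / "fluxes.tsv"
    with open(fluxes_tsv, "w") as fh:
        fh.write("k\treaction\tflux\n")
        for k, p in enumerate(result.paths, start=1):
            for r in sorted(p.active_reactions):
                fh.write(f"{k}\t{r}\t{p.fluxes.get(r, 0.0):.6g}\n")
    written.append(fluxes_tsv)

    summary = out / "summary.json"
    with open(summary, "w") as fh:
        json.dump(
            {
                "query": result.to_dict()["query"],
                "n_paths": len(result.paths),
                "exhausted": result.exhausted,
                "lengths": [p.length for p in result.paths],
            },
            fh,
            indent=1,
        )
        fh.write("\n")
    written.append(summary)

    if dot:
        dot_file = out / "graph.dot"
        dot_file.write_text(result_set_to_dot(result))
        written.append(dot_file)
    return written


def result_set_to_dot(result: CFPResultSet) -> str:
    """Graphviz digraph with node sizes and arc widths scaled by their
    frequency of appearance among the returned paths."""
    table = frequency_table(result)
    k = max(1, len(result.paths))
    lines = ["digraph cfp {", "  rankdir=LR;"]
    for met, count in sorted(table.metabolite_frequency.items()):
        size = 0.3 + 0.7 * count / k
        lines.append(
            f'  "{met}" [width={size:.2f}, height={size:.2f}, '
            f'label="{met}\\n{count}"];'
        )
    for (i, j), count in sorted(table.arc_frequency.items()):
        width = 0.5 + 4.5 * count / k
        lines.append(f'  "{i}" -> "{j}" [penwidth={width:.2f}, label="{count}"];')
    lines.append("}")
    return "\n".join(lines) + "\n"
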