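# cfpath — carbon flux paths in metabolic networks

`cfpath` finds **K-shortest carbon flux paths (CFPs)** between two
metabolites in a stoichiometric metabolic network. A CFP is a simple
directed path in the metabolite graph, restricted to arcs with
effective carbon exchange, that can additionally operate inside a
steady-state flux distribution of the whole network. Classical
path-finding treats the network as a bare graph and routinely returns
routes that no steady state can carry; `cfpath` closes that gap by
coupling the path search to the flux space in one mixed-integer linear
program, solved with HiGHS through SciPy.

It is aimed at people analysing metabolic models (constraint-based
modellers, systems biologists) who want path-level answers — "how can
acetyl-CoA become glucose 6-phosphate, and under which medium?" — with
a stoichiometric guarantee attached.

## The model

For a network with reactions *r* = 1..R (reversibles split into
irreversible pairs, set *B*), metabolites *c* = 1..C partitioned into
internal *I* and external *E* with growth medium *E_m ⊆ E*, and binary
carbon-exchange coefficients *d_ijr*:

* binary *u_ij* = 1 iff arc *i→j* is on the path; arcs exist only where
  some reaction carries carbon from *i* to *j*;
* binary *z_r* = 1 iff reaction *r* is active; continuous flux
  *v_r ∈ [0, M]*;
* path structure: one arc leaves the source α and one enters the target
  β, none enter α or leave β, flow is conserved at every other node,
  and in-degree ≤ 1 everywhere (simple path);
* steady state: `Σ_r S_cr v_r = 0` for *c ∈ I*; `Σ_r S_cr v_r ≥ 0` for
  *c ∈ E \ E_m* (non-medium externals may only be produced);
* activity coupling: `z_r ≤ v_r ≤ M·z_r` (fluxes scaled so the minimum
  non-zero flux is 1); `z_λ + z_μ ≤ 1` for (λ,μ) ∈ *B*;
* linking: `u_ij ≤ Σ_{r: d_ijr = 1} z_r` — every path arc must be
  covered by an active supporting reaction, while reactions may be
  active off-path to balance the path;
* objective: minimise `Σ u_ij` (or node-weighted arcs for the
  connectivity baseline). The k-th solution is excluded by the integer
  cut `Σ_{(i,j) ∈ path_k} u_ij ≤ L_k − 1` before re-solving.

The package also implements the classical stoichiometry-free baselines
(unadjusted topology, hub removal, connectivity weighting), recovery
and accuracy scoring against reference pathways, connectivity curves,
and arc/metabolite frequency tables over K solutions.

## Worked example

The packaged nine-metabolite toy network has one route from A to F,
A→B→C→E→F, which needs three reactions *off* the path (the importers of
A and D and the exporter of F) to balance:

```python
from cfpath import CFPQuery, figure2_network, solve_shortest_cfp

bundle = figure2_network()
network, graph = bundle.prepare()
path = solve_shortest_cfp(graph, network, bundle.medium, CFPQuery("A", "F"))
print(path.node_sequence)            # ['A', 'B', 'C', 'E', 'F']
print(path.length)                   # 4
print(sorted(path.active_reactions)) # ['r1', 'r2', 'r3', 'r4', 'r5', 'r6', 'r7']
print(sorted(path.off_path_reactions(graph)))  # ['r1', 'r6', 'r7']

starved = bundle.medium.without("D_ext")
print(solve_shortest_cfp(graph, network, starved, CFPQuery("A", "F")))  # None
```

Removing `D_ext` from the medium leaves the graph path intact but no
steady state can carry it, so no CFP exists — the distinction the whole
method is about. The same from the shell:

```sh
cfpath find --model src/cfpath/data/figure2_model.json \
            --carbon src/cfpath/data/figure2_carbon.tsv \
            --medium src/cfpath/data/figure2_medium.txt \
            --source A --target F -k 5 --out-dir out/
# -> "1 CFP(s) found (exhausted); wrote out/paths.tsv, ..."
```

`cfpath fixtures` materialises all packaged networks; `cfpath
connectivity` and `cfpath validate` produce reachability curves and
recovery/accuracy tables. Models load from the JSON dialect or SBML;
carbon-exchange arcs come from a curated three-column TSV or, as a
flagged over-approximating fallback, from elemental formulas.

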