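# Methods

## The carbon-flux-path model

A metabolic network is a stoichiometric matrix *S* over metabolites
partitioned into internal (balanced at steady state) and external
(boundary) species, with every reversible reaction split into two
irreversible copies so all fluxes are non-negative; the split pairs are
collected in a set *B*. On top of the network sits a directed
*metabolite graph*: an arc *i→j* exists for each reaction in which
input *i* passes carbon atoms to output *j*. Which input–output pairs
count as effective carbon exchange is curated biochemical knowledge
supplied as a table of (input, output, reaction) triples; the graph arc
carries the set of reactions supporting it.

A carbon flux path from α to β is (a) a simple directed path in that
graph, and (b) operable within a steady-state flux distribution of the
whole network. Both conditions live in one MILP (binary arc variables
*u*, binary reaction-activity variables *z*, continuous fluxes *v*),
with the linking constraint `u_ij ≤ Σ_{supporting r} z_r`: choosing an
arc forces at least one supporting reaction active, and activity forces
flux at least 1 (`z_r ≤ v_r ≤ M z_r`). Reactions may be active without
lying on the path — that is what lets importers, exporters and
co-substrate producers balance the path. The objective minimises the
arc count; enumeration adds, per found path with arc set *A* and
length *L*, the integer cut `Σ_{(i,j)∈A} u_ij ≤ L − 1`.

Assumptions worth stating explicitly:

* The in-degree ≤ 1 and flow-conservation constraints admit, in
  principle, a path plus a node-disjoint cycle. Such a solution is
  strictly longer than its path part, and the cut form above also
  forbids strict supersets of already-found paths, so no returned
  solution contains a detached cycle; the verifier asserts this and a
  property test checks it on random instances.
* Carbon exchange is guaranteed between consecutive path steps, not
  end-to-end between α and β (that would require full atom mappings,
  which are out of scope).
* Solutions are identified by their arc set; two flux distributions
  supporting the same arcs are the same CFP.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `big_M` | 1000 | flux ceiling after scaling the minimum non-zero flux to 1; any steady state needing a flux ratio beyond M:1 is infeasible, so M is exposed in `SolverConfig`. A fixture test checks results are invariant under M×10. |
| `min_flux` | 1 (fixed) | the flux-scaling convention above |
| `int_tolerance` | 1e-6 | threshold for reading binaries off solver output |
| `flux_tolerance` | 1e-6 | verifier tolerance for balances and activity; sits above the HiGHS default primal feasibility tolerance (1e-7) |
| `time_limit_seconds` | none | per-solve limit; a limit hit raises a distinct "unsolved" error and is never reported as "no CFP" |
| `use_stoichiometry` | true | dropping it removes exactly the internal-balance and external-no-uptake constraints; activity coupling and arc covering remain, which reproduces the classical stoichiometry-free comparison mode |
| `forbid_reverse_pairs` | true | the `z_λ + z_μ ≤ 1` exclusion; switchable to demonstrate the forward/backward-cycle pathology |

The MILP engine is HiGHS via `scipy.optimize.milp`, behind a small
facade (variables, linear constraints, minimise, statuses
optimal/infeasible/limit) so another engine can be slotted in.
`SolverConfig.random_seed` is recorded for provenance; HiGHS is
deterministic for a fixed problem and SciPy exposes no seed, so
repeated runs are bit-identical anyway. Ties among equal-length CFPs
are solver-dependent and deliberately unspecified; all comparisons in
the tests group arc sets by length.

## Fixtures and the synthetic-data generator

Three hand-reconstructed networks ship with the package (as
constructors and as JSON/TSV under `src/cfpath/data/`, round-trip
tested):

* **Toy network** (9 metabolites, 7 reactions): the minimal
  unit-coefficient network consistent with its documented behaviour —
  a unique route A→B→C→E→F, off-path balancing by exactly the two
  importers and one exporter, and loss of feasibility when the
  co-substrate source D_ext leaves the medium. The original drawing is
  not machine readable; coefficients other than 1 cannot be excluded
  from the prose, and unit coefficients are documented in the bundle
  provenance.
* **Fatty-acid-to-sugar network** (27 metabolites, 21–23 reactions):
  TCA cycle, anaplerotic and gluconeogenic steps with textbook
  stoichiometries, lumped beta-oxidation and gluconeogenesis, internal
  balanced cofactors (NAD(H), NADP(H), CoA, ATP/ADP, CoQ/CoQH2) and an
  O2-dependent quinol oxidase. Without isocitrate lyase and malate
  synthase, every route from acetyl-CoA loses both acetyl carbons as
  CO2 before reaching a C4 acid, so no steady-state route to glucose
  6-phosphate exists even though graph search still finds one; with
  the shunt, 4 AcCoA → G6P closes. Removing O2 from the medium also
  removes the route (quinol cannot be reoxidised), which demonstrates
  the anoxic behaviour of succinate dehydrogenase on the same fixture.
* **Acetyltransferase toy** (8 metabolites, 5 reactions): a reversible
  glucose O-acetyltransferase whose forward+backward pair forms the
  classic meaningless two-step cycle unless reverse pairs are barred.

The random generator produces small connected networks
(default 8 internal metabolites, 11 internal reactions, 20% reversible,
all sizes seed-determined): a chain m1→…→mn with importer/exporter
exchanges on the first and last quarter of metabolites guarantees one
supportable route, while random extra reactions create paths whose
supportability is instance-specific. This is exactly the regime where
the brute-force oracle (DFS over all simple paths + one per-path
feasibility program each) is still exhaustive, so enumeration can be
compared against ground truth as a multiset of arc sets. Sizes were
chosen so the oracle stays exhaustive, not to emulate genome-scale
models: the generator reproduces none of the scale, compartments,
currency-metabolite hubs or curated carbon tables of real
reconstructions, so passing tests certify the correctness of the
formulation and solver pipeline, not recovery statistics on real
networks.

## Numerical choices and degenerate inputs

Stoichiometric sign tests use a 1e-9 tolerance (coefficients are small
rationals). Self-arcs are dropped at graph build; a simple path cannot
use them. Carbon-table entries naming an unsplit reversible reaction
apply to both split directions with input/output swapped, so one
curated table serves pre-split models; entries violating the
stoichiometric signs, or naming unknown species, are rejected at load
time with the offending triple. The formula-based carbon-arc heuristic
(both partners contain carbon) over-approximates true atom transfer
and is flagged `heuristic` in provenance; the hexokinase test shows the
spurious cofactor pairs it admits. Endpoints may be external
metabolites; no constraint beyond the source/target degree equations
applies to them. Infeasible and limit-hit solves are distinct statuses
everywhere, including per-target queries inside connectivity curves
(limit hits are warned about and excluded, never counted unreachable).

## Problem sizes in the shipped analyses

The test-suite and acceptance runs use the fixtures above and twenty
seeded random networks of 12 graph nodes with full enumeration
(K up to 60) cross-checked against the oracle, plus connectivity curves
over all sources/targets of the fixtures; the complete suite solves a
few thousand MILPs. Genome-scale analyses are supported by the same
code paths (SBML input, curated carbon TSV, medium files) but no
genome-scale model or curated arc database is bundled, so published
genome-scale recovery percentages and reachability counts are not
reproduced here.

## Known limitations

* No atom tracing from source to target; carbon exchange is stepwise.
* The curated-table format is a normalisation of published arc lists;
  cofactor-pair policy is the curator's, and the loader takes the table
  verbatim.
* `big_M` bounds attainable flux ratios; pathological networks needing
  ratios above M:1 require raising it.
* The oracle is exponential and refuses graphs beyond its node budget;
  it is a testing device, not an analysis tool.
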