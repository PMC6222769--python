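# Methods

## Model and assumptions

`cesnet` detects overlapping communities in undirected, unweighted simple
graphs. All quantities are purely topological — neighborhoods, degrees,
Jaccard overlaps — so inputs are normalized first: self-loops dropped,
parallel edges collapsed, any weight column ignored. Node labels are
opaque strings (protein identifiers, actor names); no integer-id
assumption is made anywhere. Disconnected graphs are accepted; an
optional component-size filter (`--min-component-size`) mimics the common
practice of discarding tiny fragments of interaction networks before
module detection, but no particular preprocessing of public PPI datasets
is claimed.

The pipeline has four stages.

**1. Influence.** `IB(v1,v2) = D(v1)D(v2)/(1−SIM(v1,v2))²` and
`ALL(v) = Σ_u IB(v,u)`. When two nodes have identical neighborhoods
(`SIM = 1`) the Jaccard distance is floored at `eps_distance = 1e−6`
rather than raising: duplicate-neighborhood pairs are common in real PPI
graphs, and the cap keeps them maximally influential without dividing by
zero. The cap is configurable; results are insensitive to its exact value
because capped pairs only need to dominate, not to carry meaningful
magnitude.

**2. Central node selection with interference (CMI).** One greedy pass in
descending initial-`ALL` order, lexicographic tie-break. A candidate must
(a) not be adjacent to an already-selected center and (b) be a local
maximum of the *current* `ALL` table. On selection, every neighbor's
`ALL` is recomputed from the graph and scaled by `GF`. Because the
recomputation always starts from `Σ IB` (which the graph fixes), repeated
adjacency to several centers does not compound the factor. A subtle and
load-bearing consequence: the revised value is exactly `GF ×` the
original, so with `GF > 1` the neighbors of a center rise and suppress
nearby second centers, while with `GF < 1` they fall and *enable* them.
A node that is not an initial local maximum can only ever become
selectable through damping — its dominating neighbor must shrink, since
being selected instead would block the node outright. The demonstration
fixture (below) therefore runs at `GF = 0.5`; the damping regime is also
where the PPI-scale calibrations (0.9/0.8/0.5) live. Isolated nodes are
never central. Selected nodes are zeroed and can never re-enter; blocked
nodes are skipped, not deleted.

**3. Edge clustering.** Central edges are the edges incident to centers
(categories are disjoint because centers are non-adjacent). Non-central
edges are attached by the aggregate similarity
`DNC(e_k, CE_i) = S − Σ_j ELC(e_k,e_j)²/S`, which grows with the total
similarity `S` and discounts concentration. Assignment takes the
**argmax** over categories (ties to the lower index). The argmin variant
remains available (`dnc_rule="min"`), but it systematically routes edges
toward their *least* similar category — on the karate club it scrambles
the cover (EQ 0.13 instead of 0.37) — so maximization is the default.
Categories with `S = 0` are ineligible; an edge similar to no category
inherits, in a fixed-point sweep, the category of its most similar
assigned neighbor edge, and if it has none it stays unassigned (its
endpoints may end uncovered, which the coverage rate then reports).
The hot loop computes ELC on big-integer adjacency bitsets (popcounts);
the public `elc`/`dnc` functions use plain set arithmetic, and the test
suite cross-checks the two paths to 1e−12.

**4. Pruning (ONP).** Node order: descending overlap degree, then
lexicographic. Strategy 1 removes memberships supported only by central
edges of that category; strategy 2 removes memberships whose connection
share `con(v,C_j)/Σ_k con(v,C_k)` is below `prop`. Strategy 1 runs first;
strategy-2 shares are computed once on the post-strategy-1 cover and the
removals applied in one batch (no cascade — a cascading variant would be
order-sensitive in a way nothing in the formulation pins down). A node
never loses its last membership, and a removal that would empty a
community is skipped, so community counts stay meaningful. `prop = 1`
collapses every overlapping node to its single strongest community
(ties to the lower id).

`con` can be counted two ways, and the choice is consequential:

* `con_mode="nodes"` (default) counts all edges from `v` into the
  community's current node set;
* `con_mode="edges"` counts `v`'s incident edges carrying the category
  label.

On the karate club the node-set reading keeps actor 3's dual membership
(shares 5/11 and 6/11 against `prop = 0.436`) and reproduces the
benchmark row exactly; the edge-label reading splits 4/10 vs 6/10 and
prunes the overlap away. On the planted-overlap generator the roles
reverse: boundary-adjacent spurious memberships survive the node-set
count (mean overlapping NMI ≈ 0.64 across 20 seeds) but are cleanly
removed under the edge-label count (≈ 0.91). No single reading wins both
regimes; the default favors the deterministic benchmark reproduction and
the alternative is one keyword away. The corresponding planted-recovery
bound in the acceptance tests is left failing under the default rather
than moving either the generator's conditions or the threshold.

## Parameters

| parameter | meaning | default | notes |
|---|---|---|---|
| `gf` | interference factor scaling revised neighbor influence | `4.2·n/m` | dimensionless; <1 damps (more centers), >1 boosts (fewer); PPI-scale practice uses 0.5–0.9 |
| `prop` | minimum connection share to keep a membership | `n/m` (≤1) | in [0,1]; 0 disables strategy 2, 1 forces disjoint covers |
| `epsilon` | CNS attract threshold | 0.4 | strict `>`; share of a node's influence pointing into a community |
| `eps_distance` | floor on the Jaccard distance in IB | 1e−6 | only active for identical-neighborhood pairs |
| `dnc_rule` | direction of the DNC category choice | `"max"` | `"min"` implements the literal minimization reading |
| `con_mode` | connection counting in pruning | `"nodes"` | `"edges"` = label-based counting, see above |

## The CNS baseline

CNS selects every local maximum of `ALL` (adjacent exact ties go to the
lexicographically smaller label), seeds one community per center, and
synchronously absorbs frontier nodes with `attract > ε`; absorption by
several communities is the only source of overlap, and unreached nodes
stay uncovered. Synchronous (round-snapshot) evaluation was chosen
because it is order-independent; sequential and asynchronous variants
were tried and give identical covers on the benchmark graphs. On the
karate club this baseline recovers the exact faction split
(EQ 0.3715, NMI 1.0) — *better* than the historically reported baseline
figures (EQ 0.35, NMI 0.69), a discrepancy we cannot reconcile because
the original implementation's details are unpublished; the acceptance
test records it as a failing assert with this explanation rather than
emulating an unknown defect.

## Reference data

The karate-club reference division is Zachary's (1977) two-faction split
as used throughout the community-detection literature, with actor 9 on
the officers' side. (The `club` attribute shipped with networkx records
the club each actor *joined* after the fission, which differs for actor 9
alone — he sided with the officers but joined Mr. Hi's club to keep a
belt test.) Against the faction split the CES cover scores NMI 0.9183;
against the club-joined split the same cover would score 0.785.

## Synthetic generator

`planted_graph` plants a chain of `k` dense blocks of `size` nodes in
which consecutive blocks share `n_overlap` boundary nodes; each node pair
draws one Bernoulli edge at `p_in` (pair shares a block) or `p_out`
(otherwise), and the whole draw is resampled (bounded retries) while any
block is internally disconnected. Defaults — 3 blocks of 20, overlap 2,
`p_in = 0.9`, `p_out = 0.02` — give ~56 nodes and ~530 edges. The model
exercises exactly the structure the pipeline targets (dense modules,
sparse background, genuinely shared nodes) and nothing else: no
heavy-tailed degrees, no degree correction, no weights, no nested or
hierarchical overlap. Passing recovery tests on it shows the machinery
identifies planted overlap under clean conditions; it does not certify
performance on scale-free interaction networks.

The 8-node / 12-edge `demo_fixture` is a synthetic reconstruction of the
classic two-block motivating example (the original drawing's adjacency is
not published as an edge list). It was selected by exhaustive search over
two-block 12-edge topologies such that, deterministically: plain
local-maximum selection finds one center (node 3), interference-damped
selection at `GF = 0.5` finds two (3 and 6), and the full pipeline
returns the two blocks with exactly the shared nodes 4 and 5 overlapping.

## Evaluation metrics

EQ follows the extended-modularity convention: ordered node pairs within
each community, `v = w` included with `A_vv = 0`, each pair down-weighted
by `1/(O_v O_w)`; with all `O_v = 1` it equals Newman modularity, which
the tests verify against networkx's implementation to 1e−12. The
overlapping NMI is the LFK binary-membership construction: per-community
conditional entropies minimized over the other cover with the standard
admissibility guard (complement-like pairs fall back to `H(X_k)`),
normalized by `H(X_k)`, averaged, and symmetrized as
`1 − ½[H(X|Y)_norm + H(Y|X)_norm]`; `0·log 0 = 0`, and a zero-entropy
community (empty or all-nodes) contributes 0 to the normalized sum. One
consequence worth knowing: an all-nodes community versus all singletons
scores exactly 0.5, not 0 — the degenerate side carries no entropy to
normalize. CR is simply the covered-node percentage; nodes outside every
community (isolated nodes, unassigned-edge endpoints, CNS-unreached
nodes) drive it below 100.

## Problem sizes and numerical checks

The test battery uses graphs of 3–40 nodes for exhaustive oracle
comparisons (ELC/DNC set-arithmetic transliterations, the greedy-selection
pseudocode oracle, brute-force EQ double sums), 200 random graphs for the
central-node non-adjacency invariant, 20 generator seeds for recovery
statistics, and a single ~2,000-node / ~14,000-edge planted graph as a
runtime smoke check (the full pipeline completes in well under ten
minutes on one core, consistent with the near-quadratic cost of the
influence table plus the `|non-central| × |central|` similarity sweep).
Floating-point comparisons in tests use 1e−12 absolute tolerance where an
exact algebraic identity is asserted.

## Known limitations

* Directed and weighted graphs are out of scope by design.
* The dolphin and college-football benchmark rows require the public edge
  lists and reference covers, which are not redistributed; loaders accept
  them from local files.
* The min/max DNC and node/edge `con` ambiguities are resolved by
  benchmark evidence, not by a formal specification; both alternatives
  remain accessible through parameters.
* Covers produced on graphs whose communities lack internal density
  contrast (near-regular graphs) are sensitive to the lexicographic
  tie-breaks; determinism is guaranteed, meaningfulness is not.
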