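# Methods

## Scope and containers

`epiclust` computes duplication-loss reconciliation of binary gene trees
against a rooted binary species tree and clusters gene duplications into
multiple-gene-duplication episodes, for rooted and for unrooted gene tree
collections. Newick input is parsed with dendropy; internally trees live in
dense integer-indexed containers (`SpeciesTree`, `RootedGeneTree`,
`UnrootedGeneTree`) whose node ids follow Newick reading order — that order
also fixes every deterministic tie-break (canonical edge order, species
postorder for episode ties). The species tree carries an Euler-tour +
sparse-table lca index built once and shared by all queries, since one
species tree is typically reconciled against thousands of gene trees.

Rooted gene trees given as input to the unrooted machinery are silently
unrooted by suppressing the degree-2 root: inference tools emit arbitrarily
rooted binary trees, and the analysis treats the root position as unknown.
Polytomies other than a single top-level trifurcation are rejected rather
than resolved, because the plateau theory assumes internal nodes of degree
three. Branch lengths and internal labels are parsed and discarded — every
cost here is topology-only. Gene leaf labels map to species through a
configurable rule (`identity`, or `prefix:<sep>` which truncates at the
first separator); the mapping is validated when a gene tree is paired with
a species tree, not at parse time.

## Rooted reconciliation

The lca-mapping is computed in one postorder pass with O(1) lca queries.
Losses use L = 2D + Σ_internal(‖M(a),M(b)‖ − 2) with path lengths from
depths: ‖a,b‖ = depth(a) + depth(b) − 2·depth(lca(a,b)). Gene trees whose
species form a strict subset of the species tree are allowed; costs are
well-defined in full *S*.

## Unrooted machinery

For each of the 2·|E| directed edges the lca-image of the subtree on its
far side is computed by an inward and an outward dynamic-programming pass
(O(|G|) lca operations). The top node ⊤ used for edge classification is the
lca of the gene tree's species set — equal to root(S) for species-spanning
trees and the only convention that keeps edge classes well-defined for
non-spanning ones. Edges are empty / single / double according to whether
neither / one / both side-images reach ⊤; stars S1–S5 summarize the classes
around each internal node, and any other combination raises an internal
invariant error rather than being silently accepted.

The duplication-cost profile over all rootings is computed incrementally:
the base edge is costed in full, and moving the root across an adjacent
edge changes only the duplication status of the shared node and of the
root, giving O(1) updates from the directed images. The quadratic
recompute-per-edge profile is retained (`naive_cost_profile`) purely as an
independent oracle for tests; the two must agree bit-for-bit. The DL
profile re-roots per edge — the collections this package targets make that
cost irrelevant, and it keeps the reference semantics obvious. Plateau
extraction verifies connectivity of the minimal-edge set as a structural
invariant. `find_opt_edge` locates an empty or double edge by greedy
descent: an S1 star always points across its incoming edge toward the
region mapping to ⊤, and following those arrows terminates without
computing any profile.

## Episode clustering (rooted)

The four validity conditions confine each duplication *d* to a species path
from M(*d*) up to the node just below the image of its nearest speciation
ancestor (root(S) when there is none). The nearest ancestor gives the
tightest cap; capping at all speciation ancestors is equivalent by
monotonicity of M, and the tests assert this. For a non-spanning gene tree
the cap for top-most duplications is root(S), not the tree's own ⊤ — the
validity conditions reference *S* only — so such duplications may be raised
above the lca of the tree's species; this choice propagates into the
unrooted solver (below).

EC is solved by greedy stabbing of the pooled intervals: repeatedly place
an episode at the top of the interval whose top is deepest (ties by species
postorder), discard stabbed intervals. The classic exchange argument
applies because intervals are root-directed paths: a deepest top can
replace any stab point of its interval without uncovering others. Each
duplication then takes the deepest selected location inside its interval —
an assignment that automatically satisfies the time-consistency condition —
and the result is re-checked against all four conditions by an independent
checker; a failure raises an invariant error. `ec_brute` enumerates every
placement inside every interval (refusing inputs beyond a configurable
duplication count) and is the oracle the greedy solver is certified
against. A strictly linear-time EC algorithm exists in the literature; this
package deliberately ships the near-linear greedy with an empirical
certificate instead of re-deriving it.

## Episode clustering (unrooted)

Rootings are restricted to the D-plateau; anything else is inadmissible
because it inflates the duplication count. Per tree the solver builds a
candidate pool: the canonical plateau edge found by greedy descent when a
double edge exists (all plateau rootings of such trees are
interchangeable), or the empty edge plus the plateau edges of the at most
two S2 stars flanking it — never more than five edges.

The pool is then pruned by **interval dominance**, the package's own
refinement. A tree's contribution to any joint clustering is fully
determined by the multiset of its duplication intervals: the minimal
episode count is a pure path-stabbing optimum, because the deepest-location
assignment realizes any stabbing set as a valid mapping. Hence if every
interval of rooting *A* contains some interval of rooting *B*, any location
set serving *B* serves *A*, and *A* can be kept in *B*'s stead regardless
of the other trees. Dominance is evaluated separately under the two
exhaustive scenarios — the final clustering does or does not place an
episode at root(S). Under the with-root scenario, intervals containing
root(S) are covered for free, which collapses most trees to a single
candidate; under the without-root scenario, rootings owning an interval
pinned exactly at root(S) are infeasible (for species-spanning trees this
leaves only the empty-edge rooting, or nothing for double-edge trees). A
simpler rule — keep one qualifying edge per S2 star, chosen by a local
lca-image equality — fails on two kinds of inputs: stars whose both edges
satisfy the local test yet differ in joint cost, and non-spanning trees
whose duplications can be raised above the tree's own top node; the
dominance comparator handles both, and the exact solver is certified
against full Cartesian-product brute force over all plateau rootings on 150
simulated collections (and 400 more during development).

`uec_exact` enumerates the with-root product of surviving candidates
(ambiguous trees, those with two or more with-root candidates, contribute
the exponential factor ≈ 2^k) plus the without-root product (a single
all-empty-rootings instance for spanning inputs), taking the overall
minimum with witnessing rooting edges. A configurable cap (default 2^20
combinations) guards the enumeration. `uec_heuristic` solves the
unique-candidate subcollection exactly, extends tree by tree preferring
candidates whose intervals are already stabbed, and certifies optimality
when the full collection achieves the subcollection's cost (a valid
certificate because adding trees can never lower the optimum); otherwise it
returns its best answer flagged non-optimal, and the command-line
`--exact-fallback` flag re-runs the exact solver in that case.
`single_uec` evaluates every plateau rooting of one tree exhaustively and
returns all optimal edges; when the tree has an empty edge, that rooting is
always among them.

## Simulator

The generator emulates gene family evolution along the species tree under
a per-branch Bernoulli duplication-loss process: on each species branch
every surviving lineage dies with probability `loss_prob` (default 0.2) or
duplicates with probability `dup_prob` (default 0.3), both daughters
continuing down the same branch without further same-branch events; a stem
branch above the root allows root duplications. Lost lineages are pruned,
unary nodes suppressed, and trees are regenerated until at least
`min_leaves` (default 3) survive, up to 1000 attempts. Default rates are
moderate — enough duplication signal for plateaus and candidate sets to be
non-trivial at 5–10 species without blowing up tree size. All randomness
flows from a single `random.Random(seed)` per call, so identical seeds give
identical trees.

What the simulator does **not** emulate: horizontal transfer, sequence
evolution and reconstruction error (gene tree topologies are true
histories), correlated duplications across families (each family is
independent, so simulated "episodes" arise only by chance overlap), and
rate heterogeneity across branches. Passing tests therefore certify the
combinatorial machinery on correctly specified duplication-loss histories,
not robustness to gene tree estimation error in real data.

Curated fixtures complement the random generator: the 3-leaf star (empty
edge), a double-edge tree, a tree with one S2 star in its plateau, and a
hand-built tree with two S2 stars in the plateau (the ambiguous case with
two refined candidates), each with hand-derived expected edge classes,
plateaus, candidate sets and single-tree episode counts asserted in tests.

## Problem sizes and numerical choices

Test and acceptance runs use species trees of 4–10 leaves, gene trees
capped at a few dozen leaves, collections of 1–5 trees, and exhaustive
oracles bounded at ~10 duplications (EC) and ~3000–4000 rooting
combinations (UEC) — sizes chosen so the oracles stay exhaustive while the
whole suite certifies several hundred instances. All costs and counts are
exact integers; there is no floating-point tolerance anywhere except the
percentage helper (episodes per species-tree node, reported as a float).
Ties are never broken randomly: candidate enumeration follows input order
and canonical edge order, and the first minimum encountered is kept.

## Known limitations

* The minimum-episodes (ME) variant, scenario/DLS-tree reconstruction, and
  transfer-aware models are out of scope.
* The heuristic's non-optimal answers carry no approximation guarantee.
* For non-spanning gene trees the 2^k enumeration bound can be exceeded by
  a small constant factor (the without-root branch may hold a few variants
  per tree); the exact solver remains exact.
* `ec_percent_locations` follows the convention of counting all 2n−1
  species-tree nodes as potential locations, including leaves.
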