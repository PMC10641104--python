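# Methods

## Model

Given `n ≥ 3` taxa and a symmetric non-negative dissimilarity matrix `d`,
the balanced minimum evolution criterion scores an unrooted binary
leaf-labeled tree `T` by

    L(T) = Σ_{i<j} d_ij · 2^(1 − τ_ij),

with `τ_ij` the topological (edge-count) distance between leaves `i` and
`j`.  Equivalently `L(T) = Σ_i Σ_{j≠i} d_ij 2^(−τ_ij)` over ordered pairs;
both evaluation routes are implemented and cross-checked.  The weights
`2^(1−τ_ij)` sum to 1 over the partners of each taxon for every topology —
a property asserted to `1e−12` in the tests — so a constant matrix `d ≡ c`
gives `L = cn/2` regardless of topology.  The criterion is consistent: on an
additive matrix (path sums of a positively-weighted tree) the optimum is
exactly the generating topology, which the tests verify by exhaustive
enumeration up to `n = 7` and via the search at `n = 10` and `20`.

Trees are stored as adjacency maps with leaves `1..n` and internal nodes
`n+1..2n−2`, all of degree 3; a validator enforces degrees, connectivity,
and the `2n−3` edge count at every construction.  Topologies are compared
by split sets: the Robinson–Foulds distance is the cardinality of the
symmetric difference of the two trees' nontrivial bipartitions (not halved,
not normalized — hence always even for two binary trees).

## Step-wise encoding

A topology is encoded as the integer vector `(h_1, …, h_{n−3})`: starting
from the star on taxa 1, 2, 3 (center `n+1`), step `i` inserts taxon `i+3`
on the `h_i`-th edge of the current tree's *ordered edge list* (edges sorted
ascending by lower endpoint label, ties by higher endpoint label), the new
internal node being `n+1+i`.  The partial tree before step `i` has `2i+1`
edges, so `1 ≤ h_i ≤ 2i+1` and the code space has size
`Π(2i+1) = (2n−5)!!`, matching the number of topologies; the map is a
bijection (verified exhaustively through `n = 7` and on random trees up to
`n = 64`).

Encoding inverts the construction: leaves `n` down to 4 are stripped, each
suppression recording the edge it restores; the construction is then
replayed forward under canonical labels, reading off each recorded edge's
index.  Both directions are `O(n²)` here — adequate at the problem sizes
this implementation targets — rather than the asymptotically optimal
`O(n log n)`.

The tie-break for edges sharing their lower endpoint is *ascending* by the
higher endpoint (plain lexicographic order).  The order must be bit-stable,
because codes are exchanged between individuals during recombination.

## Local search

BNNI and BSPR are steepest-descent searches: all neighbors are scored, the
single best strictly improving move is applied (ties resolved by the
canonical enumeration order; equal-length moves are never accepted, which
prevents cycling), and the descent ends at a local optimum.  `rearrange_tree`
— BNNI followed by BSPR — is applied to every tree the engine touches.

Neighbor scores use delta formulas derived from how a move shifts `τ`:

- *NNI*, swapping subtrees P (at endpoint u, sibling Q) and R (at endpoint
  v, sibling S): `τ` gains 1 on P×Q and R×S and loses 1 on P×S and Q×R, so
  `ΔL = −(S(P,Q)+S(R,S))/2 + S(P,S) + S(Q,R)` with
  `S(X,Y) = Σ_{i∈X,j∈Y} d_ij 2^(1−τ_ij)`.
- *SPR*, pruning the subtree S behind directed edge `(p, r)` and regrafting
  on edge `(x, y)`: suppressing `p` lowers `τ` by 1 across the two resident
  sides; the insertion raises it by 1 across the regraft edge; and each
  pair (s ∈ S, t outside) moves to `τ' = δ(p,s) + 1 + q_t` with
  `q_t = min(δ(x,t), δ(y,t))` corrected by 1 when the path crosses the
  suppressed node.  All regraft candidates of one prune edge are evaluated
  as a numpy batch, giving an `O(n²)`-sized neighborhood scanned in a few
  vector operations per prune edge.

The deltas agree with direct recomputation of `L` to well below `1e−10`
(tested exhaustively on random instances), and every *accepted* move is
additionally re-verified by a from-scratch evaluation inside the descent
loop, so the fast path can only influence candidate ranking, never
correctness.  In the rare event that a predicted improvement fails the
recomputation check the descent stops, so returned trees are local optima
up to float resolution (the brute-force verification in the tests allows a
`1e−10` slack for this reason).

## Evolution strategy

One individual is a (code, tree, length) triple with `tree = decode(code)`
and fitness the balanced length.  The loop:

1. **Initialization** — λ uniform random codes, each decoded and refined by
   BNNI + BSPR.
2. **Recombination** — one child per current member; component `j` of a
   child is drawn uniformly from the multiset of `j`-th components of all
   parents (independently per component).  Validity is automatic since each
   parent component is in range.  Children are refined by BNNI + BSPR and
   re-encoded.
3. **Selection** — truncation: the μ smallest lengths among parents ∪
   offspring survive, with a stable tie-break (parents before offspring).
   Elitism is implied: the incumbent best is never lost.
4. **Replacement** — if the worst length occurs more than once and a
   strictly better individual exists, one duplicate of the worst is
   replaced by a copy of the best individual strictly below it.  This
   breaks stagnation by gradually shifting a stalled population toward
   convergence.
5. **Stop** — convergence (all codes identical), the generation cap
   `maxiter` (default 1000), or length spread `L(worst) − L(best) ≤ tol`
   (default `1e−12`); exactly one reason is reported.

μ = λ = the scheduled population size: 64 for generations 0–4, 32 for 5–24,
16 afterwards (a halving schedule favoring early exploration; retention on
shrink keeps the best, the standard elitist choice).  For `n ≤ 4` the code
space (1 or 3 topologies) is enumerated directly, returning the same
statistics structure.

Randomness comes from a single root seed that spawns independent
initialization and recombination streams, so identical (matrix, config)
inputs give bit-identical trajectories and adding instrumentation cannot
perturb a run.  The search compares raw floating-point lengths, as the
descent operators do; the ω machinery (below) is for reporting and
verification.

The random-initialization baseline (`run_ri`) performs `budget` independent
BNNI + BSPR descents from uniform random topologies;
`matched_budget_comparison` runs the evolution strategy first, counts its
generated trees, and gives the baseline the same budget — the harness used
to study whether recombination earns its overhead (with per-seed lengths,
NNI/SPR call counts, and the RF distance between the two winners).

## Numerical tolerance ω

With `τ ≥ 50` the factor `2^(1−τ)` drops below double-precision resolution
relative to `L`'s leading terms.  Splitting `L = l_A + l_B` by `τ < 50`
versus `τ ≥ 50`, and using that a binary tree has at least two cherries (so
fewer than `n²/2` deep pairs, each contributing at most `2^(1−50) max d`):

    l_B(T) < n² · 2^(−49) · max_ij d_ij = ω.

`certified_less(l1, l2, ω)` therefore certifies the exact ordering of two
computed lengths whenever their gap exceeds ω; `False` means *not
certified*, not *greater*.  The tests construct a 60-taxon caterpillar
(diameter 59) with `d ∈ (0, 1]` and confirm the deep-pair contribution
stays below ω.

## Synthetic data

`random_additive_matrix` samples a uniform topology, draws branch lengths
from an exponential with mean 0.1 (a conventional simulation default;
configurable), and returns leaf-to-leaf path sums — exactly additive, hence
satisfying the four-point condition, with the generating tree as the known
optimum.  `perturb_matrix` applies multiplicative noise
`d'_ij = d_ij · max(0, 1 + ε_ij)`, `ε ~ N(0, σ)`, one draw per unordered
pair — chosen over additive noise so matrices stay non-negative and
symmetric without rescaling.  Metric (but non-additive) test instances are
built from Euclidean distances between random points.

What passing these tests does and does not show: additive and mildly noisy
matrices make the balanced-length landscape benign (the true tree has a
wide basin), so recovery there demonstrates correctness of the machinery,
not search power on hard instances.  Real distance matrices estimated from
alignments carry correlated, heteroscedastic noise that none of these
generators emulate; conclusions about field performance require real data.

## Problem sizes and defaults

The reference implementation is sequential pure Python + numpy, and the
shipped tests run the full search at `n ≤ 20` (exhaustive cross-checks at
`n ≤ 7`, structural checks to `n = 64`) — sizes chosen so the entire suite
completes in a few minutes on one core while still exercising every code
path; the algorithm itself has no such limit.  Defaults mirror the standard
configuration: `maxiter = 1000`, `tol = 1e−12`, population schedule
`64:5, 32:25, 16`.

## Known limitations

- No branch-length estimation; the output is a topology.
- Square symmetric PHYLIP only (no lower-triangular dialect); distances are
  consumed, never estimated from sequences.
- Binary trees only, apart from the transient construction stars; rooted
  Newick inputs are accepted but immediately unrooted.
- The `O(n⁴)`-ish per-generation cost of batched SPR scanning is fine at
  desk scale but far from the vectorized/compiled implementations used for
  hundreds of taxa.
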