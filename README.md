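# phyloes

Evolution-strategy search for **balanced minimum evolution** phylogenies.

Distance methods estimate a phylogeny from a matrix of pairwise
dissimilarities between taxa.  Under the balanced minimum evolution (BME)
criterion, the tree sought is the unrooted binary leaf-labeled tree *T*
minimizing the balanced length

    L(T) = Σ_{i<j} d_ij · 2^(1 − τ_ij)

where `d_ij` is the dissimilarity between taxa *i* and *j* and `τ_ij` is the
number of edges on the path connecting them in *T* (Pauplin's weighting: for
every taxon the weights `2^(1−τ_ij)` over its partners sum to 1).  The
criterion is statistically consistent but NP-hard to optimize; practical
tools rely on greedy construction plus local search, whose deterministic
exploration can converge prematurely on large instances.

`phyloes` implements a stochastic alternative: a (μ+λ) evolution strategy
over a step-wise tree encoding, hybridized with the two classical
balanced-length local searches.

- **Encoding** — every topology corresponds bijectively to an integer vector
  `(h_1, …, h_{n−3})` with `1 ≤ h_i ≤ 2i+1`, recording which edge of the
  growing tree receives each successive taxon.  Uniform topologies are
  sampled by drawing each component uniformly; any per-component change of a
  valid code is again a valid code.
- **Local search** — BNNI and BSPR: steepest-descent over the
  nearest-neighbor-interchange (2(n−3) neighbors) and
  subtree-prune-and-regraft (O(n²) neighbors) neighborhoods under *L*.
  Every tree the engine touches is refined by BNNI followed by BSPR.
- **Recombination** — component *j* of a child code is sampled uniformly
  from the *j*-th components of all current parents; μ = λ = population
  size, truncation selection over parents ∪ offspring, population halving
  (64 → 32 → 16 by default), and an anti-stagnation rule that replaces a
  duplicated worst individual with a copy of the next-best one.
- **Certified comparisons** — lengths of trees with deep pairs
  (τ ≥ 50) lose digits to underflow; the tolerance
  `ω = n²·2^(−49)·max d_ij` bounds that error, and `L̃(T1) + ω < L̃(T2)`
  certifies `L(T1) < L(T2)`.

A matched-budget random-initialization baseline (`run_ri`, the same local
search from uniformly random starts) is included for benchmarking the value
of the evolutionary recombination.

## Worked example

Simulate a 10-taxon additive matrix (path sums on a random tree with
exponential branch lengths), search it, and compare against the truth:

```console
$ phyloes simulate --n 10 --seed 42 --matrix-out dist.phy --tree-out true.nwk
$ phyloes run dist.phy --seed 1 --tree-out best.nwk --stats-out stats.json
$ cat best.nwk
(t1,((t2,t10),t3),(((t4,t7),t9),((t5,t8),t6)));
$ phyloes length dist.phy best.nwk
length 1.48305776632
omega 1.45705e-13
$ phyloes rf best.nwk true.nwk
0
```

The search returns the generating topology (Robinson–Foulds distance 0), as
it must on exactly additive input: its balanced length, 1.48305776632, is
the minimum over all 2 027 025 ten-taxon topologies, and the margin to any
other tree dwarfs the certification tolerance ω ≈ 1.5·10⁻¹³.  `stats.json`
records the trajectory; here all 64 initial individuals already descend to
the same topology, so the run stops on the convergence criterion after the
initialization generation (64 trees, 633 accepted NNI moves, 0 SPR moves).

The same machinery is available as a library:

```python
from phyloes import ESConfig, SyntheticSpec, random_additive_matrix, run_phyloes

d, truth = random_additive_matrix(SyntheticSpec(n=20, seed=7))
tree, stats = run_phyloes(d, ESConfig(seed=7))
print(stats.stop_reason, stats.best_length)
```

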