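# cliquehop

Hopfield networks whose memories are the k-cliques of a graph — an
exponentially large, noise-tolerant code implemented with binary threshold
neurons.

A network on `n = v(v-1)/2` neurons identifies each binary state with a graph
on `v` vertices (one neuron per vertex pair).  The package provides:

- **`cliquehop.core`** — symmetric zero-diagonal Hopfield networks, energy,
  asynchronous threshold dynamics (single state and batched), convergence to
  fixed points, seeded per-bit corruption, and plain-text serialization.
- **`cliquehop.codec`** — the bijection between graphs and bit-strings
  (lexicographic edge indexing), clique states, edge-pair statistics
  (`#E`, `S1`, `S0`), exact and asymptotic clique counts, seeded clique
  sampling, edge-list/adjacency-matrix text I/O.
- **`cliquehop.mpf`** — the convex probability-flow objective and its
  analytic gradient, L-BFGS fitting of full `(W, theta)` networks, and the
  local single-pattern learning rule with post-hoc symmetrization.
- **`cliquehop.symmetric`** — the 3-parameter `(x, y, z)` family obtained by
  vertex-permutation symmetry: closed-form restricted flow and its unique
  minimizer `x = 2z/(3k-5)`, the large-deviation robust setting
  `x = z(3+2p)/(4k(1+2p))`, r-stability certificates (a 4x2 system of strict
  linear inequalities) with an exhaustive enumeration oracle, clique-range
  feasibility (`x_M < x_m`, constants `C ~ 0.43`, `D ~ 13.93`), and a sparse
  dynamics path that never materializes the dense weight matrix.
- **`cliquehop.permnets`** — machinery showing networks that store all
  permutations cannot robustly store derangements: permutation encoding on
  `k(k-1)` off-diagonal slots, critical-pair construction, indistinguishability
  probability bounds, and a seeded Monte-Carlo estimator.
- **`cliquehop.experiments`** — seeded drivers: robustness curves (recovery
  vs corruption, with common random numbers across the grid), MPF training
  curves on held-out cliques, weight-group statistics of trained networks,
  hidden-clique denoising, degree-concentration statistics, and a
  robustness-index estimator.

## CLI

```sh
cliquehop mpf-optx --k 64                  # flow-minimizing x (0.0107)
cliquehop ld-x --k 64 --p 0.25             # large-deviation x (0.0091)
cliquehop certify --k 8 --r 2 --x 0.1056   # r-stability certificate (JSON)
cliquehop range-check --m 5 --M 15         # clique-range feasibility
cliquehop sym-build --v 16 --x 0.105 --out net.txt
cliquehop robustness --config cfg.json --seed 1 --out rb   # TSV + JSON meta
cliquehop train-curve --seed 1
cliquehop hidden-clique --graph adj.txt --k 8
cliquehop neighbor-stats --seed 1
cliquehop alpha --seed 1
```

Experiment subcommands accept `--config` with a JSON object (keys documented
in `cliquehop/cli.py`) and write a TSV trial table plus a JSON metadata
sidecar.

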