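# Methods

This document describes the models implemented in `netforge`, the conventions
and numerical choices the implementation commits to, and the limits of what it
computes. Nothing here is an empirical claim beyond what the code and its test
suite actually verify.

## 1. Graphs and notation

All networks are simple, undirected, unweighted graphs on `N` nodes, stored as
dense boolean adjacency matrices `A` (`Network` in `graph_core`). `M` denotes
the number of links, `k_i = Σ_j a_ij` the degree of node `i`, and
`λ = 2M/N` the mean degree.

Two density conventions appear in the literature and both are used here,
explicitly:

- **Edge density** `2M / (N(N−1))` — the fraction of possible node pairs that
  are linked. This is the `Network.density` property.
- **Connectivity density** `λ/N = 2M/N²` — mean degree relative to system
  size. For the standard condition (`N = 100`, `λ = 10`) this is exactly 0.1,
  while the edge density is `1000/9900 ≈ 0.10101`.

Random substrates come from `generate_er(n, lam, seed)`, an Erdős–Rényi
`G(n, M)` ensemble with `M = round(λ·n/2)`. The fixed-`M` flavour (rather
than fixed-`p`) is deliberate: the rewiring rules conserve the link count
exactly, so the entire study operates at one exact edge budget and observed
effects cannot be confounded by density fluctuations between realisations.

## 2. Topological overlap

The matrix score driving the primary rewiring rule is the topological overlap

```
TO_ij = ( Σ_k a_ik a_kj + a_ij ) / ( min(k_i, k_j) + 1 − a_ij ),   TO_ii = 0.
```

The numerator counts common neighbours plus the direct link; the denominator
normalises by the smaller degree so that `TO_ij ∈ [0, 1]`, with 1 meaning the
lower-degree node's neighbourhood (plus the link itself) is fully shared.
`topological_overlap` computes this vectorised (`A² + A` over an outer-min of
degrees); the test suite checks it against explicit common-neighbour counting
on hundreds of random graphs.

## 3. Topological reinforcement (TR)

`run_topological_reinforcement` evolves a network by repeated
density-preserving batch rewiring (`rewire_step`):

1. **Eligibility.** Nodes with `0 < k_i < N−1` can gain a link (isolated
   nodes have no overlap signal; saturated nodes have no non-neighbour).
2. **Batch.** A uniform sample of `⌊N/2⌋` eligible nodes (all of them if
   fewer) is drawn without replacement.
3. **Insertion.** Each sampled node links to the non-neighbour with maximal
   score, ties broken uniformly at random. Scores are evaluated against the
   adjacency *at entry to the step* (simultaneous semantics): insertions
   within a batch do not see one another. Duplicate proposals for the same
   node pair collapse to a single link.
4. **Pruning.** From the post-insertion link set, links equal in number to
   the links actually added are removed uniformly at random. Density is
   therefore conserved *exactly* at every step.

The number of steps is `r = round(λ·K)` with `K = 3` by default, i.e. roughly
`3M` candidate insertions over a run — enough for every link to have turned
over in expectation a few times. Per step the trajectory records density,
number of connected components, and (optionally, over `n_detect` Louvain
restarts) mean and standard deviation of modularity `Q` and module count.

The rule is greedy and local; it has no temperature, no annealing, and no
global objective. Modularity emergence is a measured outcome, not an input.

## 4. SER excitable dynamics and functional connectivity

`ser` implements the three-state susceptible–excited–refractory cellular
automaton with synchronous updates:

- `S → E` if at least one neighbour is excited, otherwise with probability
  `f` (spontaneous drive);
- `E → R` always (one time step of excitation);
- `R → S` with probability `p` (recovery).

The **deterministic regime** is `f = 0, p = 1`: all randomness then lives in
the initial condition, and activity is pure neighbour-to-neighbour
propagation. Co-activation counts `c_ij = Σ_t 1[x_i^t = E]·1[x_j^t = E]`
include the initial state `t = 0`. Functional connectivity normalises by the
smaller self-count,

```
FC_ij = c_ij / min(c_ii, c_jj),   FC_ii = 0,
```

with the convention `FC_ij = 0` whenever the denominator is zero (a node that
was never excited carries no signal).

Two estimation protocols:

- **Deterministic FC** (`simulate_deterministic_fc`): many short runs
  (default 5000 runs × 30 steps). Each run's initial composition
  `(n_E, n_S, n_R)` is drawn *uniformly over the discrete simplex*
  `{(a,b,c) ∈ ℕ³ : a+b+c = N}` via stars-and-bars, then assigned to nodes by
  a uniform permutation. Counts are accumulated over runs and normalised
  once at the end (averaging counts before normalising, not averaging
  per-run FC matrices). The discrete-uniform composition law was chosen over
  a continuous Dirichlet draw followed by rounding because it admits an
  *exact* enumeration oracle: for small `N` the test suite sums over all
  `3^N` initial states with the correct composition weights and checks the
  Monte-Carlo estimator against it to statistical tolerance.
- **Stochastic FC** (`simulate_stochastic_fc`): one long run (default 50 000
  steps) of the noisy model (`f > 0` or `p < 1`), started from
  `round(0.1·N)` excited nodes with the remainder split evenly between `S`
  and `R` (an odd remainder gives the extra node to `S`). Deterministic
  parameters are rejected here, since a single deterministic run explores
  only one attractor.

The simulator is vectorised across runs (states held as an
`(n_runs × N)` int8 array; propagation is a boolean matrix product), which is
what makes protocol-length FC windows affordable inside the Hebbian loop.

Note a structural fact the tests pin down: at the extreme `f = 1, p = 1` the
dynamics are *fully deterministic* after one step — the population
phase-locks with period 3 and FC becomes binary. "High noise" in the sense of
washing out structure requires `f, p` large but strictly below 1 (e.g.
`f = p = 0.9`), where the topology–FC correlation is indistinguishable from
zero.

## 5. Hebbian rewiring

`run_hebbian` reuses the TR engine unchanged, substituting estimated FC for
TO as the insertion score (a `score_fn` callback). Before every rewiring step
the FC matrix is re-estimated on the current topology with a fresh window
(deterministic regime: `window_runs × window_steps`; stochastic regime: one
`window_steps`-long run). If a window produces an all-zero FC matrix the step
falls back to uniform tie-breaking, with a warning.

The mechanism claim this package supports computationally: in the
deterministic regime FC is a noisy proxy of TO, so FC-driven rewiring
reproduces the TR phenomenology (modularity growth; agreement structure
correlated with TR's); in the high-noise stochastic regime the proxy breaks
(`|corr(TO, FC)| ≈ 0`) and the rule degenerates to random rewiring, leaving
modularity flat. The FC window length matters quantitatively: short windows
attenuate the TO–FC correlation (sampling noise in `c_ij`) and with it the
per-run modularity gain. Unit tests therefore check *direction* at small
windows (300 runs), while the full-scale replication checks the gain
threshold at protocol-length windows (2000 runs).

`parameter_sweep` runs a grid of regimes/parameters, recording the pre-run
TO–FC correlation, final `Q`, and `ΔQ` per cell, tolerating and recording
per-cell failures.

## 6. Consensus, agreement, and null models

- **Agreement matrix** `P` (`agreement`): given partitions of the same node
  set, `P_ij` is the fraction in which `i` and `j` share a module.
- **Consensus partitions** (`consensus_partitions`): weighted Louvain applied
  to `P` itself, repeated with independent seeds.
- **Null agreement** (`null_agreement`): each partition's labels are shuffled
  over nodes (sizes preserved) before building `P`. The expected off-diagonal
  entry for a partition with module sizes `s_m` is
  `Σ_m s_m(s_m−1)/(N(N−1))`, which the tests check in closed form.
- **Partition overlap** (`partition_overlap`): arithmetic-mean normalised
  mutual information (scikit-learn), with explicit degenerate conventions —
  two trivial (single-module) partitions give 1.0 with a warning, one
  trivial against one non-trivial gives 0.0.
- **Matrix similarity** (`matrix_similarity`): Pearson correlation over the
  strictly-upper off-diagonal entries.
- **Intramodule density** (`intramodule_density`): mean edge density inside
  modules, unweighted across modules, singleton modules excluded.
- **Empirical p-values** (`empirical_pvalue`): `(b+1)/(n+1)` with `b` the
  number of null draws at least as extreme as the observation.

`proto_module_analysis` assembles these into the amplification analysis on a
single substrate graph: `P_init` from many Louvain runs on the *initial*
graph; `P` from modularity partitions of many independent rewiring runs;
comparisons of `P_init` vs `P` (matrix similarity and consensus-partition
NMI) against shuffle-null distributions; and intramodule-density
distributions of consensus partitions, direct graph partitions, and shuffled
partitions evaluated on the initial graph. Degree-preserving rewired controls
use Maslov–Sneppen double-edge swaps (`maslov_sneppen_rewire`, `M` accepted
swaps).

## 7. Planted-partition fixtures and experiments

`generate_planted_partition` wraps a stochastic block model with equal-size
blocks. The package's own default (`p_within = 0.3`, `p_between = 0.05`,
four blocks of 25) is chosen so that the planted structure dominates chance
fluctuations: amplification of planted blocks by TR is only detectable when
the expected within-block degree exceeds the between-block degree
(`p_within·(s−1) > p_between·(N−s)`). Parameter pairs violating this — e.g.
`0.15/0.08` at `N = 100`, `s = 25`, where within-degree 3.6 < between-degree
6.0 — plant structure *weaker* than the ER proto-modules that TR amplifies
anyway, and no rule driven by local overlap can be expected to recover it.

`run_experiment` provides reproducible runners (trajectories and scaling of
TR, proto-module analysis, Hebbian sweeps, TR/Hebbian correspondence, and a
disconnection study at small `K`), each writing a `manifest.json` with
package and dependency versions, the configuration, and a status flag. The
`scale` knob multiplies replicate counts only — never model parameters.

## 8. Numerical and statistical choices

- All randomness flows through NumPy `Generator` objects; every public entry
  point takes a seed or generator. Seeded runs are bit-reproducible.
- Louvain community detection and modularity come from NetworkX
  (`louvain_communities`); weighted Louvain on agreement matrices uses the
  same implementation with `P` as edge weights. Louvain is stochastic, so
  `Q` is always reported across restarts where it matters.
- Statistical tests that compare a Monte-Carlo estimate against an exact
  oracle entry-wise across many entries use a Šidák-corrected simultaneous
  z-threshold (family-wise equivalent of a single 3-SE check), plus a pooled
  signed-z bias bound across independent graphs. Per-entry z-values within
  one graph share the same runs and are correlated; bounds that assume their
  independence are unsound and are not used.
- Default problem sizes in tests and the acceptance script (replicate counts
  of tens to a few hundred, FC windows of 1500–2000 runs) are this package's
  own scaling choices for a single-CPU budget; the model parameters
  themselves (`N = 100`, `λ = 10`, `K = 3`, 30-step windows) are the
  standard condition throughout.

## 9. Scope and limitations

- Graphs are dense-matrix backed; the implementation targets `N` up to a few
  thousand, not large sparse networks.
- The SER model is synchronous and unweighted; no transmission delays,
  weighted coupling, or asynchronous updates.
- Only undirected simple graphs are supported; the rewiring rules assume
  symmetric adjacency.
- `proto_module_analysis` quantifies amplification on a single substrate per
  call; population-level statements require aggregating over substrates,
  which the experiment runners (not the core function) do.
- No inferential machinery beyond empirical p-values and the closed-form
  null expectations described above is provided; the package computes
  descriptive network statistics, not fitted models.
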