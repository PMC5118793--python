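# Methods

## The model

`llna` implements Life-Like Network Automata: a two-state cellular
automaton whose lattice is an arbitrary undirected network.  Every node
carries a binary state s_i ∈ {0 (dead), 1 (alive)}.  Classic Life-like
rules are written B*x*/S*y*: on an 8-neighbor Moore grid, a dead cell is
born when its alive-neighbor count is in the birth set B, and an alive
cell survives when the count is in the survival set S.  With both sets
drawn from {0,…,8} there are 2^18 = 262144 rules.

On a network the neighbor count is replaced by the neighborhood density

    rho_i = (1/k_i) * sum_j A_ij s_j,

the fraction of node i's neighbors that are alive.  Each rule digit x is
identified with the density interval [x/9, (x+1)/9), the last interval
[8/9, 1] being closed, so the nine intervals partition [0, 1].  The
synchronous update is then: a dead node becomes alive iff rho_i falls in
a birth digit's interval; an alive node stays alive iff rho_i falls in a
survival digit's interval; otherwise the node is (or becomes) dead.

On a toroidal grid where every node has exactly the 8 Moore neighbors the
density n/8 of n alive neighbors falls in interval n, so the network
automaton reduces bit-for-bit to the classic Life-like CA — the test
suite verifies B3/S23 against an independent convolution-based Game of
Life oracle for 100 steps, including glider translation.

Evolving t steps from a random initial state (each node alive with
probability σ) yields a (t+1) × N binary space-time diagram; row 0 is the
initial configuration and each column is one node's time series.

### Numerical choices

* Interval membership is decided by comparisons against the shared
  floating-point bounds {1/9, …, 8/9} (`np.searchsorted`), identically in
  the scalar and vectorized paths, so the partition of [0, 1] holds
  bitwise and no epsilon policy is needed.
* Isolated nodes (k_i = 0) get density 0: they are born only if 0 ∈ B and
  survive only if 0 ∈ S, the continuous limit of "no alive neighbors".
* The update is strictly synchronous; one step is a single sparse
  mat-vec plus two table lookups.
* Degree-ordering of diagram columns is a visualization convention only;
  every descriptor is invariant under node permutation.

## Measurements

For each diagram three quantities are computed (by default on the full
t+1-row series; a flag drops the random initial row so both conventions
can be compared — the effect is one row in ~350):

* **Shannon entropy** per node: H = −p₀log₂p₀ − p₁log₂p₁ of the node's
  binary series, in [0, 1] bits.
* **Word lengths**, pooled over all nodes (a global measurement): a word
  is a maximal run of 1s.  Runs touching the series boundaries count, so
  word lengths always sum to the number of 1s.
* **Lempel-Ziv complexity** per node: the series is decomposed by an
  incremental dictionary (each block is the shortest prefix of the
  remainder not yet in the dictionary; a trailing remainder that matches
  an existing block is not counted), giving g blocks.  The alternating
  sequence 0101…01 of length 20 decomposes into 0|1|01|010|10|101|0101,
  g = 7.  The normalized complexity is g/(l/log₂l), the block count
  relative to the asymptotic rate of a random sequence; the raw g and the
  normalization choice are both exposed, since variants of this
  normalization exist in the literature.

## Descriptors

Each network is summarized by 20-bin histograms: h_S of node entropies
over [0, 1]; h_W of word lengths over {1–2},…,{39–40} (words longer than
40 are discarded — their frequency is negligible at t = 350); h_L of node
LZ values over [0, group_max].  h_S and h_W are relative frequencies
(counts would break size invariance).  group_max is the maximum LZ value
over the group of samples being described; it is fit once per dataset
group so all histograms share a binning, and a caller can pass an
explicit (e.g. training-split) value instead — values beyond group_max
clip into the last bin.  The combined descriptor is the 60-value
concatenation [h_S, h_W, h_L]; the averages descriptor is
[⟨μ_S⟩, ⟨μ_W⟩, ⟨μ_L⟩].

## Synthetic network generators

All datasets are generated, never downloaded.  Defaults (N, ⟨k⟩ grids,
replicate counts) follow the benchmark design; per-network seeds derive
deterministically from a master seed and the network's coordinates
(model, ⟨k⟩, N, replicate), so datasets are reproducible and rule
comparisons are paired.

* **random** (Erdős–Rényi): each pair connected with p = ⟨k⟩/N.
* **small_world** (Watts–Strogatz): ring lattice with ⟨k⟩/2 neighbors per
  side, each edge rewired with probability 0.1.
* **scalefree** (Barabási–Albert, attachment exponent α): growth from an
  (m+1)-clique, m = ⟨k⟩/2 edges per new node, targets sampled without
  replacement with probability ∝ k^α.  α = 1 is the classic linear model;
  the 4-model dataset's scale-free class cycles α through
  {0.5, 1.0, 1.5, 2.0} across replicates.
* **scalefree_dm** (Dorogovtsev–Mendes): each new node attaches to both
  endpoints of ⟨k⟩/4 distinct uniformly chosen existing edges (closing a
  triangle per selection); ⟨k⟩ → 8 with two selections per step.
* **geographical**: N points uniform in the unit square; pair (i, j)
  connected with probability c·exp(−λ·d_ij), where d_ij is the pair
  distance *in units of the mean point spacing* (1/√N) and c is
  calibrated by bisection so the expected ⟨k⟩ hits the target within 5%.
  Measuring distance relative to the point density keeps the model's
  local topology independent of N — without this, a fixed decay length
  degenerates to an Erdős–Rényi graph at low density and to a strict
  nearest-neighbor graph at high density, and "the same model at
  different sizes" would not be the same model.  Default λ = 1 (decay
  over about one inter-node spacing), giving strongly spatial graphs
  (clustering 0.1–0.4 across the dataset grid versus ~k/N for ER).

A noise operation removes round(ρ_N·E) random edges and adds as many
random absent pairs, preserving the edge count, for robustness studies.

## Structural baselines

Six classic measures serve as the comparison feature vector: mean degree
⟨k⟩; hierarchical degrees ⟨k₁⟩, ⟨k₂⟩; mean local clustering ⟨cc⟩; mean
shortest path length l over reachable pairs (finite on disconnected
graphs); and degree assortativity ρ_P (Pearson correlation of endpoint
degrees over edges, defined as 0 on degree-regular graphs where the
correlation is 0/0).

Two hierarchical-degree conventions are implemented.  `structural_measures`
defaults to the ring convention (nodes at distance exactly d; level 1
then equals the ordinary degree).  The baseline classification vector
[⟨k₁⟩, ⟨k₂⟩, ⟨cc⟩, l, ρ_P] built by `structural_feature_matrix` instead
defaults to the inter-ring-edge convention of the hierarchical-
measurement framework (edges between ring d and ring d+1): the protocol
excludes ⟨k⟩ from the baseline because ⟨k⟩ is part of the class
definition in the 28-class task, and that exclusion is only meaningful if
level-1 hierarchical degree is not the degree itself.  Under the ring
convention the baseline would carry the class label ⟨k⟩ verbatim and its
28-class accuracy jumps by ~20 points, inverting the comparison the
baseline exists to make.

## Classification protocol

Repeated stratified n-fold cross-validation: fold assignment is
re-randomized each repetition, predictions are pooled over folds, and
accuracy is reported as mean ± std *across repetitions* (the CA evolution
of each network is fixed; only fold assignment varies).  For unbalanced
datasets a resampling variant subsamples every class to the smallest
class size per configuration and aggregates over configurations
(default 3 folds, 100 configurations).

Two classifiers are exposed: nearest neighbour (k = 1; k is
configurable) and a max-margin SVM.  Rule selection scans candidate rules
with the entropy histogram + nearest-neighbour combination, ranking rules
by mean CV accuracy with ties broken by canonical rule order; per-network
evolution seeds are reused across rules so scan comparisons are paired
and results are independent of any parallel execution order.

## Problem sizes

The bundled experiments run at a reduced scale chosen to keep a complete
run on one CPU in minutes: the 4-model dataset uses 7 mean degrees
⟨k⟩ ∈ {4,…,16}, sizes N ∈ {500, 1000} and 20 replicates per cell (1120
networks; the full-scale benchmark uses four sizes and 100 replicates, 11200
networks), with repeated 10-fold CV; the five-class scale-free dataset
uses 30 replicates per class at N = 1000, ⟨k⟩ = 8.  Accuracies at this
scale sit a few points below the full-scale figures simply because
28-class discrimination with 40 samples per class is data-limited.

## What the synthetic data does and does not show

The generators emulate the benchmark conditions (model families, ⟨k⟩ and N
grids, σ = 0.5, t = 350) but not real-world messiness: metabolic, social
or stomatal networks have degree correlations, community structure and
noise that no clean generative model produces.  Passing tests therefore
demonstrate the pipeline's correctness and the descriptors' discriminative
power on known topologies, not performance on any real dataset.  The
point-pattern module ships synthetic uniform/clustered/regular pattern
generators as stand-ins for segmented stomata centroids, labelled as
such.

## Known limitations

* Only outer-totalistic two-state Life-like rules; no asynchronous,
  weighted or directed dynamics.
* The LZ normalization and the geographical kernel follow standard forms
  where the original formulations are ambiguous; both are configurable.
* The full 262144-rule scan is supported (deterministic, checkpointable
  by rule mask) but takes CPU-days at full dataset scale; the shipped
  examples scan small rule subsets.
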