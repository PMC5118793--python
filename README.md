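# llna — Life-Like Network Automata

`llna` classifies complex networks by *running a cellular automaton on
them*.  A network (random, small-world, scale-free, geographical, a
metabolic or social graph, a proximity graph built from a point pattern)
is used as the lattice of a binary CA governed by a Life-like rule
B*x*/S*y*; the spatio-temporal pattern of the evolution is summarized by
histogram descriptors that feed a standard classifier.  It is aimed at
researchers in network science and pattern recognition who need
topology-sensitive network signatures that go beyond classic structural
measurements.

## The method

Every node i carries a binary state s_i.  Because node degrees vary, the
usual alive-neighbor *count* is replaced by the neighborhood *density*

    rho_i = (1/k_i) * sum_j A_ij s_j ,

and each rule digit x in B (birth) or S (survival) is mapped to the
density interval [x/9, (x+1)/9) (the ninth interval [8/9, 1] is closed).
A dead node becomes alive iff rho_i lies in a birth interval; an alive
node persists iff rho_i lies in a survival interval.  On a torus where
every node has the 8 Moore neighbors this reduces exactly to the classic
Life-like CA (B3/S23 = Conway's Game of Life).  There are 2^18 = 262144
rules.

Evolving t steps (default t = 350 from a σ = 50% random start) yields a
(t+1) × N space-time diagram.  Per node, the Shannon entropy and the
normalized Lempel-Ziv complexity g/(l/log₂l) of its binary series are
computed; maximal runs of 1s ("words") are pooled over all nodes.  Three
20-bin histograms — h_S (entropy), h_W (word lengths ≤ 40, bin width 2),
h_L (LZ, binned over the group maximum) — concatenate into the 60-value
descriptor used for classification; rule selection scans rules by the
cross-validated accuracy their descriptors achieve.

## A worked example

```sh
python examples/02_descriptors.py
```

```
rule B1357/S2468, N=500, <k>=4, t=350
model           <mu_S>  top-fifth h_S mass
random           0.517               0.500
small_world      0.202               0.202
scalefree        0.421               0.410
geographical     0.527               0.518
```

Each network was evolved by the same rule from the same seed; `<mu_S>`
is the mean per-node entropy and the last column is the entropy-histogram
mass above 0.8.  The same rule lands in different dynamical regimes on
different topologies — the small-world ring stays nearly frozen, random
and geographical graphs sustain disordered activity, the scale-free
graph mixes chaotic hubs with stable leaves — and these histogram shapes
are exactly what the classifier separates.
`examples/03_classify_models.py` runs the full scaled-down
4-model experiment and prints the cross-validated accuracy and confusion
matrix; the other examples cover diagram export, rule scanning and
point-pattern sweeps.

A thin CLI mirrors the library (`llna generate | evolve | measure |
features | scan | classify | sweep`); see `llna --help`.

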