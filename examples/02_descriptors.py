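"""Compare LLNA descriptors of the four classic network models.

For one network per model (N=500, <k>=4) this prints the mean node
entropy and the entropy-histogram mass in the top fifth of [0, 1].  The
models drive the same rule into very different regimes — the small-world
ring stays nearly frozen while random and geographical graphs sustain
disordered dynamics and the scale-free graph mixes chaotic hubs with
stable leaves — and those histogram differences are the classification
signal.
"""

from llna import assemble, evolve, generate_model, measure_diagram, parse_rule

rule = parse_rule("B1357/S2468")
print(f"rule {rule.canonical_name}, N=500, <k>=4, t=350")
print(f"{'model':<14}{'<mu_S>':>8}{'top-fifth h_S mass':>20}")
for model in ("random", "small_world", "scalefree", "geographical"):
    net = generate_model(model, 500, 4, seed=3)
    ms = measure_diagram(evolve(rule, net, t=350, sigma=0.5, seed=4))
    fv = assemble(ms, group_max=float(ms.node_lz.max()))
    print(f"{model:<14}{ms.node_entropy.mean():>8.3f}{fv.h_s[16:].sum():>20.3f}")
print("\nEach row is one 60-dim descriptor away from being classified;")
print("the differing histogram shapes are what the classifiers exploit.")
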