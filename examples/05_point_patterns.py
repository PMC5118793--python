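"""Threshold-sweep descriptors of 2-D point patterns.

Builds clustered and uniform synthetic point patterns (stand-ins for
stomata centroid sets), converts each into a family of proximity networks
over the default threshold sweep, and prints the per-threshold average
entropy — the curve that separates spatial arrangement classes.
"""

import numpy as np

from llna import synth_point_pattern, threshold_sweep_descriptor
from llna.pointpattern import DEFAULT_DELTAS

for kind in ("uniform", "clustered"):
    p = synth_point_pattern(kind, 80, seed=5)
    vec = threshold_sweep_descriptor(p, "B12345/S04568", t=350, seed=6)
    mu_s = vec[0::3]  # entropy average at each threshold
    with np.printoptions(precision=2, suppress=True):
        print(f"{kind:<10} <mu_S> over deltas {DEFAULT_DELTAS[0]}..{DEFAULT_DELTAS[-1]}: {mu_s}")
print("\nlow thresholds probe local arrangement (where the classes differ);")
print("near delta=1 every pattern is a complete graph and the curves merge.")
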