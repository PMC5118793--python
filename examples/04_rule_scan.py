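"""Rank a handful of Life-like rules by their discriminative power.

Scans a small rule subset on a fresh rule-selection dataset (entropy
histogram + nearest-neighbour classifier, as in the selection protocol)
and prints the descending accuracy ranking.  A full scan over all 262144
rules uses the same call with `enumerate_rules()`.
"""

from llna import rule_selection_dataset
from llna.classify import rule_scan

networks = rule_selection_dataset(master_seed=2, replicates=5, n_nodes=300)
candidates = ["B135678/S03456", "B01678/S0457", "B0157/S457", "B3/S23", "B/S"]
ranking = rule_scan(candidates, networks, feature="h_s",
                    classifier="nearest_neighbour", t=200, folds=5,
                    repetitions=3, seed=2)
print(f"{len(networks)} networks, 4 models; descriptor h_S, 1-NN, 5-fold CV")
for entry in ranking:
    print(f"{entry.rule.canonical_name:<20}{entry.mean_accuracy:6.2f} +/- {entry.std_accuracy:.2f}%")
print("\nhigh-ranking rules are kept for the classification experiments;")
print("B/S (no births, no survivals) kills all activity and scores at chance.")
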