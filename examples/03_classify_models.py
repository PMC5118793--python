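"""Small 4-model classification experiment, end to end.

Generates a reduced synthetic dataset (4 models x 7 mean degrees x 6
replicates at N=500), evolves rule B135678/S03456, extracts the combined
60-bin descriptor and reports repeated 10-fold CV accuracy — a scaled-down
version of the model-classification experiment.
"""

from llna import ExperimentConfig, run_experiment, synthetic_dataset

networks = synthetic_dataset(master_seed=1, sizes=(500,), replicates=6)
config = ExperimentConfig(
    rule="B135678/S03456", t=350, sigma=0.5,
    feature="combined", classifier="max_margin",
    folds=10, repetitions=5, seed=1,
)
result = run_experiment(config, networks)
print(f"{len(networks)} networks, classes: {result.classes}")
print(f"accuracy: {result.summary()}")
print("confusion matrix (rows = true class, pooled over repetitions):")
print(result.confusion)
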