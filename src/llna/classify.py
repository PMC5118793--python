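"""Rule selection, cross-validated classification and experiment orchestration.

Evaluation uses repeated stratified
n-fold cross-validation (fold assignment re-randomized per repetition, CA
evolutions fixed per network), accuracy reported as mean +/- std over
repetitions, plus a class-balanced resampling variant for unbalanced
datasets.  Classifiers: nearest neighbour (k=1) and a max-margin SVM
(RBF kernel behind a standard scaler); both are config-exposed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import accuracy_score, confusion_matrix
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from . import features as feat
from .automaton import evolve
from .generators import LabeledNetwork
from .measures import measure_diagram
from .rules import LifeLikeRule, parse_rule

CLASSIFIERS = ("nearest_neighbour", "max_margin")


def make_classifier(name: str, **params):
    """Instantiate a classifier by short name.

    ``nearest_neighbour`` -> 1-NN; ``max_margin`` -> RBF-kernel SVM behind
    a standard scaler (library-default regularization).  Keyword params
    override the defaults of the underlying estimator.
    """
    if name == "nearest_neighbour":
        return KNeighborsClassifier(n_neighbors=params.pop("n_neighbors", 1), **params)
    if name == "max_margin":
        return make_pipeline(StandardScaler(), SVC(**params))
    raise ValueError(f"unknown classifier {name!r}; known: {CLASSIFIERS}")


@dataclass
class ExperimentResult:
    """Accuracy summary of one repeated-CV run (accuracies in percent)."""

    accuracies: np.ndarray
    confusion: np.ndarray
    classes: list
    folds: int
    repetitions: int
    classifier: str

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.accuracies))

    @property
    def std_accuracy(self) -> float:
        return float(np.std(self.accuracies))

    def per_class_accuracy(self) -> np.ndarray:
        totals = self.confusion.sum(axis=1)
        return np.where(totals > 0, self.confusion.diagonal() / np.maximum(totals, 1), 0.0)

    def summary(self) -> str:
        return (
            f"{self.mean_accuracy:.2f} +/- {self.std_accuracy:.2f}% "
            f"({self.classifier}, {self.folds}-fold x {self.repetitions})"
        )


def _check_labels(y: np.ndarray, folds: int) -> None:
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("need at least two classes")
    if counts.min() < folds:
        raise ValueError(
            f"smallest class has {counts.min()} samples, fewer than {folds} folds"
        )


def cross_validate(
    X,
    y,
    classifier: str = "nearest_neighbour",
    folds: int = 10,
    repetitions: int = 100,
    seed=None,
    classifier_params: dict | None = None,
) -> ExperimentResult:
    """Repeated stratified k-fold CV; accuracy pooled over folds per repetition.

    The reported std is across repetitions (each with a fresh random fold
    assignment), matching the protocol where only the fold assignment is
    re-randomized between runs.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    _check_labels(y, folds)
    classes = np.unique(y)
    rng = np.random.default_rng(seed)
    accs = np.empty(repetitions)
    conf = np.zeros((classes.size, classes.size), dtype=np.int64)
    for rep in range(repetitions):
        skf = StratifiedKFold(
            n_splits=folds, shuffle=True, random_state=int(rng.integers(0, 2**31))
        )
        pred = np.empty_like(y)
        for train, test in skf.split(X, y):
            clf = make_classifier(classifier, **(classifier_params or {}))
            clf.fit(X[train], y[train])
            pred[test] = clf.predict(X[test])
        accs[rep] = accuracy_score(y, pred) * 100.0
        conf += confusion_matrix(y, pred, labels=classes)
    return ExperimentResult(accs, conf, classes.tolist(), folds, repetitions, classifier)


def resampled_validate(
    X,
    y,
    classifier: str = "nearest_neighbour",
    folds: int = 3,
    configurations: int = 100,
    seed=None,
    classifier_params: dict | None = None,
) -> ExperimentResult:
    """Class-balanced resampling CV for unbalanced datasets.

    Each configuration subsamples every class down to the smallest class
    size, then runs one stratified ``folds``-fold CV; accuracy is
    aggregated over configurations.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("need at least two classes")
    n_min = counts.min()
    if n_min < folds:
        raise ValueError(f"smallest class has {n_min} samples, fewer than {folds} folds")
    rng = np.random.default_rng(seed)
    accs = np.empty(configurations)
    conf = np.zeros((classes.size, classes.size), dtype=np.int64)
    for cfg in range(configurations):
        idx = np.concatenate(
            [
                rng.choice(np.flatnonzero(y == c), size=n_min, replace=False)
                for c in classes
            ]
        )
        Xs, ys = X[idx], y[idx]
        skf = StratifiedKFold(
            n_splits=folds, shuffle=True, random_state=int(rng.integers(0, 2**31))
        )
        pred = np.empty_like(ys)
        for train, test in skf.split(Xs, ys):
            clf = make_classifier(classifier, **(classifier_params or {}))
            clf.fit(Xs[train], ys[train])
            pred[test] = clf.predict(Xs[test])
        accs[cfg] = accuracy_score(ys, pred) * 100.0
        conf += confusion_matrix(ys, pred, labels=classes)
    return ExperimentResult(
        accs, conf, classes.tolist(), folds, configurations, classifier
    )


def evolve_and_measure(
    networks: list[LabeledNetwork],
    rule: LifeLikeRule | str,
    t: int = 350,
    sigma: float = 0.5,
    include_initial: bool = True,
    lz_normalization: str = "rate",
):
    """Evolve every network with its own seed and measure the diagrams.

    The per-network evolution seed is derived from the network's stored
    generation seed, so rule comparisons are paired: two rules see the
    same initial configurations.
    """
    if isinstance(rule, str):
        rule = parse_rule(rule)
    out = []
    for ln in networks:
        diagram = evolve(rule, ln.net, t=t, sigma=sigma, seed=ln.seed + 2**31)
        out.append(
            measure_diagram(
                diagram,
                include_initial=include_initial,
                lz_normalization=lz_normalization,
            )
        )
    return out


def llna_features(
    networks: list[LabeledNetwork],
    rule: LifeLikeRule | str,
    t: int = 350,
    sigma: float = 0.5,
    variant: str = "combined",
    group_max: float | None = None,
    include_initial: bool = True,
) -> np.ndarray:
    """End-to-end descriptor matrix: evolve -> measure -> histogram features."""
    measures = evolve_and_measure(networks, rule, t=t, sigma=sigma, include_initial=include_initial)
    return feat.feature_matrix(measures, variant=variant, group_max=group_max)


@dataclass
class RuleScanEntry:
    rule: LifeLikeRule
    mean_accuracy: float
    std_accuracy: float


def rule_scan(
    rules,
    networks: list[LabeledNetwork],
    feature: str = "h_s",
    classifier: str = "nearest_neighbour",
    t: int = 350,
    sigma: float = 0.5,
    folds: int = 10,
    repetitions: int = 10,
    seed: int = 0,
) -> list[RuleScanEntry]:
    """Score every rule by the CV accuracy of its descriptor; rank descending.

    Per-network evolution seeds are fixed across rules (paired comparison).
    Ties break by ascending canonical rule mask so the ranking is
    deterministic and checkpointable.
    """
    y = np.array([ln.label for ln in networks])
    entries = []
    for rule in rules:
        if isinstance(rule, str):
            rule = parse_rule(rule)
        X = llna_features(networks, rule, t=t, sigma=sigma, variant=feature)
        res = cross_validate(
            X, y, classifier=classifier, folds=folds, repetitions=repetitions, seed=seed
        )
        entries.append(RuleScanEntry(rule, res.mean_accuracy, res.std_accuracy))
    entries.sort(key=lambda e: (-e.mean_accuracy, e.rule.mask))
    return entries


def top_rules(entries: list[RuleScanEntry], n: int = 10) -> list[LifeLikeRule]:
    return [e.rule for e in entries[:n]]


@dataclass
class ExperimentConfig:
    """Everything needed to rerun one classification experiment."""

    rule: str
    t: int = 350
    sigma: float = 0.5
    feature: str = "combined"
    classifier: str = "max_margin"
    folds: int = 10
    repetitions: int = 10
    seed: int = 0
    include_initial: bool = True
    label_by: str = "label"  # or "model_k": class = (model, <k>) pair
    classifier_params: dict = field(default_factory=dict)


def experiment_labels(networks: list[LabeledNetwork], label_by: str = "label") -> np.ndarray:
    if label_by == "label":
        return np.array([ln.label for ln in networks])
    if label_by == "model_k":
        return np.array([f"{ln.label}_k{ln.mean_degree:g}" for ln in networks])
    raise ValueError(f"unknown labeling {label_by!r}")


def run_experiment(
    config: ExperimentConfig, networks: list[LabeledNetwork]
) -> ExperimentResult:
    """Full pipeline: evolve -> measure -> featurize -> repeated CV."""
    y = experiment_labels(networks, config.label_by)
    X = llna_features(
        networks,
        config.rule,
        t=config.t,
        sigma=config.sigma,
        variant=config.feature,
        include_initial=config.include_initial,
    )
    return cross_validate(
        X,
        y,
        classifier=config.classifier,
        folds=config.folds,
        repetitions=config.repetitions,
        seed=config.seed,
        classifier_params=config.classifier_params,
    )
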