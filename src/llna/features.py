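"""Fixed-length histogram descriptors built from spatio-temporal measures.

Each network is summarized by three 20-bin histograms — Shannon entropy
over [0, 1], word lengths 1-40 with bin width 2, and Lempel-Ziv complexity
over [0, group_max] — their 60-value concatenation, and the three average
measurements [<mu_S>, <mu_W>, <mu_L>].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .measures import MeasureSet

N_BINS = 20
WORD_CAP = 40

VARIANTS = ("h_s", "h_w", "h_l", "combined", "averages")


@dataclass
class FeatureVector:
    h_s: np.ndarray
    h_w: np.ndarray
    h_l: np.ndarray
    combined: np.ndarray
    averages: np.ndarray

    def get(self, variant: str) -> np.ndarray:
        if variant not in VARIANTS:
            raise ValueError(f"unknown feature variant {variant!r}; use one of {VARIANTS}")
        return getattr(self, variant)


def entropy_histogram(values) -> np.ndarray:
    """20 relative frequencies over [0, 1]; the last bin is closed at 1."""
    v = np.asarray(values, dtype=float)
    if v.size and (v.min() < 0 or v.max() > 1):
        raise ValueError("entropy values must lie in [0, 1]")
    counts, _ = np.histogram(v, bins=N_BINS, range=(0.0, 1.0))
    return _relative(counts)


def word_histogram(word_lengths) -> np.ndarray:
    """20 relative frequencies over lengths {1-2}, {3-4}, ..., {39-40}.

    Words longer than 40 are discarded before normalization (their
    frequency is negligible for the adopted evolution lengths); if no word
    survives the cap the histogram is all zeros.
    """
    w = np.asarray(word_lengths, dtype=np.int64)
    if w.size and w.min() < 1:
        raise ValueError("word lengths must be positive integers")
    w = w[w <= WORD_CAP]
    idx = (w - 1) // 2
    counts = np.bincount(idx, minlength=N_BINS)[:N_BINS]
    return _relative(counts)


def lz_histogram(values, group_max: float) -> np.ndarray:
    """20 relative frequencies over [0, group_max].

    group_max is the maximum LZ value over the group of samples being
    described (fit once per dataset group and reused, so histograms of
    different networks share the binning); values above group_max fall
    into the last bin.
    """
    if group_max <= 0:
        raise ValueError("group_max must be positive")
    v = np.asarray(values, dtype=float)
    if v.size and v.min() < 0:
        raise ValueError("LZ values must be non-negative")
    idx = np.minimum((v / group_max * N_BINS).astype(np.int64), N_BINS - 1)
    counts = np.bincount(idx, minlength=N_BINS)[:N_BINS]
    return _relative(counts)


def lz_group_max(measure_sets) -> float:
    """Maximum node LZ value over a group of MeasureSets."""
    return float(max(ms.node_lz.max() for ms in measure_sets))


def _relative(counts: np.ndarray) -> np.ndarray:
    total = counts.sum()
    if total == 0:
        return np.zeros(N_BINS)
    return counts / total


def assemble(measures: MeasureSet, group_max: float) -> FeatureVector:
    """Build all descriptor variants for one diagram's measures."""
    h_s = entropy_histogram(measures.node_entropy)
    h_w = word_histogram(measures.word_lengths)
    h_l = lz_histogram(measures.node_lz, group_max)
    averages = np.array(
        [
            measures.node_entropy.mean(),
            measures.word_lengths.mean() if measures.word_lengths.size else 0.0,
            measures.node_lz.mean(),
        ]
    )
    return FeatureVector(
        h_s=h_s,
        h_w=h_w,
        h_l=h_l,
        combined=np.concatenate([h_s, h_w, h_l]),
        averages=averages,
    )


def feature_matrix(measure_sets, variant: str = "combined", group_max=None) -> np.ndarray:
    """Stack one descriptor row per MeasureSet.

    If group_max is not given it is fit on the supplied group (the
    maximum LZ value achieved among the group of samples).
    """
    measure_sets = list(measure_sets)
    if group_max is None:
        group_max = lz_group_max(measure_sets)
    return np.vstack([assemble(ms, group_max).get(variant) for ms in measure_sets])


def feature_names(variant: str = "combined") -> list[str]:
    names = {
        "h_s": [f"hS_{i:02d}" for i in range(N_BINS)],
        "h_w": [f"hW_{i:02d}" for i in range(N_BINS)],
        "h_l": [f"hL_{i:02d}" for i in range(N_BINS)],
        "averages": ["muS", "muW", "muL"],
    }
    names["combined"] = names["h_s"] + names["h_w"] + names["h_l"]
    if variant not in names:
        raise ValueError(f"unknown feature variant {variant!r}")
    return names[variant]
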