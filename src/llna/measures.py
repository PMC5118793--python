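"""Spatio-temporal measurements of a space-time diagram.

Three quantities summarize each diagram: the per-node Shannon entropy of
the binary time series, the per-node Lempel-Ziv complexity (incremental
dictionary block count, normalized), and the pooled word-length
distribution (a word is a maximal run of ones), which is a global
measurement over the whole diagram.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .automaton import SpaceTimeDiagram


@dataclass
class MeasureSet:
    """Per-node entropy/LZ values plus pooled word lengths for one diagram."""

    node_entropy: np.ndarray
    node_lz: np.ndarray
    word_lengths: np.ndarray
    lz_block_counts: np.ndarray = field(default=None)  # raw g per node

    def __post_init__(self) -> None:
        self.node_entropy = np.asarray(self.node_entropy, dtype=float)
        self.node_lz = np.asarray(self.node_lz, dtype=float)
        self.word_lengths = np.asarray(self.word_lengths, dtype=np.int64)


def _as_binary(series) -> np.ndarray:
    s = np.asarray(series, dtype=np.uint8).ravel()
    if s.size and not np.isin(s, (0, 1)).all():
        raise ValueError("series must be binary")
    return s


def shannon_entropy(series) -> float:
    """Binary Shannon entropy -p0*log2(p0) - p1*log2(p1), in [0, 1] bits."""
    s = _as_binary(series)
    if s.size == 0:
        raise ValueError("series must be non-empty")
    p1 = s.mean()
    return float(_binary_entropy(np.asarray(p1)))


def _binary_entropy(p1: np.ndarray) -> np.ndarray:
    p0 = 1.0 - p1
    with np.errstate(divide="ignore", invalid="ignore"):
        h = -np.where(p0 > 0, p0 * np.log2(p0), 0.0) - np.where(
            p1 > 0, p1 * np.log2(p1), 0.0
        )
    return np.clip(h, 0.0, 1.0)


def extract_words(series) -> np.ndarray:
    """Lengths of maximal runs of ones ("words"), e.g. 0011101100 -> [3, 2].

    Runs touching the sequence ends count as words, so the lengths always
    sum to the number of ones in the series.
    """
    s = _as_binary(series)
    padded = np.concatenate(([0], s, [0])).astype(np.int8)
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return (ends - starts).astype(np.int64)


def lempel_ziv_blocks(series) -> tuple[list[str], int]:
    """Incremental-dictionary decomposition of a binary sequence.

    Scanning left to right, each block is the shortest prefix of the
    remaining sequence not yet in the dictionary (an existing block plus
    one symbol).  A trailing remainder that already matches a dictionary
    block is not counted.  E.g. 01010101010101010101 decomposes into
    0|1|01|010|10|101|0101 with g = 7 blocks.
    """
    s = _as_binary(series)
    if s.size == 0:
        raise ValueError("series must be non-empty")
    blocks: list[str] = []
    trie: dict[int, int] = {}
    node = 0
    next_id = 1
    start = 0
    for pos, sym in enumerate(s):
        key = node * 2 + int(sym)
        child = trie.get(key)
        if child is not None:
            node = child
        else:
            trie[key] = next_id
            next_id += 1
            blocks.append("".join(str(int(b)) for b in s[start : pos + 1]))
            node = 0
            start = pos + 1
    return blocks, len(blocks)


def _lz_block_count(s: np.ndarray) -> int:
    # count-only fast path of lempel_ziv_blocks
    trie: dict[int, int] = {}
    node = 0
    next_id = 1
    g = 0
    get = trie.get
    for sym in s:
        key = node * 2 + sym
        child = get(key)
        if child is not None:
            node = child
        else:
            trie[key] = next_id
            next_id += 1
            g += 1
            node = 0
    return g


def lempel_ziv_complexity(series, normalization: str = "rate") -> float:
    """Normalized Lempel-Ziv complexity of a binary sequence.

    With the default ``"rate"`` normalization the block count g is divided
    by l / log2(l), the asymptotic block count of a random sequence of
    length l; ``"raw"`` returns g itself.  Requires l >= 2.
    """
    s = _as_binary(series)
    if s.size < 2:
        raise ValueError("series must have length >= 2")
    g = _lz_block_count(s.astype(np.int64))
    return _normalize_lz(g, s.size, normalization)


def _normalize_lz(g, l: int, normalization: str):
    if normalization == "rate":
        return g * np.log2(l) / l
    if normalization == "raw":
        return g if np.ndim(g) else float(g)
    raise ValueError(f"unknown LZ normalization {normalization!r}")


def measure_diagram(
    diagram: SpaceTimeDiagram,
    include_initial: bool = True,
    lz_normalization: str = "rate",
) -> MeasureSet:
    """Compute entropy and LZ per node column, pooled word lengths globally.

    ``include_initial`` controls whether the t=0 row enters the node
    series (default yes, so series have length t+1); flipping it allows
    comparing both conventions.
    """
    m = diagram.matrix if include_initial else diagram.matrix[1:]
    if m.shape[0] < 2:
        raise ValueError("need at least 2 time rows to measure a diagram")
    n = m.shape[1]
    entropy = _binary_entropy(m.mean(axis=0))

    cols = np.ascontiguousarray(m.T).astype(np.int64)
    g = np.fromiter(
        (_lz_block_count(col) for col in cols), dtype=np.int64, count=n
    )
    lz = _normalize_lz(g.astype(float), m.shape[0], lz_normalization)

    # words: pad with zero rows so runs never cross column boundaries
    z = np.zeros((1, n), dtype=np.uint8)
    flat = np.vstack([z, m, z]).ravel(order="F").astype(np.int8)
    d = np.diff(flat)
    words = (np.flatnonzero(d == -1) - np.flatnonzero(d == 1)).astype(np.int64)

    return MeasureSet(
        node_entropy=entropy,
        node_lz=np.asarray(lz, dtype=float),
        word_lengths=words,
        lz_block_counts=g,
    )
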