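"""File formats and result records.

Graphs are read/written as whitespace-delimited edge lists (0-based ids,
``#`` comments) or GraphML; space-time diagrams export to portable graymap
(white = alive) or PNG; experiment results serialize to JSON with full
provenance (config hash, seeds) plus CSV tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .automaton import NetworkTessellation, SpaceTimeDiagram
from .classify import ExperimentResult
from .features import feature_names
from .measures import MeasureSet

logger = logging.getLogger("llna")


def read_network(path, fmt: str | None = None) -> NetworkTessellation:
    """Read a graph from an edge-list or GraphML file.

    Format is inferred from the extension unless given.  Inputs are
    coerced to simple undirected graphs: self-loops are dropped and
    directed/weighted structure is symmetrized/binarized, with a warning.
    """
    path = Path(path)
    fmt = fmt or ("graphml" if path.suffix == ".graphml" else "edge_list")
    if fmt == "graphml":
        g = nx.read_graphml(path)
        if g.is_directed():
            logger.warning("%s: directed graph symmetrized", path)
            g = g.to_undirected()
        net = NetworkTessellation.from_networkx(nx.Graph(g))
    elif fmt == "edge_list":
        edges = []
        max_node = -1
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                text = line.split("#", 1)[0].strip()
                if not text:
                    continue
                parts = text.split()
                if len(parts) < 2:
                    raise ValueError(f"{path}:{lineno}: expected two node ids, got {text!r}")
                try:
                    u, v = int(parts[0]), int(parts[1])
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: non-integer node id in {text!r}") from exc
                if u < 0 or v < 0:
                    raise ValueError(f"{path}:{lineno}: node ids must be >= 0")
                if u == v:
                    logger.warning("%s:%d: self-loop on node %d dropped", path, lineno, u)
                    continue
                edges.append((u, v))
                max_node = max(max_node, u, v)
        if max_node < 0:
            raise ValueError(f"{path}: no edges found")
        net = NetworkTessellation(max_node + 1, edges)
    else:
        raise ValueError(f"unknown graph format {fmt!r}")
    if net.n_edges == 0:
        raise ValueError(f"{path}: graph has no edges")
    return net


def write_network(net: NetworkTessellation, path, fmt: str | None = None) -> None:
    path = Path(path)
    fmt = fmt or ("graphml" if path.suffix == ".graphml" else "edge_list")
    if fmt == "graphml":
        nx.write_graphml(net.to_networkx(), path)
    elif fmt == "edge_list":
        with open(path, "w") as fh:
            fh.write(f"# {net.n_nodes} nodes, {net.n_edges} edges\n")
            for u, v in sorted(net.edges):
                fh.write(f"{u} {v}\n")
    else:
        raise ValueError(f"unknown graph format {fmt!r}")


def write_diagram(
    diagram: SpaceTimeDiagram, path, net: NetworkTessellation | None = None
) -> None:
    """Export a diagram as PGM/PNG (white = alive) or a raw text matrix.

    If a network is given, columns are ordered by ascending degree — a
    visualization convention only.
    """
    path = Path(path)
    m = diagram.ordered_by_degree(net) if net is not None else diagram.matrix
    img = (m * 255).astype(np.uint8)
    if path.suffix == ".pgm":
        with open(path, "w") as fh:
            fh.write(f"P2\n{img.shape[1]} {img.shape[0]}\n255\n")
            for row in img:
                fh.write(" ".join(map(str, row)) + "\n")
    elif path.suffix == ".png":
        try:
            from PIL import Image
        except ImportError as exc:  # pragma: no cover
            raise RuntimeError("PNG export needs pillow; use .pgm instead") from exc
        Image.fromarray(img, mode="L").save(path)
    else:
        np.savetxt(path, diagram.matrix, fmt="%d")


def write_measures(measures: MeasureSet, path) -> None:
    """Per-node entropy/LZ CSV plus a word-length count table alongside."""
    path = Path(path)
    pd.DataFrame(
        {
            "node": np.arange(measures.node_entropy.size),
            "entropy": measures.node_entropy,
            "lz": measures.node_lz,
        }
    ).to_csv(path, index=False)
    lengths, counts = np.unique(measures.word_lengths, return_counts=True)
    pd.DataFrame({"word_length": lengths, "count": counts}).to_csv(
        path.with_name(path.stem + "_words.csv"), index=False
    )


def write_feature_matrix(
    X: np.ndarray, labels, path, variant: str = "combined", columns=None
) -> None:
    """Feature CSV: one row per network, named columns plus a label column.

    ``columns`` overrides the LLNA descriptor names, e.g. with
    ``llna.structural.FEATURE_NAMES`` for a baseline matrix aligned to the
    same manifest.
    """
    df = pd.DataFrame(X, columns=columns or feature_names(variant))
    df["label"] = list(labels)
    df.to_csv(path, index=False)


def write_dataset(networks, directory) -> "pd.DataFrame":
    """Write labeled networks as edge-list files plus a manifest CSV.

    The manifest records (file, label, model, mean_degree, n_nodes,
    replicate, seed) so any experiment can be rerun from disk.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, ln in enumerate(networks):
        fname = f"net_{i:05d}_{ln.model}_k{ln.mean_degree:g}_n{ln.n_nodes}_r{ln.replicate}.edges"
        write_network(ln.net, directory / fname)
        rows.append(
            {
                "file": fname,
                "label": ln.label,
                "model": ln.model,
                "mean_degree": ln.mean_degree,
                "n_nodes": ln.n_nodes,
                "replicate": ln.replicate,
                "seed": ln.seed,
            }
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(directory / "manifest.csv", index=False)
    return manifest


def config_hash(config) -> str:
    """Stable hash of a config (dataclass or dict); changes with any field."""
    if dataclasses.is_dataclass(config):
        config = dataclasses.asdict(config)
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_results(result: ExperimentResult, path, config=None) -> dict:
    """JSON result record with provenance; returns the written manifest."""
    path = Path(path)
    record = {
        "mean_accuracy": result.mean_accuracy,
        "std_accuracy": result.std_accuracy,
        "accuracies": result.accuracies.tolist(),
        "confusion": result.confusion.tolist(),
        "classes": [str(c) for c in result.classes],
        "folds": result.folds,
        "repetitions": result.repetitions,
        "classifier": result.classifier,
    }
    if config is not None:
        record["config"] = (
            dataclasses.asdict(config) if dataclasses.is_dataclass(config) else dict(config)
        )
        record["config_hash"] = config_hash(config)
    with open(path, "w") as fh:
        json.dump(record, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return record


def read_results(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
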