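"""Disease-network construction from a confidence-scored PPI edge list.

Edges below the confidence threshold are dropped (STRING-style scores on the
0–999 integer scale are normalized by 1000 first), the graph is induced on
the upregulated protein-coding genes, isolated nodes are optionally removed,
and per-node topology statistics (degree, component, normalized-degree hub
score) are computed for the downstream drug selector.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

from .errors import ConfigurationError, InputError


@dataclass(frozen=True)
class NetworkConfig:
    """Confidence filter settings.

    ``score_scale``: "unit" for confidences already in [0, 1], "string999"
    for integer scores in [0, 999] (divided by 1000 on load), or "auto" to
    infer the scale (any value > 1 implies string999; mixed scales error).
    The comparison is keep-if->=, so an edge at exactly the threshold stays.
    """

    min_confidence: float = 0.85
    score_scale: str = "auto"
    drop_isolated: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_confidence <= 1.0:
            raise ConfigurationError(
                f"min_confidence must lie in [0, 1], got {self.min_confidence!r}"
            )
        if self.score_scale not in ("unit", "string999", "auto"):
            raise ConfigurationError(
                f"score_scale must be 'unit', 'string999' or 'auto', got {self.score_scale!r}"
            )


def _normalize_confidences(edges: pd.DataFrame, scale: str) -> pd.Series:
    conf = pd.to_numeric(edges["confidence"], errors="coerce")
    if conf.isna().any():
        row = int(conf.index[conf.isna()][0])
        raise InputError(f"non-numeric confidence in edge row {row}")
    if scale == "auto":
        above_one = conf > 1.0
        scale = "string999" if above_one.any() else "unit"
        if scale == "string999" and not above_one.all():
            # Heuristic cannot separate a genuine mixed-scale file from a
            # string999 file that happens to contain scores <= 1; only
            # fractional sub-unity values are unambiguous evidence of mixing.
            fractional = (conf <= 1.0) & (conf != conf.round())
            if fractional.any():
                row = int(conf.index[fractional][0])
                raise InputError(
                    f"mixed confidence scales: fractional value in edge row {row} "
                    "alongside scores > 1"
                )
    if scale == "string999":
        out_of_range = (conf < 0) | (conf > 999)
        if out_of_range.any():
            row = int(conf.index[out_of_range][0])
            raise InputError(f"string999 confidence out of [0, 999] in edge row {row}")
        return conf / 1000.0
    out_of_range = (conf < 0) | (conf > 1)
    if out_of_range.any():
        row = int(conf.index[out_of_range][0])
        raise InputError(f"confidence out of [0, 1] in edge row {row}")
    return conf


def build_network(
    edges: pd.DataFrame,
    keep_nodes: Iterable[str] | None = None,
    cfg: NetworkConfig | None = None,
) -> nx.Graph:
    """Filter, induce, and clean the PPI graph.

    ``edges`` needs columns node_a, node_b, confidence. ``keep_nodes``
    restricts the graph to those nodes (both endpoints must be kept);
    ``None`` keeps everything. Self-loops are discarded; duplicate edges
    collapse to the highest-confidence record.
    """
    cfg = cfg or NetworkConfig()
    required = {"node_a", "node_b", "confidence"}
    if not required.issubset(edges.columns):
        raise InputError(f"edge list must have columns {sorted(required)}")
    conf = _normalize_confidences(edges, cfg.score_scale)

    keep = set(map(str, keep_nodes)) if keep_nodes is not None else None
    graph = nx.Graph()
    if keep is not None:
        graph.add_nodes_from(keep)
    for (a, b, c) in zip(edges["node_a"].astype(str), edges["node_b"].astype(str), conf):
        if a == b:
            continue
        if c < cfg.min_confidence:
            continue
        if keep is not None and (a not in keep or b not in keep):
            continue
        if graph.has_edge(a, b):
            graph[a][b]["confidence"] = max(graph[a][b]["confidence"], float(c))
        else:
            graph.add_edge(a, b, confidence=float(c))
    if keep is None:
        # Without an explicit node list the graph is just the filtered edges
        # plus any endpoints; nothing else to add.
        pass
    if cfg.drop_isolated:
        graph.remove_nodes_from(list(nx.isolates(graph)))
    assert all(d["confidence"] >= cfg.min_confidence for _, _, d in graph.edges(data=True))
    return graph


def node_stats(net: nx.Graph) -> pd.DataFrame:
    """Per-node degree, component id, and hub score.

    Components are numbered in decreasing size order (ties broken by their
    smallest node id); hub_score is degree / max degree (0 on an edgeless
    graph).
    """
    nodes = sorted(net.nodes())
    degrees = dict(net.degree())
    max_degree = max(degrees.values(), default=0)
    components = sorted(
        (frozenset(c) for c in nx.connected_components(net)),
        key=lambda c: (-len(c), min(c)),
    )
    comp_of = {node: i for i, comp in enumerate(components) for node in comp}
    return pd.DataFrame(
        {
            "node": nodes,
            "degree": [degrees[n] for n in nodes],
            "component_id": [comp_of[n] for n in nodes],
            "hub_score": [
                degrees[n] / max_degree if max_degree > 0 else 0.0 for n in nodes
            ],
        }
    )


def top_hubs(stats: pd.DataFrame, k: int) -> list[str]:
    """The k highest-hub-score nodes; ties broken lexicographically by id."""
    if k < 0:
        raise InputError(f"k must be >= 0, got {k}")
    ranked = sorted(
        zip(stats["node"], stats["hub_score"]), key=lambda t: (-t[1], t[0])
    )
    if k > len(ranked):
        warnings.warn(
            f"k={k} exceeds node count {len(ranked)}; returning all nodes",
            stacklevel=2,
        )
        k = len(ranked)
    return [node for node, _ in ranked[:k]]


# -- I/O --------------------------------------------------------------------

def read_edges_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"node_a": str, "node_b": str})


def write_network_tsv(net: nx.Graph, path: str | Path) -> None:
    rows = [
        {"node_a": min(a, b), "node_b": max(a, b), "confidence": d["confidence"]}
        for a, b, d in net.edges(data=True)
    ]
    frame = pd.DataFrame(rows, columns=["node_a", "node_b", "confidence"])
    frame.sort_values(["node_a", "node_b"]).to_csv(path, sep="\t", index=False)


def write_graphml(net: nx.Graph, path: str | Path) -> None:
    """GraphML export for interactive inspection (e.g., in Cytoscape)."""
    nx.write_graphml(net, str(path))


def read_graphml(path: str | Path) -> nx.Graph:
    return nx.read_graphml(str(path))


def write_node_stats_tsv(stats: pd.DataFrame, path: str | Path) -> None:
    stats.to_csv(path, sep="\t", index=False)
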