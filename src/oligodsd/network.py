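"""Gene/protein interaction graph and MAMLD1-anchored connectivity.

Edges come from a trimmed protein-interaction export (tab-separated
``node1  node2  combined_score  channels``): an undirected graph whose edge
confidence is the combined score in [0, 1] and whose channel labels record
the evidence type (curated, experimental, neighborhood, fusion, cooccurrence,
textmining, coexpression, homology).  The packaged fixture transcribes the
connectivity reported for the 41-gene cohort around the MAMLD1 anchor.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Iterable

import networkx as nx

from .panel import normalize_symbol

CHANNELS = frozenset(
    {
        "curated",
        "experimental",
        "neighborhood",
        "fusion",
        "cooccurrence",
        "textmining",
        "coexpression",
        "homology",
    }
)

DEFAULT_MIN_SCORE = 0.4  # conventional medium-confidence cutoff


class EdgeFileError(ValueError):
    """Malformed interaction edge file."""


def load_edges(
    path: str | Path,
    min_score: float = DEFAULT_MIN_SCORE,
    declared_nodes: Iterable[str] | None = None,
) -> nx.Graph:
    """Load an interaction edge list, dropping edges below ``min_score``.

    Symbols are normalized like panel symbols; declared nodes without any
    retained edge remain in the graph as isolated nodes.
    """
    if not (0.0 <= min_score <= 1.0):
        raise EdgeFileError(f"min_score {min_score} outside [0, 1]")
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    if not lines:
        raise EdgeFileError(f"{path}: empty file, header required")
    header = lines[0].split("\t")
    required = ["node1", "node2", "combined_score", "channels"]
    if header[: len(required)] != required:
        raise EdgeFileError(f"{path}: header must start with {required}")
    graph = nx.Graph()
    if declared_nodes:
        graph.add_nodes_from(normalize_symbol(n) for n in declared_nodes)
    for lineno, raw in enumerate(lines[1:], start=2):
        if not raw.strip():
            continue
        cells = raw.split("\t")
        if len(cells) < 4:
            raise EdgeFileError(f"{path}:{lineno}: expected 4 columns")
        a, b = normalize_symbol(cells[0]), normalize_symbol(cells[1])
        if a == b:
            raise EdgeFileError(f"{path}:{lineno}: self-loop on {a}")
        score = float(cells[2])
        if not (0.0 <= score <= 1.0):
            raise EdgeFileError(
                f"{path}:{lineno}: combined_score {score} outside [0, 1]"
            )
        channels = frozenset(c.strip() for c in cells[3].split("|") if c.strip())
        unknown = channels - CHANNELS
        if unknown:
            raise EdgeFileError(
                f"{path}:{lineno}: unknown channel(s) {sorted(unknown)}"
            )
        if score < min_score:
            continue
        graph.add_edge(a, b, combined_score=score, channels=channels)
    return graph


def write_edges(graph: nx.Graph, path: str | Path) -> None:
    path = Path(path)
    lines = ["node1\tnode2\tcombined_score\tchannels"]
    pairs = sorted((min(a, b), max(a, b)) for a, b in graph.edges)
    for a, b in pairs:
        data = graph.edges[a, b]
        score = data.get("combined_score", 1.0)
        channels = "|".join(sorted(data.get("channels", {"curated"})))
        lines.append(f"{a}\t{b}\t{score}\t{channels}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def load_interaction_fixture(min_score: float = DEFAULT_MIN_SCORE) -> nx.Graph:
    """The packaged cohort interaction graph (anchor MAMLD1)."""
    return load_edges(
        Path(str(resources.files("oligodsd").joinpath("data/interaction_edges.tsv"))),
        min_score=min_score,
    )


def component_of(graph: nx.Graph, anchor: str) -> set[str]:
    """Connected component containing ``anchor`` (anchor itself excluded)."""
    anchor = normalize_symbol(anchor)
    if anchor not in graph:
        raise KeyError(f"anchor {anchor!r} not in graph")
    return set(nx.node_connected_component(graph, anchor)) - {anchor}


def connected_genes(graph: nx.Graph, genes: Iterable[str]) -> set[str]:
    """Members of ``genes`` incident to at least one retained edge."""
    result = set()
    for gene in genes:
        g = normalize_symbol(gene)
        if g in graph and graph.degree(g) >= 1:
            result.add(g)
    return result


def patient_subnetwork(
    graph: nx.Graph, patient_genes: Iterable[str], anchor: str = "MAMLD1"
) -> tuple[nx.Graph, list[str]]:
    """Induced subgraph on a patient's genes plus the anchor.

    Returns the induced subgraph (every requested gene is a node, with or
    without edges) and the sorted list of nodes with zero induced degree —
    the genes drawn apart as connectionless in per-patient network figures.
    """
    nodes = {normalize_symbol(g) for g in patient_genes} | {normalize_symbol(anchor)}
    sub = nx.Graph()
    sub.add_nodes_from(nodes)
    present = nodes & set(graph.nodes)
    sub.add_edges_from(
        (a, b, d) for a, b, d in graph.subgraph(present).edges(data=True)
    )
    isolated = sorted(n for n in sub.nodes if sub.degree(n) == 0)
    return sub, isolated


def network_report(
    graph: nx.Graph, genes: Iterable[str], anchor: str = "MAMLD1"
) -> dict:
    """Anchor-component membership and connectivity over a gene set."""
    genes = {normalize_symbol(g) for g in genes}
    comp = component_of(graph, anchor) if normalize_symbol(anchor) in graph else set()
    connected = connected_genes(graph, genes)
    return {
        "anchor": normalize_symbol(anchor),
        "anchor_component": sorted(comp),
        "anchor_component_size": len(comp),
        "n_genes": len(genes),
        "connected_genes": sorted(connected),
        "n_connected": len(connected),
        "isolated_genes": sorted(genes - connected),
    }
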