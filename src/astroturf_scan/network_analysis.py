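"""Directed retweet-network construction and tie analysis.

Edges point from the information source to the retweeter (A→B means B
retweeted A), so information flow and edge direction coincide.  Outdegree
counts *distinct* retweeters; the number of retweet events along an edge is
kept separately as the edge weight.  Asymmetric ties (reverse edge absent)
are weak links that facilitate dissemination; mutual ties are rare, strong
links worth inspecting individually, so they are reported as explicit pairs.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

from .retweet_resolution import RetweetResolution

logger = logging.getLogger(__name__)


def build_network(
    resolution: Sequence[RetweetResolution], authors: Iterable[str]
) -> nx.DiGraph:
    """Build the directed retweet graph from a resolved corpus.

    Every corpus author is a node (originals contribute nodes only); every
    retweet event with source ``s`` and retweeter ``r`` adds 1 to the weight
    of edge ``s``→``r``.  Self-retweets are dropped with a log entry — they
    carry no dissemination information.
    """
    g = nx.DiGraph()
    g.add_nodes_from(sorted(set(authors)))
    n_self = 0
    for res in resolution:
        g.add_node(res.author)
        g.add_node(res.source_author)
        if res.status == "original":
            continue
        s, r = res.source_author, res.author
        if s == r:
            n_self += 1
            continue
        if g.has_edge(s, r):
            g[s][r]["weight"] += 1
        else:
            g.add_edge(s, r, weight=1)
    if n_self:
        logger.info("dropped %d self-retweet event(s)", n_self)
    return g


def classify_ties(network: nx.DiGraph) -> tuple[int, int, list[tuple[str, str]]]:
    """Count asymmetric ties and mutual pairs.

    An unordered pair {u, v} is mutual iff both u→v and v→u exist; an
    ordered edge is asymmetric iff its reverse is absent.  Hence
    ``n_asymmetric + 2 * n_mutual`` equals the ordered-edge count.
    """
    mutual = {
        tuple(sorted((u, v)))
        for u, v in network.edges
        if network.has_edge(v, u)
    }
    n_mutual = len(mutual)
    n_asymmetric = network.number_of_edges() - 2 * n_mutual
    return n_asymmetric, n_mutual, sorted(mutual)


@dataclass
class CentralityReport:
    """Per-node degree measures plus network-level tie bookkeeping."""

    per_node: pd.DataFrame  # index handle; outdegree, indegree, out_events
    n_asymmetric: int
    n_mutual: int
    mutual_pairs: list[tuple[str, str]]
    isolates: list[str]

    @property
    def n_isolates(self) -> int:
        return len(self.isolates)


def centrality_report(network: nx.DiGraph) -> CentralityReport:
    nodes = sorted(network.nodes)
    rows = {
        "outdegree": [network.out_degree(n) for n in nodes],
        "indegree": [network.in_degree(n) for n in nodes],
        "out_events": [
            sum(d["weight"] for _, _, d in network.out_edges(n, data=True)) for n in nodes
        ],
    }
    per_node = pd.DataFrame(rows, index=pd.Index(nodes, name="handle"))
    n_asym, n_mut, pairs = classify_ties(network)
    isolates = sorted(nx.isolates(network))
    return CentralityReport(per_node, n_asym, n_mut, pairs, isolates)


def top_retweeted(report: CentralityReport, k: int) -> pd.DataFrame:
    """The k most-retweeted accounts by distinct retweeters.

    Sorted by outdegree descending, ties broken by handle ascending;
    ``k <= 0`` returns an empty frame, ``k`` beyond the node count returns
    everything.
    """
    if k <= 0:
        return report.per_node.iloc[0:0][["outdegree", "out_events"]]
    # index is already handle-ascending; a stable sort keeps that order on ties
    ranked = report.per_node.sort_index().sort_values(
        "outdegree", ascending=False, kind="mergesort"
    )
    return ranked.head(k)[["outdegree", "out_events"]]


# ---------------------------------------------------------------------------
# Exports


def write_pajek(network: nx.DiGraph, path: Path) -> None:
    """Pajek .net export: 1-indexed ``*Vertices`` then weighted ``*Arcs``."""
    nodes = sorted(network.nodes)
    index = {n: i + 1 for i, n in enumerate(nodes)}
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"*Vertices {len(nodes)}\n")
        for n in nodes:
            fh.write(f'{index[n]} "{n}"\n')
        fh.write("*Arcs\n")
        for u, v in sorted(network.edges):
            fh.write(f"{index[u]} {index[v]} {network[u][v]['weight']}\n")


def write_graphml(network: nx.DiGraph, path: Path) -> None:
    ordered = nx.DiGraph()
    ordered.add_nodes_from(sorted(network.nodes))
    ordered.add_edges_from(
        (u, v, d) for u, v, d in sorted(network.edges(data=True), key=lambda e: (e[0], e[1]))
    )
    nx.write_graphml(ordered, path)


def write_centrality_csv(report: CentralityReport, path: Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["handle", "outdegree", "indegree", "out_events"])
        for handle, row in report.per_node.iterrows():
            w.writerow([handle, row["outdegree"], row["indegree"], row["out_events"]])
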