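"""Layered gene-interaction networks and four-centrality gene ranking.

Classified interactions are assembled into an undirected, unweighted
network around a seed gene, in three nested layers: *generic* (every
extracted interaction), *concept* (only interactions from sentences that
mention the generic concept word, e.g. "vaccine"), and
*concept_ontology* (sentences mentioning either the generic word or a
specific ontology term).  Genes are ranked by degree, eigenvector,
closeness and betweenness centrality with competition ("1224") ranks.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import networkx as nx
import pandas as pd

from .corpus import GENERIC_VACCINE_TAG, VO_TERM_TAG_PREFIX
from .relations import ExtractedInteraction

__all__ = [
    "LAYERS",
    "GeneNetwork",
    "AnalysisConfig",
    "CentralityReport",
    "EigenvectorConvergenceError",
    "build_network",
    "centrality_report",
    "top_by_any",
    "write_edge_list",
    "read_edge_list",
    "write_graphml",
]

LAYERS = ("generic", "concept", "concept_ontology")

METRICS = ("degree", "eigenvector", "closeness", "betweenness")


class EigenvectorConvergenceError(RuntimeError):
    """Power iteration failed to converge; carries the residual message."""


@dataclass(frozen=True)
class AnalysisConfig:
    """Seed gene, ranking cut-off, and eigenvector solver settings."""

    seed_gene: str | None = None
    top_k: int = 20
    eigenvector_tol: float = 1e-10
    eigenvector_max_iter: int = 10_000

    def __post_init__(self) -> None:
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")


@dataclass
class GeneNetwork:
    """Undirected gene graph with per-edge sentence evidence and a layer tag.

    Edge evidence is a list of ``(document_id, sentence_index, tags)``
    records; multiplicity never weights centrality.
    """

    graph: nx.Graph
    layer: str = "generic"
    seed_gene: str | None = None

    def __post_init__(self) -> None:
        if self.layer not in LAYERS:
            raise ValueError(f"layer must be one of {LAYERS}, got {self.layer!r}")
        if any(u == v for u, v in self.graph.edges):
            raise ValueError("gene network must not contain self-loops")

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def edges(self) -> list[tuple[str, str]]:
        return sorted(tuple(sorted(e)) for e in self.graph.edges)

    def evidence(self, gene_a: str, gene_b: str) -> list[tuple[str, int, frozenset[str]]]:
        return list(self.graph.edges[gene_a, gene_b]["evidence"])


def _layer_keeps(layer: str, tags: frozenset[str]) -> bool:
    if layer == "generic":
        return True
    has_generic = GENERIC_VACCINE_TAG in tags
    if layer == "concept":
        return has_generic
    has_vo = any(t.startswith(VO_TERM_TAG_PREFIX) for t in tags)
    return has_generic or has_vo  # concept_ontology


def build_network(
    interactions: Iterable[ExtractedInteraction],
    layer: str = "generic",
    seed_gene: str | None = None,
) -> GeneNetwork:
    """Assemble a layer's network, restricted to the seed's neighborhood.

    Evidence from repeated extractions of a pair is aggregated on a
    single edge.  With a seed gene, the result keeps the seed and every
    node reachable from it; without one, the whole graph is kept.
    """
    if layer not in LAYERS:
        raise ValueError(f"layer must be one of {LAYERS}, got {layer!r}")
    g = nx.Graph()
    if seed_gene is not None:
        g.add_node(seed_gene)
    for inter in interactions:
        if inter.gene_a == inter.gene_b:
            continue
        if not _layer_keeps(layer, inter.context_tags):
            continue
        u, v = sorted((inter.gene_a, inter.gene_b))
        if not g.has_edge(u, v):
            g.add_edge(u, v, evidence=[])
        g.edges[u, v]["evidence"].append(
            (inter.document_id, inter.sentence_index, inter.context_tags)
        )
    if seed_gene is not None:
        keep = nx.node_connected_component(g, seed_gene)
        g = g.subgraph(keep).copy()
    return GeneNetwork(graph=g, layer=layer, seed_gene=seed_gene)


# ---------------------------------------------------------------------------
# centralities


def _eigenvector_scores(
    g: nx.Graph,
    tol: float,
    max_iter: int,
    nstart: dict | None = None,
) -> dict[str, float]:
    """Dominant-eigenvector centrality, computed per connected component.

    Each component with edges gets its L2-normalized Perron vector via
    power iteration; isolated nodes score 0.
    """
    scores: dict[str, float] = {}
    for comp in nx.connected_components(g):
        sub = g.subgraph(comp)
        if sub.number_of_edges() == 0:
            for node in comp:
                scores[node] = 0.0
            continue
        try:
            start = (
                {n: nstart[n] for n in sub} if nstart is not None else None
            )
            vec = nx.eigenvector_centrality(
                sub, max_iter=max_iter, tol=tol, nstart=start
            )
        except nx.PowerIterationFailedConvergence as exc:
            raise EigenvectorConvergenceError(
                f"eigenvector centrality did not converge within {max_iter} "
                f"iterations at tolerance {tol:g}: {exc}"
            ) from exc
        scores.update(vec)
    return scores


def centrality_report(
    net: GeneNetwork | nx.Graph,
    config: AnalysisConfig = AnalysisConfig(),
) -> pd.DataFrame:
    """Degree/eigenvector/closeness/betweenness scores and competition ranks.

    Degree is the raw neighbor count; closeness uses the
    Wasserman–Faust within-component scaling; betweenness is the
    unnormalized Brandes accumulation over unordered pairs.  The seed
    gene (when configured) is excluded from the ranked table, mirroring
    its trivial rank-1 position in a seed-centred network.
    """
    g = net.graph if isinstance(net, GeneNetwork) else net
    if g.number_of_nodes() == 0:
        raise ValueError("cannot rank an empty network")
    degree = dict(g.degree())
    eigen = _eigenvector_scores(
        g, tol=config.eigenvector_tol, max_iter=config.eigenvector_max_iter
    )
    closeness = nx.closeness_centrality(g, wf_improved=True)
    betweenness = nx.betweenness_centrality(g, normalized=False)
    nodes = sorted(g.nodes)
    if config.seed_gene is not None:
        nodes = [n for n in nodes if n != config.seed_gene]
    if not nodes:
        raise ValueError("no nodes left to rank after excluding the seed gene")
    df = pd.DataFrame(
        {
            "degree": [float(degree[n]) for n in nodes],
            "eigenvector": [eigen[n] for n in nodes],
            "closeness": [closeness[n] for n in nodes],
            "betweenness": [betweenness[n] for n in nodes],
        },
        index=pd.Index(nodes, name="gene"),
    )
    for metric in METRICS:
        df[f"{metric}_rank"] = (
            df[metric].rank(method="min", ascending=False).astype(int)
        )
    return df


def top_by_any(
    report: pd.DataFrame, top_k: int | AnalysisConfig = 20
) -> set[str]:
    """Genes with competition rank <= top_k on at least one metric.

    Competition ranking makes the tie policy inclusive: every gene tied
    at the cut-off rank is kept.
    """
    k = top_k.top_k if isinstance(top_k, AnalysisConfig) else top_k
    out: set[str] = set()
    for metric in METRICS:
        out.update(report.index[report[f"{metric}_rank"] <= k])
    return set(out)


# ---------------------------------------------------------------------------
# I/O


def write_edge_list(net: GeneNetwork, path: str | Path) -> None:
    """2-column TSV edge list, plus evidence in a 3rd column when present."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        for u, v in net.edges:
            ev = net.graph.edges[u, v].get("evidence", [])
            ev_str = ";".join(f"{d}:{s}" for d, s, _ in ev)
            writer.writerow([u, v, ev_str])


def read_edge_list(
    path: str | Path, layer: str = "generic", seed_gene: str | None = None
) -> GeneNetwork:
    g = nx.Graph()
    if seed_gene is not None:
        g.add_node(seed_gene)
    with open(path, encoding="utf-8", newline="") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            u, v = row[0], row[1]
            evidence: list[tuple[str, int, frozenset[str]]] = []
            if len(row) > 2 and row[2]:
                for item in row[2].split(";"):
                    doc, _, idx = item.rpartition(":")
                    evidence.append((doc, int(idx), frozenset()))
            g.add_edge(u, v, evidence=evidence)
    return GeneNetwork(graph=g, layer=layer, seed_gene=seed_gene)


def write_graphml(net: GeneNetwork | nx.Graph, path: str | Path) -> None:
    """GraphML export with list/set attributes flattened to strings."""
    g = (net.graph if isinstance(net, GeneNetwork) else net).copy()
    for _, _, data in g.edges(data=True):
        if "evidence" in data:
            data["evidence"] = ";".join(
                f"{d}:{s}" for d, s, _ in data["evidence"]
            )
        if "shared_genes" in data:
            data["shared_genes"] = ",".join(sorted(data["shared_genes"]))
    for _, data in g.nodes(data=True):
        for key, value in list(data.items()):
            if isinstance(value, (set, frozenset, list, tuple)):
                data[key] = ",".join(str(x) for x in sorted(value))
    nx.write_graphml(g, path)
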