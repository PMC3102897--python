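"""Gene-concept co-occurrence and the derived concept-concept network.

A gene and a concept (vaccine) term are *associated* when they occur in
the same abstract.  The association table induces a concept-concept
network — two concepts are linked when they share at least one central
gene — which is ranked with the same four centralities as the gene
networks and partitioned by greedy modularity maximization (start with
singleton communities, repeatedly merge the connected pair with the
largest modularity gain, return the partition at the maximum-modularity
point of the merge history).
"""

from __future__ import annotations

import csv
import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .corpus import GeneDictionary
from .networks import AnalysisConfig, centrality_report
from .ontology import DEFAULT_MATCH_CONFIG, MatchConfig, OntologyTerm, match_terms

__all__ = [
    "AbstractRecord",
    "AssociationTable",
    "CommunityPartition",
    "cooccurrence",
    "build_concept_network",
    "modularity",
    "greedy_communities",
    "concept_centrality",
]


@dataclass(frozen=True)
class AbstractRecord:
    """A document's title+abstract text, keyed by its id."""

    document_id: str
    text: str


class AssociationTable:
    """Concept term -> associated genes, with per-pair supporting documents."""

    def __init__(self) -> None:
        self._assoc: dict[str, dict[str, set[str]]] = {}

    def add(self, concept_id: str, gene: str, document_id: str) -> None:
        self._assoc.setdefault(concept_id, {}).setdefault(gene, set()).add(
            document_id
        )

    @property
    def concepts(self) -> list[str]:
        return sorted(self._assoc)

    def genes_for(self, concept_id: str) -> set[str]:
        return set(self._assoc.get(concept_id, {}))

    def support(self, concept_id: str, gene: str) -> set[str]:
        return set(self._assoc.get(concept_id, {}).get(gene, set()))

    def all_genes(self) -> set[str]:
        out: set[str] = set()
        for genes in self._assoc.values():
            out.update(genes)
        return out

    def __len__(self) -> int:
        return len(self._assoc)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AssociationTable):
            return NotImplemented
        return self._assoc == other._assoc

    # -- construction and I/O ----------------------------------------------

    @classmethod
    def from_gene_sets(
        cls,
        gene_sets: Mapping[str, Iterable[str]],
        document_id: str = "curated",
    ) -> "AssociationTable":
        """Build a table from plain concept -> gene-set data (e.g. fixtures)."""
        table = cls()
        for concept, genes in gene_sets.items():
            for gene in genes:
                table.add(concept, gene, document_id)
        return table

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t")
            for concept in self.concepts:
                for gene in sorted(self._assoc[concept]):
                    writer.writerow(
                        [concept, gene, ";".join(sorted(self._assoc[concept][gene]))]
                    )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "AssociationTable":
        table = cls()
        with open(path, encoding="utf-8", newline="") as fh:
            for row in csv.reader(fh, delimiter="\t"):
                if not row or row[0].startswith("#"):
                    continue
                concept, gene, docs = row[0], row[1], row[2] if len(row) > 2 else ""
                for doc in docs.split(";") if docs else [""]:
                    table.add(concept, gene, doc)
        return table


def cooccurrence(
    abstracts: Iterable[AbstractRecord],
    genes: Iterable[str],
    dictionary: GeneDictionary,
    terms: Sequence[OntologyTerm],
    config: MatchConfig = DEFAULT_MATCH_CONFIG,
) -> AssociationTable:
    """Abstract-level gene-concept co-occurrence.

    A (gene, concept) pair is associated iff some abstract contains a
    whole-token occurrence of at least one synonym of each.  Gene
    matching reuses the term matcher over the dictionary's synonyms,
    restricted to the supplied (central) gene set; concept terms whose
    label contains the generic concept word are excluded.
    """
    gene_terms = dictionary.as_terms(genes)
    specific_terms = [t for t in terms if not t.has_vaccine_word]
    table = AssociationTable()
    for record in abstracts:
        gene_hits = {
            m.term_id for m in match_terms(record.text, gene_terms, config)
        }
        if not gene_hits:
            continue
        concept_hits = {
            m.term_id for m in match_terms(record.text, specific_terms, config)
        }
        for concept_id in concept_hits:
            for gene in gene_hits:
                table.add(concept_id, gene, record.document_id)
    return table


def build_concept_network(table: AssociationTable) -> nx.Graph:
    """Concept-concept graph: an edge where two concepts share a gene.

    Every concept in the table becomes a node; the edge attribute
    ``shared_genes`` holds the (non-empty) intersection of the two
    concepts' gene sets.
    """
    if len(table) == 0:
        raise ValueError("association table is empty")
    g = nx.Graph()
    g.add_nodes_from(table.concepts)
    for u, v in itertools.combinations(table.concepts, 2):
        shared = table.genes_for(u) & table.genes_for(v)
        if shared:
            g.add_edge(u, v, shared_genes=frozenset(shared))
    return g


# ---------------------------------------------------------------------------
# modularity and greedy (CNM) community detection


def modularity(g: nx.Graph, partition: Mapping[object, int]) -> float:
    """Newman modularity Q = sum_c (e_c/m - (d_c/2m)^2).

    ``e_c`` counts intra-community edges, ``d_c`` sums community degree,
    ``m`` is the total edge count.  An edgeless graph has Q = 0.
    """
    missing = set(g.nodes) - set(partition)
    if missing:
        raise ValueError(f"partition misses nodes: {sorted(map(str, missing))}")
    m = g.number_of_edges()
    if m == 0:
        return 0.0
    intra: dict[int, int] = {}
    deg: dict[int, int] = {}
    for node, d in g.degree():
        deg[partition[node]] = deg.get(partition[node], 0) + d
    for u, v in g.edges:
        if partition[u] == partition[v]:
            intra[partition[u]] = intra.get(partition[u], 0) + 1
    q = 0.0
    for c in set(partition[n] for n in g.nodes):
        q += intra.get(c, 0) / m - (deg.get(c, 0) / (2 * m)) ** 2
    return q


@dataclass
class CommunityPartition:
    """Node -> community assignment with its modularity and merge history.

    ``history`` records each greedy merge as ``(rep_a, rep_b, q_after)``
    where the reps are the lexicographically smallest members of the two
    merged communities.
    """

    membership: dict[object, int]
    q: float
    history: list[tuple[object, object, float]] = field(default_factory=list)

    @property
    def communities(self) -> list[set]:
        by_id: dict[int, set] = {}
        for node, cid in self.membership.items():
            by_id.setdefault(cid, set()).add(node)
        return [by_id[cid] for cid in sorted(by_id)]

    @property
    def sizes(self) -> list[int]:
        return sorted((len(c) for c in self.communities), reverse=True)


def greedy_communities(g: nx.Graph) -> CommunityPartition:
    """Agglomerative modularity maximization (CNM-style greedy merging).

    Starting from singleton communities, the connected community pair
    with the largest modularity gain

        dQ = m_ab/m - 2 (d_a / 2m)(d_b / 2m)

    is merged (ties: the pair whose lexicographically smallest member,
    then other member, sorts first); merging continues to a single
    community and the partition at the maximum-Q point of the merge
    history is returned.  Disconnected community pairs are never merged:
    with ``m_ab = 0`` the gain is non-positive and the merge can only
    lower Q.
    """
    if g.number_of_nodes() == 0:
        raise ValueError("graph has no nodes")
    m = g.number_of_edges()
    nodes = sorted(g.nodes, key=str)
    if m == 0:
        return CommunityPartition(
            membership={n: i for i, n in enumerate(nodes)}, q=0.0
        )
    # community state keyed by representative = min member
    members: dict[object, set] = {n: {n} for n in nodes}
    deg: dict[object, int] = {n: g.degree(n) for n in nodes}
    between: dict[frozenset, int] = {}
    loops: dict[object, int] = {n: 0 for n in nodes}
    for u, v in g.edges:
        between[frozenset((u, v))] = between.get(frozenset((u, v)), 0) + 1

    def q_current() -> float:
        return sum(
            loops[c] / m - (deg[c] / (2 * m)) ** 2 for c in members
        )

    q = q_current()
    best_q = q
    best_membership = {n: i for i, n in enumerate(nodes)}
    history: list[tuple[object, object, float]] = []

    while len(members) > 1:
        best_pair: tuple[object, object] | None = None
        best_gain = None
        for pair, m_ab in between.items():
            if m_ab == 0:
                continue
            a, b = sorted(pair, key=str)
            gain = m_ab / m - 2 * (deg[a] / (2 * m)) * (deg[b] / (2 * m))
            key = (str(a), str(b))
            if (
                best_gain is None
                or gain > best_gain + 1e-15
                or (abs(gain - best_gain) <= 1e-15 and key < best_key)
            ):
                best_gain = gain
                best_pair = (a, b)
                best_key = key
        if best_pair is None:  # remaining communities mutually disconnected
            break
        a, b = best_pair
        rep, other = (a, b) if str(a) < str(b) else (b, a)
        history.append((rep, other, q + best_gain))
        # merge `other` into `rep`
        loops[rep] += loops.pop(other) + between.pop(frozenset((a, b)))
        deg[rep] += deg.pop(other)
        members[rep] |= members.pop(other)
        for c in list(members):
            if c == rep:
                continue
            moved = between.pop(frozenset((other, c)), 0)
            if moved:
                between[frozenset((rep, c))] = (
                    between.get(frozenset((rep, c)), 0) + moved
                )
        q += best_gain
        if q > best_q + 1e-12:
            best_q = q
            best_membership = {}
            for cid, rep_c in enumerate(sorted(members, key=str)):
                for node in members[rep_c]:
                    best_membership[node] = cid
    return CommunityPartition(membership=best_membership, q=best_q, history=history)


def concept_centrality(
    g: nx.Graph, config: AnalysisConfig = AnalysisConfig()
) -> pd.DataFrame:
    """Four-centrality report for a concept network (no seed exclusion)."""
    if config.seed_gene is not None:
        config = AnalysisConfig(
            seed_gene=None,
            top_k=config.top_k,
            eigenvector_tol=config.eigenvector_tol,
            eigenvector_max_iter=config.eigenvector_max_iter,
        )
    return centrality_report(g, config)
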