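"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive — exhaustive recursion and
enumeration — and shares no code with the package's algorithms.
"""

from __future__ import annotations

import itertools
from collections import deque

import numpy as np


# ---------------------------------------------------------------------------
# edit distance: exhaustive recursion over all edit scripts


def edit_distance_recursive(a: tuple[str, ...], b: tuple[str, ...]) -> int:
    if not a:
        return len(b)
    if not b:
        return len(a)
    branches = [
        edit_distance_recursive(a[1:], b) + 1,  # delete a[0]
        edit_distance_recursive(a, b[1:]) + 1,  # insert b[0]
        edit_distance_recursive(a[1:], b[1:]) + (0 if a[0] == b[0] else 1),
    ]
    return min(branches)


# ---------------------------------------------------------------------------
# centralities on small graphs


def degree_oracle(adj: np.ndarray, nodes: list) -> dict:
    return {n: float(adj[i].sum()) for i, n in enumerate(nodes)}


def components_oracle(adj: np.ndarray) -> list[list[int]]:
    n = adj.shape[0]
    seen: set[int] = set()
    comps = []
    for start in range(n):
        if start in seen:
            continue
        comp = [start]
        seen.add(start)
        queue = deque([start])
        while queue:
            u = queue.popleft()
            for v in range(n):
                if adj[u, v] and v not in seen:
                    seen.add(v)
                    comp.append(v)
                    queue.append(v)
        comps.append(sorted(comp))
    return comps


def eigenvector_oracle(adj: np.ndarray, nodes: list) -> dict:
    """Dominant eigenvector of each component's adjacency block (eigh),
    L2-normalized per component with non-negative sign; isolated nodes 0."""
    out = {}
    for comp in components_oracle(adj):
        block = adj[np.ix_(comp, comp)]
        if block.sum() == 0:
            for i in comp:
                out[nodes[i]] = 0.0
            continue
        w, v = np.linalg.eigh(block)
        vec = v[:, np.argmax(w)]
        if vec.sum() < 0:
            vec = -vec
        vec = np.abs(vec)  # Perron vector is non-negative
        vec = vec / np.linalg.norm(vec)
        for i, val in zip(comp, vec):
            out[nodes[i]] = float(val)
    return out


def bfs_distances(adj: np.ndarray, src: int) -> dict[int, int]:
    dist = {src: 0}
    queue = deque([src])
    while queue:
        u = queue.popleft()
        for v in range(adj.shape[0]):
            if adj[u, v] and v not in dist:
                dist[v] = dist[u] + 1
                queue.append(v)
    return dist


def closeness_oracle(adj: np.ndarray, nodes: list) -> dict:
    """Wasserman-Faust closeness: (n_c-1)/sum(d) scaled by (n_c-1)/(n-1)."""
    n = adj.shape[0]
    out = {}
    for i, node in enumerate(nodes):
        dist = bfs_distances(adj, i)
        reachable = len(dist) - 1
        total = sum(dist.values())
        if reachable == 0 or total == 0:
            out[node] = 0.0
        else:
            out[node] = (reachable / total) * (reachable / (n - 1)) if n > 1 else 0.0
    return out


def all_shortest_paths(adj: np.ndarray, src: int, dst: int) -> list[list[int]]:
    """Every shortest path src->dst, enumerated from BFS distance labels."""
    dist = bfs_distances(adj, src)
    if dst not in dist:
        return []
    paths: list[list[int]] = []

    def extend(path: list[int]) -> None:
        u = path[-1]
        if u == dst:
            paths.append(list(path))
            return
        for v in range(adj.shape[0]):
            if adj[u, v] and dist.get(v) == dist[u] + 1 and dist[v] <= dist[dst]:
                path.append(v)
                extend(path)
                path.pop()

    extend([src])
    return [p for p in paths if len(p) - 1 == dist[dst]]


def betweenness_oracle(adj: np.ndarray, nodes: list) -> dict:
    """Unnormalized betweenness over unordered pairs, by path enumeration."""
    n = adj.shape[0]
    score = {node: 0.0 for node in nodes}
    for s, t in itertools.combinations(range(n), 2):
        paths = all_shortest_paths(adj, s, t)
        if not paths:
            continue
        for mid in range(n):
            if mid in (s, t):
                continue
            through = sum(1 for p in paths if mid in p)
            score[nodes[mid]] += through / len(paths)
    return score


# ---------------------------------------------------------------------------
# modularity: direct pairwise double sum


def modularity_pairwise_oracle(edges: list[tuple], nodes: list, partition) -> float:
    m = len(edges)
    if m == 0:
        return 0.0
    deg = {n: 0 for n in nodes}
    aset = set()
    for u, v in edges:
        deg[u] += 1
        deg[v] += 1
        aset.add(frozenset((u, v)))
    q = 0.0
    for u in nodes:
        for v in nodes:
            if partition[u] != partition[v]:
                continue
            a_uv = 1.0 if u != v and frozenset((u, v)) in aset else 0.0
            q += a_uv - deg[u] * deg[v] / (2 * m)
    return q / (2 * m)


def all_set_partitions(items: list):
    """Every partition of ``items`` into non-empty blocks."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in all_set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1 :]
        yield [[first]] + part


# ---------------------------------------------------------------------------
# random graphs


def random_graph(rng, n_max: int = 12, p: float = 0.35):
    """Random undirected graph as (adjacency matrix, node labels)."""
    n = rng.randint(2, n_max)
    adj = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                adj[i, j] = adj[j, i] = 1
    nodes = [f"n{i}" for i in range(n)]
    return adj, nodes
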