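"""Interaction extraction: shortest dependency paths, edit kernel, SVM.

The semantic relation between two gene mentions is summarised by the
shortest path between them in the sentence's dependency tree, rendered
as the alternating sequence of edge labels and intermediate words (the
gene tokens themselves are excluded).  Paths are compared by classical
sequence edit distance; the distance is turned into a similarity
``sim(p, q) = exp(-gamma * d(p, q))`` that serves as a precomputed SVM
kernel for classifying each path as stating an interaction or not.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from sklearn.svm import SVC

from .corpus import CandidateSentence, GeneMention, SentenceParse

__all__ = [
    "DependencyPath",
    "KernelConfig",
    "LabeledPath",
    "PathClassifier",
    "PathNotFound",
    "INTERACTING",
    "NOT_INTERACTING",
    "shortest_path",
    "edit_distance",
    "similarity",
    "gram_matrix",
    "train",
    "evaluate",
    "ExtractedInteraction",
    "extract_interactions",
]

logger = logging.getLogger(__name__)

INTERACTING = "interacting"
NOT_INTERACTING = "not-interacting"

#: reserved separator for serializing path elements in TSV files
ELEMENT_SEPARATOR = "|"


class PathNotFound(ValueError):
    """The two mentions lie in disconnected dependency fragments."""


@dataclass(frozen=True)
class DependencyPath:
    """Alternating edge-label/word sequence between two gene mentions.

    ``elements`` starts and ends with dependency-edge labels; the words
    in between are the intermediate tokens on the tree path.  The gene
    endpoint tokens are never part of the sequence.  ``endpoints`` holds
    the two gene symbols, unordered.
    """

    elements: tuple[str, ...]
    endpoints: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.elements:
            raise ValueError("a dependency path needs at least one edge label")
        if len(self.elements) % 2 == 0:
            raise ValueError(
                "path elements must alternate label, word, ..., label "
                f"(odd length); got {len(self.elements)}"
            )

    def __len__(self) -> int:
        return len(self.elements)


@dataclass(frozen=True)
class KernelConfig:
    """Edit-kernel parameters.

    ``gamma`` is the decay rate of the exponential similarity; the three
    costs price the edit operations (unit costs make the distance a
    metric); ``diagonal_ridge`` is added to Gram-matrix diagonals to keep
    the (not guaranteed PSD) edit kernel well-conditioned for the solver.
    """

    gamma: float = 0.5
    insert_cost: float = 1.0
    delete_cost: float = 1.0
    substitute_cost: float = 1.0
    diagonal_ridge: float = 0.01

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if min(self.insert_cost, self.delete_cost, self.substitute_cost) < 0:
            raise ValueError("edit costs must be non-negative")
        if self.substitute_cost > self.insert_cost + self.delete_cost:
            raise ValueError(
                "substitute_cost must not exceed insert_cost + delete_cost"
            )
        if self.diagonal_ridge < 0:
            raise ValueError("diagonal_ridge must be non-negative")


DEFAULT_KERNEL_CONFIG = KernelConfig()


@dataclass(frozen=True)
class LabeledPath:
    path: DependencyPath
    label: str

    def __post_init__(self) -> None:
        if self.label not in (INTERACTING, NOT_INTERACTING):
            raise ValueError(f"label must be binary, got {self.label!r}")


# ---------------------------------------------------------------------------
# shortest dependency path


def mention_head(sentence: SentenceParse, mention: GeneMention) -> int:
    """Head token of a (possibly multi-token) mention span.

    The head is the span token that is the dependency-tree ancestor of
    the others within the span; operationally, a span token whose parent
    lies outside the span.  Ties resolve to the rightmost such token.
    """
    span = range(mention.start, mention.end)
    span_set = set(span)
    parent: dict[int, int] = {}
    for head, dep, _ in sentence.dep_edges:
        parent[dep] = head
    heads = [
        i for i in span if i not in parent or parent[i] not in span_set
    ]
    if not heads:  # degenerate: internal cycle cannot happen in a forest
        heads = list(span)
    return heads[-1]


def shortest_path(
    sentence: SentenceParse, pair: tuple[GeneMention, GeneMention]
) -> DependencyPath:
    """Tree path between two mention heads as a label/word sequence.

    Edges are traversed direction-agnostically and keep their label.
    Raises :class:`PathNotFound` when the mentions sit in disconnected
    parse fragments.
    """
    a, b = pair
    src, dst = mention_head(sentence, a), mention_head(sentence, b)
    if src > dst:  # canonical orientation: sentence order of the heads
        src, dst = dst, src
    if src == dst:
        raise PathNotFound(
            f"{sentence.document_id}:{sentence.sentence_index}: mentions share "
            "a head token"
        )
    adjacency: dict[int, list[tuple[int, str]]] = {}
    for head, dep, label in sentence.dep_edges:
        adjacency.setdefault(head, []).append((dep, label))
        adjacency.setdefault(dep, []).append((head, label))
    # BFS; the dependency forest makes the path unique when it exists
    prev: dict[int, tuple[int, str]] = {}
    seen = {src}
    frontier = [src]
    while frontier and dst not in prev:
        nxt: list[int] = []
        for node in frontier:
            for nbr, label in adjacency.get(node, ()):
                if nbr not in seen:
                    seen.add(nbr)
                    prev[nbr] = (node, label)
                    nxt.append(nbr)
        frontier = nxt
    if dst not in prev:
        raise PathNotFound(
            f"{sentence.document_id}:{sentence.sentence_index}: no dependency "
            f"path between tokens {src} and {dst}"
        )
    nodes: list[int] = [dst]
    labels: list[str] = []
    cur = dst
    while cur != src:
        cur, label = prev[cur]
        labels.append(label)
        nodes.append(cur)
    nodes.reverse()
    labels.reverse()
    elements: list[str] = []
    for i, label in enumerate(labels):
        elements.append(label)
        if i < len(labels) - 1:
            elements.append(sentence.tokens[nodes[i + 1]])
    endpoints = frozenset(
        s for s in (a.symbol or a.surface, b.symbol or b.surface)
    )
    return DependencyPath(elements=tuple(elements), endpoints=endpoints)


# ---------------------------------------------------------------------------
# edit distance and kernel


def edit_distance(
    p: DependencyPath | Sequence[str],
    q: DependencyPath | Sequence[str],
    config: KernelConfig = DEFAULT_KERNEL_CONFIG,
) -> float:
    """Minimal-cost sequence edit distance between two paths.

    Elements (edge labels and words alike) compare by exact string
    equality; a whole element is inserted, deleted, or substituted at the
    configured costs.  Symmetric under unit costs.
    """
    a = p.elements if isinstance(p, DependencyPath) else tuple(p)
    b = q.elements if isinstance(q, DependencyPath) else tuple(q)
    ins, dele, sub = config.insert_cost, config.delete_cost, config.substitute_cost
    m, n = len(a), len(b)
    prev = [j * ins for j in range(n + 1)]
    for i in range(1, m + 1):
        cur = [i * dele] + [0.0] * n
        for j in range(1, n + 1):
            cost_sub = prev[j - 1] + (0.0 if a[i - 1] == b[j - 1] else sub)
            cur[j] = min(prev[j] + dele, cur[j - 1] + ins, cost_sub)
        prev = cur
    return prev[n]


def similarity(
    p: DependencyPath | Sequence[str],
    q: DependencyPath | Sequence[str],
    config: KernelConfig = DEFAULT_KERNEL_CONFIG,
) -> float:
    """Exponential edit kernel ``exp(-gamma * d(p, q))``, in (0, 1]."""
    return math.exp(-config.gamma * edit_distance(p, q, config))


def gram_matrix(
    paths: Sequence[DependencyPath],
    config: KernelConfig = DEFAULT_KERNEL_CONFIG,
    *,
    rhs: Sequence[DependencyPath] | None = None,
) -> np.ndarray:
    """Pairwise similarity matrix; square form gets the diagonal ridge.

    With ``rhs`` given, returns the rectangular ``len(paths) x len(rhs)``
    kernel between two path collections (no ridge).
    """
    if len(paths) == 0:
        raise ValueError("paths must be non-empty")
    if rhs is None:
        n = len(paths)
        K = np.empty((n, n), dtype=float)
        for i in range(n):
            K[i, i] = 1.0 + config.diagonal_ridge
            for j in range(i + 1, n):
                K[i, j] = K[j, i] = similarity(paths[i], paths[j], config)
        return K
    K = np.empty((len(paths), len(rhs)), dtype=float)
    for i, p in enumerate(paths):
        for j, q in enumerate(rhs):
            K[i, j] = similarity(p, q, config)
    return K


# ---------------------------------------------------------------------------
# SVM over the precomputed kernel


@dataclass
class PathClassifier:
    """Kernel-SVM decision function over support dependency paths.

    The decision value is the bias plus the dual-coefficient-weighted sum
    of kernel similarities to the support paths; a positive value means
    "interacting", and an exact zero resolves to "not-interacting".
    """

    support_paths: list[DependencyPath]
    dual_coef: np.ndarray
    bias: float
    config: KernelConfig = field(default_factory=KernelConfig)
    C: float = 1.0

    def __post_init__(self) -> None:
        if len(self.support_paths) == 0:
            raise ValueError("classifier needs at least one support path")
        self.dual_coef = np.asarray(self.dual_coef, dtype=float)
        if self.dual_coef.shape != (len(self.support_paths),):
            raise ValueError("one dual coefficient per support path required")

    def decision(self, path: DependencyPath) -> float:
        sims = np.array(
            [similarity(path, sp, self.config) for sp in self.support_paths]
        )
        return float(self.dual_coef @ sims + self.bias)

    def classify(self, path: DependencyPath) -> tuple[str, float]:
        value = self.decision(path)
        return (INTERACTING if value > 0 else NOT_INTERACTING), value

    # -- serialization ------------------------------------------------------

    def save(self, path: str | Path) -> None:
        payload = {
            "format": "condl-path-classifier/1",
            "C": self.C,
            "config": {
                "gamma": self.config.gamma,
                "insert_cost": self.config.insert_cost,
                "delete_cost": self.config.delete_cost,
                "substitute_cost": self.config.substitute_cost,
                "diagonal_ridge": self.config.diagonal_ridge,
            },
            "bias": self.bias,
            "support": [
                {"elements": list(sp.elements), "coef": float(c)}
                for sp, c in zip(self.support_paths, self.dual_coef)
            ],
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def load(cls, path: str | Path) -> "PathClassifier":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        config = KernelConfig(**payload["config"])
        support = [
            DependencyPath(elements=tuple(rec["elements"]))
            for rec in payload["support"]
        ]
        coef = np.array([rec["coef"] for rec in payload["support"]], dtype=float)
        return cls(
            support_paths=support,
            dual_coef=coef,
            bias=float(payload["bias"]),
            config=config,
            C=float(payload["C"]),
        )


def train(
    examples: Sequence[LabeledPath],
    C: float = 1.0,
    config: KernelConfig = DEFAULT_KERNEL_CONFIG,
    solver_tol: float = 1e-6,
) -> PathClassifier:
    """Fit a soft-margin SVM on the precomputed edit-kernel Gram matrix.

    Deterministic given fixed inputs; ``solver_tol`` is the SMO stopping
    tolerance, kept tight so refits on reordered data agree.
    """
    labels = {ex.label for ex in examples}
    if labels != {INTERACTING, NOT_INTERACTING}:
        raise ValueError(
            f"training requires both classes; got labels {sorted(labels)}"
        )
    paths = [ex.path for ex in examples]
    y = np.array([1 if ex.label == INTERACTING else 0 for ex in examples])
    K = gram_matrix(paths, config)
    svc = SVC(kernel="precomputed", C=C, tol=solver_tol)
    svc.fit(K, y)
    support_idx = svc.support_
    return PathClassifier(
        support_paths=[paths[i] for i in support_idx],
        dual_coef=svc.dual_coef_[0].copy(),
        bias=float(svc.intercept_[0]),
        config=config,
        C=C,
    )


def evaluate(
    clf: PathClassifier, examples: Sequence[LabeledPath]
) -> dict[str, float]:
    """Precision/recall/F1 (positive class = interacting) and accuracy."""
    tp = fp = fn = tn = 0
    for ex in examples:
        predicted, _ = clf.classify(ex.path)
        if predicted == INTERACTING:
            if ex.label == INTERACTING:
                tp += 1
            else:
                fp += 1
        elif ex.label == INTERACTING:
            fn += 1
        else:
            tn += 1
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = (
        2 * precision * recall / (precision + recall) if precision + recall else 0.0
    )
    accuracy = (tp + tn) / len(examples) if examples else 0.0
    return {
        "precision": precision,
        "recall": recall,
        "f1": f1,
        "accuracy": accuracy,
    }


# ---------------------------------------------------------------------------
# end-to-end extraction over candidate sentences


@dataclass(frozen=True)
class ExtractedInteraction:
    """A classified-positive gene pair with its sentence provenance."""

    gene_a: str
    gene_b: str
    document_id: str
    sentence_index: int
    context_tags: frozenset[str] = frozenset()
    decision_value: float = 0.0

    @property
    def pair(self) -> tuple[str, str]:
        return tuple(sorted((self.gene_a, self.gene_b)))  # type: ignore[return-value]


def paths_for_candidate(
    candidate: CandidateSentence,
) -> list[tuple[tuple[str, str], DependencyPath]]:
    """Shortest dependency path per gene pair; unreachable pairs skipped."""
    sent = candidate.sentence
    by_symbol: dict[str, GeneMention] = {}
    for m in sent.mentions:
        if m.symbol and m.symbol not in by_symbol:
            by_symbol[m.symbol] = m
    out: list[tuple[tuple[str, str], DependencyPath]] = []
    for ga, gb in candidate.gene_pairs:
        try:
            path = shortest_path(sent, (by_symbol[ga], by_symbol[gb]))
        except PathNotFound as exc:
            logger.warning("skipping pair (%s, %s): %s", ga, gb, exc)
            continue
        out.append(((ga, gb), path))
    return out


def extract_interactions(
    candidates: Iterable[CandidateSentence], clf: PathClassifier
) -> list[ExtractedInteraction]:
    """Classify every candidate gene pair; keep the interacting ones."""
    out: list[ExtractedInteraction] = []
    for cand in candidates:
        for (ga, gb), path in paths_for_candidate(cand):
            label, value = clf.classify(path)
            if label == INTERACTING:
                out.append(
                    ExtractedInteraction(
                        gene_a=ga,
                        gene_b=gb,
                        document_id=cand.sentence.document_id,
                        sentence_index=cand.sentence.sentence_index,
                        context_tags=cand.context_tags,
                        decision_value=value,
                    )
                )
    return out


# ---------------------------------------------------------------------------
# labeled-path TSV I/O (elements joined by the reserved separator)


def write_labeled_paths(examples: Iterable[LabeledPath], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for ex in examples:
            if any(ELEMENT_SEPARATOR in el for el in ex.path.elements):
                raise ValueError(
                    f"path element contains reserved separator {ELEMENT_SEPARATOR!r}"
                )
            fh.write(ELEMENT_SEPARATOR.join(ex.path.elements) + "\t" + ex.label + "\n")


def read_labeled_paths(path: str | Path) -> list[LabeledPath]:
    out: list[LabeledPath] = []
    with open(path, encoding="utf-8") as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if not line:
                continue
            elements_str, label = line.split("\t")
            out.append(
                LabeledPath(
                    path=DependencyPath(
                        elements=tuple(elements_str.split(ELEMENT_SEPARATOR))
                    ),
                    label=label,
                )
            )
    return out
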