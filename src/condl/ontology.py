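"""Concept-ontology support: flat term files, synonym matching, structural subsumption.

The vaccine vocabulary used throughout the pipeline is a flat list of
concept terms (one per line, label and synonyms separated by the literal
``|#|``).  An optional hierarchy side file adds asserted ``is_a`` parents
and ``has_quality`` annotations, which a minimal structural-subsumption
rule turns into an inferred hierarchy: a term falls under a defined class
(genus plus required qualities) when the genus is among its ancestors and
it carries every required quality.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "OntologyTerm",
    "DefinedClass",
    "TermMatch",
    "MatchConfig",
    "OntologyError",
    "load_term_file",
    "load_hierarchy",
    "match_terms",
    "infer_subclasses",
]

#: word-level variants of "vaccine"; terms whose label contains one are
#: flagged so pipelines can exclude them (the generic word is queried
#: separately and such terms add no specific-concept signal).
_VACCINE_WORD = re.compile(r"(?i)\bvaccin(?:e|es|ation|ations|ated|ating)?\b")

_TOKEN = re.compile(r"[A-Za-z0-9]+")


class OntologyError(ValueError):
    """Raised for malformed term files or inconsistent hierarchies."""


@dataclass
class OntologyTerm:
    """A concept term with its synonyms and (optional) hierarchy annotations.

    ``id`` is the term label for flat files (labels are unique there);
    ``parents`` holds asserted ``is_a`` superclass ids and ``qualities``
    the fillers of ``has_quality`` restrictions.
    """

    id: str
    label: str
    synonyms: list[str] = field(default_factory=list)
    parents: list[str] = field(default_factory=list)
    qualities: list[str] = field(default_factory=list)
    has_vaccine_word: bool = False

    def __post_init__(self) -> None:
        if not self.label:
            raise OntologyError("term label must be non-empty")

    @property
    def names(self) -> list[str]:
        """Label plus synonyms, in matching priority order."""
        return [self.label, *self.synonyms]


@dataclass(frozen=True)
class DefinedClass:
    """A fully defined class: a genus term plus required quality fillers."""

    id: str
    genus: str
    required_qualities: frozenset[str]

    def __post_init__(self) -> None:
        if not self.required_qualities:
            raise OntologyError(
                f"defined class {self.id!r} needs at least one required quality"
            )


@dataclass(frozen=True)
class TermMatch:
    """One whole-token occurrence of a term name in a piece of text."""

    term_id: str
    matched_synonym: str
    document_id: str = ""
    sentence_index: int = -1
    span: tuple[int, int] = (0, 0)


@dataclass(frozen=True)
class MatchConfig:
    """Matching policy: case folding and the short-synonym exception.

    Matching is case-insensitive with word boundaries at non-alphanumeric
    characters; names shorter than ``min_fold_length`` characters are
    matched case-sensitively to limit false hits from short acronyms.
    """

    case_insensitive: bool = True
    min_fold_length: int = 3


DEFAULT_MATCH_CONFIG = MatchConfig()


def load_term_file(path: str | Path) -> list[OntologyTerm]:
    """Read a flat concept-term file (``label|#|syn1|#|syn2...`` per line).

    Synonyms are de-duplicated preserving order.  Terms whose label
    contains the word "vaccine" or a variant get ``has_vaccine_word``
    set so callers can exclude them from specific-term matching.
    """
    terms: list[OntologyTerm] = []
    seen_ids: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            fields = [f.strip() for f in line.split("|#|")]
            label = fields[0]
            if not label:
                raise OntologyError(f"{path}: line {lineno}: empty term label")
            if label in seen_ids:
                raise OntologyError(f"{path}: line {lineno}: duplicate term {label!r}")
            seen_ids.add(label)
            synonyms: list[str] = []
            for syn in fields[1:]:
                if syn and syn != label and syn not in synonyms:
                    synonyms.append(syn)
            terms.append(
                OntologyTerm(
                    id=label,
                    label=label,
                    synonyms=synonyms,
                    has_vaccine_word=bool(_VACCINE_WORD.search(label)),
                )
            )
    return terms


def load_hierarchy(
    path: str | Path, terms: Sequence[OntologyTerm]
) -> list[OntologyTerm]:
    """Attach asserted parents and qualities from a 3-column TSV side file.

    Rows are ``term_id<TAB>relation<TAB>filler`` with relation ``is_a``
    (filler must be a known term id) or ``has_quality`` (filler is an
    opaque quality id).  Returns new term objects; the asserted ``is_a``
    graph is checked to be acyclic.
    """
    by_id = {t.id: t for t in terms}
    parents: dict[str, list[str]] = {t.id: list(t.parents) for t in terms}
    qualities: dict[str, list[str]] = {t.id: list(t.qualities) for t in terms}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 3:
                raise OntologyError(f"{path}: line {lineno}: expected 3 columns")
            term_id, relation, filler = (c.strip() for c in cols)
            if term_id not in by_id:
                raise OntologyError(f"{path}: line {lineno}: unknown term {term_id!r}")
            if relation == "is_a":
                if filler not in by_id:
                    raise OntologyError(
                        f"{path}: line {lineno}: unknown parent {filler!r}"
                    )
                if filler not in parents[term_id]:
                    parents[term_id].append(filler)
            elif relation == "has_quality":
                if filler not in qualities[term_id]:
                    qualities[term_id].append(filler)
            else:
                raise OntologyError(
                    f"{path}: line {lineno}: unknown relation {relation!r}"
                )
    updated = [
        replace(t, parents=parents[t.id], qualities=qualities[t.id]) for t in terms
    ]
    _check_acyclic({t.id: t.parents for t in updated})
    return updated


def _check_acyclic(parents: Mapping[str, Sequence[str]]) -> None:
    state: dict[str, int] = {}  # 0 visiting, 1 done

    def visit(node: str, stack: list[str]) -> None:
        if state.get(node) == 1:
            return
        if state.get(node) == 0:
            cycle = stack[stack.index(node):] + [node]
            raise OntologyError("asserted hierarchy has a cycle: " + " -> ".join(cycle))
        state[node] = 0
        stack.append(node)
        for p in parents.get(node, ()):
            visit(p, stack)
        stack.pop()
        state[node] = 1

    for node in parents:
        visit(node, [])


def tokenize_with_spans(text: str) -> list[tuple[str, int, int]]:
    """Split on non-alphanumeric characters, keeping character spans."""
    return [(m.group(0), m.start(), m.end()) for m in _TOKEN.finditer(text)]


def _name_matches(
    name: str, config: MatchConfig
) -> tuple[list[str], bool]:
    """Tokenized form of a term name plus whether comparison folds case."""
    fold = config.case_insensitive and len(name) >= config.min_fold_length
    toks = [m.group(0) for m in _TOKEN.finditer(name)]
    if fold:
        toks = [t.casefold() for t in toks]
    return toks, fold


def match_terms(
    text: str,
    terms: Iterable[OntologyTerm],
    config: MatchConfig = DEFAULT_MATCH_CONFIG,
    *,
    document_id: str = "",
    sentence_index: int = -1,
) -> list[TermMatch]:
    """Find whole-token occurrences of term labels/synonyms in ``text``.

    Word boundaries fall at non-alphanumeric characters (so a hyphen
    separates tokens).  On overlapping candidates the longest match wins;
    candidates covering the same span for different terms are all kept.
    Results are ordered by span start, then term id.
    """
    tokens = tokenize_with_spans(text)
    folded = [t.casefold() for t, _, _ in tokens]
    candidates: list[TermMatch] = []
    for term in terms:
        for name in term.names:
            name_toks, fold = _name_matches(name, config)
            if not name_toks:
                continue
            k = len(name_toks)
            for i in range(len(tokens) - k + 1):
                window = folded[i : i + k] if fold else [t for t, _, _ in tokens[i : i + k]]
                if window == name_toks:
                    start = tokens[i][1]
                    end = tokens[i + k - 1][2]
                    candidates.append(
                        TermMatch(
                            term_id=term.id,
                            matched_synonym=text[start:end],
                            document_id=document_id,
                            sentence_index=sentence_index,
                            span=(start, end),
                        )
                    )
    # longest-match-wins; identical spans (distinct terms) are all kept
    candidates.sort(key=lambda m: (-(m.span[1] - m.span[0]), m.span[0], m.term_id))
    selected: list[TermMatch] = []
    for cand in candidates:
        same_span = any(cand.span == kept.span for kept in selected)
        overlaps = any(
            cand.span != kept.span
            and cand.span[0] < kept.span[1]
            and kept.span[0] < cand.span[1]
            for kept in selected
        )
        if (same_span or not overlaps) and cand not in selected:
            selected.append(cand)
    selected.sort(key=lambda m: (m.span[0], m.term_id))
    return selected


def ancestors(term_id: str, by_id: Mapping[str, OntologyTerm]) -> set[str]:
    """Reflexive-transitive closure of asserted parents of ``term_id``."""
    out: set[str] = set()
    stack = [term_id]
    while stack:
        node = stack.pop()
        if node in out:
            continue
        out.add(node)
        term = by_id.get(node)
        if term is not None:
            stack.extend(term.parents)
    return out


def infer_subclasses(
    terms: Sequence[OntologyTerm], defined: Sequence[DefinedClass]
) -> dict[str, set[str]]:
    """Structural subsumption of terms under genus-plus-qualities classes.

    A term ``T`` is inferred under defined class ``D`` iff ``D.genus`` is
    ``T`` itself or an ancestor of ``T`` (asserted ``is_a`` closure) and
    every required quality of ``D`` appears among ``T``'s qualities.
    """
    by_id = {t.id: t for t in terms}
    for d in defined:
        if d.genus not in by_id:
            raise OntologyError(f"defined class {d.id!r}: unknown genus {d.genus!r}")
    result: dict[str, set[str]] = {}
    for t in terms:
        anc = ancestors(t.id, by_id)
        quals = set(t.qualities)
        hits = {
            d.id
            for d in defined
            if d.genus in anc and d.required_qualities <= quals
        }
        result[t.id] = hits
    return result
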