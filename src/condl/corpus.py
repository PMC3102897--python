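"""Parsed-sentence corpus: records, gene-name normalization, candidate selection.

The pipeline consumes sentences that were tagged and dependency-parsed
upstream; each record carries the token list, labelled dependency edges
and pre-resolved gene-mention spans.  Gene surfaces are normalized
against a symbol/synonym dictionary so every gene is a single network
node, and candidate sentences are those with at least two distinct
normalized genes plus an interaction keyword.
"""

from __future__ import annotations

import csv
import itertools
import json
import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from .ontology import (
    DEFAULT_MATCH_CONFIG,
    MatchConfig,
    OntologyTerm,
    match_terms,
)

__all__ = [
    "GeneMention",
    "SentenceParse",
    "GeneDictionary",
    "CandidateSentence",
    "CorpusError",
    "load_gene_dictionary",
    "normalize_mentions",
    "select_candidates",
    "read_corpus",
    "write_corpus",
    "DEFAULT_VACCINE_VARIANTS",
    "GENERIC_VACCINE_TAG",
    "VO_TERM_TAG_PREFIX",
]

logger = logging.getLogger(__name__)

GENERIC_VACCINE_TAG = "generic_vaccine"
VO_TERM_TAG_PREFIX = "vo_term:"

#: word-level variants of the generic concept word used for layer tagging
DEFAULT_VACCINE_VARIANTS = (
    "vaccine",
    "vaccines",
    "vaccination",
    "vaccinated",
    "vaccinating",
)


class CorpusError(ValueError):
    """Raised for malformed corpus records or dictionaries."""


@dataclass(frozen=True)
class GeneMention:
    """A gene mention: half-open token span, surface form, normalized symbol."""

    start: int
    end: int
    surface: str
    symbol: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise CorpusError(f"invalid mention span ({self.start}, {self.end})")


@dataclass(frozen=True)
class SentenceParse:
    """One dependency-parsed sentence with pre-tagged gene mentions.

    ``dep_edges`` are ``(head_index, dependent_index, label)`` triples with
    0-based token indices; the undirected graph they induce must be a
    forest (the usual dependency tree, possibly fragmented).
    """

    document_id: str
    sentence_index: int
    tokens: tuple[str, ...]
    dep_edges: tuple[tuple[int, int, str], ...]
    mentions: tuple[GeneMention, ...] = ()

    def __post_init__(self) -> None:
        n = len(self.tokens)
        covered: set[int] = set()
        for head, dep, label in self.dep_edges:
            if not (0 <= head < n and 0 <= dep < n):
                raise CorpusError(
                    f"{self.document_id}:{self.sentence_index}: dependency edge "
                    f"({head}, {dep}, {label!r}) out of token range"
                )
            covered.update((head, dep))
        # a forest has |E| = |covered nodes| - #components
        if self.dep_edges:
            comp = _count_components(covered, self.dep_edges)
            if len(self.dep_edges) != len(covered) - comp:
                raise CorpusError(
                    f"{self.document_id}:{self.sentence_index}: dependency graph "
                    "contains a cycle or duplicate edge"
                )
        for m in self.mentions:
            if m.end > n:
                raise CorpusError(
                    f"{self.document_id}:{self.sentence_index}: mention span "
                    f"({m.start}, {m.end}) exceeds sentence length {n}"
                )

    @property
    def text(self) -> str:
        return " ".join(self.tokens)


def _count_components(
    nodes: set[int], edges: Sequence[tuple[int, int, str]]
) -> int:
    parent = {v: v for v in nodes}

    def find(v: int) -> int:
        while parent[v] != v:
            parent[v] = parent[parent[v]]
            v = parent[v]
        return v

    for a, b, _ in edges:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
    return len({find(v) for v in nodes})


class GeneDictionary:
    """Approved gene symbols with synonyms; case-folded unambiguous lookup.

    A synonym that would map to two different symbols after case folding
    is dropped at construction with a logged warning, so every lookup hit
    is unambiguous.  Every symbol is a synonym of itself.
    """

    def __init__(self, synonyms_by_symbol: dict[str, Iterable[str]]):
        self._synonyms: dict[str, list[str]] = {}
        folded: dict[str, set[str]] = {}
        for symbol, syns in synonyms_by_symbol.items():
            names = [symbol]
            for s in syns:
                if s and s not in names:
                    names.append(s)
            self._synonyms[symbol] = names
            for name in names:
                folded.setdefault(name.casefold(), set()).add(symbol)
        self._lookup: dict[str, str] = {}
        for key, symbols in folded.items():
            if len(symbols) == 1:
                self._lookup[key] = next(iter(symbols))
            else:
                logger.warning(
                    "ambiguous gene synonym %r maps to %s; dropped from lookup",
                    key,
                    sorted(symbols),
                )

    @property
    def symbols(self) -> list[str]:
        return sorted(self._synonyms)

    def synonyms_of(self, symbol: str) -> list[str]:
        return list(self._synonyms[symbol])

    def lookup(self, surface: str) -> str | None:
        """Map a surface form to its approved symbol, or None."""
        return self._lookup.get(surface.casefold())

    def __len__(self) -> int:
        return len(self._synonyms)

    def __contains__(self, symbol: str) -> bool:
        return symbol in self._synonyms

    def as_terms(self, symbols: Iterable[str] | None = None) -> list[OntologyTerm]:
        """View (a subset of) the dictionary as matchable concept terms."""
        chosen = self.symbols if symbols is None else sorted(symbols)
        return [
            OntologyTerm(
                id=s, label=s, synonyms=[x for x in self._synonyms[s] if x != s]
            )
            for s in chosen
            if s in self._synonyms
        ]


def load_gene_dictionary(path: str | Path) -> GeneDictionary:
    """Load a 2-column TSV (symbol, synonym); symbols repeat across rows."""
    table: dict[str, list[str]] = {}
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        for row in reader:
            if not row or row[0].startswith("#"):
                continue
            if len(row) < 2:
                raise CorpusError(f"{path}: expected 2 columns, got {row!r}")
            symbol, synonym = row[0].strip(), row[1].strip()
            table.setdefault(symbol, [])
            if synonym:
                table[symbol].append(synonym)
    return GeneDictionary(table)


def normalize_mentions(
    sentence: SentenceParse, dictionary: GeneDictionary
) -> SentenceParse:
    """Set each mention's symbol from a case-folded exact dictionary match."""
    mentions = tuple(
        replace(m, symbol=dictionary.lookup(m.surface)) for m in sentence.mentions
    )
    return replace(sentence, mentions=mentions)


def _subtokens(token: str) -> list[str]:
    """The token itself plus its pieces split at non-alphanumeric characters."""
    pieces = [p for p in _split_non_alnum(token) if p]
    out = [token]
    out.extend(p for p in pieces if p != token)
    return out


def _split_non_alnum(token: str) -> list[str]:
    parts: list[str] = []
    buf: list[str] = []
    for ch in token:
        if ch.isalnum():
            buf.append(ch)
        elif buf:
            parts.append("".join(buf))
            buf = []
    if buf:
        parts.append("".join(buf))
    return parts


def sentence_token_set(sentence: SentenceParse) -> set[str]:
    """Case-folded tokens and hyphen-split subtokens of the sentence."""
    out: set[str] = set()
    for tok in sentence.tokens:
        for sub in _subtokens(tok):
            out.add(sub.casefold())
    return out


@dataclass(frozen=True)
class CandidateSentence:
    """A sentence kept for relation extraction.

    Carries the matched interaction keywords, every unordered pair of the
    distinct normalized gene symbols, and the concept-context tags used
    for network layering (``generic_vaccine`` and/or ``vo_term:<id>``).
    """

    sentence: SentenceParse
    matched_keywords: tuple[str, ...]
    gene_pairs: tuple[tuple[str, str], ...]
    context_tags: frozenset[str] = frozenset()


def load_keywords(path: str | Path) -> list[str]:
    """One interaction keyword per line; blank lines and # comments skipped."""
    out: list[str] = []
    with open(path, encoding="utf-8") as fh:
        for raw in fh:
            line = raw.strip()
            if line and not line.startswith("#"):
                out.append(line)
    return out


def select_candidates(
    sentences: Iterable[SentenceParse],
    keywords: Sequence[str],
    vaccine_variants: Sequence[str] = DEFAULT_VACCINE_VARIANTS,
    terms: Sequence[OntologyTerm] = (),
    match_config: MatchConfig = DEFAULT_MATCH_CONFIG,
) -> list[CandidateSentence]:
    """Keep sentences with >=2 distinct normalized genes and a keyword.

    Keyword matching is case-insensitive whole-token matching including
    hyphen-split subtokens ("BCG-induced" matches "induced").  Context
    tags record whether the sentence mentions the generic concept word
    (``generic_vaccine``) and which specific ontology terms it mentions
    (``vo_term:<id>``); terms whose label contains the generic word are
    excluded from specific matching.
    """
    if not keywords:
        raise CorpusError("keyword list must be non-empty")
    folded_keywords = {k.casefold(): k for k in keywords}
    variants = {v.casefold() for v in vaccine_variants}
    specific_terms = [t for t in terms if not t.has_vaccine_word]
    out: list[CandidateSentence] = []
    for sent in sentences:
        symbols = sorted({m.symbol for m in sent.mentions if m.symbol})
        if len(symbols) < 2:
            continue
        toks = sentence_token_set(sent)
        matched = tuple(
            kw for folded, kw in sorted(folded_keywords.items()) if folded in toks
        )
        if not matched:
            continue
        tags: set[str] = set()
        if toks & variants:
            tags.add(GENERIC_VACCINE_TAG)
        for m in match_terms(sent.text, specific_terms, match_config):
            tags.add(VO_TERM_TAG_PREFIX + m.term_id)
        pairs = tuple(itertools.combinations(symbols, 2))
        out.append(
            CandidateSentence(
                sentence=sent,
                matched_keywords=matched,
                gene_pairs=pairs,
                context_tags=frozenset(tags),
            )
        )
    return out


# ---------------------------------------------------------------------------
# corpus I/O: one JSON record per line


def write_corpus(sentences: Iterable[SentenceParse], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for s in sentences:
            rec = {
                "document_id": s.document_id,
                "sentence_index": s.sentence_index,
                "tokens": list(s.tokens),
                "dep_edges": [list(e) for e in s.dep_edges],
                "mentions": [
                    {"start": m.start, "end": m.end, "surface": m.surface,
                     **({"symbol": m.symbol} if m.symbol else {})}
                    for m in s.mentions
                ],
            }
            fh.write(json.dumps(rec, ensure_ascii=False) + "\n")


def read_corpus(path: str | Path) -> Iterator[SentenceParse]:
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CorpusError(f"{path}: line {lineno}: {exc}") from exc
            yield SentenceParse(
                document_id=str(rec["document_id"]),
                sentence_index=int(rec["sentence_index"]),
                tokens=tuple(rec["tokens"]),
                dep_edges=tuple(
                    (int(h), int(d), str(label)) for h, d, label in rec["dep_edges"]
                ),
                mentions=tuple(
                    GeneMention(
                        start=int(m["start"]),
                        end=int(m["end"]),
                        surface=str(m["surface"]),
                        symbol=m.get("symbol"),
                    )
                    for m in rec.get("mentions", ())
                ),
            )
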