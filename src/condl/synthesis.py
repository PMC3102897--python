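"""Synthetic parsed corpora with known ground truth.

Stands in for a tagged, dependency-parsed literature corpus so every
pipeline stage — candidate selection, path extraction, kernel-SVM
classification, network layering, and abstract-level co-occurrence — is
testable end to end with exact bookkeeping.  Sentences are instantiated
from three fixed dependency-parse templates (subject-verb-object, a
conjunction chain mirroring the worked example, and a nominalised
prepositional chain); decoy sentences carry two genes but no interaction
keyword.  Generation is fully deterministic given the spec's seed.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from .associations import AbstractRecord
from .corpus import GeneDictionary, GeneMention, SentenceParse, normalize_mentions
from .ontology import OntologyTerm
from .relations import (
    INTERACTING,
    NOT_INTERACTING,
    LabeledPath,
    shortest_path,
)

__all__ = [
    "SyntheticSpec",
    "SentenceGroundTruth",
    "GroundTruth",
    "SyntheticCorpus",
    "generate_corpus",
    "labeled_paths",
]

_VERBS = (
    "activates",
    "induces",
    "inhibits",
    "stimulates",
    "suppresses",
    "up-regulates",
    "down-regulates",
    "binds",
)
_NOUNS = (
    "activation",
    "induction",
    "inhibition",
    "stimulation",
    "suppression",
    "regulation",
)

TEMPLATES = ("svo", "conjunction", "nominal")


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for one synthetic corpus.

    Defaults emulate a small focused literature sample: 20 documents, 5
    planted gene-gene interactions connected to the seed gene, and a 30%
    decoy rate (sentences with two genes but no interaction keyword).
    Interaction sentences mention the generic concept word, a specific
    vaccine term, or neither, with probabilities ``context_probs``.
    """

    seed: int = 0
    n_documents: int = 20
    n_planted_interactions: int = 5
    decoy_rate: float = 0.3
    gene_vocab: tuple[str, ...] = (
        "IFNG",
        "IL2",
        "IL6",
        "TNF",
        "IL10",
        "CD4",
        "TLR2",
        "TLR4",
        "CSF2",
        "CXCL10",
        "IL18",
        "NFKB1",
    )
    vaccine_vocab: tuple[str, ...] = ("BCG", "LVS", "Dryvax")
    context_probs: tuple[float, float, float] = (0.4, 0.3, 0.3)  # none/generic/vo
    n_cooccurrence_abstracts: int = 6

    def __post_init__(self) -> None:
        if not self.gene_vocab or not self.vaccine_vocab:
            raise ValueError("gene and vaccine vocabularies must be non-empty")
        if not 0 <= self.decoy_rate < 1:
            raise ValueError("decoy_rate must be in [0, 1)")
        if set(self.gene_vocab) & set(self.vaccine_vocab):
            raise ValueError("gene and vaccine vocabularies must be disjoint")

    @property
    def seed_gene(self) -> str:
        return self.gene_vocab[0]


@dataclass(frozen=True)
class SentenceGroundTruth:
    """What one generated sentence plants: pairs, tags, decoy status."""

    document_id: str
    sentence_index: int
    template: str
    positive_pairs: frozenset[tuple[str, str]]
    negative_pairs: frozenset[tuple[str, str]]
    tags: frozenset[str]
    is_decoy: bool = False


@dataclass
class GroundTruth:
    """Exact bookkeeping of everything the generator planted."""

    planted_pairs: set[tuple[str, str]] = field(default_factory=set)
    sentences: list[SentenceGroundTruth] = field(default_factory=list)
    #: vaccine -> gene -> supporting document ids, by construction
    associations: dict[str, dict[str, set[str]]] = field(default_factory=dict)

    def pairs_with_tag(self, predicate) -> set[tuple[str, str]]:
        out: set[tuple[str, str]] = set()
        for s in self.sentences:
            if not s.is_decoy and predicate(s.tags):
                out |= s.positive_pairs
        return out


@dataclass
class SyntheticCorpus:
    """Generated sentences, abstracts and their ground-truth ledger."""

    spec: SyntheticSpec
    sentences: list[SentenceParse]
    abstracts: list[AbstractRecord]
    truth: GroundTruth

    def gene_dictionary(self) -> GeneDictionary:
        return GeneDictionary({g: [g] for g in self.spec.gene_vocab})

    def ontology_terms(self) -> list[OntologyTerm]:
        return [OntologyTerm(id=v, label=v) for v in self.spec.vaccine_vocab]


def _pair(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


def _template_svo(a: str, verb: str, b: str):
    tokens = [a, verb, b]
    edges = [(1, 0, "nominal-subject"), (1, 2, "direct-object")]
    mentions = [(0, 1, a), (2, 3, b)]
    return tokens, edges, mentions, 1, {_pair(a, b)}, set()


def _template_conjunction(a: str, verb: str, b: str, c: str):
    tokens = [a, verb, b, "and", c]
    edges = [
        (1, 0, "nominal-subject"),
        (1, 2, "direct-object"),
        (2, 4, "conjunct-and"),
        (2, 3, "coordination"),
    ]
    mentions = [(0, 1, a), (2, 3, b), (4, 5, c)]
    return tokens, edges, mentions, 1, {_pair(a, b), _pair(a, c)}, {_pair(b, c)}


def _template_nominal(a: str, noun: str, b: str):
    tokens = [noun, "of", b, "by", a]
    edges = [
        (0, 2, "prepositional-of"),
        (2, 1, "case-marker"),
        (0, 4, "prepositional-by"),
        (4, 3, "case-marker"),
    ]
    mentions = [(2, 3, b), (4, 5, a)]
    return tokens, edges, mentions, 0, {_pair(a, b)}, set()


def _template_decoy(a: str, b: str):
    tokens = [a, "and", b, "were", "measured"]
    edges = [
        (4, 0, "passive-subject"),
        (0, 2, "conjunct-and"),
        (0, 1, "coordination"),
        (4, 3, "auxiliary"),
    ]
    mentions = [(0, 1, a), (2, 3, b)]
    return tokens, edges, mentions, 4, set(), set()


def _decorate_context(tokens, edges, root, context_token: str | None):
    """Append "after <token>" attached to the root, e.g. a vaccine mention."""
    if context_token is None:
        return tokens, edges
    i_after = len(tokens)
    tokens = tokens + ["after", context_token]
    edges = edges + [
        (root, i_after + 1, "nominal-modifier"),
        (i_after + 1, i_after, "case-marker"),
    ]
    return tokens, edges


def generate_corpus(spec: SyntheticSpec) -> SyntheticCorpus:
    """Deterministically generate sentences, abstracts and their ledger.

    Planted interaction pairs form a connected graph containing the seed
    gene, so the seed-restricted generic network can recover them all.
    The first interaction sentence uses the conjunction template, which
    also plants a known non-interacting pair for classifier training.
    """
    rng = random.Random(spec.seed)
    truth = GroundTruth()
    connected: list[str] = [spec.seed_gene]
    forbidden: set[tuple[str, str]] = set()  # planted-negative pairs

    def fresh_partner(a: str, exclude: set[str]) -> str | None:
        options = [
            g
            for g in spec.gene_vocab
            if g != a
            and g not in exclude
            and _pair(a, g) not in truth.planted_pairs
            and _pair(a, g) not in forbidden
        ]
        return rng.choice(options) if options else None

    # --- plan interaction sentences ------------------------------------
    planned: list[tuple] = []  # (tokens, edges, mentions, root, pos, neg, template)
    while len(truth.planted_pairs) < spec.n_planted_interactions:
        remaining = spec.n_planted_interactions - len(truth.planted_pairs)
        force_conj = not planned  # guarantee one negative-pair example
        template = (
            "conjunction"
            if force_conj and remaining >= 2
            else rng.choice(
                [t for t in TEMPLATES if t != "conjunction" or remaining >= 2]
            )
        )
        a = rng.choice(connected)
        if template == "conjunction":
            b = fresh_partner(a, exclude=set())
            if b is None:
                continue
            c = fresh_partner(a, exclude={b})
            if c is None or _pair(b, c) in truth.planted_pairs:
                template = "svo"
            else:
                tok, ed, men, root, pos, neg = _template_conjunction(
                    a, rng.choice(_VERBS), b, c
                )
                forbidden |= neg
                planned.append((tok, ed, men, root, pos, neg, "conjunction"))
                truth.planted_pairs |= pos
                for g in (b, c):
                    if g not in connected:
                        connected.append(g)
                continue
        b = fresh_partner(a, exclude=set())
        if b is None:
            break
        if template == "nominal":
            tok, ed, men, root, pos, neg = _template_nominal(
                a, rng.choice(_NOUNS), b
            )
        else:
            tok, ed, men, root, pos, neg = _template_svo(a, rng.choice(_VERBS), b)
        planned.append((tok, ed, men, root, pos, neg, template))
        truth.planted_pairs |= pos
        if b not in connected:
            connected.append(b)

    # --- decoys ----------------------------------------------------------
    n_int = len(planned)
    n_decoys = round(n_int * spec.decoy_rate / (1 - spec.decoy_rate))
    for _ in range(n_decoys):
        a, b = rng.sample(spec.gene_vocab, 2)
        tok, ed, men, root, pos, neg = _template_decoy(a, b)
        planned.append((tok, ed, men, root, pos, neg, "decoy"))
    rng.shuffle(planned)

    # --- assign documents, contexts; build sentence objects --------------
    sentences: list[SentenceParse] = []
    doc_texts: dict[str, list[str]] = {}
    doc_sentence_count: dict[str, int] = {}
    doc_contents: dict[str, tuple[set[str], set[str]]] = {}  # genes, vaccines
    p_none, p_generic, _ = spec.context_probs
    for tok, ed, men, root, pos, neg, template in planned:
        doc_id = f"SYN{rng.randrange(spec.n_documents):04d}"
        idx = doc_sentence_count.get(doc_id, 0)
        doc_sentence_count[doc_id] = idx + 1
        tags: set[str] = set()
        context_token: str | None = None
        if template != "decoy":
            u = rng.random()
            if u < p_none:
                pass
            elif u < p_none + p_generic:
                context_token = "vaccination"
                tags.add("generic_vaccine")
            else:
                context_token = rng.choice(spec.vaccine_vocab)
                tags.add("vo_term:" + context_token)
        tok2, ed2 = _decorate_context(tok, ed, root, context_token)
        sent = SentenceParse(
            document_id=doc_id,
            sentence_index=idx,
            tokens=tuple(tok2),
            dep_edges=tuple(ed2),
            mentions=tuple(
                GeneMention(start=s, end=e, surface=g) for s, e, g in men
            ),
        )
        sentences.append(sent)
        doc_texts.setdefault(doc_id, []).append(sent.text)
        genes_here = {g for _, _, g in men}
        vaccines_here = (
            {context_token} if context_token in spec.vaccine_vocab else set()
        )
        prev_g, prev_v = doc_contents.get(doc_id, (set(), set()))
        doc_contents[doc_id] = (prev_g | genes_here, prev_v | vaccines_here)
        truth.sentences.append(
            SentenceGroundTruth(
                document_id=doc_id,
                sentence_index=idx,
                template=template,
                positive_pairs=frozenset(pos),
                negative_pairs=frozenset(neg),
                tags=frozenset(tags),
                is_decoy=template == "decoy",
            )
        )

    # --- abstracts: per-document digests + dedicated co-occurrence plants
    abstracts = [
        AbstractRecord(document_id=doc, text=" . ".join(texts))
        for doc, texts in sorted(doc_texts.items())
    ]
    for i in range(spec.n_cooccurrence_abstracts):
        doc_id = f"COOC{i:04d}"
        vaccine = rng.choice(spec.vaccine_vocab)
        genes = rng.sample(spec.gene_vocab, rng.randint(1, 2))
        text = (
            "Expression of "
            + " and ".join(genes)
            + f" was studied after {vaccine} administration ."
        )
        abstracts.append(AbstractRecord(document_id=doc_id, text=text))
        doc_contents[doc_id] = (set(genes), {vaccine})
    for doc_id, (genes, vaccines) in doc_contents.items():
        for v in vaccines:
            for g in genes:
                truth.associations.setdefault(v, {}).setdefault(g, set()).add(
                    doc_id
                )

    sentences.sort(key=lambda s: (s.document_id, s.sentence_index))
    return SyntheticCorpus(
        spec=spec, sentences=sentences, abstracts=abstracts, truth=truth
    )


def labeled_paths(corpus: SyntheticCorpus) -> list[LabeledPath]:
    """Ground-truth labeled dependency paths for every planted pair.

    Positive examples are the shortest paths of planted interacting
    pairs; negatives are the sibling pairs of conjunction sentences.
    """
    dictionary = corpus.gene_dictionary()
    by_key = {(s.document_id, s.sentence_index): s for s in corpus.sentences}
    out: list[LabeledPath] = []
    for gt in corpus.truth.sentences:
        if gt.is_decoy:
            continue
        sent = normalize_mentions(
            by_key[(gt.document_id, gt.sentence_index)], dictionary
        )
        mention_by_symbol = {m.symbol: m for m in sent.mentions if m.symbol}
        for pairs, label in (
            (gt.positive_pairs, INTERACTING),
            (gt.negative_pairs, NOT_INTERACTING),
        ):
            for ga, gb in sorted(pairs):
                path = shortest_path(
                    sent, (mention_by_symbol[ga], mention_by_symbol[gb])
                )
                out.append(LabeledPath(path=path, label=label))
    return out
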