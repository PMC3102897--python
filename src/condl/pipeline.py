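"""End-to-end convenience wrappers tying the pipeline stages together."""

from __future__ import annotations

from typing import Iterable, Sequence

from .corpus import (
    DEFAULT_VACCINE_VARIANTS,
    GeneDictionary,
    SentenceParse,
    normalize_mentions,
    select_candidates,
)
from .networks import LAYERS, GeneNetwork, build_network
from .ontology import OntologyTerm
from .relations import (
    ExtractedInteraction,
    PathClassifier,
    extract_interactions,
)

__all__ = ["run_extraction", "build_layered_networks"]


def run_extraction(
    sentences: Iterable[SentenceParse],
    dictionary: GeneDictionary,
    keywords: Sequence[str],
    classifier: PathClassifier,
    terms: Sequence[OntologyTerm] = (),
    vaccine_variants: Sequence[str] = DEFAULT_VACCINE_VARIANTS,
) -> list[ExtractedInteraction]:
    """Normalize, select candidate sentences, and classify every gene pair."""
    normalized = (normalize_mentions(s, dictionary) for s in sentences)
    candidates = select_candidates(
        normalized, keywords, vaccine_variants=vaccine_variants, terms=terms
    )
    return extract_interactions(candidates, classifier)


def build_layered_networks(
    interactions: Sequence[ExtractedInteraction],
    seed_gene: str | None = None,
) -> dict[str, GeneNetwork]:
    """The three nested seed-gene networks, one per layer."""
    return {
        layer: build_network(interactions, layer=layer, seed_gene=seed_gene)
        for layer in LAYERS
    }
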