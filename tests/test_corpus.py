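from __future__ import annotations

import itertools
import math

import pytest

from condl.corpus import (
    CorpusError,
    GeneDictionary,
    GeneMention,
    SentenceParse,
    load_gene_dictionary,
    normalize_mentions,
    read_corpus,
    select_candidates,
    write_corpus,
)
from condl import fixtures as fx
from condl.ontology import OntologyTerm

KEYWORDS = ["up-regulated", "induced", "down-regulated", "activates"]


def simple_sentence(symbols, extra_tokens=(), keyword="activates"):
    """A flat parse: token 0 is the verb's subject, the rest its children."""
    tokens = [symbols[0], keyword, *symbols[1:], *extra_tokens]
    edges = [(1, 0, "nominal-subject")] + [
        (1, i, "dependent") for i in range(2, len(tokens))
    ]
    mentions = tuple(
        GeneMention(start=i, end=i + 1, surface=tok)
        for i, tok in enumerate(tokens)
        if tok in symbols
    )
    return SentenceParse(
        document_id="doc1",
        sentence_index=0,
        tokens=tuple(tokens),
        dep_edges=tuple(edges),
        mentions=mentions,
    )


class TestGeneDictionary:
    def test_symbol_accumulates_synonyms(self, tmp_path):
        path = tmp_path / "d.tsv"
        path.write_text("IFNG\tIFN-gamma\nIFNG\tinterferon gamma\n")
        d = load_gene_dictionary(path)
        assert d.symbols == ["IFNG"]
        assert d.synonyms_of("IFNG") == ["IFNG", "IFN-gamma", "interferon gamma"]
        assert d.lookup("ifn-GAMMA") == "IFNG"

    def test_empty_file_gives_empty_dictionary(self, tmp_path):
        path = tmp_path / "d.tsv"
        path.write_text("")
        assert len(load_gene_dictionary(path)) == 0

    def test_ambiguous_synonym_dropped_from_lookup(self, caplog):
        d = GeneDictionary({"A1": ["shared"], "A2": ["shared", "unique"]})
        assert d.lookup("shared") is None
        assert d.lookup("unique") == "A2"
        # the raw rows still resolve unambiguous names (lookup oracle)
        for symbol in ("A1", "A2"):
            assert d.lookup(symbol) == symbol

    def test_symbol_is_its_own_synonym(self):
        d = GeneDictionary({"TNF": []})
        assert d.lookup("tnf") == "TNF"


class TestNormalizeMentions:
    def test_surface_resolves_via_synonym(self, worked_example_dictionary):
        sent = simple_sentence(["IFN-alpha", "IL-12"])
        out = normalize_mentions(sent, worked_example_dictionary)
        assert [m.symbol for m in out.mentions] == ["IFNA1", "IL12B"]

    def test_unknown_surface_gets_null_symbol(self, worked_example_dictionary):
        sent = simple_sentence(["NOSUCH", "IL-12"])
        out = normalize_mentions(sent, worked_example_dictionary)
        assert [m.symbol for m in out.mentions] == [None, "IL12B"]

    def test_duplicate_symbol_yields_no_self_pair(self, worked_example_dictionary):
        sent = SentenceParse(
            document_id="d",
            sentence_index=0,
            tokens=("IL-12", "activates", "IL-12", "and", "TNF-alpha"),
            dep_edges=(
                (1, 0, "nominal-subject"),
                (1, 2, "direct-object"),
                (2, 4, "conjunct-and"),
                (2, 3, "coordination"),
            ),
            mentions=(
                GeneMention(0, 1, "IL-12"),
                GeneMention(2, 3, "IL-12"),
                GeneMention(4, 5, "TNF-alpha"),
            ),
        )
        out = normalize_mentions(sent, worked_example_dictionary)
        (cand,) = select_candidates([out], KEYWORDS)
        # 2 distinct symbols -> C(2,2)=1 pair, never a self-pair
        assert cand.gene_pairs == (("IL12B", "TNF"),)


class TestSelectCandidates:
    def test_worked_example_kept_with_six_pairs(self, worked_example):
        (cand,) = select_candidates([worked_example], KEYWORDS)
        assert len(cand.gene_pairs) == 6
        assert set(cand.matched_keywords) == {
            "up-regulated",
            "induced",
            "down-regulated",
        }

    def test_hyphenated_token_matches_keyword_subtoken(self, worked_example):
        (cand,) = select_candidates([worked_example], ["induced"])
        assert cand.matched_keywords == ("induced",)

    def test_single_gene_sentence_dropped(self, worked_example_dictionary):
        sent = normalize_mentions(
            simple_sentence(["IL-12", "nothing"]), worked_example_dictionary
        )
        assert select_candidates([sent], KEYWORDS) == []

    def test_no_keyword_sentence_dropped(self, worked_example_dictionary):
        sent = normalize_mentions(
            simple_sentence(["IL-12", "TNF-alpha"], keyword="measured"),
            worked_example_dictionary,
        )
        assert select_candidates([sent], KEYWORDS) == []

    def test_vo_term_tag_without_generic_word(self, worked_example):
        terms = [OntologyTerm(id="BCG", label="BCG")]
        (cand,) = select_candidates([worked_example], KEYWORDS, terms=terms)
        assert cand.context_tags == {"vo_term:BCG"}

    def test_generic_tag_from_variant_token(self, worked_example_dictionary):
        sent = normalize_mentions(
            simple_sentence(["IFN-alpha", "IL-12"], extra_tokens=("vaccination",)),
            worked_example_dictionary,
        )
        (cand,) = select_candidates([sent], KEYWORDS)
        assert cand.context_tags == {"generic_vaccine"}

    def test_vaccine_word_terms_excluded_from_specific_matching(self, worked_example_dictionary):
        sent = normalize_mentions(
            simple_sentence(["IFN-alpha", "IL-12"], extra_tokens=("Fluarix",)),
            worked_example_dictionary,
        )
        terms = [
            OntologyTerm(id="Fluarix", label="Fluarix"),
            OntologyTerm(
                id="influenza vaccine", label="influenza vaccine",
                synonyms=["Fluarix"], has_vaccine_word=True,
            ),
        ]
        (cand,) = select_candidates([sent], KEYWORDS, terms=terms)
        assert cand.context_tags == {"vo_term:Fluarix"}

    @pytest.mark.parametrize("k", [2, 3, 4, 5])
    def test_pair_count_is_k_choose_2(self, k, worked_example_dictionary):
        surfaces = ["IFN-alpha", "IL-12", "TNF-alpha", "IL-10"][:k]
        extra = [] if k <= 4 else ["IFN-gamma"]
        d = GeneDictionary(
            {
                "IFNA1": ["IFN-alpha"],
                "IL12B": ["IL-12"],
                "TNF": ["TNF-alpha"],
                "IL10": ["IL-10"],
                "IFNG": ["IFN-gamma"],
            }
        )
        sent = normalize_mentions(simple_sentence(surfaces + extra), d)
        (cand,) = select_candidates([sent], KEYWORDS)
        assert len(cand.gene_pairs) == math.comb(len(surfaces) + len(extra), 2)
        # pairs are exactly the unordered pairs of distinct symbols
        symbols = sorted({m.symbol for m in sent.mentions})
        assert set(cand.gene_pairs) == set(itertools.combinations(symbols, 2))

    def test_idempotent_and_order_independent(self, worked_example, worked_example_dictionary):
        other = normalize_mentions(
            simple_sentence(["IL-12", "TNF-alpha"]), worked_example_dictionary
        )
        forward = select_candidates([worked_example, other], KEYWORDS)
        backward = select_candidates([other, worked_example], KEYWORDS)
        assert {c.sentence.document_id for c in forward} == {
            c.sentence.document_id for c in backward
        }
        again = select_candidates([c.sentence for c in forward], KEYWORDS)
        assert [c.gene_pairs for c in again] == [c.gene_pairs for c in forward]

    def test_tagging_monotone_in_variant_list(self, worked_example_dictionary):
        sent = normalize_mentions(
            simple_sentence(["IFN-alpha", "IL-12"], extra_tokens=("immunisation",)),
            worked_example_dictionary,
        )
        base = select_candidates([sent], KEYWORDS)
        extended = select_candidates(
            [sent], KEYWORDS,
            vaccine_variants=("vaccine", "vaccines", "vaccination", "vaccinated",
                              "immunisation"),
        )
        assert base[0].context_tags <= extended[0].context_tags
        assert "generic_vaccine" in extended[0].context_tags

    def test_empty_keyword_list_rejected(self, worked_example):
        with pytest.raises(CorpusError):
            select_candidates([worked_example], [])


class TestSentenceValidation:
    def test_edge_index_out_of_range(self):
        with pytest.raises(CorpusError, match="out of token range"):
            SentenceParse("d", 0, ("a", "b"), ((0, 5, "x"),))

    def test_cycle_rejected(self):
        with pytest.raises(CorpusError, match="cycle"):
            SentenceParse(
                "d", 0, ("a", "b", "c"),
                ((0, 1, "x"), (1, 2, "y"), (2, 0, "z")),
            )

    def test_mention_span_out_of_range(self):
        with pytest.raises(CorpusError, match="exceeds sentence length"):
            SentenceParse(
                "d", 0, ("a", "b"), ((0, 1, "x"),),
                mentions=(GeneMention(1, 3, "b c"),),
            )


def test_corpus_round_trip(tmp_path, worked_example):
    path = tmp_path / "corpus.jsonl"
    write_corpus([worked_example], path)
    (back,) = list(read_corpus(path))
    assert back == worked_example


def test_packaged_keyword_list_loads():
    keywords = fx.default_keywords()
    assert "induced" in keywords and len(keywords) > 20
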