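from __future__ import annotations

import math
import random

import numpy as np
import pytest

from helpers_oracles import edit_distance_recursive

from condl.corpus import GeneMention, SentenceParse
from condl.relations import (
    DependencyPath,
    INTERACTING,
    NOT_INTERACTING,
    KernelConfig,
    LabeledPath,
    PathClassifier,
    PathNotFound,
    edit_distance,
    evaluate,
    gram_matrix,
    read_labeled_paths,
    shortest_path,
    similarity,
    train,
    write_labeled_paths,
)
from condl import fixtures as fx

ALPHABET = ["nominal-subject", "direct-object", "conjunct-and", "up-regulated", "IL-12"]


def random_path(rng, max_len=6):
    length = rng.randrange(1, max_len + 1, 2)  # odd: label, word, ..., label
    return DependencyPath(elements=tuple(rng.choice(ALPHABET) for _ in range(length)))


class TestShortestPath:
    @pytest.mark.parametrize("pair_key", sorted(fx.WORKED_EXAMPLE_PATHS, key=sorted))
    def test_worked_example_paths(self, pair_key, worked_example, worked_example_mentions):
        a, b = sorted(pair_key)
        path = shortest_path(worked_example, (worked_example_mentions[a], worked_example_mentions[b]))
        assert path.elements == fx.WORKED_EXAMPLE_PATHS[pair_key]

    def test_direct_head_dependent_pair_single_label(self, worked_example, worked_example_mentions):
        # IL-12 and TNF-alpha are a direct head-dependent pair
        path = shortest_path(
            worked_example, (worked_example_mentions["IL-12"], worked_example_mentions["TNF-alpha"])
        )
        assert path.elements == ("conjunct-and",)

    def test_path_is_direction_agnostic(self, worked_example, worked_example_mentions):
        ab = shortest_path(worked_example, (worked_example_mentions["IFN-alpha"], worked_example_mentions["IL-10"]))
        ba = shortest_path(worked_example, (worked_example_mentions["IL-10"], worked_example_mentions["IFN-alpha"]))
        assert ab.elements == ba.elements

    def test_disconnected_fragments_raise(self):
        sent = SentenceParse(
            "d", 0, ("A", "activates", "B", "C"),
            ((1, 0, "nominal-subject"), (1, 2, "direct-object")),
            mentions=(GeneMention(0, 1, "A"), GeneMention(3, 4, "C")),
        )
        with pytest.raises(PathNotFound):
            shortest_path(sent, (sent.mentions[0], sent.mentions[1]))

    def test_multi_token_mention_head_is_span_root(self):
        # "complement component 3" spans 3 tokens headed by the last one
        sent = SentenceParse(
            "d", 0,
            ("complement", "component", "3", "activates", "B"),
            (
                (2, 0, "compound"), (2, 1, "compound"),
                (3, 2, "nominal-subject"), (3, 4, "direct-object"),
            ),
            mentions=(GeneMention(0, 3, "complement component 3"),
                      GeneMention(4, 5, "B")),
        )
        path = shortest_path(sent, (sent.mentions[0], sent.mentions[1]))
        assert path.elements == ("nominal-subject", "activates", "direct-object")


class TestEditDistance:
    def test_worked_example_distance_is_two(self, worked_example, worked_example_mentions):
        p1 = shortest_path(worked_example, (worked_example_mentions["IFN-alpha"], worked_example_mentions["IL-12"]))
        p2 = shortest_path(
            worked_example, (worked_example_mentions["IFN-alpha"], worked_example_mentions["TNF-alpha"])
        )
        # two insertions: the intermediate word and the conjunction label
        assert edit_distance(p1, p2) == 2

    def test_self_distance_zero(self):
        rng = random.Random(0)
        for _ in range(20):
            p = random_path(rng)
            assert edit_distance(p, p) == 0

    def test_matches_exhaustive_recursion_oracle(self):
        rng = random.Random(1)
        for _ in range(200):
            p, q = random_path(rng), random_path(rng)
            assert edit_distance(p, q) == edit_distance_recursive(
                p.elements, q.elements
            )

    def test_weighted_costs(self):
        config = KernelConfig(insert_cost=2.0, delete_cost=0.5, substitute_cost=1.5)
        assert edit_distance(("a",), ("a", "b", "c"), config) == 4.0
        assert edit_distance(("a", "b", "c"), ("a",), config) == 1.0
        assert edit_distance(("a",), ("b",), config) == 1.5


class TestSimilarity:
    def test_identical_paths_have_similarity_one(self):
        p = DependencyPath(elements=("nominal-subject",))
        assert similarity(p, p) == 1.0

    def test_closed_form_decay(self):
        config = KernelConfig(gamma=1.0)
        p = DependencyPath(elements=("a", "w", "b"))
        q = DependencyPath(elements=("a", "w", "b", "x", "c"))
        assert similarity(p, q, config) == pytest.approx(math.exp(-2), abs=1e-12)

    def test_symmetric_and_bounded(self):
        rng = random.Random(2)
        for _ in range(50):
            p, q = random_path(rng), random_path(rng)
            s = similarity(p, q)
            assert 0 < s <= 1
            assert s == pytest.approx(similarity(q, p), abs=1e-15)

    def test_exponent_is_additive_over_distances(self):
        config = KernelConfig(gamma=0.7)
        p = DependencyPath(elements=("a", "w", "b"))
        q = DependencyPath(elements=("a", "w", "c"))          # d(p,q)=1
        r = DependencyPath(elements=("a", "x", "c"))          # d(q,r)=1, d(p,r)=2
        assert similarity(p, r, config) == pytest.approx(
            similarity(p, q, config) * similarity(q, r, config), rel=1e-12
        )


class TestGramMatrix:
    def test_single_path_gets_ridge(self):
        p = DependencyPath(elements=("a",))
        K = gram_matrix([p], KernelConfig(diagonal_ridge=0.25))
        assert K.shape == (1, 1) and K[0, 0] == 1.25

    def test_identical_paths_all_ones_without_ridge(self):
        p = DependencyPath(elements=("a", "w", "b"))
        K = gram_matrix([p, p], KernelConfig(diagonal_ridge=0.0))
        assert np.allclose(K, 1.0)

    def test_matches_pairwise_similarity_oracle(self):
        rng = random.Random(3)
        paths = [random_path(rng) for _ in range(10)]
        config = KernelConfig(gamma=0.5, diagonal_ridge=0.01)
        K = gram_matrix(paths, config)
        assert np.allclose(K, K.T)
        for i in range(10):
            for j in range(10):
                expected = (
                    1.0 + config.diagonal_ridge
                    if i == j
                    else math.exp(-0.5 * edit_distance_recursive(
                        paths[i].elements, paths[j].elements))
                )
                assert K[i, j] == pytest.approx(expected, rel=1e-12)

    def test_large_ridge_makes_matrix_positive_definite(self):
        rng = random.Random(4)
        paths = [random_path(rng) for _ in range(8)]
        n = len(paths)
        # diagonal dominance: ridge >= (n-1) * max off-diagonal similarity
        K = gram_matrix(paths, KernelConfig(diagonal_ridge=float(n - 1)))
        assert np.linalg.eigvalsh(K).min() > 0


def separable_examples(n_pos=8, n_neg=8, seed=5):
    """Positives all contain the word "activates"; negatives never do."""
    rng = random.Random(seed)
    labels_pool = ["nominal-subject", "direct-object", "nominal-modifier"]
    examples = []
    for i in range(n_pos):
        path = (rng.choice(labels_pool), "activates", rng.choice(labels_pool))
        examples.append(
            LabeledPath(DependencyPath(elements=path), INTERACTING)
        )
    for i in range(n_neg):
        path = (rng.choice(labels_pool), "conjunct-and")
        examples.append(
            LabeledPath(
                DependencyPath(elements=(path[1],)), NOT_INTERACTING
            )
        )
    return examples


class TestClassifier:
    def test_separable_set_training_accuracy(self):
        examples = separable_examples()
        clf = train(examples, C=1.0, config=KernelConfig(gamma=2.0))
        metrics = evaluate(clf, examples)
        assert metrics["accuracy"] == 1.0

    def test_path_identical_to_support_gets_its_label(self):
        examples = separable_examples()
        clf = train(examples, C=1.0, config=KernelConfig(gamma=2.0))
        for sp in clf.support_paths:
            by_elements = {ex.path.elements: ex.label for ex in examples}
            label, _ = clf.classify(sp)
            assert label == by_elements[sp.elements]

    def test_training_order_invariance(self):
        examples = separable_examples()
        clf1 = train(examples, C=1.0)
        shuffled = list(examples)
        random.Random(9).shuffle(shuffled)
        clf2 = train(shuffled, C=1.0)
        rng = random.Random(10)
        for _ in range(20):
            probe = random_path(rng)
            assert clf1.decision(probe) == pytest.approx(
                clf2.decision(probe), abs=1e-6
            )

    def test_single_class_input_rejected(self):
        pos_only = [ex for ex in separable_examples() if ex.label == INTERACTING]
        with pytest.raises(ValueError, match="both classes"):
            train(pos_only)

    def test_empty_model_rejected_at_construction(self):
        with pytest.raises(ValueError, match="support path"):
            PathClassifier(support_paths=[], dual_coef=np.array([]), bias=0.0)

    def test_zero_decision_resolves_to_not_interacting(self):
        p = DependencyPath(elements=("a",))
        clf = PathClassifier(
            support_paths=[p], dual_coef=np.array([0.0]), bias=0.0
        )
        label, value = clf.classify(p)
        assert value == 0.0 and label == NOT_INTERACTING

    def test_model_round_trip(self, tmp_path):
        clf = train(separable_examples(), C=2.0, config=KernelConfig(gamma=0.8))
        path = tmp_path / "model.json"
        clf.save(path)
        back = PathClassifier.load(path)
        assert back.C == 2.0 and back.config.gamma == 0.8
        probe = DependencyPath(elements=("nominal-subject", "activates", "x"))
        assert back.decision(probe) == pytest.approx(clf.decision(probe), abs=1e-12)


def test_labeled_path_tsv_round_trip(tmp_path):
    examples = separable_examples(n_pos=3, n_neg=3)
    path = tmp_path / "paths.tsv"
    write_labeled_paths(examples, path)
    assert read_labeled_paths(path) == examples
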