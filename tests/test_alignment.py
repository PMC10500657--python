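"""Cross-ontology score alignment: baseline, affiliation, training, reranking."""

import numpy as np
import pytest

import chemkgqa as c
from chemkgqa.alignment import merged_gold_ranks
from chemkgqa.qa import ScoredCandidate
from chemkgqa.synthetic import generate_alignment_benchmark


def cand(entity, score, ont="o1"):
    return ScoredCandidate(entity=entity, score=score, normalized_score=score,
                           ontology_label=ont)


class TestBaselineNormalization:
    def test_divides_by_maximum(self):
        out = c.normalize_scores_baseline({"o1": [cand("a", 2.0), cand("b", 4.0)]})
        assert [(x.entity, x.normalized_score) for x in out] == [("b", 1.0), ("a", 0.5)]

    def test_single_answer_becomes_one(self):
        out = c.normalize_scores_baseline({"o1": [cand("a", 0.3)]})
        assert out[0].normalized_score == 1.0

    def test_scale_invariance(self):
        answers = {"o1": [cand("a", 1.0), cand("b", 0.5)],
                   "o2": [cand("x", 3.0, "o2"), cand("y", 1.5, "o2")]}
        base = [x.entity for x in c.normalize_scores_baseline(answers)]
        answers2 = {"o1": answers["o1"],
                    "o2": [cand("x", 300.0, "o2"), cand("y", 150.0, "o2")]}
        assert [x.entity for x in c.normalize_scores_baseline(answers2)] == base

    def test_nonpositive_maximum_maps_to_zero(self, caplog):
        import logging
        with caplog.at_level(logging.WARNING):
            out = c.normalize_scores_baseline({"o1": [cand("a", -1.0), cand("b", -2.0)]})
        assert all(x.normalized_score == 0.0 for x in out)
        assert any("non-positive" in r.message for r in caplog.records)


class TestAffiliation:
    @pytest.fixture(scope="class")
    @staticmethod
    def trained():
        train, test = generate_alignment_benchmark(seed=1, n_questions=80)
        # make half the questions belong to a second ontology so both labels
        # have positive base rates and disjoint vocabularies
        for i, ex in enumerate(train + test):
            if i % 2:
                ex.question = ex.question.replace("what is the",
                                                  "compute the orbital")
                ex.gold_ontology = "ontoB"
                ex.gold_entity = ex.answers["ontoB"][0].entity
        model = c.train_alignment(train, seed=0, epochs=30)
        return model, train, test

    def test_disjoint_vocabulary_accuracy(self, trained):
        model, _, test = trained
        correct = 0
        for ex in test:
            aff = c.compute_affiliation(ex.question, model)
            if max(aff, key=aff.get) == ex.gold_ontology:
                correct += 1
        assert correct / len(test) >= 0.95

    def test_empty_question_returns_base_rates(self, trained):
        model, train, _ = trained
        aff = c.compute_affiliation("", model)
        for ont in ("ontoA", "ontoB"):
            base = sum(1 for ex in train if ex.gold_ontology == ont) / len(train)
            assert aff[ont] == pytest.approx(base)

    def test_deterministic(self, trained):
        model, _, test = trained
        q = test[0].question
        assert c.compute_affiliation(q, model) == c.compute_affiliation(q, model)

    def test_untrained_model_rejected(self):
        model = c.AlignmentModel(ontologies=["o"], vocabulary={}, scale={"o": 1.0},
                                 bias_weights={"o": np.zeros(1)})
        with pytest.raises(ValueError):
            c.compute_affiliation("q", model)


class TestTraining:
    def test_single_ontology_rejected(self):
        ex = c.AlignmentExample("q", "a", "o1", {"o1": [cand("a", 1.0)]})
        with pytest.raises(ValueError, match="2 ontologies"):
            c.train_alignment([ex])

    def test_same_seed_identical_parameters(self):
        train, _ = generate_alignment_benchmark(seed=2, n_questions=20)
        m1 = c.train_alignment(train, seed=7, epochs=20)
        m2 = c.train_alignment(train, seed=7, epochs=20)
        assert m1.scale == m2.scale
        for o in m1.ontologies:
            assert np.array_equal(m1.bias_weights[o], m2.bias_weights[o])

    def test_already_aligned_engines_stay_perfect(self):
        """When scores are already comparable and gold is the global top,
        the learned adjustment preserves hits@1 = 1."""
        rng = np.random.default_rng(4)
        examples = []
        for i in range(30):
            gold = f"A:g{i}"
            a = [cand(gold, 1.0, "oA"), cand(f"A:d{i}", float(rng.uniform(0.2, 0.6)), "oA")]
            b = [cand(f"B:d{i}", float(rng.uniform(0.2, 0.6)), "oB")]
            examples.append(c.AlignmentExample(f"prop {i}?", gold, "oA",
                                               {"oA": a, "oB": b}))
        model = c.train_alignment(examples, seed=0, epochs=50)
        ranks = merged_gold_ranks(examples, model)
        assert c.hits_at_k(ranks, 1) == 1.0

    def test_scale_mismatch_experiment_beats_baseline(self):
        """10x-scale junk engine: learned alignment strictly improves merged
        hits@1 over max normalization."""
        train, test = generate_alignment_benchmark(seed=5)
        model = c.train_alignment(train, seed=0)
        base_hits = c.hits_at_k(merged_gold_ranks(test, model=None), 1)
        aligned_hits = c.hits_at_k(merged_gold_ranks(test, model=model), 1)
        assert aligned_hits > base_hits
        assert aligned_hits >= 0.9


class TestRerank:
    def test_identity_model_matches_baseline_order(self):
        answers = {"o1": [cand("a", 1.0), cand("b", 0.25)],
                   "o2": [cand("x", 8.0, "o2"), cand("y", 2.0, "o2")]}
        model = c.AlignmentModel(ontologies=["o1", "o2"], vocabulary={},
                                 scale={"o1": 1.0, "o2": 1.0},
                                 bias_weights={"o1": np.zeros(1), "o2": np.zeros(1)})
        merged = c.rerank_cross_ontology("q", answers, model)
        base = c.normalize_scores_baseline(answers)
        assert [x.entity for x in merged] == [x.entity for x in base]

    def test_single_ontology_order_unchanged(self):
        answers = {"o1": [cand("a", 0.9), cand("b", 0.7), cand("c", 0.1)]}
        model = c.AlignmentModel(ontologies=["o1"], vocabulary={},
                                 scale={"o1": 3.7}, bias_weights={"o1": np.ones(1)})
        merged = c.rerank_cross_ontology("q", answers, model)
        assert [x.entity for x in merged] == ["a", "b", "c"]

    def test_within_ontology_order_never_changes(self):
        train, test = generate_alignment_benchmark(seed=6, n_questions=30)
        model = c.train_alignment(train, seed=1, epochs=50)
        for ex in test:
            merged = c.rerank_cross_ontology(ex.question, ex.answers, model)
            for ont, cands in ex.answers.items():
                orig = [x.entity for x in sorted(cands, key=lambda z: -z.normalized_score)]
                kept = [x.entity for x in merged if x.ontology_label == ont]
                assert kept == orig

    def test_matches_full_sort_oracle(self):
        train, test = generate_alignment_benchmark(seed=8, n_questions=20)
        model = c.train_alignment(train, seed=2, epochs=30)
        for ex in test[:5]:
            merged = c.rerank_cross_ontology(ex.question, ex.answers, model)
            adjusted = []
            for ont, cands in ex.answers.items():
                top = max(x.normalized_score for x in cands)
                for x in cands:
                    adjusted.append((model.adjust(ex.question, ont,
                                                  x.normalized_score / top),
                                     ont, x.entity))
            oracle = [e for _, _, e in sorted(adjusted, key=lambda z: (-z[0], z[1], z[2]))]
            assert [x.entity for x in merged] == oracle

    def test_unknown_ontology_rejected(self):
        model = c.AlignmentModel(ontologies=["o1"], vocabulary={},
                                 scale={"o1": 1.0}, bias_weights={"o1": np.zeros(1)})
        with pytest.raises(KeyError):
            c.rerank_cross_ontology("q", {"o2": [cand("a", 1.0, "o2")]}, model)

    def test_save_load_roundtrip(self, tmp_path):
        train, test = generate_alignment_benchmark(seed=9, n_questions=20)
        model = c.train_alignment(train, seed=3, epochs=20)
        model.save(tmp_path / "model.json")
        back = c.AlignmentModel.load(tmp_path / "model.json")
        ex = test[0]
        assert [x.entity for x in c.rerank_cross_ontology(ex.question, ex.answers, back)] == \
               [x.entity for x in c.rerank_cross_ontology(ex.question, ex.answers, model)]
        assert c.compute_affiliation(ex.question, back) == \
               pytest.approx(c.compute_affiliation(ex.question, model))
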