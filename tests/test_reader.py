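"""The attention-sum reader: embeddings, encoders, attention, training."""

import copy
import math

import numpy as np
import pytest

from biocloze.cloze import PLACEHOLDER, ClozeInstance
from biocloze.corpus_io import WordVectorTable
from biocloze.nn import GRUDirection
from biocloze.reader import (INIT_INTERVAL, ReaderConfig,
                             ReaderModel, TYPE_ORDER, Vocabulary,
                             attention_distribution, encode_instance,
                             init_embeddings, pointer_sum, train)


def tiny_instance(doc, question, answer, types=None):
    doc, question = tuple(doc.split()), tuple(question.split())
    candidates = tuple(dict.fromkeys(t for t in doc if t.startswith("@entity")))
    positions = {c: tuple(i for i, t in enumerate(doc) if t == c)
                 for c in candidates}
    return ClozeInstance(doc, question, answer, candidates, positions,
                         types or {c: "Unknown" for c in candidates}, "T", "toy")


@pytest.fixture()
def toy_instances():
    first = tiny_instance(
        "@entity1 binds w1 @entity2 near w2 @entity1 end",
        f"what binds {PLACEHOLDER} ?", "@entity1")
    second = tiny_instance(
        "w3 @entity2 w1 @entity3 w4 @entity2",
        f"{PLACEHOLDER} appears twice", "@entity2")
    return [first, second]


class TestInitEmbeddings:
    def test_pretrained_rows_copied_exactly_and_oov_in_interval(self):
        vocab = Vocabulary(["ncoa1", "@entity1", "w1"])
        table = WordVectorTable(4, {"ncoa1": np.array([1.0, -2.0, 0.5, 3.0])})
        config = ReaderConfig(word_dim=4, type_dim=0, hidden_size=2, seed=0)
        emb = init_embeddings(vocab, table, config)
        assert emb.word_rows[vocab.id("ncoa1")].tolist() == [1.0, -2.0, 0.5, 3.0]
        oov_rows = [emb.word_rows[vocab.id(t)] for t in ("@entity1", "w1", "@unk")]
        for row in oov_rows:
            assert np.all(np.abs(row) < INIT_INTERVAL)

    def test_case_insensitive_pretrained_lookup(self):
        vocab = Vocabulary(["NCOA1"])
        table = WordVectorTable(2, {"ncoa1": np.array([9.0, 9.0])})
        config = ReaderConfig(word_dim=2, type_dim=0, hidden_size=2)
        emb = init_embeddings(vocab, table, config)
        assert emb.word_rows[vocab.id("NCOA1")].tolist() == [9.0, 9.0]

    def test_dimension_mismatch_is_an_error(self):
        vocab = Vocabulary(["a"])
        table = WordVectorTable(3, {"a": np.zeros(3)})
        with pytest.raises(ValueError, match="dimension"):
            init_embeddings(vocab, table,
                            ReaderConfig(word_dim=5, hidden_size=2))

    def test_type_embedding_widens_model_input(self):
        vocab = Vocabulary(["a"])
        config = ReaderConfig(word_dim=6, type_dim=20, hidden_size=2,
                              use_type_embedding=True)
        emb = init_embeddings(vocab, None, config)
        assert emb.input_dim == 26
        assert emb.type_rows.shape == (len(TYPE_ORDER), 20)
        assert np.all(np.abs(emb.type_rows) < INIT_INTERVAL)


class TestAttentionDistribution:
    def test_single_position_is_certain(self):
        s = attention_distribution(np.ones((1, 4)), np.ones(4))
        assert s.tolist() == [1.0]

    def test_equal_scores_give_uniform(self):
        s = attention_distribution(np.tile([1.0, 2.0], (5, 1)), np.array([0.3, -0.1]))
        assert np.allclose(s, 0.2)

    def test_closed_form_softmax(self):
        # dot products (ln 2, 0, 0) -> (0.5, 0.25, 0.25)
        enc = np.array([[math.log(2.0)], [0.0], [0.0]])
        s = attention_distribution(enc, np.array([1.0]))
        assert np.allclose(s, [0.5, 0.25, 0.25])

    def test_width_mismatch_raises(self):
        with pytest.raises(ValueError, match="width"):
            attention_distribution(np.ones((2, 3)), np.ones(4))

    def test_overflow_safe(self):
        enc = np.array([[800.0], [700.0]])
        s = attention_distribution(enc, np.array([1.0]))
        assert np.isfinite(s).all() and abs(s.sum() - 1.0) < 1e-12


class TestPointerSum:
    def test_worked_example(self):
        s = np.array([0.5, 0.3, 0.2])
        probs, predicted = pointer_sum(s, {"A": (0, 2), "B": (1,)})
        assert probs == {"A": 0.7, "B": 0.3} and predicted == "A"

    def test_empty_position_set_scores_zero(self):
        probs, predicted = pointer_sum(np.array([1.0]), {"A": (0,), "B": ()})
        assert probs["B"] == 0.0 and predicted == "A"

    def test_out_of_range_position_raises(self):
        with pytest.raises(IndexError):
            pointer_sum(np.array([1.0]), {"A": (3,)})

    def test_tie_breaks_to_earliest_first_occurrence(self):
        s = np.array([0.25, 0.25, 0.25, 0.25])
        _, predicted = pointer_sum(s, {"late": (1, 3), "early": (0, 2)})
        assert predicted == "early"

    def test_matches_double_loop_oracle_exactly(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = int(rng.integers(2, 40))
            s = rng.dirichlet(np.ones(n))
            positions = {f"c{k}": tuple(sorted(map(int, rng.choice(
                n, size=rng.integers(1, min(n, 4) + 1), replace=False))))
                for k in range(int(rng.integers(1, 6)))}
            probs, _ = pointer_sum(s, positions)
            for candidate, pos in positions.items():
                oracle = 0.0
                for p in sorted(pos):
                    oracle += float(s[p])
                assert probs[candidate] == oracle


class TestGruCell:
    def test_single_step_matches_hand_computation(self):
        gru = GRUDirection(2, 2, np.random.default_rng(0), "g")
        W = np.arange(12).reshape(2, 6) * 0.1 - 0.3
        Uzr = np.arange(8).reshape(2, 4) * 0.05
        Un = np.array([[0.2, -0.1], [0.4, 0.3]])
        b = np.linspace(-0.2, 0.2, 6)
        gru.params.update({"g.W": W, "g.Uzr": Uzr, "g.Un": Un, "g.b": b})
        x = np.array([[0.5, -1.0]])
        states, final, _ = gru.forward(x[:, None, :], np.ones((1, 1)))
        # hand evaluation of one gated step from h0 = 0
        a = x @ W + b
        z = 1 / (1 + np.exp(-a[:, 0:2]))
        r = 1 / (1 + np.exp(-a[:, 2:4]))
        n = np.tanh(a[:, 4:6])  # h0 = 0 so the recurrent term vanishes
        expected = (1 - z) * n
        assert np.allclose(final, expected, atol=1e-12)
        assert np.allclose(states[0, 0], expected[0], atol=1e-12)

    def test_reverse_direction_equals_forward_on_reversed_input(self):
        rng = np.random.default_rng(1)
        gru = GRUDirection(3, 4, rng, "g")
        X = rng.normal(size=(2, 7, 3))
        mask = np.ones((2, 7))
        states_rev, final_rev, _ = gru.forward(X, mask, reverse=True)
        states_fwd, final_fwd, _ = gru.forward(X[:, ::-1, :], mask)
        assert np.allclose(states_rev, states_fwd[:, ::-1, :])
        assert np.allclose(final_rev, final_fwd)


@pytest.fixture()
def toy_model(toy_instances):
    config = ReaderConfig(word_dim=6, type_dim=3, hidden_size=4,
                          use_type_embedding=True, seed=2)
    vocab = Vocabulary.from_instances(toy_instances)
    rng = np.random.default_rng(2)
    return ReaderModel(config, init_embeddings(vocab, None, config, rng), rng)


class TestEncoders:
    def test_context_encoding_shape(self, toy_model, toy_instances):
        fd = toy_model.encode_context(toy_instances[0])
        assert fd.shape == (len(toy_instances[0].document_tokens), 8)

    def test_query_encoding_width(self, toy_model, toy_instances):
        assert toy_model.encode_query(toy_instances[0]).shape == (8,)

    def test_distinct_questions_encode_distinctly(self, toy_model, toy_instances):
        g1 = toy_model.encode_query(toy_instances[0])
        g2 = toy_model.encode_query(toy_instances[1])
        assert not np.allclose(g1, g2)

    def test_empty_document_is_an_error(self, toy_model, toy_instances):
        import dataclasses
        empty = dataclasses.replace(toy_instances[0], document_tokens=())
        with pytest.raises(ValueError, match="empty document"):
            toy_model.encode_context(empty)


class TestPredict:
    def test_top1_is_argmax_and_full_ranking_is_everything(
            self, toy_model, toy_instances):
        result = toy_model.predict(toy_instances[0])
        assert result.top(1) == [result.predicted]
        assert set(result.top(100)) == set(toy_instances[0].candidates)
        assert abs(result.position_probs.sum() - 1.0) < 1e-6
        assert sum(result.candidate_probs.values()) <= 1.0 + 1e-6

    def test_tied_weights_still_rank_deterministically(self, toy_instances):
        config = ReaderConfig(word_dim=4, type_dim=0, hidden_size=3, seed=0)
        vocab = Vocabulary.from_instances(toy_instances)
        model = ReaderModel(config, init_embeddings(vocab, None, config))
        for key in model.params:
            model.params[key][...] = 0.0
        result = model.predict(toy_instances[0])
        # uniform attention: probabilities proportional to mention counts
        assert result.predicted == "@entity1"
        again = model.predict(toy_instances[0])
        assert result.ranked == again.ranked

    def test_relabeling_candidates_permutes_probabilities(
            self, toy_model, toy_instances):
        import dataclasses
        instance = toy_instances[0]
        swap = {"@entity1": "@entity2", "@entity2": "@entity1"}
        relabeled = dataclasses.replace(
            instance,
            document_tokens=tuple(swap.get(t, t) for t in instance.document_tokens),
            question_tokens=tuple(swap.get(t, t) for t in instance.question_tokens),
            answer=swap[instance.answer],
            candidates=tuple(swap.get(c, c) for c in instance.candidates),
            mention_positions={swap.get(c, c): p
                               for c, p in instance.mention_positions.items()},
            candidate_types={swap.get(c, c): t
                             for c, t in instance.candidate_types.items()})
        twin = copy.deepcopy(toy_model)
        vocab = twin.embeddings.vocab
        i1, i2 = vocab.id("@entity1"), vocab.id("@entity2")
        twin.params["emb.W"][[i1, i2]] = twin.params["emb.W"][[i2, i1]]
        base = toy_model.predict(instance)
        permuted = twin.predict(relabeled)
        for candidate, p in base.candidate_probs.items():
            assert permuted.candidate_probs[swap.get(candidate, candidate)] == \
                pytest.approx(p, abs=1e-12)


class TestTraining:
    def test_single_instance_loss_strictly_decreases(self, toy_instances):
        config = ReaderConfig(word_dim=6, type_dim=0, hidden_size=4, seed=1,
                              batch_size=1, max_epochs=5, patience=10)
        result = train(toy_instances[:1], toy_instances[:1], config)
        losses = [h["train_loss"] for h in result.history]
        assert all(b < a for a, b in zip(losses, losses[1:]))

    def test_same_seed_reproduces_history(self, toy_instances):
        config = ReaderConfig(word_dim=5, type_dim=0, hidden_size=3, seed=7,
                              batch_size=2, max_epochs=3, patience=5)
        first = train(toy_instances, toy_instances, config)
        second = train(toy_instances, toy_instances, config)
        assert first.history == second.history
        for key in first.model.params:
            assert np.array_equal(first.model.params[key],
                                  second.model.params[key])

    def test_structurally_invalid_instance_fails_before_training(
            self, toy_instances):
        import dataclasses
        broken = dataclasses.replace(toy_instances[0],
                                     mention_positions={"@entity1": (0,),
                                                        "@entity2": (3,),
                                                        "ghost": (1,)})
        config = ReaderConfig(word_dim=4, hidden_size=2, seed=0)
        with pytest.raises(Exception, match="position map|ghost"):
            train([broken], toy_instances[1:], config)

    def test_gradients_match_finite_differences(self, toy_model, toy_instances):
        encoded = [encode_instance(i, toy_model.embeddings.vocab)
                   for i in toy_instances]
        _, grads = toy_model.loss_and_gradients(encoded)
        rng = np.random.default_rng(6)
        eps = 1e-6
        for name, param in toy_model.params.items():
            for _ in range(3):
                idx = tuple(int(rng.integers(s)) for s in param.shape)
                original = param[idx]
                param[idx] = original + eps
                up, _ = toy_model.loss_and_gradients(encoded)
                param[idx] = original - eps
                down, _ = toy_model.loss_and_gradients(encoded)
                param[idx] = original
                numeric = (up - down) / (2 * eps)
                analytic = grads[name][idx]
                assert abs(numeric - analytic) <= 1e-4 * max(
                    1e-6, abs(numeric) + abs(analytic)), name

    def test_learns_planted_cue_task(self, trained_small, cue_splits):
        _, _, test_set = cue_splits
        assert trained_small.best_accuracy >= 0.9
        assert trained_small.model.accuracy(test_set) >= 0.9


class TestPersistence:
    def test_checkpoint_roundtrip_preserves_predictions(
            self, trained_small, cue_splits, tmp_path):
        _, _, test_set = cue_splits
        path = tmp_path / "model.json"
        trained_small.model.save(path)
        restored = ReaderModel.load(path)
        for instance in test_set[:5]:
            a = trained_small.model.predict(instance)
            b = restored.predict(instance)
            assert a.ranked == b.ranked
            assert np.array_equal(a.position_probs, b.position_probs)
        assert restored.validation_accuracy == trained_small.model.validation_accuracy


class TestTypeEmbeddingFlag:
    def test_disabled_flag_means_no_type_rows_at_all(self, toy_instances):
        config = ReaderConfig(word_dim=4, type_dim=20, hidden_size=3, seed=3,
                              use_type_embedding=False)
        vocab = Vocabulary.from_instances(toy_instances)
        model = ReaderModel(config, init_embeddings(vocab, None, config))
        assert "emb.T" not in model.params
        assert model.embeddings.type_dim == 0

    def test_type_rows_change_predictions_only_when_enabled(self, toy_instances):
        vocab = Vocabulary.from_instances(toy_instances)
        config_on = ReaderConfig(word_dim=4, type_dim=3, hidden_size=3, seed=3,
                                 use_type_embedding=True)
        model_on = ReaderModel(config_on, init_embeddings(vocab, None, config_on))
        before = model_on.predict(toy_instances[0]).candidate_probs
        model_on.params["emb.T"][...] += 1.0
        after = model_on.predict(toy_instances[0]).candidate_probs
        assert before != after
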