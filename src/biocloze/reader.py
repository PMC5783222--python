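"""The attention-sum reader: embeddings, bidirectional encoders, pointer sum.

The model embeds every token of the context ``d`` and the question ``q``
(optionally concatenating a learned entity-type vector to each word vector),
encodes ``d`` with a bidirectional gated recurrent encoder ``f`` into
per-position vectors ``f_i(d)`` and ``q`` with a second bidirectional
encoder ``g`` into a single vector ``g(q)``, scores every context position
by the dot product ``<f_i(d), g(q)>`` passed through a softmax, and scores
a candidate answer by *summing* the attention mass over all positions where
that candidate occurs:

    P(a | d, q) = sum_{i in I(a, d)} s_i

The candidate with maximal aggregated probability is the predicted answer.
Training minimizes -log P(a | d, q) of the gold candidate with Adam.
Word rows may be initialized from pretrained biomedical vectors; all rows
(word and type) remain trainable.
"""

from __future__ import annotations

import copy
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .cloze import ClozeInstance, PLACEHOLDER, validate_instance
from .corpus_io import WordVectorTable
from .lexicon import TYPE_LABELS, UNKNOWN_TYPE
from .nn import Adam, GRUDirection, clip_global_norm

log = logging.getLogger(__name__)

__all__ = [
    "UNK_TOKEN",
    "TYPE_ORDER",
    "ReaderConfig",
    "Vocabulary",
    "EmbeddingMatrix",
    "AttentionResult",
    "TrainResult",
    "ReaderModel",
    "init_embeddings",
    "attention_distribution",
    "pointer_sum",
    "train",
]

UNK_TOKEN = "@unk"

#: Stable row order for the merged type vocabulary (``Unknown`` included).
TYPE_ORDER: tuple[str, ...] = tuple(sorted(TYPE_LABELS))
_TYPE_INDEX = {label: i for i, label in enumerate(TYPE_ORDER)}
_UNKNOWN_INDEX = _TYPE_INDEX[UNKNOWN_TYPE]

#: Untrained embedding rows are drawn uniformly from this open interval.
INIT_INTERVAL = 0.25


@dataclass
class ReaderConfig:
    """Hyperparameters of one reader.

    ``word_dim`` 200 and ``type_dim`` 20 are the reference sizes; the
    learning rate defaults to 1e-3 (5e-4 is the documented alternative),
    batches hold 32 instances, and training runs at most ``max_epochs``
    epochs with early stopping after ``patience`` epochs without
    validation improvement.
    """

    word_dim: int = 200
    type_dim: int = 20
    hidden_size: int = 128
    learning_rate: float = 1e-3
    batch_size: int = 32
    max_epochs: int = 20
    patience: int = 3
    seed: int = 0
    use_pretrained: bool = False
    use_type_embedding: bool = False
    grad_clip: float = 10.0

    def __post_init__(self):
        for name in ("word_dim", "hidden_size", "learning_rate", "batch_size",
                     "max_epochs", "patience"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.type_dim < 0:
            raise ValueError("type_dim must be >= 0")
        if self.use_type_embedding and self.type_dim == 0:
            raise ValueError("type embedding enabled but type_dim is 0")


class Vocabulary:
    """Token -> row-index map with an UNK fallback row."""

    def __init__(self, tokens: Sequence[str]):
        self.tokens: list[str] = []
        self.index: dict[str, int] = {}
        for token in (UNK_TOKEN, PLACEHOLDER, *tokens):
            if token not in self.index:
                self.index[token] = len(self.tokens)
                self.tokens.append(token)
        self.unk_id = self.index[UNK_TOKEN]

    @classmethod
    def from_instances(cls, instances: Sequence[ClozeInstance]) -> "Vocabulary":
        tokens: list[str] = []
        seen: set[str] = set()
        for instance in instances:
            for token in (*instance.document_tokens, *instance.question_tokens):
                if token not in seen:
                    seen.add(token)
                    tokens.append(token)
        return cls(tokens)

    def __len__(self) -> int:
        return len(self.tokens)

    def __contains__(self, token: str) -> bool:
        return token in self.index

    def id(self, token: str) -> int:
        return self.index.get(token, self.unk_id)


@dataclass
class EmbeddingMatrix:
    """Word lookup matrix W_v plus the optional type lookup matrix."""

    vocab: Vocabulary
    word_dim: int
    type_dim: int  # 0 when type embeddings are disabled
    word_rows: np.ndarray  # (|V|, word_dim)
    type_rows: np.ndarray | None  # (|types|, type_dim) or None

    @property
    def input_dim(self) -> int:
        return self.word_dim + self.type_dim


def init_embeddings(vocab: Vocabulary,
                    word_vectors: WordVectorTable | None,
                    config: ReaderConfig,
                    rng: np.random.Generator | None = None) -> EmbeddingMatrix:
    """Initialize the lookup matrices.

    Tokens found in ``word_vectors`` (case-insensitive) copy their
    pretrained vector exactly; every other word row and every type row is
    drawn uniformly from the open interval (-0.25, 0.25).  All rows remain
    trainable.
    """
    if word_vectors is not None and word_vectors.dimension != config.word_dim:
        raise ValueError(
            f"pretrained dimension {word_vectors.dimension} != "
            f"configured word_dim {config.word_dim}")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n_rows = len(vocab)
    word_rows = rng.uniform(-INIT_INTERVAL, INIT_INTERVAL,
                            (n_rows, config.word_dim))
    n_pretrained = 0
    if word_vectors is not None:
        for token, row in vocab.index.items():
            vector = word_vectors.get(token)
            if vector is not None:
                word_rows[row] = vector
                n_pretrained += 1
        log.info("initialized %d/%d rows from pretrained vectors",
                 n_pretrained, n_rows)
    if config.use_type_embedding:
        type_rows = rng.uniform(-INIT_INTERVAL, INIT_INTERVAL,
                                (len(TYPE_ORDER), config.type_dim))
        type_dim = config.type_dim
    else:
        type_rows, type_dim = None, 0
    return EmbeddingMatrix(vocab, config.word_dim, type_dim, word_rows, type_rows)


# ---------------------------------------------------------------------------
# Attention and pointer-sum (the model's output layer)
# ---------------------------------------------------------------------------


def attention_distribution(context_encodings: np.ndarray,
                           query_encoding: np.ndarray) -> np.ndarray:
    """Softmax over document positions of ``<f_i(d), g(q)>``.

    Computed with max-subtraction for overflow safety; the result is a
    probability vector over the ``len(context_encodings)`` positions.
    """
    context_encodings = np.asarray(context_encodings, dtype=np.float64)
    query_encoding = np.asarray(query_encoding, dtype=np.float64)
    if context_encodings.ndim != 2 or context_encodings.shape[1] != query_encoding.shape[0]:
        raise ValueError(
            f"width mismatch: context {context_encodings.shape} vs "
            f"query {query_encoding.shape}")
    logits = context_encodings @ query_encoding
    logits -= logits.max()
    weights = np.exp(logits)
    return weights / weights.sum()


def pointer_sum(position_probs: np.ndarray,
                mention_positions: dict[str, Sequence[int]],
                ) -> tuple[dict[str, float], str | None]:
    """Aggregate per-position attention into per-candidate probabilities.

    ``P(a) = sum_{i in I(a, d)} s_i``, accumulated in ascending position
    order.  The prediction is the argmax candidate; exact ties go to the
    candidate whose first document occurrence is earliest.
    """
    n = len(position_probs)
    probs: dict[str, float] = {}
    for candidate, positions in mention_positions.items():
        total = 0.0
        for position in sorted(positions):
            if not 0 <= position < n:
                raise IndexError(
                    f"position {position} out of range for candidate "
                    f"{candidate!r} (document length {n})")
            total += float(position_probs[position])
        probs[candidate] = total
    predicted = None
    if probs:
        predicted = min(
            probs,
            key=lambda c: (-probs[c], min(mention_positions[c], default=n)))
    return probs, predicted


@dataclass
class AttentionResult:
    """Per-position attention and aggregated candidate probabilities."""

    position_probs: np.ndarray
    candidate_probs: dict[str, float]
    ranked: list[str]

    @property
    def predicted(self) -> str:
        return self.ranked[0]

    def top(self, n: int) -> list[str]:
        if n < 1:
            raise ValueError("n must be >= 1")
        return self.ranked[:n]


def _rank_candidates(probs: dict[str, float],
                     mention_positions: dict[str, Sequence[int]]) -> list[str]:
    big = max((max(p, default=0) for p in mention_positions.values()), default=0) + 1
    return sorted(probs, key=lambda c: (-probs[c],
                                        min(mention_positions[c], default=big)))


# ---------------------------------------------------------------------------
# Encoded instances and batching
# ---------------------------------------------------------------------------


@dataclass
class EncodedInstance:
    instance: ClozeInstance
    doc_ids: np.ndarray
    doc_type_ids: np.ndarray
    q_ids: np.ndarray
    q_type_ids: np.ndarray
    answer_positions: np.ndarray


def _type_ids(tokens: Sequence[str], types: dict[str, str]) -> np.ndarray:
    return np.array([_TYPE_INDEX.get(types.get(tok, UNKNOWN_TYPE), _UNKNOWN_INDEX)
                     for tok in tokens], dtype=np.int64)


def encode_instance(instance: ClozeInstance, vocab: Vocabulary) -> EncodedInstance:
    if not instance.document_tokens:
        raise ValueError("empty document")
    if not instance.question_tokens:
        raise ValueError("empty question")
    return EncodedInstance(
        instance=instance,
        doc_ids=np.array([vocab.id(t) for t in instance.document_tokens], dtype=np.int64),
        doc_type_ids=_type_ids(instance.document_tokens, instance.candidate_types),
        q_ids=np.array([vocab.id(t) for t in instance.question_tokens], dtype=np.int64),
        q_type_ids=_type_ids(instance.question_tokens, instance.candidate_types),
        answer_positions=np.array(
            sorted(instance.mention_positions.get(instance.answer, ())), dtype=np.int64),
    )


def _pad_batch(encoded: Sequence[EncodedInstance], unk_id: int):
    B = len(encoded)
    Ld = max(len(e.doc_ids) for e in encoded)
    Lq = max(len(e.q_ids) for e in encoded)
    doc_ids = np.full((B, Ld), unk_id, dtype=np.int64)
    doc_types = np.full((B, Ld), _UNKNOWN_INDEX, dtype=np.int64)
    doc_mask = np.zeros((B, Ld))
    q_ids = np.full((B, Lq), unk_id, dtype=np.int64)
    q_types = np.full((B, Lq), _UNKNOWN_INDEX, dtype=np.int64)
    q_mask = np.zeros((B, Lq))
    for b, e in enumerate(encoded):
        nd, nq = len(e.doc_ids), len(e.q_ids)
        doc_ids[b, :nd] = e.doc_ids
        doc_types[b, :nd] = e.doc_type_ids
        doc_mask[b, :nd] = 1.0
        q_ids[b, :nq] = e.q_ids
        q_types[b, :nq] = e.q_type_ids
        q_mask[b, :nq] = 1.0
    return doc_ids, doc_types, doc_mask, q_ids, q_types, q_mask


# ---------------------------------------------------------------------------
# The model
# ---------------------------------------------------------------------------


class ReaderModel:
    """A trained (or freshly initialized) attention-sum reader."""

    def __init__(self, config: ReaderConfig, embeddings: EmbeddingMatrix,
                 rng: np.random.Generator | None = None):
        if rng is None:
            rng = np.random.default_rng(config.seed)
        self.config = config
        self.embeddings = embeddings
        h = config.hidden_size
        d_in = embeddings.input_dim
        self.ctx_f = GRUDirection(d_in, h, rng, "ctx_f")
        self.ctx_b = GRUDirection(d_in, h, rng, "ctx_b")
        self.qry_f = GRUDirection(d_in, h, rng, "qry_f")
        self.qry_b = GRUDirection(d_in, h, rng, "qry_b")
        self.params: dict[str, np.ndarray] = {"emb.W": embeddings.word_rows}
        if embeddings.type_rows is not None:
            self.params["emb.T"] = embeddings.type_rows
        for gru in (self.ctx_f, self.ctx_b, self.qry_f, self.qry_b):
            self.params.update(gru.params)
        self.validation_accuracy: float | None = None

    # -- embedding ----------------------------------------------------------

    def _embed(self, ids: np.ndarray, type_ids: np.ndarray) -> np.ndarray:
        X = self.params["emb.W"][ids]
        if self.embeddings.type_dim:
            X = np.concatenate([X, self.params["emb.T"][type_ids]], axis=-1)
        return X

    # -- encoders -----------------------------------------------------------

    def encode_context(self, instance: ClozeInstance) -> np.ndarray:
        """Per-position encodings ``f_i(d)``, shape (|d|, 2*hidden)."""
        e = encode_instance(instance, self.embeddings.vocab)
        X = self._embed(e.doc_ids[None, :], e.doc_type_ids[None, :])
        mask = np.ones((1, len(e.doc_ids)))
        Hf, _, _ = self.ctx_f.forward(X, mask, reverse=False)
        Hb, _, _ = self.ctx_b.forward(X, mask, reverse=True)
        return np.concatenate([Hf[0], Hb[0]], axis=1)

    def encode_query(self, instance: ClozeInstance) -> np.ndarray:
        """Query encoding ``g(q)``: concatenated final states, width 2*hidden."""
        e = encode_instance(instance, self.embeddings.vocab)
        X = self._embed(e.q_ids[None, :], e.q_type_ids[None, :])
        mask = np.ones((1, len(e.q_ids)))
        _, gf, _ = self.qry_f.forward(X, mask, reverse=False)
        _, gb, _ = self.qry_b.forward(X, mask, reverse=True)
        return np.concatenate([gf[0], gb[0]])

    # -- batched forward/backward ------------------------------------------

    def _forward_batch(self, doc_ids, doc_types, doc_mask, q_ids, q_types, q_mask):
        Xd = self._embed(doc_ids, doc_types)
        Hf, _, cache_f = self.ctx_f.forward(Xd, doc_mask, reverse=False)
        Hb, _, cache_b = self.ctx_b.forward(Xd, doc_mask, reverse=True)
        Hd = np.concatenate([Hf, Hb], axis=2)
        Xq = self._embed(q_ids, q_types)
        _, gf, cache_qf = self.qry_f.forward(Xq, q_mask, reverse=False)
        _, gb, cache_qb = self.qry_b.forward(Xq, q_mask, reverse=True)
        g = np.concatenate([gf, gb], axis=1)
        logits = (Hd * g[:, None, :]).sum(axis=2)
        logits = np.where(doc_mask > 0, logits, -np.inf)
        logits = logits - logits.max(axis=1, keepdims=True)
        weights = np.exp(logits)
        s = weights / weights.sum(axis=1, keepdims=True)
        cache = dict(Xd=Xd, Xq=Xq, Hd=Hd, g=g, cache_f=cache_f, cache_b=cache_b,
                     cache_qf=cache_qf, cache_qb=cache_qb,
                     doc_ids=doc_ids, doc_types=doc_types, q_ids=q_ids,
                     q_types=q_types, doc_mask=doc_mask, q_mask=q_mask)
        return s, cache

    def loss_and_gradients(self, encoded: Sequence[EncodedInstance]):
        """Mean -log P(a|d,q) over a batch, and gradients for every parameter."""
        doc_ids, doc_types, doc_mask, q_ids, q_types, q_mask = _pad_batch(
            encoded, self.embeddings.vocab.unk_id)
        s, cache = self._forward_batch(doc_ids, doc_types, doc_mask,
                                       q_ids, q_types, q_mask)
        B, Ld = s.shape
        indicator = np.zeros((B, Ld))
        for b, e in enumerate(encoded):
            indicator[b, e.answer_positions] = 1.0
        P = (s * indicator).sum(axis=1)
        loss = float(-np.mean(np.log(P)))

        h = self.config.hidden_size
        dlogits = (s - s * indicator / P[:, None]) / B
        Hd, g = cache["Hd"], cache["g"]
        dHd = dlogits[:, :, None] * g[:, None, :]
        dg = (dlogits[:, :, None] * Hd).sum(axis=1)

        grads: dict[str, np.ndarray] = {}
        dXd_f, grads_f = self.ctx_f.backward(cache["Xd"], dHd[:, :, :h], None,
                                             cache["cache_f"])
        dXd_b, grads_b = self.ctx_b.backward(cache["Xd"], dHd[:, :, h:], None,
                                             cache["cache_b"])
        dXd = dXd_f + dXd_b
        zeros_q = np.zeros((B, q_ids.shape[1], h))
        dXq_f, grads_qf = self.qry_f.backward(cache["Xq"], zeros_q, dg[:, :h],
                                              cache["cache_qf"])
        dXq_b, grads_qb = self.qry_b.backward(cache["Xq"], zeros_q, dg[:, h:],
                                              cache["cache_qb"])
        dXq = dXq_f + dXq_b
        for gru_grads in (grads_f, grads_b, grads_qf, grads_qb):
            grads.update(gru_grads)

        word_dim = self.embeddings.word_dim
        dW = np.zeros_like(self.params["emb.W"])
        np.add.at(dW, doc_ids, dXd[:, :, :word_dim])
        np.add.at(dW, q_ids, dXq[:, :, :word_dim])
        grads["emb.W"] = dW
        if self.embeddings.type_dim:
            dT = np.zeros_like(self.params["emb.T"])
            np.add.at(dT, doc_types, dXd[:, :, word_dim:])
            np.add.at(dT, q_types, dXq[:, :, word_dim:])
            grads["emb.T"] = dT
        return loss, grads

    # -- prediction ---------------------------------------------------------

    def predict(self, instance: ClozeInstance, n: int | None = None) -> AttentionResult:
        """Score one instance; ``n`` (if given) truncates the ranking."""
        fd = self.encode_context(instance)
        g = self.encode_query(instance)
        s = attention_distribution(fd, g)
        probs, _ = pointer_sum(s, instance.mention_positions)
        ranked = _rank_candidates(probs, instance.mention_positions)
        if n is not None:
            ranked = ranked[:max(1, n)]
        return AttentionResult(s, probs, ranked)

    def predict_batch(self, instances: Sequence[ClozeInstance]) -> list[str]:
        """Argmax predictions for many instances (batched forward pass)."""
        predictions: list[str] = []
        batch_size = self.config.batch_size
        order = sorted(range(len(instances)),
                       key=lambda i: len(instances[i].document_tokens))
        by_index: dict[int, str] = {}
        for start in range(0, len(order), batch_size):
            chunk = order[start:start + batch_size]
            encoded = [encode_instance(instances[i], self.embeddings.vocab)
                       for i in chunk]
            padded = _pad_batch(encoded, self.embeddings.vocab.unk_id)
            s, _ = self._forward_batch(*padded)
            for row, i in enumerate(chunk):
                probs, predicted = pointer_sum(
                    s[row, :len(instances[i].document_tokens)],
                    instances[i].mention_positions)
                by_index[i] = predicted
        return [by_index[i] for i in range(len(instances))]

    def accuracy(self, instances: Sequence[ClozeInstance]) -> float:
        predictions = self.predict_batch(instances)
        correct = sum(p == inst.answer for p, inst in zip(predictions, instances))
        return correct / len(instances)

    # -- persistence --------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Write a JSON checkpoint (config, vocabulary, all weights, seed)."""
        payload = {
            "config": asdict(self.config),
            "vocab": self.embeddings.vocab.tokens,
            "type_order": list(TYPE_ORDER),
            "validation_accuracy": self.validation_accuracy,
            "weights": {k: v.tolist() for k, v in self.params.items()},
        }
        with open(path, "w", encoding="utf-8") as handle:
            json.dump(payload, handle)

    @classmethod
    def load(cls, path: str | Path) -> "ReaderModel":
        with open(path, encoding="utf-8") as handle:
            payload = json.load(handle)
        config = ReaderConfig(**payload["config"])
        if payload["type_order"] != list(TYPE_ORDER):
            raise ValueError("checkpoint type inventory differs from this build")
        vocab = Vocabulary(payload["vocab"])
        embeddings = init_embeddings(vocab, None, config)
        model = cls(config, embeddings)
        for key, value in payload["weights"].items():
            model.params[key][...] = np.array(value, dtype=np.float64)
        model.validation_accuracy = payload.get("validation_accuracy")
        return model


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------


@dataclass
class TrainResult:
    model: ReaderModel
    history: list[dict] = field(default_factory=list)
    best_epoch: int = -1
    best_accuracy: float = 0.0


def _make_batches(n_instances: int, lengths: Sequence[int], batch_size: int,
                  rng: np.random.Generator) -> list[list[int]]:
    # length-bucketed batches in randomized order (seeded, hence reproducible)
    order = sorted(rng.permutation(n_instances), key=lambda i: lengths[i])
    batches = [list(order[s:s + batch_size])
               for s in range(0, n_instances, batch_size)]
    rng.shuffle(batches)
    return batches


def train(train_set: Sequence[ClozeInstance],
          valid_set: Sequence[ClozeInstance],
          config: ReaderConfig,
          word_vectors: WordVectorTable | None = None) -> TrainResult:
    """Train a reader, returning the epoch snapshot with best validation accuracy.

    Every instance is structurally validated before training starts.  The
    run is fully reproducible given ``config.seed`` on one device.
    """
    if not train_set or not valid_set:
        raise ValueError("train and validation sets must be non-empty")
    for instance in (*train_set, *valid_set):
        validate_instance(instance, min_candidates=1)
    if config.use_pretrained and word_vectors is None:
        raise ValueError("use_pretrained is set but no word vectors were given")

    rng = np.random.default_rng(config.seed)
    vocab = Vocabulary.from_instances(train_set)
    embeddings = init_embeddings(
        vocab, word_vectors if config.use_pretrained else None, config, rng)
    model = ReaderModel(config, embeddings, rng)
    adam = Adam(model.params, config.learning_rate)
    encoded = [encode_instance(inst, vocab) for inst in train_set]
    lengths = [len(e.doc_ids) for e in encoded]

    result = TrainResult(model=model)
    best_params: dict[str, np.ndarray] | None = None
    epochs_since_best = 0
    for epoch in range(1, config.max_epochs + 1):
        losses = []
        for batch_indices in _make_batches(len(encoded), lengths,
                                           config.batch_size, rng):
            loss, grads = model.loss_and_gradients([encoded[i] for i in batch_indices])
            clip_global_norm(grads, config.grad_clip)
            adam.step(grads)
            losses.append(loss)
        valid_accuracy = model.accuracy(valid_set)
        result.history.append({"epoch": epoch,
                               "train_loss": float(np.mean(losses)),
                               "valid_accuracy": valid_accuracy})
        log.info("epoch %d: loss %.4f, valid acc %.4f",
                 epoch, result.history[-1]["train_loss"], valid_accuracy)
        if valid_accuracy > result.best_accuracy or best_params is None:
            result.best_accuracy = valid_accuracy
            result.best_epoch = epoch
            best_params = copy.deepcopy(model.params)
            epochs_since_best = 0
        else:
            epochs_since_best += 1
            if epochs_since_best >= config.patience:
                break
    for key, value in best_params.items():
        model.params[key][...] = value
    model.validation_accuracy = result.best_accuracy
    return result
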