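"""Construction of cloze-style comprehension instances from tagged articles.

Two dataset variants are built from one article.  The *title* variant (T)
uses the abstract as the context ``d`` and the article title as the question
``q``; the *last-sentence* variant (LS) uses the abstract's last sentence as
the question and the remaining sentences as the context.  One entity shared
by ``d`` and ``q`` is blanked out of the question (the answer ``a``), and
every entity occurring in ``d`` becomes a candidate in ``A``, yielding the
tuple (d, q, a, A) plus the per-candidate position sets I(a, d) the
pointer-sum reader aggregates over.

Instances are filtered: the answer must appear in both context and question,
and the candidate count must exceed 20.  Multi-token mentions collapse to a
single anonymized ID token; IDs are assigned either globally (stable per
entity across the corpus, letting a model accumulate background knowledge
about recurring entities) or locally (re-assigned per context).
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .corpus_io import Article
from .lexicon import Lexicon, Mention, tag_text, tokenize

__all__ = [
    "PLACEHOLDER",
    "ClozeInstance",
    "Rejection",
    "FilterResult",
    "IdAssignment",
    "InstanceValidationError",
    "split_sentences",
    "collapse_mentions",
    "build_instance",
    "build_corpus",
    "passes_filters",
    "assign_ids",
    "split_corpus",
    "read_dataset",
    "write_dataset",
    "export_cnn_format",
    "validate_instance",
    "validate_dataset",
]

#: The single-token blank marking where the answer was removed from q.
PLACEHOLDER = "@placeholder"

_SENTENCE_END = {".", "!", "?"}
_ABBREVIATIONS = {"al", "fig", "figs", "i.e", "e.g", "cf", "vs", "etc"}


def split_sentences(tokens: Sequence[str]) -> list[tuple[int, int]]:
    """Split a token sequence into contiguous, exhaustive sentence spans.

    A boundary falls after a sentence-final ``.``, ``!`` or ``?`` token,
    except when the token preceding a period is a known abbreviation
    (``al``, ``Fig``, ``i.e``, ``e.g``, ...).  A boundary-free sequence
    yields one span.
    """
    spans: list[tuple[int, int]] = []
    start = 0
    for i, token in enumerate(tokens):
        if token not in _SENTENCE_END:
            continue
        if token == ".":
            prev = tokens[i - 1] if i > start else ""
            if prev.lower() in _ABBREVIATIONS:
                continue
        spans.append((start, i + 1))
        start = i + 1
    if start < len(tokens):
        spans.append((start, len(tokens)))
    return spans


@dataclass(frozen=True)
class ClozeInstance:
    """One (d, q, a, A) tuple with entity-anonymized tokens.

    ``mention_positions`` maps every candidate to the sorted 0-based
    positions of its ID token in ``document_tokens`` — the position sets
    the reader's pointer-sum aggregates.  ``candidate_types`` carries each
    candidate's merged entity-type label for type embeddings.
    """

    document_tokens: tuple[str, ...]
    question_tokens: tuple[str, ...]
    answer: str
    candidates: tuple[str, ...]
    mention_positions: dict[str, tuple[int, ...]]
    candidate_types: dict[str, str]
    variant: str  # "T" or "LS"
    source_article_id: str


@dataclass(frozen=True)
class Rejection:
    """An article/variant pair that produced no instance, with the reason."""

    source_article_id: str
    variant: str
    reason: str


@dataclass(frozen=True)
class FilterResult:
    passed: bool
    reason: str = ""

    def __bool__(self) -> bool:
        return self.passed


def passes_filters(instance: ClozeInstance, min_candidates: int = 21) -> FilterResult:
    """Apply the two dataset filters.

    (1) the answer appears at least once in both the context and the
    question, and (2) the number of candidate answers exceeds 20 (i.e. is at
    least ``min_candidates``, default 21).
    """
    in_d = (instance.answer in instance.candidates
            and bool(instance.mention_positions.get(instance.answer)))
    in_q = PLACEHOLDER in instance.question_tokens
    if not (in_d and in_q):
        return FilterResult(False, "answer not in both")
    if len(instance.candidates) < min_candidates:
        return FilterResult(False, "candidate count")
    return FilterResult(True)


def collapse_mentions(tokens: Sequence[str], mentions: Sequence[Mention],
                      ) -> tuple[list[str], dict[str, str]]:
    """Replace each mention span by a single entity-ID token.

    Returns the collapsed token list and a map entity_id -> merged type.
    Mentions must be sorted and non-overlapping (as ``tag_text`` returns).
    """
    out: list[str] = []
    types: dict[str, str] = {}
    cursor = 0
    for mention in mentions:
        out.extend(tokens[cursor:mention.start])
        out.append(mention.entity_id)
        types[mention.entity_id] = mention.type
        cursor = mention.end
    out.extend(tokens[cursor:])
    return out, types


def _occurrence_order(tokens: Sequence[str], known: set[str]) -> list[str]:
    seen: list[str] = []
    for token in tokens:
        if token in known and token not in seen:
            seen.append(token)
    return seen


def build_instance(article: Article, lexicon: Lexicon, variant: str,
                   answer_rule: str = "first", seed: int = 0,
                   min_candidates: int = 21) -> ClozeInstance | Rejection:
    """Build one cloze instance (or a Rejection) from an article.

    ``answer_rule`` chooses the blank when several entities occur in both
    ``d`` and ``q``: ``"first"`` (default) takes the entity whose first
    occurrence in the question is earliest; ``"random"`` draws one with a
    generator seeded by (seed, article id), so the choice is reproducible.
    Every occurrence of the chosen entity in the question becomes the
    placeholder, preventing answer leakage.
    """
    if variant not in ("T", "LS"):
        raise ValueError(f"unknown variant {variant!r}")
    abstract_tokens = tokenize(article.abstract)
    if variant == "T":
        d_raw = abstract_tokens
        q_raw = tokenize(article.title)
    else:
        spans = split_sentences(abstract_tokens)
        if len(spans) < 2:
            return Rejection(article.article_id, variant, "empty context")
        last_start = spans[-1][0]
        d_raw = abstract_tokens[:last_start]
        q_raw = abstract_tokens[last_start:]

    d_tokens, d_types = collapse_mentions(d_raw, tag_text(d_raw, lexicon))
    q_tokens, _ = collapse_mentions(q_raw, tag_text(q_raw, lexicon))

    entity_ids = set(d_types)
    candidates = _occurrence_order(d_tokens, entity_ids)
    shared = [eid for eid in _occurrence_order(q_tokens, entity_ids)]
    if not shared:
        return Rejection(article.article_id, variant, "no shared entity")

    if answer_rule == "first":
        answer = shared[0]
    elif answer_rule == "random":
        rng = np.random.default_rng([seed, zlib.crc32(article.article_id.encode())])
        answer = shared[int(rng.integers(len(shared)))]
    else:
        raise ValueError(f"unknown answer rule {answer_rule!r}")

    question = tuple(PLACEHOLDER if tok == answer else tok for tok in q_tokens)
    positions = {cand: tuple(i for i, tok in enumerate(d_tokens) if tok == cand)
                 for cand in candidates}
    instance = ClozeInstance(
        document_tokens=tuple(d_tokens), question_tokens=question,
        answer=answer, candidates=tuple(candidates),
        mention_positions=positions,
        candidate_types={cand: d_types[cand] for cand in candidates},
        variant=variant, source_article_id=article.article_id)
    verdict = passes_filters(instance, min_candidates)
    if not verdict:
        return Rejection(article.article_id, variant, verdict.reason)
    return instance


def build_corpus(articles: Sequence[Article], lexicon: Lexicon, variant: str,
                 answer_rule: str = "first", seed: int = 0,
                 min_candidates: int = 21,
                 ) -> tuple[list[ClozeInstance], list[Rejection]]:
    """Build at most one instance per article; collect rejections separately."""
    instances, rejections = [], []
    for article in articles:
        built = build_instance(article, lexicon, variant, answer_rule, seed,
                               min_candidates)
        if isinstance(built, Rejection):
            rejections.append(built)
        else:
            instances.append(built)
    return instances, rejections


# ---------------------------------------------------------------------------
# Entity-ID anonymization
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class IdAssignment:
    """Record of how canonical entity IDs became ``@entityN`` tokens."""

    mode: str  # "global" or "local"
    mapping: dict | tuple  # global: one map; local: one map per instance
    seed: int


def _relabel(instance: ClozeInstance, mapping: dict[str, str]) -> ClozeInstance:
    def sub(token: str) -> str:
        return mapping.get(token, token)

    return replace(
        instance,
        document_tokens=tuple(sub(t) for t in instance.document_tokens),
        question_tokens=tuple(sub(t) for t in instance.question_tokens),
        answer=sub(instance.answer),
        candidates=tuple(sub(c) for c in instance.candidates),
        mention_positions={sub(c): p for c, p in instance.mention_positions.items()},
        candidate_types={sub(c): t for c, t in instance.candidate_types.items()},
    )


def _instance_entities(instance: ClozeInstance) -> list[str]:
    """Entities of one instance: d in first-occurrence order, then q-only."""
    ids = set(instance.candidates) | {instance.answer}
    order = list(instance.candidates)
    for token in instance.question_tokens:
        if token in ids and token not in order:
            order.append(token)
    return order


def assign_ids(instances: Sequence[ClozeInstance], mode: str = "global",
               seed: int = 0) -> tuple[list[ClozeInstance], IdAssignment]:
    """Replace canonical entity IDs by anonymized ``@entityN`` tokens.

    Global mode builds one corpus-wide injective map numbered by first
    appearance in corpus order, so an entity keeps one stable ID everywhere
    (IDs are deliberately *not* permuted per context).  Local mode restarts
    numbering at ``@entity1`` inside each instance with a per-instance
    seeded random order, hiding cross-context entity identity.
    """
    if mode == "global":
        mapping: dict[str, str] = {}
        for instance in instances:
            for eid in _instance_entities(instance):
                if eid not in mapping:
                    mapping[eid] = f"@entity{len(mapping) + 1}"
        out = [_relabel(instance, mapping) for instance in instances]
        return out, IdAssignment("global", mapping, seed)
    if mode == "local":
        out = []
        maps = []
        for index, instance in enumerate(instances):
            entities = _instance_entities(instance)
            rng = np.random.default_rng([seed, index])
            order = rng.permutation(len(entities))
            mapping = {eid: f"@entity{int(order[k]) + 1}"
                       for k, eid in enumerate(entities)}
            maps.append(mapping)
            out.append(_relabel(instance, mapping))
        return out, IdAssignment("local", tuple(maps), seed)
    raise ValueError(f"unknown ID mode {mode!r}")


# ---------------------------------------------------------------------------
# Splitting and serialization
# ---------------------------------------------------------------------------


def split_corpus(instances: Sequence[ClozeInstance],
                 fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
                 seed: int = 0,
                 group_by: Callable[[ClozeInstance], str] | None = None,
                 ) -> tuple[list[ClozeInstance], list[ClozeInstance], list[ClozeInstance]]:
    """Partition instances into disjoint, exhaustive train/validation/test.

    With ``group_by`` (e.g. the source-file key), all instances sharing a
    key stay in one partition, mirroring a file-level corpus split.
    """
    if len(fractions) != 3 or any(f <= 0 for f in fractions):
        raise ValueError("three positive fractions required")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    rng = np.random.default_rng(seed)
    n = len(instances)
    if group_by is None:
        order = rng.permutation(n)
        n_train = int(n * fractions[0])
        n_valid = int(n * fractions[1])
        parts = (order[:n_train], order[n_train:n_train + n_valid],
                 order[n_train + n_valid:])
        splits = tuple([instances[i] for i in part] for part in parts)
    else:
        keys: list[str] = []
        by_key: dict[str, list[ClozeInstance]] = {}
        for instance in instances:
            key = group_by(instance)
            if key not in by_key:
                keys.append(key)
                by_key[key] = []
            by_key[key].append(instance)
        order = rng.permutation(len(keys))
        splits = ([], [], [])
        counts = [0, 0, 0]
        cut1, cut2 = n * fractions[0], n * (fractions[0] + fractions[1])
        bucket = 0
        for key_index in order:
            group = by_key[keys[key_index]]
            total = sum(counts)
            if bucket == 0 and total >= cut1:
                bucket = 1
            if bucket == 1 and total >= cut2:
                bucket = 2
            splits[bucket].extend(group)
            counts[bucket] += len(group)
    if any(len(split) == 0 for split in splits):
        raise ValueError("a requested partition is empty")
    return tuple(list(split) for split in splits)


def _to_record(instance: ClozeInstance) -> dict:
    return {
        "document": list(instance.document_tokens),
        "question": list(instance.question_tokens),
        "answer": instance.answer,
        "candidates": list(instance.candidates),
        "positions": {c: list(p) for c, p in instance.mention_positions.items()},
        "types": dict(instance.candidate_types),
        "variant": instance.variant,
        "source_article_id": instance.source_article_id,
    }


def _from_record(record: dict) -> ClozeInstance:
    return ClozeInstance(
        document_tokens=tuple(record["document"]),
        question_tokens=tuple(record["question"]),
        answer=record["answer"],
        candidates=tuple(record["candidates"]),
        mention_positions={c: tuple(p) for c, p in record["positions"].items()},
        candidate_types=dict(record["types"]),
        variant=record["variant"],
        source_article_id=record["source_article_id"],
    )


def write_dataset(instances: Sequence[ClozeInstance], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for instance in instances:
            handle.write(json.dumps(_to_record(instance), ensure_ascii=False) + "\n")


def read_dataset(path: str | Path) -> list[ClozeInstance]:
    instances = []
    with open(path, encoding="utf-8") as handle:
        for line in handle:
            if line.strip():
                instances.append(_from_record(json.loads(line)))
    return instances


def export_cnn_format(instances: Sequence[ClozeInstance],
                      directory: str | Path) -> list[Path]:
    """Export instances in the CNN/Daily-Mail question-file layout.

    One file per instance: source id, context, question, answer, then one
    ``token:token`` line per candidate, each section separated by a blank
    line.  (Original surface forms are not retained post-anonymization, so
    the entity map lists the ID token on both sides.)
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for instance in instances:
        path = directory / f"{instance.source_article_id}_{instance.variant}.question"
        with open(path, "w", encoding="utf-8") as handle:
            handle.write(instance.source_article_id + "\n\n")
            handle.write(" ".join(instance.document_tokens) + "\n\n")
            handle.write(" ".join(instance.question_tokens) + "\n\n")
            handle.write(instance.answer + "\n\n")
            for candidate in instance.candidates:
                handle.write(f"{candidate}:{candidate}\n")
        paths.append(path)
    return paths


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


class InstanceValidationError(ValueError):
    """An instance (or dataset) violates the cloze-instance invariants."""


def validate_instance(instance: ClozeInstance, min_candidates: int = 21) -> None:
    """Independently re-check every cloze-instance invariant.

    Position sets are compared against a brute-force rescan of the document;
    for the LS variant the question must not survive as a contiguous block
    of the context.
    """
    errors = []
    d, q = instance.document_tokens, instance.question_tokens
    if instance.answer not in instance.candidates:
        errors.append("answer not among candidates")
    # one blanked entity; all its question occurrences carry the placeholder
    if PLACEHOLDER not in q:
        errors.append("question lacks a placeholder")
    if len(instance.candidates) < min_candidates:
        errors.append(f"only {len(instance.candidates)} candidates")
    if set(instance.mention_positions) != set(instance.candidates):
        errors.append("position map keys differ from candidates")
    for candidate in instance.candidates:
        expected = tuple(i for i, tok in enumerate(d) if tok == candidate)
        got = instance.mention_positions.get(candidate, ())
        if not got:
            errors.append(f"{candidate}: empty position set")
        elif tuple(sorted(got)) != expected:
            errors.append(f"{candidate}: positions {got} != rescan {expected}")
    if instance.variant == "LS" and len(q) <= len(d):
        restored = tuple(instance.answer if t == PLACEHOLDER else t for t in q)
        for start in range(len(d) - len(q) + 1):
            if d[start:start + len(q)] in (q, restored):
                errors.append("LS question appears contiguously in context")
                break
    if errors:
        raise InstanceValidationError(
            f"{instance.source_article_id}/{instance.variant}: " + "; ".join(errors))


def validate_dataset(instances: Sequence[ClozeInstance],
                     min_candidates: int = 21) -> None:
    """Validate every instance plus the one-instance-per-article rule."""
    seen: set[tuple[str, str]] = set()
    for instance in instances:
        key = (instance.source_article_id, instance.variant)
        if key in seen:
            raise InstanceValidationError(f"duplicate instance for {key}")
        seen.add(key)
        validate_instance(instance, min_candidates)
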