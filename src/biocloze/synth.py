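"""Synthetic corpus generator with the statistical shape of the real datasets.

Generates an entity lexicon (entities with one to three surface forms, raw
types drawn over the BEST and MeSH inventories) and articles whose
abstracts interleave Zipf-distributed filler tokens with entity mentions.
Per-document shape follows the real corpus statistics: ~25 candidate
entities per document (never fewer than 21, so the dataset filters pass by
construction) and a configurable token count (~290 at full scale).

Each title and each generated last sentence contains exactly one entity of
the abstract — the planted answer — so both dataset variants are buildable
and the ground truth is known.  With ``cue_strength`` > 0 the answer's
body occurrences are preceded by a fixed cue token, making the task
learnable by attention ("the entity after the cue"); with ``cue_strength``
0 the answer is statistically indistinguishable from the other candidates
and any model is reduced to chance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .corpus_io import Article
from .lexicon import BEST_TYPES, MESH_TYPES, LexiconEntry

__all__ = ["SynthConfig", "ArticleTruth", "generate_lexicon",
           "generate_articles", "generate_corpus", "TINY", "BMKC_LIKE"]

_RAW_TYPES = tuple(sorted(BEST_TYPES | MESH_TYPES))


@dataclass(frozen=True)
class SynthConfig:
    """Shape parameters of the generated corpus (all counts per document)."""

    n_articles: int = 500
    vocab_size: int = 2000          # filler vocabulary size
    n_entities: int = 300           # lexicon size
    entities_per_doc_mean: float = 25.6
    entities_per_doc_sd: float = 3.0
    entities_per_doc_min: int = 21  # keeps the candidate-count filter satisfied
    tokens_per_doc_mean: float = 290.0
    tokens_per_doc_sd: float = 29.0
    cue_strength: float = 0.0       # P(cue token precedes an answer mention)
    cue_token: str = "zzcue"
    seed: int = 0

    def __post_init__(self):
        if min(self.n_articles, self.vocab_size, self.n_entities,
               self.entities_per_doc_min) <= 0:
            raise ValueError("all counts must be positive")
        if self.n_entities < self.entities_per_doc_min:
            raise ValueError("n_entities smaller than entities_per_doc_min")
        if not 0.0 <= self.cue_strength <= 1.0:
            raise ValueError("cue_strength must lie in [0, 1]")


#: Preset: desk-scale smoke corpus.
TINY = SynthConfig(n_articles=30, vocab_size=300, n_entities=80,
                   tokens_per_doc_mean=120.0, tokens_per_doc_sd=12.0)
#: Preset: the full-scale statistical shape.
BMKC_LIKE = SynthConfig()


@dataclass
class ArticleTruth:
    """Generator-side ground truth for one article."""

    answer: str  # canonical entity id planted in title and last sentence
    entities: list[str]  # distinct entity ids occurring in the body
    abstract_mentions: list[tuple[str, int, int]]  # (entity_id, start, end)
    title_mentions: list[tuple[str, int, int]]


def generate_lexicon(config: SynthConfig) -> list[LexiconEntry]:
    """Entities ``E00000..`` with 1-3 surface forms each.

    Some entities get a second single-token synonym and/or a two-token
    form, exercising entity resolution and longest-match tagging.
    """
    rng = np.random.default_rng([config.seed, 1])
    entries: list[LexiconEntry] = []
    for i in range(config.n_entities):
        entity_id = f"E{i:05d}"
        raw_type = str(rng.choice(_RAW_TYPES))
        n_extra = int(rng.integers(0, 3))
        surfaces = [f"ent{i:05d}"]
        if n_extra >= 1:
            surfaces.append(f"syn{i:05d}a")
        if n_extra == 2:
            surfaces.append(f"ent{i:05d} cplx")
        for surface in surfaces:
            entries.append(LexiconEntry(surface, entity_id, raw_type))
    return entries


def _zipf_probs(size: int) -> np.ndarray:
    weights = 1.0 / np.arange(1, size + 1)
    return weights / weights.sum()


class _DocBuilder:
    """Accumulates tokens, inserting sentence breaks at unit boundaries."""

    def __init__(self, rng: np.random.Generator):
        self.rng = rng
        self.tokens: list[str] = []
        self.mentions: list[tuple[str, int, int]] = []
        self._since_break = 0
        self._gap = int(rng.integers(8, 16))

    def add_unit(self, unit: Sequence[str], entity_id: str | None = None) -> None:
        start = len(self.tokens)
        self.tokens.extend(unit)
        if entity_id is not None:
            self.mentions.append((entity_id, start, start + len(unit)))
        self._since_break += len(unit)
        if self._since_break >= self._gap:
            self.tokens.append(".")
            self._since_break = 0
            self._gap = int(self.rng.integers(8, 16))

    def close_sentence(self) -> None:
        if self.tokens and self.tokens[-1] != ".":
            self.tokens.append(".")
            self._since_break = 0


def generate_articles(config: SynthConfig,
                      lexicon_entries: Sequence[LexiconEntry],
                      ) -> tuple[list[Article], dict[str, ArticleTruth]]:
    """Generate articles plus their ground truth.

    The body carries every sampled entity at least once (~20% twice, with
    no bias toward the answer); the constructed last sentence and the title
    each carry the answer and no other entity.  Entity mentions are
    separated by at least one filler token, so dictionary tagging recovers
    exactly the planted mention set.

    Note the answer's presence in the last sentence is itself a signal: in
    the title variant (where the last sentence stays inside the context) a
    model can exploit it even without the cue.  The last-sentence variant
    removes that sentence from the context, so with ``cue_strength`` 0 the
    answer carries no signal at all there.
    """
    surfaces_of: dict[str, list[str]] = {}
    for entry in lexicon_entries:
        surfaces_of.setdefault(entry.entity_id, []).append(entry.surface)
    entity_ids = sorted(surfaces_of)
    rng = np.random.default_rng([config.seed, 2])
    filler_vocab = np.array([f"w{j:05d}" for j in range(config.vocab_size)])
    filler_probs = _zipf_probs(config.vocab_size)

    def fillers(count: int) -> list[str]:
        return [str(t) for t in rng.choice(filler_vocab, size=count, p=filler_probs)]

    def pick_surface(entity_id: str) -> list[str]:
        forms = surfaces_of[entity_id]
        return forms[int(rng.integers(len(forms)))].split(" ")

    articles: list[Article] = []
    truths: dict[str, ArticleTruth] = {}
    for i in range(config.n_articles):
        n_ent = int(np.clip(round(rng.normal(config.entities_per_doc_mean,
                                             config.entities_per_doc_sd)),
                            config.entities_per_doc_min, len(entity_ids)))
        chosen = [entity_ids[k] for k in
                  rng.choice(len(entity_ids), size=n_ent, replace=False)]
        answer = chosen[int(rng.integers(n_ent))]

        # one body mention per entity; ~20% of entities (answer not favored)
        # get a second mention, exercising multi-mention pointer sums
        mention_ids = list(chosen)
        for k in rng.choice(n_ent, size=max(1, n_ent // 5), replace=False):
            mention_ids.append(chosen[int(k)])
        rng.shuffle(mention_ids)

        target = max(int(round(rng.normal(config.tokens_per_doc_mean,
                                          config.tokens_per_doc_sd))),
                     3 * len(mention_ids) + 12)
        mention_tokens = sum(len(pick_surface(e)) for e in mention_ids)  # approx
        n_gaps = len(mention_ids) + 1
        budget = max(n_gaps, target - mention_tokens - target // 11 - 8)
        cuts = np.sort(rng.integers(0, budget - n_gaps + 1, size=n_gaps - 1))
        gap_sizes = np.diff(np.concatenate([[0], cuts, [budget - n_gaps]])) + 1

        builder = _DocBuilder(rng)
        for gap_size, entity_id in zip(gap_sizes, mention_ids):
            for token in fillers(int(gap_size)):
                builder.add_unit([token])
            unit = pick_surface(entity_id)
            if entity_id == answer and rng.random() < config.cue_strength:
                unit = [config.cue_token, *unit]
            builder.add_unit(unit, entity_id)
        for token in fillers(int(gap_sizes[-1])):
            builder.add_unit([token])
        builder.close_sentence()

        # last sentence: the answer and nothing else entity-like
        ls_fill = fillers(int(rng.integers(4, 9)))
        insert_at = int(rng.integers(len(ls_fill) + 1))
        start = len(builder.tokens) + insert_at
        answer_unit = pick_surface(answer)
        ls_tokens = ls_fill[:insert_at] + answer_unit + ls_fill[insert_at:] + ["."]
        builder.mentions.append((answer, start, start + len(answer_unit)))
        builder.tokens.extend(ls_tokens)

        title_fill = fillers(int(rng.integers(3, 7)))
        t_insert = int(rng.integers(len(title_fill) + 1))
        title_unit = pick_surface(answer)
        title_tokens = title_fill[:t_insert] + title_unit + title_fill[t_insert:]
        title_mentions = [(answer, t_insert, t_insert + len(title_unit))]

        article_id = f"SYN{i:07d}"
        articles.append(Article(
            article_id=article_id,
            title=" ".join(title_tokens),
            abstract=" ".join(builder.tokens),
            year=int(rng.integers(2010, 2017))))
        truths[article_id] = ArticleTruth(
            answer=answer, entities=sorted(set(chosen)),
            abstract_mentions=builder.mentions,
            title_mentions=title_mentions)
    return articles, truths


def generate_corpus(config: SynthConfig,
                    ) -> tuple[list[Article], list[LexiconEntry], dict[str, ArticleTruth]]:
    """Convenience wrapper: lexicon + articles + truth in one call."""
    entries = generate_lexicon(config)
    articles, truths = generate_articles(config, entries)
    return articles, entries, truths
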