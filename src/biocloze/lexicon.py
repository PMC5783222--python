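"""Entity lexicon: surface-form resolution, type merging, tokenization, tagging.

A lexicon maps biomedical surface forms (e.g. ``"breast cancer"``,
``"breast tumors"``) to canonical entity identifiers, MeSH-style: several
names with one meaning share one ID.  Each entity carries one merged type
label drawn from a closed vocabulary built from two inventories — a
BEST-style extractor's ten types and the sixteen top-level MeSH tree
categories — with semantically close labels merged (Gene-like labels into
``Gene``, drug/chemical labels into ``Chemicals and Drugs [D]``, disease
labels into ``Diseases [C]``) and everything untyped mapped to ``Unknown``.

Tagging is dictionary NER: greedy left-to-right longest match over token
n-grams, case-insensitive, anchored at token boundaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .corpus_io import normalize_text

log = logging.getLogger(__name__)

__all__ = [
    "BEST_TYPES",
    "MESH_TYPES",
    "TYPE_LABELS",
    "UNKNOWN_TYPE",
    "LexiconEntry",
    "Mention",
    "Lexicon",
    "LexiconConflictError",
    "merge_type",
    "tokenize",
    "tag_text",
]

UNKNOWN_TYPE = "Unknown"

#: Raw type labels emitted by a BEST-style entity extractor.
BEST_TYPES = frozenset({
    "Gene", "Drug", "Chemical Compounds", "Target", "Disease", "Toxin",
    "Transcription Factor", "miRNA", "Pathway", "Mutation",
})

#: Top-level MeSH tree categories used as raw type labels.
MESH_TYPES = frozenset({
    "Anatomy [A]", "Organisms [B]", "Diseases [C]", "Chemicals and Drugs [D]",
    "Analytical, Diagnostic and Therapeutic Techniques, and Equipment [E]",
    "Psychiatry and Psychology [F]", "Phenomena and Processes [G]",
    "Disciplines and Occupations [H]",
    "Anthropology, Education, Sociology, and Social Phenomena [I]",
    "Technology, Industry, and Agriculture [J]", "Humanities [K]",
    "Information Science [L]", "Named Groups [M]", "Health Care [N]",
    "Publication Characteristics [V]", "Geographicals [Z]",
})

# Raw label -> merged representative type.  Gene-like and chemical-like
# labels collapse; the single disease pair collapses; all other raw labels
# map to themselves.
_MERGE_RULES: dict[str, str] = {
    "Gene": "Gene",
    "Target": "Gene",
    "Transcription Factor": "Gene",
    "Drug": "Chemicals and Drugs [D]",
    "Toxin": "Chemicals and Drugs [D]",
    "Chemical Compounds": "Chemicals and Drugs [D]",
    "Chemicals and Drugs [D]": "Chemicals and Drugs [D]",
    "Disease": "Diseases [C]",
    "Diseases [C]": "Diseases [C]",
}
for _label in BEST_TYPES | MESH_TYPES:
    _MERGE_RULES.setdefault(_label, _label)
_MERGE_RULES[UNKNOWN_TYPE] = UNKNOWN_TYPE

#: The closed merged type vocabulary (includes ``Unknown``).
TYPE_LABELS = frozenset(_MERGE_RULES.values())


def merge_type(raw_type: str | None) -> str:
    """Map a raw type label onto the merged representative vocabulary.

    Total and idempotent: absent or unrecognized labels map to ``Unknown``,
    and merged labels map to themselves.
    """
    if raw_type is None:
        return UNKNOWN_TYPE
    return _MERGE_RULES.get(raw_type, UNKNOWN_TYPE)


# ---------------------------------------------------------------------------
# Tokenization
# ---------------------------------------------------------------------------

_OPEN_PUNCT = set("([{\"'‘“")
_CLOSE_PUNCT = set(")]}\"'’”.,;:!?")


def tokenize(text: str) -> list[str]:
    """Split text into tokens, detaching punctuation.

    Whitespace splits; leading/trailing punctuation characters become their
    own tokens; ``/`` splits slash-joined terms (``NCOA1/AP-1/CSF1``) with
    the slash kept as a token.  Internal hyphens (``SRC-1``) and internal
    periods (``i.e``, ``0.3``) are preserved.  Deterministic and idempotent:
    re-tokenizing the space-join of the output reproduces the same tokens.
    """
    tokens: list[str] = []
    for chunk in normalize_text(text).split(" "):
        if not chunk:
            continue
        for j, piece in enumerate(chunk.split("/")):
            if j > 0:
                tokens.append("/")
            if piece:
                _split_punct(piece, tokens)
    return tokens


def _split_punct(piece: str, out: list[str]) -> None:
    leading: list[str] = []
    while piece and piece[0] in _OPEN_PUNCT:
        leading.append(piece[0])
        piece = piece[1:]
    trailing: list[str] = []
    while len(piece) > 1 and piece[-1] in _CLOSE_PUNCT:
        trailing.append(piece[-1])
        piece = piece[:-1]
    out.extend(leading)
    if piece:
        out.append(piece)
    out.extend(reversed(trailing))


# ---------------------------------------------------------------------------
# Lexicon
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LexiconEntry:
    """One (surface form, entity ID, raw type) triple."""

    surface: str
    entity_id: str
    raw_type: str | None = None


@dataclass(frozen=True)
class Mention:
    """A located entity occurrence as a token span [start, end)."""

    entity_id: str
    type: str
    start: int
    end: int


class LexiconConflictError(ValueError):
    """A surface mapped to two entities, or an entity to two merged types."""


class Lexicon:
    """Indexed surface-form dictionary supporting longest-match lookup."""

    def __init__(self, entries: Iterable[LexiconEntry]):
        entries = list(entries)
        if not entries:
            raise ValueError("cannot build a lexicon from zero entries")
        # keyed by the lowercased token tuple of the surface
        self._index: dict[tuple[str, ...], str] = {}
        self._surface_of: dict[tuple[str, ...], str] = {}
        self.surfaces_by_entity: dict[str, list[str]] = {}
        self.max_ngram = 1
        raw_types: dict[str, list[str]] = {}
        for entry in entries:
            if not entry.surface.strip():
                raise ValueError(f"empty surface for entity {entry.entity_id!r}")
            key = tuple(token.lower() for token in tokenize(entry.surface))
            previous = self._index.get(key)
            if previous is not None and previous != entry.entity_id:
                raise LexiconConflictError(
                    f"surface {entry.surface!r} maps to both {previous!r} "
                    f"and {entry.entity_id!r}")
            self._index[key] = entry.entity_id
            self._surface_of.setdefault(key, entry.surface)
            bucket = self.surfaces_by_entity.setdefault(entry.entity_id, [])
            if entry.surface not in bucket:
                bucket.append(entry.surface)
            if entry.raw_type is not None:
                raw_types.setdefault(entry.entity_id, []).append(entry.raw_type)
            self.max_ngram = max(self.max_ngram, len(key))
        self.entity_type = {eid: self._resolve_type(eid, raw_types.get(eid, []))
                            for eid in self.surfaces_by_entity}

    @staticmethod
    def _resolve_type(entity_id: str, raw: list[str]) -> str:
        """One merged type per entity; a BEST label beats a MeSH category."""
        best = {merge_type(r) for r in raw if r in BEST_TYPES}
        mesh = {merge_type(r) for r in raw if r not in BEST_TYPES}
        mesh.discard(UNKNOWN_TYPE)
        if len(best) > 1 or (not best and len(mesh) > 1):
            raise LexiconConflictError(
                f"entity {entity_id!r} has contradictory merged types: "
                f"{sorted(best or mesh)}")
        if best:
            if mesh - best:
                log.warning("entity %r: BEST type %s overrides MeSH %s",
                            entity_id, sorted(best), sorted(mesh))
            return next(iter(best))
        if mesh:
            return next(iter(mesh))
        return UNKNOWN_TYPE

    def __len__(self) -> int:
        return len(self.surfaces_by_entity)

    def lookup(self, tokens: Sequence[str]) -> str | None:
        """Entity ID for an exact (case-insensitive) token sequence, or None."""
        return self._index.get(tuple(token.lower() for token in tokens))

    def type_of(self, entity_id: str) -> str:
        return self.entity_type.get(entity_id, UNKNOWN_TYPE)

    # -- serialization ------------------------------------------------------

    @classmethod
    def read_tsv(cls, path: str | Path) -> "Lexicon":
        """Read a tab-separated (surface, entity_id, raw_type) file.

        Lines starting with ``#`` are comments; the third column is optional.
        """
        entries = []
        with open(path, encoding="utf-8") as handle:
            for lineno, line in enumerate(handle, start=1):
                line = line.rstrip("\n")
                if not line.strip() or line.lstrip().startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) < 2:
                    raise ValueError(f"{path}:{lineno}: need at least 2 columns")
                raw_type = fields[2].strip() if len(fields) > 2 and fields[2].strip() else None
                entries.append(LexiconEntry(fields[0].strip(), fields[1].strip(), raw_type))
        return cls(entries)

    @staticmethod
    def write_tsv(entries: Sequence[LexiconEntry], path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as handle:
            handle.write("# surface\tentity_id\traw_type\n")
            for entry in entries:
                handle.write(f"{entry.surface}\t{entry.entity_id}\t{entry.raw_type or ''}\n")


def tag_text(tokens: Sequence[str], lexicon: Lexicon,
             max_ngram: int | None = None) -> list[Mention]:
    """Tag entity mentions by greedy left-to-right longest match.

    At each position the longest matching n-gram (up to ``max_ngram``,
    default 6 capped at the lexicon's longest surface) wins and the scan
    resumes after it, so returned mentions are sorted and never overlap.
    Matching is case-insensitive and token-boundary-anchored.
    """
    if max_ngram is None:
        max_ngram = min(6, lexicon.max_ngram)
    mentions: list[Mention] = []
    lowered = [token.lower() for token in tokens]
    i, n = 0, len(tokens)
    while i < n:
        hit = None
        for width in range(min(max_ngram, n - i), 0, -1):
            entity_id = lexicon._index.get(tuple(lowered[i:i + width]))
            if entity_id is not None:
                hit = Mention(entity_id, lexicon.type_of(entity_id), i, i + width)
                break
        if hit is not None:
            mentions.append(hit)
            i = hit.end
        else:
            i += 1
    return mentions
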