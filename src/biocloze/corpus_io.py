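"""Reading and writing article records, MEDLINE XML, and word-vector files.

The pipeline consumes plain article records (id, title, abstract, year).
Two on-disk sources are supported: a line-delimited JSON format (one record
per line) and a minimal subset of MEDLINE/PubMed XML.  Pretrained word
embeddings are read from the word2vec *text* dialect (header line
``"<count> <dimension>"`` followed by one token and its components per line).
"""

from __future__ import annotations

import json
import logging
import re
import unicodedata
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
from lxml import etree

log = logging.getLogger(__name__)

__all__ = [
    "Article",
    "ReadResult",
    "WordVectorTable",
    "WordVectorFormatError",
    "normalize_text",
    "read_articles_jsonl",
    "write_articles_jsonl",
    "read_medline_xml",
    "read_word_vectors",
    "write_word_vectors",
]


def normalize_text(text: str) -> str:
    """Unicode NFC normalization plus whitespace collapsing.

    Runs of whitespace (including newlines inside structured abstracts)
    become a single space; leading/trailing whitespace is stripped.  Applied
    at read time so downstream tokenization is stable.
    """
    text = unicodedata.normalize("NFC", text)
    return re.sub(r"\s+", " ", text).strip()


@dataclass(frozen=True)
class Article:
    """One scientific article record: the unit the pipeline consumes."""

    article_id: str
    title: str
    abstract: str
    year: int | None = None

    def is_valid(self) -> bool:
        return bool(self.article_id) and bool(self.title) and bool(self.abstract)


@dataclass
class ReadResult:
    """Articles read from a file plus the count of skipped records."""

    articles: list[Article] = field(default_factory=list)
    n_skipped: int = 0

    def __iter__(self) -> Iterator[Article]:
        return iter(self.articles)

    def __len__(self) -> int:
        return len(self.articles)

    def __getitem__(self, i):
        return self.articles[i]


def _make_article(article_id, title, abstract, year) -> Article | None:
    title = normalize_text(str(title or ""))
    abstract = normalize_text(str(abstract or ""))
    article = Article(str(article_id or ""), title, abstract,
                      int(year) if year is not None else None)
    return article if article.is_valid() else None


def read_articles_jsonl(path: str | Path) -> ReadResult:
    """Read articles from a line-delimited JSON file.

    Each line carries ``article_id``, ``title``, ``abstract`` and optionally
    ``year``.  Records violating the Article invariants (empty title or
    abstract after normalization, malformed JSON) are skipped with a logged
    warning and counted; order is preserved.
    """
    result = ReadResult()
    seen: set[str] = set()
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip():
                continue
            try:
                record = json.loads(line)
                article = _make_article(
                    record.get("article_id"), record.get("title"),
                    record.get("abstract"), record.get("year"))
            except (json.JSONDecodeError, ValueError, TypeError, AttributeError):
                article = None
            if article is None or article.article_id in seen:
                log.warning("%s:%d: skipping malformed or duplicate record", path, lineno)
                result.n_skipped += 1
                continue
            seen.add(article.article_id)
            result.articles.append(article)
    return result


def write_articles_jsonl(articles: Sequence[Article], path: str | Path) -> None:
    """Write articles one JSON record per line (round-trips with the reader)."""
    with open(path, "w", encoding="utf-8") as handle:
        for article in articles:
            record = {"article_id": article.article_id, "title": article.title,
                      "abstract": article.abstract, "year": article.year}
            handle.write(json.dumps(record, ensure_ascii=False) + "\n")


_YEAR_RE = re.compile(r"\b(\d{4})\b")


def _citation_year(citation) -> int | None:
    # First 4-digit year in DateCompleted, else PubDate; absent -> unset.
    for xpath in (".//DateCompleted", ".//PubDate"):
        node = citation.find(xpath)
        if node is not None:
            match = _YEAR_RE.search(" ".join(node.itertext()))
            if match:
                return int(match.group(1))
    return None


def read_medline_xml(path: str | Path) -> ReadResult:
    """Read a minimal MEDLINE/PubMed XML subset.

    One Article per ``PubmedArticle``/``MedlineCitation`` element that has
    both an ``ArticleTitle`` and at least one ``AbstractText``.  Structured
    abstracts (multiple AbstractText sections) are concatenated with a single
    space in document order.  Citations missing a title or abstract are
    skipped with a warning.
    """
    tree = etree.parse(str(path))
    result = ReadResult()
    citations = tree.findall(".//MedlineCitation")
    if not citations:
        citations = tree.findall(".//PubmedArticle")
    for citation in citations:
        pmid_node = citation.find(".//PMID")
        title_node = citation.find(".//ArticleTitle")
        abstract_parts = [" ".join(node.itertext())
                          for node in citation.findall(".//AbstractText")]
        abstract = " ".join(part for part in abstract_parts if part.strip())
        article = _make_article(
            pmid_node.text if pmid_node is not None else None,
            " ".join(title_node.itertext()) if title_node is not None else None,
            abstract, _citation_year(citation))
        if article is None:
            log.warning("%s: skipping citation without title/abstract", path)
            result.n_skipped += 1
        else:
            result.articles.append(article)
    return result


class WordVectorFormatError(ValueError):
    """Raised when a word-vector file violates the word2vec text format."""


@dataclass
class WordVectorTable:
    """Token -> vector lookup with a fixed dimension."""

    dimension: int
    vectors: dict[str, np.ndarray]

    def __contains__(self, token: str) -> bool:
        return token in self.vectors

    def __len__(self) -> int:
        return len(self.vectors)

    def get(self, token: str) -> np.ndarray | None:
        """Case-insensitive lookup: exact form first, then lowercased."""
        hit = self.vectors.get(token)
        if hit is None:
            hit = self.vectors.get(token.lower())
        return hit


def read_word_vectors(path: str | Path) -> WordVectorTable:
    """Parse a word2vec text-format vector file.

    The header line gives the entry count and dimension.  A row whose
    component count differs from the header dimension is a format error
    naming the line; on duplicate tokens the first occurrence wins.
    """
    vectors: dict[str, np.ndarray] = {}
    with open(path, encoding="utf-8") as handle:
        header = handle.readline().split()
        if len(header) != 2:
            raise WordVectorFormatError(f"{path}: missing 'count dimension' header")
        try:
            _, dimension = int(header[0]), int(header[1])
        except ValueError as exc:
            raise WordVectorFormatError(f"{path}: malformed header {header!r}") from exc
        if dimension <= 0:
            raise WordVectorFormatError(f"{path}: non-positive dimension {dimension}")
        for lineno, line in enumerate(handle, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split()
            token, components = parts[0], parts[1:]
            if len(components) != dimension:
                raise WordVectorFormatError(
                    f"{path}:{lineno}: expected {dimension} components, "
                    f"got {len(components)}")
            if token in vectors:
                log.warning("%s:%d: duplicate token %r, keeping first", path, lineno, token)
                continue
            vectors[token] = np.array([float(c) for c in components], dtype=np.float64)
    return WordVectorTable(dimension=dimension, vectors=vectors)


def write_word_vectors(table: WordVectorTable, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        handle.write(f"{len(table.vectors)} {table.dimension}\n")
        for token, vector in table.vectors.items():
            handle.write(token + " " + " ".join(repr(float(v)) for v in vector) + "\n")
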