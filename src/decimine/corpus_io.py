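"""Reading PubMed-style XML corpora into article records.

Articles are parsed from ``PubmedArticleSet`` XML (PMID, ArticleTitle,
AbstractText, PubDate/Year), abstracts are split into sentences with a
deterministic rule-based tokenizer, and per-year publication counts are
derived for cumulative-growth summaries.
"""

from __future__ import annotations

import logging
import re
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Sentence",
    "Article",
    "Corpus",
    "YearCounts",
    "tokenize_sentences",
    "parse_pubmed_xml",
    "load_corpus",
    "publications_by_year",
]


@dataclass(frozen=True)
class Sentence:
    """One sentence of an abstract.

    Offsets are 0-based, half-open into the source abstract, so
    ``abstract[char_start:char_end] == text``.
    """

    text: str
    index: int
    char_start: int
    char_end: int

    def __post_init__(self) -> None:
        if self.char_start >= self.char_end:
            raise ValueError("sentence span must be non-empty")


@dataclass
class Article:
    """One parsed publication."""

    pmid: str
    year: int | None
    title: str
    abstract: str
    sentences: list[Sentence] = field(default_factory=list)


@dataclass
class Corpus:
    """A deduplicated collection of articles."""

    articles: list[Article] = field(default_factory=list)
    source_files: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.articles)

    def __iter__(self):
        return iter(self.articles)


# Sentence-final punctuation followed by whitespace and an uppercase letter
# or digit starts a new sentence, unless the text ends in a known
# abbreviation.
_SPLIT_RE = re.compile(r"[.!?](?=\s+[A-Z0-9])")
_ABBREVIATIONS = (
    "e.g.",
    "i.e.",
    "et al.",
    "fig.",
    "figs.",
    "vs.",
    "ca.",
    "approx.",
    "sp.",
    "spp.",
    "cf.",
    "no.",
)


def tokenize_sentences(text: str) -> list[Sentence]:
    """Split ``text`` into sentences with recoverable character offsets.

    The rule is deterministic: split after ``.``, ``!`` or ``?`` when
    followed by whitespace and an uppercase letter or digit; a fixed
    abbreviation stop-list suppresses spurious splits. Total function:
    any string (including ``""``) is accepted.
    """
    sentences: list[Sentence] = []
    if not text:
        return sentences

    boundaries: list[int] = []
    for m in _SPLIT_RE.finditer(text):
        end = m.end()
        if text[end - 1] == ".":
            head = text[:end].lower()
            if any(head.endswith(abbr) for abbr in _ABBREVIATIONS):
                continue
        boundaries.append(end)
    boundaries.append(len(text))

    cursor = 0
    index = 0
    for end in boundaries:
        segment = text[cursor:end]
        stripped = segment.strip()
        if stripped:
            start = cursor + segment.index(stripped[0])
            stop = start + len(segment.rstrip()) - (start - cursor)
            sentences.append(Sentence(text=text[start:stop], index=index, char_start=start, char_end=stop))
            index += 1
        cursor = end
    return sentences


def _article_from_element(elem: ET.Element) -> Article | None:
    pmid_el = elem.find(".//PMID")
    if pmid_el is None or not (pmid_el.text or "").strip():
        logger.warning("article element without PMID skipped")
        return None
    pmid = pmid_el.text.strip()

    title = "".join((elem.findtext(".//ArticleTitle") or "").split("\n")).strip()

    abstract_parts = [
        (t.text or "").strip() for t in elem.findall(".//Abstract/AbstractText")
    ]
    abstract = " ".join(p for p in abstract_parts if p)
    if not abstract:
        logger.warning("PMID %s has no abstract; empty sentence list", pmid)

    year_text = elem.findtext(".//PubDate/Year") or elem.findtext(".//Year")
    year: int | None = None
    if year_text and year_text.strip().isdigit():
        year = int(year_text.strip())
        if year < 1900:
            logger.warning("PMID %s has implausible year %d; treated as missing", pmid, year)
            year = None

    return Article(
        pmid=pmid,
        year=year,
        title=title,
        abstract=abstract,
        sentences=tokenize_sentences(abstract),
    )


def parse_pubmed_xml(path: str | Path) -> Corpus:
    """Parse one PubMed article-set XML file into a :class:`Corpus`.

    Raises ``xml.etree.ElementTree.ParseError`` (which carries the
    line/column position) on malformed XML. Articles missing a PMID are
    skipped with a warning; duplicate PMIDs keep the first occurrence.
    """
    path = Path(path)
    tree = ET.parse(path)
    root = tree.getroot()

    elems = root.findall(".//PubmedArticle")
    if not elems and root.tag == "PubmedArticle":
        elems = [root]

    corpus = Corpus(source_files=[path.name])
    seen: set[str] = set()
    for elem in elems:
        article = _article_from_element(elem)
        if article is None:
            continue
        if article.pmid in seen:
            logger.warning("duplicate PMID %s dropped (first occurrence kept)", article.pmid)
            continue
        seen.add(article.pmid)
        corpus.articles.append(article)
    return corpus


def load_corpus(paths: Iterable[str | Path]) -> Corpus:
    """Parse and merge several XML files, deduplicating PMIDs across files."""
    merged = Corpus()
    seen: set[str] = set()
    for path in sorted(str(p) for p in paths):
        part = parse_pubmed_xml(path)
        merged.source_files.extend(part.source_files)
        for article in part.articles:
            if article.pmid in seen:
                logger.warning("duplicate PMID %s across files dropped", article.pmid)
                continue
            seen.add(article.pmid)
            merged.articles.append(article)
    return merged


@dataclass
class YearCounts:
    """Per-year and cumulative publication counts."""

    per_year: dict[int, int]
    cumulative: list[int]
    n_missing_year: int

    def to_frame(self) -> pd.DataFrame:
        years = sorted(self.per_year)
        return pd.DataFrame(
            {"year": years, "n": [self.per_year[y] for y in years], "cumulative": self.cumulative}
        )

    def recent_slope(self, window: int = 10) -> float:
        """Least-squares slope of the cumulative series over the trailing
        ``window`` years — the average number of new articles per year."""
        frame = self.to_frame().tail(window)
        if len(frame) < 2:
            raise ValueError("need at least two years for a slope")
        import numpy as np

        return float(np.polyfit(frame["year"], frame["cumulative"], 1)[0])


def publications_by_year(corpus: Corpus) -> YearCounts:
    """Count articles per publication year; the cumulative series is the
    prefix sum. Articles without a year are excluded and counted."""
    per_year: dict[int, int] = {}
    missing = 0
    for article in corpus:
        if article.year is None:
            missing += 1
            continue
        per_year[article.year] = per_year.get(article.year, 0) + 1
    cumulative: list[int] = []
    total = 0
    for year in sorted(per_year):
        total += per_year[year]
        cumulative.append(total)
    return YearCounts(per_year=per_year, cumulative=cumulative, n_missing_year=missing)
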