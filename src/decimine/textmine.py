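"""Sentence-level gene/topic co-occurrence mining.

The evidence rule: a gene counts as decidualization-related in a species
when a sentence of an abstract contains both a topic keyword (the seven
query terms: decidualization, decidual, decidua, deciduas, deciduoma,
decidualized, decidualizing) and a gene mention that normalizes to a
unique gene identifier through a synonym dictionary. Articles are first
assigned to a species group (human, including monkey; mouse, including
rat) from a surface-form lexicon; articles matching neither or both
groups are set aside for review and contribute no evidence.

Gene tagging is a deterministic dictionary matcher: longest-match-first
at word boundaries, case-insensitive except that short synonyms (three
characters or fewer) must match case-sensitively to avoid collisions
with ordinary English words. Ambiguous mentions (several candidate
genes) are resolved by a fixed cascade — restrict to the article's
species group, then prefer an exact official-symbol match — and
otherwise routed to a review file rather than guessed.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .corpus_io import Article, Corpus, Sentence

logger = logging.getLogger(__name__)

HUMAN_GROUP = "human_group"
MOUSE_GROUP = "mouse_group"
AMBIGUOUS = "ambiguous"

#: The topic keyword list (the query's seven terms).
DEFAULT_KEYWORDS: tuple[str, ...] = (
    "decidualization",
    "decidual",
    "decidua",
    "deciduas",
    "deciduoma",
    "decidualized",
    "decidualizing",
)

#: Synonyms at or below this length must match case-sensitively.
SHORT_SYNONYM_LEN = 3


# ---------------------------------------------------------------------------
# lexicon and dictionary


@dataclass
class SpeciesLexicon:
    """Maps lowercase surface forms ("mice", "women", ...) to a group."""

    forms: dict[str, str]

    def __post_init__(self) -> None:
        if not self.forms:
            raise ValueError("species lexicon must be non-empty")
        bad = {g for g in self.forms.values() if g not in (HUMAN_GROUP, MOUSE_GROUP)}
        if bad:
            raise ValueError(f"unknown species groups in lexicon: {sorted(bad)}")
        self.forms = {k.lower(): v for k, v in self.forms.items()}

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SpeciesLexicon":
        forms: dict[str, str] = {}
        for line_no, line in enumerate(Path(path).read_text().splitlines(), 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{line_no}: expected 2 columns, got {len(parts)}")
            forms[parts[0].strip().lower()] = parts[1].strip()
        return cls(forms)

    def to_tsv(self, path: str | Path) -> None:
        lines = [f"{form}\t{group}" for form, group in sorted(self.forms.items())]
        Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class DictEntry:
    gene_id: str
    species_group: str
    official_symbol: str
    synonyms: list[str]


class SynonymDictionary:
    """Gene synonym dictionary with a normalized-surface-form lookup.

    The lookup covers every official symbol and every synonym; a surface
    form may map to several gene identifiers (cross-species symbols,
    shared aliases), which is what mention resolution disambiguates.
    """

    def __init__(self, entries: Sequence[DictEntry], short_len: int = SHORT_SYNONYM_LEN):
        ids = [e.gene_id for e in entries]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate gene_id in dictionary")
        for e in entries:
            if not e.official_symbol or any(not s for s in e.synonyms):
                raise ValueError(f"empty symbol or synonym for {e.gene_id}")
        self.entries: dict[str, DictEntry] = {e.gene_id: e for e in entries}
        self.short_len = short_len
        # surface key -> sorted candidate gene ids; short forms keyed
        # exactly, longer forms keyed lowercase
        self._lookup: dict[str, list[str]] = {}
        for e in entries:
            for form in [e.official_symbol, *e.synonyms]:
                key = form if len(form) <= short_len else form.lower()
                self._lookup.setdefault(key, [])
                if e.gene_id not in self._lookup[key]:
                    self._lookup[key].append(e.gene_id)
        for key in self._lookup:
            self._lookup[key].sort()
        # scan order: longest surface form first, then lexicographic
        self._scan_keys = sorted(self._lookup, key=lambda k: (-len(k), k))
        self._patterns = {
            key: re.compile(
                r"(?<![A-Za-z0-9_])" + re.escape(key) + r"(?![A-Za-z0-9_])",
                0 if len(key) <= short_len else re.IGNORECASE,
            )
            for key in self._scan_keys
        }

    def __len__(self) -> int:
        return len(self.entries)

    def candidates(self, surface: str) -> list[str]:
        key = surface if len(surface) <= self.short_len else surface.lower()
        return list(self._lookup.get(key, []))

    def symbol_of(self, gene_id: str) -> str:
        return self.entries[gene_id].official_symbol

    @classmethod
    def from_tsv(cls, path: str | Path, **kwargs) -> "SynonymDictionary":
        """Read ``gene_id <TAB> species_group <TAB> symbol <TAB> syn|syn|...``."""
        entries = []
        for line_no, line in enumerate(Path(path).read_text().splitlines(), 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) not in (3, 4):
                raise ValueError(f"{path}:{line_no}: expected 3-4 columns")
            synonyms = [s for s in parts[3].split("|") if s] if len(parts) == 4 else []
            entries.append(DictEntry(parts[0], parts[1], parts[2], synonyms))
        return cls(entries, **kwargs)

    def to_tsv(self, path: str | Path) -> None:
        lines = []
        for gid in sorted(self.entries):
            e = self.entries[gid]
            lines.append(f"{e.gene_id}\t{e.species_group}\t{e.official_symbol}\t{'|'.join(e.synonyms)}")
        Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# mentions and co-occurrence records


@dataclass
class GeneMention:
    pmid: str
    sentence_index: int
    char_start: int
    char_end: int
    surface: str
    candidates: list[str]
    resolved: str | None = None

    @property
    def unresolved(self) -> bool:
        return self.resolved is None


@dataclass(frozen=True)
class CoOccurrence:
    """One evidence unit: gene and topic keyword in the same sentence."""

    pmid: str
    sentence_index: int
    gene_id: str
    keyword: str
    species_group: str


@dataclass
class SpeciesGeneSet:
    """Per-species gene ids with supporting PMIDs."""

    species_group: str
    genes: dict[str, set[str]] = field(default_factory=dict)

    def publication_count(self, gene_id: str) -> int:
        return len(self.genes.get(gene_id, ()))

    def __len__(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class VennCounts:
    n_a_only: int
    n_b_only: int
    n_shared: int

    @property
    def n_union(self) -> int:
        return self.n_a_only + self.n_b_only + self.n_shared


@dataclass
class MiningResult:
    """Full output of the mining stage, including review material."""

    cooccurrences: list[CoOccurrence]
    species_calls: dict[str, str]
    ambiguous_pmids: list[str]
    unresolved_mentions: list[GeneMention]


# ---------------------------------------------------------------------------
# operations


def classify_species(article: Article, lexicon: SpeciesLexicon) -> str:
    """Assign an article to a species group from its title and abstract.

    Exactly one group's lexicon forms present -> that group; none or
    both -> ``ambiguous`` (set aside for review, as manual curation
    would handle it).
    """
    text = f"{article.title} {article.abstract}".lower()
    groups_found: set[str] = set()
    for form, group in lexicon.forms.items():
        if re.search(r"(?<![a-z0-9_])" + re.escape(form) + r"(?![a-z0-9_])", text):
            groups_found.add(group)
            if len(groups_found) == 2:
                break
    if len(groups_found) == 1:
        return next(iter(groups_found))
    return AMBIGUOUS


def tag_mentions(
    sentence: Sentence, dictionary: SynonymDictionary, pmid: str = ""
) -> list[GeneMention]:
    """Find dictionary gene mentions in a sentence.

    Longest-match-first; overlapping shorter matches are suppressed, so
    "IGFBP1" wins over an embedded "IGFBP".
    """
    occupied: list[tuple[int, int]] = []
    mentions: list[GeneMention] = []
    for key in dictionary._scan_keys:
        for m in dictionary._patterns[key].finditer(sentence.text):
            span = (m.start(), m.end())
            if any(span[0] < e and s < span[1] for s, e in occupied):
                continue
            occupied.append(span)
            surface = sentence.text[span[0] : span[1]]
            mentions.append(
                GeneMention(
                    pmid=pmid,
                    sentence_index=sentence.index,
                    char_start=span[0],
                    char_end=span[1],
                    surface=surface,
                    candidates=dictionary.candidates(surface),
                )
            )
    mentions.sort(key=lambda m: m.char_start)
    return mentions


def resolve_mention(
    mention: GeneMention, article_species: str, dictionary: SynonymDictionary
) -> GeneMention:
    """Resolve a mention to a single gene id, or mark it unresolved.

    Cascade: (1) restrict candidates to the article's species group;
    (2) prefer the candidate whose official symbol equals the surface
    form case-insensitively; (3) otherwise leave unresolved for review.
    """
    if not mention.candidates:
        raise ValueError("mention has no candidates")
    candidates = list(mention.candidates)
    if len(candidates) == 1:
        mention.resolved = candidates[0]
        return mention

    if article_species in (HUMAN_GROUP, MOUSE_GROUP):
        same_species = [
            g for g in candidates if dictionary.entries[g].species_group == article_species
        ]
        if same_species:
            candidates = same_species
    if len(candidates) == 1:
        mention.resolved = candidates[0]
        return mention

    symbol_hits = [
        g
        for g in candidates
        if dictionary.entries[g].official_symbol.lower() == mention.surface.lower()
    ]
    if len(symbol_hits) == 1:
        mention.resolved = symbol_hits[0]
        return mention

    mention.resolved = None
    return mention


def _keyword_patterns(keywords: Sequence[str]) -> list[tuple[str, re.Pattern]]:
    return [
        (
            kw,
            re.compile(r"(?<![A-Za-z0-9_])" + re.escape(kw) + r"(?![A-Za-z0-9_])", re.IGNORECASE),
        )
        for kw in keywords
    ]


def first_keyword(text: str, keywords: Sequence[str]) -> str | None:
    """Earliest keyword occurrence in the text (position, then list order)."""
    best: tuple[int, int] | None = None
    for order, (kw, pat) in enumerate(_keyword_patterns(keywords)):
        m = pat.search(text)
        if m and (best is None or (m.start(), order) < best):
            best = (m.start(), order)
            best_kw = kw
    return best_kw if best is not None else None


def mine_corpus(
    corpus: Corpus,
    dictionary: SynonymDictionary,
    lexicon: SpeciesLexicon,
    keywords: Sequence[str] = DEFAULT_KEYWORDS,
) -> MiningResult:
    """Run species classification, tagging, resolution and co-occurrence
    extraction over a whole corpus. Pure function of its inputs."""
    if not keywords:
        raise ValueError("keyword list must be non-empty")
    records: list[CoOccurrence] = []
    species_calls: dict[str, str] = {}
    ambiguous: list[str] = []
    unresolved: list[GeneMention] = []

    for article in corpus:
        group = classify_species(article, lexicon)
        species_calls[article.pmid] = group
        if group == AMBIGUOUS:
            ambiguous.append(article.pmid)
            continue
        for sentence in article.sentences:
            keyword = first_keyword(sentence.text, keywords)
            if keyword is None:
                continue
            seen_genes: set[str] = set()
            for mention in tag_mentions(sentence, dictionary, pmid=article.pmid):
                mention = resolve_mention(mention, group, dictionary)
                if mention.unresolved:
                    unresolved.append(mention)
                    continue
                if mention.resolved in seen_genes:
                    continue
                seen_genes.add(mention.resolved)
                records.append(
                    CoOccurrence(
                        pmid=article.pmid,
                        sentence_index=sentence.index,
                        gene_id=mention.resolved,
                        keyword=keyword,
                        species_group=group,
                    )
                )
    return MiningResult(
        cooccurrences=records,
        species_calls=species_calls,
        ambiguous_pmids=ambiguous,
        unresolved_mentions=unresolved,
    )


def extract_cooccurrences(
    corpus: Corpus,
    keywords: Sequence[str],
    dictionary: SynonymDictionary,
    lexicon: SpeciesLexicon,
) -> list[CoOccurrence]:
    """Co-occurrence records only (see :func:`mine_corpus` for review data)."""
    return mine_corpus(corpus, dictionary, lexicon, keywords).cooccurrences


def compile_gene_sets(
    cooccurrences: Iterable[CoOccurrence],
) -> tuple[SpeciesGeneSet, SpeciesGeneSet]:
    """Aggregate evidence into per-species gene sets with PMID support."""
    sets = {
        HUMAN_GROUP: SpeciesGeneSet(HUMAN_GROUP),
        MOUSE_GROUP: SpeciesGeneSet(MOUSE_GROUP),
    }
    for rec in cooccurrences:
        sets[rec.species_group].genes.setdefault(rec.gene_id, set()).add(rec.pmid)
    return sets[HUMAN_GROUP], sets[MOUSE_GROUP]


def compare_gene_sets(
    a: SpeciesGeneSet,
    b: SpeciesGeneSet,
    ortholog_map: Mapping[str, str] | None = None,
    symbols: Mapping[str, str] | None = None,
) -> VennCounts:
    """Venn comparison of two species gene sets.

    With an ortholog map (partial 1:1, a-namespace -> b-namespace),
    genes are matched through it; otherwise genes are matched on
    case-normalized official symbols when a ``symbols`` mapping is
    supplied, or on raw gene ids.
    """
    genes_a = set(a.genes)
    genes_b = set(b.genes)
    if ortholog_map is not None:
        values = list(ortholog_map.values())
        if len(values) != len(set(values)) or len(ortholog_map) != len(set(ortholog_map)):
            raise ValueError("ortholog map must be 1:1")
        mapped_a = {ortholog_map.get(g, g) for g in genes_a}
        shared = len(mapped_a & genes_b)
        return VennCounts(len(genes_a) - shared, len(genes_b) - shared, shared)
    if symbols is not None:
        keys_a = {symbols[g].lower() for g in genes_a}
        keys_b = {symbols[g].lower() for g in genes_b}
    else:
        keys_a, keys_b = genes_a, genes_b
    shared = len(keys_a & keys_b)
    return VennCounts(len(keys_a) - shared, len(keys_b) - shared, shared)


def read_ortholog_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV: gene id in namespace A -> gene id in namespace B."""
    mapping: dict[str, str] = {}
    for line_no, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 2:
            raise ValueError(f"{path}:{line_no}: expected 2 columns")
        if parts[0] in mapping:
            raise ValueError(f"{path}:{line_no}: duplicate source id {parts[0]}")
        mapping[parts[0]] = parts[1]
    if len(set(mapping.values())) != len(mapping):
        raise ValueError(f"{path}: ortholog map is not 1:1")
    return mapping
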