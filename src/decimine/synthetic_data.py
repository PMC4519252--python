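"""Seeded generators for fully self-contained pipeline scenarios.

A scenario consists of a synthetic gene dictionary and species lexicon,
a PubMed-dialect XML corpus with planted sentence-level gene/keyword
co-occurrences, a GMT term collection with one planted enriched term,
and an interaction table with a planted hub — plus a machine-readable
ground-truth manifest sufficient to score every pipeline stage without
re-running generation.

Noise is injected in two controlled ways: *decoy synonyms* (common
English words that the sentence templates also use, the classic failure
mode of dictionary-based gene tagging) and *ambiguous articles* (no
species cue, or cues from both groups). At zero rates the generated
corpus is noiseless by construction and mining recovery is exact.

All randomness flows from one root seed; each component draws from its
own labelled substream, so adding a component never perturbs others.
Sentence templates are fixed strings with slot filling, so tokenizer
behavior on generated abstracts is exactly predictable.
"""

from __future__ import annotations

import json
import string
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .textmine import (
    DEFAULT_KEYWORDS,
    HUMAN_GROUP,
    MOUSE_GROUP,
    DictEntry,
    SpeciesLexicon,
    SynonymDictionary,
)

__all__ = [
    "ScenarioConfig",
    "GroundTruth",
    "ScenarioPaths",
    "generate_dictionary",
    "generate_corpus",
    "generate_term_collection",
    "generate_interactions",
    "generate_scenario",
    "STOP_WORDS",
    "DECOY_POOL",
]

#: Common short English words a synonym dictionary must never contain.
STOP_WORDS = frozenset(
    "the was for and all can has not with this from were are had into over".split()
)

#: Decoy candidates: ordinary words that the sentence templates use, so a
#: decoy synonym produces traceable false-positive mentions.
DECOY_POOL = (
    "during",
    "samples",
    "expression",
    "observed",
    "cells",
    "treatment",
    "analysis",
    "conditions",
)

_LEXICON_FORMS = {
    "human": HUMAN_GROUP,
    "humans": HUMAN_GROUP,
    "woman": HUMAN_GROUP,
    "women": HUMAN_GROUP,
    "patient": HUMAN_GROUP,
    "patients": HUMAN_GROUP,
    "monkey": HUMAN_GROUP,
    "monkeys": HUMAN_GROUP,
    "mouse": MOUSE_GROUP,
    "mice": MOUSE_GROUP,
    "rat": MOUSE_GROUP,
    "rats": MOUSE_GROUP,
    "murine": MOUSE_GROUP,
}

_CUE_FORM = {HUMAN_GROUP: "human", MOUSE_GROUP: "mouse"}

_PLANTED_TEMPLATE = "Expression of {syn} was observed during {kw} in cultured samples."
_CUE_TEMPLATE = "Samples were collected from {form} subjects in this study."
_BOTH_CUE = "Samples were collected from human and mouse subjects in this study."
_FILLERS = (
    "The cells were maintained under standard laboratory conditions.",
    "Hormone treatment was continued for five days.",
    "Statistical analysis confirmed the main comparisons.",
    "The experimental protocol was approved by the committee.",
)

_STREAM_LABELS = {"dictionary": 101, "corpus": 202, "terms": 303, "interactions": 404}


def component_rng(seed: int, label: str) -> np.random.Generator:
    """Independent substream for one generator component."""
    return np.random.default_rng(np.random.SeedSequence((int(seed), _STREAM_LABELS[label])))


@dataclass
class ScenarioConfig:
    """Knobs of one synthetic scenario; defaults define the study
    conditions the pipeline is exercised under."""

    seed: int = 0
    n_articles: tuple[int, int] = (50, 50)  # (human_group, mouse_group)
    n_genes: tuple[int, int] = (10, 10)
    n_shared_genes: int = 3
    association_density: float = 2.0  # planted genes per article (Poisson mean, clipped 1..3)
    decoy_synonym_rate: float = 0.1
    ambiguous_article_rate: float = 0.1
    term_size: int = 10
    planted_fraction: float | None = 1.0  # None -> uniform draw (null term)
    n_terms: int = 20
    edge_probability: float = 0.02
    hub_degree: int = 15
    hub_pub_multiplier: float = 10.0
    year_range: tuple[int, int] = (1980, 2014)

    def __post_init__(self) -> None:
        for rate in (self.decoy_synonym_rate, self.ambiguous_article_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if self.planted_fraction is not None and not 0.0 <= self.planted_fraction <= 1.0:
            raise ValueError("planted_fraction must lie in [0, 1] or be None")
        if min(*self.n_articles, *self.n_genes, self.term_size, self.n_terms) <= 0:
            raise ValueError("counts must be positive")
        if self.n_shared_genes > min(self.n_genes):
            raise ValueError("n_shared_genes exceeds a group's gene count")
        if self.year_range[0] > self.year_range[1]:
            raise ValueError("empty year range")


@dataclass
class GroundTruth:
    """Manifest of everything planted; sufficient to score each stage."""

    config: dict
    articles: dict[str, dict] = field(default_factory=dict)
    expected_support: dict[str, dict[str, list[str]]] = field(default_factory=dict)
    expected_venn: dict[str, int] = field(default_factory=dict)
    decoys: dict[str, str] = field(default_factory=dict)  # word -> gene_id
    symbols: dict[str, str] = field(default_factory=dict)  # gene_id -> symbol
    enriched_term_id: str = ""
    planted_query: list[str] = field(default_factory=list)
    adjacency: list[list[str]] = field(default_factory=list)  # symbol pairs
    hub_symbol: str = ""
    expected_selected: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        return cls(**json.loads(Path(path).read_text()))


def _random_token(rng: np.random.Generator, length: int = 5) -> str:
    return "".join(rng.choice(list(string.ascii_uppercase), size=length))


def generate_dictionary(
    config: ScenarioConfig,
) -> tuple[SynonymDictionary, SpeciesLexicon, GroundTruth]:
    """Synthetic gene ids, symbols and synonyms for both species groups.

    Shared genes carry the same official symbol in both groups (distinct
    per-species gene ids), mirroring cross-species symbol matching.
    Decoy synonyms are drawn from :data:`DECOY_POOL` at the configured
    rate.
    """
    rng = component_rng(config.seed, "dictionary")
    truth = GroundTruth(config=asdict(config))

    def symbols_for(n: int, prefix: str) -> list[str]:
        shared = [f"DSG{i + 1}" for i in range(config.n_shared_genes)]
        specific = [f"{prefix}{i + 1}" for i in range(n - config.n_shared_genes)]
        return shared + specific

    entries: list[DictEntry] = []
    used: set[str] = set(STOP_WORDS)
    decoy_pool = list(DECOY_POOL)
    specs = [
        (HUMAN_GROUP, "h", symbols_for(config.n_genes[0], "HDG")),
        (MOUSE_GROUP, "m", symbols_for(config.n_genes[1], "MDG")),
    ]
    for group, id_prefix, symbols in specs:
        for i, symbol in enumerate(symbols):
            gene_id = f"{id_prefix}{i + 1:04d}"
            n_syn = int(rng.integers(1, 4))
            synonyms: list[str] = []
            while len(synonyms) < n_syn:
                tok = _random_token(rng)
                if tok not in used and tok != symbol:
                    used.add(tok)
                    synonyms.append(tok)
            if decoy_pool and rng.random() < config.decoy_synonym_rate:
                word = decoy_pool.pop(int(rng.integers(len(decoy_pool))))
                synonyms.append(word)
                truth.decoys[word] = gene_id
            entries.append(DictEntry(gene_id, group, symbol, synonyms))
            truth.symbols[gene_id] = symbol

    dictionary = SynonymDictionary(entries)
    lexicon = SpeciesLexicon(dict(_LEXICON_FORMS))
    return dictionary, lexicon, truth


def _group_gene_ids(truth: GroundTruth, group_prefix: str) -> list[str]:
    return sorted(g for g in truth.symbols if g.startswith(group_prefix))


def _hub_gene_ids(
    config: ScenarioConfig, truth: GroundTruth
) -> tuple[str, dict[str, str]]:
    """Hub symbol and the gene id carrying it in each group."""
    hub_symbol = "DSG1" if config.n_shared_genes >= 1 else "HDG1"
    carriers: dict[str, str] = {}
    for group, prefix in ((HUMAN_GROUP, "h"), (MOUSE_GROUP, "m")):
        for gid in _group_gene_ids(truth, prefix):
            if truth.symbols[gid] == hub_symbol:
                carriers[group] = gid
                break
    return hub_symbol, carriers


def generate_corpus(
    config: ScenarioConfig,
    dictionary: SynonymDictionary,
    truth: GroundTruth,
    path: str | Path,
) -> GroundTruth:
    """Write a PubMed-dialect XML corpus with planted co-occurrences.

    Each article gets a species cue sentence (or none/both at the
    ambiguous rate), one planted sentence per planted gene (a non-decoy
    synonym plus one topic keyword), and neutral filler sentences. The
    manifest records every planted tuple and the support a perfect miner
    recovers (ambiguous articles excluded).
    """
    rng = component_rng(config.seed, "corpus")
    hub_symbol, hub_ids = _hub_gene_ids(config, truth)
    decoy_words = set(truth.decoys)

    group_ids = {
        HUMAN_GROUP: _group_gene_ids(truth, "h"),
        MOUSE_GROUP: _group_gene_ids(truth, "m"),
    }
    support: dict[str, dict[str, set[str]]] = {HUMAN_GROUP: {}, MOUSE_GROUP: {}}

    root = ET.Element("PubmedArticleSet")
    pmid_counter = 2000000
    plan = [(HUMAN_GROUP, config.n_articles[0]), (MOUSE_GROUP, config.n_articles[1])]
    for group, n_articles in plan:
        ids = group_ids[group]
        weights = np.array(
            [config.hub_pub_multiplier if g == hub_ids.get(group) else 1.0 for g in ids]
        )
        weights /= weights.sum()
        for _ in range(n_articles):
            pmid_counter += 1
            pmid = str(pmid_counter)
            year = int(rng.integers(config.year_range[0], config.year_range[1] + 1))
            ambiguous = bool(rng.random() < config.ambiguous_article_rate)
            amb_style = str(rng.choice(["none", "both"])) if ambiguous else None

            n_planted = int(np.clip(rng.poisson(config.association_density), 1, 3))
            n_planted = min(n_planted, len(ids))
            planted_genes = list(rng.choice(ids, size=n_planted, replace=False, p=weights))

            if amb_style == "none":
                sentences = [_FILLERS[int(rng.integers(len(_FILLERS)))]]
            elif amb_style == "both":
                sentences = [_BOTH_CUE]
            else:
                sentences = [_CUE_TEMPLATE.format(form=_CUE_FORM[group])]

            planted_tuples = []
            for gene_id in planted_genes:
                entry = dictionary.entries[gene_id]
                surfaces = [entry.official_symbol] + [
                    s for s in entry.synonyms if s not in decoy_words
                ]
                surface = str(rng.choice(surfaces))
                keyword = str(rng.choice(list(DEFAULT_KEYWORDS)))
                planted_tuples.append([len(sentences), gene_id, keyword])
                sentences.append(_PLANTED_TEMPLATE.format(syn=surface, kw=keyword))
                if not ambiguous:
                    support[group].setdefault(gene_id, set()).add(pmid)

            for _ in range(int(rng.integers(1, 3))):
                sentences.append(_FILLERS[int(rng.integers(len(_FILLERS)))])

            truth.articles[pmid] = {
                "group": group,
                "ambiguous": ambiguous,
                "year": year,
                "planted": planted_tuples,
            }

            art = ET.SubElement(root, "PubmedArticle")
            cit = ET.SubElement(art, "MedlineCitation")
            ET.SubElement(cit, "PMID").text = pmid
            article_el = ET.SubElement(cit, "Article")
            journal = ET.SubElement(article_el, "Journal")
            issue = ET.SubElement(journal, "JournalIssue")
            pubdate = ET.SubElement(issue, "PubDate")
            ET.SubElement(pubdate, "Year").text = str(year)
            ET.SubElement(article_el, "ArticleTitle").text = (
                f"Regulation of stromal differentiation in study {pmid}."
            )
            abstract_el = ET.SubElement(article_el, "Abstract")
            ET.SubElement(abstract_el, "AbstractText").text = " ".join(sentences)

    truth.expected_support = {
        group: {g: sorted(pmids) for g, pmids in sorted(genes.items())}
        for group, genes in support.items()
    }
    sym_a = {truth.symbols[g].lower() for g in support[HUMAN_GROUP]}
    sym_b = {truth.symbols[g].lower() for g in support[MOUSE_GROUP]}
    truth.expected_venn = {
        "n_a_only": len(sym_a - sym_b),
        "n_b_only": len(sym_b - sym_a),
        "n_shared": len(sym_a & sym_b),
        "n_union": len(sym_a | sym_b),
    }

    tree = ET.ElementTree(root)
    ET.indent(tree)
    tree.write(path, encoding="utf-8", xml_declaration=True)
    return truth


def generate_term_collection(
    config: ScenarioConfig, truth: GroundTruth, path: str | Path
) -> GroundTruth:
    """GMT collection over all synthetic gene ids with one planted term.

    The planted term draws ``planted_fraction`` of its members from the
    planted query (the human-group gene set); ``planted_fraction=None``
    draws uniformly from the background, the null behavior.
    """
    rng = component_rng(config.seed, "terms")
    background = sorted(truth.symbols)
    query = _group_gene_ids(truth, "h")
    truth.planted_query = query
    truth.enriched_term_id = "T0001"

    lines = []
    size = min(config.term_size, len(background))
    if config.planted_fraction is None:
        members = list(rng.choice(background, size=size, replace=False))
    else:
        n_from_query = min(round(size * config.planted_fraction), len(query))
        rest = sorted(set(background) - set(query))
        n_rest = min(size - n_from_query, len(rest))
        members = list(rng.choice(query, size=n_from_query, replace=False))
        if n_rest > 0:
            members += list(rng.choice(rest, size=n_rest, replace=False))
    lines.append("\t".join(["T0001", "planted term", *sorted(members)]))

    for t in range(2, config.n_terms + 1):
        tsize = int(rng.integers(5, min(16, len(background) + 1)))
        members = list(rng.choice(background, size=tsize, replace=False))
        lines.append("\t".join([f"T{t:04d}", f"random term {t}", *sorted(members)]))

    Path(path).write_text("\n".join(lines) + "\n")
    return truth


def generate_interactions(
    config: ScenarioConfig, truth: GroundTruth, path: str | Path
) -> GroundTruth:
    """Interaction TSV over official symbols: an Erdos-Renyi background
    plus a planted hub wired to ``hub_degree`` neighbors."""
    rng = component_rng(config.seed, "interactions")
    symbols = sorted(set(truth.symbols.values()))
    hub_symbol, _ = _hub_gene_ids(config, truth)

    edges: set[tuple[str, str]] = set()
    for i, a in enumerate(symbols):
        for b in symbols[i + 1 :]:
            if rng.random() < config.edge_probability:
                edges.add((a, b))

    partners = [s for s in symbols if s != hub_symbol]
    k = min(config.hub_degree, len(partners))
    for partner in rng.choice(partners, size=k, replace=False):
        edges.add(tuple(sorted((hub_symbol, str(partner)))))

    ordered = sorted(edges)
    truth.adjacency = [list(e) for e in ordered]
    truth.hub_symbol = hub_symbol
    truth.expected_selected = [hub_symbol]
    Path(path).write_text("\n".join(f"{a}\t{b}" for a, b in ordered) + "\n")
    return truth


@dataclass
class ScenarioPaths:
    outdir: Path
    corpus: Path
    dictionary: Path
    lexicon: Path
    terms: Path
    interactions: Path
    manifest: Path


def generate_scenario(config: ScenarioConfig, outdir: str | Path) -> tuple[ScenarioPaths, GroundTruth]:
    """Generate every scenario file plus the ground-truth manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = ScenarioPaths(
        outdir=outdir,
        corpus=outdir / "corpus.xml",
        dictionary=outdir / "dictionary.tsv",
        lexicon=outdir / "lexicon.tsv",
        terms=outdir / "terms.gmt",
        interactions=outdir / "interactions.tsv",
        manifest=outdir / "manifest.json",
    )
    dictionary, lexicon, truth = generate_dictionary(config)
    dictionary.to_tsv(paths.dictionary)
    lexicon.to_tsv(paths.lexicon)
    truth = generate_corpus(config, dictionary, truth, paths.corpus)
    truth = generate_term_collection(config, truth, paths.terms)
    truth = generate_interactions(config, truth, paths.interactions)
    truth.to_json(paths.manifest)
    return paths, truth
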