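"""End-to-end orchestration: corpus -> gene sets -> enrichment -> network.

A single config file drives the full analysis. Each stage persists its
outputs as TSV under the configured output directory, and the run ends
with a machine-readable JSON report whose counts equal the row counts
of the corresponding output files. Identical config + inputs produce
byte-identical outputs, except the report's timestamp field.
"""

from __future__ import annotations

import glob as globlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import __version__
from .corpus_io import load_corpus, publications_by_year
from .enrichment import enrich_terms, read_gmt
from .network import (
    compute_dif,
    degree_map,
    fit_power_law,
    induce_network,
    load_interactions,
    prioritize_genes,
    write_edge_list,
    write_sif,
)
from .textmine import (
    DEFAULT_KEYWORDS,
    HUMAN_GROUP,
    MOUSE_GROUP,
    SpeciesLexicon,
    SynonymDictionary,
    compare_gene_sets,
    compile_gene_sets,
    mine_corpus,
    read_ortholog_map,
)

logger = logging.getLogger(__name__)

QUERY_SET_NAMES = ("human", "mouse", "union", "intersection", "human_only", "mouse_only")


@dataclass
class PipelineConfig:
    corpus: list[str]
    dictionary: str
    lexicon: str
    outdir: str
    gmt: list[str] = field(default_factory=list)
    interactions: str | None = None
    ortholog_map: str | None = None
    id_map: str | None = None
    keywords: list[str] = field(default_factory=lambda: list(DEFAULT_KEYWORDS))
    alpha: float = 0.05
    sd_ddof: int = 1
    query_sets: list[str] = field(default_factory=lambda: list(QUERY_SET_NAMES))
    seed: int = 0


def validate_config(path: str | Path) -> tuple[PipelineConfig | None, list[str]]:
    """Parse and validate a YAML pipeline config.

    Returns the config and an empty list, or ``None`` and the complete
    list of violations (not just the first).
    """
    raw = yaml.safe_load(Path(path).read_text())
    errors: list[str] = []
    if not isinstance(raw, dict):
        return None, ["config must be a mapping"]

    known = set(PipelineConfig.__dataclass_fields__)
    unknown = set(raw) - known
    for key in sorted(unknown):
        errors.append(f"unknown config key: {key}")

    for key in ("corpus", "dictionary", "lexicon", "outdir"):
        if key not in raw:
            errors.append(f"missing required key: {key}")
    if errors:
        return None, errors

    if isinstance(raw["corpus"], str):
        raw["corpus"] = [raw["corpus"]]
    if isinstance(raw.get("gmt"), str):
        raw["gmt"] = [raw["gmt"]]
    config = PipelineConfig(**{k: v for k, v in raw.items() if k in known})

    matched = sorted(f for pattern in config.corpus for f in globlib.glob(pattern))
    if not matched:
        errors.append(f"corpus pattern(s) match no files: {config.corpus}")
    for name in ("dictionary", "lexicon", "interactions", "ortholog_map", "id_map"):
        value = getattr(config, name)
        if value is not None and not Path(value).exists():
            errors.append(f"{name} path does not exist: {value}")
    for path_ in config.gmt:
        if not Path(path_).exists():
            errors.append(f"gmt path does not exist: {path_}")
    if not 0 < config.alpha < 1:
        errors.append(f"alpha must be in (0, 1), got {config.alpha}")
    if config.sd_ddof not in (0, 1):
        errors.append(f"sd_ddof must be 0 or 1, got {config.sd_ddof}")
    for qs in config.query_sets:
        if qs not in QUERY_SET_NAMES:
            errors.append(f"unknown query set: {qs}")
    if not config.keywords:
        errors.append("keyword list must be non-empty")
    return (config, []) if not errors else (None, errors)


@dataclass
class RunReport:
    config: dict
    version: str = __version__
    timestamp: str = ""
    failed_stage: str | None = None
    counts: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = asdict(self)
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")


def _id_query_sets(human_set, mouse_set, symbols: dict[str, str]) -> dict[str, set[str]]:
    """The six named query sets, built on symbols and mapped back to ids."""
    ids_a, ids_b = set(human_set.genes), set(mouse_set.genes)
    sym = lambda g: symbols[g].lower()
    sym_a = {sym(g) for g in ids_a}
    sym_b = {sym(g) for g in ids_b}
    return {
        "human": ids_a,
        "mouse": ids_b,
        "union": ids_a | ids_b,
        "intersection": {g for g in ids_a | ids_b if sym(g) in sym_a & sym_b},
        "human_only": {g for g in ids_a if sym(g) not in sym_b},
        "mouse_only": {g for g in ids_b if sym(g) not in sym_a},
    }


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Run every stage in order; see module docstring for the contract."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logging.getLogger("decimine").addHandler(handler)

    report = RunReport(config=asdict(config))
    counts = report.counts
    try:
        # stage 1: corpus
        files = sorted(f for pattern in config.corpus for f in globlib.glob(pattern))
        corpus = load_corpus(files)
        years = publications_by_year(corpus)
        years.to_frame().to_csv(outdir / "years.tsv", sep="\t", index=False)
        counts["articles"] = len(corpus)
        counts["missing_year"] = years.n_missing_year

        # stage 2: mining
        dictionary = SynonymDictionary.from_tsv(config.dictionary)
        lexicon = SpeciesLexicon.from_tsv(config.lexicon)
        mining = mine_corpus(corpus, dictionary, lexicon, config.keywords)
        counts["ambiguous_articles"] = len(mining.ambiguous_pmids)
        counts["cooccurrences"] = len(mining.cooccurrences)
        counts["unresolved_mentions"] = len(mining.unresolved_mentions)

        pd.DataFrame(
            sorted(
                (r.pmid, r.sentence_index, r.gene_id, r.keyword, r.species_group)
                for r in mining.cooccurrences
            ),
            columns=["pmid", "sentence_idx", "gene_id", "keyword", "group"],
        ).to_csv(outdir / "cooccurrences.tsv", sep="\t", index=False)
        pd.DataFrame(sorted(mining.ambiguous_pmids), columns=["pmid"]).to_csv(
            outdir / "review_ambiguous.tsv", sep="\t", index=False
        )
        pd.DataFrame(
            sorted(
                (m.pmid, m.sentence_index, m.surface, "|".join(m.candidates))
                for m in mining.unresolved_mentions
            ),
            columns=["pmid", "sentence_idx", "surface", "candidates"],
        ).to_csv(outdir / "review_unresolved.tsv", sep="\t", index=False)

        human_set, mouse_set = compile_gene_sets(mining.cooccurrences)
        counts["genes_human"] = len(human_set)
        counts["genes_mouse"] = len(mouse_set)
        symbols = {gid: e.official_symbol for gid, e in dictionary.entries.items()}
        rows = [
            (s.species_group, gid, symbols[gid], len(pmids), ",".join(sorted(pmids)))
            for s in (human_set, mouse_set)
            for gid, pmids in sorted(s.genes.items())
        ]
        pd.DataFrame(rows, columns=["group", "gene_id", "symbol", "n_pubs", "pmids"]).to_csv(
            outdir / "gene_sets.tsv", sep="\t", index=False
        )

        ortholog = read_ortholog_map(config.ortholog_map) if config.ortholog_map else None
        venn = compare_gene_sets(human_set, mouse_set, ortholog_map=ortholog, symbols=symbols)
        counts["venn"] = {
            "human_only": venn.n_a_only,
            "mouse_only": venn.n_b_only,
            "shared": venn.n_shared,
            "union": venn.n_union,
        }
        pd.DataFrame(
            [(venn.n_a_only, venn.n_b_only, venn.n_shared, venn.n_union)],
            columns=["human_only", "mouse_only", "shared", "union"],
        ).to_csv(outdir / "venn.tsv", sep="\t", index=False)

        # stage 3: enrichment
        queries = _id_query_sets(human_set, mouse_set, symbols)
        counts["significant_terms"] = {}
        for gmt_path in config.gmt:
            collection = read_gmt(gmt_path)
            stem = Path(gmt_path).stem
            for qs_name in config.query_sets:
                results = enrich_terms(queries[qs_name], collection, alpha=config.alpha)
                frame = pd.DataFrame(
                    [
                        (r.term_id, r.name, r.k, r.K, r.n, r.N, r.p_raw, r.p_adj, r.significant)
                        for r in results
                    ],
                    columns=["term_id", "name", "k", "K", "n", "N", "p_raw", "p_adj", "significant"],
                )
                frame.to_csv(outdir / f"enrichment_{stem}_{qs_name}.tsv", sep="\t", index=False)
                counts["significant_terms"][f"{stem}/{qs_name}"] = int(
                    sum(r.significant for r in results)
                )

        # stage 4: network + prioritization (merged species, symbol namespace)
        if config.interactions:
            id_map = read_ortholog_map(config.id_map) if config.id_map else None
            table = load_interactions(config.interactions, id_map=id_map)
            union_symbols = {symbols[g] for g in queries["union"]}
            network = induce_network(union_symbols, table)
            counts["network_nodes"] = len(network.nodes)
            counts["network_edges"] = network.n_edges
            counts["network_isolated"] = len(network.isolated)
            write_edge_list(network, outdir / "network_edges.tsv")
            write_sif(network, outdir / "network.sif")

            pubs_by_symbol: dict[str, set[str]] = {}
            for s in (human_set, mouse_set):
                for gid, pmids in s.genes.items():
                    pubs_by_symbol.setdefault(symbols[gid], set()).update(pmids)
            pubcounts = {sym: len(pmids) for sym, pmids in pubs_by_symbol.items()}

            if len(network.nodes) >= 2:
                dist = degree_map(network)
                try:
                    fit = fit_power_law(dist)
                    counts["power_law"] = {"gamma": fit.gamma, "r_squared": fit.r_squared}
                except ValueError:
                    logger.warning("degree histogram too degenerate for a power-law fit")
                records = compute_dif(network, pubcounts)
                result = prioritize_genes(records, ddof=config.sd_ddof)
                counts["dif_threshold"] = result.threshold
                counts["selected_genes"] = [r.gene_id for r in result.selected]
                group_of = {}
                for s, tag in ((human_set, "human"), (mouse_set, "mouse")):
                    for gid in s.genes:
                        sym = symbols[gid]
                        group_of[sym] = "shared" if group_of.get(sym, tag) != tag else tag
                pd.DataFrame(
                    [
                        (r.gene_id, group_of.get(r.gene_id, "unknown"), r.degree, r.n_pubs, r.dif, r.selected)
                        for r in result.records
                    ],
                    columns=["gene_id", "group", "degree", "n_pubs", "dif", "selected"],
                ).to_csv(outdir / "prioritization.tsv", sep="\t", index=False)
            else:
                logger.warning("network too small for prioritization; skipped")
                counts["selected_genes"] = []
    except Exception as exc:
        report.failed_stage = f"{type(exc).__name__}: {exc}"
        report.timestamp = time.strftime("%Y-%m-%dT%H:%M:%S")
        report.to_json(outdir / "report.json")
        logging.getLogger("decimine").removeHandler(handler)
        handler.close()
        raise

    report.timestamp = time.strftime("%Y-%m-%dT%H:%M:%S")
    report.to_json(outdir / "report.json")
    logging.getLogger("decimine").removeHandler(handler)
    handler.close()
    return report
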