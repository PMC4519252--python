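"""Mine the corpus: classify article species, extract sentence-level
gene/keyword co-occurrences, and compile the per-species gene sets with
their publication counts and Venn comparison.

Reads results/scenario/, writes results/mining/.
"""

from pathlib import Path

import pandas as pd

from decimine.corpus_io import parse_pubmed_xml, publications_by_year
from decimine.textmine import (
    SpeciesLexicon,
    SynonymDictionary,
    compare_gene_sets,
    compile_gene_sets,
    mine_corpus,
)

ROOT = Path(__file__).resolve().parents[1] / "results"
OUT = ROOT / "mining"
OUT.mkdir(parents=True, exist_ok=True)

corpus = parse_pubmed_xml(ROOT / "scenario" / "corpus.xml")
dictionary = SynonymDictionary.from_tsv(ROOT / "scenario" / "dictionary.tsv")
lexicon = SpeciesLexicon.from_tsv(ROOT / "scenario" / "lexicon.tsv")

result = mine_corpus(corpus, dictionary, lexicon)
human, mouse = compile_gene_sets(result.cooccurrences)
symbols = {gid: e.official_symbol for gid, e in dictionary.entries.items()}
venn = compare_gene_sets(human, mouse, symbols=symbols)

pd.DataFrame(
    sorted((r.pmid, r.sentence_index, r.gene_id, r.keyword, r.species_group)
           for r in result.cooccurrences),
    columns=["pmid", "sentence_idx", "gene_id", "keyword", "group"],
).to_csv(OUT / "cooccurrences.tsv", sep="\t", index=False)

pd.DataFrame(
    [(s.species_group, g, symbols[g], len(p), ",".join(sorted(p)))
     for s in (human, mouse) for g, p in sorted(s.genes.items())],
    columns=["group", "gene_id", "symbol", "n_pubs", "pmids"],
).to_csv(OUT / "gene_sets.tsv", sep="\t", index=False)

publications_by_year(corpus).to_frame().to_csv(OUT / "years.tsv", sep="\t", index=False)

print(f"co-occurrence records: {len(result.cooccurrences)}")
print(f"gene sets: {len(human)} human, {len(mouse)} mouse")
print(f"Venn (on symbols): human-only {venn.n_a_only}, mouse-only {venn.n_b_only}, "
      f"shared {venn.n_shared}, union {venn.n_union}")
print(f"ambiguous articles: {len(result.ambiguous_pmids)}; "
      f"unresolved mentions: {len(result.unresolved_mentions)}")
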