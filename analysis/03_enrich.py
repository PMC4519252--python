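"""Over-representation analysis of the mined gene sets against the term
collection: hypergeometric upper-tail p-values with BH correction,
run for six query sets (human, mouse, union, intersection, and the two
species-specific differences).

Reads results/scenario/ and results/mining/, writes results/enrichment/.
"""

from pathlib import Path

import pandas as pd

from decimine.enrichment import enrich_terms, read_gmt

ROOT = Path(__file__).resolve().parents[1] / "results"
OUT = ROOT / "enrichment"
OUT.mkdir(parents=True, exist_ok=True)

gene_sets = pd.read_csv(ROOT / "mining" / "gene_sets.tsv", sep="\t")
collection = read_gmt(ROOT / "scenario" / "terms.gmt")

ids = {g: set(gene_sets[gene_sets.group == g].gene_id) for g in ("human_group", "mouse_group")}
sym = dict(zip(gene_sets.gene_id, gene_sets.symbol))
sym_h = {sym[g] for g in ids["human_group"]}
sym_m = {sym[g] for g in ids["mouse_group"]}
all_ids = ids["human_group"] | ids["mouse_group"]
queries = {
    "human": ids["human_group"],
    "mouse": ids["mouse_group"],
    "union": all_ids,
    "intersection": {g for g in all_ids if sym[g] in sym_h & sym_m},
    "human_only": {g for g in ids["human_group"] if sym[g] not in sym_m},
    "mouse_only": {g for g in ids["mouse_group"] if sym[g] not in sym_h},
}

for name, query in queries.items():
    results = enrich_terms(query, collection)
    frame = pd.DataFrame(
        [(r.term_id, r.name, r.k, r.K, r.n, r.N, r.p_raw, r.p_adj, r.significant)
         for r in results],
        columns=["term_id", "name", "k", "K", "n", "N", "p_raw", "p_adj", "significant"],
    )
    frame.to_csv(OUT / f"enrichment_{name}.tsv", sep="\t", index=False)
    n_sig = int(frame.significant.sum())
    top = frame.iloc[0]
    print(f"{name:13s} n={len(query):3d}  significant terms: {n_sig}  "
          f"top: {top.term_id} (p_adj={top.p_adj:.3g})")
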