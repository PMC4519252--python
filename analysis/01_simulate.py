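"""Generate the study scenario: a two-species synthetic corpus with
planted gene/keyword co-occurrences, dictionary, lexicon, term
collection, and interaction table, plus the ground-truth manifest.

Writes results/scenario/ and prints the planted structure.
"""

from pathlib import Path

from decimine.synthetic_data import ScenarioConfig, generate_scenario

OUT = Path(__file__).resolve().parents[1] / "results" / "scenario"

config = ScenarioConfig(seed=1, decoy_synonym_rate=0.0, ambiguous_article_rate=0.0)
paths, truth = generate_scenario(config, OUT)

n_human = len(truth.expected_support["human_group"])
n_mouse = len(truth.expected_support["mouse_group"])
print(f"scenario written to {OUT}")
print(f"articles: {len(truth.articles)} ({config.n_articles[0]} human-group, {config.n_articles[1]} mouse-group)")
print(f"planted gene support: {n_human} human genes, {n_mouse} mouse genes")
print(f"expected Venn: {truth.expected_venn}")
print(f"planted enriched term: {truth.enriched_term_id}; planted hub: {truth.hub_symbol}")
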