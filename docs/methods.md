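# Methods

## The evidence model

The pipeline treats a gene as related to decidualization in a species
when at least one abstract sentence contains both a topic keyword and a
gene mention that normalizes to a unique identifier. The sentence-level
co-occurrence requirement is the precision device: a keyword in one
sentence and a gene in another contributes nothing. Seven keywords
define the topic (decidualization, decidual, decidua, deciduas,
deciduoma, decidualized, decidualizing), matched case-insensitively at
word boundaries — "Decidualization" matches, "predecidual" does not,
since no substring matches are allowed. When several keywords share a
sentence, the earliest occurrence is recorded with each gene.

Publication support per gene is the number of distinct PMIDs carrying
at least one co-occurrence for it. For the merged network, support is
pooled across species groups on the official-symbol namespace.

## Sentence tokenization

Abstracts are split after `. ! ?` when followed by whitespace and an
uppercase letter or digit. A fixed abbreviation stop-list (e.g., i.e.,
et al., fig., figs., vs., ca., approx., sp., spp., cf., no.)
suppresses false splits. Offsets are 0-based half-open into the source
abstract, so every sentence is an exact slice; joining sentence texts
restores all non-whitespace characters in order (a property test).
The tokenizer is deliberately rule-based rather than model-based:
tokenizer identity is not part of the scientific contribution, and a
deterministic rule makes every downstream count reproducible.

## Species classification

A lexicon maps surface forms to two groups: human (human, women,
patients, monkey, ...) and mouse (mouse, mice, rat, murine, ...),
reflecting the grouping of monkey with human and rat with mouse. Title
and abstract are scanned at word boundaries; exactly one group's forms
present assigns the article, otherwise (none, or both) the article is
*ambiguous*: excluded from gene-set evidence, still counted in the
publication time series, and listed in a review file — the automated
stand-in for a manual curation step. Titles are used for
classification but not mined for co-occurrence; mining operates on
abstract sentences only.

## Gene tagging and normalization

Tagging is a deterministic dictionary matcher over the synonym
dictionary (gene id, species group, official symbol, synonyms).
Matching is longest-match-first at word boundaries so "IGFBP1" beats an
embedded "IGFBP"; matches are case-insensitive except that synonyms of
three characters or fewer must match exactly, a guard against
collisions with ordinary English words — the known failure mode of
dictionary NER. The threshold is configurable on the dictionary.

Ambiguous mentions (a surface form shared by several genes) are
resolved by a fixed cascade: restrict to candidates of the article's
species group; then prefer a candidate whose official symbol equals the
surface form case-insensitively; otherwise the mention goes to a review
file and contributes no evidence. The cascade replaces manual
disambiguation with stated rules while preserving the curation hook.

## Cross-species comparison

Human and mouse gene namespaces are matched on case-normalized official
symbols by default; a partial 1:1 ortholog-map TSV can override this.
Venn counts satisfy |A∪B| = |A| + |B| − |A∩B| (property-tested). The
merged PPI network uses the same symbol convention for node identity.

## Enrichment

Over-representation only: P(X ≥ k) for X hypergeometric with
population N (the collection's background), K marked (term size) and n
drawn (query size), evaluated through the survival function in log
space; P(X ≥ 0) is exactly 1. The test suite checks it against an
exact rational enumeration oracle (Fraction arithmetic over the
hypergeometric pmf) for 500 random parameter sets with N ≤ 25 at
1e-12. BH adjustment is the step-up procedure (sort ascending, scale
p(i) by m/i, cumulative minimum from the top, cap at 1), applied per
collection; it is permutation-invariant and dominates the raw p-values
elementwise. The background defaults to all genes annotated anywhere
in the collection and is configurable. Six named query sets (human,
mouse, union, intersection, and both differences) are built on the
symbol namespace and mapped back to gene ids, since collections
annotate ids. GO DAG structure and term redundancy are out of scope:
collections are flat.

## Network and prioritization

Interaction files (two-column TSV or MITAB 2.5 columns 1–2) are
canonicalized to undirected sorted pairs; duplicates collapse,
self-pairs are flagged and never contribute to degree. The
decidualization subnetwork is the induced subgraph on the mined genes;
genes with no internal partner are excluded from the network and from
all downstream statistics but reported (the network is therefore
smaller than the gene list, as observed in practice). Degree is the
neighbor-set size; the handshake identity Σdeg = 2|E| is asserted on
every constructed graph.

Scale-freeness is assessed by least-squares on log(count) vs
log(degree) over occupied histogram bins — the NetworkAnalyzer-era
convention, kept for comparability; a maximum-likelihood fit is out of
scope. γ is the negated slope.

DIF = degree × publications, exact integer arithmetic. The selection
threshold is mean + 2 standard deviations of DIF over network nodes,
with the sample (n−1) flavor by default (the population flavor is a
config switch); selection is strictly greater than the threshold.
Two consequences worth knowing: with fewer than ~6 nodes nothing can
ever be selected (the maximum sample z-score is (n−1)/√n < 2 at n = 5,
asserted as a property), and selection is invariant under uniform
positive rescaling of all DIF values.

## Synthetic scenarios

The generator emulates the statistical structure the analysis assumes,
not biomedical prose. Fixed sentence templates with slot filling make
tokenizer behavior exactly predictable. Each article gets one species
cue sentence, 1–3 planted sentences (one gene synonym + one keyword
each), and 1–2 neutral fillers — 3–6 sentences total. Noise enters two
ways, both off by default in the fixture scenario and at rate 0.1 in
the general defaults: *decoy synonyms*, common English words from the
templates inserted as synonyms so that false positives are injected
and individually traceable to their decoy; and *ambiguous articles*
(no species cue, or both), which must be excluded by classification.

Default scenario conditions: 50+50 articles, 10+10 genes with 3 shared
symbols, association density 2 planted genes/article, years 1980–2014
(the span of the mined literature), a 20-term GMT collection with one
planted term of size 10 drawn entirely from the human-group gene set
(`planted_fraction=None` draws it uniformly — the null construction),
and an interaction table of Erdős–Rényi background p = 0.02 plus a hub
wired to 15 partners whose corpus publication weight is multiplied by
10. The hub-selection scenario widens to 30+30 genes and 100+100
articles so the hub's DIF stands against a realistic spread. All
generation flows from one root seed through fixed per-component
substreams, so adding a component never perturbs another's draws;
regeneration is byte-identical.

What passing these tests shows — and does not. Exact recovery on
noiseless scenarios validates the plumbing and the determinism
contract, and decoy/ambiguity scenarios validate the failure-mode
handling; none of this certifies recall on real abstracts, which is a
property of the real dictionary and of prose the templates do not
imitate (abbreviations defined in-text, coordination, anaphora).

## Numerical and design choices

- Character offsets: 0-based, half-open, everywhere.
- Duplicate PMIDs (within or across files): first occurrence wins,
  rest logged.
- Articles without a usable year are excluded from the time series and
  counted separately; the "recent growth" rate is the least-squares
  slope of the cumulative curve over a trailing window (default 10
  years).
- Enrichment results sort by adjusted p then term id; DIF records by
  DIF descending then gene id — total orders, so outputs are
  byte-stable.
- Problem sizes in tests and in the acceptance script (100–200
  articles, 20–60 genes, 500-tuple oracle sweeps, 20-seed null runs,
  a 2000-node preferential-attachment graph) are chosen so the full
  suite completes in seconds while every claim is still exercised at a
  size where failure modes would show.

## Limitations

- Dictionary NER only: no statistical tagger, no abbreviation
  expansion, no coreference; recall on real text is bounded by the
  supplied dictionary.
- Flat term collections; no GO DAG propagation.
- The published headline counts that depend on 2014 database snapshots
  (gene-set sizes, network size, the DIF threshold value and its 12
  selected genes, specific enriched terms) are data-dependent and not
  reproduction targets; the pipeline reproduces the *procedures* and
  their arithmetic identities.
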