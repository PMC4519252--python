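"""Species classification, dictionary tagging, mention resolution,
co-occurrence extraction, gene-set compilation and Venn comparison."""

import pytest
from hypothesis import given, settings, strategies as st

from decimine.corpus_io import Article, Sentence, parse_pubmed_xml, tokenize_sentences
from decimine.textmine import (
    AMBIGUOUS,
    DEFAULT_KEYWORDS,
    HUMAN_GROUP,
    MOUSE_GROUP,
    DictEntry,
    SpeciesGeneSet,
    SpeciesLexicon,
    SynonymDictionary,
    VennCounts,
    classify_species,
    compare_gene_sets,
    compile_gene_sets,
    extract_cooccurrences,
    mine_corpus,
    resolve_mention,
    tag_mentions,
)


@pytest.fixture
def lexicon():
    return SpeciesLexicon(
        {"human": HUMAN_GROUP, "women": HUMAN_GROUP, "monkey": HUMAN_GROUP,
         "mouse": MOUSE_GROUP, "mice": MOUSE_GROUP, "rat": MOUSE_GROUP}
    )


@pytest.fixture
def dictionary():
    return SynonymDictionary(
        [
            DictEntry("g1", MOUSE_GROUP, "G1A", ["GENEONE"]),
            DictEntry("g2", HUMAN_GROUP, "ABC", ["ALPHA"]),
            DictEntry("g9", MOUSE_GROUP, "XYZ", ["ABC"]),
            DictEntry("g3", HUMAN_GROUP, "IGFBP", []),
            DictEntry("g4", HUMAN_GROUP, "IGFBP1", []),
            DictEntry("g5", HUMAN_GROUP, "QQQ1", ["ALPHA"]),
        ]
    )


def _article(abstract, title="A study."):
    return Article(pmid="1", year=2000, title=title, abstract=abstract,
                   sentences=tokenize_sentences(abstract))


def _sentence(text):
    return Sentence(text=text, index=0, char_start=0, char_end=len(text))


class TestClassifySpecies:
    @pytest.mark.parametrize(
        "abstract,expected",
        [
            ("Decidualization in mice was studied.", MOUSE_GROUP),
            ("The rat uterus was examined.", MOUSE_GROUP),
            ("Studies in the monkey endometrium.", HUMAN_GROUP),
            ("Samples from human and mouse tissue.", AMBIGUOUS),
            ("No species term appears here.", AMBIGUOUS),
        ],
    )
    def test_grouping_rule(self, lexicon, abstract, expected):
        assert classify_species(_article(abstract), lexicon) == expected

    def test_title_counts_for_classification(self, lexicon):
        art = _article("No species here.", title="Decidual change in women.")
        assert classify_species(art, lexicon) == HUMAN_GROUP

    def test_word_boundary_no_substring_match(self, lexicon):
        # "ratio" must not match the lexicon form "rat"
        assert classify_species(_article("The ratio was high."), lexicon) == AMBIGUOUS

    def test_empty_lexicon_rejected(self):
        with pytest.raises(ValueError):
            SpeciesLexicon({})


class TestTagMentions:
    def test_exact_hit(self, dictionary):
        mentions = tag_mentions(_sentence("G1A marks decidualization"), dictionary)
        assert [(m.surface, m.candidates) for m in mentions] == [("G1A", ["g1"])]

    def test_longest_match_wins(self, dictionary):
        mentions = tag_mentions(_sentence("Serum IGFBP1 was high"), dictionary)
        assert [m.surface for m in mentions] == ["IGFBP1"]
        assert mentions[0].candidates == ["g4"]

    def test_no_dictionary_word(self, dictionary):
        assert tag_mentions(_sentence("Nothing to see here"), dictionary) == []

    def test_short_synonyms_case_sensitive(self, dictionary):
        # "abc" lowercase must not match the 3-char symbol "ABC"
        assert tag_mentions(_sentence("the abc of biology"), dictionary) == []
        assert len(tag_mentions(_sentence("ABC binds DNA"), dictionary)) == 1

    def test_long_synonyms_case_insensitive(self, dictionary):
        mentions = tag_mentions(_sentence("geneone was induced"), dictionary)
        assert [m.candidates for m in mentions] == [["g1"]]

    def test_ambiguous_surface_lists_all_candidates(self, dictionary):
        mentions = tag_mentions(_sentence("ALPHA rises"), dictionary)
        assert mentions[0].candidates == ["g2", "g5"]

    def test_surface_equals_sentence_slice(self, dictionary):
        s = _sentence("Here IGFBP1 and G1A interact")
        for m in tag_mentions(s, dictionary):
            assert s.text[m.char_start : m.char_end] == m.surface


class TestResolveMention:
    def _mention(self, dictionary, text):
        [m] = tag_mentions(_sentence(text), dictionary)
        return m

    def test_singleton_resolves(self, dictionary):
        m = resolve_mention(self._mention(dictionary, "G1A rises"), MOUSE_GROUP, dictionary)
        assert m.resolved == "g1"

    def test_species_then_symbol_cascade(self, dictionary):
        # "ABC" is g2's symbol (human) and g9's synonym (mouse)
        m = self._mention(dictionary, "ABC rises")
        assert set(m.candidates) == {"g2", "g9"}
        assert resolve_mention(m, HUMAN_GROUP, dictionary).resolved == "g2"

    def test_species_restriction_alone_resolves(self, dictionary):
        m = self._mention(dictionary, "ABC rises")
        assert resolve_mention(m, MOUSE_GROUP, dictionary).resolved == "g9"

    def test_exhausted_cascade_unresolved(self, dictionary):
        # ALPHA is a synonym of two human genes; neither symbol matches
        m = resolve_mention(self._mention(dictionary, "ALPHA rises"), HUMAN_GROUP, dictionary)
        assert m.unresolved


class TestExtractCooccurrences:
    def _corpus_of(self, abstract, species="mice"):
        art = _article(f"Work in {species} follows. {abstract}")
        from decimine.corpus_io import Corpus

        return Corpus(articles=[art])

    def test_same_sentence_rule(self, dictionary, lexicon):
        corpus = self._corpus_of("G1A is induced during decidualization.")
        records = extract_cooccurrences(corpus, DEFAULT_KEYWORDS, dictionary, lexicon)
        assert len(records) == 1
        assert records[0].gene_id == "g1" and records[0].keyword == "decidualization"
        assert records[0].species_group == MOUSE_GROUP

    def test_cross_sentence_pair_yields_nothing(self, dictionary, lexicon):
        corpus = self._corpus_of("G1A is induced strongly. The decidua thickens.")
        assert extract_cooccurrences(corpus, DEFAULT_KEYWORDS, dictionary, lexicon) == []

    def test_keyword_without_gene_yields_nothing(self, dictionary, lexicon):
        corpus = self._corpus_of("Decidualization proceeds normally.")
        assert extract_cooccurrences(corpus, DEFAULT_KEYWORDS, dictionary, lexicon) == []

    def test_no_substring_keyword_match(self, dictionary, lexicon):
        # "predecidual" must not trigger the keyword "decidual"
        corpus = self._corpus_of("G1A rises in predecidual tissue.")
        assert extract_cooccurrences(corpus, DEFAULT_KEYWORDS, dictionary, lexicon) == []

    def test_ambiguous_article_yields_nothing(self, dictionary, lexicon):
        corpus = self._corpus_of("G1A is induced during decidualization.", species="tissue")
        assert extract_cooccurrences(corpus, DEFAULT_KEYWORDS, dictionary, lexicon) == []

    def test_first_keyword_recorded(self, dictionary, lexicon):
        corpus = self._corpus_of("In decidua, G1A drives decidualization.")
        [rec] = extract_cooccurrences(corpus, DEFAULT_KEYWORDS, dictionary, lexicon)
        assert rec.keyword == "decidua"

    def test_emitted_records_rescan_clean(self, noiseless_scenario):
        """Every emitted record's sentence really contains a keyword and
        the resolved gene's surface form (spec invariant, re-scanned)."""
        from decimine.textmine import SynonymDictionary, SpeciesLexicon, first_keyword

        _, paths, _ = noiseless_scenario
        corpus = parse_pubmed_xml(paths.corpus)
        dictionary = SynonymDictionary.from_tsv(paths.dictionary)
        lexicon = SpeciesLexicon.from_tsv(paths.lexicon)
        records = extract_cooccurrences(corpus, DEFAULT_KEYWORDS, dictionary, lexicon)
        assert records
        by_pmid = {a.pmid: a for a in corpus}
        for rec in records:
            sentence = by_pmid[rec.pmid].sentences[rec.sentence_index]
            assert first_keyword(sentence.text, DEFAULT_KEYWORDS) is not None
            tagged = tag_mentions(sentence, dictionary)
            assert any(rec.gene_id in m.candidates for m in tagged)

    def test_determinism_byte_identical(self, noiseless_scenario):
        _, paths, _ = noiseless_scenario
        corpus = parse_pubmed_xml(paths.corpus)
        dictionary = SynonymDictionary.from_tsv(paths.dictionary)
        lexicon = SpeciesLexicon.from_tsv(paths.lexicon)
        r1 = mine_corpus(corpus, dictionary, lexicon)
        r2 = mine_corpus(corpus, dictionary, lexicon)
        assert r1.cooccurrences == r2.cooccurrences
        assert r1.species_calls == r2.species_calls


class TestCompileAndCompare:
    def test_support_counting(self):
        from decimine.textmine import CoOccurrence

        records = [
            CoOccurrence("1", 0, "g1", "decidua", MOUSE_GROUP),
            CoOccurrence("2", 1, "g1", "decidua", MOUSE_GROUP),
        ]
        human, mouse = compile_gene_sets(records)
        assert len(human) == 0
        assert mouse.genes == {"g1": {"1", "2"}}
        assert mouse.publication_count("g1") == 2

    def test_empty_records(self):
        human, mouse = compile_gene_sets([])
        assert len(human) == len(mouse) == 0

    def test_small_venn(self):
        a = SpeciesGeneSet(HUMAN_GROUP, {g: {"1"} for g in "xyz"})
        b = SpeciesGeneSet(MOUSE_GROUP, {g: {"2"} for g in "yzw"})
        venn = compare_gene_sets(a, b)
        assert (venn.n_shared, venn.n_union) == (2, 4)

    def test_disjoint_sets(self):
        a = SpeciesGeneSet(HUMAN_GROUP, {"x": {"1"}})
        b = SpeciesGeneSet(MOUSE_GROUP, {"y": {"2"}})
        venn = compare_gene_sets(a, b)
        assert venn.n_shared == 0 and venn.n_union == 2

    def test_symbol_based_matching(self):
        a = SpeciesGeneSet(HUMAN_GROUP, {"h1": {"1"}, "h2": {"1"}})
        b = SpeciesGeneSet(MOUSE_GROUP, {"m1": {"2"}})
        symbols = {"h1": "Prl", "h2": "PGR", "m1": "PRL"}
        venn = compare_gene_sets(a, b, symbols=symbols)
        assert venn.n_shared == 1 and venn.n_union == 2

    def test_ortholog_map_matching(self):
        a = SpeciesGeneSet(HUMAN_GROUP, {"h1": {"1"}, "h2": {"1"}})
        b = SpeciesGeneSet(MOUSE_GROUP, {"m1": {"2"}, "m3": {"2"}})
        venn = compare_gene_sets(a, b, ortholog_map={"h1": "m1", "h2": "m2"})
        assert venn.n_shared == 1 and venn.n_union == 3

    def test_many_to_many_ortholog_rejected(self):
        a = SpeciesGeneSet(HUMAN_GROUP, {"h1": {"1"}})
        b = SpeciesGeneSet(MOUSE_GROUP, {"m1": {"2"}})
        with pytest.raises(ValueError):
            compare_gene_sets(a, b, ortholog_map={"h1": "m1", "h2": "m1"})

    @given(
        st.sets(st.integers(0, 50), max_size=30),
        st.sets(st.integers(0, 50), max_size=30),
    )
    @settings(max_examples=200, deadline=None)
    def test_inclusion_exclusion_property(self, ga, gb):
        a = SpeciesGeneSet(HUMAN_GROUP, {str(g): {"1"} for g in ga})
        b = SpeciesGeneSet(MOUSE_GROUP, {str(g): {"2"} for g in gb})
        venn = compare_gene_sets(a, b)
        assert venn.n_union == len(ga) + len(gb) - venn.n_shared
        assert venn.n_union == venn.n_a_only + venn.n_b_only + venn.n_shared
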