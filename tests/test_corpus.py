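"""Corpus data model, dictionary matching, splitting, statistics, I/O."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ubisent.corpus import (
    AnnotatedSentence,
    E3Dictionary,
    Sentence,
    corpus_stats,
    filter_sentences,
    find_e3_mentions,
    read_corpus_jsonl,
    read_dictionary_tsv,
    segment_article,
    split_corpus,
    tokenize,
    write_corpus_jsonl,
    write_dictionary_tsv,
)


class TestSegmentation:
    def test_two_terminal_periods_give_two_sentences(self):
        sents = segment_article("A is X. B is Y.")
        assert [s.text for s in sents] == ["A is X.", "B is Y."]

    def test_abbreviation_guard_keeps_fig_reference_together(self):
        assert len(segment_article("See Fig. 2 for details.")) == 1

    def test_et_al_does_not_break_sentence(self):
        sents = segment_article("As shown by Smith et al. Previous work agrees.")
        assert len(sents) == 1

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            segment_article("")

    def test_segmentation_recovers_text(self):
        text = "Mdm2 ubiquitylates p53. This was shown in Fig. 3! Was it conclusive? Yes."
        sents = segment_article(text)
        assert " ".join(s.text for s in sents) == text


class TestMentionFinding:
    def test_mdm2_found_at_token_rank_four(self, fixture_dictionary):
        sent = Sentence(text="These data identify Mdm2 as a novel E3 ligase for FOXOs")
        mentions = find_e3_mentions(sent, fixture_dictionary)
        assert len(mentions) == 1
        assert mentions[0].surface == "Mdm2"
        assert mentions[0].token_rank == 4

    def test_case_insensitive_match(self):
        d = E3Dictionary(entries={"MDM2_HUMAN": ("Mdm2",)})
        mentions = find_e3_mentions(Sentence(text="MDM2 is degraded"), d)
        assert len(mentions) == 1
        assert mentions[0].surface == "MDM2"
        assert mentions[0].canonical_id == "MDM2_HUMAN"

    def test_no_match_yields_empty_list(self):
        d = E3Dictionary(entries={"X": ("Zzz9",)})
        assert find_e3_mentions(Sentence(text="Nothing relevant here"), d) == []

    def test_longest_match_wins_over_nested_synonym(self):
        d = E3Dictionary(entries={"MDM2_HUMAN": ("Mdm2", "Oncoprotein Mdm2")})
        mentions = find_e3_mentions(
            Sentence(text="The Oncoprotein Mdm2 was purified"), d
        )
        assert [m.surface for m in mentions] == ["Oncoprotein Mdm2"]

    def test_word_boundary_blocks_substring_hit(self):
        d = E3Dictionary(entries={"CBL_HUMAN": ("Cbl",)})
        # "Cbl" must not fire inside an unrelated longer word.
        assert find_e3_mentions(Sentence(text="The Cblike domain folds"), d) == []

    def test_offsets_round_trip_on_synthetic_corpus(self, small_corpus):
        for item in small_corpus:
            for m in item.e3_mentions:
                assert item.text[m.char_start : m.char_end].lower() == m.surface.lower()
                assert 1 <= m.token_rank <= len(tokenize(item.text))


class TestFilter:
    def test_retains_exactly_sentences_with_mentions(self, fixture_dictionary):
        sents = [
            Sentence(text="Mdm2 ubiquitylates p53", sent_index=0),
            Sentence(text="No ligase here", sent_index=1),
            Sentence(text="Cbl-b targets Src", sent_index=2),
        ]
        kept = filter_sentences(sents, fixture_dictionary)
        assert [a.sentence.sent_index for a in kept] == [0, 2]

    def test_filter_is_idempotent(self, fixture_dictionary, small_corpus):
        once = filter_sentences([a.sentence for a in small_corpus], fixture_dictionary)
        twice = filter_sentences([a.sentence for a in once], fixture_dictionary)
        assert [a.sentence.text for a in once] == [a.sentence.text for a in twice]

    def test_no_e3_gives_empty(self):
        d = E3Dictionary(entries={"X": ("Qqq7",)})
        assert filter_sentences([Sentence(text="plain text")], d) == []


class TestSplit:
    def test_benchmark_sizes_3195_to_2236_959(self, fixture_dictionary):
        corpus = _dummy_corpus(3195)
        result = split_corpus(corpus, train_fraction=0.70, seed=0)
        assert (len(result.train), len(result.test)) == (2236, 959)

    def test_floor_split_of_ten(self):
        result = split_corpus(_dummy_corpus(10), train_fraction=0.70, seed=1)
        assert (len(result.train), len(result.test)) == (7, 3)

    def test_same_seed_same_membership(self):
        corpus = _dummy_corpus(50)
        a = split_corpus(corpus, seed=7)
        b = split_corpus(corpus, seed=7)
        assert [s.sentence.sent_index for s in a.train] == [
            s.sentence.sent_index for s in b.train
        ]

    def test_fraction_out_of_range_raises(self):
        with pytest.raises(ValueError):
            split_corpus(_dummy_corpus(10), train_fraction=1.0)

    @settings(max_examples=25, deadline=None)
    @given(
        n=st.integers(min_value=2, max_value=200),
        frac=st.floats(min_value=0.05, max_value=0.95),
        seed=st.integers(min_value=0, max_value=2**31 - 1),
    )
    def test_split_conserves_the_corpus(self, n, frac, seed):
        corpus = _dummy_corpus(n)
        result = split_corpus(corpus, train_fraction=frac, seed=seed)
        assert len(result.train) == int(np.floor(frac * n))
        assert len(result.train) + len(result.test) == n
        combined = sorted(
            s.sentence.sent_index for s in (*result.train, *result.test)
        )
        assert combined == list(range(n))


class TestStats:
    def test_benchmark_partition_totals(self):
        split = _labeled_split(739, 1497, 317, 642)
        table = corpus_stats(split)
        assert table.loc["Training", "total"] == 2236
        assert table.loc["Test", "total"] == 959
        assert table.loc["Total"].tolist() == [1056, 2139, 3195]

    def test_single_positive_sentence(self):
        table = corpus_stats(_labeled(1, 0))
        assert table.loc["Total"].tolist() == [1, 0, 1]

    def test_unlabeled_sentence_raises(self):
        item = _labeled(1, 0)[0]
        unlabeled = AnnotatedSentence(
            sentence=item.sentence, label=None, e3_mentions=item.e3_mentions
        )
        with pytest.raises(ValueError):
            corpus_stats([unlabeled])

    def test_row_sums_reconcile_on_random_split(self, small_corpus):
        result = split_corpus(small_corpus, seed=3)
        table = corpus_stats(result)
        assert (table["positive"] + table["negative"]).equals(table["total"])
        assert (table.loc["Training"] + table.loc["Test"]).equals(table.loc["Total"])


class TestIO:
    def test_corpus_jsonl_round_trip(self, small_corpus, tmp_path):
        path = tmp_path / "corpus.jsonl"
        write_corpus_jsonl(small_corpus, path)
        loaded = read_corpus_jsonl(path)
        assert loaded == list(small_corpus)

    def test_dictionary_tsv_round_trip(self, fixture_dictionary, tmp_path):
        path = tmp_path / "dict.tsv"
        write_dictionary_tsv(fixture_dictionary, path)
        loaded = read_dictionary_tsv(path)
        assert loaded.entries == fixture_dictionary.entries

    def test_empty_synonym_rejected(self):
        with pytest.raises(ValueError):
            E3Dictionary(entries={"X": ("ok", "  ")})


def _dummy_corpus(n):
    from ubisent.corpus import E3Mention

    out = []
    for i in range(n):
        sent = Sentence(text=f"Mdm2 sentence {i}", doc_id="d", sent_index=i)
        out.append(
            AnnotatedSentence(
                sentence=sent,
                label="negative",
                e3_mentions=(
                    E3Mention(
                        surface="Mdm2", canonical_id="MDM2_HUMAN",
                        char_start=0, char_end=4, token_rank=1,
                    ),
                ),
            )
        )
    return out


def _labeled(n_pos, n_neg):
    items = _dummy_corpus(n_pos + n_neg)
    out = []
    for i, item in enumerate(items):
        out.append(
            AnnotatedSentence(
                sentence=item.sentence,
                label="positive" if i < n_pos else "negative",
                e3_mentions=item.e3_mentions,
            )
        )
    return out


def _labeled_split(train_pos, train_neg, test_pos, test_neg):
    from ubisent.corpus import CorpusSplit

    return CorpusSplit(
        train=tuple(_labeled(train_pos, train_neg)),
        test=tuple(_labeled(test_pos, test_neg)),
        train_fraction=0.70,
        seed=0,
    )
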