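"""Wordlist parsing, vowel-length normalization, and domain extraction."""

import io

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import phylofl as pf
from phylofl.lexicon import LexiconError


class TestTokenize:
    @pytest.mark.parametrize(
        "raw, expected",
        [
            ("pata", ["p", "a", "t", "a"]),
            ("panta", ["p", "a", "nt", "a"]),  # longest match wins
            ("paata", ["p", "a", "a", "t", "a"]),
            ("aːta", ["aː", "t", "a"]),
        ],
    )
    def test_greedy_longest_match(self, rich_table, raw, expected):
        assert pf.tokenize(raw, rich_table) == expected

    def test_unmatchable_residue_names_position(self, rich_table):
        with pytest.raises(LexiconError, match="position 2"):
            pf.tokenize("paxta", rich_table)

    @settings(max_examples=200, derandomize=True)
    @given(st.lists(st.sampled_from(
        ["p", "t", "nt", "a", "aː", "i", "u", "w", "j", "k"]), min_size=1,
        max_size=12))
    def test_round_trip_concatenation(self, rich_table, symbols):
        """Joining the output symbols reproduces the input string."""
        raw = "".join(symbols)
        assert "".join(pf.tokenize(raw, rich_table)) == raw


class TestNormalizeVowelLength:
    @pytest.mark.parametrize(
        "segments, expected",
        [
            (["p", "a", "a", "t", "a"], ["p", "aː", "t", "a"]),
            (["p", "u", "w", "u", "t", "a"], ["p", "uː", "t", "a"]),
            (["p", "i", "j", "i", "t", "a"], ["p", "iː", "t", "a"]),
            (["p", "a", "t", "a"], ["p", "a", "t", "a"]),
            # non-identical adjacent vowels stay as hiatus
            (["p", "a", "i", "t", "a"], ["p", "a", "i", "t", "a"]),
            # long vowels are never re-matched
            (["p", "aː", "a", "t", "a"], ["p", "aː", "a", "t", "a"]),
            # /uwa/ is not a long-vowel sequence
            (["p", "u", "w", "a", "t", "a"], ["p", "u", "w", "a", "t", "a"]),
        ],
    )
    def test_rules(self, rich_table, segments, expected):
        assert pf.normalize_vowel_length(segments, rich_table) == expected

    def test_triple_checked_before_pair(self, rich_table):
        # u-w-u wins over pairing the first u with nothing
        segs = ["u", "w", "u", "u", "w", "u"]
        assert pf.normalize_vowel_length(segs, rich_table) == ["uː", "uː"]

    def test_missing_long_partner_is_configuration_error(self):
        table = pf.SegmentTable(
            [
                pf.Segment("a", "vowel", length="short"),
                pf.Segment("t", "consonant", place="apical", manner="stop"),
            ]
        )
        with pytest.raises(LexiconError, match="partner"):
            pf.normalize_vowel_length(["a", "a", "t"], table)

    @settings(max_examples=200, derandomize=True)
    @given(st.lists(st.sampled_from(
        ["p", "t", "a", "aː", "i", "u", "w", "j"]), min_size=1, max_size=10))
    def test_idempotent(self, rich_table, segments):
        once = pf.normalize_vowel_length(segments, rich_table)
        assert pf.normalize_vowel_length(once, rich_table) == once


class TestExtractDomain:
    def _inst(self, segs, table):
        return pf.extract_domain(pf.Wordform("L", tuple(segs)), table)

    def test_canonical_cvcv(self, rich_table):
        inst = self._inst(["p", "a", "t", "a"], rich_table)
        assert (inst.vowel, inst.vowel_length, inst.consonant) == (
            "a", "short", "t")
        assert inst.place == "apical" and inst.manner == "stop"

    def test_long_vowel_domain(self, rich_table):
        inst = self._inst(["p", "aː", "t", "a"], rich_table)
        assert (inst.vowel, inst.vowel_length) == ("aː", "long")

    @pytest.mark.parametrize(
        "segs",
        [
            ["p", "a", "w", "t", "a"],  # cluster after tonic vowel
            ["p", "a", "t"],  # word-final consonant
            ["p", "a"],  # nothing after tonic vowel
            ["p", "a", "i", "t", "a"],  # vowel hiatus
            ["p", "t", "p"],  # no vowel at all
        ],
    )
    def test_no_instance(self, rich_table, segs):
        assert self._inst(segs, rich_table) is None

    def test_vowel_initial_word_allowed(self, rich_table):
        inst = self._inst(["a", "t", "a"], rich_table)
        assert inst.vowel == "a" and inst.consonant == "t"

    def test_insensitive_to_outer_material(self, rich_table):
        base = self._inst(["p", "a", "t", "a"], rich_table)
        longer = self._inst(["p", "a", "t", "a", "nt", "i", "k", "u"],
                            rich_table)
        assert base == longer


class TestProfile:
    def test_counts_and_multiset_semantics(self, rich_table):
        words = [("p", "a", "t", "a"), ("p", "a", "a", "t", "a"),
                 ("p", "a", "d", "a"), ("p", "a", "t", "a")]
        lex = pf.Lexicon("L", [pf.Wordform("L", w) for w in words])
        prof = pf.profile(lex, rich_table)
        assert prof.counts == {("a", "t"): 2, ("aː", "t"): 1, ("a", "d"): 1}
        assert prof.n_instances == 4

    def test_profile_applies_normalization(self, rich_table):
        lex = pf.Lexicon("L", [pf.Wordform("L", ("p", "u", "w", "u", "t",
                                                 "a"))])
        prof = pf.profile(lex, rich_table)
        assert prof.counts == {("uː", "t"): 1}

    def test_monosyllabic_cvc_words_give_empty_profile(self, rich_table):
        lex = pf.Lexicon("L", [pf.Wordform("L", ("p", "a", "t"))])
        assert pf.profile(lex, rich_table).n_instances == 0

    def test_at_most_one_instance_per_word(self, rich_table):
        lex = pf.Lexicon("L", [pf.Wordform("L", ("p", "a", "t", "a", "k",
                                                 "a"))])
        assert pf.profile(lex, rich_table).n_instances == 1


class TestFilterLanguages:
    def _profile(self, lang, counts):
        return pf.DomainProfile(lang, dict(counts))

    def test_threshold_is_strict(self, rich_table):
        tables = {"at200": rich_table, "at201": rich_table}
        p200 = self._profile("at200", {("a", "t"): 100, ("aː", "t"): 100})
        p201 = self._profile("at201", {("a", "t"): 100, ("aː", "t"): 101})
        assert pf.filter_languages([p200, p201], tables) == ["at201"]

    def test_length_contrast_must_be_attested(self, rich_table):
        tables = {"nolong": rich_table}
        p = self._profile("nolong", {("a", "t"): 5000, ("i", "t"): 10})
        assert pf.filter_languages([p], tables) == []

    def test_any_pair_suffices(self, rich_table):
        tables = {"ok": rich_table}
        p = self._profile("ok", {("i", "t"): 150, ("iː", "t"): 60})
        assert pf.filter_languages([p], tables) == ["ok"]


class TestIO:
    def test_segment_table_round_trip(self, tmp_path, rich_table):
        path = tmp_path / "segments.csv"
        pf.lexicon.write_segment_table(rich_table, path)
        back = pf.read_segment_table(path)
        assert set(back.symbols) == set(rich_table.symbols)
        assert back["aː"].length_partner == "a"
        assert back["t"].manner == "stop"

    def test_read_lexicons_segmented_and_contiguous(self, rich_table):
        tables = {"L1": rich_table}
        seg = io.StringIO("# comment\nL1\tp a t a\nL1\tp aː t a\n")
        lex = pf.read_lexicons(seg, tables, segmented=True)["L1"]
        assert [w.segments for w in lex.words] == [
            ("p", "a", "t", "a"), ("p", "aː", "t", "a")]
        raw = io.StringIO("L1\tpanta\n")
        lex2 = pf.read_lexicons(raw, tables, segmented=False)["L1"]
        assert lex2.words[0].segments == ("p", "a", "nt", "a")

    def test_unknown_segment_is_an_error(self, rich_table):
        bad = io.StringIO("L1\tp a x a\n")
        with pytest.raises(LexiconError, match="'x'"):
            pf.read_lexicons(bad, {"L1": rich_table})

    def test_profile_export(self, tmp_path, rich_table):
        prof = pf.DomainProfile("L1", {("a", "t"): 2, ("aː", "d"): 1})
        out = tmp_path / "profiles.csv"
        pf.lexicon.write_profiles([prof], out)
        text = out.read_text()
        assert "language_id,vowel,consonant,count" in text
        assert "L1,a,t,2" in text


def test_segment_table_invariants_enforced():
    with pytest.raises(LexiconError):  # asymmetric partnership
        pf.SegmentTable(
            [
                pf.Segment("a", "vowel", length="short", length_partner="aː"),
                pf.Segment("aː", "vowel", length="long", length_partner="a"),
                pf.Segment("i", "vowel", length="short", length_partner="aː"),
            ]
        )
    with pytest.raises(LexiconError):  # consonant without manner
        pf.SegmentTable([pf.Segment("t", "consonant", place="apical")])
    with pytest.raises(LexiconError):  # duplicate symbol
        pf.SegmentTable(
            [
                pf.Segment("a", "vowel"),
                pf.Segment("a", "vowel"),
            ]
        )
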