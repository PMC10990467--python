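from __future__ import annotations

import csv

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from verbagg.lexicon import (
    ALL_CATEGORIES,
    EXPLICIT_CATEGORIES,
    OTHER,
    FlagCounts,
    Lexicon,
    LexiconError,
    Pattern,
    TokenFrequencyTable,
    UtteranceRecord,
    build_frequency_table,
    default_lexicon,
    flag_records,
    flag_utterance,
    load_lexicon,
    save_lexicon,
    tabulate_flag_counts,
    tokenize,
)


def rec(text, pid="p1"):
    return UtteranceRecord(pid, text)


class TestTokenize:
    def test_punctuation_and_case(self):
        assert tokenize("Useless! Useless!") == ["useless", "useless"]

    def test_empty(self):
        assert tokenize("") == []

    def test_lemma_lookup(self):
        # oracle: split first, then a direct table lookup per token
        lemma_map = {"killed": "kill"}
        raw = tokenize("killed")
        assert [lemma_map.get(t, t) for t in raw] == ["kill"]
        assert tokenize("killed", lemma_map) == ["kill"]

    def test_nfkc_normalization(self):
        # full-width input folds to ASCII before splitting
        assert tokenize("ＵＳＥＬＥＳＳ") == ["useless"]


class TestLexiconValidation:
    def test_missing_category(self):
        with pytest.raises(LexiconError, match="life_threat"):
            Lexicon(patterns={
                "job_performance": [Pattern("x")],
                "personality_looks": [Pattern("y")],
            })

    def test_other_must_not_carry_patterns(self):
        lx = default_lexicon()
        with pytest.raises(LexiconError, match="residual"):
            Lexicon(patterns={**lx.patterns, OTHER: [Pattern("z")]})

    def test_bad_regex_names_category_and_pattern(self):
        patterns = {c: [Pattern("x")] for c in EXPLICIT_CATEGORIES}
        patterns["life_threat"] = [Pattern("(unclosed", "regex")]
        with pytest.raises(LexiconError, match=r"\(unclosed.*life_threat"):
            Lexicon(patterns=patterns)

    def test_empty_pattern_rejected(self):
        with pytest.raises(LexiconError):
            Pattern("")

    def test_non_idempotent_lemma_map_rejected(self):
        patterns = {c: [Pattern("x")] for c in EXPLICIT_CATEGORIES}
        with pytest.raises(LexiconError, match="idempotent"):
            Lexicon(patterns=patterns, lemma_map={"a": "b", "b": "c"})

    def test_default_lemma_map_is_idempotent(self, lexicon):
        m = lexicon.lemma_map
        for surface in m:
            assert m.get(m[surface], m[surface]) == m[surface]


class TestFlagUtterance:
    def test_useless_is_job_performance(self, lexicon):
        flags = flag_utterance(rec("Useless!"), lexicon)
        assert flags.flags == {
            "job_performance": True, "personality_looks": False,
            "life_threat": False, OTHER: False,
        }
        assert flags.matched_patterns["job_performance"] == ["useless"]

    def test_please_die_is_life_threat(self, lexicon):
        assert flag_utterance(rec("Please die."), lexicon).flags["life_threat"]

    def test_configured_pattern_fires(self, lexicon):
        extended = Lexicon(
            patterns={
                **lexicon.patterns,
                "personality_looks": lexicon.patterns["personality_looks"] + [Pattern("fatty")],
            },
            lemma_map=lexicon.lemma_map,
        )
        flags = flag_utterance(rec("Lose weight, fatty!"), extended)
        assert flags.flags["personality_looks"]

    def test_residual_other(self, lexicon):
        flags = flag_utterance(rec("You're so slow today"), lexicon)
        assert flags.flags == {
            "job_performance": False, "personality_looks": False,
            "life_threat": False, OTHER: True,
        }
        assert flags.matched_patterns[OTHER] == []

    def test_multiword_pattern_spans_tokens(self, lexicon):
        assert flag_utterance(rec("What a poor memory you have"), lexicon).flags[
            "job_performance"
        ]

    def test_multi_flag(self, lexicon):
        flags = flag_utterance(rec("You idiot. Hey, I'll kill you."), lexicon)
        assert flags.flags["job_performance"] and flags.flags["life_threat"]
        assert not flags.flags[OTHER]

    def test_case_insensitive(self, lexicon):
        assert flag_utterance(rec("USELESS"), lexicon).flags["job_performance"]

    def test_regex_pattern(self, lexicon):
        lx = Lexicon(
            patterns={
                **lexicon.patterns,
                "life_threat": [Pattern(r"\bdies?\b", "regex")],
            }
        )
        assert flag_utterance(rec("He dies"), lx).flags["life_threat"]
        assert not flag_utterance(rec("diesel engine"), lx).flags["life_threat"]

    @given(st.text(max_size=80))
    @settings(max_examples=200, deadline=None)
    def test_residual_completeness(self, text):
        flags = flag_utterance(UtteranceRecord("p", text), default_lexicon())
        explicit = any(flags.flags[c] for c in EXPLICIT_CATEGORIES)
        assert flags.flags[OTHER] == (not explicit)
        for cat in EXPLICIT_CATEGORIES:
            assert flags.flags[cat] == bool(flags.matched_patterns[cat])

    @given(st.text(max_size=60), st.sampled_from(EXPLICIT_CATEGORIES),
           st.text(min_size=1, max_size=10))
    @settings(max_examples=100, deadline=None)
    def test_adding_pattern_is_monotone(self, text, category, new_pattern):
        base = default_lexicon()
        grown = Lexicon(
            patterns={
                cat: pats + ([Pattern(new_pattern)] if cat == category else [])
                for cat, pats in base.patterns.items()
            },
            lemma_map=base.lemma_map,
        )
        record = UtteranceRecord("p", text)
        before = flag_utterance(record, base).flags[category]
        after = flag_utterance(record, grown).flags[category]
        assert after or not before


class TestPersonLevelUnion:
    def test_union_recomputes_other(self, lexicon):
        records = [rec("nothing aggressive", "p1"), rec("useless", "p1")]
        flags = flag_records(records, lexicon)["p1"]
        assert flags.flags["job_performance"]
        assert not flags.flags[OTHER]

    def test_union_of_matches(self, lexicon):
        records = [rec("useless", "p1"), rec("please die", "p1")]
        flags = flag_records(records, lexicon)["p1"]
        assert flags.flags["job_performance"] and flags.flags["life_threat"]


class TestFrequencyTable:
    def test_counting(self, lexicon):
        records = [rec("die die", "p1"), rec("die", "p2")]
        table = build_frequency_table(records, "life_threat", lexicon, min_frequency=2)
        assert dict(table.entries) == {"die": 3}

    def test_min_frequency_filters_singletons(self, lexicon):
        table = build_frequency_table([rec("kill")], "life_threat", lexicon,
                                      min_frequency=2)
        assert table.entries == []
        assert table.counts  # raw counts survive

    def test_unknown_category(self, lexicon):
        with pytest.raises(ValueError, match="unknown category"):
            build_frequency_table([], "insults", lexicon)

    def test_brute_force_recount(self, lexicon):
        phrases = [
            "useless idiot", "quit now", "so useless", "resign resign",
            "poor memory again", "idiot idiot idiot", "useless!", "quit",
            "you should resign", "what an idiot",
        ]
        records = [rec(p, f"p{i}") for i, p in enumerate(phrases)]
        # independent oracle: hand tokenization + Counter over flagged records
        from collections import Counter
        expect = Counter()
        for p in phrases:  # all match job_performance by construction
            expect.update(tokenize(p, lexicon.lemma_map))
        table = build_frequency_table(records, "job_performance", lexicon,
                                      min_frequency=1)
        assert table.counts == dict(expect)
        assert table.total_tokens == sum(expect.values())

    def test_ordering_descending_then_lexicographic(self):
        table = TokenFrequencyTable({"b": 2, "a": 2, "c": 5}, min_frequency=1)
        assert table.entries == [("c", 5), ("a", 2), ("b", 2)]

    @given(st.lists(st.sampled_from(["die", "kill", "useless", "quit", "x"]),
                    max_size=30))
    @settings(max_examples=100, deadline=None)
    def test_frequency_conservation(self, words):
        lexicon = default_lexicon()
        records = [UtteranceRecord(f"p{i}", w) for i, w in enumerate(words)]
        table = build_frequency_table(records, "life_threat", lexicon,
                                      min_frequency=1)
        expected_total = sum(
            len(tokenize(r.text, lexicon.lemma_map))
            for r in records
            if flag_utterance(r, lexicon).flags["life_threat"]
        )
        assert table.total_tokens == expected_total


class TestTabulateFlagCounts:
    def _flags(self, pid, cats):
        from verbagg.lexicon import UtteranceFlags
        flags = {c: c in cats for c in EXPLICIT_CATEGORIES}
        flags[OTHER] = not any(flags.values())
        return UtteranceFlags(pid, flags, {c: [] for c in ALL_CATEGORIES})

    def test_enumeration(self):
        flags = [
            self._flags("p1", {"job_performance"}),
            self._flags("p2", {"job_performance", "personality_looks"}),
            self._flags("p3", set()),
        ]
        counts = tabulate_flag_counts(flags)
        assert counts == FlagCounts(
            overall=3,
            by_category={"job_performance": 2, "personality_looks": 1,
                         "life_threat": 0, OTHER: 1},
        )

    def test_duplicate_participant_rejected(self):
        flags = [self._flags("p1", set()), self._flags("p1", set())]
        with pytest.raises(ValueError, match="duplicate"):
            tabulate_flag_counts(flags)

    def test_category_sum_can_exceed_overall(self):
        # multi-label structure: 37 + 21 + 9 + 72 = 139 over 108 participants
        assert 37 + 21 + 9 + 72 >= 108


class TestLexiconIO:
    def test_yaml_round_trip(self, lexicon, tmp_path):
        path = tmp_path / "lex.yaml"
        save_lexicon(lexicon, path)
        loaded = load_lexicon(path)
        assert loaded.patterns == lexicon.patterns

    def test_tsv_load(self, tmp_path):
        path = tmp_path / "lex.tsv"
        rows = [("category", "pattern", "pattern_type"),
                ("job_performance", "useless", "literal"),
                ("personality_looks", "ugly", "literal"),
                ("life_threat", r"kill(ed|ing)?", "regex")]
        with open(path, "w", newline="") as fh:
            csv.writer(fh, delimiter="\t").writerows(rows)
        lx = load_lexicon(path)
        assert flag_utterance(rec("killing spree"), lx).flags["life_threat"]

    def test_lemma_map_tsv(self, tmp_path):
        path = tmp_path / "lemmas.tsv"
        path.write_text("surface\tlemma\nkilled\tkill\n", encoding="utf-8")
        from verbagg.lexicon import load_lemma_map
        assert load_lemma_map(path) == {"killed": "kill"}
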