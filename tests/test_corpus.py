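"""Corpus I/O, diagnosis-statement detection, review flags, cohort filters."""

import dataclasses
import json
import re

import pytest

from gadprofiler.corpus import (
    Cohort, DIAGNOSIS_PATTERN, Group, HASHTAG_RE, MENTION_RE,
    anonymize_cohort, apply_cohort_filters, detect_diagnosis_candidates,
    flag_for_review, read_corpus, remove_group_overlap, write_corpus,
    write_review_worksheet,
)

from conftest import make_tweet, make_user


class TestIO:
    def test_round_trip_identity(self, two_user_cohort, tmp_path):
        write_corpus(two_user_cohort, tmp_path / "c")
        back = read_corpus(tmp_path / "c")
        assert sorted(back.user_ids()) == sorted(two_user_cohort.user_ids())
        for uc in two_user_cohort.users:
            other = back.get(uc.user.user_id)
            assert dataclasses.asdict(other.user) == dataclasses.asdict(uc.user)
            assert [dataclasses.asdict(t) for t in other.tweets] == \
                   [dataclasses.asdict(t) for t in uc.tweets]

    def test_write_is_bit_stable(self, two_user_cohort, tmp_path):
        write_corpus(two_user_cohort, tmp_path / "a")
        write_corpus(two_user_cohort, tmp_path / "b")
        assert (tmp_path / "a/tweets.jsonl").read_bytes() == \
               (tmp_path / "b/tweets.jsonl").read_bytes()
        assert (tmp_path / "a/users.jsonl").read_bytes() == \
               (tmp_path / "b/users.jsonl").read_bytes()

    def test_tweets_sorted_ascending_with_id_tiebreak(self):
        t0 = make_tweet("u", 5, hours=2.0)
        t1 = make_tweet("u", 3, hours=1.0)
        t2 = make_tweet("u", 1, hours=2.0)  # same time as t0, smaller id
        from gadprofiler.corpus import UserCorpus, UserRecord
        corpus = UserCorpus(UserRecord(user_id="u"), [t0, t1, t2])
        assert [t.tweet_id for t in corpus.tweets] == \
               ["u-0003", "u-0001", "u-0005"]

    def test_malformed_line_recorded_not_dropped_silently(self, two_user_cohort, tmp_path):
        write_corpus(two_user_cohort, tmp_path / "c")
        path = tmp_path / "c/tweets.jsonl"
        lines = path.read_text().splitlines()
        lines.insert(3, "{not valid json")
        path.write_text("\n".join(lines) + "\n")
        back = read_corpus(tmp_path / "c")
        assert back.n_tweets() == two_user_cohort.n_tweets()  # others intact
        assert len(back.errors) == 1
        assert back.errors[0].line_no == 4

    def test_empty_cohort_round_trips(self, tmp_path):
        write_corpus(Cohort([]), tmp_path / "e")
        back = read_corpus(tmp_path / "e")
        assert len(back) == 0 and not back.errors

    def test_missing_file_fatal(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_corpus(tmp_path / "nope")

    def test_anonymization_is_stable_and_consistent(self, two_user_cohort):
        a = anonymize_cohort(two_user_cohort, salt="s1")
        b = anonymize_cohort(two_user_cohort, salt="s1")
        c = anonymize_cohort(two_user_cohort, salt="s2")
        assert a.user_ids() == b.user_ids() != c.user_ids()
        assert "alice" not in a.user_ids()
        for uc in a.users:  # tweets follow their user pseudonym
            assert all(t.user_id == uc.user.user_id for t in uc.tweets)


class TestDiagnosisDetection:
    def test_reported_statement_matches(self):
        t = make_tweet("u", 0,
                       "i was diagnosed with generalized anxiety disorder (gad) in 2019")
        (cand,) = detect_diagnosis_candidates([t])
        assert "diagnosed with generalized anxiety disorder (gad)" in cand.span_text

    def test_non_statement_does_not_match(self):
        t = make_tweet("u", 0, "generalized anxiety is awful")
        assert detect_diagnosis_candidates([t]) == []

    def test_parenthetical_abbreviation_optional(self):
        t = make_tweet("u", 0,
                       "I was diagnosed with generalized anxiety disorder last year")
        assert len(detect_diagnosis_candidates([t])) == 1

    def test_invalid_pattern_fatal(self):
        with pytest.raises(ValueError, match="invalid"):
            detect_diagnosis_candidates([], pattern="(unclosed")

    def test_equals_brute_force_scan(self):
        texts = [
            "I was diagnosed with Generalized Anxiety Disorder (GAD)",
            "i was  diagnosed with generalized anxiety disorder",
            "she said anxiety disorder",
            "diagnosed with gad",
            "I WAS DIAGNOSED WITH GENERALIZED ANXIETY DISORDER ( GAD )",
        ]
        tweets = [make_tweet("u", i, t) for i, t in enumerate(texts)]
        got = {c.tweet.tweet_id for c in detect_diagnosis_candidates(tweets)}
        expected = {t.tweet_id for t in tweets if DIAGNOSIS_PATTERN.search(t.text)}
        assert got == expected
        assert len(got) == 3


class TestReviewFlags:
    def _candidate(self, text):
        t = make_tweet("u", 0, text)
        m = re.search(r"i was (?:never )?diagnosed with generalized anxiety disorder",
                      text, re.IGNORECASE)
        from gadprofiler.corpus import DiagnosisCandidate
        return DiagnosisCandidate(t, m.start(), m.end())

    def test_plain_first_person_is_auto_ok(self):
        fl = flag_for_review(self._candidate(
            "i was diagnosed with generalized anxiety disorder in march"))
        assert fl.status == "auto_ok" and fl.reasons == []

    def test_quoted_reported_speech_collects_reasons(self):
        fl = flag_for_review(self._candidate(
            '"I was diagnosed with generalized anxiety disorder," she said'))
        assert fl.status == "needs_review"
        assert {"quotation", "reported-speech", "third-person"} <= set(fl.reasons)

    def test_negation_flagged(self):
        fl = flag_for_review(self._candidate(
            "I was never diagnosed with generalized anxiety disorder"))
        assert fl.status == "needs_review" and "negation" in fl.reasons

    def test_worksheet_columns(self, tmp_path):
        fl = flag_for_review(self._candidate(
            "i was diagnosed with generalized anxiety disorder"))
        write_review_worksheet([fl], tmp_path / "w.tsv")
        header, row = (tmp_path / "w.tsv").read_text().splitlines()
        assert header.split("\t") == \
            ["tweet_id", "user_id", "matched_span", "status", "reasons"]
        assert row.startswith("u-0000\tu\t")


def _user_langs(uid, langs, n_extra_en=0):
    texts = [f"tweet {i}" for i in range(len(langs) + n_extra_en)]
    kwargs = [{"language": l} for l in langs] + [{"language": "en"}] * n_extra_en
    return make_user(uid, texts, tweet_kwargs=kwargs)


class TestCohortFilters:
    def test_low_english_fraction_excluded(self):
        # 150/200 = 75% English -> rule 1
        u = _user_langs("u", ["es"] * 50, n_extra_en=150)
        out = apply_cohort_filters(Cohort([u]))
        assert len(out) == 0
        assert out.provenance[0].rule == "english_fraction"

    def test_surviving_user_loses_non_english_tweets(self):
        # 110/120 = 91.7% English -> kept with the 110 English tweets
        u = _user_langs("u", ["es"] * 10, n_extra_en=110)
        out = apply_cohort_filters(Cohort([u]))
        assert len(out) == 1
        assert len(out.users[0].tweets) == 110
        assert all(t.language == "en" for t in out.users[0].tweets)

    def test_short_history_excluded_after_language_pass(self):
        u = _user_langs("u", ["en"] * 99)
        out = apply_cohort_filters(Cohort([u]))
        assert len(out) == 0
        assert out.provenance[0].rule == "min_tweets"

    def test_idempotent(self):
        users = [_user_langs("a", ["en"] * 120),
                 _user_langs("b", ["es"] * 30, n_extra_en=100)]
        once = apply_cohort_filters(Cohort(users))
        twice = apply_cohort_filters(once)
        assert once.user_ids() == twice.user_ids()
        assert once.n_tweets() == twice.n_tweets()

    def test_conservation_every_user_accounted_for(self):
        users = [_user_langs(f"u{i}", ["en"] * (90 + 5 * i)) for i in range(6)]
        cohort = Cohort(users)
        out = apply_cohort_filters(cohort)
        assert len(out) + len(out.provenance) == len(cohort)

    def test_missing_language_needs_classifier(self):
        u = make_user("u", ["hola"], tweet_kwargs=[{"language": None}])
        with pytest.raises(ValueError, match="classifier"):
            apply_cohort_filters(Cohort([u]))
        out = apply_cohort_filters(Cohort([u]), min_tweets=1,
                                   language_classifier=lambda s: "en")
        assert len(out) == 1


class TestGroupOverlap:
    def test_overlap_removed_from_control_only(self):
        gad = Cohort([make_user("x", 2), make_user("y", 2)], group=Group.GAD)
        ctl = Cohort([make_user("x", 2), make_user("z", 2)], group=Group.CONTROL)
        g2, c2 = remove_group_overlap(gad, ctl)
        assert g2.user_ids() == ["x", "y"]
        assert c2.user_ids() == ["z"]
        assert c2.provenance[0].rule == "group_overlap"

    def test_disjoint_unchanged(self):
        gad = Cohort([make_user("x", 2)])
        ctl = Cohort([make_user("z", 2)])
        g2, c2 = remove_group_overlap(gad, ctl)
        assert g2.user_ids() == ["x"] and c2.user_ids() == ["z"]

    def test_control_fully_contained_becomes_empty(self):
        gad = Cohort([make_user("x", 2), make_user("z", 2)])
        ctl = Cohort([make_user("x", 2), make_user("z", 2)])
        _, c2 = remove_group_overlap(gad, ctl)
        assert len(c2) == 0


class TestExtraction:
    def test_mention_and_hashtag_regexes(self):
        text = "RT @Alice_1: see #MentalHealth and #worry2 with @bob"
        assert MENTION_RE.findall(text) == ["@Alice_1", "@bob"]
        assert HASHTAG_RE.findall(text) == ["#MentalHealth", "#worry2"]
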