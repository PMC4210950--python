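"""Canonicalisation, retweet classification and URL-variant cluster detection."""

import random
from collections import Counter

import pytest
from hypothesis import given, settings, strategies as st

from astroturf_scan.corpus_io import UrlMap
from astroturf_scan.retweet_resolution import (
    canonicalize_text,
    detect_url_variant_clusters,
    resolve_retweets,
)
from astroturf_scan.synthetic_data import evaluate_attribution

from conftest import make_tweet


class TestCanonicalize:
    @settings(max_examples=200, derandomize=True)
    @given(st.text(max_size=300))
    def test_idempotent(self, text):
        once = canonicalize_text(text)
        assert canonicalize_text(once) == once

    def test_rt_prefix_and_url_masked(self):
        a = canonicalize_text("RT @E: hello http://bit.ly/a")
        b = canonicalize_text("hello http://t.co/zz9")
        assert a == b == "hello <url>"

    def test_stacked_prefixes_and_case(self):
        assert canonicalize_text("rt @A: RT @b:  Hello   WORLD") == "hello world"
        assert canonicalize_text("MT @x: Hello world") == "hello world"

    def test_trailing_ellipsis_stripped(self):
        assert canonicalize_text("hello world…") == "hello world"
        assert canonicalize_text("hello world...") == "hello world"

    def test_truncated_url_variants_collapse(self):
        """Copies clipped at different points inside the trailing URL all land
        in one group: cuts keeping a scheme mask to <url>, a cut losing the
        scheme drops the clipped tail and is joined by the prefix merge."""
        full = "RT @e: new paper shows no danger from second hand vape http://t.co/abc123"
        variants = {canonicalize_text(full)}
        for cut in range(len(full) - 15, len(full)):
            variants.add(canonicalize_text(full[:cut] + "…"))
        assert variants <= {
            "new paper shows no danger from second hand vape <url>",
            "new paper shows no danger from second hand vape",
        }
        src_text = "new paper shows no danger from second hand vape http://t.co/abc123"
        corpus = [make_tweet("t00", src_text, author="e")] + [
            make_tweet(f"t{i + 1:02d}", full[: len(full) - 15 + i] + "…",
                       author=f"u{i}", offset_s=i + 1)
            for i in range(15)
        ]
        res = resolve_retweets(corpus)
        assert all(
            r.status == "nonnative_rt" and r.source_author == "e"
            for r in res
            if r.tweet_id != "t00"
        )


class TestResolve:
    def test_distinct_texts_are_originals(self):
        corpus = [make_tweet(f"t{i}", f"unique message {i}", offset_s=i) for i in range(3)]
        res = resolve_retweets(corpus)
        assert all(r.status == "original" for r in res)
        assert all(r.source_author == corpus[i].author for i, r in enumerate(res))

    def test_53_copies_attributed_to_source(self):
        src = make_tweet("t000", "big news @agency #tag http://t.co/orig", author="hub")
        copies = [
            make_tweet(f"t{i:03d}", f"big news @agency #tag http://t.co/v{i}",
                       author=f"user{i}", offset_s=i)
            for i in range(1, 54)
        ]
        res = resolve_retweets([src] + copies)
        counts = Counter(r.status for r in res)
        assert counts == {"original": 1, "nonnative_rt": 53}
        for r in res:
            if r.status == "nonnative_rt":
                assert r.source_author == "hub" and r.source_tweet_id == "t000"

    def test_equal_timestamps_tie_broken_by_id(self):
        a = make_tweet("t2", "same words", author="later")
        b = make_tweet("t1", "same words", author="earlier")
        res = {r.tweet_id: r for r in resolve_retweets([a, b])}
        assert res["t1"].status == "original"
        assert res["t2"].status == "nonnative_rt"
        assert res["t2"].source_author == "earlier"

    def test_native_metadata_wins(self):
        src = make_tweet("t1", "original words", author="alice")
        rt = make_tweet("t2", "RT @alice: original words", author="bob",
                        offset_s=10, native=("t1", "alice"))
        res = {r.tweet_id: r for r in resolve_retweets([src, rt])}
        assert res["t2"].status == "native_rt"
        assert res["t2"].source_author == "alice"
        assert res["t2"].source_tweet_id == "t1"

    def test_native_unknown_handle_kept(self, caplog):
        rt = make_tweet("t1", "RT @ghost: spooky", author="bob", native=(None, "ghost"))
        with caplog.at_level("WARNING"):
            res = resolve_retweets([rt])
        assert res[0].status == "native_rt" and res[0].source_author == "ghost"

    def test_truncated_copy_merged_by_prefix(self):
        full = "electronic cigs contain a dangerous addictive drug and should be regulated"
        src = make_tweet("t1", full, author="agency")
        clipped = make_tweet("t2", "RT @agency: " + full[:-6] + "…", author="fan", offset_s=5)
        res = {r.tweet_id: r for r in resolve_retweets([src, clipped])}
        assert res["t2"].status == "nonnative_rt"
        assert res["t2"].source_author == "agency"

    def test_partition_property(self, default_dataset):
        res = resolve_retweets(default_dataset.tweets)
        assert len(res) == len(default_dataset.tweets)
        counts = Counter(r.status for r in res)
        assert sum(counts.values()) == len(default_dataset.tweets)
        assert set(counts) <= {"original", "native_rt", "nonnative_rt"}

    def test_source_never_later_than_retweet(self, default_dataset):
        by_id = {t.tweet_id: t for t in default_dataset.tweets}
        for r in resolve_retweets(default_dataset.tweets):
            if r.status == "nonnative_rt":
                assert by_id[r.source_tweet_id].timestamp <= by_id[r.tweet_id].timestamp

    def test_resolution_invariant_under_shuffle(self, default_dataset):
        corpus = list(default_dataset.tweets)
        base = {r.tweet_id: (r.status, r.source_author) for r in resolve_retweets(corpus)}
        rng = random.Random(0)
        for _ in range(3):
            rng.shuffle(corpus)
            shuffled = {
                r.tweet_id: (r.status, r.source_author) for r in resolve_retweets(corpus)
            }
            assert shuffled == base

    def test_ground_truth_attribution(self, default_dataset):
        res = resolve_retweets(default_dataset.tweets)
        assert evaluate_attribution(res, default_dataset.truth) == 1.0


class TestClusters:
    def _cluster(self, n_copies, urls, mapping):
        src = make_tweet("t00", f"read this now {urls[0]}", author="hub")
        copies = [
            make_tweet(f"t{i:02d}", f"read this now {urls[min(i, len(urls) - 1)]}",
                       author=f"u{i}", offset_s=i)
            for i in range(1, n_copies + 1)
        ]
        corpus = [src] + copies
        res = resolve_retweets(corpus)
        return detect_url_variant_clusters(corpus, res, UrlMap(mapping))

    def test_24_variants_one_destination_flagged(self):
        urls = [f"http://t.co/v{i}" for i in range(25)]
        mapping = {u: "http://journal.example/landing" for u in urls}
        clusters = self._cluster(24, urls, mapping)
        assert len(clusters) == 1
        c = clusters[0]
        assert c.n_url_variants == 25
        assert c.same_destination == "yes"
        assert c.url_variant_cluster

    def test_single_shared_url_not_flagged(self):
        urls = ["http://t.co/only"] * 6
        clusters = self._cluster(5, urls, {"http://t.co/only": "http://x.example"})
        (c,) = clusters
        assert c.n_url_variants == 1
        assert not c.url_variant_cluster

    def test_two_destinations_not_flagged(self):
        urls = ["http://t.co/a", "http://t.co/b", "http://t.co/c"]
        mapping = {"http://t.co/a": "http://one.example",
                   "http://t.co/b": "http://two.example",
                   "http://t.co/c": "http://one.example"}
        clusters = self._cluster(3, urls, mapping)
        (c,) = clusters
        assert c.same_destination == "no"
        assert not c.url_variant_cluster

    def test_unmapped_url_is_unresolved_not_no(self):
        urls = ["http://t.co/a", "http://t.co/b"]
        clusters = self._cluster(2, urls, {"http://t.co/a": "http://one.example"})
        (c,) = clusters
        assert c.same_destination == "unresolved"
        assert c.url_variant_cluster  # unresolved is not evidence of difference

    def test_membership_invariant_under_shuffle(self, default_dataset):
        corpus = list(default_dataset.tweets)
        res = resolve_retweets(corpus)
        base = {
            c.canonical_text: tuple(c.members)
            for c in detect_url_variant_clusters(corpus, res, default_dataset.urlmap)
        }
        rng = random.Random(1)
        rng.shuffle(corpus)
        res2 = resolve_retweets(corpus)
        shuffled = {
            c.canonical_text: tuple(c.members)
            for c in detect_url_variant_clusters(corpus, res2, default_dataset.urlmap)
        }
        assert shuffled == base
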