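"""Content tables, timelines and the sentiment × location chi-square."""

from datetime import date, datetime, timezone
from zoneinfo import ZoneInfo

import numpy as np
import pandas as pd
import pytest

from astroturf_scan.retweet_resolution import resolve_retweets
from astroturf_scan.tabulation_stats import (
    chi_square_location,
    contingency_test,
    hashtag_counts,
    round_pct,
    sentiment_summary,
    theme_table,
    timeline,
)

from conftest import make_tweet, make_user


def textbook_chi_square(obs: np.ndarray):
    """Independent textbook implementation: expected = row*col/N, sum of
    (O-E)^2/E, df = (r-1)(c-1)."""
    obs = np.asarray(obs, dtype=float)
    n = obs.sum()
    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / n
    chi2 = ((obs - expected) ** 2 / expected).sum()
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    return chi2, df, expected


class TestSentimentSummary:
    def test_reference_shares(self):
        corpus = (
            [make_tweet(f"a{i}", "x", sentiment="anti") for i in range(609)]
            + [make_tweet(f"p{i}", "x", sentiment="pro") for i in range(51)]
            + [make_tweet(f"u{i}", "x", sentiment="unclear") for i in range(23)]
        )
        out = sentiment_summary(corpus)
        assert out["anti"] == {"n": 609, "pct": 89.2}
        assert out["pro"] == {"n": 51, "pct": 7.5}
        assert out["unclear"] == {"n": 23, "pct": 3.4}

    def test_single_pro(self):
        out = sentiment_summary([make_tweet("t", "x", sentiment="pro")])
        assert out["pro"] == {"n": 1, "pct": 100.0}

    def test_unlabeled_corpus_warns(self, caplog):
        with caplog.at_level("WARNING"):
            out = sentiment_summary([make_tweet("t", "x")])
        assert out["pro"]["pct"] == 0.0
        assert out["unlabeled"]["n"] == 1


def test_round_pct_half_up():
    assert round_pct(7.45) == 7.5
    assert round_pct(7.44) == 7.4
    assert round_pct(89.165) == 89.2


class TestThemeTable:
    def test_original_plus_retweets_cell(self):
        src = make_tweet("t1", "msg one", author="a", sentiment="anti", themes={"safety"})
        copies = [
            make_tweet(f"c{i}", "msg one", author=f"b{i}", offset_s=i + 1,
                       sentiment="anti", themes={"safety"})
            for i in range(3)
        ]
        corpus = [src] + copies
        table = theme_table(corpus, resolve_retweets(corpus))
        cell = table.loc[("safety", "anti")]
        assert (cell["n_all"], cell["n_tweets"], cell["n_retweets"]) == (4, 1, 3)
        assert cell["retweet_fraction"] == 75.0

    def test_multi_theme_counts_each_row_once(self):
        t = make_tweet("t1", "x", sentiment="anti", themes={"safety", "science"})
        table = theme_table([t], resolve_retweets([t]))
        assert table.loc[("safety", "anti"), "n_all"] == 1
        assert table.loc[("science", "anti"), "n_all"] == 1
        assert table["n_all"].sum() == 2

    def test_empty_corpus_all_zero(self):
        table = theme_table([], [])
        assert (table[["n_all", "n_tweets", "n_retweets"]] == 0).all().all()

    def test_unknown_theme_label_raises(self):
        t = make_tweet("t1", "x", sentiment="anti", themes={"conspiracy"})
        with pytest.raises(ValueError, match="conspiracy"):
            theme_table([t], resolve_retweets([t]))

    def test_cell_additivity(self, default_dataset):
        res = resolve_retweets(default_dataset.tweets)
        table = theme_table(default_dataset.tweets, res)
        assert (table["n_all"] == table["n_tweets"] + table["n_retweets"]).all()


class TestChiSquare:
    def test_observed_equals_expected(self):
        obs = pd.DataFrame([[10, 20], [20, 40]])
        r = contingency_test(obs)
        assert r.chi2 == pytest.approx(0.0, abs=1e-12)
        assert (r.pearson_residuals.abs() < 1e-9).all().all()

    def test_hand_checked_2x2(self):
        r = contingency_test(pd.DataFrame([[10, 20], [20, 10]]))
        assert r.chi2 == pytest.approx(20 / 3, abs=1e-9)
        assert r.df == 1
        assert np.allclose(np.abs(r.adjusted_residuals.to_numpy()), np.sqrt(20 / 3))
        assert r.adjusted_residuals.iloc[0, 0] == pytest.approx(-2.5819889, abs=1e-6)

    def test_agrees_with_textbook_on_random_tables(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            shape = (int(rng.integers(2, 5)), int(rng.integers(2, 6)))
            obs = rng.integers(1, 60, size=shape)
            chi2, df, expected = textbook_chi_square(obs)
            r = contingency_test(pd.DataFrame(obs))
            assert r.chi2 == pytest.approx(chi2, abs=1e-9)
            assert r.df == df
            np.testing.assert_allclose(r.expected.to_numpy(), expected, atol=1e-9)

    def test_residual_identity(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            obs = rng.integers(1, 40, size=(3, 4))
            r = contingency_test(pd.DataFrame(obs))
            assert (r.pearson_residuals.to_numpy() ** 2).sum() == pytest.approx(
                r.chi2, abs=1e-9
            )

    def test_zero_margin_raises(self):
        with pytest.raises(ValueError, match="margin"):
            contingency_test(pd.DataFrame([[0, 0], [5, 5]]))

    def test_drop_unclear_gives_df4_on_full_table(self, default_dataset):
        r = chi_square_location(default_dataset.tweets, default_dataset.users)
        assert r.observed.shape == (2, 5)
        assert r.df == 4
        assert r.chi2 > 0

    def test_keep_unclear_changes_df(self, default_dataset):
        r = chi_square_location(
            default_dataset.tweets, default_dataset.users, drop_unclear=False
        )
        assert r.df == 8

    def test_collapse_columns(self, default_dataset):
        collapse = {"illinois_other": "us_other", "non_us": "elsewhere",
                    "us_other": "us_other"}
        r = chi_square_location(default_dataset.tweets, default_dataset.users,
                                collapse=collapse)
        assert r.df == 3


class TestTimeline:
    WINDOW = (date(2014, 1, 8), date(2014, 1, 15))

    def test_single_day(self):
        corpus = [make_tweet(f"t{i}", f"m{i}", sentiment="anti") for i in range(5)]
        tl = timeline(corpus, resolve_retweets(corpus), self.WINDOW)
        assert tl["n"].sum() == 5
        assert set(tl["day"]) == {"2014-01-09"}

    def test_late_evening_binned_to_local_day(self):
        # 23:30 Chicago on Jan 9 is 05:30 UTC on Jan 10
        ts = datetime(2014, 1, 10, 5, 30, tzinfo=timezone.utc)
        t = make_tweet("t1", "x", ts=ts, sentiment="anti")
        tl = timeline([t], resolve_retweets([t]), self.WINDOW)
        assert list(tl["day"]) == ["2014-01-09"]

    def test_outside_window_binned_separately(self, caplog):
        t = make_tweet("t1", "x", ts=datetime(2014, 3, 1, tzinfo=timezone.utc))
        with caplog.at_level("WARNING"):
            tl = timeline([t], resolve_retweets([t]), self.WINDOW)
        assert list(tl["day"]) == ["outside"]

    def test_grand_total_conservation(self, default_dataset, default_window):
        res = resolve_retweets(default_dataset.tweets)
        tl = timeline(default_dataset.tweets, res, default_window)
        assert tl["n"].sum() == len(default_dataset.tweets)

    def test_burst_days_are_modal_for_anti_retweets(self, default_dataset, default_window):
        res = resolve_retweets(default_dataset.tweets)
        tl = timeline(default_dataset.tweets, res, default_window)
        anti_rt = tl[(tl["sentiment"] == "anti") & (tl["kind"] == "retweet")]
        ranked = anti_rt.groupby("day")["n"].sum().sort_values(ascending=False)
        assert set(ranked.index[:2]) == {"2014-01-09", "2014-01-13"}


class TestHashtags:
    def test_absent_tag_zero(self):
        corpus = [make_tweet("t1", "no tags here")]
        table = hashtag_counts(corpus, ["ecigtruths"])
        assert table.loc["ecigtruths", "total"] == 0

    def test_case_insensitive_merge(self):
        corpus = [
            make_tweet("t1", "#ECigTruths yes", sentiment="anti"),
            make_tweet("t2", "#ecigtruths no", sentiment="pro"),
        ]
        table = hashtag_counts(corpus, ["#ECigTruths"])
        assert table.loc["ecigtruths", "anti"] == 1
        assert table.loc["ecigtruths", "pro"] == 1
        assert table.loc["ecigtruths", "total"] == 2

    def test_agency_campaign_tag_count(self, agency_corpus):
        table = hashtag_counts(agency_corpus, ["ecigtruths"])
        assert table.loc["ecigtruths", "total"] == 12
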