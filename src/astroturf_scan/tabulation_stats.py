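"""Content tables and association tests for an annotated tweet corpus.

Sentiment and theme labels are *inputs*: they come from human coding of the
tweets and are consumed as annotations, never predicted.  This module turns
them into the standard campaign-forensics tables — sentiment shares, a
theme × sentiment × tweet/retweet table, hashtag counts, daily timelines in
a reporting timezone — and runs the sentiment × location chi-square with
Pearson and adjusted standardized residuals to show which cells drive any
association.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import date
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Optional, Sequence
from zoneinfo import ZoneInfo

import numpy as np
import pandas as pd
from scipy import stats

from .corpus_io import LOCATION_CATEGORIES, THEMES, TweetRecord, UserProfile
from .retweet_resolution import RetweetResolution

logger = logging.getLogger(__name__)

REPORTING_TZ_DEFAULT = "America/Chicago"


def round_pct(x: float, places: int = 1) -> float:
    """Percentage rounding: half-up to one decimal, as printed in reports."""
    q = Decimal(1).scaleb(-places)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def sentiment_summary(corpus: Sequence[TweetRecord]) -> dict[str, dict[str, float]]:
    """Counts and percentage shares for pro / anti / unclear sentiment.

    Shares are percentages of the labeled tweets, rounded half-up to one
    decimal.  An unlabeled corpus reports zero shares with a warning.
    """
    counts = {s: 0 for s in ("pro", "anti", "unclear")}
    n_unlabeled = 0
    for t in corpus:
        if t.sentiment in counts:
            counts[t.sentiment] += 1
        else:
            n_unlabeled += 1
    total = sum(counts.values())
    if total == 0:
        logger.warning("no sentiment-labeled tweets; shares reported as 0")
    out = {
        s: {"n": n, "pct": round_pct(100.0 * n / total) if total else 0.0}
        for s, n in counts.items()
    }
    out["unlabeled"] = {"n": n_unlabeled, "pct": 0.0}
    return out


def theme_table(
    corpus: Sequence[TweetRecord], resolution: Sequence[RetweetResolution]
) -> pd.DataFrame:
    """Theme × sentiment table of tweet / retweet counts.

    A tweet counts once per assigned theme (multi-theme tweets appear in
    several rows).  ``n_tweets`` are originals, ``n_retweets`` native plus
    non-native retweets, per the resolution.  Percentages are column
    percentages of the corpus-wide totals; ``retweet_fraction`` is the
    within-cell share of retweets.
    """
    status = {r.tweet_id: r.status for r in resolution}
    index = pd.MultiIndex.from_product(
        [THEMES, ("pro", "anti")], names=["theme", "sentiment"]
    )
    table = pd.DataFrame(0, index=index, columns=["n_all", "n_tweets", "n_retweets"])
    n_orig_total = sum(1 for s in status.values() if s == "original")
    n_rt_total = len(status) - n_orig_total
    for t in corpus:
        if t.sentiment not in ("pro", "anti"):
            continue
        unknown = t.themes - set(THEMES)
        if unknown:
            raise ValueError(f"tweet {t.tweet_id}: unknown theme label(s) {sorted(unknown)}")
        is_original = status.get(t.tweet_id, "original") == "original"
        for theme in t.themes:
            table.loc[(theme, t.sentiment), "n_all"] += 1
            col = "n_tweets" if is_original else "n_retweets"
            table.loc[(theme, t.sentiment), col] += 1
    n = max(len(corpus), 1)
    table["pct_all"] = [round_pct(100.0 * v / n) for v in table["n_all"]]
    table["pct_tweets"] = [
        round_pct(100.0 * v / n_orig_total) if n_orig_total else 0.0
        for v in table["n_tweets"]
    ]
    table["pct_retweets"] = [
        round_pct(100.0 * v / n_rt_total) if n_rt_total else 0.0
        for v in table["n_retweets"]
    ]
    table["retweet_fraction"] = [
        round_pct(100.0 * r / a) if a else 0.0
        for r, a in zip(table["n_retweets"], table["n_all"])
    ]
    return table


@dataclass
class ContingencyResult:
    observed: pd.DataFrame
    expected: pd.DataFrame
    chi2: float
    df: int
    p_value: float
    pearson_residuals: pd.DataFrame
    adjusted_residuals: pd.DataFrame
    n_cells_expected_lt5: int


def contingency_test(observed: pd.DataFrame) -> ContingencyResult:
    """Pearson chi-square (no continuity correction) with both residual
    variants for an arbitrary observed table."""
    obs = observed.to_numpy(dtype=float)
    if (obs.sum(axis=1) == 0).any() or (obs.sum(axis=0) == 0).any():
        zero_rows = list(observed.index[obs.sum(axis=1) == 0])
        zero_cols = list(observed.columns[obs.sum(axis=0) == 0])
        raise ValueError(
            f"degenerate contingency table: zero margin for rows {zero_rows} / columns {zero_cols}"
        )
    chi2, p, df, expected = stats.chi2_contingency(obs, correction=False)
    n = obs.sum()
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    pearson = (obs - expected) / np.sqrt(expected)
    adjusted = (obs - expected) / np.sqrt(expected * (1 - row / n) * (1 - col / n))
    wrap = lambda a: pd.DataFrame(a, index=observed.index, columns=observed.columns)
    return ContingencyResult(
        observed=observed.astype(int),
        expected=wrap(expected),
        chi2=float(chi2),
        df=int(df),
        p_value=float(p),
        pearson_residuals=wrap(pearson),
        adjusted_residuals=wrap(adjusted),
        n_cells_expected_lt5=int((expected < 5).sum()),
    )


def chi_square_location(
    corpus: Sequence[TweetRecord],
    users: Sequence[UserProfile],
    drop_unclear: bool = True,
    collapse: Optional[Mapping[str, str]] = None,
) -> ContingencyResult:
    """Sentiment × author-location chi-square over labeled tweets.

    The "unclear" sentiment row is dropped by default, leaving a 2 × k
    table (df = k − 1; with all five location categories populated, df = 4).
    Location columns empty in the corpus are dropped with a warning before
    testing; ``collapse`` optionally maps location categories onto merged
    column names.  Cells with expected counts below 5 are counted and
    reported on the result.
    """
    loc_of = {u.handle: u.location_category for u in users}
    sentiments = ("pro", "anti") if drop_unclear else ("pro", "anti", "unclear")
    columns = list(dict.fromkeys((collapse or {}).get(c, c) for c in LOCATION_CATEGORIES))
    observed = pd.DataFrame(0, index=list(sentiments), columns=columns)
    for t in corpus:
        if t.sentiment not in sentiments:
            continue
        loc = loc_of.get(t.author, "unknown")
        observed.loc[t.sentiment, (collapse or {}).get(loc, loc)] += 1
    empty = [c for c in observed.columns if observed[c].sum() == 0]
    if empty:
        logger.warning("dropping empty location column(s): %s", empty)
        observed = observed.drop(columns=empty)
    if observed.shape[0] < 2 or observed.shape[1] < 2:
        raise ValueError(
            f"contingency table too small after dropping empty columns: shape {observed.shape}"
        )
    result = contingency_test(observed)
    if result.n_cells_expected_lt5:
        logger.warning(
            "%d cell(s) have expected count < 5; chi-square approximation may be poor",
            result.n_cells_expected_lt5,
        )
    return result


def timeline(
    corpus: Sequence[TweetRecord],
    resolution: Sequence[RetweetResolution],
    window: tuple[date, date],
    tz: str = REPORTING_TZ_DEFAULT,
) -> pd.DataFrame:
    """Daily tweet/retweet counts by sentiment in the reporting timezone.

    Campaign days are defined by local (default Chicago) time, so a tweet at
    23:30 local lands on its local calendar day even though it is past
    midnight UTC.  Tweets outside the window go to an "outside" bin with a
    warning.  Long-form frame: day, sentiment, kind, n; the grand total
    equals the corpus size.
    """
    zone = ZoneInfo(tz)
    status = {r.tweet_id: r.status for r in resolution}
    start, end = window
    counts: dict[tuple[str, str, str], int] = {}
    n_outside = 0
    for t in corpus:
        local_day = t.timestamp.astimezone(zone).date()
        if start <= local_day <= end:
            day = local_day.isoformat()
        else:
            day = "outside"
            n_outside += 1
        kind = "tweet" if status.get(t.tweet_id, "original") == "original" else "retweet"
        key = (day, t.sentiment, kind)
        counts[key] = counts.get(key, 0) + 1
    if n_outside:
        logger.warning("%d tweet(s) fall outside the declared window", n_outside)
    rows = [
        {"day": d, "sentiment": s, "kind": k, "n": n}
        for (d, s, k), n in sorted(counts.items())
    ]
    return pd.DataFrame(rows, columns=["day", "sentiment", "kind", "n"])


def hashtag_counts(
    corpus: Sequence[TweetRecord], tags: Sequence[str]
) -> pd.DataFrame:
    """Per-tag, per-sentiment tweet counts (case-insensitive, once per tweet)."""
    wanted = [t.lstrip("#").lower() for t in tags]
    sentiments = ("pro", "anti", "unclear", "unlabeled")
    table = pd.DataFrame(0, index=wanted, columns=list(sentiments))
    table.index.name = "tag"
    for t in corpus:
        present = set(t.hashtags)
        for tag in wanted:
            if tag in present:
                table.loc[tag, t.sentiment] += 1
    table["total"] = table.sum(axis=1)
    return table
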