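"""Shared fixtures: hand-built micro-corpora and the default synthetic corpus."""

from __future__ import annotations

from datetime import date, datetime, timedelta, timezone
from zoneinfo import ZoneInfo

import pytest

from astroturf_scan.corpus_io import TweetRecord, UserProfile
from astroturf_scan.synthetic_data import SyntheticConfig, generate

CHICAGO = ZoneInfo("America/Chicago")

# The public agency's one-day e-cigarette campaign: 12 tweets, all tagged
# #ecigtruths, sent the morning the analysis window opens.  URLs stand in
# for the shortened links in the originals.
AGENCY_CAMPAIGN = [
    ("10:05", "#ECigs look like, are labeled & contain nicotine like cigarettes. They should be regulated as such. Let's talk about it! #ecigtruths"),
    ("10:10", "#ECigs come in cotton candy, bubble gum & gummy bear flavors - clearly meant for children http://t.co/cdph02 #ecigtruths"),
    ("10:14", "The “water vapor” from #ECigs contains benzene, nickel, tin, arsenic, formaldehyde & acrolein #ecigtruths http://t.co/cdph03"),
    ("10:18", "Percentage of middle school and high school students who used e-cigarettes DOUBLED from 2011 to 2012. They must be regulated. #ecigtruths"),
    ("10:22", "Electronic cigarettes contain a dangerous, addictive drug & should be regulated like other nicotine products #ecigtruths"),
    ("10:25", "We have a duty to protect our children from ever picking up a nicotine habit #ecigtruths http://t.co/cdph06"),
    ("10:28", "Youth are particularly susceptible to behavioral advertising http://t.co/cdph07 #ecigtruths"),
    ("10:30", "We do not want to create a new generation of nicotine-addicted residents. It’s time to regulate #ecigtruths http://t.co/cdph08"),
    ("10:33", "In Chicago, smoking rates are lower than ever. Let’s not reverse decades of life-saving progress #ecigtruths"),
    ("10:38", "“9 Terribly Disturbing Things About Electronic Cigarettes” http://t.co/cdph10 via @HuffPostBiz #ecigtruths"),
    ("11:34", "Electronic cigs contain a dangerous, addictive drug & should be regulated like other nicotine products #ecigtruths"),
    ("12:37", "Safe? #ecigtruths http://t.co/cdph12"),
]


def make_tweet(
    tweet_id: str,
    text: str,
    author: str = "someone",
    ts: datetime | None = None,
    offset_s: int = 0,
    native=None,
    sentiment: str = "unlabeled",
    themes=frozenset(),
) -> TweetRecord:
    base = ts or datetime(2014, 1, 9, 12, 0, tzinfo=timezone.utc)
    return TweetRecord(
        tweet_id=tweet_id,
        timestamp=base + timedelta(seconds=offset_s),
        author=author,
        text=text,
        native_retweet_of=native,
        sentiment=sentiment,
        themes=frozenset(themes),
    )


@pytest.fixture(scope="session")
def agency_corpus() -> list[TweetRecord]:
    tweets = []
    for i, (hhmm, text) in enumerate(AGENCY_CAMPAIGN, start=1):
        h, m = map(int, hhmm.split(":"))
        ts = datetime(2014, 1, 8, h, m, tzinfo=CHICAGO).astimezone(timezone.utc)
        tweets.append(
            make_tweet(f"agency{i:02d}", text, author="chipublichealth", ts=ts,
                       sentiment="pro")
        )
    return tweets


@pytest.fixture(scope="session")
def default_config() -> SyntheticConfig:
    return SyntheticConfig()


@pytest.fixture(scope="session")
def default_dataset(default_config):
    """The default synthetic campaign corpus (seed 42, ~2,000 tweets)."""
    return generate(default_config)


@pytest.fixture(scope="session")
def default_window(default_config):
    return (default_config.window_start, default_config.window_end)


def make_user(handle: str, followers=100, following=100, created: date | None = date(2010, 6, 1),
              location: str = "") -> UserProfile:
    from astroturf_scan.corpus_io import categorize_location

    return UserProfile(
        handle=handle,
        followers=followers,
        following=following,
        statuses=50,
        created=created,
        location_raw=location,
        location_category=categorize_location(location),
    )
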