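"""Three-indicator astroturf account scoring and tweet-level evidence flags.

Accounts engaged in manufactured grassroots campaigns tend to (1) follow
many more accounts than follow them back, (2) carry machine-generated
handles mixing letters and digits, and (3) be freshly created for the
campaign.  An account is scored on all three; following-to-follower ratios
are standardised across the whole observed account set and flagged when
z ≥ 1.96, and an account tripping at least two of the three indicators is
considered likely astroturf.  At the tweet level, a tweet is
astroturf-consistent if its author is a likely-astroturf account or it
belongs to a URL-variant duplicate cluster (same text re-posted under
rotating shortened URLs that all resolve to one destination).
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np

from .corpus_io import UserProfile
from .retweet_resolution import DuplicateCluster, RetweetResolution

logger = logging.getLogger(__name__)

Z_THRESHOLD_DEFAULT = 1.96
MIN_INDICATORS_DEFAULT = 2

_LETTER_RE = re.compile(r"[A-Za-z]")
_DIGIT_RE = re.compile(r"[0-9]")


def compute_ratio(following: int, followers: int) -> float:
    """Following-to-follower ratio; zero-follower accounts are given one
    follower so the ratio stays finite."""
    return following / max(followers, 1)


def zscore_ratios(ratios: Sequence[float]) -> np.ndarray:
    """Standardise ratios over the whole account set (population SD).

    Zero spread yields all-zero z-scores (and therefore no flags) with a
    warning rather than a division error.
    """
    arr = np.asarray(ratios, dtype=float)
    sd = arr.std(ddof=0)
    if arr.size == 0:
        return arr
    if sd == 0:
        logger.warning("ratio spread is zero; all z-scores set to 0")
        return np.zeros_like(arr)
    return (arr - arr.mean()) / sd


def username_alphanum_flag(handle: str) -> bool:
    """True iff the handle mixes at least one letter with at least one digit
    (underscores ignored)."""
    s = handle.replace("_", "")
    return bool(_LETTER_RE.search(s)) and bool(_DIGIT_RE.search(s))


@dataclass(frozen=True)
class AstroturfIndicators:
    handle: str
    ratio: float
    z_ratio: float
    flag_high_ratio: bool
    flag_alphanum: bool
    flag_new_account: bool

    @property
    def indicator_count(self) -> int:
        return int(self.flag_high_ratio) + int(self.flag_alphanum) + int(self.flag_new_account)


@dataclass(frozen=True)
class TweetFlag:
    tweet_id: str
    evidence: tuple[str, ...]  # subset of {"account", "url_variant"}


@dataclass
class AstroturfReport:
    indicators: list[AstroturfIndicators]
    min_indicators: int
    z_threshold: float
    tweet_flags: list[TweetFlag] = field(default_factory=list)

    def is_likely(self, ind: AstroturfIndicators) -> bool:
        return ind.indicator_count >= self.min_indicators

    @property
    def likely_handles(self) -> set[str]:
        return {i.handle for i in self.indicators if self.is_likely(i)}

    @property
    def n_accounts_any_indicator(self) -> int:
        return sum(1 for i in self.indicators if i.indicator_count >= 1)

    @property
    def n_accounts_likely(self) -> int:
        return len(self.likely_handles)

    @property
    def n_tweets_consistent(self) -> int:
        return len(self.tweet_flags)


def score_accounts(
    profiles: Sequence[UserProfile],
    window: tuple[date, date],
    z_threshold: float = Z_THRESHOLD_DEFAULT,
    min_indicators: int = MIN_INDICATORS_DEFAULT,
) -> AstroturfReport:
    """Score every account on the three astroturf indicators.

    ``window`` is the (inclusive) analysis window; an account created inside
    it trips the new-account indicator.  Profiles with no creation date get
    ``flag_new_account = False`` with a per-account warning.
    """
    start, end = window
    if start > end:
        raise ValueError(f"window start {start} after end {end}")
    ratios = [compute_ratio(p.following, p.followers) for p in profiles]
    zs = zscore_ratios(ratios)
    indicators = []
    for p, ratio, z in zip(profiles, ratios, zs):
        if p.created is None:
            logger.warning("account %s: no creation date; new-account flag unset", p.handle)
            new = False
        else:
            new = start <= p.created <= end
        indicators.append(
            AstroturfIndicators(
                handle=p.handle,
                ratio=ratio,
                z_ratio=float(z),
                flag_high_ratio=bool(z >= z_threshold),
                flag_alphanum=username_alphanum_flag(p.handle),
                flag_new_account=new,
            )
        )
    return AstroturfReport(indicators, min_indicators, z_threshold)


def flag_astroturf_tweets(
    report: AstroturfReport,
    resolution: Sequence[RetweetResolution],
    clusters: Sequence[DuplicateCluster],
) -> list[TweetFlag]:
    """Flag tweets whose author is likely astroturf or that sit in a
    URL-variant cluster; each flag cites its evidence.  The result is also
    stored on ``report.tweet_flags``."""
    likely = report.likely_handles
    in_cluster = {
        tid for c in clusters if c.url_variant_cluster for tid in c.members
    }
    flags = []
    for res in resolution:
        evidence = []
        if res.author in likely:
            evidence.append("account")
        if res.tweet_id in in_cluster:
            evidence.append("url_variant")
        if evidence:
            flags.append(TweetFlag(res.tweet_id, tuple(evidence)))
    report.tweet_flags = flags
    return flags


# ---------------------------------------------------------------------------
# Exports


def write_astroturf_csv(report: AstroturfReport, path: Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(
            ["handle", "ratio", "z", "flag_high_ratio", "flag_alphanum",
             "flag_new_account", "indicator_count", "likely"]
        )
        for ind in sorted(report.indicators, key=lambda i: i.handle):
            w.writerow(
                [ind.handle, f"{ind.ratio:.6g}", f"{ind.z_ratio:.6g}",
                 int(ind.flag_high_ratio), int(ind.flag_alphanum),
                 int(ind.flag_new_account), ind.indicator_count,
                 int(report.is_likely(ind))]
            )


def write_astroturf_tweets_csv(flags: Sequence[TweetFlag], path: Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["tweet_id", "evidence"])
        for f in sorted(flags, key=lambda f: f.tweet_id):
            w.writerow([f.tweet_id, "+".join(f.evidence)])
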