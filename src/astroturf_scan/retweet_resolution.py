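"""Retweet classification and duplicate-tweet forensics.

Manual ("non-native") retweets carry no platform metadata: the only way to
attribute them is to notice that several tweets share the same text modulo
a "RT @handle:" prefix, a swapped shortened URL, or client-side truncation.
This module canonicalises tweet text, partitions a corpus into originals,
native retweets and non-native retweets, and surfaces duplicate clusters
whose members differ only in their shortened URL — a known spam-evasion
tactic and astroturf-consistent evidence when all variants point to the
same destination.
"""

from __future__ import annotations

import logging
import re
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .corpus_io import URL_RE, TweetRecord, UrlMap

logger = logging.getLogger(__name__)

# Leading manual-retweet marker: "RT @user:" or "MT @user:" (modified tweet),
# possibly stacked ("RT @a: RT @b: ...").
_RT_PREFIX_RE = re.compile(r"^\s*(?:rt|mt)\s+@\w+\s*:?\s*", re.IGNORECASE)
_ELLIPSIS_RE = re.compile(r"(?:\.\.\.|…)\s*$")
# A URL clipped so early that no scheme survives ("htt…", "http:/…"): only
# recognisable once the truncation ellipsis has been seen.
_CLIPPED_URL_TAIL_RE = re.compile(r"\s+(?:h|ht|htt|https?|https?:|https?:/|https?://\S*)$", re.IGNORECASE)
URL_PLACEHOLDER = "<url>"

# Minimum fraction of the longer text a truncated prefix must cover before
# two canonical texts are merged as the same message.
TRUNCATION_MIN_OVERLAP = 0.8


def _canonicalize(text: str) -> tuple[str, bool]:
    """Canonical form plus a flag marking client-side truncation (trailing …)."""
    while True:
        m = _RT_PREFIX_RE.match(text)
        if not m:
            break
        text = text[m.end():]
    text = URL_RE.sub(URL_PLACEHOLDER, text)
    truncated = bool(_ELLIPSIS_RE.search(text))
    text = _ELLIPSIS_RE.sub("", text)
    if truncated:
        text = _CLIPPED_URL_TAIL_RE.sub("", text)
    text = text.lower()
    text = " ".join(text.split())
    return text, truncated


def canonicalize_text(text: str) -> str:
    """Canonicalise tweet text for duplicate matching.

    Rule order is fixed: strip any number of leading ``RT @handle:`` /
    ``MT @handle:`` prefixes, mask every URL token with a placeholder,
    drop a trailing truncation ellipsis, lowercase, collapse whitespace.
    The function is idempotent.
    """
    return _canonicalize(text)[0]


@dataclass(frozen=True)
class RetweetResolution:
    """Per-tweet classification with attribution to the original tweeter."""

    tweet_id: str
    author: str
    status: str  # "original" | "native_rt" | "nonnative_rt"
    source_author: str
    source_tweet_id: Optional[str]
    canonical_text: str


@dataclass
class DuplicateCluster:
    """Tweets sharing one canonical text; candidates for URL-variant evidence."""

    canonical_text: str
    members: list[str]  # tweet ids, chronological
    n_url_variants: int
    same_destination: str  # "yes" | "no" | "unresolved"

    @property
    def url_variant_cluster(self) -> bool:
        return self.n_url_variants >= 2 and self.same_destination != "no"


def _chronological(tweets: Iterable[TweetRecord]) -> list[TweetRecord]:
    return sorted(tweets, key=lambda t: (t.timestamp, t.tweet_id))


def resolve_retweets(corpus: Sequence[TweetRecord]) -> list[RetweetResolution]:
    """Classify every tweet as original / native / non-native retweet.

    Tweets carrying native metadata are attributed from it.  The remainder
    are grouped by canonical text; within each group the earliest tweet
    (ties broken by ascending tweet id) is the original and the rest are
    non-native retweets attributed to it.  A truncated text whose canonical
    form is a prefix of exactly one longer group, covering at least
    ``TRUNCATION_MIN_OVERLAP`` of it, is merged into that group.
    """
    known = {t.author for t in corpus}
    canonical: dict[str, tuple[str, bool]] = {
        t.tweet_id: _canonicalize(t.text) for t in corpus
    }

    native: dict[str, RetweetResolution] = {}
    manual: list[TweetRecord] = []
    for t in corpus:
        if t.native_retweet_of is not None:
            src_id, src_handle = t.native_retweet_of
            if src_handle not in known:
                logger.warning(
                    "tweet %s: native retweet of unknown handle %s (kept as stated)",
                    t.tweet_id, src_handle,
                )
            native[t.tweet_id] = RetweetResolution(
                t.tweet_id, t.author, "native_rt", src_handle, src_id,
                canonical[t.tweet_id][0],
            )
        else:
            manual.append(t)

    groups: dict[str, list[TweetRecord]] = defaultdict(list)
    truncated_group: dict[str, bool] = defaultdict(bool)
    for t in manual:
        text, trunc = canonical[t.tweet_id]
        groups[text].append(t)
        truncated_group[text] = truncated_group[text] or trunc

    # Merge truncated prefixes into their (unique) longer counterpart.
    for key in sorted(groups, key=lambda k: (len(k), k)):
        if key not in groups or not truncated_group[key] or not key:
            continue
        candidates = [
            other
            for other in groups
            if other != key
            and other.startswith(key)
            and len(key) >= TRUNCATION_MIN_OVERLAP * len(other)
        ]
        if len(candidates) == 1:
            groups[candidates[0]].extend(groups.pop(key))
        elif len(candidates) > 1:
            logger.warning(
                "truncated text %r matches %d longer groups; left unmerged",
                key, len(candidates),
            )

    resolved: dict[str, RetweetResolution] = dict(native)
    for key, members in groups.items():
        members = _chronological(members)
        head = members[0]
        resolved[head.tweet_id] = RetweetResolution(
            head.tweet_id, head.author, "original", head.author, head.tweet_id, key
        )
        for t in members[1:]:
            resolved[t.tweet_id] = RetweetResolution(
                t.tweet_id, t.author, "nonnative_rt", head.author, head.tweet_id, key
            )

    return [resolved[t.tweet_id] for t in corpus]


def detect_url_variant_clusters(
    corpus: Sequence[TweetRecord],
    resolution: Sequence[RetweetResolution],
    urlmap: UrlMap,
) -> list[DuplicateCluster]:
    """Find same-canonical-text clusters and test their URL variants.

    ``same_destination`` is "yes" iff every member URL resolves through the
    map to one destination, "no" iff at least two distinct destinations are
    seen, and "unresolved" when any lookup is unmapped (absence of a map
    entry is not evidence of different destinations).
    """
    by_id = {t.tweet_id: t for t in corpus}
    groups: dict[str, list[str]] = defaultdict(list)
    for res in resolution:
        groups[res.canonical_text].append(res.tweet_id)

    clusters: list[DuplicateCluster] = []
    for key in sorted(groups):
        ids = groups[key]
        if len(ids) < 2:
            continue
        ids = [t.tweet_id for t in _chronological(by_id[i] for i in ids)]
        urls = sorted({u for i in ids for u in by_id[i].urls})
        destinations = [urlmap.resolve(u) for u in urls]
        if not urls or any(d is UrlMap.UNRESOLVED for d in destinations):
            same = "unresolved"
        elif len(set(destinations)) == 1:
            same = "yes"
        else:
            same = "no"
        clusters.append(DuplicateCluster(key, ids, len(urls), same))
    return clusters
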