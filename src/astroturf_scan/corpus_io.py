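"""Reading, validating and normalising tweet corpora, user profiles and URL maps.

The pipeline consumes three plain-text inputs:

``tweets.jsonl``
    One JSON object per line with keys ``id``, ``created_at`` (ISO-8601),
    ``user``, ``text`` and, optionally, ``retweeted_status_id`` /
    ``retweeted_status_user`` (native-retweet metadata) plus human annotation
    fields ``sentiment`` and ``themes``.
``users.csv``
    Header ``handle,followers,following,statuses,created,location``.
``urlmap.tsv``
    Two tab-separated columns: short URL, destination URL.  Stands in for
    live URL expansion, which this package never performs over the network.

All handles are normalised to lowercase without the leading ``@`` on the way
in; timestamps are normalised to UTC.  Entity lists (URLs, hashtags,
mentions) are re-derived from the text, so they are always consistent with
it regardless of what the upstream collector recorded.
"""

from __future__ import annotations

import csv
import json
import logging
import re
from dataclasses import dataclass, field, replace
from datetime import date, datetime, timezone
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import yaml

logger = logging.getLogger(__name__)

SENTIMENTS = ("pro", "anti", "unclear", "unlabeled")
THEMES = (
    "safety",
    "lies_propaganda",
    "science",
    "flavor",
    "regulation",
    "issue_salience",
)
LOCATION_CATEGORIES = (
    "chicago_area",
    "illinois_other",
    "us_other",
    "non_us",
    "unknown",
)

# Conservative URL pattern: explicit scheme, then any run of non-space.
URL_RE = re.compile(r"[A-Za-z][A-Za-z0-9+.\-]*://\S+")
_TRAILING_PUNCT = "'\").,;:!?…"
HASHTAG_RE = re.compile(r"#(\w+)")
MENTION_RE = re.compile(r"@(\w+)")
_LEADING_MENTION_RE = re.compile(r"\s*@\w")


def normalize_handle(handle: str) -> str:
    """Lowercase a handle and strip any leading ``@`` (Twitter semantics)."""
    return handle.strip().lstrip("@").lower()


@dataclass(frozen=True)
class EntitySet:
    urls: tuple[str, ...]
    hashtags: tuple[str, ...]
    mentions: tuple[str, ...]
    first_token_is_mention: bool


def extract_entities(text: str) -> EntitySet:
    """Extract URLs, hashtags and mentions from tweet text.

    Hashtags are lowercased without ``#``; mentions are lowercased without
    ``@``; URLs keep their raw form with trailing punctuation stripped.
    ``first_token_is_mention`` is True iff the text, after leading
    whitespace, begins with a mention — on Twitter a leading mention
    restricts timeline visibility, so campaigns aimed at one account tend
    to start their tweets with it.
    """
    urls = tuple(
        u.rstrip(_TRAILING_PUNCT) for u in URL_RE.findall(text) if u.rstrip(_TRAILING_PUNCT)
    )
    masked = URL_RE.sub(" ", text)
    hashtags = tuple(h.lower() for h in HASHTAG_RE.findall(masked))
    mentions = tuple(m.lower() for m in MENTION_RE.findall(masked))
    first = bool(_LEADING_MENTION_RE.match(text))
    return EntitySet(urls, hashtags, mentions, first)


@dataclass(frozen=True)
class TweetRecord:
    """One tweet with authorship, timing and optional human annotations."""

    tweet_id: str
    timestamp: datetime  # timezone-aware, UTC
    author: str  # normalised handle
    text: str
    native_retweet_of: Optional[tuple[Optional[str], str]] = None  # (tweet_id, handle)
    sentiment: str = "unlabeled"
    themes: frozenset[str] = frozenset()

    @property
    def entities(self) -> EntitySet:
        return extract_entities(self.text)

    @property
    def urls(self) -> tuple[str, ...]:
        return self.entities.urls

    @property
    def hashtags(self) -> tuple[str, ...]:
        return self.entities.hashtags

    @property
    def mentions(self) -> tuple[str, ...]:
        return self.entities.mentions


@dataclass(frozen=True)
class UserProfile:
    """Account metadata feeding the three astroturf indicators."""

    handle: str
    followers: int = 0
    following: int = 0
    statuses: int = 0
    created: Optional[date] = None
    location_raw: str = ""
    location_category: str = "unknown"


class UrlMap:
    """Short-URL → destination lookups; unmapped URLs resolve to ``None``."""

    UNRESOLVED = None

    def __init__(self, mapping: Optional[Mapping[str, str]] = None):
        self._map = dict(mapping or {})

    def resolve(self, url: str) -> Optional[str]:
        return self._map.get(url, self.UNRESOLVED)

    def __len__(self) -> int:
        return len(self._map)

    def items(self):
        return self._map.items()

    def __eq__(self, other) -> bool:
        return isinstance(other, UrlMap) and self._map == other._map


# ---------------------------------------------------------------------------
# Location gazetteer


def load_gazetteer(path: Optional[Path] = None) -> dict[str, list[str]]:
    """Load the location keyword lists (editable YAML shipped with the package)."""
    if path is not None:
        text = Path(path).read_text(encoding="utf-8")
    else:
        text = (
            resources.files("astroturf_scan").joinpath("data/gazetteer.yaml").read_text("utf-8")
        )
    gaz = yaml.safe_load(text)
    for key in ("chicago_area", "illinois", "us_states", "countries"):
        gaz.setdefault(key, [])
    return gaz


_GAZ_PRECEDENCE = (
    ("chicago_area", "chicago_area"),
    ("illinois_other", "illinois"),
    ("us_other", "us_states"),
    ("non_us", "countries"),
)

_compiled_gaz_cache: dict[int, list[tuple[str, re.Pattern]]] = {}


def _compile_gazetteer(gazetteer: Mapping[str, Sequence[str]]):
    key = id(gazetteer)
    cached = _compiled_gaz_cache.get(key)
    if cached is not None:
        return cached
    compiled = []
    for category, gaz_key in _GAZ_PRECEDENCE:
        kws = sorted((k.lower() for k in gazetteer.get(gaz_key, [])), key=len, reverse=True)
        if not kws:
            continue
        pattern = re.compile(
            "|".join(r"(?<!\w)" + re.escape(k) + r"(?!\w)" for k in kws), re.IGNORECASE
        )
        compiled.append((category, pattern))
    _compiled_gaz_cache[key] = compiled
    return compiled


def categorize_location(
    location_raw: str, gazetteer: Optional[Mapping[str, Sequence[str]]] = None
) -> str:
    """Map a free-text profile location to one of five categories.

    Matching is whole-word and case-insensitive, longest keyword first,
    with precedence chicago_area > illinois_other > us_other > non_us.
    Blank or unmatched strings (profile jokes like "a galaxy far far away")
    fall through to ``unknown``.
    """
    if not location_raw or not location_raw.strip():
        return "unknown"
    if gazetteer is None:
        gazetteer = _default_gazetteer()
    for category, pattern in _compile_gazetteer(gazetteer):
        if pattern.search(location_raw):
            return category
    return "unknown"


_default_gaz: Optional[dict] = None


def _default_gazetteer() -> dict:
    global _default_gaz
    if _default_gaz is None:
        _default_gaz = load_gazetteer()
    return _default_gaz


# ---------------------------------------------------------------------------
# Parsing


def _parse_timestamp(value: str) -> datetime:
    ts = datetime.fromisoformat(value.replace("Z", "+00:00"))
    if ts.tzinfo is None:
        ts = ts.replace(tzinfo=timezone.utc)
    return ts.astimezone(timezone.utc)


def parse_tweet(obj: Mapping) -> TweetRecord:
    """Build a :class:`TweetRecord` from one decoded JSONL object."""
    native = None
    if obj.get("retweeted_status_user"):
        native = (
            str(obj["retweeted_status_id"]) if obj.get("retweeted_status_id") else None,
            normalize_handle(str(obj["retweeted_status_user"])),
        )
    sentiment = obj.get("sentiment") or "unlabeled"
    if sentiment not in SENTIMENTS:
        raise ValueError(f"unknown sentiment label: {sentiment!r}")
    themes = frozenset(obj.get("themes") or ())
    unknown = themes - set(THEMES)
    if unknown:
        raise ValueError(f"unknown theme label(s): {sorted(unknown)}")
    text = str(obj["text"])
    if len(text) > 1000:
        raise ValueError(f"tweet {obj['id']}: text longer than 1000 characters")
    return TweetRecord(
        tweet_id=str(obj["id"]),
        timestamp=_parse_timestamp(str(obj["created_at"])),
        author=normalize_handle(str(obj["user"])),
        text=text,
        native_retweet_of=native,
        sentiment=sentiment,
        themes=themes,
    )


def read_tweets_jsonl(path: Path) -> list[TweetRecord]:
    """Read a JSON-Lines tweet file; malformed lines are skipped with a warning."""
    tweets: list[TweetRecord] = []
    seen: set[str] = set()
    n_skipped = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
                record = parse_tweet(obj)
            except ValueError as exc:
                if "duplicate" in str(exc):
                    raise
                n_skipped += 1
                logger.warning("%s:%d: skipping malformed record (%s)", path, lineno, exc)
                continue
            if record.tweet_id in seen:
                raise ValueError(f"duplicate tweet id: {record.tweet_id}")
            seen.add(record.tweet_id)
            tweets.append(record)
    logger.info("%s: read %d tweets, skipped %d", path, len(tweets), n_skipped)
    return tweets


def read_users_csv(
    path: Path, gazetteer: Optional[Mapping[str, Sequence[str]]] = None
) -> list[UserProfile]:
    users: list[UserProfile] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8", newline="") as fh:
        for row in csv.DictReader(fh):
            handle = normalize_handle(row["handle"])
            if handle in seen:
                raise ValueError(f"duplicate user handle: {handle}")
            seen.add(handle)
            created = date.fromisoformat(row["created"]) if row.get("created") else None
            loc = (row.get("location") or "").strip()
            users.append(
                UserProfile(
                    handle=handle,
                    followers=int(row.get("followers") or 0),
                    following=int(row.get("following") or 0),
                    statuses=int(row.get("statuses") or 0),
                    created=created,
                    location_raw=loc,
                    location_category=categorize_location(loc, gazetteer),
                )
            )
    logger.info("%s: read %d user profiles", path, len(users))
    return users


def read_urlmap_tsv(path: Path) -> UrlMap:
    mapping: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            short, _, dest = line.partition("\t")
            if not dest:
                logger.warning("%s: ignoring malformed urlmap line %r", path, line)
                continue
            mapping[short.strip()] = dest.strip()
    return UrlMap(mapping)


def read_corpus(
    tweets_path: Path,
    users_path: Path,
    urlmap_path: Optional[Path] = None,
    gazetteer: Optional[Mapping[str, Sequence[str]]] = None,
) -> tuple[list[TweetRecord], list[UserProfile], UrlMap]:
    """Read a full corpus, synthesising minimal profiles for unknown authors."""
    tweets = read_tweets_jsonl(tweets_path)
    users = read_users_csv(users_path, gazetteer)
    urlmap = read_urlmap_tsv(urlmap_path) if urlmap_path else UrlMap()

    known = {u.handle for u in users}
    missing = sorted({t.author for t in tweets} - known)
    for handle in missing:
        users.append(UserProfile(handle=handle))
    if missing:
        logger.warning(
            "synthesised %d minimal profiles for authors missing from %s: %s",
            len(missing), users_path, ", ".join(missing[:10]),
        )
    return tweets, users, urlmap


# ---------------------------------------------------------------------------
# Writing (round-trip partners of the readers)


def tweet_to_json(t: TweetRecord) -> dict:
    obj: dict = {
        "id": t.tweet_id,
        "created_at": t.timestamp.astimezone(timezone.utc).isoformat(),
        "user": t.author,
        "text": t.text,
    }
    if t.native_retweet_of is not None:
        obj["retweeted_status_id"] = t.native_retweet_of[0]
        obj["retweeted_status_user"] = t.native_retweet_of[1]
    if t.sentiment != "unlabeled":
        obj["sentiment"] = t.sentiment
    if t.themes:
        obj["themes"] = sorted(t.themes)
    return obj


def write_tweets_jsonl(tweets: Iterable[TweetRecord], path: Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for t in tweets:
            fh.write(json.dumps(tweet_to_json(t), ensure_ascii=False, sort_keys=True) + "\n")


def write_users_csv(users: Iterable[UserProfile], path: Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["handle", "followers", "following", "statuses", "created", "location"])
        for u in users:
            w.writerow(
                [
                    u.handle,
                    u.followers,
                    u.following,
                    u.statuses,
                    u.created.isoformat() if u.created else "",
                    u.location_raw,
                ]
            )


def write_urlmap_tsv(urlmap: UrlMap, path: Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for short, dest in sorted(urlmap.items()):
            fh.write(f"{short}\t{dest}\n")
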