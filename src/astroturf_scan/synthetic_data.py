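"""Synthetic tweet corpora with planted coordinated campaigns.

The generator emits a mention stream aimed at one public-agency account
with the statistical structure the analysis pipeline assumes, all labeled
with ground truth so every stage is testable without any download:

* organic users with heavy-tailed follower counts and modest
  following-to-follower ratios, versus a coordinated astroturf cell with
  inflated ratios, digit-suffixed handles and in-window creation dates;
* a handful of hub authors whose originals collect tens of distinct
  retweeters (capped heavy-tailed cascade sizes), while everyone else stays
  at ten or fewer;
* native retweets (with metadata) mixed with manual "RT @user:" copies;
* coordinated duplicate clusters whose members differ only in a rotating
  shortened URL, all mapped to one destination;
* a strong ~9:1 anti:pro sentiment skew whose location mix differs by
  sentiment, plus per-sentiment theme labels;
* burst days concentrating anti-policy traffic.

Tweet texts are template strings carrying a unique token per original
message — sufficient for canonicalisation, hashtag and mention logic, with
no pretence of linguistic realism.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from datetime import date, datetime, time, timedelta, timezone
from pathlib import Path
from typing import Optional, Sequence
from zoneinfo import ZoneInfo

import numpy as np
import yaml

from .astroturf_scoring import AstroturfReport
from .corpus_io import (
    TweetRecord,
    UrlMap,
    UserProfile,
    categorize_location,
    write_tweets_jsonl,
    write_urlmap_tsv,
    write_users_csv,
)
from .retweet_resolution import RetweetResolution

logger = logging.getLogger(__name__)

GENERATOR_TZ = "America/Chicago"
AGENCY_HANDLE = "chipublichealth"

_ADJ = [
    "cloud", "vapor", "windy", "free", "happy", "urban", "smoky", "misty",
    "true", "steam", "frosty", "mellow", "chill", "blue", "neon", "quiet",
    "brave", "lucky", "rapid", "gold", "silver", "crimson", "vivid", "noble",
    "wild", "calm", "keen", "bold",
]
_NOUN = [
    "vaper", "chaser", "rider", "citizen", "skeptic", "advocate", "builder",
    "dreamer", "tinkerer", "runner", "critic", "voice", "neighbor", "fan",
    "maker", "walker", "thinker", "reader", "coder", "painter", "drifter",
    "pilot", "sailor", "gardener", "baker", "scout",
]

_SLOGANS = {
    "anti": [
        "vaping saved my life stop the ban",
        "harm reduction is public health",
        "regulate facts not fear",
        "switching works let vapers vape",
        "no smoke no tar no sense in this rule",
        "adults deserve safer choices",
        "keep calm and vape on",
        "this policy helps big tobacco",
    ],
    "pro": [
        "nicotine is nicotine regulate it",
        "protect kids from candy flavored nicotine",
        "vapor is not just water science says so",
        "smart rule for a healthier city",
        "regulation keeps youth off nicotine",
    ],
    "unclear": [
        "interesting debate tonight",
        "what is going on with this hearing",
    ],
}

_LOCATION_STRINGS = {
    "chicago_area": [
        "Chicago, IL", "Chicago", "Evanston, IL", "Oak Park, IL",
        "Windy City", "Chicagoland", "Skokie, IL",
    ],
    "illinois_other": [
        "Springfield, IL", "Peoria, Illinois", "Rockford, IL", "Champaign, IL",
    ],
    "us_other": [
        "Denver, CO", "Austin, Texas", "Brooklyn, NY", "Seattle, WA",
        "Phoenix, AZ", "Atlanta, GA", "Tampa, FL", "Portland, Oregon",
    ],
    "non_us": [
        "London, UK", "Toronto, Canada", "Manchester, England",
        "Athens, Greece", "Sydney, Australia", "Dublin, Ireland",
    ],
    "unknown": [
        "", "a galaxy far far away", "everywhere and nowhere",
        "the internet", "planet earth", "vapeland",
    ],
}

LOCATION_ORDER = ("chicago_area", "illinois_other", "us_other", "non_us", "unknown")


def _default_sentiment_location_probs() -> dict:
    # Pro-policy voices are mostly local; the opposition is mostly from
    # elsewhere or hides its location.
    return {
        "pro": {"chicago_area": 0.57, "illinois_other": 0.11, "us_other": 0.05,
                "non_us": 0.0, "unknown": 0.27},
        "anti": {"chicago_area": 0.05, "illinois_other": 0.03, "us_other": 0.30,
                 "non_us": 0.20, "unknown": 0.42},
    }


def _default_theme_probs() -> dict:
    return {
        "pro": {"safety": 0.25, "lies_propaganda": 0.0, "science": 0.30,
                "flavor": 0.04, "regulation": 0.75, "issue_salience": 0.0},
        "anti": {"safety": 0.50, "lies_propaganda": 0.33, "science": 0.30,
                 "flavor": 0.04, "regulation": 0.25, "issue_salience": 0.02},
    }


@dataclass
class SyntheticConfig:
    """All knobs of the generator; defaults emulate a week-long mention-stream
    campaign against one agency account at roughly 2,000 tweets."""

    n_organic: int = 750
    n_astroturf: int = 25
    window_start: date = date(2014, 1, 8)
    window_end: date = date(2014, 1, 15)
    # account descriptives
    follower_median: float = 200.0
    follower_sigma: float = 1.6
    p_zero_followers: float = 0.02
    organic_ratio_median: float = 1.0
    organic_ratio_sigma: float = 0.6
    astroturf_ratio_multiplier: float = 8.0
    p_alphanum_organic: float = 0.30
    p_alphanum_astroturf: float = 0.90
    p_new_account_organic: float = 0.005
    p_new_account_astroturf: float = 0.70
    # tweet volume and cascades
    n_hubs: int = 6
    n_hub_tweets: int = 3
    hub_outdegree_min: int = 22
    hub_outdegree_max: int = 59
    mean_originals_organic: float = 1.1
    mean_originals_astroturf: float = 0.2
    p_cascade: float = 0.55
    cascade_zipf_a: float = 2.2
    cascade_cap: int = 10
    p_nonnative: float = 0.4
    p_repeat_retweet: float = 0.04
    p_retweet_same_day: float = 0.6  # cascades cluster on the source's day
    n_mutual_planted: int = 3
    # coordinated duplicate clusters (member counts are copies of one source)
    coordinated_cluster_sizes: tuple[int, ...] = (53, 24)
    p_url_variant: float = 1.0
    p_truncate_noise: float = 0.0
    # content
    p_pro_user: float = 0.12
    pro_activity_factor: float = 0.75  # pro authors tweet / get retweeted less
    p_unclear: float = 0.03
    p_leading_mention: float = 0.4
    p_hashtag: dict = field(default_factory=lambda: {"pro": 0.84, "anti": 0.29, "unclear": 0.2})
    p_url: float = 0.7
    sentiment_location_probs: dict = field(default_factory=_default_sentiment_location_probs)
    theme_probs: dict = field(default_factory=_default_theme_probs)
    burst_day_weights: tuple[float, ...] = (0.05, 0.45, 0.08, 0.06, 0.05, 0.20, 0.08, 0.03)
    seed: int = 42

    def validate(self) -> None:
        if self.n_organic < 0 or self.n_astroturf < 0:
            raise ValueError("account counts must be >= 0")
        if self.window_start > self.window_end:
            raise ValueError("window start after end")
        n_days = (self.window_end - self.window_start).days + 1
        if len(self.burst_day_weights) != n_days:
            raise ValueError(
                f"burst_day_weights has {len(self.burst_day_weights)} entries for a {n_days}-day window"
            )
        probs = [
            self.p_zero_followers, self.p_alphanum_organic, self.p_alphanum_astroturf,
            self.p_new_account_organic, self.p_new_account_astroturf, self.p_cascade,
            self.p_nonnative, self.p_repeat_retweet, self.p_retweet_same_day,
            self.p_url_variant,
            self.p_truncate_noise, self.p_pro_user, self.p_unclear,
            self.p_leading_mention, self.p_url, self.pro_activity_factor,
        ] + list(self.p_hashtag.values())
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        for row, table in self.sentiment_location_probs.items():
            if abs(sum(table.values()) - 1.0) > 1e-9:
                raise ValueError(f"sentiment_location_probs[{row!r}] does not sum to 1")
        if self.n_hubs < len(self.coordinated_cluster_sizes):
            raise ValueError("need at least one hub per coordinated cluster")
        if self.hub_outdegree_min > self.hub_outdegree_max:
            raise ValueError("hub outdegree range inverted")

    # --- YAML round-trip (dates as ISO strings) -------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["window_start"] = self.window_start.isoformat()
        d["window_end"] = self.window_end.isoformat()
        d["coordinated_cluster_sizes"] = list(self.coordinated_cluster_sizes)
        d["burst_day_weights"] = list(self.burst_day_weights)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        d = dict(d)
        for key in ("window_start", "window_end"):
            if isinstance(d.get(key), str):
                d[key] = date.fromisoformat(d[key])
        for key in ("coordinated_cluster_sizes", "burst_day_weights"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "SyntheticConfig":
        return cls.from_dict(yaml.safe_load(text) or {})


# ---------------------------------------------------------------------------
# Ground truth containers


@dataclass(frozen=True)
class AccountTruth:
    is_astroturf: bool
    high_ratio_planted: bool
    alphanum: bool
    new_account: bool


@dataclass(frozen=True)
class TweetTruth:
    status: str  # original | native_rt | nonnative_rt
    source_tweet_id: str
    source_author: str
    cluster_id: Optional[str]
    sentiment: str
    themes: frozenset[str]


@dataclass
class GroundTruth:
    accounts: dict[str, AccountTruth]
    tweets: dict[str, TweetTruth]
    coordinated_clusters: dict[str, list[str]]
    authors: dict[str, str] = field(default_factory=dict)  # tweet id -> handle

    @property
    def astroturf_handles(self) -> set[str]:
        return {h for h, a in self.accounts.items() if a.is_astroturf}

    @property
    def consistent_tweet_ids(self) -> set[str]:
        """Tweets sent by a planted astroturf account or in a planted cluster."""
        return {
            tid
            for tid, t in self.tweets.items()
            if t.cluster_id is not None
            or self.accounts[self.authors[tid]].is_astroturf
        }


@dataclass
class SyntheticDataset:
    tweets: list[TweetRecord]
    users: list[UserProfile]
    urlmap: UrlMap
    truth: GroundTruth
    config: SyntheticConfig

    def write(self, out_dir: Path) -> dict[str, Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {
            "tweets": out_dir / "tweets.jsonl",
            "users": out_dir / "users.csv",
            "urlmap": out_dir / "urlmap.tsv",
        }
        write_tweets_jsonl(self.tweets, paths["tweets"])
        write_users_csv(self.users, paths["users"])
        write_urlmap_tsv(self.urlmap, paths["urlmap"])
        return paths


# ---------------------------------------------------------------------------
# Generation


class _Draft:
    """One tweet before global ordering and id assignment."""

    __slots__ = (
        "order", "author", "ts", "text", "native_src_order", "sentiment",
        "themes", "status", "source_order", "cluster_id",
    )

    def __init__(self, order, author, ts, text, status, source_order,
                 sentiment, themes, cluster_id=None, native_src_order=None):
        self.order = order
        self.author = author
        self.ts = ts  # aware UTC datetime
        self.text = text
        self.status = status
        self.source_order = source_order  # draft order of the original
        self.cluster_id = cluster_id
        self.native_src_order = native_src_order
        self.sentiment = sentiment
        self.themes = themes


def _lognormal(rng, median: float, sigma: float, size: int) -> np.ndarray:
    return np.exp(rng.normal(np.log(median), sigma, size))


def _short_code(n: int) -> str:
    digits = "abcdefghijklmnopqrstuvwxyz0123456789"
    out = []
    n += 1
    while n:
        n, r = divmod(n, 36)
        out.append(digits[r])
    return "".join(reversed(out))


def generate(config: SyntheticConfig) -> SyntheticDataset:
    """Generate a fully labeled corpus; reproducible from ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    zone = ZoneInfo(GENERATOR_TZ)
    days = [
        config.window_start + timedelta(days=i)
        for i in range((config.window_end - config.window_start).days + 1)
    ]
    day_weights = np.asarray(config.burst_day_weights, dtype=float)
    day_weights = day_weights / day_weights.sum() if day_weights.sum() else None

    def local_ts(day: date, seconds: float) -> datetime:
        base = datetime.combine(day, time(0, 0), tzinfo=zone)
        return (base + timedelta(seconds=float(seconds))).astimezone(timezone.utc)

    def draw_day(sentiment: str, not_before: Optional[date] = None) -> date:
        if sentiment == "anti" and day_weights is not None:
            w = day_weights.copy()
        else:
            w = np.ones(len(days))
        if not_before is not None:
            for i, d in enumerate(days):
                if d < not_before:
                    w[i] = 0.0
        if w.sum() == 0:
            return days[-1]
        return days[rng.choice(len(days), p=w / w.sum())]

    # ---- accounts ------------------------------------------------------
    n_total = config.n_organic + config.n_astroturf
    if n_total == 0:
        return SyntheticDataset([], [], UrlMap(), GroundTruth({}, {}, {}), config)
    handles: list[str] = []
    seen: set[str] = set()

    def make_handle(astroturf: bool) -> str:
        for _ in range(200):
            base = _ADJ[rng.integers(len(_ADJ))] + _NOUN[rng.integers(len(_NOUN))]
            p_digits = config.p_alphanum_astroturf if astroturf else config.p_alphanum_organic
            if rng.random() < p_digits:
                n_dig = 4 if astroturf else int(rng.integers(1, 4))
                base += "".join(str(rng.integers(10)) for _ in range(n_dig))
            if base not in seen:
                seen.add(base)
                return base
        raise RuntimeError("handle space exhausted; enlarge word lists")

    is_astro = [False] * config.n_organic + [True] * config.n_astroturf
    for astro in is_astro:
        handles.append(make_handle(astro))

    followers = np.maximum(
        0, np.round(_lognormal(rng, config.follower_median, config.follower_sigma, n_total))
    ).astype(int)
    followers[rng.random(n_total) < config.p_zero_followers] = 0
    organic_ratios = _lognormal(
        rng, config.organic_ratio_median, config.organic_ratio_sigma, n_total
    )
    astro_ratios = config.astroturf_ratio_multiplier * config.organic_ratio_median * rng.uniform(
        1.0, 2.0, n_total
    )
    ratios = np.where(is_astro, astro_ratios, organic_ratios)
    following = np.round(ratios * np.maximum(followers, 1)).astype(int)
    statuses = np.maximum(2, np.round(_lognormal(rng, 1000.0, 1.5, n_total))).astype(int)

    window_days = (config.window_end - config.window_start).days
    oldest = date(2007, 3, 11)
    created: list[date] = []
    new_flags: list[bool] = []
    for i in range(n_total):
        p_new = config.p_new_account_astroturf if is_astro[i] else config.p_new_account_organic
        if rng.random() < p_new:
            created.append(config.window_start + timedelta(days=int(rng.integers(window_days + 1))))
            new_flags.append(True)
        else:
            span = (config.window_start - oldest).days
            created.append(oldest + timedelta(days=int(rng.integers(max(span, 1)))))
            new_flags.append(False)

    stances: list[str] = []
    locations: list[str] = []
    for i in range(n_total):
        stance = "anti" if is_astro[i] else ("pro" if rng.random() < config.p_pro_user else "anti")
        stances.append(stance)
        loc_table = config.sentiment_location_probs[stance]
        probs = np.array([loc_table.get(c, 0.0) for c in LOCATION_ORDER])
        cat = LOCATION_ORDER[rng.choice(len(LOCATION_ORDER), p=probs / probs.sum())]
        pool = _LOCATION_STRINGS[cat]
        locations.append(pool[rng.integers(len(pool))])

    users = [
        UserProfile(
            handle=handles[i],
            followers=int(followers[i]),
            following=int(following[i]),
            statuses=int(statuses[i]),
            created=created[i],
            location_raw=locations[i],
            location_category=categorize_location(locations[i]),
        )
        for i in range(n_total)
    ]

    account_truth = {
        handles[i]: AccountTruth(
            is_astroturf=bool(is_astro[i]),
            high_ratio_planted=bool(is_astro[i]),
            alphanum=any(c.isdigit() for c in handles[i]),
            new_account=new_flags[i],
        )
        for i in range(n_total)
    }

    # ---- originals -----------------------------------------------------
    anti_organic = [i for i in range(config.n_organic) if stances[i] == "anti"]
    if len(anti_organic) < config.n_hubs:
        raise ValueError("not enough anti-stance organic users to seat the hubs")
    hub_idx = list(rng.choice(anti_organic, size=config.n_hubs, replace=False))

    drafts: list[_Draft] = []
    urlmap: dict[str, str] = {}
    next_url = [0]

    def fresh_url(dest: Optional[str] = None) -> str:
        code = _short_code(next_url[0])
        next_url[0] += 1
        short = f"http://t.co/{code}"
        urlmap[short] = dest or f"http://example.org/page/{code}"
        return short

    def tweet_text(idx: int, sentiment: str, url: Optional[str]) -> str:
        pool = _SLOGANS[sentiment]
        slogan = pool[rng.integers(len(pool))]
        parts = []
        leading = rng.random() < config.p_leading_mention
        if leading:
            parts.append(f"@{AGENCY_HANDLE}")
        parts.append(slogan)
        if not leading:
            parts.append(f"@{AGENCY_HANDLE}")
        if rng.random() < config.p_hashtag.get(sentiment, 0.0):
            parts.append("#ecigtruths")
        parts.append(f"m{idx}")
        if url:
            parts.append(url)
        return " ".join(parts)

    def add_original(author_i: int, force_url: bool = False) -> _Draft:
        order = len(drafts)
        sentiment = stances[author_i]
        if rng.random() < config.p_unclear:
            sentiment = "unclear"
        theme_row = config.theme_probs.get(sentiment, {})
        themes = frozenset(t for t, p in theme_row.items() if rng.random() < p)
        url = fresh_url() if (force_url or rng.random() < config.p_url) else None
        day = draw_day(sentiment)
        ts = local_ts(day, rng.uniform(0, 86_399))
        d = _Draft(order, handles[author_i], ts, tweet_text(order, sentiment, url),
                   "original", order, sentiment, themes)
        drafts.append(d)
        return d

    hub_originals: dict[int, list[_Draft]] = {}
    for h in hub_idx:
        hub_originals[h] = [add_original(h, force_url=True) for _ in range(config.n_hub_tweets)]

    organic_originals: dict[int, list[_Draft]] = {}
    for i in range(n_total):
        if i in hub_idx:
            continue
        mean = config.mean_originals_astroturf if is_astro[i] else config.mean_originals_organic
        if stances[i] == "pro":
            mean *= config.pro_activity_factor
        n = int(rng.poisson(mean))
        if n:
            organic_originals[i] = [add_original(i) for _ in range(n)]

    # ---- retweet events ------------------------------------------------
    def retweet_ts(src: _Draft) -> datetime:
        src_local = src.ts.astimezone(zone)
        if rng.random() < config.p_retweet_same_day:
            day = src_local.date()
        else:
            day = draw_day(src.sentiment, not_before=src_local.date())
        if day == src_local.date():
            start_s = (src_local - datetime.combine(day, time(0, 0), tzinfo=zone)).total_seconds() + 1
        else:
            start_s = 0.0
        ts = local_ts(day, rng.uniform(min(start_s, 86_398), 86_399))
        if ts <= src.ts:  # source sat in the final seconds of its day
            ts = src.ts + timedelta(seconds=float(rng.uniform(1, 60)))
        return ts

    def truncate(text: str) -> str:
        cut = int(len(text) * rng.uniform(0.8, 0.97))
        return text[:cut].rstrip() + "…"

    def add_retweet(src: _Draft, retweeter_i: int, *, coordinated: bool = False,
                    cluster_id: Optional[str] = None, cluster_dest: Optional[str] = None,
                    force_native: bool = False) -> _Draft:
        order = len(drafts)
        ts = retweet_ts(src)
        if coordinated:
            text = src.text
            if rng.random() < config.p_url_variant:
                new_short = fresh_url(dest=cluster_dest)
                src_urls = [tok for tok in src.text.split() if "://" in tok]
                if src_urls:
                    text = src.text.replace(src_urls[0], new_short)
                else:
                    text = src.text + " " + new_short
            d = _Draft(order, handles[retweeter_i], ts, text, "nonnative_rt",
                       src.order, src.sentiment, src.themes, cluster_id=cluster_id)
        else:
            native = force_native or rng.random() >= config.p_nonnative
            text = f"RT @{src.author}: {src.text}"
            if not native and rng.random() < config.p_truncate_noise:
                text = truncate(text)
            d = _Draft(order, handles[retweeter_i], ts, text,
                       "native_rt" if native else "nonnative_rt", src.order,
                       src.sentiment, src.themes,
                       native_src_order=src.order if native else None,
                       cluster_id=src.cluster_id if coordinated else None)
        drafts.append(d)
        return d

    handle_to_idx = {h: i for i, h in enumerate(handles)}
    coordinated_clusters: dict[str, list[int]] = {}  # cluster id -> draft orders
    astro_pool = list(range(config.n_organic, n_total))

    for c_i, size in enumerate(config.coordinated_cluster_sizes):
        hub = hub_idx[c_i]
        src = hub_originals[hub][0]
        cluster_id = f"cluster{c_i}"
        dest = f"http://example.org/campaign/{c_i}"
        # the source's own URL also points at the campaign destination
        src_urls = [tok for tok in src.text.split() if "://" in tok]
        if src_urls:
            urlmap[src_urls[0]] = dest
        senders: list[int] = [i for i in astro_pool if i != hub]
        rng.shuffle(senders)
        organics = [i for i in range(config.n_organic) if i != hub]
        extra = list(rng.choice(organics, size=max(0, size - len(senders)), replace=False))
        senders = (senders + extra)[:size]
        members = [src.order]
        for s in senders:
            d = add_retweet(src, s, coordinated=True, cluster_id=cluster_id, cluster_dest=dest)
            members.append(d.order)
        src.cluster_id = cluster_id
        coordinated_clusters[cluster_id] = members

    # hub cascades beyond the coordinated copies; a hub seating a planted
    # cluster keeps that original out of further cascades so the cluster
    # membership stays exactly as planted
    for h_i, hub in enumerate(hub_idx):
        has_cluster = h_i < len(config.coordinated_cluster_sizes)
        target = int(rng.integers(config.hub_outdegree_min, config.hub_outdegree_max + 1))
        already = len(coordinated_clusters[f"cluster{h_i}"]) - 1 if has_cluster else 0
        if already:
            target = min(already + int(rng.integers(3, 7)), config.hub_outdegree_max)
        n_more = max(0, target - already)
        used = (
            {drafts[o].author for o in coordinated_clusters[f"cluster{h_i}"]}
            if has_cluster
            else set()
        )
        sources = hub_originals[hub][1:] if has_cluster else hub_originals[hub]
        if not sources:
            continue
        candidates = [i for i in range(n_total) if i != hub and handles[i] not in used]
        chosen = list(rng.choice(candidates, size=min(n_more, len(candidates)), replace=False))
        for r in chosen:
            src = sources[int(rng.integers(len(sources)))]
            add_retweet(src, r)

    # ordinary cascades on organic originals; distinct retweeters per non-hub
    # author stay at or below cascade_cap so the hubs dominate outdegree
    for i, originals in organic_originals.items():
        author_retweeters: set[str] = set()
        for src in originals:
            p_casc = config.p_cascade
            if src.sentiment == "pro":
                p_casc *= config.pro_activity_factor
            if rng.random() >= p_casc:
                continue
            size = int(min(rng.zipf(config.cascade_zipf_a), config.cascade_cap))
            size = min(size, config.cascade_cap - len(author_retweeters))
            if size <= 0:
                continue
            candidates = [
                j for j in range(n_total) if j != i and handles[j] not in author_retweeters
            ]
            chosen = list(rng.choice(candidates, size=min(size, len(candidates)), replace=False))
            for r in chosen:
                author_retweeters.add(handles[r])
                add_retweet(src, r)
                if rng.random() < config.p_repeat_retweet:
                    add_retweet(src, r)  # same retweeter, second event

    # planted mutual ties: a hub natively retweets one of its retweeters
    planted_mutual = 0
    for hub in hub_idx:
        if planted_mutual >= config.n_mutual_planted:
            break
        hub_handle = handles[hub]
        retweeter_handles = {
            d.author for d in drafts
            if d.status != "original" and drafts[d.source_order].author == hub_handle
        }
        for r_handle in sorted(retweeter_handles):
            r_i = handle_to_idx[r_handle]
            back = organic_originals.get(r_i) or []
            if back:
                add_retweet(back[0], hub, force_native=True)
                planted_mutual += 1
                break

    # ---- finalise: global order, ids, records --------------------------
    ordered = sorted(drafts, key=lambda d: (d.ts, d.order))
    width = max(5, len(str(len(ordered))))
    final_id = {d.order: f"t{idx:0{width}d}" for idx, d in enumerate(ordered, start=1)}

    tweets: list[TweetRecord] = []
    tweet_truth: dict[str, TweetTruth] = {}
    authors_by_id: dict[str, str] = {}
    for d in ordered:
        tid = final_id[d.order]
        native = None
        if d.native_src_order is not None:
            native = (final_id[d.native_src_order], drafts[d.native_src_order].author)
        tweets.append(
            TweetRecord(
                tweet_id=tid,
                timestamp=d.ts,
                author=d.author,
                text=d.text,
                native_retweet_of=native,
                sentiment=d.sentiment,
                themes=d.themes,
            )
        )
        src = drafts[d.source_order]
        tweet_truth[tid] = TweetTruth(
            status=d.status,
            source_tweet_id=final_id[d.source_order],
            source_author=src.author,
            cluster_id=d.cluster_id,
            sentiment=d.sentiment,
            themes=d.themes,
        )
        authors_by_id[tid] = d.author

    truth = GroundTruth(
        accounts=account_truth,
        tweets=tweet_truth,
        coordinated_clusters={
            cid: sorted(final_id[o] for o in orders)
            for cid, orders in coordinated_clusters.items()
        },
        authors=authors_by_id,
    )

    logger.info(
        "generated %d tweets by %d users (%d astroturf), %d coordinated cluster(s)",
        len(tweets), n_total, config.n_astroturf, len(coordinated_clusters),
    )
    return SyntheticDataset(tweets, users, UrlMap(urlmap), truth, config)


# ---------------------------------------------------------------------------
# Recovery evaluation


@dataclass
class RecoveryMetrics:
    account_tp: int
    account_fp: int
    account_fn: int
    account_tn: int
    account_precision: Optional[float]
    account_recall: Optional[float]
    tweet_tp: int
    tweet_fp: int
    tweet_fn: int
    tweet_precision: Optional[float]
    tweet_recall: Optional[float]


def _safe_div(num: int, den: int) -> Optional[float]:
    return num / den if den else None


def evaluate_recovery(report: AstroturfReport, truth: GroundTruth) -> RecoveryMetrics:
    """Confusion counts and precision/recall for planted accounts and tweets.

    Undefined ratios (zero denominator) are reported as ``None``, never 0.
    """
    report_handles = {i.handle for i in report.indicators}
    if report_handles != set(truth.accounts):
        missing = set(truth.accounts) ^ report_handles
        raise ValueError(f"report/truth handle mismatch (e.g. {sorted(missing)[:5]})")
    likely = report.likely_handles
    planted = truth.astroturf_handles
    tp = len(likely & planted)
    fp = len(likely - planted)
    fn = len(planted - likely)
    tn = len(report_handles) - tp - fp - fn

    flagged = {f.tweet_id for f in report.tweet_flags}
    true_tweets = truth.consistent_tweet_ids
    t_tp = len(flagged & true_tweets)
    t_fp = len(flagged - true_tweets)
    t_fn = len(true_tweets - flagged)
    return RecoveryMetrics(
        account_tp=tp, account_fp=fp, account_fn=fn, account_tn=tn,
        account_precision=_safe_div(tp, tp + fp),
        account_recall=_safe_div(tp, tp + fn),
        tweet_tp=t_tp, tweet_fp=t_fp, tweet_fn=t_fn,
        tweet_precision=_safe_div(t_tp, t_tp + t_fp),
        tweet_recall=_safe_div(t_tp, t_tp + t_fn),
    )


def evaluate_attribution(
    resolution: Sequence[RetweetResolution], truth: GroundTruth
) -> float:
    """Fraction of tweets whose resolved status, source author and source
    tweet id all match the generator's ground truth."""
    if not resolution:
        return 1.0
    ok = 0
    for res in resolution:
        t = truth.tweets[res.tweet_id]
        if (
            res.status == t.status
            and res.source_author == t.source_author
            and (res.source_tweet_id is None or res.source_tweet_id == t.source_tweet_id)
        ):
            ok += 1
    return ok / len(resolution)
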