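"""End-to-end orchestration: corpus in, report tables out.

Runs the full forensic sequence — retweet resolution, URL-variant cluster
detection, network construction and tie classification, astroturf scoring,
content tabulation and the sentiment × location test — and optionally
writes every report as deterministic plain-text artifacts (identical inputs
always produce byte-identical files).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Optional, Sequence

import networkx as nx
import pandas as pd

from . import network_analysis as net
from .astroturf_scoring import (
    AstroturfReport,
    TweetFlag,
    flag_astroturf_tweets,
    score_accounts,
    write_astroturf_csv,
    write_astroturf_tweets_csv,
)
from .corpus_io import TweetRecord, UrlMap, UserProfile
from .retweet_resolution import (
    DuplicateCluster,
    RetweetResolution,
    detect_url_variant_clusters,
    resolve_retweets,
)
from .tabulation_stats import (
    ContingencyResult,
    REPORTING_TZ_DEFAULT,
    chi_square_location,
    round_pct,
    sentiment_summary,
    theme_table,
    timeline,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    resolution: list[RetweetResolution]
    clusters: list[DuplicateCluster]
    network: nx.DiGraph
    centrality: net.CentralityReport
    astroturf: AstroturfReport
    tweet_flags: list[TweetFlag]
    sentiment: dict
    themes: pd.DataFrame
    timeline: pd.DataFrame
    contingency: Optional[ContingencyResult]
    contingency_error: Optional[str] = None

    def summary(self) -> dict:
        n = sum(1 for r in self.resolution)
        n_rt = sum(1 for r in self.resolution if r.status != "original")
        out = {
            "n_tweets": n,
            "n_originals": n - n_rt,
            "n_retweets": n_rt,
            "pct_retweets": round_pct(100.0 * n_rt / n) if n else 0.0,
            "n_users": int(self.centrality.per_node.shape[0]),
            "n_asymmetric_ties": self.centrality.n_asymmetric,
            "n_mutual_ties": self.centrality.n_mutual,
            "n_isolates": self.centrality.n_isolates,
            "n_url_variant_clusters": sum(1 for c in self.clusters if c.url_variant_cluster),
            "n_accounts_any_indicator": self.astroturf.n_accounts_any_indicator,
            "n_accounts_likely_astroturf": self.astroturf.n_accounts_likely,
            "n_tweets_astroturf_consistent": self.astroturf.n_tweets_consistent,
            "sentiment": self.sentiment,
        }
        if self.contingency is not None:
            out["chi2"] = round(self.contingency.chi2, 4)
            out["chi2_df"] = self.contingency.df
            out["chi2_p"] = float(f"{self.contingency.p_value:.3e}")
        return out


def infer_window(tweets: Sequence[TweetRecord], tz: str = REPORTING_TZ_DEFAULT) -> tuple[date, date]:
    from zoneinfo import ZoneInfo

    zone = ZoneInfo(tz)
    days = [t.timestamp.astimezone(zone).date() for t in tweets]
    return (min(days), max(days)) if days else (date.today(), date.today())


def run_pipeline(
    tweets: Sequence[TweetRecord],
    users: Sequence[UserProfile],
    urlmap: UrlMap,
    window: Optional[tuple[date, date]] = None,
    tz: str = REPORTING_TZ_DEFAULT,
    z_threshold: float = 1.96,
    min_indicators: int = 2,
    drop_unclear: bool = True,
    out_dir: Optional[Path] = None,
) -> PipelineResult:
    """Run every analysis stage; write report artifacts if ``out_dir`` given."""
    if window is None:
        window = infer_window(tweets, tz)
    resolution = resolve_retweets(tweets)
    clusters = detect_url_variant_clusters(tweets, resolution, urlmap)
    authors = {t.author for t in tweets} | {u.handle for u in users}
    network = net.build_network(resolution, authors)
    centrality = net.centrality_report(network)
    astro = score_accounts(users, window, z_threshold, min_indicators)
    flags = flag_astroturf_tweets(astro, resolution, clusters)
    senti = sentiment_summary(tweets)
    themes = theme_table(tweets, resolution)
    tl = timeline(tweets, resolution, window, tz)
    contingency: Optional[ContingencyResult] = None
    cont_err: Optional[str] = None
    try:
        contingency = chi_square_location(tweets, users, drop_unclear=drop_unclear)
    except ValueError as exc:
        cont_err = str(exc)
        logger.warning("sentiment × location test skipped: %s", exc)

    result = PipelineResult(
        resolution=resolution,
        clusters=clusters,
        network=network,
        centrality=centrality,
        astroturf=astro,
        tweet_flags=flags,
        sentiment=senti,
        themes=themes,
        timeline=tl,
        contingency=contingency,
        contingency_error=cont_err,
    )
    if out_dir is not None:
        write_reports(result, Path(out_dir))
    return result


def _json_dump(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n", encoding="utf-8")


def write_reports(result: PipelineResult, out_dir: Path) -> dict[str, Path]:
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    p = paths["resolution"] = out_dir / "resolution.csv"
    with open(p, "w", encoding="utf-8") as fh:
        fh.write("tweet_id,author,status,source_author,source_tweet_id,canonical_hash\n")
        for r in sorted(result.resolution, key=lambda r: r.tweet_id):
            import hashlib

            h = hashlib.sha1(r.canonical_text.encode("utf-8")).hexdigest()[:12]
            fh.write(
                f"{r.tweet_id},{r.author},{r.status},{r.source_author},{r.source_tweet_id or ''},{h}\n"
            )

    p = paths["clusters"] = out_dir / "clusters.json"
    _json_dump(
        [
            {
                "canonical_text": c.canonical_text,
                "members": c.members,
                "n_url_variants": c.n_url_variants,
                "same_destination": c.same_destination,
                "url_variant_cluster": c.url_variant_cluster,
            }
            for c in result.clusters
        ],
        p,
    )

    paths["pajek"] = out_dir / "retweet_network.net"
    net.write_pajek(result.network, paths["pajek"])
    paths["graphml"] = out_dir / "retweet_network.graphml"
    net.write_graphml(result.network, paths["graphml"])
    paths["centrality"] = out_dir / "centrality.csv"
    net.write_centrality_csv(result.centrality, paths["centrality"])

    paths["astroturf"] = out_dir / "astroturf.csv"
    write_astroturf_csv(result.astroturf, paths["astroturf"])
    paths["astroturf_tweets"] = out_dir / "astroturf_tweets.csv"
    write_astroturf_tweets_csv(result.tweet_flags, paths["astroturf_tweets"])

    p = paths["sentiment"] = out_dir / "sentiment_summary.json"
    _json_dump(result.sentiment, p)
    p = paths["themes"] = out_dir / "theme_table.csv"
    result.themes.to_csv(p)
    p = paths["timeline"] = out_dir / "timeline.csv"
    result.timeline.to_csv(p, index=False)

    p = paths["contingency"] = out_dir / "contingency.json"
    if result.contingency is not None:
        c = result.contingency
        _json_dump(
            {
                "observed": {r: c.observed.loc[r].to_dict() for r in c.observed.index},
                "expected": {r: c.expected.loc[r].round(6).to_dict() for r in c.expected.index},
                "chi2": round(c.chi2, 6),
                "df": c.df,
                "p_value": float(f"{c.p_value:.6e}"),
                "pearson_residuals": {
                    r: c.pearson_residuals.loc[r].round(6).to_dict()
                    for r in c.pearson_residuals.index
                },
                "adjusted_residuals": {
                    r: c.adjusted_residuals.loc[r].round(6).to_dict()
                    for r in c.adjusted_residuals.index
                },
                "n_cells_expected_lt5": c.n_cells_expected_lt5,
            },
            p,
        )
    else:
        _json_dump({"error": result.contingency_error}, p)

    p = paths["summary"] = out_dir / "summary.json"
    _json_dump(result.summary(), p)
    return paths
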