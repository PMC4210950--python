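"""Resolve manual retweets and spot a URL-variant duplicate cluster.

Five accounts repost one message, each under a different shortened URL that
expands to the same destination — the spam-evasion pattern that marks a
tweet as astroturf-consistent even when the account itself looks organic.
"""

from datetime import datetime, timedelta, timezone

from astroturf_scan import TweetRecord, UrlMap, detect_url_variant_clusters, resolve_retweets

t0 = datetime(2014, 1, 9, 15, 0, tzinfo=timezone.utc)
source = TweetRecord("t01", t0, "hubuser",
                     "please review all of the science #ecigtruths http://sh.rt/a")
copies = [
    TweetRecord(f"t{i + 2:02d}", t0 + timedelta(minutes=i + 1), f"helper{i}",
                f"please review all of the science #ecigtruths http://sh.rt/{c}")
    for i, c in enumerate("bcdef")
]
manual_rt = TweetRecord("t99", t0 + timedelta(hours=2), "fan",
                        "RT @hubuser: please review all of the science #ecigtruths http://sh.rt/a")
corpus = [source, *copies, manual_rt]

urlmap = UrlMap({f"http://sh.rt/{c}": "http://journal.example/article" for c in "abcdef"})

resolution = resolve_retweets(corpus)
for r in resolution:
    print(f"{r.tweet_id}: {r.status:12s} source={r.source_author}")

clusters = detect_url_variant_clusters(corpus, resolution, urlmap)
for c in clusters:
    print(f"\ncluster of {len(c.members)} tweets, {c.n_url_variants} URL variants, "
          f"same destination: {c.same_destination} -> flagged: {c.url_variant_cluster}")

# All seven tweets share one canonical text, so six are attributed to
# hubuser; six distinct short URLs resolving to one page flag the cluster.
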