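"""Generate the default synthetic campaign corpus and look at its shape.

The generator plants a coordinated astroturf cell, six retweet hubs and two
duplicate clusters inside an organic mention stream, and returns the ground
truth alongside the corpus.
"""

from collections import Counter

from astroturf_scan import SyntheticConfig, generate

config = SyntheticConfig(seed=42)
dataset = generate(config)

statuses = Counter(t.status for t in dataset.truth.tweets.values())
sentiments = Counter(t.sentiment for t in dataset.tweets)
n = len(dataset.tweets)

print(f"tweets: {n} by {len(dataset.users)} users "
      f"({len(dataset.truth.astroturf_handles)} planted astroturf accounts)")
print(f"statuses: {dict(statuses)}")
print(f"sentiment: " + ", ".join(f"{s}={c} ({100 * c / n:.1f}%)"
                                 for s, c in sentiments.most_common()))
for cid, members in dataset.truth.coordinated_clusters.items():
    print(f"planted {cid}: {len(members)} tweets differing only by shortened URL")

# The corpus is written as plain-text files any stage can re-read.
paths = dataset.write("scratch/example_corpus")
print("wrote:", ", ".join(str(p) for p in paths.values()))

# A ~9:1 anti:pro skew, a majority of retweets, and two URL-variant clusters
# are the structural signature the analysis stages are asked to recover.
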