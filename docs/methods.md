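# Methods

This note documents the models, rules and numerical choices behind
`astroturf-scan`: what each stage assumes, which parameters matter, what
the synthetic corpus generator does and does not emulate, and where the
design was genuinely open.

## Data model and input conventions

A corpus is a JSON-Lines tweet stream, a CSV user-profile table and an
optional TSV short-URL → destination map. Handles are normalised to
lowercase without `@` everywhere (platform handles are case-insensitive);
timestamps are normalised to UTC on read. URLs, hashtags and mentions are
always re-derived from the tweet text with conservative patterns (URLs
require an explicit `scheme://`; trailing punctuation is stripped), so
entity lists can never drift out of sync with the text. Day binning for
timelines uses a configurable reporting timezone, default
`America/Chicago`, because campaign days are defined by local time: a
tweet at 23:30 local is past midnight UTC but belongs to its local day.

Free-text profile locations map to five categories — `chicago_area`,
`illinois_other`, `us_other`, `non_us`, `unknown` — via an editable YAML
gazetteer. Matching is whole-word, case-insensitive, longest keyword
first, with category precedence `chicago_area` > `illinois_other` >
`us_other` > `non_us`; blank or unmatched strings ("a galaxy far far
away") fall to `unknown`. Two-letter state abbreviations that collide with
common English words (IN, OR, ME, OK, HI, DE, OH, AL) are deliberately
omitted from the shipped gazetteer; users who need them can supply their
own lists.

## Retweet resolution

Tweets with native retweet metadata are classified from it directly. For
the rest, duplicate detection rests on text canonicalisation with a fixed
rule order:

1. strip any number of leading `RT @handle:` / `MT @handle:` prefixes;
2. mask every URL token with a fixed placeholder;
3. remove a trailing truncation ellipsis (`…` or `...`); when one was
   present, also drop a final token that is a clipped URL fragment
   (`htt…`, `http:/…`) — such fragments only become recognisable once the
   ellipsis reveals truncation;
4. lowercase;
5. collapse whitespace.

Masking URLs before lowercasing is safe because URLs are wholly replaced;
the function is idempotent. Tweets without native metadata are grouped by
exact canonical text; within a group the earliest tweet (ties broken by
ascending tweet id) is the original and the rest are non-native retweets
attributed to it. Exact matching was chosen over fuzzy similarity because
manual copies differ only by prefix, swapped URL or client truncation, and
fuzzy thresholds would be arbitrary. Truncated copies whose canonical text
is a strict prefix of exactly one longer group, covering at least 0.8 of
it, are merged into that group; an ambiguous prefix (several candidate
groups) is left unmerged with a warning rather than guessed.

A duplicate cluster (≥ 2 members sharing canonical text) is a
**URL-variant cluster** when its members carry at least two distinct raw
URL tokens and the URL map does not prove they lead to different places:
`same_destination` is *yes* only if every member URL resolves to one
destination, *no* if two destinations are observed, and *unresolved* when
any lookup is unmapped — absence of a map entry is treated as missing
evidence, never as evidence of difference.

## Retweet network

The network is a directed graph with an edge source → retweeter per
retweet relationship, weight = number of events. Outdegree counts
*distinct* retweeters, kept separate from event totals, so "69 retweets
from 59 unique users" is outdegree 59 with out-events 69. Self-retweets
are dropped (they carry no dissemination information). An unordered pair
is a mutual tie iff edges run both ways; an ordered edge is asymmetric iff
its reverse is absent, giving the bookkeeping identity
`n_asymmetric + 2·n_mutual = ordered edges`, which is property-tested
against an O(n²) brute-force oracle. Mutual pairs are listed explicitly
because in campaign forensics the handful of reciprocal ties is worth
inspecting by hand. Exports are Pajek `.net` (1-indexed vertices, weighted
arcs) and GraphML, both with sorted nodes and edges for byte-stable
output.

## Astroturf scoring

Three indicators per account:

* **high ratio** — following ÷ max(followers, 1), standardised with the
  *population* standard deviation over the entire observed account set
  (the account set under study is the population, not a sample), flagged
  at z ≥ 1.96. The threshold and the population-SD choice are both
  configurable. Zero spread yields all-zero z-scores and a warning rather
  than a division error.
* **alphanumeric handle** — at least one ASCII letter and one digit,
  underscores ignored.
* **new account** — created inside the (inclusive) analysis window, which
  is a parameter; a missing creation date leaves the flag unset with a
  per-account warning.

An account with ≥ 2 indicators (configurable) is likely astroturf. At the
tweet level the package reports an explicit, documented union rule: a
tweet is astroturf-consistent iff its author is likely astroturf **or**
the tweet belongs to a URL-variant cluster, and every flag cites its
evidence (`account`, `url_variant`, or both). This union is this
package's operationalisation of "account or tweet strategy consistent
with astroturfing"; other definitions are possible and the evidence lists
make reclassification cheap.

## Content tables and the location test

Sentiment shares and all percentages are printed to one decimal with
half-up rounding. The theme table counts a tweet once per assigned theme
(multi-theme tweets appear in several rows) and splits each cell into
originals and retweets using the resolution. The sentiment × location
chi-square is Pearson's test without continuity correction; the "unclear"
row is dropped by default, giving a 2 × 5 table and df = 4 (keeping it
gives df = 8; both are available). Location columns entirely absent from
the corpus are dropped with a warning before testing; a zero margin in the
retained table raises an error. Cells with expected counts below 5 are
counted and reported. Both Pearson and adjusted standardized residuals are
returned; the adjusted form divides by `√(E(1−row/N)(1−col/N))` and is the
one to read for cell-level significance.

## Synthetic corpus generator

The generator emulates a week-long mention stream aimed at one agency
account. Default conditions (all configurable, all driven by one seed):

* **scale** — 750 organic + 25 astroturf accounts producing ≈ 2,000 tweets
  over an 8-day window (Jan 8–15, 2014, Chicago time);
* **accounts** — followers log-normal (median 200, σ = 1.6, a few
  zero-follower accounts), organic ratios log-normal (median 1, σ = 0.6);
  astroturf ratios 8–16× the organic median, digit-suffixed handles with
  probability 0.9 (vs 0.3 for organics, where mixed handles are common and
  legitimate), in-window creation dates with probability 0.7 (vs 0.005);
* **cascades** — six hub authors drawing 22–59 distinct retweeters each;
  every other author is capped at 10 distinct retweeters, reproducing the
  hub-dominated outdegree landscape. Ordinary cascade sizes are Zipf
  (a = 2.2) capped at 10; 40% of ordinary retweets are manual `RT @user:`
  copies, the rest native with metadata; occasional repeat retweets
  exercise edge weights; three reciprocal ties are planted so mutual-tie
  code paths are exercised while the network stays overwhelmingly
  asymmetric;
* **coordination** — two duplicate clusters of 53 and 24 copies of a hub
  original, every copy swapping in a fresh shortened URL mapped to one
  destination, sent preferentially by the astroturf cell;
* **content** — 12% of organic users are pro-policy, but pro authors tweet
  and are retweeted at 0.75× the anti rate, yielding the ~9:1 anti:pro
  tweet skew with ~2–3% "unclear"; location is drawn conditionally on
  stance (pro mostly Chicago, anti mostly elsewhere/unknown), which the
  chi-square then detects; anti traffic is concentrated on two burst days
  (days 2 and 6 of the window), and retweets fall on their source's day
  with probability 0.6;
* **texts** — template strings with a unique per-message token, a mention
  of the agency (leading with probability 0.4), the campaign hashtag and
  an optional short URL. Sufficient for canonicalisation, entity and
  hashtag logic; deliberately not linguistically realistic.

Ground truth records every account's planted role and every tweet's true
status, source and cluster membership. With text noise off, retweet
resolution recovers this truth exactly; an optional truncation-noise
parameter clips manual copies to exercise the prefix-merge path, under
which attribution degrades gracefully instead of failing.

What the generator does **not** emulate: real language (so nothing here
validates canonicalisation against paraphrase or quote-tweets), organic
virality dynamics, follower-graph structure (retweeters are sampled from
the user pool, not from followers), deleted or protected accounts, and
label noise in the human coding. Passing tests therefore demonstrate that
the pipeline's logic is correct under the stated structural assumptions,
not that the indicators are optimal discriminators on live data.

## Evaluation sizes and numerical choices

The shipped checks use: 1,000 random directed graphs (≤ 50 nodes) for tie
bookkeeping, 500 random tables for chi-square oracle agreement (tolerance
1e-9), 100 seeded generator replicates for account precision/recall
(each ≥ 0.9 on average at the default settings above), and repeated full
pipeline runs compared byte-for-byte for determinism. All randomness flows
from explicit integer seeds; report files sort keys and rows so identical
inputs always produce identical bytes. Ratios with zero denominators
(precision with nothing flagged) are reported as undefined, never as 0.

## Known limitations

* Exact canonical matching misses paraphrased or quote-tweet duplication
  by design; near-duplicate detection (MinHash, embeddings) is out of
  scope.
* The z ≥ 1.96 gate is corpus-relative: a corpus dominated by
  high-ratio accounts raises the mean and hides individually extreme
  accounts. The threshold is a parameter for exactly this reason.
* The tweet-level astroturf-consistency rule is a documented union, not an
  estimate of a latent "coordinated" label; its counts should be read as
  "tweets carrying at least one concrete piece of evidence".
* URL expansion comes solely from the supplied map; no network resolution
  is performed, and unmapped URLs leave clusters in the `unresolved`
  state.
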