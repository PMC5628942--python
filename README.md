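# tweetwatch

Threshold-based early-warning signal detection for mass-casualty events
from social-media activity streams.

The pipeline: ingest newline-delimited JSON tweet streams, filter them
with a boolean keyword query language, aggregate onset-anchored
tweets-per-minute series, compute first-hour cumulative milestone
statistics and stream summaries, and detect threshold-crossing alerts
whose timing is compared against official notification marks (first 911
call, county disaster page, hospital standby, patient arrival).  A
synthetic-stream generator provides calibrated event and control
streams for end-to-end validation.

## Modules

| module              | role |
|---------------------|------|
| `tweetwatch.ingest` | read/validate/deduplicate NDJSON streams, rate-limit notice accounting, pre-onset clipping, event configuration |
| `tweetwatch.rules`  | parse and evaluate the boolean keyword query language; joint event+location matching |
| `tweetwatch.signal` | per-minute binning, milestone statistics, cross-event medians, summaries, threshold alert detection with lead times |
| `tweetwatch.synth`  | inhomogeneous-Poisson burst simulation (thinning), retweet/follower/text marks, control streams, named presets |
| `tweetwatch.report` | CLI and file outputs (CSV/JSON/NDJSON, optional PNG), run manifests |

## Input formats

Streams are newline-delimited JSON, optionally gzip-compressed (detected
by magic bytes).  The canonical flat schema per line:

```json
{"id": "t1", "posted_at": "2016-02-07T18:30:05Z", "text": "...",
 "user_id": "u1", "follower_count": 120, "is_retweet": false,
 "retweeted_id": null, "retweet_count": 0, "geo": [37.77, -122.42]}
```

`posted_at` must carry an explicit UTC offset (or `Z`); naive
timestamps are counted as malformed.  An activity-stream dialect is
also accepted best-effort (`postedTime`, `body`, `actor.id`,
`actor.followersCount`, `verb == "share"` marking a repost of
`object.id`).  A rate-limit notice line `{"limit": {"track": N}}`
yields no tweet but adds `N` to the missed-message tally.

Event configuration is YAML or JSON:

```yaml
name: ne
onset: 2014-08-24 03:20:44     # local civil time
timezone: America/Los_Angeles  # IANA name; ambiguous/nonexistent onsets rejected
horizon_minutes: 720
rules:
  - "Earthquake (San Francisco OR 'sf' OR Napa OR '6.0')"
timeline:
  first_911_call: 2014-08-24 03:21:30     # naive -> event timezone
  county_disaster_page: 2014-08-24T10:40:00Z
```

### Rule language

A space between operands means AND, an uppercase standalone `OR`
separates alternatives, parentheses group, and quoted spans match as
exact consecutive-token phrases.  Matching is case-insensitive over
letter/digit tokens (`#sf` matches `sf`; `'214'` does not match
`62148`).  A multi-word OR alternative such as `finish line` is treated
as a phrase.  Bundled rule/keyword fixtures live in
`src/tweetwatch/data/`.

## CLI

```sh
tweetwatch analyze --config event.yaml --out out/ stream.ndjson ...
tweetwatch detect  --config event.yaml --threshold 200 --out out/ stream.ndjson
tweetwatch simulate --preset ne --seed 7 --out ne.ndjson     # + .meta.json sidecar
tweetwatch report-medians                                    # bundled milestone table
```

Every run writes a `manifest.json` listing inputs, parameters and
artifacts; re-running reproduces numeric outputs byte-for-byte.
Binning is 1-based and half-open (minute m covers
`[onset+(m-1)·60s, onset+m·60s)`); an alert fires at the end of the
first minute whose count reaches the threshold.

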