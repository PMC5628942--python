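"""Synthetic tweet-stream generation for pipeline validation.

Streams are drawn from an inhomogeneous Poisson process whose intensity
is a background rate plus a single-timescale pulse

    lambda(t) = background + (peak - background) * (t/tau) * exp(1 - t/tau)

with ``tau = time_to_peak`` minutes, so the pulse vanishes at onset and
attains exactly ``peak`` at ``t = tau``.  A ``dead_time`` of d minutes
zeroes the intensity on [0, d) and shifts the pulse right — the
delayed-initiation signature seen when few witnesses can post early.
Sampling uses thinning against the constant majorant ``max(background,
peak)``.

Each accepted arrival is marked independently: a retweet flag
(``retweet_prob``), a log-normal follower count, and a bag-of-words
text that contains at least one event-vocabulary word with probability
``match_prob_event`` and at least one location word with probability
``match_prob_location``, padded with decoy words.  Decoy vocabulary
must be disjoint from the event/location vocabularies or match rates
will be inflated.  Identical spec + seed gives byte-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta, timezone
from typing import Optional, Sequence

import numpy as np
from scipy.integrate import quad

from .ingest import ConfigError, Tweet

__all__ = [
    "BurstSpec",
    "intensity",
    "generate_stream",
    "first_crossing_minute",
    "generate_control",
    "generate_preset",
    "PRESETS",
    "CONTROL_CEILINGS",
    "DEFAULT_START",
]

DEFAULT_START = datetime(2016, 2, 7, 18, 30, tzinfo=timezone.utc)

_EVENT_WORDS = (
    "crash", "shooting", "shot", "explosion", "earthquake", "victims",
    "stabbing", "accident", "breaking", "attack", "fatality", "flood",
)
_LOCATION_WORDS = (
    "sf", "sanfrancisco", "bayarea", "francisco", "norcal", "baybridge",
    "sfgh", "bart", "muni",
)
_DECOY_WORDS = (
    "coffee", "morning", "lunch", "sunny", "music", "photo", "weekend",
    "team", "game", "score", "touchdown", "halftime", "party", "pizza",
    "traffic", "lol", "omg", "love", "tonight", "watching",
)


@dataclass(frozen=True)
class BurstSpec:
    """Parameters of one synthetic stream."""

    background_rate: float  # tweets/min
    peak_rate: float  # tweets/min, max of the intensity
    time_to_peak: float  # minutes
    duration: float  # minutes
    decay_time: Optional[float] = None  # reserved for a two-timescale variant
    dead_time: float = 0.0  # minutes of zero intensity after onset
    retweet_prob: float = 0.55
    follower_log_mean: float = 7.5
    follower_log_sd: float = 1.2
    event_vocab: tuple[str, ...] = _EVENT_WORDS
    location_vocab: tuple[str, ...] = _LOCATION_WORDS
    decoy_vocab: tuple[str, ...] = _DECOY_WORDS
    match_prob_event: float = 1.0
    match_prob_location: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.background_rate < 0 or self.peak_rate < 0 or self.duration < 0:
            raise ConfigError("rates and duration must be non-negative")
        if self.time_to_peak <= 0 or self.dead_time < 0:
            raise ConfigError("time_to_peak must be positive, dead_time non-negative")
        for name in ("retweet_prob", "match_prob_event", "match_prob_location"):
            p = getattr(self, name)
            if not (0.0 <= p <= 1.0):
                raise ConfigError(f"{name} must lie in [0, 1]")
        if self.match_prob_event > 0 and not self.event_vocab:
            raise ConfigError("event_vocab empty but match_prob_event > 0")
        if self.match_prob_location > 0 and not self.location_vocab:
            raise ConfigError("location_vocab empty but match_prob_location > 0")


def intensity(t, spec: BurstSpec):
    """Expected tweets/min at *t* minutes after onset (scalar or array)."""
    t_arr = np.asarray(t, dtype=np.float64)
    if (t_arr < 0).any():
        raise ValueError("intensity undefined for negative times")
    u = t_arr - spec.dead_time
    tau = spec.time_to_peak
    excess = spec.peak_rate - spec.background_rate
    with np.errstate(invalid="ignore"):
        pulse = excess * (u / tau) * np.exp(1.0 - u / tau)
    lam = np.where(u < 0, 0.0, spec.background_rate + pulse)
    return float(lam) if np.isscalar(t) or t_arr.ndim == 0 else lam


def _bin_expected(spec: BurstSpec, minute: int, scale: float = 1.0) -> float:
    """Expected count of the 1-based bin [minute-1, minute), optionally
    scaled by a joint-match thinning factor."""
    a, b = float(minute - 1), float(minute)
    if b <= spec.dead_time:
        return 0.0
    a = max(a, spec.dead_time)
    val, _ = quad(lambda t: intensity(t, spec), a, b, limit=200)
    return scale * val


def first_crossing_minute(
    spec: BurstSpec, threshold_tpm: float, scale: float = 1.0
) -> Optional[int]:
    """Smallest minute m with expected bin count >= threshold, by
    numerical integration of the intensity; None if no bin within
    the spec duration qualifies."""
    for m in range(1, int(math.ceil(spec.duration)) + 1):
        if _bin_expected(spec, m, scale=scale) >= threshold_tpm:
            return m
    return None


def _assemble_texts(
    rng: np.random.Generator,
    n: int,
    spec: BurstSpec,
    retweet_flags: np.ndarray,
) -> list[str]:
    decoys = np.asarray(spec.decoy_vocab)
    n_decoy = rng.integers(3, 9, size=n)
    has_event = rng.random(n) < spec.match_prob_event
    has_location = rng.random(n) < spec.match_prob_location
    event_pick = (
        rng.integers(0, len(spec.event_vocab), size=n) if spec.event_vocab else np.zeros(n, int)
    )
    location_pick = (
        rng.integers(0, len(spec.location_vocab), size=n)
        if spec.location_vocab
        else np.zeros(n, int)
    )
    texts: list[str] = []
    for i in range(n):
        words = list(decoys[rng.integers(0, len(decoys), size=n_decoy[i])])
        if has_event[i]:
            words.insert(int(rng.integers(0, len(words) + 1)), spec.event_vocab[event_pick[i]])
        if has_location[i]:
            words.insert(
                int(rng.integers(0, len(words) + 1)), spec.location_vocab[location_pick[i]]
            )
        body = " ".join(words)
        if retweet_flags[i]:
            body = f"RT @user{int(rng.integers(1, 100000))}: {body}"
        texts.append(body)
    return texts


def generate_stream(
    spec: BurstSpec,
    start: datetime = DEFAULT_START,
    seed: Optional[int] = None,
) -> list[Tweet]:
    """Draw one synthetic stream; *seed* (when given) overrides the
    spec's own seed."""
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    lam_max = max(spec.background_rate, spec.peak_rate)
    if lam_max == 0 or spec.duration == 0:
        return []
    n_candidate = rng.poisson(lam_max * spec.duration)
    times = np.sort(rng.uniform(0.0, spec.duration, size=n_candidate))
    keep = rng.random(n_candidate) * lam_max < intensity(times, spec)
    times = times[keep]
    n = times.size
    retweet_flags = rng.random(n) < spec.retweet_prob
    followers = np.floor(
        rng.lognormal(spec.follower_log_mean, spec.follower_log_sd, size=n)
    ).astype(np.int64)
    # originals accumulate reposts; mean repost count ~150
    retweet_counts = np.where(retweet_flags, 0, rng.geometric(1.0 / 150.0, size=n))
    texts = _assemble_texts(rng, n, spec, retweet_flags)
    tweets: list[Tweet] = []
    tag = spec.seed if seed is None else seed
    for i in range(n):
        posted = start + timedelta(seconds=round(times[i] * 60.0, 3))
        tweets.append(
            Tweet(
                tweet_id=f"s{tag}-{i:07d}",
                posted_at=posted,
                text=texts[i],
                user_id=f"u{tag}-{i:07d}",
                follower_count=int(followers[i]),
                is_retweet=bool(retweet_flags[i]),
                retweeted_id=f"s{tag}-orig{i:07d}" if retweet_flags[i] else None,
                retweet_count=int(retweet_counts[i]),
            )
        )
    return tweets


def generate_control(
    spec: BurstSpec,
    joint_match_ceiling: float,
    start: datetime = DEFAULT_START,
    seed: Optional[int] = None,
) -> list[Tweet]:
    """High-volume stream whose expected rate of *joint-matching* tweets
    stays at or below *joint_match_ceiling* tweets/min, by capping the
    event/location match probabilities at sqrt(ceiling / peak rate)."""
    if joint_match_ceiling <= 0:
        raise ConfigError("joint_match_ceiling must be positive")
    lam_max = max(spec.background_rate, spec.peak_rate)
    q = math.sqrt(min(1.0, joint_match_ceiling / lam_max))
    capped = replace(
        spec,
        match_prob_event=min(spec.match_prob_event, q),
        match_prob_location=min(spec.match_prob_location, q),
    )
    return generate_stream(capped, start=start, seed=seed)


# --------------------------------------------------------------------------
# Presets
#
# The five event-like presets carry first-hour peak rates spanning the
# range observed across real mass-casualty streams (209-3326 tweets/min)
# with rise times well inside three hours; the "sh"-like preset adds a
# dead time for its delayed initiation.  Controls emulate a high-volume
# public event whose joint-matching volume is capped far below the alert
# threshold.

PRESETS: dict[str, BurstSpec] = {
    "bb": BurstSpec(background_rate=2.0, peak_rate=3326.0, time_to_peak=35.0, duration=12.0),
    "sf": BurstSpec(background_rate=2.0, peak_rate=1423.0, time_to_peak=32.0, duration=12.0),
    "mv": BurstSpec(background_rate=2.0, peak_rate=957.0, time_to_peak=14.0, duration=12.0),
    "ne": BurstSpec(background_rate=1.0, peak_rate=739.0, time_to_peak=5.5, duration=12.0),
    "sh": BurstSpec(
        background_rate=1.0, peak_rate=209.0, time_to_peak=1.5, dead_time=10.0, duration=25.0
    ),
    "control-sb50": BurstSpec(
        background_rate=300.0, peak_rate=300.0, time_to_peak=1.0, duration=120.0,
        match_prob_event=0.9, match_prob_location=0.9,
    ),
    "control-chp": BurstSpec(
        background_rate=300.0, peak_rate=300.0, time_to_peak=1.0, duration=120.0,
        match_prob_event=0.9, match_prob_location=0.9,
    ),
}

# joint-match ceilings (tweets/min) for the control presets
CONTROL_CEILINGS: dict[str, float] = {"control-sb50": 100.0, "control-chp": 30.0}

# embedded low-casualty incident for the "control-chp" preset: a small
# pulse of fully matching tweets whose rate stays well under the alert
# threshold even stacked on the control's matching background
_CHP_INCIDENT = BurstSpec(
    background_rate=0.0, peak_rate=120.0, time_to_peak=5.0, dead_time=30.0, duration=120.0,
    match_prob_event=1.0, match_prob_location=1.0,
)


def generate_preset(
    name: str,
    seed: Optional[int] = None,
    duration: Optional[float] = None,
    threshold_tpm: float = 200.0,
    start: datetime = DEFAULT_START,
) -> tuple[list[Tweet], dict]:
    """Generate a named preset stream plus its ground-truth sidecar.

    The sidecar records the analytic first minute at which the
    *joint-matching* expected rate reaches *threshold_tpm* (None when it
    never does), which is the reference answer for detector recovery.
    """
    if name not in PRESETS:
        raise ConfigError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    spec = PRESETS[name]
    if duration is not None:
        spec = replace(spec, duration=float(duration))
    used_seed = spec.seed if seed is None else seed
    if name in CONTROL_CEILINGS:
        ceiling = CONTROL_CEILINGS[name]
        tweets = generate_control(spec, ceiling, start=start, seed=used_seed)
        lam_max = max(spec.background_rate, spec.peak_rate)
        q = math.sqrt(min(1.0, ceiling / lam_max))
        scale = min(spec.match_prob_event, q) * min(spec.match_prob_location, q)
        crossing = first_crossing_minute(spec, threshold_tpm, scale=scale)
        if name == "control-chp":
            incident = _CHP_INCIDENT
            if duration is not None:
                incident = replace(incident, duration=float(duration))
            extra = generate_stream(incident, start=start, seed=used_seed + 7919)
            extra = [
                replace_tweet_ids(t, prefix="chp") for t in extra
            ]
            tweets = sorted(tweets + extra, key=lambda t: t.posted_at)
            if crossing is None:
                crossing = _combined_first_crossing(
                    [(spec, scale), (incident, 1.0)], threshold_tpm
                )
    else:
        tweets = generate_stream(spec, start=start, seed=used_seed)
        scale = spec.match_prob_event * spec.match_prob_location
        crossing = first_crossing_minute(spec, threshold_tpm, scale=scale)
    sidecar = {
        "preset": name,
        "seed": used_seed,
        "duration_minutes": spec.duration,
        "n_tweets": len(tweets),
        "threshold_tpm": threshold_tpm,
        "first_crossing_minute": crossing,
    }
    return tweets, sidecar


def replace_tweet_ids(tweet: Tweet, prefix: str) -> Tweet:
    """Re-prefix ids so merged sub-streams cannot collide."""
    return Tweet(
        tweet_id=f"{prefix}-{tweet.tweet_id}",
        posted_at=tweet.posted_at,
        text=tweet.text,
        user_id=f"{prefix}-{tweet.user_id}",
        follower_count=tweet.follower_count,
        is_retweet=tweet.is_retweet,
        retweeted_id=None if tweet.retweeted_id is None else f"{prefix}-{tweet.retweeted_id}",
        retweet_count=tweet.retweet_count,
        geo=tweet.geo,
    )


def _combined_first_crossing(
    specs_scales: Sequence[tuple[BurstSpec, float]], threshold_tpm: float
) -> Optional[int]:
    duration = max(spec.duration for spec, _ in specs_scales)
    for m in range(1, int(math.ceil(duration)) + 1):
        total = sum(
            _bin_expected(spec, m, scale=scale)
            for spec, scale in specs_scales
            if m <= math.ceil(spec.duration)
        )
        if total >= threshold_tpm:
            return m
    return None
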