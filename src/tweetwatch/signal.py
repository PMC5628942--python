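"""Onset-anchored per-minute aggregation and threshold alert detection.

Bin convention (used everywhere): bins are 1-based and half-open, bin
``m`` covering ``[onset + (m-1)*60s, onset + m*60s)``.  A statistic
"reached in k minutes" is reported as the 1-based index of the bin in
which it is reached.  An alert instant is anchored to the *end* of the
qualifying bin, since a per-minute count is only known once the minute
completes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from typing import Mapping, Optional, Sequence

import numpy as np

from .ingest import ConfigError, IngestStats, Tweet

__all__ = [
    "MinuteSeries",
    "MilestoneResult",
    "EventSummary",
    "AlertResult",
    "bin_per_minute",
    "milestones",
    "median_across_events",
    "summarize",
    "detect_threshold",
    "fraction_first_hour",
]


@dataclass
class MinuteSeries:
    """Per-minute counts of filtered tweets, anchored at event onset."""

    onset: datetime
    counts: np.ndarray  # int counts, length == horizon_minutes
    beyond_horizon: int = 0
    stats: Optional[IngestStats] = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 1:
            raise ValueError("counts must be one-dimensional")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def horizon_minutes(self) -> int:
        return int(self.counts.size)

    def cumulative(self) -> np.ndarray:
        return np.cumsum(self.counts)


@dataclass(frozen=True)
class MilestoneResult:
    """First minute at which cumulative first-hour volume reaches a
    percentage of the first-hour total."""

    percent: float
    minute: Optional[int]
    window_total: int


@dataclass(frozen=True)
class EventSummary:
    total_tweets: int
    unique_fraction: Optional[float]
    retweet_fraction: Optional[float]
    mean_followers: Optional[float]
    mean_retweets_of_retweeted: Optional[float]
    peak_tpm_60: int
    peak_tpm_overall: int
    peak_minute_overall: Optional[int]


@dataclass
class AlertResult:
    threshold_tpm: int
    fired: bool
    fire_minute: Optional[int]
    fire_instant: Optional[datetime]
    lead_times: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "threshold_tpm": self.threshold_tpm,
            "fired": self.fired,
            "fire_minute": self.fire_minute,
            "fire_instant": None if self.fire_instant is None else self.fire_instant.isoformat(),
            "lead_times_seconds": dict(self.lead_times),
        }


def bin_per_minute(
    tweets: Sequence[Tweet],
    onset: datetime,
    horizon_minutes: int,
    stats: Optional[IngestStats] = None,
) -> MinuteSeries:
    """Count tweets per one-minute bin over the first *horizon_minutes*
    after *onset*; tweets at or beyond the horizon are ignored (tallied
    in ``beyond_horizon``).  Expects a cleaned stream with no pre-onset
    entries."""
    if horizon_minutes <= 0:
        raise ConfigError("horizon_minutes must be positive")
    offsets = np.array(
        [(t.posted_at - onset).total_seconds() for t in tweets], dtype=np.float64
    )
    if (offsets < 0).any():
        raise ValueError("stream contains pre-onset tweets; clean it first")
    bins = np.floor(offsets / 60.0).astype(np.int64)  # 0-based bin index
    inside = bins < horizon_minutes
    counts = np.bincount(bins[inside], minlength=horizon_minutes)[:horizon_minutes]
    return MinuteSeries(
        onset=onset,
        counts=counts,
        beyond_horizon=int((~inside).sum()),
        stats=stats,
    )


def milestones(series: MinuteSeries, percents: Sequence[float]) -> list[MilestoneResult]:
    """For each percentage p, the first minute m in 1..60 with
    ``cum(m) >= (p/100) * cum(60)``; None when the first hour is empty.

    The comparison uses the exact real-valued target (no rounding), so
    p=100 always lands on the last minute in which the cumulative count
    still increases.
    """
    if series.horizon_minutes < 60:
        raise ConfigError("milestones need a horizon of at least 60 minutes")
    cum = np.cumsum(series.counts[:60])
    total = int(cum[-1])
    out: list[MilestoneResult] = []
    for p in percents:
        if not (0 < p <= 100):
            raise ConfigError(f"milestone percent {p!r} outside (0, 100]")
        if total == 0:
            out.append(MilestoneResult(percent=float(p), minute=None, window_total=0))
            continue
        target = p * total / 100.0
        # integer cumulative counts: nudge the target to absorb float error
        minute = int(np.argmax(cum >= target - 1e-9)) + 1
        out.append(MilestoneResult(percent=float(p), minute=minute, window_total=total))
    return out


def median_across_events(per_event_minutes: Mapping[str, int] | Sequence[int]) -> int:
    """Cross-event median of a milestone row: the middle order statistic
    for odd counts, the half-up-rounded mean of the central pair for
    even counts."""
    if isinstance(per_event_minutes, Mapping):
        values = sorted(per_event_minutes.values())
    else:
        values = sorted(per_event_minutes)
    n = len(values)
    if n == 0:
        raise ValueError("median of empty input")
    if n % 2 == 1:
        return int(values[n // 2])
    return int(math.floor((values[n // 2 - 1] + values[n // 2]) / 2.0 + 0.5))


def summarize(
    tweets: Sequence[Tweet],
    series: MinuteSeries,
    followers_per: str = "user",
) -> EventSummary:
    """Stream composition and peak statistics.

    ``followers_per="user"`` (default) averages follower counts over
    distinct users, keeping each user's last observed value;
    ``followers_per="tweet"`` averages over tweets.
    """
    total = len(tweets)
    if total == 0:
        unique_fraction = retweet_fraction = mean_followers = None
    else:
        n_retweets = sum(1 for t in tweets if t.is_retweet)
        retweet_fraction = n_retweets / total
        unique_fraction = 1.0 - retweet_fraction
        if followers_per == "tweet":
            mean_followers = sum(t.follower_count for t in tweets) / total
        elif followers_per == "user":
            last_seen: dict[str, int] = {}
            for t in tweets:
                last_seen[t.user_id] = t.follower_count
            mean_followers = sum(last_seen.values()) / len(last_seen)
        else:
            raise ConfigError(f"followers_per must be 'user' or 'tweet', got {followers_per!r}")
    retweeted = [t.retweet_count for t in tweets if t.retweet_count > 0]
    mean_rt = sum(retweeted) / len(retweeted) if retweeted else None
    counts = series.counts
    peak_60 = int(counts[:60].max()) if counts.size else 0
    peak_all = int(counts.max()) if counts.size else 0
    peak_minute = int(np.argmax(counts)) + 1 if counts.size and peak_all > 0 else None
    return EventSummary(
        total_tweets=total,
        unique_fraction=unique_fraction,
        retweet_fraction=retweet_fraction,
        mean_followers=mean_followers,
        mean_retweets_of_retweeted=mean_rt,
        peak_tpm_60=peak_60,
        peak_tpm_overall=peak_all,
        peak_minute_overall=peak_minute,
    )


def detect_threshold(
    series: MinuteSeries,
    threshold_tpm: int,
    timeline: Optional[Mapping[str, datetime]] = None,
    sustain: int = 1,
) -> AlertResult:
    """First minute whose count reaches *threshold_tpm*.

    With ``sustain=w`` the alert instead requires ``w`` consecutive
    qualifying bins and fires at the end of the w-th.  Lead times are
    ``mark_instant - fire_instant`` in seconds (positive when the alert
    precedes the mark).
    """
    if threshold_tpm < 1:
        raise ConfigError("threshold must be a positive integer")
    if sustain < 1:
        raise ConfigError("sustain window must be >= 1")
    hits = series.counts >= threshold_tpm
    fire_minute: Optional[int] = None
    run = 0
    for idx, hit in enumerate(hits):
        run = run + 1 if hit else 0
        if run >= sustain:
            fire_minute = idx + 1
            break
    if fire_minute is None:
        return AlertResult(threshold_tpm=threshold_tpm, fired=False, fire_minute=None, fire_instant=None)
    fire_instant = series.onset + timedelta(minutes=fire_minute)
    lead_times = {
        mark: (instant - fire_instant).total_seconds()
        for mark, instant in (timeline or {}).items()
    }
    return AlertResult(
        threshold_tpm=threshold_tpm,
        fired=True,
        fire_minute=fire_minute,
        fire_instant=fire_instant,
        lead_times=lead_times,
    )


def fraction_first_hour(series: MinuteSeries) -> Optional[float]:
    """Share of the whole collection period's volume that falls in the
    first 60 minutes; None for an empty series."""
    total = int(series.counts.sum())
    if total == 0:
        return None
    return float(series.counts[: min(60, series.horizon_minutes)].sum()) / total
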