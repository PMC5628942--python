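"""Command-line interface and reporting layer.

Subcommands
-----------
``analyze``        filter a stream by an event's rules and emit the
                   per-minute series, milestone table and summary.
``detect``         run the threshold alert detector and report lead
                   times against configured timeline marks.
``simulate``       generate a synthetic stream from a named preset or a
                   spec file, with a ground-truth sidecar.
``report-medians`` cross-event median of each milestone row.

Machine-readable results go to files/stdout; logging goes to stderr.
Numeric formatting is fixed (minutes as integers, proportions to four
decimals, rates to one decimal) so outputs diff cleanly.
"""

from __future__ import annotations

import csv
import dataclasses
import json
import logging
import sys
from datetime import datetime, timezone
from importlib import resources
from pathlib import Path

import click
import yaml

from . import __version__, ingest, rules, signal, synth

log = logging.getLogger("tweetwatch")

DEFAULT_PERCENTS = (1.0, 2.0, 5.0, 10.0, 50.0, 75.0, 90.0, 100.0)


def _fmt_prop(x) -> str:
    return "" if x is None else f"{x:.4f}"


def _fmt_rate(x) -> str:
    return "" if x is None else f"{x:.1f}"


@dataclasses.dataclass
class RunManifest:
    """Record of one CLI run: inputs, parameters and every artifact
    written, sufficient to reproduce the numeric outputs."""

    command: str
    inputs: list[str]
    outputs: list[str]
    parameters: dict
    version: str = __version__
    created: str = ""

    def write(self, path: Path) -> None:
        self.created = datetime.now(timezone.utc).isoformat()
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def load(cls, path) -> "RunManifest":
        with open(path, "r", encoding="utf-8") as fh:
            return cls(**json.load(fh))


def packaged_milestone_table():
    """The bundled cross-event milestone table (percent row -> per-event
    minutes), as (fieldnames, rows)."""
    ref = resources.files("tweetwatch.data") / "milestone_minutes.csv"
    with ref.open("r", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        return reader.fieldnames, list(reader)


def packaged_event_stats() -> dict:
    """Bundled per-event reference statistics (totals, first-hour peaks)."""
    ref = resources.files("tweetwatch.data") / "event_stats.json"
    with ref.open("r", encoding="utf-8") as fh:
        return json.load(fh)


def packaged_historical_rules() -> dict[str, list]:
    """Bundled historical filtering rules, parsed, keyed by event code."""
    ref = resources.files("tweetwatch.data") / "historical_rules.yaml"
    with ref.open("r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    return {event: [rules.parse_rule(r) for r in lines] for event, lines in raw.items()}


def packaged_keyword_sets() -> rules.KeywordSets:
    """Bundled joint event+location keyword sets for prospective matching."""
    ref = resources.files("tweetwatch.data") / "prospective_keywords.yaml"
    with ref.open("r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    return rules.KeywordSets.from_words(raw["event"], raw["location"])


def _analyze_stream(config: ingest.EventConfig, stream_paths, percents):
    onset = ingest.resolve_onset(config)
    tweets, stats = ingest.read_streams(stream_paths, onset=onset)
    if config.rules:
        kept = [t for t in tweets if rules.matches_any(config.rules, t.text)]
    else:
        kept = list(tweets)
    series = signal.bin_per_minute(kept, onset, config.horizon_minutes, stats=stats)
    miles = signal.milestones(series, percents) if config.horizon_minutes >= 60 else []
    summary = signal.summarize(kept, series)
    return onset, kept, stats, series, miles, summary


def _write_series_csv(series: signal.MinuteSeries, path: Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["minute", "tweets"])
        for m, count in enumerate(series.counts, start=1):
            writer.writerow([m, int(count)])


def read_series_csv(path) -> list[tuple[int, int]]:
    with open(path, "r", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        return [(int(row["minute"]), int(row["tweets"])) for row in reader]


@click.group()
@click.option("-v", "--verbose", is_flag=True, help="Debug logging on stderr.")
def main(verbose: bool) -> None:
    """Early-warning signal detection on tweet activity streams."""
    logging.basicConfig(
        stream=sys.stderr,
        level=logging.DEBUG if verbose else logging.INFO,
        format="%(levelname)s %(name)s: %(message)s",
    )


@main.command()
@click.option("--config", "config_path", required=True, type=click.Path(exists=True))
@click.option("--out", "out_dir", required=True, type=click.Path(file_okay=False))
@click.option(
    "--percents", default=",".join(str(int(p)) for p in DEFAULT_PERCENTS), show_default=True
)
@click.option("--plot", is_flag=True, help="Also write a tweets-per-minute PNG.")
@click.argument("streams", nargs=-1, required=True, type=click.Path(exists=True))
def analyze(config_path, out_dir, percents, plot, streams) -> None:
    """Filter STREAMS by the event's rules and summarize them."""
    config = ingest.load_event_config(config_path)
    percent_list = [float(p) for p in percents.split(",") if p.strip()]
    onset, kept, stats, series, miles, summary = _analyze_stream(
        config, list(streams), percent_list
    )
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    series_path = out / "series.csv"
    _write_series_csv(series, series_path)

    milestones_path = out / "milestones.csv"
    with open(milestones_path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["percent", "minute", "window_total"])
        for res in miles:
            writer.writerow(
                [int(res.percent) if res.percent == int(res.percent) else res.percent,
                 "" if res.minute is None else res.minute,
                 res.window_total]
            )

    summary_path = out / "summary.json"
    with open(summary_path, "w", encoding="utf-8") as fh:
        json.dump(
            {
                "event": config.name,
                "onset_utc": onset.isoformat(),
                "total_tweets": summary.total_tweets,
                "unique_fraction": None if summary.unique_fraction is None else round(summary.unique_fraction, 4),
                "retweet_fraction": None if summary.retweet_fraction is None else round(summary.retweet_fraction, 4),
                "mean_followers": None if summary.mean_followers is None else round(summary.mean_followers, 1),
                "mean_retweets_of_retweeted": None if summary.mean_retweets_of_retweeted is None else round(summary.mean_retweets_of_retweeted, 1),
                "peak_tpm_60": summary.peak_tpm_60,
                "peak_tpm_overall": summary.peak_tpm_overall,
                "peak_minute_overall": summary.peak_minute_overall,
                "first_hour_fraction": None
                if (fh60 := signal.fraction_first_hour(series)) is None
                else round(fh60, 4),
                "ingest": stats.to_dict(),
            },
            fh,
            indent=2,
        )
        fh.write("\n")

    outputs = [str(series_path), str(milestones_path), str(summary_path)]
    if plot:
        outputs.append(_plot_series(series, out / "series.png", config.name))
    RunManifest(
        command="analyze",
        inputs=[str(config_path), *map(str, streams)],
        outputs=outputs,
        parameters={"percents": percent_list, "horizon_minutes": config.horizon_minutes},
    ).write(out / "manifest.json")
    click.echo(str(summary_path))


@main.command()
@click.option("--config", "config_path", required=True, type=click.Path(exists=True))
@click.option("--threshold", default=200, show_default=True, type=int)
@click.option("--sustain", default=1, show_default=True, type=int)
@click.option("--out", "out_dir", required=True, type=click.Path(file_okay=False))
@click.argument("streams", nargs=-1, required=True, type=click.Path(exists=True))
def detect(config_path, threshold, sustain, out_dir, streams) -> None:
    """Run the threshold alert detector on filtered STREAMS."""
    config = ingest.load_event_config(config_path)
    onset, kept, stats, series, _, _ = _analyze_stream(config, list(streams), [])
    alert = signal.detect_threshold(series, threshold, timeline=config.timeline, sustain=sustain)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    alert_path = out / "alert.json"
    payload = alert.to_dict()
    payload["event"] = config.name
    payload["lead_times_minutes"] = {
        mark: round(seconds / 60.0, 4) for mark, seconds in alert.lead_times.items()
    }
    with open(alert_path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
    RunManifest(
        command="detect",
        inputs=[str(config_path), *map(str, streams)],
        outputs=[str(alert_path)],
        parameters={"threshold": threshold, "sustain": sustain},
    ).write(out / "manifest.json")
    click.echo(str(alert_path))


def _load_burst_spec(path) -> synth.BurstSpec:
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ingest.ConfigError(f"spec {path} is not a mapping")
    for key in ("event_vocab", "location_vocab", "decoy_vocab"):
        if key in raw:
            raw[key] = tuple(raw[key])
    try:
        return synth.BurstSpec(**raw)
    except TypeError as exc:
        raise ingest.ConfigError(f"bad burst spec: {exc}") from exc


@main.command()
@click.option("--preset", type=click.Choice(sorted(synth.PRESETS)), default=None)
@click.option("--spec", "spec_path", type=click.Path(exists=True), default=None)
@click.option("--seed", type=int, default=None, help="Overrides the spec seed.")
@click.option("--duration", type=float, default=None, help="Minutes; overrides the preset.")
@click.option("--threshold", default=200, show_default=True, type=int)
@click.option("--out", "out_path", required=True, type=click.Path(dir_okay=False))
def simulate(preset, spec_path, seed, duration, threshold, out_path) -> None:
    """Write a synthetic NDJSON stream plus a ground-truth sidecar."""
    if (preset is None) == (spec_path is None):
        raise click.UsageError("give exactly one of --preset or --spec")
    out = Path(out_path)
    out.parent.mkdir(parents=True, exist_ok=True)
    if preset is not None:
        tweets, sidecar = synth.generate_preset(
            preset, seed=seed, duration=duration, threshold_tpm=float(threshold)
        )
        inputs = [f"preset:{preset}"]
    else:
        spec = _load_burst_spec(spec_path)
        if duration is not None:
            spec = dataclasses.replace(spec, duration=duration)
        tweets = synth.generate_stream(spec, seed=seed)
        scale = spec.match_prob_event * spec.match_prob_location
        sidecar = {
            "preset": None,
            "seed": spec.seed if seed is None else seed,
            "duration_minutes": spec.duration,
            "n_tweets": len(tweets),
            "threshold_tpm": float(threshold),
            "first_crossing_minute": synth.first_crossing_minute(
                spec, float(threshold), scale=scale
            ),
        }
        inputs = [str(spec_path)]
    ingest.write_stream(tweets, out)
    sidecar_path = out.with_suffix(out.suffix + ".meta.json")
    with open(sidecar_path, "w", encoding="utf-8") as fh:
        json.dump(sidecar, fh, indent=2, sort_keys=True)
        fh.write("\n")
    RunManifest(
        command="simulate",
        inputs=inputs,
        outputs=[str(out), str(sidecar_path)],
        parameters={"seed": sidecar["seed"], "threshold": threshold, "duration": duration},
    ).write(out.with_suffix(out.suffix + ".manifest.json"))
    click.echo(str(out))


@main.command("report-medians")
@click.option("--table", "table_path", type=click.Path(exists=True), default=None,
              help="Milestone CSV (percent + one column per event); defaults to the bundled table.")
@click.option("--out", "out_path", type=click.Path(dir_okay=False), default=None)
def report_medians(table_path, out_path) -> None:
    """Median milestone minute across events, one row per percentage."""
    if table_path is None:
        fieldnames, table = packaged_milestone_table()
    else:
        with open(table_path, "r", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            fieldnames, table = reader.fieldnames, list(reader)
    event_cols = [c for c in fieldnames if c != "percent"]
    rows = []
    for row in table:
        per_event = {c: int(row[c]) for c in event_cols}
        rows.append((row["percent"], signal.median_across_events(per_event)))
    lines = ["percent,median"] + [f"{p},{m}" for p, m in rows]
    text = "\n".join(lines) + "\n"
    if out_path:
        Path(out_path).parent.mkdir(parents=True, exist_ok=True)
        Path(out_path).write_text(text, encoding="utf-8")
        click.echo(out_path)
    else:
        click.echo(text, nl=False)


def _plot_series(series: signal.MinuteSeries, path: Path, title: str) -> str:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 3.5))
    ax.plot(range(1, series.horizon_minutes + 1), series.counts, lw=0.8)
    ax.set_xlabel("minutes since onset")
    ax.set_ylabel("tweets per minute")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return str(path)


if __name__ == "__main__":
    main()
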