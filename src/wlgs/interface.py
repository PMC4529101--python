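"""Command-line surface and end-to-end pipelines.

Subcommands:

* ``wlgs simulate`` — render a synthetic mission (logs + ground truth).
* ``wlgs analyze``  — logs directory → contact matrices, cohesion series,
  recoded choices, subgroup times, group centers, plots.
* ``wlgs forecast`` — cohesion CSV → spline → ARIMA → forecast bundle.
* ``wlgs report``   — regenerate plots from an analysis bundle.

Every run writes a ``manifest.json`` (config, seed, input digests) so a
deterministic stage can be re-run bit-identically from its manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import click
import numpy as np
import pandas as pd
import yaml

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import networkx as nx  # noqa: E402

from . import contacts, simulate, sociometry, timeseries, validate  # noqa: E402
from .errors import ConfigurationError, EmptyDayError, InsufficientDataError  # noqa: E402

log = logging.getLogger("wlgs")

SECONDS_PER_HOUR = 3600


def _parse_window(text: str) -> tuple[int, int]:
    try:
        a, b = text.split("-")
        h1, m1 = (int(v) for v in a.split(":"))
        h2, m2 = (int(v) for v in b.split(":"))
    except ValueError as exc:
        raise ConfigurationError(f"window must look like HH:MM-HH:MM, got {text!r}") from exc
    return h1 * 3600 + m1 * 60, h2 * 3600 + m2 * 60


@dataclass
class RunConfig:
    """Analysis-run parameters, fully serialized into every output bundle."""

    epoch_seconds: int = 5
    rssi_threshold_db: float = float("-inf")
    rule: str = "union"
    window: tuple[int, int] | None = None  # e.g. the 14:18-20:18 afternoon
    min_session_s: float = 6 * SECONDS_PER_HOUR
    crew_ids: tuple[str, ...] = tuple(simulate.CREW_IDS)
    arima_d: int = 1
    arima_max_pq: int = 3
    plots: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.rule not in ("union", "mutual"):
            raise ConfigurationError(f"rule: expected union|mutual, got {self.rule!r}")
        if self.epoch_seconds <= 0:
            raise ConfigurationError("epoch_seconds: must be positive")
        if self.min_session_s < 0:
            raise ConfigurationError("min_session_s: must be non-negative")
        if self.window is not None and not self.window[0] < self.window[1]:
            raise ConfigurationError("window: start must precede end")
        if self.arima_d < 0 or self.arima_max_pq < 0:
            raise ConfigurationError("arima_d / arima_max_pq: must be non-negative")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config fields: {sorted(unknown)}")
        if "window" in raw and isinstance(raw["window"], str):
            raw["window"] = _parse_window(raw["window"])
        elif "window" in raw and raw["window"] is not None:
            raw["window"] = tuple(raw["window"])
        if "crew_ids" in raw:
            raw["crew_ids"] = tuple(raw["crew_ids"])
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["window"] = list(self.window) if self.window else None
        d["crew_ids"] = list(self.crew_ids)
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_manifest(outdir: Path, config: dict, inputs: list[Path]) -> None:
    manifest = {
        "config": config,
        "inputs": {p.name: _sha256(p) for p in sorted(inputs)},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2), encoding="utf-8")


# ---------------------------------------------------------------- pipelines


def analyze_logs(
    logs_dir: str | Path, config: RunConfig, outdir: str | Path
) -> dict[int, contacts.DailyContactMatrix]:
    """Full analysis pipeline: parse → binarize → tensor → contact time →
    cohesion/choices/subgroups/centers, everything written to ``outdir``."""
    config.validate()
    logs_dir, outdir = Path(logs_dir), Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files = sorted(logs_dir.glob("*.csv"))
    by_day: dict[int, dict[str, contacts.SensorLog]] = {}
    for f in files:
        try:
            sl = contacts.parse_sensor_log(f)
        except contacts.EmptyLogError:
            log.warning("skipping empty log %s", f.name)
            continue
        by_day.setdefault(sl.day, {})[sl.sensor_id] = sl
    crew = [c for c in config.crew_ids]

    matrices: dict[int, contacts.DailyContactMatrix] = {}
    tensors: dict[int, contacts.ContactTensor] = {}
    for day in sorted(by_day):
        logs = by_day[day]
        crew_logs = {s: l for s, l in logs.items() if s in crew}
        if not crew_logs:
            continue
        lo = min(l.epochs[0] for l in crew_logs.values())
        hi = max(l.epochs[-1] for l in crew_logs.values())
        grid = np.arange(lo, hi + config.epoch_seconds, config.epoch_seconds)
        det = {
            s: contacts.binarize(l, config.rssi_threshold_db, grid)
            for s, l in crew_logs.items()
        }
        tensor = contacts.build_contact_tensor(det, rule=config.rule, sensors=crew, day=day)
        if config.window is not None:
            try:
                tensor = contacts.filter_epochs(tensor, window=config.window)
            except EmptyDayError:
                log.warning("day %d has no epochs in the window; skipped", day)
                continue
        tensors[day] = tensor
        matrices[day] = contacts.contact_time(tensor)

    if not matrices:
        raise EmptyDayError("no analyzable measurement days found")

    mats = list(matrices.values())
    contacts.write_contact_matrices(mats, outdir / "contact_matrices.csv")

    series = sociometry.CohesionSeries.from_daily(mats, min_session_s=config.min_session_s)
    series.to_frame().to_csv(outdir / "cohesion.csv", index=False)

    choice_frames = []
    for day, m in matrices.items():
        try:
            ct = sociometry.time_to_choices(m)
        except Exception:
            continue
        choice_frames.append(ct.to_frame().assign(day=day))
    if choice_frames:
        pd.concat(choice_frames, ignore_index=True).to_csv(
            outdir / "choices.csv", index=False
        )

    sub_rows = []
    for day, tensor in tensors.items():
        for k in (2, 3, 4):
            if k > len(tensor.sensors):
                continue
            for members, seconds in sociometry.subgroup_times(tensor, k).items():
                sub_rows.append(
                    {"day": day, "members": "+".join(members), "size": k, "seconds": seconds}
                )
    pd.DataFrame(sub_rows).to_csv(outdir / "subgroups.csv", index=False)

    centers = sociometry.group_center_series(mats)
    centers.daily_center.assign(
        overall_x=centers.overall_center[0], overall_y=centers.overall_center[1]
    ).to_csv(outdir / "group_centers.csv")

    if config.plots:
        render_plots(outdir, mats, series, centers)
    write_manifest(outdir, config.to_dict(), files)
    return matrices


def render_plots(
    outdir: Path,
    mats: list[contacts.DailyContactMatrix],
    series: sociometry.CohesionSeries,
    centers: sociometry.GroupCenterSeries,
) -> None:
    outdir = Path(outdir)
    # sociogram of mean pair times; edge thickness proportional to time
    mean_t = pd.concat([m.t_ab for m in mats], axis=1).mean(axis=1)
    g = nx.Graph()
    for (a, b), v in mean_t.items():
        if v > 0:
            g.add_edge(a, b, weight=v)
    fig, ax = plt.subplots(figsize=(5, 5))
    if g.number_of_edges():
        pos = nx.circular_layout(g)
        wmax = max(d["weight"] for _, _, d in g.edges(data=True))
        widths = [6 * d["weight"] / wmax for _, _, d in g.edges(data=True)]
        nx.draw_networkx(g, pos, ax=ax, width=widths, node_color="#cfe2f3")
    ax.set_title("Mean time spent together (edge width ∝ time)")
    ax.axis("off")
    fig.savefig(outdir / "sociogram.png", dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(7, 3.2))
    s = series.to_series(complete_only=True)
    ax.plot(s.index, s.to_numpy(), "o-", ms=3)
    if len(s) >= 3 and np.ptp(s.to_numpy()) > 0:
        tr = timeseries.linear_trend(s)
        ax.plot(s.index, tr.intercept + tr.slope * s.index, "r--",
                label=f"trend β={tr.beta:.3f}")
        ax.legend()
    ax.set_xlabel("mission day")
    ax.set_ylabel("CRTI [ppm]")
    fig.tight_layout()
    fig.savefig(outdir / "crti.png", dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.plot(centers.daily_center["x"], centers.daily_center["y"], "o", ms=3, alpha=0.5,
            label="daily center")
    ax.plot(*centers.overall_center, "r*", ms=12, label="overall center")
    ax.axhline(0, lw=0.5, color="gray")
    ax.axvline(0, lw=0.5, color="gray")
    ax.legend()
    ax.set_title("Group centers")
    fig.tight_layout()
    fig.savefig(outdir / "group_centers.png", dpi=120)
    plt.close(fig)


def forecast_pipeline(
    cohesion_csv: str | Path,
    cut_day: int,
    horizon: int,
    config: RunConfig,
    outdir: str | Path,
) -> pd.DataFrame:
    """Spline the cohesion series, fit an ARIMA up to ``cut_day``, and
    forecast ``horizon`` days, with a holdout error table where observed
    data exist."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    raw = timeseries.read_series(cohesion_csv, value_col="crti_ppm")
    df = pd.read_csv(cohesion_csv)
    if "complete" in df.columns:
        raw = raw[df.set_index("day")["complete"].astype(bool).reindex(raw.index, fill_value=True)]
    if not raw.index.min() < cut_day <= raw.index.max():
        raise ValueError(f"cut_day {cut_day} outside the observed range")
    daily = timeseries.spline_resample(raw)
    train = daily[daily.index <= cut_day]
    fitted = timeseries.fit_arima(train, d=config.arima_d, max_pq=config.arima_max_pq)
    fc = timeseries.forecast(fitted, horizon)
    fc.to_csv(outdir / "forecast.csv")
    fitted.write_report(outdir / "model.json")

    observed = daily.reindex(fc.index).dropna()
    if len(observed):
        err = (fc["forecast"].reindex(observed.index) - observed).rename("error")
        pd.DataFrame({"observed": observed, "forecast": fc["forecast"].reindex(observed.index),
                      "error": err}).to_csv(outdir / "holdout.csv")

    if config.plots:
        fig, ax = plt.subplots(figsize=(7, 3.2))
        ax.plot(daily.index, daily.to_numpy(), lw=0.8, label="observed (splined)")
        ax.plot(fc.index, fc["forecast"], "r-", label=f"ARIMA{fitted.order} forecast")
        ax.fill_between(fc.index, fc["lo"], fc["hi"], color="r", alpha=0.15)
        ax.axvline(cut_day, color="gray", ls=":")
        ax.set_xlabel("mission day")
        ax.set_ylabel("CRTI [ppm]")
        ax.legend()
        fig.tight_layout()
        fig.savefig(outdir / "forecast.png", dpi=120)
        plt.close(fig)
    write_manifest(outdir, {**config.to_dict(), "cut_day": cut_day, "horizon": horizon},
                   [Path(cohesion_csv)])
    return fc


# ---------------------------------------------------------------- CLI


def _setup_logging(verbose: bool) -> None:
    logging.basicConfig(
        stream=sys.stderr,
        level=logging.DEBUG if verbose else logging.INFO,
        format="%(levelname)s %(name)s: %(message)s",
    )


def _load_config(config_path: str | None, **overrides) -> RunConfig:
    cfg = RunConfig.from_yaml(config_path) if config_path else RunConfig()
    for k, v in overrides.items():
        if v is not None:
            setattr(cfg, k, v)
    cfg.validate()
    return cfg


@click.group()
@click.option("--verbose", is_flag=True, help="Debug logging to stderr.")
def main(verbose: bool) -> None:
    """Proximity-sensor crew-cohesion analytics."""
    _setup_logging(verbose)


@main.command("simulate")
@click.option("--config", "config_path", type=click.Path(exists=True), default=None,
              help="Mission config YAML (MissionConfig fields).")
@click.option("--seed", type=int, default=0, show_default=True)
@click.option("--days", type=int, default=60, show_default=True,
              help="Mission length in days.")
@click.option("--out", type=click.Path(), required=True)
def cmd_simulate(config_path: str | None, seed: int, days: int, out: str) -> None:
    """Generate a synthetic mission dataset with ground truth."""
    kwargs = {}
    if config_path:
        kwargs = yaml.safe_load(Path(config_path).read_text(encoding="utf-8")) or {}
        if "measurement_weekdays" in kwargs:
            kwargs["measurement_weekdays"] = tuple(kwargs["measurement_weekdays"])
        if "session" in kwargs:
            kwargs["session"] = tuple(kwargs["session"])
    kwargs.setdefault("mission_days", days)
    kwargs["seed"] = seed
    try:
        mc = simulate.MissionConfig(**kwargs)
    except (TypeError, ValueError) as exc:
        raise click.ClickException(f"invalid mission config: {exc}") from exc
    outdir = Path(out)
    if not outdir.exists():
        log.info("creating output directory %s", outdir)
    ds = simulate.simulate_mission(mc)
    simulate.write_dataset(ds, outdir)
    log.info("wrote %d measurement days to %s", len(ds.days), outdir)


@main.command("analyze")
@click.argument("logs_dir", type=click.Path(exists=True))
@click.option("--config", "config_path", type=click.Path(exists=True), default=None)
@click.option("--out", type=click.Path(), required=True)
@click.option("--rule", type=click.Choice(["union", "mutual"]), default=None)
@click.option("--threshold-db", type=float, default=None)
@click.option("--window", type=str, default=None, help="HH:MM-HH:MM time-of-day window.")
@click.option("--seed", type=int, default=None)
def cmd_analyze(logs_dir: str, config_path: str | None, out: str, rule: str | None,
                threshold_db: float | None, window: str | None, seed: int | None) -> None:
    """Analyze a directory of sensor logs into a results bundle."""
    cfg = _load_config(
        config_path,
        rule=rule,
        rssi_threshold_db=threshold_db,
        window=_parse_window(window) if window else None,
        seed=seed,
    )
    try:
        analyze_logs(logs_dir, cfg, out)
    except EmptyDayError as exc:
        raise click.ClickException(str(exc)) from exc
    log.info("analysis bundle written to %s", out)


@main.command("forecast")
@click.argument("cohesion_csv", type=click.Path(exists=True))
@click.option("--config", "config_path", type=click.Path(exists=True), default=None)
@click.option("--cut-day", type=int, required=True)
@click.option("--horizon", type=int, default=45, show_default=True)
@click.option("--out", type=click.Path(), required=True)
def cmd_forecast(cohesion_csv: str, config_path: str | None, cut_day: int,
                 horizon: int, out: str) -> None:
    """Forecast the cohesion index past a cut day."""
    cfg = _load_config(config_path)
    try:
        forecast_pipeline(cohesion_csv, cut_day, horizon, cfg, out)
    except (ValueError, InsufficientDataError) as exc:
        raise click.ClickException(str(exc)) from exc
    log.info("forecast bundle written to %s", out)


@main.command("report")
@click.argument("results_dir", type=click.Path(exists=True))
def cmd_report(results_dir: str) -> None:
    """Regenerate plots from an existing analysis bundle."""
    rd = Path(results_dir)
    mats = contacts.read_contact_matrices(rd / "contact_matrices.csv")
    series = sociometry.CohesionSeries.from_daily(mats)
    centers = sociometry.group_center_series(mats)
    render_plots(rd, mats, series, centers)
    log.info("plots refreshed in %s", rd)


if __name__ == "__main__":
    main()
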