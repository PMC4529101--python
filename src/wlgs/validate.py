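"""Reliability and validity metrics for the proximity system.

Four independent checks of the sensor data:

* **congruence** — how often two sensors register each other mutually,
  as a percentage of the epochs in which at least one of them registered
  the other.  Under independent per-direction detection with probability
  p on truly co-present epochs the expected congruence is 100·p/(2−p).
* **binary pair correlation** — the Pearson (phi) correlation of two
  sensors' 0/1 detection series.
* **localization vs video** — each crew sensor is placed at the habitat
  beacon it hears loudest; runs of constant placement are compared
  against human-annotated video intervals, binned hourly, yielding
  correct/failed detection counts and percentages.
* **actigraphy synchronization** — the badge's internal activity signal
  is aligned to an external actigraph by the lag that maximizes their
  cross-correlation, estimated per day (the two systems' clocks drift
  independently across a long mission).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .contacts import EPOCH_SECONDS, SensorLog
from .errors import AlignmentError, ConstantSeriesError, EmptyReportError


def _aligned(a: pd.Series | np.ndarray, b: pd.Series | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(a, pd.Series) and isinstance(b, pd.Series):
        if len(a) != len(b) or not np.array_equal(np.asarray(a.index), np.asarray(b.index)):
            raise AlignmentError("series are on different epoch grids")
        return a.to_numpy(), b.to_numpy()
    a, b = np.asarray(a), np.asarray(b)
    if a.shape != b.shape:
        raise AlignmentError("series have different lengths")
    return a, b


def congruence(a_to_b: pd.Series | np.ndarray, b_to_a: pd.Series | np.ndarray) -> float:
    """Percentage of mutual registration, normalized by the count of
    epochs with at least one-sided registration.

    Returns NaN when neither side ever registered the other (undefined).
    """
    a, b = _aligned(a_to_b, b_to_a)
    a, b = a.astype(bool), b.astype(bool)
    union = int((a | b).sum())
    if union == 0:
        return float("nan")
    return 100.0 * int((a & b).sum()) / union


def binary_pair_correlation(a: pd.Series | np.ndarray, b: pd.Series | np.ndarray) -> float:
    """Pearson correlation of two 0/1 detection series (the phi
    coefficient of their 2×2 contingency table)."""
    x, y = _aligned(a, b)
    x, y = x.astype(float), y.astype(float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ConstantSeriesError("correlation undefined for a constant series")
    return float(np.corrcoef(x, y)[0, 1])


def localize(
    crew_log: SensorLog,
    habitat_ids: Sequence[str],
    grid: np.ndarray | None = None,
) -> pd.Series:
    """Per-epoch location of a crew member: the habitat beacon received
    with the strongest signal, or ``"none"`` when no beacon was heard."""
    habitat_ids = set(habitat_ids)
    r = crew_log.records
    hits = r[r["detected_id"].isin(habitat_ids)]
    if grid is None:
        e = crew_log.epochs
        grid = np.arange(e[0], e[-1] + EPOCH_SECONDS, EPOCH_SECONDS)
    out = pd.Series("none", index=grid, dtype=object)
    if len(hits):
        best = hits.sort_values("rssi_db").drop_duplicates("epoch_start_s", keep="last")
        best = best[best["epoch_start_s"].isin(grid)]
        out.loc[best["epoch_start_s"].to_numpy()] = best["detected_id"].to_numpy()
    out.index.name = "epoch_start_s"
    return out


@dataclass
class AgreementReport:
    """Hourly-binned agreement between sensor localization and video.

    Per bin: total detections, failed detections, and percent correct
    (100·(detections − failed)/detections); the summary row holds the
    column sums and the percentage recomputed from them.
    """

    bins: pd.DataFrame  # index bin label, columns percent_correct, detections, failed
    summary_percent: float
    summary_detections: int
    summary_failed: int

    @classmethod
    def from_counts(
        cls, labels: Sequence[str], detections: Sequence[int], failed: Sequence[int]
    ) -> "AgreementReport":
        det = np.asarray(detections, dtype=int)
        fai = np.asarray(failed, dtype=int)
        with np.errstate(invalid="ignore", divide="ignore"):
            pct = 100.0 * (det - fai) / det
        bins = pd.DataFrame(
            {"percent_correct": pct, "detections": det, "failed": fai},
            index=pd.Index(labels, name="bin"),
        )
        td, tf = int(det.sum()), int(fai.sum())
        if td == 0:
            raise EmptyReportError("no detections to report")
        return cls(
            bins=bins,
            summary_percent=100.0 * (td - tf) / td,
            summary_detections=td,
            summary_failed=tf,
        )

    def to_frame(self) -> pd.DataFrame:
        out = self.bins.copy()
        out.loc["summary"] = [self.summary_percent, self.summary_detections, self.summary_failed]
        return out


def _bin_label(t: float) -> str:
    h = int(t // 3600)
    return f"{h:02d}:{int(t % 3600) // 60:02d}"


def video_agreement(
    locations: Mapping[str, pd.Series],
    video: Mapping[str, Sequence[tuple[str, float, float]]],
    bin_seconds: int = 3600,
    bin_anchor: float | None = None,
    mode: str = "runs",
) -> AgreementReport:
    """Compare sensor localization against video annotation intervals.

    Only epochs where the video places a member in a filmed location AND
    the sensor assigns some location enter the comparison (private,
    unfilmed intervals are simply absent from the annotation).  A
    *detection* is, by default (``mode="runs"``), a maximal run of
    consecutive such epochs with a constant (video location, assigned
    location) state — event-like counts — and it *fails* when the
    assigned location differs from the video's; ``mode="epochs"`` counts
    every epoch instead.  Detections are binned by their start time.
    """
    if mode not in ("runs", "epochs"):
        raise ValueError(f"unknown agreement mode: {mode!r}")
    events: list[tuple[float, bool]] = []  # (start time, failed?)
    for member, loc in locations.items():
        tracks = video.get(member, [])
        if not len(tracks):
            continue
        grid = np.asarray(loc.index, dtype=float)
        vloc = np.full(len(grid), None, dtype=object)
        for zone, s, e in tracks:
            vloc[(grid >= s) & (grid < e)] = zone
        wloc = loc.to_numpy(dtype=object)
        valid = (vloc != None) & (wloc != "none")  # noqa: E711
        if not valid.any():
            continue
        if mode == "epochs":
            for i in np.flatnonzero(valid):
                events.append((grid[i], wloc[i] != vloc[i]))
        else:
            run_start = None
            state = None
            for i in range(len(grid) + 1):
                cur = (vloc[i], wloc[i]) if i < len(grid) and valid[i] else None
                contiguous = (
                    cur is not None
                    and state is not None
                    and i > 0
                    and grid[i] - grid[i - 1] == EPOCH_SECONDS
                )
                if cur != state or not (cur is None or contiguous):
                    if state is not None:
                        events.append((run_start, state[1] != state[0]))
                    run_start = grid[i] if cur is not None else None
                    state = cur
    if not events:
        raise EmptyReportError("no overlapping video/sensor coverage")
    start = bin_anchor if bin_anchor is not None else min(t for t, _ in events)
    binned: dict[float, list[int]] = {}
    for t, fail in events:
        b = start + bin_seconds * int((t - start) // bin_seconds)
        d = binned.setdefault(b, [0, 0])
        d[0] += 1
        d[1] += int(fail)
    keys = sorted(binned)
    labels = [f"{_bin_label(b)}–{_bin_label(b + bin_seconds)}" for b in keys]
    return AgreementReport.from_counts(
        labels, [binned[b][0] for b in keys], [binned[b][1] for b in keys]
    )


def activity_series(log: SensorLog, grid: np.ndarray | None = None) -> pd.Series:
    """Per-epoch activity magnitude from a badge's accelerometer records
    (mean |ax| over the epoch's records; gaps forward-filled)."""
    r = log.records
    if grid is None:
        e = log.epochs
        grid = np.arange(e[0], e[-1] + EPOCH_SECONDS, EPOCH_SECONDS)
    per_epoch = r.groupby("epoch_start_s")["ax"].apply(lambda v: float(np.abs(v).mean()))
    out = per_epoch.reindex(grid).ffill().bfill()
    out.index.name = "epoch_start_s"
    return out


@dataclass
class SyncResult:
    lag_s: float  # external clock minus internal clock
    correlation: float
    corrected: pd.Series  # internal series re-stamped onto the external clock
    flat: bool = False


def sync_activity(
    internal: pd.Series,
    external: pd.Series,
    max_lag_s: float = 600.0,
    epoch_seconds: int = EPOCH_SECONDS,
) -> SyncResult:
    """Align the badge's internal activity series to an external
    actigraph for one day.

    Searches lags on the epoch grid within ±``max_lag_s`` for the maximum
    of the cross-correlation of the mean-centered series; the returned
    ``corrected`` series is the internal one re-stamped by that
    day-specific constant.  Flat series yield a warning and lag 0.
    """
    x = internal.to_numpy(dtype=float)
    y = external.to_numpy(dtype=float)
    gx = np.asarray(internal.index, dtype=float)
    gy = np.asarray(external.index, dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("flat activity series; applying zero lag", stacklevel=2)
        return SyncResult(lag_s=0.0, correlation=float("nan"), corrected=internal, flat=True)
    xc = x - x.mean()
    yc = y - y.mean()
    max_k = int(max_lag_s // epoch_seconds)
    best = (-np.inf, 0)
    for k in range(-max_k, max_k + 1):
        lag = k * epoch_seconds
        common = np.intersect1d(gx + lag, gy)
        if len(common) < 10:
            continue
        xi = np.searchsorted(gx, common - lag)
        yi = np.searchsorted(gy, common)
        a, b = xc[xi], yc[yi]
        denom = np.sqrt((a**2).sum() * (b**2).sum())
        if denom == 0:
            continue
        r = float((a * b).sum() / denom)
        if r > best[0]:
            best = (r, lag)
    r, lag = best
    corrected = pd.Series(x, index=gx + lag, name=internal.name)
    return SyncResult(lag_s=float(lag), correlation=r, corrected=corrected)


def read_video_annotations(path: str | Path) -> dict[str, list[tuple[str, float, float]]]:
    """Read the ``member,location,start_s,end_s`` annotation dialect."""
    df = pd.read_csv(path)
    out: dict[str, list[tuple[str, float, float]]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(str(row.member), []).append(
            (str(row.location), float(row.start_s), float(row.end_s))
        )
    return out


def write_agreement_report(report: AgreementReport, path: str | Path) -> None:
    report.to_frame().to_csv(path, index_label="bin")
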