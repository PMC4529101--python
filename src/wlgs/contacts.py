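"""Raw proximity-log handling: parsing, binarization, contact tensors and
daily contact-time matrices.

The badge sensors sample at 0.2 Hz: each 5-second epoch a sensor records
which other sensors it heard and at what signal strength (dB), plus a
3-axis accelerometer sample.  This module turns those per-sensor logs into
a symmetric per-epoch co-presence tensor and, from it, the seconds each
unordered crew pair spent together on a measurement day (``t_AB``) along
with the total registration time ``T``.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import AlignmentError, ConfigurationError, EmptyDayError, EmptyLogError

EPOCH_SECONDS = 5
#: CSV/JSON-lines field order for the sensor-log dialects.
LOG_FIELDS = ("epoch_start_s", "sensor_id", "detected_id", "rssi_db", "ax", "ay", "az")

_DAY_RE = re.compile(r"day(\d+)")


def snap_to_grid(t: float, epoch_seconds: int = EPOCH_SECONDS) -> int:
    """Snap a timestamp (seconds since midnight) to the nearest epoch start.

    Epochs are half-open intervals ``[t, t+5)`` anchored at midnight; ties
    (exactly halfway) resolve toward the earlier epoch.
    """
    base = int(np.floor(t / epoch_seconds)) * epoch_seconds
    rem = t - base
    return base + epoch_seconds if rem > epoch_seconds / 2 else base


@dataclass
class SensorLog:
    """One sensor's raw detections for one measurement day.

    ``records`` has columns ``epoch_start_s`` (grid-snapped int),
    ``detected_id``, ``rssi_db``, ``ax``, ``ay``, ``az`` with at most one
    row per (epoch, detected_id).
    """

    sensor_id: str
    day: int
    records: pd.DataFrame
    n_malformed: int = 0
    n_snapped: int = 0

    def __post_init__(self) -> None:
        r = self.records
        if len(r) and (r["detected_id"] == self.sensor_id).any():
            raise ValueError("a sensor cannot detect itself")
        if len(r) and not np.isfinite(r["rssi_db"]).all():
            raise ValueError("non-finite rssi")

    @property
    def epochs(self) -> np.ndarray:
        return np.unique(self.records["epoch_start_s"].to_numpy())

    def span_seconds(self) -> float:
        """Wall time covered, first epoch start to last epoch end."""
        e = self.epochs
        if len(e) == 0:
            return 0.0
        return float(e[-1] + EPOCH_SECONDS - e[0])


def _day_from_path(path: Path) -> int:
    m = _DAY_RE.search(path.stem)
    return int(m.group(1)) if m else 0


def parse_sensor_log(
    path: str | Path,
    dialect: str = "csv",
    day: int | None = None,
    epoch_seconds: int = EPOCH_SECONDS,
) -> SensorLog:
    """Read one sensor's log file (CSV or JSON-lines dialect).

    Timestamps are snapped to the 5-s grid; malformed lines are counted on
    the returned :class:`SensorLog` (``n_malformed``) rather than silently
    dropped; duplicate (epoch, detected_id) records keep the strongest
    signal.  Raises :class:`EmptyLogError` if no valid record remains and
    :class:`ConfigurationError` for an unknown dialect.
    """
    path = Path(path)
    if dialect not in ("csv", "jsonl"):
        raise ConfigurationError(f"unknown sensor-log dialect: {dialect!r}")
    text = path.read_text(encoding="utf-8")
    lines = [ln for ln in text.splitlines() if ln.strip()]
    n_malformed = 0
    if dialect == "csv":
        if lines and lines[0].replace(" ", "").startswith("epoch_start_s,"):
            lines = lines[1:]
        n_fields = len(LOG_FIELDS)
        good = [ln for ln in lines if ln.count(",") == n_fields - 1]
        n_malformed = len(lines) - len(good)
        if not good:
            raise EmptyLogError(f"no valid records in {path}")
        from io import StringIO

        df = pd.read_csv(
            StringIO("\n".join(good)), names=list(LOG_FIELDS), header=None, dtype=str
        )
        for col in ("epoch_start_s", "rssi_db", "ax", "ay", "az"):
            df[col] = pd.to_numeric(df[col], errors="coerce")
        bad = df[["epoch_start_s", "rssi_db", "ax", "ay", "az"]].isna().any(axis=1)
        n_malformed += int(bad.sum())
        df = df[~bad]
    else:
        rows = []
        for ln in lines:
            try:
                obj = json.loads(ln)
                rows.append(
                    (
                        float(obj["epoch_start_s"]),
                        str(obj["sensor_id"]),
                        str(obj["detected_id"]),
                        float(obj["rssi_db"]),
                        float(obj["ax"]),
                        float(obj["ay"]),
                        float(obj["az"]),
                    )
                )
            except (json.JSONDecodeError, KeyError, TypeError, ValueError):
                n_malformed += 1
        if not rows:
            raise EmptyLogError(f"no valid records in {path}")
        df = pd.DataFrame(rows, columns=list(LOG_FIELDS))
    if df.empty:
        raise EmptyLogError(f"no valid records in {path}")
    df = df.astype({c: np.float64 for c in ("rssi_db", "ax", "ay", "az")})
    sensor_ids = df["sensor_id"].unique()
    if len(sensor_ids) != 1:
        raise ConfigurationError(
            f"{path} mixes records from several sensors: {sorted(sensor_ids)}"
        )
    t = df["epoch_start_s"].to_numpy(dtype=float)
    base = np.floor(t / epoch_seconds) * epoch_seconds
    snapped = np.where(t - base > epoch_seconds / 2, base + epoch_seconds, base)
    n_snapped = int((snapped != t).sum())
    df["epoch_start_s"] = snapped.astype(np.int64)
    df = df[np.isfinite(df["rssi_db"]) & (df["detected_id"] != df["sensor_id"])]
    if df.empty:
        raise EmptyLogError(f"no valid records in {path}")
    # strongest signal wins when snapping creates duplicates
    df = (
        df.sort_values("rssi_db")
        .drop_duplicates(["epoch_start_s", "detected_id"], keep="last")
        .sort_values(["epoch_start_s", "detected_id"])
        .reset_index(drop=True)
    )
    return SensorLog(
        sensor_id=str(sensor_ids[0]),
        day=day if day is not None else _day_from_path(path),
        records=df.drop(columns=["sensor_id"]),
        n_malformed=n_malformed,
        n_snapped=n_snapped,
    )


def write_sensor_log(log: SensorLog, path: str | Path, dialect: str = "csv") -> None:
    """Write a log back out in a parse-compatible dialect (round-trip safe)."""
    path = Path(path)
    df = log.records.copy()
    df.insert(1, "sensor_id", log.sensor_id)
    if dialect == "csv":
        df.to_csv(path, index=False, columns=list(LOG_FIELDS))
    elif dialect == "jsonl":
        with open(path, "w", encoding="utf-8") as fh:
            for row in df[list(LOG_FIELDS)].itertuples(index=False):
                fh.write(json.dumps(dict(zip(LOG_FIELDS, row))) + "\n")
    else:
        raise ConfigurationError(f"unknown sensor-log dialect: {dialect!r}")


def binarize(
    log: SensorLog,
    rssi_threshold: float = -np.inf,
    grid: np.ndarray | None = None,
) -> pd.DataFrame:
    """Recode signal amplitudes into per-epoch presence (1) / absence (0).

    A detected sensor is *present* at an epoch iff a record exists there
    with ``rssi_db >= rssi_threshold``.  Returns a dense 0/1 frame indexed
    by epoch start (the log's own span by default, or an explicit ``grid``)
    with one column per detected sensor id.
    """
    if np.isnan(rssi_threshold) or rssi_threshold == np.inf:
        raise ConfigurationError("rssi_threshold must be finite or -inf")
    r = log.records
    if grid is None:
        e = log.epochs
        grid = np.arange(e[0], e[-1] + EPOCH_SECONDS, EPOCH_SECONDS)
    hits = r[r["rssi_db"] >= rssi_threshold]
    det = (
        hits.assign(v=1)
        .pivot_table(index="epoch_start_s", columns="detected_id", values="v", fill_value=0)
        .reindex(grid, fill_value=0)
        .astype(np.int8)
    )
    det.index.name = "epoch_start_s"
    det.columns.name = None
    return det


@dataclass
class ContactTensor:
    """Binary co-presence per epoch per sensor pair for one day.

    ``directed[e, i, j]`` is 1 when sensor ``sensors[i]`` heard
    ``sensors[j]`` during epoch ``e``; ``symmetric`` is the undirected
    co-presence layer under the chosen symmetrization rule (``union``:
    either direction suffices; ``mutual``: both required).
    """

    day: int
    sensors: list[str]
    epochs: np.ndarray  # epoch start seconds, strictly increasing, step 5
    directed: np.ndarray  # bool (n_epochs, n, n)
    rule: str = "union"
    epoch_seconds: int = EPOCH_SECONDS
    symmetric: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if self.rule not in ("union", "mutual"):
            raise ConfigurationError(f"unknown symmetrization rule: {self.rule!r}")
        d = np.asarray(self.directed, dtype=bool)
        sym = d | d.transpose(0, 2, 1) if self.rule == "union" else d & d.transpose(0, 2, 1)
        n = len(self.sensors)
        sym[:, np.arange(n), np.arange(n)] = False
        self.directed = d
        self.symmetric = sym

    @property
    def n_epochs(self) -> int:
        return len(self.epochs)

    def pairs(self) -> list[tuple[str, str]]:
        s = self.sensors
        return [(s[i], s[j]) for i in range(len(s)) for j in range(i + 1, len(s))]


def build_contact_tensor(
    detections: Mapping[str, pd.DataFrame],
    rule: str = "union",
    sensors: Sequence[str] | None = None,
    day: int = 0,
) -> ContactTensor:
    """Assemble per-sensor detection frames into one co-presence tensor.

    All frames must share an identical epoch grid (:class:`AlignmentError`
    otherwise).  ``sensors`` restricts the tensor to the given ids (e.g.
    crew only, so crew–habitat detections never enter contact time);
    detections of ids outside the list are ignored.
    """
    if sensors is None:
        sensors = sorted(detections)
    sensors = list(sensors)
    grids = [np.asarray(detections[s].index) for s in sensors if s in detections]
    if not grids:
        raise EmptyDayError("no detection series supplied")
    grid = grids[0]
    for g in grids[1:]:
        if len(g) != len(grid) or not np.array_equal(g, grid):
            raise AlignmentError("detection series are on different epoch grids")
    n = len(sensors)
    directed = np.zeros((len(grid), n, n), dtype=bool)
    for i, s in enumerate(sensors):
        if s not in detections:
            continue
        det = detections[s]
        for j, t in enumerate(sensors):
            if t in det.columns and t != s:
                directed[:, i, j] = det[t].to_numpy() > 0
    return ContactTensor(day=day, sensors=sensors, epochs=grid, directed=directed, rule=rule)


@dataclass
class DailyContactMatrix:
    """Seconds spent together per unordered crew pair on one day.

    ``t_ab`` is indexed by ``(a, b)`` tuples with ``a < b``; ``T`` is the
    total registration time of the session in seconds.
    """

    day: int
    t_ab: pd.Series
    T: float
    n_crew: int

    def __post_init__(self) -> None:
        if self.T <= 0:
            raise EmptyDayError(f"day {self.day}: total registration time is zero")
        if (self.t_ab < 0).any() or (self.t_ab > self.T + 1e-9).any():
            raise ValueError("t_AB must lie in [0, T]")

    def crew_time(self) -> pd.Series:
        """Per-subject total time spent with any other crew member (the
        marginal of the pair matrix)."""
        members = sorted({m for pair in self.t_ab.index for m in pair})
        out = pd.Series(0.0, index=members)
        for (a, b), v in self.t_ab.items():
            out[a] += v
            out[b] += v
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "day": self.day,
                "member_a": [p[0] for p in self.t_ab.index],
                "member_b": [p[1] for p in self.t_ab.index],
                "t_ab_s": self.t_ab.to_numpy(),
                "total_s": self.T,
            }
        )


def contact_time(tensor: ContactTensor) -> DailyContactMatrix:
    """Sum co-presence epochs into pairwise seconds together.

    ``t_AB = 5 s × Σ_epochs symmetric(epoch, {A,B})`` and ``T = 5 s ×
    n_epochs`` (the session's registration time).
    """
    if tensor.n_epochs == 0:
        raise EmptyDayError(f"day {tensor.day}: contact tensor has no epochs")
    counts = tensor.symmetric.sum(axis=0)
    idx, vals = [], []
    for i, a in enumerate(tensor.sensors):
        for j in range(i + 1, len(tensor.sensors)):
            b = tensor.sensors[j]
            idx.append((a, b) if a < b else (b, a))
            vals.append(counts[i, j] * tensor.epoch_seconds)
    t_ab = pd.Series(vals, index=pd.Index(idx, tupleize_cols=False), dtype=float)
    return DailyContactMatrix(
        day=tensor.day,
        t_ab=t_ab,
        T=float(tensor.n_epochs * tensor.epoch_seconds),
        n_crew=len(tensor.sensors),
    )


def filter_epochs(
    tensor: ContactTensor,
    window: tuple[float, float] | None = None,
    activity: Mapping[str, pd.Series] | None = None,
) -> ContactTensor:
    """Restrict a tensor to a time-of-day window and/or ACTIVE epochs.

    ``window`` is (start, end) in seconds-of-day; epochs whose start lies
    in ``[start, end)`` are kept.  With an ``activity`` mask (per-member
    boolean series on the same epoch grid) a pair's co-presence is kept
    only at epochs where both members are ACTIVE; the session length T
    still reflects the windowed epoch count.
    """
    keep = np.ones(tensor.n_epochs, dtype=bool)
    if window is not None:
        start, end = window
        keep &= (tensor.epochs >= start) & (tensor.epochs < end)
    if not keep.any():
        raise EmptyDayError(f"day {tensor.day}: no epochs remain after filtering")
    epochs = tensor.epochs[keep]
    directed = tensor.directed[keep].copy()
    if activity is not None:
        n = len(tensor.sensors)
        active = np.ones((len(epochs), n), dtype=bool)
        for i, s in enumerate(tensor.sensors):
            if s in activity:
                mask = activity[s]
                if not np.array_equal(np.asarray(mask.index), tensor.epochs):
                    raise AlignmentError(f"activity mask for {s} is on a different grid")
                active[:, i] = mask.to_numpy(dtype=bool)[keep]
        both = active[:, :, None] & active[:, None, :]
        directed &= both
    return ContactTensor(
        day=tensor.day,
        sensors=list(tensor.sensors),
        epochs=epochs,
        directed=directed,
        rule=tensor.rule,
        epoch_seconds=tensor.epoch_seconds,
    )


def write_contact_matrices(matrices: Iterable[DailyContactMatrix], path: str | Path) -> None:
    """Long-format CSV ``day,member_a,member_b,t_ab_s,total_s``."""
    pd.concat([m.to_frame() for m in matrices], ignore_index=True).to_csv(path, index=False)


def read_contact_matrices(path: str | Path) -> list[DailyContactMatrix]:
    df = pd.read_csv(path)
    out = []
    for day, grp in df.groupby("day", sort=True):
        pairs = [tuple(sorted((a, b))) for a, b in zip(grp["member_a"], grp["member_b"])]
        t_ab = pd.Series(grp["t_ab_s"].to_numpy(dtype=float),
                         index=pd.Index(pairs, tupleize_cols=False))
        members = {m for p in pairs for m in p}
        out.append(
            DailyContactMatrix(
                day=int(day), t_ab=t_ab, T=float(grp["total_s"].iloc[0]), n_crew=len(members)
            )
        )
    return out
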