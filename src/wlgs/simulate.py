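"""Synthetic sensor-network generator with known ground truth.

Emulates a small isolated crew (default 6 members, 6 fixed habitat
beacons) wearing proximity badges on twice-weekly measurement days over a
long mission.  Each day has two behavioural regimes: a morning driven by a
deterministic work roster (co-presence dictated by shared work zones) and
an afternoon where social contacts are sampled from a latent pairwise
affinity matrix (higher affinity -> more and longer shared time, with
occasional triads and quads).  Detection is imperfect: each direction of
each in-range pair is registered independently per 5-s epoch with
probability ``detect_prob``, signal strengths are drawn from a truncated
normal in dB, battery dropout truncates logs, and whole sessions go
missing.  The generator emits raw per-sensor logs plus the ground truth
needed to validate every downstream stage: true pair contact times, true
locations (as a video-annotation interval table), and an external
actigraphy series with a per-day clock offset.

Randomness policy: one master seed; each day draws from an independent
substream keyed by (seed, day) so any day is reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import yaml

from .contacts import EPOCH_SECONDS, SensorLog, write_sensor_log

CREW_IDS = ("A", "B", "C", "D", "E", "F")

# time-of-day anchors (seconds since midnight)
SESSION_START = 9 * 3600 + 18 * 60   # 09:18
SESSION_END = 20 * 3600 + 18 * 60    # 20:18
AFTERNOON_START = 14 * 3600 + 18 * 60  # 14:18, start of spare time


@dataclass
class MissionConfig:
    """Study-design parameters of a simulated mission.

    Defaults mirror the monitored mission: 6 crew + 6 habitat sensors,
    520 mission days with twice-weekly (Tue/Fri) sessions starting on day
    15, an 11-hour daily session, 0.2 Hz epochs, and per-direction
    per-epoch detection probability 0.953 (the level that yields ~91%
    mutual-registration congruence).
    """

    n_crew: int = 6
    n_habitat: int = 6
    mission_days: int = 520
    start_day: int = 15
    measurement_weekdays: tuple[int, ...] = (1, 4)  # Mon=0; Tue and Fri
    session: tuple[int, int] = (SESSION_START, SESSION_END)
    epoch_seconds: int = EPOCH_SECONDS
    detect_prob: float = 0.953
    rssi_mean_db: float = -60.0
    rssi_sd_db: float = 8.0
    dropout_prob: float = 0.3
    missing_session_prob: float = 0.015
    afternoon_start: int = AFTERNOON_START
    social_events_per_day: float = 40.0
    mean_event_s: float = 600.0
    clock_offset_s: float | None = None  # None -> per-day N(0, clock_offset_sd)
    clock_offset_sd: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.detect_prob, self.dropout_prob, self.missing_session_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.n_crew < 2:
            raise ValueError("need at least two crew members")
        start, end = self.session
        if not (0 <= start < end <= 24 * 3600) or end - start > 20 * 3600:
            raise ValueError("session must fit the day and the 20 h battery limit")

    @property
    def crew_ids(self) -> list[str]:
        if self.n_crew <= len(CREW_IDS):
            return list(CREW_IDS[: self.n_crew])
        return [f"S{i}" for i in range(self.n_crew)]

    @property
    def habitat_ids(self) -> list[str]:
        return [f"H{i + 1}" for i in range(self.n_habitat)]

    def epoch_grid(self) -> np.ndarray:
        return np.arange(self.session[0], self.session[1], self.epoch_seconds)


def measurement_days(config: MissionConfig) -> list[int]:
    """Scheduled session days: the configured weekdays from start_day to
    mission end, with mission day 1 taken as a Monday."""
    return [
        d
        for d in range(config.start_day, config.mission_days + 1)
        if (d - 1) % 7 in config.measurement_weekdays
    ]


def default_affinity(config: MissionConfig) -> np.ndarray:
    """Latent pairwise attraction weights in [0.15, 1], symmetric, zero
    diagonal; fixed per mission (drawn from the master seed only)."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    n = config.n_crew
    a = rng.uniform(0.15, 1.0, size=(n, n))
    a = np.triu(a, 1)
    a = a + a.T
    return a


def _merge_intervals(ivs: list[tuple[float, float]]) -> list[tuple[float, float]]:
    if not ivs:
        return []
    ivs = sorted(ivs)
    out = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


@dataclass
class GroundTruthSchedule:
    """True behaviour for one day: who was with whom, where, and when
    they were ACTIVE.  Contact implies co-location by construction."""

    day: int
    crew: list[str]
    contact_intervals: dict[tuple[str, str], list[tuple[float, float]]]
    locations: dict[str, list[tuple[str, float, float]]]  # (zone, start, end)
    activity: dict[str, list[tuple[float, float]]]  # ACTIVE intervals
    affinity: np.ndarray

    def true_t_ab(self, epoch_seconds: int = EPOCH_SECONDS) -> pd.Series:
        """Scheduled pair time quantized to the epoch grid (what a perfect
        detector recovers)."""
        out = {}
        for pair, ivs in self.contact_intervals.items():
            t = 0.0
            for s, e in ivs:
                first = int(np.ceil(s / epoch_seconds))
                last = int(np.ceil(e / epoch_seconds))
                t += (last - first) * epoch_seconds
            out[pair] = t
        return pd.Series(out, dtype=float)

    def zone_at(self, member: str, t: float) -> str | None:
        for zone, s, e in self.locations[member]:
            if s <= t < e:
                return zone
        return None


def make_schedule(
    config: MissionConfig, day: int, affinity: np.ndarray | None = None
) -> GroundTruthSchedule:
    """Build one day's ground truth; reproducible under (seed, day).

    Mornings follow a deterministic work roster: each hour block assigns
    every member a habitat zone and members sharing a zone are in contact.
    Afternoons sample social gatherings from the affinity matrix: a
    gathering picks 2 (mostly), 3 or 4 members weighted by pairwise
    affinity, a zone, and an exponential duration; members of a gathering
    are co-located for its span.  Event times are snapped to the 5-s grid.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, day, 101]))
    crew = config.crew_ids
    zones = config.habitat_ids
    n = config.n_crew
    eps = config.epoch_seconds
    sess_start, sess_end = config.session
    aft_start = min(config.afternoon_start, sess_end)
    if affinity is None:
        affinity = default_affinity(config)

    contacts: dict[tuple[str, str], list[tuple[float, float]]] = {}
    locations: dict[str, list[tuple[str, float, float]]] = {m: [] for m in crew}

    def add_contact(a: str, b: str, s: float, e: float) -> None:
        pair = (a, b) if a < b else (b, a)
        contacts.setdefault(pair, []).append((s, e))

    # --- morning work roster (deterministic in day) ---
    t = sess_start
    block = 0
    while t < aft_start:
        e = min(t + 3600, aft_start)
        assign = {m: zones[(i + block + day) % len(zones)] for i, m in enumerate(crew)}
        for m in crew:
            locations[m].append((assign[m], t, e))
        for i in range(n):
            for j in range(i + 1, n):
                if assign[crew[i]] == assign[crew[j]]:
                    add_contact(crew[i], crew[j], t, e)
        t = e
        block += 1

    # --- afternoon social gatherings (affinity-driven) ---
    busy: dict[str, list[tuple[float, float]]] = {m: [] for m in crew}
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    w = np.array([affinity[i, j] for i, j in pairs], dtype=float)
    total_aff = w.sum()
    n_events = rng.poisson(config.social_events_per_day) if total_aff > 0 else 0
    for _ in range(n_events):
        k = rng.choice([2, 3, 4], p=[0.8, 0.15, 0.05])
        i, j = pairs[rng.choice(len(pairs), p=w / total_aff)]
        members = {i, j}
        while len(members) < k:
            members.add(int(rng.integers(n)))
        # higher-affinity pairs meet not only more often but also longer
        mean_dur = config.mean_event_s * 2 * affinity[i, j]
        dur = float(np.clip(rng.exponential(mean_dur), 60, 3600))
        dur = max(eps, round(dur / eps) * eps)
        if aft_start + dur >= sess_end:
            continue
        start = float(rng.uniform(aft_start, sess_end - dur))
        start = round(start / eps) * eps
        end = start + dur
        mem_ids = [crew[m] for m in members]
        if any(s < end and start < e for m in mem_ids for s, e in busy[m]):
            continue  # members already engaged; drop the event
        zone = zones[int(rng.integers(len(zones)))]
        for m in mem_ids:
            busy[m].append((start, end))
            locations[m].append((zone, start, end))
        for a_i, a in enumerate(mem_ids):
            for b in mem_ids[a_i + 1:]:
                add_contact(a, b, start, end)

    # afternoon default zone = own quarters, overridden by gatherings
    for i, m in enumerate(crew):
        gaps = [(aft_start, sess_end)]
        for s, e in sorted(busy[m]):
            new = []
            for gs, ge in gaps:
                if e <= gs or s >= ge:
                    new.append((gs, ge))
                else:
                    if gs < s:
                        new.append((gs, s))
                    if e < ge:
                        new.append((e, ge))
            gaps = new
        own = zones[i % len(zones)]
        for gs, ge in gaps:
            if ge > gs:
                locations[m].append((own, gs, ge))
        locations[m] = sorted(locations[m], key=lambda z: z[1])

    contacts = {p: _merge_intervals(ivs) for p, ivs in contacts.items()}

    # ACTIVE everywhere except one rest block per member
    activity = {}
    for m in crew:
        rest_len = float(rng.uniform(20 * 60, 40 * 60))
        rest_start = float(rng.uniform(sess_start, sess_end - rest_len))
        rest_start = round(rest_start / eps) * eps
        rest_len = round(rest_len / eps) * eps
        activity[m] = [
            (sess_start, rest_start),
            (rest_start + rest_len, sess_end),
        ]
    return GroundTruthSchedule(
        day=day,
        crew=list(crew),
        contact_intervals=contacts,
        locations=locations,
        activity=activity,
        affinity=affinity,
    )


def _interval_mask(grid: np.ndarray, ivs: Iterable[tuple[float, float]]) -> np.ndarray:
    mask = np.zeros(len(grid), dtype=bool)
    for s, e in ivs:
        mask |= (grid >= s) & (grid < e)
    return mask


def _exertion_profile(schedule: GroundTruthSchedule, member: str, grid: np.ndarray,
                      rng: np.random.Generator) -> np.ndarray:
    """Shared activity signal both the badge accelerometer and the external
    actigraph observe: per-10-min random exertion level while ACTIVE, near
    zero at rest."""
    active = _interval_mask(grid, schedule.activity[member])
    block = (grid - grid[0]) // 600
    n_blocks = int(block.max()) + 1
    levels = rng.uniform(60.0, 220.0, size=n_blocks)
    prof = levels[block.astype(int)]
    prof[~active] = 8.0
    return prof


def simulate_day(schedule: GroundTruthSchedule, config: MissionConfig) -> dict[str, SensorLog]:
    """Render one day's schedule into noisy per-sensor logs.

    Each direction of each in-contact pair is detected independently per
    epoch with probability ``detect_prob``; co-located habitat beacons are
    detected the same way (both directions, for localization and its
    verification); battery dropout truncates a sensor's log at a uniform
    random time.  Accelerometer columns carry the member's exertion
    profile plus noise (habitat sensors are static).
    """
    day = schedule.day
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, day, 202]))
    grid = config.epoch_grid()
    crew = schedule.crew
    p = config.detect_prob

    def rssi(size: int) -> np.ndarray:
        return np.clip(rng.normal(config.rssi_mean_db, config.rssi_sd_db, size), -95.0, -20.0)

    # per-member exertion (accelerometer signal)
    exertion = {m: _exertion_profile(schedule, m, grid, rng) for m in crew}

    frames: dict[str, list[pd.DataFrame]] = {s: [] for s in crew + config.habitat_ids}

    def emit(sensor: str, detected: str, mask: np.ndarray) -> None:
        det = mask & (rng.random(len(grid)) < p)
        idx = np.flatnonzero(det)
        if len(idx) == 0:
            return
        m = len(idx)
        if sensor in exertion:
            ax = exertion[sensor][idx] + rng.normal(0, 10, m)
            noise_sd = 10.0
        else:  # habitat sensors do not move
            ax = rng.normal(0, 2, m)
            noise_sd = 2.0
        frames[sensor].append(
            pd.DataFrame(
                {
                    "epoch_start_s": grid[idx].astype(np.int64),
                    "detected_id": detected,
                    "rssi_db": rssi(m),
                    "ax": ax,
                    "ay": rng.normal(0, noise_sd, m),
                    "az": rng.normal(0, noise_sd, m),
                }
            )
        )

    # crew-crew detections
    for a_i, a in enumerate(crew):
        for b in crew[a_i + 1:]:
            pair = (a, b) if a < b else (b, a)
            ivs = schedule.contact_intervals.get(pair, [])
            if not ivs:
                continue
            mask = _interval_mask(grid, ivs)
            emit(a, b, mask)
            emit(b, a, mask)

    # crew-habitat detections (localization channel)
    for m in crew:
        for zone, s, e in schedule.locations[m]:
            mask = (grid >= s) & (grid < e)
            emit(m, zone, mask)
            emit(zone, m, mask)

    # battery dropout truncates a log
    logs: dict[str, SensorLog] = {}
    for sensor, fs in frames.items():
        if not fs:
            continue
        df = pd.concat(fs, ignore_index=True)
        if rng.random() < config.dropout_prob:
            cutoff = rng.uniform(config.session[0], config.session[1])
            df = df[df["epoch_start_s"] < cutoff]
        if df.empty:
            continue
        df = df.sort_values(["epoch_start_s", "detected_id"]).reset_index(drop=True)
        logs[sensor] = SensorLog(sensor_id=sensor, day=day, records=df)
    return logs


@dataclass
class DayData:
    day: int
    schedule: GroundTruthSchedule
    logs: dict[str, SensorLog]
    clock_offset_s: float
    actigraphy: pd.DataFrame  # member, epoch_start_s, counts (external clock)


@dataclass
class MissionDataset:
    config: MissionConfig
    days: dict[int, DayData] = field(default_factory=dict)

    def truth_t_ab(self) -> pd.DataFrame:
        rows = []
        for day, dd in sorted(self.days.items()):
            for (a, b), t in dd.schedule.true_t_ab(self.config.epoch_seconds).items():
                rows.append({"day": day, "member_a": a, "member_b": b, "t_ab_s": t})
        return pd.DataFrame(rows)


def make_external_actigraphy(
    schedule: GroundTruthSchedule, config: MissionConfig, offset_s: float
) -> pd.DataFrame:
    """External actigraph series on the session grid whose clock runs
    ``offset_s`` seconds behind the badge clock: the value stamped at
    external time t is the exertion that truly occurred at t − offset."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, schedule.day, 303]))
    grid = config.epoch_grid()
    # regenerate the same exertion profiles drawn first in simulate_day
    prof_rng = np.random.default_rng(np.random.SeedSequence([config.seed, schedule.day, 202]))
    profiles = {m: _exertion_profile(schedule, m, grid, prof_rng) for m in schedule.crew}
    true_t = grid - offset_s
    idx = np.clip(np.round((true_t - grid[0]) / config.epoch_seconds), 0,
                  len(grid) - 1).astype(int)
    rows = []
    for m in schedule.crew:
        counts = profiles[m][idx] + rng.normal(0, 10, len(grid))
        for t, c in zip(grid, counts):
            rows.append({"member": m, "epoch_start_s": int(t), "counts": float(c)})
    return pd.DataFrame(rows)


def simulate_mission(config: MissionConfig) -> MissionDataset:
    """Simulate every scheduled measurement day of the mission (minus
    randomly missing sessions) and bundle logs with ground truth."""
    ds = MissionDataset(config=config)
    miss_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 404]))
    for day in measurement_days(config):
        if miss_rng.random() < config.missing_session_prob:
            continue
        schedule = make_schedule(config, day)
        logs = simulate_day(schedule, config)
        if config.clock_offset_s is not None:
            offset = float(config.clock_offset_s)
        else:
            offset = float(
                np.random.default_rng(
                    np.random.SeedSequence([config.seed, day, 505])
                ).normal(0, config.clock_offset_sd)
            )
        acti = make_external_actigraphy(schedule, config, offset)
        ds.days[day] = DayData(
            day=day, schedule=schedule, logs=logs, clock_offset_s=offset, actigraphy=acti
        )
    return ds


def write_dataset(ds: MissionDataset, outdir: str | Path) -> Path:
    """Write the ground-truth bundle: ``logs/*.csv`` (sensor-log dialect),
    ``truth_contacts.csv``, ``truth_locations.csv``, ``truth_t_ab.csv``,
    ``actigraphy.csv`` and ``config.yaml``."""
    outdir = Path(outdir)
    (outdir / "logs").mkdir(parents=True, exist_ok=True)
    contact_rows, loc_rows, acti_frames = [], [], []
    for day, dd in sorted(ds.days.items()):
        for sensor, log in sorted(dd.logs.items()):
            write_sensor_log(log, outdir / "logs" / f"day{day:03d}_{sensor}.csv")
        for (a, b), ivs in sorted(dd.schedule.contact_intervals.items()):
            for s, e in ivs:
                contact_rows.append(
                    {"day": day, "member_a": a, "member_b": b, "start_s": s, "end_s": e}
                )
        for m, zs in sorted(dd.schedule.locations.items()):
            for zone, s, e in zs:
                loc_rows.append(
                    {"day": day, "member": m, "location": zone, "start_s": s, "end_s": e}
                )
        acti_frames.append(dd.actigraphy.assign(day=day))
    pd.DataFrame(contact_rows).to_csv(outdir / "truth_contacts.csv", index=False)
    pd.DataFrame(loc_rows).to_csv(outdir / "truth_locations.csv", index=False)
    ds.truth_t_ab().to_csv(outdir / "truth_t_ab.csv", index=False)
    if acti_frames:
        pd.concat(acti_frames, ignore_index=True).to_csv(outdir / "actigraphy.csv", index=False)
    cfg = asdict(ds.config)
    cfg["measurement_weekdays"] = list(cfg["measurement_weekdays"])
    cfg["session"] = list(cfg["session"])
    with open(outdir / "config.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(cfg, fh)
    return outdir
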