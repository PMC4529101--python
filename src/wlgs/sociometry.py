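"""Sociometric statistics on contact data.

Implements the classical Moreno sociogram indices on choice tables
(selection status S_A, rejection status R_A, crew cohesion C), their
time-based analogues on proximity data (relative pair time T_AB and the
Crew Relation Time Index, CRTI), the recoding of measured times into
questionnaire-style 2/1/0 choices, subgroup (dyad/triad/quad) interaction
times via per-epoch maximal cliques, and the star-plot group center.

Index definitions, for a crew of size N:

    S_A  = s_A / (N - 1)            selections received, normalized
    R_A  = r_A / (N - 1)            rejections received, normalized
    C    = s_AB / (N (N-1) / 2)     fraction of pairs selecting mutually
    T_AB = t_AB / T                 relative pair time
    CRTI = 1e6 * sum_pairs t_XY / (T * N (N-1) / 2)   [ppm]

CRTI is algebraically the mean relative pair time, expressed in parts per
million of the possible shared time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .contacts import ContactTensor, DailyContactMatrix
from .errors import EmptyDayError, WLGSError


@dataclass
class ChoiceTable:
    """Sociometric choices: 2 (first choice), 1 (second), 0 per ordered
    (chooser, chosen) pair; the diagonal is undefined.

    ``kind`` labels the provenance: a questionnaire scale
    (``questionnaire-mission`` / ``questionnaire-holidays``) or
    ``recoded-from-time``.
    """

    members: list[str]
    values: np.ndarray  # (N, N) int, diagonal ignored
    kind: str = "questionnaire-mission"
    tie_flags: list[str] = field(default_factory=list)  # choosers whose ranking tied
    zero_flags: list[str] = field(default_factory=list)  # choosers with no time data

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=int)
        n = len(self.members)
        if v.shape != (n, n):
            raise ValueError("choice matrix shape must be (N, N)")
        off = v[~np.eye(n, dtype=bool)]
        if ((off < 0) | (off > 2)).any():
            raise ValueError("choices must be 0, 1 or 2")
        self.values = v

    @property
    def n_crew(self) -> int:
        return len(self.members)

    def ordered_cells(self) -> pd.Series:
        """The N(N−1) ordered off-diagonal cells (30 for N = 6), indexed by
        (chooser, chosen) — the vector the rank correlations run over."""
        n = self.n_crew
        idx, vals = [], []
        for i in range(n):
            for j in range(n):
                if i != j:
                    idx.append((self.members[i], self.members[j]))
                    vals.append(self.values[i, j])
        return pd.Series(vals, index=pd.Index(idx, tupleize_cols=False), dtype=float)

    def to_frame(self) -> pd.DataFrame:
        cells = self.ordered_cells()
        return pd.DataFrame(
            {
                "chooser": [p[0] for p in cells.index],
                "chosen": [p[1] for p in cells.index],
                "value": cells.to_numpy(dtype=int),
                "kind": self.kind,
            }
        )


@dataclass
class SociometricIndices:
    """Per-subject selection/rejection status and the crew cohesion index."""

    S: pd.Series  # selection status per subject, in [0, 1]
    R: pd.Series | None  # rejection status; None when rejections unavailable
    C: float  # crew cohesion, in [0, 1]
    s_ab: int  # count of two-sided selections


def moreno_indices(
    choices: ChoiceTable, rejections: ChoiceTable | None = None
) -> SociometricIndices:
    """Selection status, rejection status and crew cohesion from choices.

    Any choice value >= 1 counts as a selection; a two-sided selection is a
    pair whose two directed values are both >= 1.  Rejection status is only
    computed when an explicit rejections table is supplied — it cannot be
    derived from time spent together.
    """
    n = choices.n_crew
    if n < 2:
        raise WLGSError("crew of fewer than two members is degenerate")
    sel = choices.values >= 1
    np.fill_diagonal(sel, False)
    s_received = sel.sum(axis=0)
    S = pd.Series(s_received / (n - 1), index=choices.members)
    R = None
    if rejections is not None:
        if rejections.members != choices.members:
            raise WLGSError("rejection table covers a different crew")
        rej = rejections.values >= 1
        np.fill_diagonal(rej, False)
        R = pd.Series(rej.sum(axis=0) / (n - 1), index=choices.members)
    mutual = sel & sel.T
    s_ab = int(np.triu(mutual, 1).sum())
    C = s_ab / (n * (n - 1) / 2)
    return SociometricIndices(S=S, R=R, C=C, s_ab=s_ab)


def relative_time(daily: DailyContactMatrix) -> pd.Series:
    """Relative pair time T_AB = t_AB / T, in [0, 1] per unordered pair."""
    if daily.T <= 0:
        raise EmptyDayError("total registration time is zero")
    return daily.t_ab / daily.T


def crti(daily: DailyContactMatrix) -> float:
    """Crew Relation Time Index in parts per million.

    CRTI = 1e6 * Σ_pairs t_XY / (T * N(N−1)/2); for a 6-member crew the
    denominator pair count is 15.
    """
    n = daily.n_crew
    if n < 2:
        raise WLGSError("crew of fewer than two members is degenerate")
    if daily.T <= 0:
        raise EmptyDayError("total registration time is zero")
    n_pairs = n * (n - 1) / 2
    return 1e6 * float(daily.t_ab.sum()) / (daily.T * n_pairs)


@dataclass
class CohesionSeries:
    """CRTI (ppm) and relative pair times indexed by mission day."""

    days: np.ndarray
    crti_ppm: np.ndarray
    relative_times: pd.DataFrame  # index day, columns unordered pairs
    complete: np.ndarray

    def to_series(self, complete_only: bool = True) -> pd.Series:
        keep = self.complete if complete_only else np.ones(len(self.days), bool)
        return pd.Series(self.crti_ppm[keep], index=self.days[keep], name="crti_ppm")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"day": self.days, "crti_ppm": self.crti_ppm, "complete": self.complete}
        )

    @classmethod
    def from_daily(
        cls,
        matrices: Sequence[DailyContactMatrix],
        min_session_s: float = 6 * 3600,
    ) -> "CohesionSeries":
        """Assemble the monitored series; a day is complete when its
        registration time reaches ``min_session_s`` (default 6 h)."""
        matrices = sorted(matrices, key=lambda m: m.day)
        days = np.array([m.day for m in matrices], dtype=int)
        vals = np.array([crti(m) for m in matrices], dtype=float)
        complete = np.array([m.T >= min_session_s for m in matrices], dtype=bool)
        rel = pd.DataFrame(
            {m.day: relative_time(m) for m in matrices}
        ).T.sort_index()
        rel.index.name = "day"
        return cls(days=days, crti_ppm=vals, relative_times=rel, complete=complete)


def time_to_choices(daily: DailyContactMatrix) -> ChoiceTable:
    """Recode measured pair times into questionnaire-style choices.

    For every subject their partners are ranked by time spent together:
    the largest time becomes a 2 (first choice), the second largest a 1,
    all others 0.  Ties are broken toward the lexicographically smaller
    partner id and flagged; a subject with no time at all gets an all-zero
    row and a flag.
    """
    members = sorted({m for pair in daily.t_ab.index for m in pair})
    n = len(members)
    if n < 3:
        raise WLGSError("time-to-choices needs at least three crew members")
    t = pd.DataFrame(0.0, index=members, columns=members)
    for (a, b), v in daily.t_ab.items():
        t.loc[a, b] = v
        t.loc[b, a] = v
    values = np.zeros((n, n), dtype=int)
    tie_flags, zero_flags = [], []
    for i, m in enumerate(members):
        times = [(t.loc[m, o], o) for o in members if o != m]
        if all(v == 0 for v, _ in times):
            zero_flags.append(m)
            continue
        # sort descending by time, ties toward smaller partner id
        ranked = sorted(times, key=lambda kv: (-kv[0], kv[1]))
        if ranked[0][0] == ranked[1][0] or (len(ranked) > 2 and ranked[1][0] == ranked[2][0]):
            tie_flags.append(m)
        values[i, members.index(ranked[0][1])] = 2
        values[i, members.index(ranked[1][1])] = 1
    return ChoiceTable(
        members=members,
        values=values,
        kind="recoded-from-time",
        tie_flags=tie_flags,
        zero_flags=zero_flags,
    )


def subgroup_times(tensor: ContactTensor, k: int) -> pd.Series:
    """Seconds each k-member subgroup spent together during the day.

    Per epoch the undirected co-presence graph over the crew is examined;
    a subset of size k accrues one epoch (5 s) iff it is a *maximal*
    clique — so dyad, triad and quad times are mutually exclusive layers
    (a triad epoch contributes to no dyad).
    """
    if k < 2 or k > len(tensor.sensors):
        raise ValueError("subgroup size must be between 2 and the crew size")
    n = len(tensor.sensors)
    iu = np.triu_indices(n, 1)
    counts: dict[tuple[int, ...], int] = {}
    cache: dict[bytes, list[tuple[int, ...]]] = {}
    for e in range(tensor.n_epochs):
        adj = tensor.symmetric[e]
        key = np.packbits(adj[iu]).tobytes()
        cliques = cache.get(key)
        if cliques is None:
            g = nx.Graph()
            g.add_nodes_from(range(n))
            g.add_edges_from(zip(*np.nonzero(np.triu(adj, 1))))
            cliques = [tuple(sorted(c)) for c in nx.find_cliques(g) if len(c) == k]
            cache[key] = cliques
        for c in cliques:
            counts[c] = counts.get(c, 0) + 1
    idx = [tuple(tensor.sensors[i] for i in c) for c in counts]
    vals = [v * tensor.epoch_seconds for v in counts.values()]
    out = pd.Series(vals, index=pd.Index(idx, tupleize_cols=False), dtype=float)
    return out.sort_index()


def star_angles(members: Sequence[str]) -> dict[str, float]:
    """Fixed star-plot angles: 2π/N spacing in sorted id order from 0."""
    members = sorted(members)
    return {m: 2 * np.pi * i / len(members) for i, m in enumerate(members)}


def group_center(
    crew_time: Mapping[str, float], angles: Mapping[str, float] | None = None
) -> tuple[pd.DataFrame, tuple[float, float]]:
    """Star-plot positions and their mean, the day's group center.

    A subject sits at (x, y) = (t·sin(angle), t·cos(angle)) where t is the
    subject's total time spent with any other crew member that day; the
    center is the arithmetic mean of all subject coordinates.
    """
    if angles is None:
        angles = star_angles(list(crew_time))
    members = sorted(crew_time)
    if len(set(np.round([angles[m] for m in members], 12))) != len(members):
        raise ValueError("star angles must be distinct")
    xs = [crew_time[m] * np.sin(angles[m]) for m in members]
    ys = [crew_time[m] * np.cos(angles[m]) for m in members]
    pos = pd.DataFrame({"member": members, "x": xs, "y": ys}).set_index("member")
    center = (float(np.mean(xs)), float(np.mean(ys)))
    return pos, center


@dataclass
class GroupCenterSeries:
    """Daily star-plot centers and their overall mean."""

    angles: dict[str, float]
    daily_positions: dict[int, pd.DataFrame]
    daily_center: pd.DataFrame  # index day, columns x, y
    overall_center: tuple[float, float]


def group_center_series(
    matrices: Iterable[DailyContactMatrix], angles: Mapping[str, float] | None = None
) -> GroupCenterSeries:
    """Daily group centers over the mission and their overall mean."""
    matrices = sorted(matrices, key=lambda m: m.day)
    if not matrices:
        raise EmptyDayError("no contact matrices supplied")
    if angles is None:
        members = sorted({m for mat in matrices for pair in mat.t_ab.index for m in pair})
        angles = star_angles(members)
    positions, centers = {}, {}
    for m in matrices:
        pos, c = group_center(m.crew_time().to_dict(), angles)
        positions[m.day] = pos
        centers[m.day] = c
    daily = pd.DataFrame(centers, index=["x", "y"]).T
    daily.index.name = "day"
    overall = (float(daily["x"].mean()), float(daily["y"].mean()))
    return GroupCenterSeries(
        angles=dict(angles),
        daily_positions=positions,
        daily_center=daily,
        overall_center=overall,
    )


def write_choice_table(table: ChoiceTable, path: str | Path) -> None:
    """CSV dialect ``chooser,chosen,value,kind`` (round-trip stable)."""
    table.to_frame().to_csv(path, index=False)


def read_choice_table(path: str | Path) -> ChoiceTable:
    df = pd.read_csv(path)
    members = sorted(set(df["chooser"]) | set(df["chosen"]))
    n = len(members)
    values = np.zeros((n, n), dtype=int)
    pos = {m: i for i, m in enumerate(members)}
    for row in df.itertuples(index=False):
        values[pos[row.chooser], pos[row.chosen]] = int(row.value)
    kind = str(df["kind"].iloc[0]) if len(df) else "questionnaire-mission"
    return ChoiceTable(members=members, values=values, kind=kind)
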