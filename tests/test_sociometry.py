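"""Moreno indices, CRTI, time-to-choices recoding, subgroup times and
star-plot group centers."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import daily_matrix, make_tensor, random_tensor
from wlgs import sociometry
from wlgs.errors import EmptyDayError, WLGSError

MEMBERS6 = list("ABCDEF")


def choice_table(directed: dict, members=MEMBERS6, kind="questionnaire-mission"):
    n = len(members)
    values = np.zeros((n, n), dtype=int)
    pos = {m: i for i, m in enumerate(members)}
    for (a, b), v in directed.items():
        values[pos[a], pos[b]] = v
    return sociometry.ChoiceTable(members=list(members), values=values, kind=kind)


class TestMorenoIndices:
    def test_subject_selected_by_everyone_has_status_one(self):
        t = choice_table({(m, "A"): 2 for m in MEMBERS6 if m != "A"})
        idx = sociometry.moreno_indices(t)
        assert idx.S["A"] == 1.0

    def test_all_pairs_mutual_gives_cohesion_one(self):
        t = choice_table({(a, b): 1 for a in MEMBERS6 for b in MEMBERS6 if a != b})
        assert sociometry.moreno_indices(t).C == 1.0

    def test_cohesion_counts_two_sided_selections(self):
        # exactly 3 mutual pairs (A-B, C-D, E-F) plus one-way picks
        directed = {
            ("A", "B"): 2, ("B", "A"): 1,
            ("C", "D"): 2, ("D", "C"): 2,
            ("E", "F"): 1, ("F", "E"): 2,
            ("A", "C"): 1, ("B", "D"): 2, ("E", "A"): 1,
        }
        idx = sociometry.moreno_indices(choice_table(directed))
        # brute-force count of two-sided selections over the table
        sel = {(a, b) for (a, b), v in directed.items() if v >= 1}
        mutual = {frozenset(p) for p in sel if (p[1], p[0]) in sel}
        assert idx.s_ab == len(mutual) == 3
        assert idx.C == pytest.approx(3 / 15)

    def test_rejections_only_from_explicit_table(self):
        t = choice_table({("A", "B"): 2})
        rej = choice_table({("A", "C"): 2, ("B", "C"): 1})
        idx = sociometry.moreno_indices(t, rejections=rej)
        assert idx.R["C"] == pytest.approx(2 / 5)
        assert sociometry.moreno_indices(t).R is None

    def test_degenerate_crew_raises(self):
        t = sociometry.ChoiceTable(members=["A"], values=np.zeros((1, 1), dtype=int))
        with pytest.raises(WLGSError):
            sociometry.moreno_indices(t)


class TestRelativeTimeAndCrti:
    def test_full_time_together_gives_one(self):
        m = daily_matrix({("A", "B"): 100.0}, T=100.0)
        assert sociometry.relative_time(m)[("A", "B")] == 1.0

    def test_no_time_gives_zero(self):
        m = daily_matrix({("A", "B"): 0.0}, T=100.0)
        assert sociometry.relative_time(m)[("A", "B")] == 0.0

    def test_relative_time_direct_division(self):
        m = daily_matrix({("A", "B"): 600.0}, T=24_000.0)
        assert sociometry.relative_time(m)[("A", "B")] == pytest.approx(0.025)

    def test_saturated_crew_reaches_one_million_ppm(self):
        t_ab = {p: 500.0 for p in itertools.combinations(MEMBERS6, 2)}
        assert sociometry.crti(daily_matrix(t_ab, T=500.0)) == pytest.approx(1e6)

    def test_six_member_crew_hand_value(self):
        # 15 pairs at 1000 s each, T = 20000 s -> 1e6 * 15000/(20000*15)
        t_ab = {p: 1000.0 for p in itertools.combinations(MEMBERS6, 2)}
        assert sociometry.crti(daily_matrix(t_ab, T=20_000.0)) == pytest.approx(50_000.0)

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.floats(0, 1), min_size=15, max_size=15), st.floats(1000, 50_000))
    def test_crti_equals_mean_relative_time(self, fracs, T):
        pairs = list(itertools.combinations(MEMBERS6, 2))
        m = daily_matrix({p: f * T for p, f in zip(pairs, fracs)}, T=T)
        assert sociometry.crti(m) == pytest.approx(
            1e6 * sociometry.relative_time(m).mean(), rel=1e-12
        )


class TestTimeToChoices:
    def test_rank_readout(self):
        t_ab = {("A", "V"): 900, ("A", "W"): 500, ("A", "X"): 100,
                ("A", "Y"): 0, ("A", "Z"): 0,
                ("V", "W"): 1, ("V", "X"): 2, ("V", "Y"): 3, ("V", "Z"): 4,
                ("W", "X"): 5, ("W", "Y"): 6, ("W", "Z"): 7,
                ("X", "Y"): 8, ("X", "Z"): 9, ("Y", "Z"): 10}
        ct = sociometry.time_to_choices(daily_matrix(t_ab, T=10_000))
        cells = ct.ordered_cells()
        assert cells[("A", "V")] == 2
        assert cells[("A", "W")] == 1
        assert cells[("A", "X")] == cells[("A", "Y")] == cells[("A", "Z")] == 0

    def test_six_member_table_has_thirty_ordered_cells(self, rng):
        pairs = list(itertools.combinations(MEMBERS6, 2))
        m = daily_matrix({p: float(v) for p, v in zip(pairs, rng.permutation(15) + 1)},
                         T=10_000)
        ct = sociometry.time_to_choices(m)
        assert len(ct.ordered_cells()) == 30
        # every chooser hands out exactly one 2 and one 1
        for chooser in MEMBERS6:
            row = [v for (c, _), v in ct.ordered_cells().items() if c == chooser]
            assert sorted(row) == [0, 0, 0, 1, 2]

    def test_tie_resolved_lexicographically_and_flagged(self):
        t_ab = {("A", "B"): 500, ("A", "C"): 500, ("A", "D"): 100,
                ("B", "C"): 50, ("B", "D"): 60, ("C", "D"): 70}
        ct = sociometry.time_to_choices(daily_matrix(t_ab, T=10_000))
        cells = ct.ordered_cells()
        assert cells[("A", "B")] == 2  # smaller id wins the tie
        assert cells[("A", "C")] == 1
        assert "A" in ct.tie_flags

    def test_all_zero_subject_flagged_with_zero_row(self):
        t_ab = {("A", "B"): 0, ("A", "C"): 0, ("B", "C"): 10, ("B", "D"): 5,
                ("A", "D"): 0, ("C", "D"): 3}
        ct = sociometry.time_to_choices(daily_matrix(t_ab, T=1000))
        assert "A" in ct.zero_flags
        assert all(v == 0 for (c, _), v in ct.ordered_cells().items() if c == "A")

    def test_moreno_invariant_to_time_rescaling(self, rng):
        pairs = list(itertools.combinations(MEMBERS6, 2))
        times = {p: float(v) for p, v in zip(pairs, rng.permutation(15) + 1)}
        a = sociometry.moreno_indices(sociometry.time_to_choices(daily_matrix(times, T=100)))
        scaled = {p: v * 7.25 for p, v in times.items()}
        b = sociometry.moreno_indices(sociometry.time_to_choices(daily_matrix(scaled, T=725)))
        pd.testing.assert_series_equal(a.S, b.S)
        assert a.C == b.C


def brute_force_subgroups(tensor, k):
    """Independent oracle: enumerate every subset, check clique-ness and
    maximality directly."""
    n = len(tensor.sensors)
    out = {}
    for e in range(tensor.n_epochs):
        adj = tensor.symmetric[e]
        for sub in itertools.combinations(range(n), k):
            if not all(adj[i, j] for i, j in itertools.combinations(sub, 2)):
                continue
            maximal = True
            for extra in range(n):
                if extra in sub:
                    continue
                if all(adj[extra, i] for i in sub):
                    maximal = False
                    break
            if maximal:
                key = tuple(tensor.sensors[i] for i in sub)
                out[key] = out.get(key, 0) + tensor.epoch_seconds
    return pd.Series(out, dtype=float).sort_index()


class TestSubgroupTimes:
    def test_lone_dyad_accrues_no_triad(self):
        d = np.zeros((1, 3, 3), dtype=bool)
        d[0, 0, 1] = True  # A-B only
        t = make_tensor(d)
        dyads = sociometry.subgroup_times(t, 2)
        assert dyads[("A", "B")] == 5
        assert len(sociometry.subgroup_times(t, 3)) == 0

    def test_triad_suppresses_inner_dyads(self):
        d = np.zeros((1, 4, 4), dtype=bool)
        for i, j in [(0, 1), (0, 2), (1, 2)]:
            d[0, i, j] = True
        t = make_tensor(d)
        assert sociometry.subgroup_times(t, 3)[("A", "B", "C")] == 5
        assert len(sociometry.subgroup_times(t, 2)) == 0

    @pytest.mark.parametrize("k", [2, 3, 4])
    def test_matches_brute_force_enumeration(self, rng, k):
        for _ in range(10):
            t = random_tensor(rng, n_epochs=100, n=6, density=0.35)
            fast = sociometry.subgroup_times(t, k)
            slow = brute_force_subgroups(t, k)
            assert dict(fast) == dict(slow)


class TestGroupCenter:
    def test_symmetric_times_center_at_origin(self):
        angles = sociometry.star_angles(MEMBERS6)
        _, center = sociometry.group_center({m: 300.0 for m in MEMBERS6}, angles)
        assert center == pytest.approx((0.0, 0.0), abs=1e-9)

    def test_single_active_subject_hand_value(self):
        angles = {m: np.deg2rad(a) for m, a in zip(MEMBERS6, range(0, 360, 60))}
        angles["B"] = np.deg2rad(90)  # x = t sin 90 = t, y = t cos 90 = 0
        times = {m: 0.0 for m in MEMBERS6}
        times["B"] = 600.0
        pos, center = sociometry.group_center(times, angles)
        assert pos.loc["B", "x"] == pytest.approx(600.0)
        assert pos.loc["B", "y"] == pytest.approx(0.0, abs=1e-9)
        assert center == pytest.approx((100.0, 0.0), abs=1e-9)

    def test_all_zero_times_center_at_origin(self):
        _, center = sociometry.group_center({m: 0.0 for m in MEMBERS6})
        assert center == (0.0, 0.0)

    def test_rotation_equivariance(self, rng):
        times = {m: float(v) for m, v in zip(MEMBERS6, rng.uniform(0, 1000, 6))}
        angles = sociometry.star_angles(MEMBERS6)
        phi = 0.7
        _, c0 = sociometry.group_center(times, angles)
        _, c1 = sociometry.group_center(times, {m: a + phi for m, a in angles.items()})
        rot = np.array([[np.cos(phi), np.sin(phi)], [-np.sin(phi), np.cos(phi)]])
        # rotating all star angles by phi rotates the center by phi
        assert np.allclose(rot @ np.array(c0), np.array(c1))

    def test_series_overall_center_is_mean_of_daily(self, rng):
        mats = [daily_matrix(
            {p: float(v) for p, v in
             zip(itertools.combinations(MEMBERS6, 2), rng.uniform(0, 500, 15))},
            T=10_000, day=d) for d in (1, 2, 3)]
        gcs = sociometry.group_center_series(mats)
        assert gcs.overall_center[0] == pytest.approx(gcs.daily_center["x"].mean())
        assert gcs.overall_center[1] == pytest.approx(gcs.daily_center["y"].mean())


class TestCohesionSeries:
    def test_series_collects_crti_and_completeness(self):
        pairs = list(itertools.combinations(MEMBERS6, 2))
        long_day = daily_matrix({p: 1000.0 for p in pairs}, T=8 * 3600, day=10)
        short_day = daily_matrix({p: 1000.0 for p in pairs}, T=2 * 3600, day=13)
        cs = sociometry.CohesionSeries.from_daily([short_day, long_day])
        assert list(cs.days) == [10, 13]
        assert list(cs.complete) == [True, False]
        assert cs.crti_ppm[0] == pytest.approx(sociometry.crti(long_day))
        # incomplete day excluded from the monitored series by default
        assert list(cs.to_series().index) == [10]

    def test_empty_day_raises(self):
        with pytest.raises(EmptyDayError):
            daily_matrix({("A", "B"): 0.0}, T=0.0)


def test_choice_table_csv_round_trip(tmp_path, rng):
    pairs = list(itertools.combinations(MEMBERS6, 2))
    m = daily_matrix({p: float(v) for p, v in zip(pairs, rng.permutation(15) + 1)}, T=900)
    ct = sociometry.time_to_choices(m)
    path = tmp_path / "choices.csv"
    sociometry.write_choice_table(ct, path)
    back = sociometry.read_choice_table(path)
    assert back.members == ct.members
    assert np.array_equal(back.values, ct.values)
    assert back.kind == "recoded-from-time"
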