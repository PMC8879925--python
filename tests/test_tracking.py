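import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_track
from phenotyper import tracking
from phenotyper.geometry import ZONE_CODES
from phenotyper.synth import BehaviorParams, StudyDesign, simulate_cohort, simulate_track
from phenotyper.tracking import (
    ArmSequence,
    Track,
    TrackFormatError,
    ZoneSeries,
    compute_sab,
    extract_arm_entries,
    locomotor_endpoints,
    read_tracks,
)


def zone_series(labels, rate=10.0):
    codes = np.array([ZONE_CODES[l] for l in labels], dtype=np.int8)
    times = np.arange(len(labels)) / rate
    return ZoneSeries(time_s=times, codes=codes, snapped=np.zeros(len(labels), bool))


# --------------------------------------------------------------------------
# read_tracks
# --------------------------------------------------------------------------
class TestReadTracks:
    def _write(self, tmp_path, df):
        path = tmp_path / "tracks.csv"
        df.to_csv(path, index=False)
        return path

    def test_grouping(self, tmp_path):
        rows = []
        for fish in ("f1", "f2"):
            for day in ("day1", "day2"):
                for i in range(5):
                    rows.append({"time_s": i * 0.1, "x_cm": 0.0, "y_cm": 0.0,
                                 "fish_id": fish, "day": day, "dose": "control"})
        tracks, report = read_tracks(self._write(tmp_path, pd.DataFrame(rows)))
        assert len(tracks) == 4
        assert report.n_tracks == 4

    def test_empty_file_with_header(self, tmp_path):
        df = pd.DataFrame(columns=["time_s", "x_cm", "y_cm", "fish_id", "day", "dose"])
        tracks, report = read_tracks(self._write(tmp_path, df))
        assert tracks == []
        assert report.n_rows == 0

    def test_nan_rows_dropped_and_counted(self, tmp_path):
        rows = [{"time_s": i * 0.1, "x_cm": 0.0, "y_cm": 0.0,
                 "fish_id": "f1", "day": "day1", "dose": "control"} for i in range(6)]
        df = pd.DataFrame(rows)
        df.loc[[1, 3, 4], "x_cm"] = np.nan
        tracks, report = read_tracks(self._write(tmp_path, df))
        assert report.dropped == 3
        assert len(tracks[0]) == 3

    def test_missing_columns(self, tmp_path):
        df = pd.DataFrame({"time_s": [0.0], "x_cm": [0.0]})
        with pytest.raises(TrackFormatError):
            read_tracks(self._write(tmp_path, df))

    def test_round_trip_with_simulator(self, tmp_path, geometry):
        design = StudyDesign(n_fish_per_group=2, trial_duration=10.0, seed=0)
        study = simulate_cohort(design, {d: BehaviorParams(d) for d in design.doses})
        path = tmp_path / "t.csv"
        study.write_csv(path)
        tracks, report = read_tracks(path)
        assert report.n_tracks == len(study.tracks)
        assert report.dropped == 0


# --------------------------------------------------------------------------
# zone series / arm entries
# --------------------------------------------------------------------------
class TestExtractArmEntries:
    def test_simple_transition(self):
        zs = zone_series(["A"] * 10 + ["junction"] * 3 + ["B"] * 10)
        seq = extract_arm_entries(zs, min_dwell=0.5)
        assert seq.entries == ["A", "B"]

    def test_flicker_ignored(self):
        zs = zone_series(["A"] * 10 + ["C"] + ["junction"] * 2 + ["B"] * 10)
        seq = extract_arm_entries(zs, min_dwell=0.5)
        assert seq.entries == ["A", "B"]

    def test_reentry_collapsed(self):
        zs = zone_series(["A"] * 10 + ["junction"] * 5 + ["A"] * 10 + ["junction"] * 2 + ["B"] * 8)
        seq = extract_arm_entries(zs, min_dwell=0.5)
        assert seq.entries == ["A", "B"]

    def test_stationary_in_arm(self, geometry):
        x, y = geometry.arm_waypoint("B")
        tr = Track("f", "d", "c", np.arange(100) / 10.0,
                   np.full(100, x), np.full(100, y))
        zs = tracking.assign_zones(tr, geometry)
        assert set(zs.labels) == {"B"}
        assert extract_arm_entries(zs).entries == ["B"]

    def test_negative_min_dwell_rejected(self):
        with pytest.raises(ValueError):
            extract_arm_entries(zone_series(["A"]), min_dwell=-1.0)


# --------------------------------------------------------------------------
# SAB
# --------------------------------------------------------------------------
def brute_force_sab(entries):
    """Independent oracle: explicit enumeration of every 3-entry window."""
    n = len(entries)
    if n < 3:
        return None
    alts = 0
    for i in range(n - 2):
        if len({entries[i], entries[i + 1], entries[i + 2]}) == 3:
            alts += 1
    return 100.0 * alts / (n - 2)


def random_arm_sequence(rng, length):
    arms = "ABC"
    seq = [arms[rng.integers(3)]]
    while len(seq) < length:
        nxt = arms[rng.integers(3)]
        if nxt != seq[-1]:
            seq.append(nxt)
    return seq


class TestComputeSAB:
    @pytest.mark.parametrize("entries,expected", [
        (["A", "B", "C", "A", "B", "C"], 100.0),
        (["A", "B", "A", "B", "A"], 0.0),
        (["A", "B", "C", "A", "C", "B"], 75.0),
    ])
    def test_hand_cases(self, entries, expected):
        res = compute_sab(ArmSequence(entries, list(range(len(entries)))))
        assert res.sab_percent == pytest.approx(expected)

    def test_undefined_below_three_entries(self):
        res = compute_sab(ArmSequence(["A", "B"], [0.0, 1.0]))
        assert not res.defined
        assert res.sab_percent is None

    def test_oracle_equivalence(self):
        rng = np.random.default_rng(0)
        for _ in range(300):
            seq = random_arm_sequence(rng, int(rng.integers(3, 51)))
            res = compute_sab(ArmSequence(seq, list(range(len(seq)))))
            assert res.sab_percent == pytest.approx(brute_force_sab(seq))

    @given(st.integers(0, 5), st.lists(st.integers(0, 2), min_size=3, max_size=40))
    @settings(max_examples=100, deadline=None)
    def test_arm_relabeling_invariance(self, perm_idx, raw):
        arms = "ABC"
        seq = []
        for r in raw:
            a = arms[r]
            if not seq or seq[-1] != a:
                seq.append(a)
        if len(seq) < 3:
            return
        perm = list(itertools.permutations("ABC"))[perm_idx]
        mapping = dict(zip("ABC", perm))
        relabeled = [mapping[a] for a in seq]
        t = list(range(len(seq)))
        assert compute_sab(ArmSequence(seq, t)).sab_percent == pytest.approx(
            compute_sab(ArmSequence(relabeled, t)).sab_percent)

    def test_alternations_bounded(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            seq = random_arm_sequence(rng, int(rng.integers(3, 30)))
            res = compute_sab(ArmSequence(seq, list(range(len(seq)))))
            assert res.n_alternations <= max(res.n_entries - 2, 0)
            assert 0.0 <= res.sab_percent <= 100.0


# --------------------------------------------------------------------------
# locomotion
# --------------------------------------------------------------------------
class TestLocomotorEndpoints:
    def test_stationary_track(self):
        n = 6000  # 600 s at 10 Hz
        tr = Track("f", "d", "c", np.arange(n) / 10.0, np.zeros(n), np.zeros(n))
        res = locomotor_endpoints(tr)
        assert res.distance_cm == 0.0
        assert res.n_freezing_bouts == 1
        assert res.total_freeze_s == pytest.approx(599.9, abs=0.2)

    def test_constant_speed_straight_line(self):
        t = np.arange(100) / 10.0
        tr = Track("f", "d", "c", t, 5.0 * t, np.zeros(100))  # 5 cm/s
        res = locomotor_endpoints(tr, freeze_speed_thresh=1.0)
        assert res.mean_speed_cm_s == pytest.approx(5.0)
        assert res.n_freezing_bouts == 0

    def test_short_track_flagged(self):
        tr = Track("f", "d", "c", np.array([0.0]), np.array([0.0]), np.array([0.0]))
        res = locomotor_endpoints(tr)
        assert not res.defined

    def test_freeze_rate_recovery(self, geometry):
        # planted 2 bouts/min over 10 min -> ~20 detected, Poisson noise
        p = BehaviorParams("c", mean_speed=6.0, freeze_rate=2.0, freeze_duration=3.0)
        counts = []
        for seed in range(5):
            sim = simulate_track(p, geometry, duration=600.0, rate=25.0, seed=seed)
            res = locomotor_endpoints(make_track(sim))
            counts.append(res.n_freezing_bouts)
        assert 10 <= np.mean(counts) <= 30

    def test_sab_distance_uncorrelated_in_null_cohort(self, geometry):
        from phenotyper.stats import correlate

        rng = np.random.default_rng(0)
        sab, dist = [], []
        for i in range(60):
            p = BehaviorParams("c", p_alternate=float(rng.uniform(0.2, 0.9)))
            sim = simulate_track(p, geometry, duration=300.0, rate=25.0, seed=100 + i)
            tr = make_track(sim)
            zones = tracking.assign_zones(tr, geometry)
            res = tracking.compute_sab(tracking.extract_arm_entries(zones))
            loco = locomotor_endpoints(tr)
            if res.defined:
                sab.append(res.sab_percent)
                dist.append(loco.distance_cm)
        corr = correlate(sab, dist)
        assert abs(corr.r) < 0.25


def test_score_tracks_table(geometry):
    design = StudyDesign(n_fish_per_group=2, trial_duration=60.0, seed=1)
    study = simulate_cohort(design, {d: BehaviorParams(d) for d in design.doses})
    tracks = [make_track(t) for t in study.tracks]
    df = tracking.score_tracks(tracks, geometry)
    assert len(df) == len(tracks)
    assert set(df.columns) == set(tracking.ENDPOINT_COLUMNS)
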