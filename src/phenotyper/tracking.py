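"""Track parsing, zone assignment, arm-entry extraction and behavioral endpoints.

The alternation score follows the continuous-alternation convention: an
alternation is a sliding window of three consecutive arm entries that are
pairwise distinct, and the percentage is
``100 * alternations / (entries - 2)`` for tracks with at least three
entries (undefined otherwise).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import ZONE_JUNCTION, ZONE_LABELS, MazeGeometry
from .synth import TRACK_COLUMNS

logger = logging.getLogger(__name__)


class TrackFormatError(ValueError):
    pass


class TrackDataError(ValueError):
    pass


@dataclass
class Track:
    fish_id: str
    day: str
    dose: str
    time_s: np.ndarray
    x_cm: np.ndarray
    y_cm: np.ndarray

    def __post_init__(self):
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.x_cm = np.asarray(self.x_cm, dtype=float)
        self.y_cm = np.asarray(self.y_cm, dtype=float)
        if not (len(self.time_s) == len(self.x_cm) == len(self.y_cm)):
            raise TrackDataError("time/x/y length mismatch")
        if len(self.time_s) > 1 and not np.all(np.diff(self.time_s) > 0):
            raise TrackDataError(f"non-monotone timestamps for fish {self.fish_id}")

    def __len__(self) -> int:
        return len(self.time_s)


@dataclass
class ParseReport:
    n_rows: int = 0
    n_tracks: int = 0
    dropped: int = 0


@dataclass
class ZoneSeries:
    """Per-sample zone labels aligned with a track's samples."""

    time_s: np.ndarray
    codes: np.ndarray           # int8, 0/1/2 arms, 3 junction
    snapped: np.ndarray         # True where the raw point fell outside the maze

    @property
    def labels(self) -> list[str]:
        return [ZONE_LABELS[int(c)] for c in self.codes]


@dataclass
class ArmSequence:
    entries: list[str]
    entry_times: list[float]

    def __post_init__(self):
        for a, b in zip(self.entries, self.entries[1:]):
            if a == b:
                raise ValueError("consecutive duplicate arm entries are not allowed")

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class SABResult:
    n_entries: int
    n_alternations: int
    sab_percent: float | None  # None when fewer than 3 entries

    @property
    def defined(self) -> bool:
        return self.sab_percent is not None


@dataclass
class LocomotorSummary:
    distance_cm: float
    mean_speed_cm_s: float | None
    n_freezing_bouts: int
    total_freeze_s: float
    defined: bool = True


def read_tracks(path) -> tuple[list[Track], ParseReport]:
    """Read a flat track table (``time_s,x_cm,y_cm,fish_id,day,dose``).

    Rows with missing coordinates are dropped and counted; rows are grouped
    by (fish_id, day) and sorted by time within each group.
    """
    df = pd.read_csv(path)
    missing = [c for c in TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise TrackFormatError(f"track table missing columns: {missing}")
    report = ParseReport(n_rows=len(df))
    if df.empty:
        logger.warning("track table %s is empty", path)
        return [], report
    clean = df.dropna(subset=["time_s", "x_cm", "y_cm"])
    report.dropped = len(df) - len(clean)
    tracks = []
    for (fish_id, day), g in clean.groupby(["fish_id", "day"], sort=True):
        g = g.sort_values("time_s")
        if g["time_s"].duplicated().any():
            raise TrackDataError(f"duplicate timestamps for fish {fish_id} / {day}")
        tracks.append(
            Track(
                fish_id=str(fish_id),
                day=str(day),
                dose=str(g["dose"].iloc[0]),
                time_s=g["time_s"].to_numpy(),
                x_cm=g["x_cm"].to_numpy(),
                y_cm=g["y_cm"].to_numpy(),
            )
        )
    report.n_tracks = len(tracks)
    return tracks, report


def assign_zones(track: Track, geometry: MazeGeometry) -> ZoneSeries:
    codes, snapped = geometry.zone_codes_of(track.x_cm, track.y_cm)
    return ZoneSeries(time_s=track.time_s, codes=codes, snapped=snapped)


def extract_arm_entries(zones: ZoneSeries, min_dwell: float = 0.5) -> ArmSequence:
    """Arm entries with dwell hysteresis.

    An entry is recorded when the fish stays in one arm for at least
    ``min_dwell`` seconds in a single uninterrupted run; shorter flickers are
    ignored and consecutive re-entries into the same arm are collapsed.
    """
    if min_dwell < 0:
        raise ValueError("min_dwell must be non-negative")
    codes = zones.codes
    times = zones.time_s
    n = len(codes)
    entries: list[str] = []
    entry_times: list[float] = []
    if n == 0:
        return ArmSequence(entries, entry_times)
    # run-length encode the zone series
    change = np.flatnonzero(np.diff(codes)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [n]))
    dt = float(np.median(np.diff(times))) if n > 1 else 0.0
    for s, e in zip(starts, ends):
        code = int(codes[s])
        if code == ZONE_JUNCTION:
            continue
        # run duration: span of samples plus one sampling interval
        dur = (times[e - 1] - times[s]) + dt
        if dur + 1e-12 < min_dwell:
            continue
        arm = ZONE_LABELS[code]
        if entries and entries[-1] == arm:
            continue
        entries.append(arm)
        entry_times.append(float(times[s]))
    return ArmSequence(entries, entry_times)


def compute_sab(seq: ArmSequence) -> SABResult:
    """Alternation score: windows of 3 consecutive pairwise-distinct entries."""
    e = seq.entries
    n = len(e)
    if n < 3:
        return SABResult(n_entries=n, n_alternations=0, sab_percent=None)
    alts = sum(
        1
        for i in range(n - 2)
        if e[i] != e[i + 1] and e[i] != e[i + 2] and e[i + 1] != e[i + 2]
    )
    return SABResult(n_entries=n, n_alternations=alts, sab_percent=100.0 * alts / (n - 2))


def locomotor_endpoints(
    track: Track,
    freeze_speed_thresh: float = 0.5,
    freeze_min_dur: float = 2.0,
) -> LocomotorSummary:
    """Distance, mean speed and freezing-bout summary for one track.

    A freezing bout is a maximal run of inter-sample speeds below the
    threshold lasting at least ``freeze_min_dur`` seconds.
    """
    if freeze_speed_thresh < 0 or freeze_min_dur < 0:
        raise ValueError("thresholds must be non-negative")
    if len(track) < 2:
        return LocomotorSummary(0.0, None, 0, 0.0, defined=False)
    dx = np.diff(track.x_cm)
    dy = np.diff(track.y_cm)
    dt = np.diff(track.time_s)
    steps = np.hypot(dx, dy)
    distance = float(steps.sum())
    elapsed = float(track.time_s[-1] - track.time_s[0])
    speeds = steps / dt
    slow = speeds < freeze_speed_thresh
    n_bouts = 0
    total_freeze = 0.0
    i = 0
    m = len(slow)
    while i < m:
        if slow[i]:
            j = i
            while j < m and slow[j]:
                j += 1
            dur = float(dt[i:j].sum())
            if dur >= freeze_min_dur:
                n_bouts += 1
                total_freeze += dur
            i = j
        else:
            i += 1
    return LocomotorSummary(
        distance_cm=distance,
        mean_speed_cm_s=distance / elapsed,
        n_freezing_bouts=n_bouts,
        total_freeze_s=total_freeze,
    )


ENDPOINT_COLUMNS = [
    "fish_id", "day", "dose", "n_entries", "sab_percent",
    "distance_cm", "mean_speed", "n_freezes",
]


def score_tracks(
    tracks: list[Track],
    geometry: MazeGeometry,
    min_dwell: float = 0.5,
    freeze_speed_thresh: float = 0.5,
    freeze_min_dur: float = 2.0,
) -> pd.DataFrame:
    """Per-fish endpoint table over a list of tracks."""
    rows = []
    for tr in tracks:
        zones = assign_zones(tr, geometry)
        seq = extract_arm_entries(zones, min_dwell=min_dwell)
        sab = compute_sab(seq)
        loco = locomotor_endpoints(tr, freeze_speed_thresh, freeze_min_dur)
        rows.append(
            {
                "fish_id": tr.fish_id,
                "day": tr.day,
                "dose": tr.dose,
                "n_entries": sab.n_entries,
                "sab_percent": sab.sab_percent if sab.defined else np.nan,
                "distance_cm": loco.distance_cm,
                "mean_speed": loco.mean_speed_cm_s if loco.defined else np.nan,
                "n_freezes": loco.n_freezing_bouts,
            }
        )
    df = pd.DataFrame(rows, columns=ENDPOINT_COLUMNS)
    n_undef = int(df["sab_percent"].isna().sum())
    if n_undef:
        logger.info("%d tracks with <3 entries excluded from alternation scoring", n_undef)
    return df
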