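"""Synthetic cohort generator: trajectories, mortality tables, avoidance latencies.

Trajectories follow a discrete-time correlated random walk steered between
waypoints (arm tips and the junction centre). The next arm at each junction
crossing is drawn so that the probability of choosing the arm that differs
from *both* previously visited arms equals ``p_alternate`` — making the
downstream alternation score a planted, controllable ground truth.

All randomness flows from explicit seeds. Per-fish streams are derived with
``numpy.random.SeedSequence`` keyed on (master seed, group index, fish index,
day index), so growing a cohort never reshuffles existing fish.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import ARM_NAMES, MazeGeometry

TRACK_COLUMNS = ["time_s", "x_cm", "y_cm", "fish_id", "day", "dose"]
MORTALITY_COLUMNS = ["dose_ug", "dose_mg_per_kg", "n", "deaths"]
IAT_COLUMNS = ["fish_id", "group", "train_latency_s", "test_latency_s"]


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class BehaviorParams:
    """Per-group kinematic and choice parameters for the track simulator."""

    dose_label: str
    mean_speed: float = 6.0          # cm/s
    speed_sd: float = 1.5            # cm/s
    freeze_rate: float = 0.0         # bouts/min
    freeze_duration: float = 3.0     # s
    p_alternate: float = 0.5
    turn_noise: float = 0.3          # rad, heading jitter per step

    def __post_init__(self):
        if not 0.0 <= self.p_alternate <= 1.0:
            raise ValueError("p_alternate must be in [0, 1]")
        for name in ("mean_speed", "speed_sd", "freeze_rate", "freeze_duration", "turn_noise"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class StudyDesign:
    doses: tuple[str, ...] = ("control", "100ug", "200ug")
    days: tuple[str, ...] = ("day1", "day2")
    n_fish_per_group: int = 10
    trial_duration: float = 600.0    # s
    sample_rate: float = 25.0        # Hz
    seed: int = 0

    def __post_init__(self):
        if self.trial_duration <= 0 or self.sample_rate <= 0:
            raise ValueError("trial_duration and sample_rate must be positive")
        if self.n_fish_per_group < 1:
            raise ValueError("n_fish_per_group must be >= 1")


@dataclass
class SimTrack:
    """A simulated track plus its planted arm-visit order (ground truth)."""

    fish_id: str
    day: str
    dose: str
    time_s: np.ndarray
    x_cm: np.ndarray
    y_cm: np.ndarray
    planted_arms: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.time_s,
                "x_cm": self.x_cm,
                "y_cm": self.y_cm,
                "fish_id": self.fish_id,
                "day": self.day,
                "dose": self.dose,
            }
        )


@dataclass
class StudyDataset:
    design: StudyDesign
    tracks: list[SimTrack]

    def to_frame(self) -> pd.DataFrame:
        return pd.concat([t.to_frame() for t in self.tracks], ignore_index=True)

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.6f")


def _choose_next_arm(rng: np.random.Generator, history: list[str], p_alternate: float) -> str:
    """Arm-choice rule at a junction crossing.

    With two distinct previous entries (prev2, prev1) the maze has exactly one
    arm differing from both; it is chosen with probability ``p_alternate``,
    otherwise the fish revisits prev2. Early entries are uniform over the
    arms other than the current one.
    """
    if not history:
        return ARM_NAMES[rng.integers(3)]
    if len(history) == 1:
        others = [a for a in ARM_NAMES if a != history[-1]]
        return others[rng.integers(2)]
    prev2, prev1 = history[-2], history[-1]
    novel = next(a for a in ARM_NAMES if a not in (prev1, prev2))
    return novel if rng.random() < p_alternate else prev2


def simulate_track(
    params: BehaviorParams,
    geometry: MazeGeometry,
    duration: float,
    rate: float,
    seed,
    forced_arm_order: list[str] | None = None,
) -> SimTrack:
    """Simulate one fish for ``duration`` seconds at ``rate`` Hz.

    ``forced_arm_order`` overrides the stochastic arm choice with a fixed
    visit order (used for round-trip tests of entry extraction).
    """
    if duration <= 0 or rate <= 0:
        raise ValueError("duration and rate must be positive")
    n = math.ceil(duration * rate)
    dt = 1.0 / rate
    rng = np.random.default_rng(seed)

    # freezing: Poisson bout starts, each freezing the fish for freeze_duration
    freeze_until = -1.0
    lam = params.freeze_rate / 60.0  # bouts per second
    next_freeze = rng.exponential(1.0 / lam) if lam > 0 else math.inf

    x = np.empty(n)
    y = np.empty(n)
    px, py = 0.0, 0.0  # uniform start at junction centroid
    planted: list[str] = []
    forced = list(forced_arm_order) if forced_arm_order is not None else None
    state = "choose"  # choose -> to_arm -> to_junction -> choose ...
    wx, wy = 0.0, 0.0
    tol = 1.0  # cm, waypoint capture radius
    contains = geometry.contains

    for i in range(n):
        t = i * dt
        if t >= next_freeze and t >= freeze_until:
            freeze_until = t + params.freeze_duration
            next_freeze = freeze_until + (rng.exponential(1.0 / lam) if lam > 0 else math.inf)
        frozen = t < freeze_until

        if state == "choose":
            if forced is not None:
                arm = forced.pop(0) if forced else None
            else:
                arm = _choose_next_arm(rng, planted, params.p_alternate)
            if arm is None:
                state = "done"
            else:
                planted.append(arm)
                wx, wy = geometry.arm_waypoint(arm)
                state = "to_arm"

        if not frozen and state in ("to_arm", "to_junction"):
            speed = params.mean_speed
            if params.speed_sd > 0:
                speed += params.speed_sd * rng.standard_normal()
            speed = max(speed, 0.0)
            ddx, ddy = wx - px, wy - py
            d = math.hypot(ddx, ddy)
            if d < tol:
                if state == "to_arm":
                    wx, wy, state = 0.0, 0.0, "to_junction"
                else:
                    state = "choose"
            elif speed > 0:
                desired = math.atan2(ddy, ddx)
                heading = desired + (params.turn_noise * rng.standard_normal()
                                     if params.turn_noise > 0 else 0.0)
                step = min(speed * dt, d)
                cx = px + step * math.cos(heading)
                cy = py + step * math.sin(heading)
                if not contains(cx, cy):
                    cx = px + step * math.cos(desired)
                    cy = py + step * math.sin(desired)
                    if not contains(cx, cy):
                        cx, cy = px, py
                px, py = cx, cy
        x[i] = px
        y[i] = py

    time_s = np.arange(n) * dt
    return SimTrack("fish", "day1", params.dose_label, time_s, x, y, planted)


def simulate_cohort(design: StudyDesign, params_by_group: dict[str, BehaviorParams]) -> StudyDataset:
    """One track per fish per day; fish identity is stable across days."""
    missing = [d for d in design.doses if d not in params_by_group]
    if missing:
        raise ConfigurationError(f"missing BehaviorParams for doses: {missing}")
    geometry = MazeGeometry()
    tracks: list[SimTrack] = []
    for gi, dose in enumerate(design.doses):
        params = params_by_group[dose]
        for fi in range(design.n_fish_per_group):
            fish_id = f"{dose}_f{fi:03d}"
            for di, day in enumerate(design.days):
                ss = np.random.SeedSequence([design.seed, gi, fi, di])
                tr = simulate_track(
                    params, geometry, design.trial_duration, design.sample_rate, ss
                )
                tr.fish_id, tr.day, tr.dose = fish_id, day, dose
                tracks.append(tr)
    return StudyDataset(design, tracks)


def simulate_mortality(
    doses_ug: list[float],
    n_per_group: list[int],
    true_ld50: float,
    probit_slope: float,
    control_rate: float = 0.0,
    seed: int = 0,
    body_weight_g: float = 1.0,
) -> pd.DataFrame:
    """Binomial dose-group mortality from a probit model plus background risk.

    Total death probability composes independent risks,
    ``p = c + (1 - c) * Phi(slope * (log10 d - log10 LD50))``, so the
    background-mortality correction downstream inverts it exactly. Dose 0
    uses the background rate alone. Doses in ug per fish are also expressed
    as mg/kg given the average body weight (default 1 g).
    """
    from scipy.stats import norm

    if probit_slope <= 0:
        raise ValueError("probit_slope must be positive")
    if not 0.0 <= control_rate < 1.0:
        raise ValueError("control_rate must be in [0, 1)")
    if len(doses_ug) != len(n_per_group):
        raise ValueError("doses_ug and n_per_group must have equal length")
    if any(d < 0 for d in doses_ug) or any(n < 1 for n in n_per_group):
        raise ValueError("doses must be >= 0 and group sizes >= 1")

    rng = np.random.default_rng(seed)
    rows = []
    for dose, n in zip(doses_ug, n_per_group):
        mg_per_kg = dose / body_weight_g
        if dose == 0:
            p = control_rate
        else:
            z = probit_slope * (math.log10(mg_per_kg) - math.log10(true_ld50))
            p = control_rate + (1.0 - control_rate) * norm.cdf(z)
        deaths = int(rng.binomial(n, p))
        rows.append({"dose_ug": dose, "dose_mg_per_kg": mg_per_kg, "n": n, "deaths": deaths})
    return pd.DataFrame(rows, columns=MORTALITY_COLUMNS)


def simulate_iat(
    n: int,
    learned_delta: float,
    noise_sd: float,
    nonavoider_rate: float = 0.0,
    seed: int = 0,
    group: str = "control",
    base_latency: float = 30.0,
    base_sd: float = 10.0,
    cutoff: float = 180.0,
) -> pd.DataFrame:
    """Paired train/test entry latencies with planted learning effect.

    ``round(n * nonavoider_rate)`` fish are flagged non-avoiders: their train
    latency is planted above ``cutoff``. All other train latencies stay below
    it. Test latency = train + learned_delta + noise, clipped at 0.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if not 0.0 <= nonavoider_rate <= 1.0:
        raise ValueError("nonavoider_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_nonavoid = round(n * nonavoider_rate)
    train = np.clip(rng.normal(base_latency, base_sd, size=n), 0.0, cutoff - 1e-6)
    flags = np.zeros(n, dtype=bool)
    if n_nonavoid:
        idx = rng.choice(n, size=n_nonavoid, replace=False)
        flags[idx] = True
        train[idx] = rng.uniform(cutoff + 1.0, cutoff + 120.0, size=n_nonavoid)
    noise = noise_sd * rng.standard_normal(n) if noise_sd > 0 else np.zeros(n)
    test = np.clip(train + learned_delta + noise, 0.0, None)
    return pd.DataFrame(
        {
            "fish_id": [f"{group}_f{i:03d}" for i in range(n)],
            "group": group,
            "train_latency_s": train,
            "test_latency_s": test,
            "nonavoider": flags,
        }
    )
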