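import numpy as np
import pytest

from phenotyper.geometry import MazeGeometry
from phenotyper.synth import BehaviorParams, StudyDesign, simulate_cohort, simulate_track
from phenotyper import imaging, tracking


@pytest.fixture(scope="session")
def geometry():
    return MazeGeometry()


def make_track(sim):
    return tracking.Track(sim.fish_id, sim.day, sim.dose, sim.time_s, sim.x_cm, sim.y_cm)


def sab_of(sim, geometry, min_dwell=0.5):
    tr = make_track(sim)
    zones = tracking.assign_zones(tr, geometry)
    return tracking.compute_sab(tracking.extract_arm_entries(zones, min_dwell=min_dwell))


@pytest.fixture(scope="session")
def two_class_images(geometry):
    """Small planted-effect image set: slow vs fast fish, 8 fish/class."""
    design = StudyDesign(doses=("slow", "fast"), days=("day1",), n_fish_per_group=8,
                         trial_duration=300.0, sample_rate=25.0, seed=42)
    params = {
        "slow": BehaviorParams("slow", mean_speed=1.5, speed_sd=0.4),
        "fast": BehaviorParams("fast", mean_speed=9.0, speed_sd=2.0),
    }
    study = simulate_cohort(design, params)
    tracks = [make_track(t) for t in study.tracks]
    return imaging.rasterize_study(tracks, geometry, size=32)


@pytest.fixture(scope="session")
def demo_images(geometry):
    """3 doses x 2 days x 6 fish, 200ug planted effect; 32px images."""
    design = StudyDesign(n_fish_per_group=6, trial_duration=300.0,
                         sample_rate=25.0, seed=5)
    params = {
        "control": BehaviorParams("control", mean_speed=6.0, p_alternate=0.55),
        "100ug": BehaviorParams("100ug", mean_speed=6.0, p_alternate=0.55),
        "200ug": BehaviorParams("200ug", mean_speed=3.0, speed_sd=1.0,
                                p_alternate=0.2, freeze_rate=3.0, freeze_duration=4.0),
    }
    study = simulate_cohort(design, params)
    tracks = [make_track(t) for t in study.tracks]
    return imaging.rasterize_study(tracks, geometry, size=32)
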