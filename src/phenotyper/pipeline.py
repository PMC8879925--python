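"""End-to-end orchestration: simulate -> score -> LD50 -> images -> classify
-> communities -> statistics, from a single config, with a machine-readable
report.

The master seed is fanned out to named substreams (synth / mortality / iat /
split / train / permute / louvain) via ``numpy.random.SeedSequence`` so each
stage is independently reproducible and the whole report hashes identically
across reruns.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import classify, community, imaging, stats, tox, tracking
from .geometry import MazeGeometry
from .nn import TrainConfig
from .synth import (
    BehaviorParams,
    StudyDesign,
    simulate_cohort,
    simulate_iat,
    simulate_mortality,
)

logger = logging.getLogger(__name__)

_STAGE_IDS = {"synth": 1, "mortality": 2, "iat": 3, "split": 4,
              "train": 5, "permute": 6, "louvain": 7}


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    seed: int = 0
    design: StudyDesign = field(default_factory=StudyDesign)
    groups: dict = field(default_factory=dict)          # dose -> BehaviorParams
    window_s: float = 30.0
    image_size: int = 64
    holdout_frac: float = 0.2
    experiments: tuple[str, ...] = ("E1", "E2A", "E2B", "E3A", "E3B")
    train: TrainConfig = field(default_factory=TrainConfig)
    permutation_reps: int = 1000
    alpha: float = 0.05
    louvain_restarts: int = 10
    mortality: dict | None = None                       # simulate_mortality kwargs
    iat: dict | None = None                             # simulate_iat kwargs per group
    min_dwell: float = 0.5
    save_images: bool = False

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        try:
            design = StudyDesign(
                doses=tuple(raw.get("doses", ("control", "100ug", "200ug"))),
                days=tuple(raw.get("days", ("day1", "day2"))),
                n_fish_per_group=raw.get("n_fish_per_group", 10),
                trial_duration=raw.get("trial_duration", 600.0),
                sample_rate=raw.get("sample_rate", 25.0),
                seed=raw.get("seed", 0),
            )
            groups = {
                dose: BehaviorParams(dose_label=dose, **params)
                for dose, params in raw.get("groups", {}).items()
            }
            train = TrainConfig(**raw.get("train", {}))
        except (TypeError, ValueError) as exc:
            raise ConfigError(str(exc)) from exc
        for dose in design.doses:
            if dose not in groups:
                raise ConfigError(f"groups: missing behavior params for dose {dose!r}")
        return cls(
            seed=raw.get("seed", 0),
            design=design,
            groups=groups,
            window_s=raw.get("window_s", 30.0),
            image_size=raw.get("image_size", 64),
            holdout_frac=raw.get("holdout_frac", 0.2),
            experiments=tuple(raw.get("experiments", ("E1", "E2A", "E2B", "E3A", "E3B"))),
            train=train,
            permutation_reps=raw.get("permutation_reps", 1000),
            alpha=raw.get("alpha", 0.05),
            louvain_restarts=raw.get("louvain_restarts", 10),
            mortality=raw.get("mortality"),
            iat=raw.get("iat"),
            min_dwell=raw.get("min_dwell", 0.5),
            save_images=raw.get("save_images", False),
        )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _substream_seed(master: int, stage: str, extra: int = 0) -> int:
    ss = np.random.SeedSequence([master, _STAGE_IDS[stage], extra])
    return int(ss.generate_state(1)[0])


def _canonical(obj):
    if isinstance(obj, dict):
        return {str(k): _canonical(v) for k, v in sorted(obj.items(), key=lambda kv: str(kv[0]))}
    if isinstance(obj, (list, tuple)):
        return [_canonical(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        return round(float(obj), 12)
    if isinstance(obj, np.integer):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return _canonical(obj.tolist())
    return obj


def report_hash(report: dict) -> str:
    payload = json.dumps(_canonical(report), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()


def run(config: PipelineConfig, outdir=None) -> dict:
    """Execute the full stage DAG and return the run report dict."""
    geometry = MazeGeometry()
    report: dict = {"seed": config.seed, "stages": {}}

    # --- synthesize cohort -------------------------------------------------
    design = StudyDesign(**{**asdict(config.design), "seed": _substream_seed(config.seed, "synth")})
    study = simulate_cohort(design, config.groups)
    logger.info("simulated %d tracks", len(study.tracks))

    # --- behavioral endpoints ---------------------------------------------
    tracks = [
        tracking.Track(t.fish_id, t.day, t.dose, t.time_s, t.x_cm, t.y_cm)
        for t in study.tracks
    ]
    endpoints = tracking.score_tracks(tracks, geometry, min_dwell=config.min_dwell)
    report["stages"]["endpoints"] = {
        "n_tracks": len(endpoints),
        "n_undefined_sab": int(endpoints["sab_percent"].isna().sum()),
        "sab_by_group": {
            f"{day}:{dose}": round(float(g["sab_percent"].mean()), 6)
            for (day, dose), g in endpoints.groupby(["day", "dose"])
        },
    }

    # --- mortality / LD50 --------------------------------------------------
    mort_cfg = config.mortality or {}
    mort_kwargs = {
        "doses_ug": mort_cfg.get("doses_ug", [0, 50, 100, 200, 400]),
        "n_per_group": mort_cfg.get("n_per_group", [40, 40, 40, 40, 40]),
        "true_ld50": mort_cfg.get("true_ld50", 292.0),
        "probit_slope": mort_cfg.get("probit_slope", 2.0),
        "control_rate": mort_cfg.get("control_rate", 0.05),
        "seed": _substream_seed(config.seed, "mortality"),
    }
    mort_table = simulate_mortality(**mort_kwargs)
    ld50 = tox.fit_ld50(mort_table)
    report["stages"]["ld50"] = {
        "estimate_mg_per_kg": round(ld50.ld50, 6),
        "slope": round(ld50.slope, 6),
        "r_squared": round(ld50.r_squared, 6),
    }

    # --- IAT ----------------------------------------------------------------
    iat_cfg = config.iat or {"control": {"learned_delta": 40.0, "noise_sd": 10.0},
                             "200ug": {"learned_delta": 0.0, "noise_sd": 10.0}}
    iat_report = {}
    for gi, (group, kwargs) in enumerate(sorted(iat_cfg.items())):
        rec = simulate_iat(n=kwargs.get("n", design.n_fish_per_group),
                           learned_delta=kwargs.get("learned_delta", 0.0),
                           noise_sd=kwargs.get("noise_sd", 10.0),
                           nonavoider_rate=kwargs.get("nonavoider_rate", 0.0),
                           seed=_substream_seed(config.seed, "iat", gi), group=group)
        kept, excluded = stats.filter_nonavoiders(rec)
        cmp = stats.compare_paired(kept["train_latency_s"], kept["test_latency_s"])
        iat_report[group] = {"n": len(kept), "excluded": excluded,
                             "paired_t": round(cmp.statistic, 6),
                             "df": cmp.df, "p_value": round(cmp.p_value, 6)}
    report["stages"]["iat"] = iat_report

    # --- images -------------------------------------------------------------
    images = imaging.rasterize_study(tracks, geometry, window_s=config.window_s,
                                     size=config.image_size)
    report["stages"]["images"] = {"n_images": len(images)}
    if outdir is not None and config.save_images:
        out = Path(outdir)
        imaging.save_images(images, out / "images", out / "images_index.csv")

    # --- classification experiments -----------------------------------------
    experiments = {}
    partitions = {}
    for ei, exp_id in enumerate(config.experiments):
        design_obj = classify.make_design(exp_id, days=config.design.days,
                                          doses=config.design.doses)
        train_set, val_set = classify.assemble_dataset(
            images, design_obj, holdout_frac=config.holdout_frac,
            seed=_substream_seed(config.seed, "split", ei))
        tc = TrainConfig(**{**asdict(config.train),
                            "seed": _substream_seed(config.seed, "train", ei)})
        model = classify.train_classifier(train_set, tc)
        preds, accuracy = classify.evaluate(model, val_set, match_on=design_obj.match_on)
        baseline = classify.permutation_baseline(
            preds, reps=config.permutation_reps, alpha=config.alpha,
            seed=_substream_seed(config.seed, "permute", ei))
        cm = classify.confusion(preds, row_labels=tuple(model.classes),
                                col_labels=tuple(sorted(set(design_obj.test_classes))))
        graph = community.build_similarity_graph(cm)
        part = community.louvain(graph, seed=_substream_seed(config.seed, "louvain", ei),
                                 restarts=config.louvain_restarts)
        partitions[exp_id] = part
        experiments[exp_id] = {
            "n_train": len(train_set),
            "n_val": len(val_set),
            "accuracy": round(accuracy, 6),
            "threshold": round(baseline.threshold, 6),
            "significant": bool(baseline.significant),
            "confusion": {
                "rows": [f"{r[0]}:{r[1]}" for r in cm.row_labels],
                "cols": [f"{c[0]}:{c[1]}" for c in cm.col_labels],
                "values": np.round(cm.values, 9).tolist(),
            },
            "partition": community.partition_to_json(part),
        }
    report["stages"]["experiments"] = experiments

    # --- group statistics ---------------------------------------------------
    defined = endpoints.dropna(subset=["sab_percent"])
    doses = list(config.design.doses)
    stat_report = {}
    if len(doses) >= 2:
        lo, hi = doses[0], doses[-1]
        a = defined.loc[defined["dose"] == lo, "sab_percent"].to_numpy()
        b = defined.loc[defined["dose"] == hi, "sab_percent"].to_numpy()
        if len(a) >= 2 and len(b) >= 2:
            cmp = stats.compare_unpaired(a, b, alpha=config.alpha)
            stat_report[f"sab_{lo}_vs_{hi}"] = {
                "test": cmp.test, "statistic": round(cmp.statistic, 6),
                "df": cmp.df, "p_value": round(cmp.p_value, 6)}
        corr = stats.correlate(defined["sab_percent"], defined["distance_cm"])
        stat_report["sab_vs_distance"] = {
            "r": round(corr.r, 6) if corr.r is not None else None,
            "df": corr.df,
            "p_value": round(corr.p_value, 6) if corr.p_value is not None else None,
        }
    report["stages"]["statistics"] = stat_report

    report["report_hash"] = report_hash(report)

    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        study.write_csv(out / "tracks.csv")
        endpoints.to_csv(out / "endpoints.csv", index=False)
        mort_table.to_csv(out / "mortality.csv", index=False)
        with open(out / "ld50.json", "w") as fh:
            json.dump(ld50.to_dict(), fh, indent=2, default=str)
        for exp_id, part in partitions.items():
            with open(out / f"partition_{exp_id}.json", "w") as fh:
                json.dump(community.partition_to_json(part), fh, indent=2)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2)
    return report
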