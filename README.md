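# phenotyper

A tested, reusable pipeline for small-fish Y-maze toxicology studies:

- **synth** — synthetic study generator: correlated-random-walk trajectories
  inside a parametric three-arm maze with a *planted* alternation
  probability and kinematics per dose group, binomial dose-group mortality
  from a probit model, and paired avoidance-latency records. Everything
  downstream can be validated against the planted ground truth.
- **tracking** — track-table parsing (flat `time_s,x_cm,y_cm,fish_id,day,dose`
  CSV), zone assignment, arm-entry extraction with dwell hysteresis,
  spontaneous-alternation scoring (`100 * alternations / (entries - 2)`),
  and locomotor endpoints (distance, speed, freezing bouts).
- **tox** — Miller–Tainter-style LD50: Abbott control-mortality correction,
  endpoint-corrected probit transform, unweighted probit-vs-log10(dose)
  regression, optional bootstrap CI.
- **imaging** — cuts tracks into 30-s windows and rasterizes each to a
  64×64 grayscale image (Bresenham lines, time-graded intensity).
- **classify** — experiment designs E1/E2A/E2B/E3A/E3B (combined-days,
  single-day, and cross-day train/test), subject-level holdout splits, a
  small residual CNN implemented in pure NumPy (`nn.py`), column-normalized
  confusion matrices, and shuffled-label permutation baselines.
- **community** — confusion-matrix similarity graphs (symmetrized off-diagonal
  confusion mass) and a deterministic Louvain modularity optimizer.
- **stats** — Shapiro–Wilk-gated two-group tests, paired t, Pearson
  correlation, non-avoider filtering, one-way ANOVA + LSD, Kruskal–Wallis.
- **pipeline** — one-config orchestration of the whole DAG with a hashed,
  reproducible JSON run report.

## Test

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (oracle
equivalence of the alternation scorer, LD50 recovery, classifier signal and
permutation calibration, confusion-matrix contracts, Louvain correctness
against brute-force enumeration, headline community structure, statistics
calibration, and whole-run determinism).

## CLI

```bash
phenotyper run --config examples/demo.yaml --out runs/demo/
phenotyper simulate --config examples/demo.yaml --out tracks.csv
phenotyper score-tracks --in tracks.csv --out endpoints.csv
phenotyper ld50 --in mortality.csv --out ld50.json
phenotyper classify --design E1 --images index.csv --out run.json
phenotyper stats --endpoints endpoints.csv --pairs control:200ug --out stats.json
```

The full demo run writes `tracks.csv`, `endpoints.csv`, `mortality.csv`,
`ld50.json`, per-experiment partitions, and `report.json` (with a
`report_hash` that is identical across reruns of the same config + seed).

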