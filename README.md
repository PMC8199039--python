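# skiscore

Motion-quality scoring for alpine skiing from boot-mounted inertial
sensors.

Recreational and competitive skiers increasingly wear small IMUs, but most
wearable systems only count motion (turns, runs, kilometres). `skiscore`
implements the scoring extension of the activity recognition chain: after
segmenting a run into turns, enriching each turn with interpretable
biomechanical variables and classifying its style and size, it answers
*how well* the skier turned, on a single 1–10 scale anchored to a
gold-standard reference cohort.

## What it computes

Input per run: two boot IMU streams (3-axis accelerometer ±16 g, 3-axis
gyroscope ±1000 dps, nominally 54 Hz) and a 1 Hz GNSS speed track, as CSV.

1. **Segmentation** — under the pendulum model of skiing the legs roll
   once per turn, so turn transitions are the alternating-sign extrema of
   the low-pass-filtered roll-rate gyroscope signal. The first and last
   turn of each run, and turns slower than `median − MAD` of the interior
   turn speeds, are excluded.
2. **Enrichment** — each turn yields four variables, linearly resampled to
   101 points over 0–100 % turn duration: edge angle (boot roll vs gravity
   via a complementary filter, degrees), edge-angle symmetry (difference
   to the neighbouring opposite-direction turn, degrees), radial force
   (v·|ω_yaw|/g, multiples of body weight) and speed (interpolated GNSS,
   m/s).
3. **Classification** — style (carving / drifting / …) from provided
   labels or a naive stand-in rule, and size (small < 8 m, medium 8–12 m,
   large > 12 m) from the quasi-static radius r = v̄/ω̄.
4. **Reference model** — for every (style, size) cell and variable, a
   centered PCA of the n × 101 reference matrix `P_ref`. The first three
   loading vectors `PC→ref`, their fractions of total variance, and the
   SDs of the reference PC scores `PCS_ref` are persisted as JSON.
5. **Scoring** — a new turn is projected into the reference PC space;
   each PC score becomes an absolute Z-score, discretised as
   Z < 0.75 → 4, 0.75–1.5 → 3, 1.5–3 → 2, Z > 3 → 1, weighted by the PC's
   variance fraction, summed within and across variables and expressed as
   a percentage of the maximum. Carving turns map linearly onto 7–10,
   drifting onto 3–6; snowplow and snowplow-steering turns carry the
   constants 1 and 2.

Because the reference distribution is centred, deviations in either
direction cost the same: a turn with an unusually *high* edge angle loses
the same points as one equally far below the reference.

## Worked example

The package ships a seeded simulator so the whole chain runs without any
field data:

```bash
skiscore simulate --out runs --preset expert --runs 6 --turns 26 --seed 7
printf 'classify:\n  style_from: intended\n' > config.yaml
skiscore fit runs --out model.json --config config.yaml
skiscore score runs --model model.json --out scores.csv --config config.yaml
skiscore evaluate scores.csv --by run_id
```

The score step prints per-run summaries:

```
expert_run00: mean=9.53 median=9.51 (19 turns)
expert_run01: mean=9.55 median=9.56 (17 turns)
expert_run02: mean=9.57 median=9.56 (18 turns)
expert_run03: mean=5.54 median=5.56 (17 turns)
...
```

Runs 0–2 are carving (band 7–10), runs 3–5 drifting (band 3–6); scoring a
reference-like cohort against its own model lands near the top of each
band, as it should. `evaluate` adds a Kruskal–Wallis comparison across
groups and per-group skewness:

```
Kruskal-Wallis across run_id (6 groups): H=78.106 p=0.0000
run_id=expert_run00: n=19 median=9.51 skewness=0.29
...
```

`scores.csv` keeps every intermediate (per-PC Z-scores per variable,
percentage, final score), so downstream tools can turn sub-scores into
coaching feedback ("your radial-force peak comes too late").

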