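# Methods

## Signal model and pipeline

`skiscore` treats a ski run as a sequence of turns produced by a pendulum
motion of the legs: the boot rolls to one side, the ski is set on edge,
the skier arcs the turn, and at the transition the roll rate peaks while
the sign of the roll flips. The pipeline is the activity recognition
chain — segmentation, enrichment, classification — extended by a scoring
stage that quantifies how similar a turn is to a gold-standard reference.

### Axis conventions and units

Boot-cuff IMU: Y vertical (superior), X lateral (right), Z posterior.
The roll-rate channel is therefore gyro Z and the yaw-rate channel gyro Y.
Accelerometer values are stored in g (±16 g full scale) and angular rates
in deg/s (±1000 dps); gravity is 9.80665 m/s². Samples arrive nominally
at 54 Hz; the GNSS speed track at 1 Hz.

### Segmentation

The roll-rate signal is low-pass filtered (zero-phase 2nd-order
Butterworth, cutoff 2 Hz) and its alternating-sign extrema are detected
with prominence ≥ 15 dps and separation ≥ 0.6 s (all configurable; the
defaults suit recreational turn periods of roughly 1–4 s). Consecutive
same-sign extrema keep the more prominent one. A turn spans one extremum
to the next, so consecutive turns alternate direction by construction.
Transmission gaps longer than three nominal sample intervals are flagged
by the reader and no segment may span one.

Exclusion rules: the first and last detected turn of every run are
dropped, then a turn is dropped iff its mean GNSS speed is strictly below
`median − MAD` of the interior turns' speeds, with the raw MAD (no
1.4826 consistency constant). Note a statistical property of this rule:
for independent identically distributed turn speeds it trims roughly a
quarter of the turns, because about 25 % of any symmetric sample lies
below median − MAD. It behaves as intended when slow turns are outliers
(run ends, recoveries), which is the regime it was designed for.

### Enrichment

* **Edge angle** (deg): complementary filter
  `θ_t = α(θ_{t−1} + ω_roll Δt) + (1−α)·atan2(ax, ay)`, α = 0.98 at
  54 Hz (≈0.9 s time constant), initialised at the first accelerometer
  estimate. The reported profile is |θ| of the outside boot of the turn
  (left turn → right boot; configurable to the two-boot mean).
* **Edge-angle symmetry** (deg): signed difference between the current
  turn's 101-point edge-angle profile and the previous opposite-direction
  turn's; the first scored turn of a run uses the following opposite turn;
  with no opposite neighbour at all the vector is zero and flagged.
* **Radial force** (body weights): quasi-static `v·|ω_yaw|/g`, pointwise.
* **Speed** (m/s): GNSS linearly interpolated to the IMU timestamps.

All four are linearly resampled to 101 points over 0–100 % turn duration
with endpoints preserved.

### Classification

Style labels supplied externally (a labels CSV, or the run's intended
style code when `classify.style_from: intended`) are taken verbatim. The
built-in fallback is an intentionally naive stand-in — carving iff mean
edge angle ≥ 30° and the radial-force waveform is single-peaked — and
never emits `non_parallel`. Size uses the quasi-static radius r = v̄/ω̄
with a closed medium band [8, 12] m; a zero mean yaw rate is flagged as a
straight glide and classified large.

### Reference model

For each (style ∈ {carving, drifting}, size) cell with at least
`min_ref_turns` (default 10) reference turns, and each variable, a
centered PCA is computed by SVD of the n × 101 matrix. Retained per cell:
the mean curve, the first three loading vectors (orthonormal, sign-fixed
so each vector's largest-magnitude element is positive), their explained
fractions of **total** variance, and the SDs (ddof = 1) of the reference
PC scores. Three components are the fixed design choice of the scoring
scale; the count is configurable only for research use. Rank-deficient
cells keep the available components and pad the rest with orthonormal
complement directions carrying zero variance fraction and a sentinel
score SD of 1 — padded components never contribute because Z is defined
as 0 where the variance fraction is 0. The rank tolerance is anchored to
the data scale so that a constant matrix (centered residual = rounding
noise) counts as rank 0.

Models persist as JSON with `schema_version: "1"`; loading re-validates
orthonormality (1e-8), ordering and completeness, and round-trips are
bit-lossless (floats serialised at full double precision, parsed with
round-trip precision).

### Scoring

For a new turn: scores_k = ⟨x − mean, loading_k⟩; Z_k = |scores_k|/SD_k;
bins 4/3/2/1 at the break-points 0.75, 1.5, 3 (the published rule leaves
the boundaries themselves undefined; they are assigned to the *lower*
score, a conservative choice); sub-score per variable Σ bin_k·varfrac_k;
percentage = 100·Σ_v sub_v / Σ_v 4·Σ_k varfrac_{v,k} ∈ [25, 100] (the
worst bin is 1, not 0); final score 7 + 3·pct/100 for carving,
3 + 3·pct/100 for drifting, constants 1/2 for snowplow and snowplow
steering. The weighting uses raw total-variance fractions, the reading
under which a perfect bin of 4 on a PC explaining 22 % of variance
contributes exactly 0.88; the percentage normalisation absorbs the fact
that per-variable maxima are then 4·Σ varfrac rather than 4.

Non-parallel turns have no band of their own on the published scale; they
are scored against the drifting cell of matching size, mapped into the
drifting band and flagged. In batch mode a turn whose (style, size) cell
is absent from the model yields an unscorable record with a reason rather
than an exception. Run summaries report both mean and median of the final
scores, since both are used when comparing against human raters.

## Synthetic data

The simulator defines the study conditions for all tests.

**Turn-curve generator.** Each variable is
`x = μ + a₁φ₁ + a₂φ₂ + a₃φ₃ + ε` on the 101-point base with
`a_k ~ N(skill_offset·σ_k, σ_k²)` and white ε. The modes are the
harmonics sin(kπτ), k = 1..3 — exactly orthogonal on the grid, zero at
the turn transitions as the pendulum model demands, and qualitatively the
three observed sources of variability: magnitude, timing shift, and
single-vs-double peak. Speed, being near-constant, instead uses shifted
Legendre polynomials (offset, trend, curvature), Gram–Schmidt-cleaned on
the grid. Mode SDs default to (8, 3, 1.5)° for edge angle, (4, 2, 1)° for
symmetry, (0.30, 0.12, 0.06) BW for radial force and (1.5, 0.5, 0.2) m/s
for speed, with noise SDs at 10 % of each σ₁ — levels at which three PCs
retain ≈98 % of total variance, comfortably above the ≥85 % regime the
scoring design assumes. Mean profiles: a half-sine edge-angle bell
(peak 50° carving / 25° drifting, i.e. means of ≈32°/16°, straddling the
naive classifier's 30° threshold), a sin² radial-force bell scaled by
v₀²/(r·g), near-constant speed, zero symmetry. `skill_offset` shifts
every coefficient draw by that many SDs: 0 emulates a reference-like
skier, 3 a clearly different one.

**Raw-run generator.** The signed boot roll within turn k is
`±A_k sin(πτ)`, giving one alternating-sign roll-rate pulse of magnitude
A_k·π/T per transition (≈78 dps at the default A ≈ 50°, T = 2 s).
Accelerometer channels follow gravity through the roll; the yaw rate is
`(π/2)(v/r)sin(πτ)` so its per-turn mean of |ω| is exactly v/r and the
radius classification recovers the intended size; GNSS samples the speed
profile at 1 Hz. The base speed is constant per run (slow variation is
available via `speed_mod` and per-turn multipliers) — because of the
25 %-trimming property of the MAD rule noted above, a constant base is
what makes end-to-end turn counts deterministic. Ground truth (boundary
times, directions, per-turn mean speeds, amplitudes, radius) is returned
for oracle tests.

What the simulator does **not** emulate: ski–snow interaction, terrain
and snow-condition effects, vibration, dropped Bluetooth packets,
magnetometer cues, and any correlation structure between the four
variables (they are generated independently, whereas real edge angle and
radial force co-vary). Passing tests therefore demonstrate algorithmic
correctness and statistical behaviour under the assumed three-mode model,
not field accuracy of the enrichment estimators.

## Numerical choices and edge cases

* PCA via SVD of the centered matrix (not covariance eigendecomposition)
  for stability; equivalence is asserted against a brute-force covariance
  oracle and scikit-learn in the tests.
* Deterministic loading signs (largest-magnitude element positive) make
  fitted models reproducible byte-for-byte.
* Bin boundaries resolve to the lower score; strictly increasing any
  single |Z| can therefore never raise a final score.
* `filter_turns` with fewer than three segments returns an empty list
  with a warning (nothing can survive removing first and last).
* Out-of-full-scale samples are clipped with a warning by default
  (`io.clip_out_of_range: false` turns them into hard errors).
* All randomness flows through `numpy.random.default_rng` seeds; the
  simulate → fit → score chain is bit-reproducible for a fixed seed.

## Problem sizes

Reference cohorts of 200 turns per (style, size) cell are used for model
fitting experiments and the acceptance computations; discrimination
experiments use 200 turns per skill group; segmentation-robustness checks
run 200 seeded replicates of 8-turn runs. These sizes put standard errors
of the recovered quantities (mode cosines, variance fractions, rank-test
p-values) well inside the asserted margins while keeping the whole suite
in the tens of seconds.

## Known limitations

* The enrichment estimators are deliberately simple stand-ins for the
  validated algorithms of the surrounding literature (complementary
  filter instead of full orientation fusion; quasi-static radial force);
  their absolute accuracy on real snow is untested here.
* The naive style classifier exists so the pipeline runs unlabelled; any
  serious use should provide labels.
* Scoring quality is only as good as the reference cohort: the model
  measures similarity to the reference distribution, not objective
  quality, and penalises "better than reference" exactly like "worse".
* Snowplow styles receive constant scores by design; their motion content
  is not modelled.
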