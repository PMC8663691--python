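# Methods

## The measurement problem

Quiet-standing postural sway is conventionally measured as the excursion of
the center of pressure (COP) on a force plate, summarized per direction
(medial-lateral, anterior-posterior) by three scalars: normalized path length
(NPL, a sway-velocity-like measure), root-mean-square amplitude (RMS), and
peak-to-peak range (P2P). A VR headset measures position too — but from above
the center of gravity rather than below it, at a far lower rate (10 Hz vs
200 Hz here), and with its own tracking noise. Validating the headset as a
sway instrument therefore splits into two questions this package answers with
standard tools: is each headset metric stable across repeated trials
(test-retest reliability, ICC), and does it covary with the force-plate metric
across subjects (agreement, regression R²)?

Because no raw recordings are distributed, the pipeline ships with a synthetic
cohort generator that encodes the study design and the statistical structure
the analyses assume. All validation is against that generator's known truth.

## Latent sway model

Each (subject, condition, trial, direction) has a latent sway path modeled as
a stationary Ornstein–Uhlenbeck (OU) process — the simplest surrogate with
COP-like mean reversion — simulated by its exact discretization

    x_{t+Δ} = x_t e^{−θΔ} + ε √(A²(1 − e^{−2θΔ})),   x_0 ~ N(0, A²),

so there is no integration error and every trace is exactly linear in its
amplitude A. Defaults: mean-reversion rate θ = 5 s⁻¹ (correlation time
0.2 s, spectral content concentrated below a few Hz, as in quiet standing),
trial length 20 s, force-plate rate 200 Hz. Time grids include t = 0
(N = duration·rate + 1 samples), which makes 200 Hz → 10 Hz decimation an
exact 20:1 subsample on aligned grids.

The amplitude is lognormal with a random-effects structure that *is* the
reliability dial:

    A = σ_base · m^{[EC]} · exp(u_i + w_it),  u_i ~ N(0, τ²),  w_it ~ N(0, ω²),

with σ_base = 0.3 cm (typical eyes-open ML COP RMS), eyes-closed multiplier
m = 1.5 (sway grows without vision), and τ² = ω² = 0.04 by default, so the
log-amplitude intraclass correlation τ²/(τ²+ω²) is 0.5 — in the "moderate"
band where real single-trial sway amplitudes live. AP amplitude is 1.2× ML
(quiet-standing anisotropy); ML and AP paths are independent. Random streams
are split per (subject, condition, trial, direction, device) from one root
seed, so cohorts are byte-reproducible and enlarging a cohort never perturbs
existing subjects.

## Headset observation model

The headset sees the *same* latent path, transformed:

    VR(t) = g·exp(η_i) · lowpass_{f_c}(COP)(t_k) + drift(t_k) + jitter_k,

decimated to 10 Hz. Defaults and rationale:

* gain g = 1.5 — sway moves the head, high above the center of gravity, more
  than the COP;
* per-subject log-gain η_i ~ N(0, 0.2²) — head height and headset fit vary by
  subject, which caps the between-subject amplitude correlation below 1 and
  keeps default RMS/P2P R² in a realistic 0.5–0.7 range rather than ≈ 1;
* low-pass cutoff f_c = 0.5 Hz (4th-order zero-phase Butterworth) — the head
  follows postural drift, not fast COP adjustments;
* jitter SD 0.15 cm per 10 Hz sample — tracking noise; at 10 Hz this is the
  dominant contributor to headset path length, which is the designed mechanism
  decorrelating NPL between devices while leaving amplitude coupled;
* Brownian drift with SD 0.05 cm at trial end — slow tracking wander.

With gain 1, jitter = drift = 0 the observation reduces exactly to the
low-passed decimated COP (tested). Non-divisor rate pairs fall back to linear
interpolation with a logged warning. VR latency is deliberately not modeled.

## Estimators

* **Metrics** — NPL = path length / duration; RMS about the trace mean with
  divisor N (population convention; at N = 201 the N vs N−1 difference is
  < 0.3%); P2P = range. No detrending or filtering before metrics: each trace
  is analyzed raw at its native rate. NPL's sampling-rate sensitivity is a
  documented property, not a defect — finer sampling of a noisy path
  accumulates more length (≈ √20 ratio between 200 and 10 Hz for near-white
  increments), and a test demonstrates it.
* **Reliability** — single-measure consistency ICC(3,1) from the two-way
  ANOVA mean squares, chosen because the analysis concerns the reliability of
  single-trial measurements and must tolerate additive trial effects;
  average-measures ICC(3,k) is available behind a flag to bracket the choice.
  95% CIs use the exact F pivot. Reported lower bounds are floored at 0 (the
  untruncated value is retained internally); negative point estimates are
  reported as computed and classified "poor". Classification bands:
  poor < 0.5 ≤ moderate < 0.75 ≤ good ≤ 0.90 < excellent — the boundary 0.90
  itself is "good" because "excellent" is read strictly as > 0.90.
  Subjects with incomplete trials are dropped listwise with a logged count;
  an all-identical matrix is flagged not-estimable rather than given a value.
* **Agreement** — OLS with the COP metric as response and the headset metric
  as the univariate predictor (the direction matters for slope/intercept,
  not for R²), per (metric, condition, direction) and per aggregation
  (first trial; mean of 3 trials). p-values from the regression F test, two
  reporting tiers (p < .001, p < .05), no multiple-testing correction —
  per-cell reporting is the convention this analysis mirrors. Zero predictor
  variance flags the cell not-estimable; zero response variance defines
  R² = 0 with a flag.

## Validation studies and their problem sizes

The simulation studies in `swayval.experiments` (run by the acceptance script
and the heavy end of the test suite) use sizes chosen to make Monte-Carlo
error small against their tolerance bands:

* *ICC recovery*: 50 replicate cohorts x 200 subjects x 3 trials per target
  ICC ∈ {0.3, 0.6, 0.9}, estimated on log COP RMS through the full trace
  pipeline. Total log-amplitude variance is set to τ²+ω² = 0.2 here because
  trace-level RMS estimation noise (Var log RMS ≈ 1/(2Tθ) = 0.005 at T = 20 s,
  θ = 5 s⁻¹) adds to the within-subject variance and attenuates the attained
  ICC to v/(v+0.005) of the dial; at v = 0.2 the worst-case attenuation
  (target 0.9 → 0.878) stays well inside the ±0.05 check.
* *CI coverage*: 1000 simulated 20 x 3 matrices at true ICC 0.6, drawn
  directly from the two-way model with fixed trial effects; the F pivot is
  exact under normality, so coverage should sit near 95%.
* *Correlation recovery*: the headset linkage is reduced to its subject-level
  gain term (jitter/drift off, cutoff at 4.5 Hz so the devices share the
  path), and the log-gain SD γ is solved in closed form from the bivariate
  lognormal correlation, γ² = ln(1 + (e^{s²}−1)/ρ²) − s², with s² the COP
  log-RMS variance estimated from a 1000-subject pilot cohort. A 500-subject
  cohort then estimates R², checked against ρ² for ρ ∈ {0.5, 0.8, 0.95}.
* *Headline contrast*: 50 replicate default cohorts; per-cell mean NPL R²
  below RMS and P2P R², and mean force-plate NPL ICC above headset NPL ICC,
  are asserted as orderings, not values.

## What the generator does and does not emulate

It reproduces the design (n = 20, 3 trials, EO/EC, ML/AP, 200/10 Hz dual-rate
paired observation), amplitude-mediated reliability structure, condition and
anisotropy effects, and the amplitude-coupled / path-length-decoupled device
linkage. It does **not** model inverted-pendulum biomechanics,
ground-reaction forces, VR latency, non-stationarity within a trial, or
trial-to-trial stability of sway *velocity* independent of amplitude. That
last omission is a known limitation: because OU path length is proportional
to amplitude, force-plate NPL inherits the amplitude ICC (≈ 0.5 by default)
instead of the near-unity NPL reliability real force plates show; the
between-device *ordering* (FP NPL ICC > VR NPL ICC) is unaffected. Passing
tests certify the pipeline's statistics and the designed qualitative
mechanism, not biomechanical realism.

## Numerical and interface choices

Trace CSVs store positions in cm to 6 decimals (both instruments resolve far
coarser); rate inference from the median time step tolerates 0.5% jitter
(real devices drop samples) and rejects worse. Cohort validation is total:
it either returns a fully indexed, pairing-checked manifest or raises with
the complete violation list. Units are cm and cm/s everywhere downstream;
any meters-to-cm conversion belongs at ingest. EO is treated as a pure
amplitude condition (the static-scene question is not resolvable here), and
COP/headset units are assumed cm in the absence of a stated convention.
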