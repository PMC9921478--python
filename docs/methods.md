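# Methods

This note records the models, conventions and numerical choices behind
`gaitstab`, in the order the pipeline applies them.

## Coordinate and sign conventions

Walkway axes: `x` nominal walking direction, `y` lateral, `z` up. All
projections use **per-gait-cycle walking axes**: the AP unit vector is the
normalized horizontal CoM displacement from stride start to stride end, and
the ML unit vector is AP rotated by +90° so that it points to the walker's
right (for a stride along +x, AP = (1, 0), ML = (0, +1)). Consequences,
all covered by tests:

* step width is **signed**: stepping-foot-minus-trailing-foot ML
  separation, multiplied by −1 for left steps, so a laterally placed foot
  gives a positive width and a crossover (tandem gait) a negative one;
* ML MoS is `s·(BoS_ML − XCoM_ML)/L` with `s = +1` for right stance and
  `−1` for left, so the margin is positive when the XCoM is medial to the
  stance foot and negative when it falls outside it;
* AP MoS is `(leading BoS_AP − XCoM_AP)/L`, positive when the XCoM is
  behind the leading foot at heel strike. The defining phrase "difference
  between the XCoM and the leading foot" is orderless; this orientation is
  chosen because it makes normal-walking values positive (≈ 0.1–0.2),
  matching how the measure is reported.

The base of support is reduced to the ball-of-foot landmark (ML edge in
single stance; AP front edge at heel strike); the heel landmark is carried
in the data model and available via configuration but not used by default.

## Filtering, differentiation, resampling

Positions are low-pass filtered with a zero-phase Butterworth filter,
cutoff 6 Hz: a second-order design applied forward and backward, i.e. an
effective fourth-order zero-phase filter — the standard biomechanics
convention for a "fourth-order, 6 Hz" specification. Order and cutoff are
configurable. CoM velocity is obtained by central differences on the
filtered positions (exact for linear motion, one-sided at the endpoints).
Resampling between the two systems' rates (100 vs 120 Hz) uses cubic-spline
interpolation, preceded by an anti-alias filter at 0.45 × the target rate
when downsampling.

**Footfall placements.** Step length, step width and the AP MoS foot
position are taken from the mid-stance average (central 25–75 % of stance)
of the filtered ball-of-foot trajectory rather than the instantaneous value
at the contact sample. A stance foot is stationary, so both estimators
target the same quantity, but the zero-phase filter's transient around the
contact-velocity discontinuity biases the instantaneous value by roughly
2 cm at typical walking speed; the mid-stance average is settled to
< 1 mm. Step width is therefore the separation of the two placements over
the stance-overlap interval, which for stationary feet equals the average
ML distance between the feet during that interval.

## Event detection

Heel strikes are local maxima, and toe-offs local minima, of the foot-
minus-CoM displacement projected on the local walking direction (CoM
displacement over a ±1 s window). Extrema are found with a minimum
separation of 0.4 × the median stride time (estimated by a first coarse
pass) and a prominence of 10 % of the signal span; events within half a
stride of the trial boundaries are dropped; alternation (exactly one
toe-off between consecutive same-foot heel strikes, feet alternating) is
enforced, keeping the more prominent extremum on conflicts. A trial whose
relative-displacement span is below 5 cm raises "no gait detected" rather
than returning noise extrema.

Turn strides are flagged when the per-stride direction deviates from the
circular median of all stride directions by more than 30° (configurable);
flagged strides are excluded from every downstream measure. Stride
matching between systems pairs same-foot heel strikes greedily by
increasing time difference within a 0.15 s tolerance (ties toward the
earlier reference event); a stride is paired when both bounding heel
strikes are.

## Lyapunov exponents

Input signal: dimensionless CoM velocity (÷ √(gL)) in AP or ML. Each of
the first 55 gait cycles is linearly resampled to 100 samples and the
cycles concatenated, so the exponent has units 1/stride. Defaults, all
exposed in `EmbeddingSpec`: embedding dimension 5; delay = first local
minimum of the average mutual information within one stride (16-bin
histogram estimator), falling back to a quarter stride; Theiler window =
half a stride; divergence horizon 1 stride; fit range 0–0.5 strides.
Nearest neighbours use a k-d tree with incremental k until a
Theiler-admissible neighbour is found; pairs with zero initial separation
are excluded; the curve reports the number of contributing pairs per time
step so users can judge convergence (55 strides is few).

Two estimator properties matter for interpretation and are deliberately
documented rather than "fixed":

* On the Lorenz system (σ = 10, ρ = 28, β = 8/3) the first ~0.5 time
  units of the divergence curve are a nearest-neighbour alignment
  transient with roughly twice the true slope; the exponential scaling
  region lies at ~0.5–3.5 time units, where the estimate agrees with a
  Benettin tangent-space oracle to within a few percent. The acceptance
  test therefore fits the scaling region; the 0–0.5-stride window remains
  the gait convention (gait signals are noisy and nearly periodic, so
  their curves saturate after ~half a stride and the early window *is*
  the informative one).
* Additive measurement noise raises the initial neighbour separation (a
  noise floor) and therefore *lowers* the fitted short-term slope; λ_s
  increases with stride-to-stride variability relative to neighbour
  density, not with sensor noise per se. The tests assert the guaranteed
  properties: an exactly periodic signal gives |λ_s| < 0.05, cycle-to-
  cycle variability gives a clearly positive λ_s, and λ_s is invariant
  under affine rescaling of the signal.

## Agreement statistics

* **Bland–Altman**: differences are reference − degraded on matched
  strides pooled across subjects; bias = mean, LoA = bias ± 1.96 × sample
  SD (n − 1 denominator — the convention for limits of agreement); a
  per-subject bias table is attached to expose participant-specific
  clusters.
* **ICC(A,1)**: two-way mean squares with rows = individual paired strides
  and columns = the two systems,
  `(MSR − MSE) / (MSR + (k−1)·MSE + (k/n)(MSC − MSE))`, per condition and
  pooled. Qualitative bands use closed lower bounds (0.50 ≤ ICC < 0.75
  moderate, etc.). Because the ICC is a ratio of between-stride variance
  to total variance, pooling heterogeneous conditions inflates it; the
  pipeline reports per-condition and pooled values side by side and the
  tests assert the inflation on the synthetic study.
* **Repeated-measures ANOVA**: one-way within-subject on subject-level
  condition means (strides averaged within trial, trials within subject),
  `F = MS_condition / MS_(subject×condition)` with (c−1, (c−1)(s−1)) df;
  no sphericity correction (none is part of the reported design).
  Post-hoc: paired t-tests of each condition against the control
  (normal), Holm–Šidák adjusted (`1 − (1 − p_(i))^(k−i+1)` with a running
  maximum). Incomplete subject × condition tables skip the ANOVA with an
  explicit notice — no imputation.

## Synthetic study generator

The generator emulates a paired-system overground study: four conditions
(normal, eyes closed, wide ≈ 2.5× normal width, tandem ≈ zero width), a
100 Hz reference system and a 120 Hz degraded system, two trials per
condition, N = 10 subjects by default.

**Kinematics.** Footfalls are placed along a heading path with per-step
Gaussian draws of length, width and duration. Feet hold position in stance
and swing along a quintic (minimum-jerk-like) profile whose boundary
velocity equals twice the local CoM velocity; the CoM–foot AP displacement
then peaks exactly at heel strike with symmetric ±v slopes, so the
ground-truth event is the precise extremum of the detection signal even
after zero-phase filtering (detection recovers truth to within ~half a
sample). The CoM follows monotone cubic keyframes placed 0.35 of a step
ahead of the trailing foot at each heel strike, plus a lateral sway spline
peaking toward the stance foot at mid single stance, with 15 % step-to-step
sway variation (real ML motion is not exactly periodic; this also gives
the divergence analysis something to measure). An optional appended
turning segment ramps the heading by 180° to exercise turn exclusion.

**Condition presets** are anchored to the published optical group means of
the validation experiment shipped in `gaitstab.reference` (step length,
width, speed and their RMS variability, converted to metres with
L = 0.92 m); stride time follows from speed and step length. Sway
amplitudes (2.0 / 2.2 / 3.6 / 1.6 cm for normal / eyes-closed / wide /
tandem at L = 0.92) were calibrated once so the per-condition mean minimum
ML MoS reproduces the published sign pattern and ordering (wide > normal >
0 > tandem). Per-subject heterogeneity: leg length N(0.92, 0.05) m,
relative speed spread 15 %, step-length spread 5 %, an additive preferred-
width offset (SD 4.5 cm), and 10 % sway spread — drawn once per subject.

**Degradation model.** The experiment gives only the symptoms of the
IMU error process, so the model is built to reproduce them: a per-subject
odometry-like scale error of all horizontal positions about the trial
origin, ML ~ N(−0.10, 0.30) and AP ~ N(+0.01, 0.02), shared across a
subject's trials — this multiplies step width / ML MoS and step length /
AP MoS by subject-specific factors, giving ML limits of agreement several
times wider than AP, per-condition step-width reliability far below step
length, and per-participant bias clustering with the published signs
(degraded system narrower widths, longer steps). White measurement noise
(5/8/3 mm AP/ML/Z on feet, smaller on the CoM), a slow common-mode drift
(8 mm, 25 s period) and optional per-foot constant biases complete it.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: joint kinematics and soft-tissue artifact,
double-support force transfer, vertical CoM dynamics (events use
horizontal kinematics only), within-stance foot rolling (placements are
points), real IMU drift nonstationarity, and any physiological coupling
between step geometry and sway beyond the phase locking described above.
Magnitudes of the synthetic Lyapunov exponents (~0.9–1.5 per stride) sit
below typical experimental values (~1.8–3.1) because the generator's
stride dynamics are an order-1 stochastic cycle, not a 30-plus-dimensional
body; the tests assert ranges and orderings, not experimental magnitudes.

**Determinism.** A master seed spawns per-subject `SeedSequence` children
(subject draws first, then one generation seed and one degradation seed
per trial in a fixed order), so every trial, CSV and statistic is
bit-reproducible from `StudySpec.seed`; report CSVs are written with a
fixed float format and row order.

## Problem sizes

Module tests run on 10–60-stride trials and 1–4-subject studies; the
statistical acceptance checks use 5 000–50 000 simulated observations
(Bland–Altman recovery, ICC convergence, ANOVA type-I calibration at
5 000 tables) and a 30 000-sample Lorenz trajectory against the Benettin
oracle; the acceptance script runs the full default design (10 × 4 × 2
× 60 strides, two systems, both Lyapunov axes). These sizes were chosen so
each check's Monte-Carlo error is well below its assertion margin.

## Known limitations

* Event detection assumes forward progression; walking in place or
  backward stepping raises "no gait detected".
* The AP MoS uses the ball-of-foot, not the toe tip, as the front BoS
  edge, slightly overestimating the margin.
* Turn exclusion classifies whole strides; a stride straddling a turn
  onset is flagged only once its direction deviates beyond the threshold.
* ICC rows are pooled strides without a subject term, matching the
  reported design; with strong per-subject biases this conflates within-
  and between-subject agreement (visible in the per-subject Bland–Altman
  table).
* λ_s from 55 strides has large trial-to-trial spread; the reported pair
  counts should be inspected before comparing conditions.
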