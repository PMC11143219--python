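# Methods

## Problem and scope

Dynamic ¹⁸F-NaF PET measures the net plasma-to-bone clearance K_i
(mL/min/mL), a proxy for regional bone formation used to grade bone
turnover in chronic kidney disease.  The routine protocol acquires 60–90
minutes of dynamic data; this package implements the analysis needed to
evaluate *shortened* protocols: Patlak estimation of K_i from truncated
time–activity curves (TACs), turnover classification by fixed cutoffs,
and the agreement battery (Spearman, ICC, Bland–Altman, Wilcoxon) between
shortened and routine estimates.  Image reconstruction, motion
correction, partial-volume correction, DICOM handling and VOI placement
are out of scope: the analysis starts from frame-level TACs (or a 4-D
activity array plus binary masks, from which VOI-mean TACs are taken).

## Data representation and numerical conventions

An acquisition is a list of `(start, end)` frames in seconds.  Two
protocols are built in: a contiguous 35-frame 60-min schedule
(12×5 s, 6×10 s, 6×30 s, 11×300 s) and a 42-frame 90-min schedule
(12×5 s, 6×10 s, 8×30 s, a 4-min pause, 16×300 s).

- The continuous tracer curve behind a TAC is represented by its
  frame-midtime samples, anchored at (t = 0, value 0): concentration is
  zero at injection.
- Integrals (the Patlak numerator ∫C_blood) are trapezoidal on that
  anchored polyline.  The 90-min protocol's pause is bridged by linear
  interpolation between the adjacent midtimes.
- A frame belongs to the 0–D-minute truncation window iff its end time is
  ≤ 60·D s (closed boundary, matching the "0–30 min" naming); truncation
  is therefore a prefix operation, idempotent and nested across durations.
- Time units: seconds in schedules, minutes in kinetics, so K_i is in
  mL/min/mL with no conversion inside the regression.
- TACs are assumed decay-corrected to injection time upstream; the flag is
  carried but no decay arithmetic is applied.

## Patlak estimation

Per frame k at midtime t_k: x_k = ∫₀^{t_k} C_blood dt / C_blood(t_k)
("stretched time", minutes) and y_k = C_bone(t_k)/C_blood(t_k).  Frames
with non-positive blood activity (possible under noise before bolus
arrival) are excluded and counted.  K_i and V₀ are the ordinary
least-squares slope and intercept through the points with t_k ≥ t*; at
least 3 points are required.  Uniform weights are the default (a
frame-duration weighting is exposed); the slope standard error follows
standard regression theory.  A fit is flagged *reliable* when the
relative slope error se(K_i)/K_i is ≤ 10 %, the conventional kinetic-fit
acceptance rule; the flag never alters the estimate.

Choice of t*: the free pool equilibrates with plasma on a timescale
1/(k₂+k₃) ≈ 3 min for the simulated regimes, so `fit_patlak` defaults to
a conservative t* = 10 min.  The *study pipeline* instead defaults to
t* = 4 min, because the 0–15-min window of the 60-min protocol contains
only one frame-midtime past 10 min — a 15-min fit is impossible there —
while t* = 4 min leaves 4 usable frames.  The cost is a small
equilibration bias shared by all durations; the benefit is that the
15-min arm of the truncation study exists at all (and its weakness is
then a quantitative finding rather than an error message).

## Synthetic cohort

No patient-level dynamic NaF data are publicly deposited for this study
design, so the cohort is simulated with known truth.

**Input function.**  A Feng-style tri-exponential bolus
C_p(t) = (A₁t − A₂ − A₃)e^(−λ₁t) + A₂e^(−λ₂t) + A₃e^(−λ₃t), clipped at
zero, with defaults A₁ = 800 kBq/mL/min, A₂ = 20, A₃ = 15 kBq/mL,
λ = (4.0, 0.5, 0.008) /min: a single peak of ≈ 70 kBq/mL at ≈ 17 s
followed by fast clearance to a slowly decaying tail — the shape of an
aortic IDIF after a bolus injection.  Per scan, the amplitudes share a
lognormal(σ = 0.15) scale factor.  Whole-blood vs plasma is deliberately
collapsed: the Patlak formulation here uses whole-blood activity.

**Bone model.**  The irreversible two-tissue (Hawkins) model with rate
constants K₁ (delivery), k₂ (efflux), k₃ (binding), k₄ = 0:
C_tissue = C_free + C_bound, C_free = K₁ e^(−(k₂+k₃)t) ⊛ C_p,
C_bound = k₃∫C_free.  The measured VOI value mixes tissue with fractional
blood volume v_b: (1−v_b)C_tissue + v_b·C_p.  The convolution uses an
exact exponential-integrator step (piecewise-linear C_p) on a 0.1-s grid;
frame values are time-averages over each frame window.  The asymptotic
Patlak slope of the measured curve is the **VOI-level clearance
(1−v_b)·K₁k₃/(k₂+k₃)**, and this is the quantity the generator treats as
ground truth: category values are drawn for it and k₃ is back-solved
(k₃ = k₂q/(K₁−q), q = K_i/(1−v_b)) at fixed K₁ = 0.12 mL/min/mL,
k₂ = 0.24 /min, v_b = 0.05.  A single knob (k₃) therefore controls the
compared quantity exactly.

**Turnover mixture.**  42 scans: 33 high, 4 normal, 5 low by default.
Lumbar K_i is drawn from truncated normals calibrated to the turnover
categories (high: 0.076 ± 0.018 on (0.055, 0.11]; normal: 0.045 ± 0.003
on [0.038, 0.055]; low: 0.038 ± 0.007 below 0.038, floored at 0.015).
The 0.11 cap keeps the back-solved k₃ finite below K₁.  Iliac truth is
the lumbar value under a lognormal(σ = 0.15) jitter, rejection-sampled
back into the category interval — rejection rather than clipping, so that
truths stay distinct and rank statistics are well defined.

**Noise.**  Independent Gaussian per frame with
SD = α·sqrt(max(value, ε)/Δt_min): variance inversely proportional to
frame duration, the post-reconstruction counting-statistics law.  The
level α is not observable from the published summary statistics, so it is
calibrated: `calibrate_noise` bisects α until the cohort Spearman
correlation between 30-min and routine 60-min K_i reaches a target
(default 0.85, the level of agreement around which the shortened-scan
question is interesting), averaged over 5 seeds.  The calibrated value
α = 1.41 is the package default.  At that level the agreement ordering
rs(15) < rs(30) < rs(45) (and the same for ICC) holds in essentially all
replicate cohorts.

**Two forward regimes.**  `model="two-tissue"` (default) is the full
compartmental simulation above.  `model="patlak-linear"` constructs bone
frames as (K_i·x_k + V₀)·C_blood(t_k) with x_k the *analysis* stretched
time — data that satisfy the graphical model exactly at frame level.  In
that regime the fitted slope is window-independent to machine precision,
which is the right reference for verifying the truncation/fit/agreement
plumbing in isolation.  Under the full two-tissue model the noiseless
shortened-vs-routine comparison is *not* exact: the equilibration
transient and the frame-level quadrature leave a window-dependent bias of
order 10⁻³ relative (larger at low K_i, where k₂+k₃ is small).  Because
that bias is a smooth monotone function of the single varying parameter,
ranks are preserved and the noiseless Spearman correlation is still
exactly 1; ICC and Bland–Altman bias are 1 and 0 only in the frame-exact
regime.  The test suite asserts both statements where they hold.

## Agreement statistics

- Spearman rho with the t-approximation p (n − 2 df), via scipy.
- ICC: two-way, single-measurement, absolute agreement — ICC(A,1) — from
  the targets×raters ANOVA mean squares, with the McGraw–Wong
  F-distribution 95 % CI (Satterthwaite df); the consistency form
  ICC(C,1) is exposed as an option.  Implemented in-package (the installed
  third-party implementation rounds CI bounds to two decimals, too coarse
  here); it is cross-checked against pingouin and a from-scratch ANOVA
  oracle in the tests.
- Bland–Altman: bias = mean(x − y), limits of agreement bias ± 1.96·sd
  (sample SD; 1.96 verbatim, not a t quantile, per the conventional
  construction), bias CI via t, LoA CIs via the large-sample variance
  sd²(1/n + 1.96²/(2(n−1))).
- Wilcoxon signed-rank, two-sided: zeros dropped; exact null for n ≤ 25,
  normal approximation with continuity correction above; all-zero
  differences give p = 1 by convention.
- All tests two-sided at 0.05; no multiple-testing correction.  The 42
  scans are treated as independent observations even though some subjects
  contribute repeat scans — a deliberate replication of the study design
  this emulates, not a modeling claim.

## Pipeline

`run_truncation_study(StudyConfig)` simulates the cohort, fits every
scan/region at the shortened durations (default 15/30/45 min) and the
routine duration (default 60 min; 90-min studies run on the 90-min
schedule), classifies turnover (low < 0.038 ≤ normal ≤ 0.055 < high;
boundary values are normal; negative noisy estimates are assigned to
low), and tabulates per region × duration the agreement battery plus
classification concordance against the routine scan.  Individual fit
failures are logged and excluded with counts, never silently dropped.
Outputs (fit, classification, counts, agreement, concordance CSVs, a
plain-text summary embedding the package version and resolved
configuration, and the cohort TAC CSVs with a manifest) are byte-identical
across runs with the same seed.

## Problem sizes

Defaults throughout mirror the emulated study design: 42 scans, two
regions, four durations.  The acceptance script uses 200 scans for the
recovery sweep, 10 replicate cohorts for the ordering property, and 50
random fixtures per statistic oracle; everything completes in well under
a minute on one core.

## Known limitations

- TAC-level simulation only: no voxel noise correlation, no motion, no
  partial-volume effects, no scanner-specific reconstruction artifacts.
  Passing tests demonstrate correctness of the estimation and agreement
  machinery under the stated noise law, not scanner realism.
- The noise level is calibrated to an agreement target, not measured from
  scans; absolute values of rs/ICC at other durations are therefore
  qualitative (their ordering is the robust finding).
- k₄ > 0 (tracer release from bone) is not simulated or fitted; K_i from
  Patlak is mildly biased when trapping is not perfectly irreversible.
- The IDIF is treated as whole-blood activity with no plasma correction
  and no arterial/venous distinction.
- Within-patient correlation of repeat scans is ignored by design (see
  above).
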