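# nafpatlak

Patlak analysis of dynamic ¹⁸F-NaF PET bone time–activity curves, with the
statistical machinery to ask: **how short can a dynamic scan be and still
measure bone plasma clearance as well as a routine 60–90-min scan?**

¹⁸F-NaF is irreversibly trapped in newly mineralizing bone, so its net
plasma-to-bone clearance K_i (mL/min/mL) is a non-invasive proxy for bone
formation rate — clinically relevant in renal osteodystrophy, where low,
normal and high bone turnover call for different treatment.  K_i is
estimated by the Patlak graphical method: for an irreversibly trapped
tracer,

    C_bone(T) = K_i · ∫₀ᵀ C_blood(t) dt + V₀ · C_blood(T),

so plotting C_bone(T)/C_blood(T) against the "stretched time"
x(T) = ∫₀ᵀ C_blood/C_blood(T) gives a line with slope K_i and intercept V₀
once the free tracer pool has equilibrated with plasma (t ≥ t*).  The blood
curve is an image-derived input function (IDIF) from an aortic volume of
interest; the bone curves come from lumbar-vertebra and iliac-crest VOIs.

The package provides:

- **Frame schedules and TACs** (`nafpatlak.frames`): the 35-frame 60-min
  and 42-frame 90-min acquisition protocols (including the 4-min pause of
  the latter), truncation to 0–15/30/45/60-min windows, midtime-anchored
  trapezoidal integration, VOI-mean extraction from 4-D arrays or NIfTI,
  and a plain CSV dialect for TACs.
- **A synthetic cohort generator** (`nafpatlak.simulate`): Feng-style
  tri-exponential bolus IDIFs and bone TACs from the irreversible
  two-tissue compartment model (Hawkins model, k₄ = 0), with ground-truth
  K_i drawn from a low/normal/high turnover mixture (counts 5/4/33 of 42
  scans by default) and count-statistics noise.  No public dynamic NaF
  dataset exists at this granularity, so every downstream stage is
  validated against known simulated truth.
- **Patlak estimation** (`nafpatlak.patlak`): the graphical transform,
  least-squares slope/intercept with standard errors, the 10 %
  relative-slope-error reliability flag, and fits at several truncated
  durations.
- **Turnover classification** (`nafpatlak.classify`): fixed cutoffs
  0.038 / 0.055 mL/min/mL separating low / normal / high turnover.
- **Agreement statistics** (`nafpatlak.agreement`): Spearman rank
  correlation, intraclass correlation ICC(A,1) with F-based 95 % CI,
  Bland–Altman bias and limits of agreement with CIs, Wilcoxon signed-rank.
- **The study pipeline and CLI** (`nafpatlak.pipeline`, `nafpatlak`):
  simulate → fit shortened + routine K_i → classify → tabulate agreement
  and classification concordance, deterministically for a given seed.

## Worked example

Fit one noiseless synthetic scan:

```python
from nafpatlak import (KineticParameters, fit_patlak, schedule_60min,
                       simulate_bone_tac, solve_k3)
from nafpatlak.frames import TimeActivityCurve
from nafpatlak.simulate import DEFAULT_IDIF, feng_fine_curve, frame_average

sched = schedule_60min()
fine = feng_fine_curve(DEFAULT_IDIF, sched)
idif = TimeActivityCurve(sched, frame_average(fine, sched), "aorta_IDIF")
kp = KineticParameters(K1=0.12, k2=0.24, k3=solve_k3(0.06), vb=0.05)
btac = simulate_bone_tac(kp, fine, sched, "lumbar")
fit = fit_patlak(btac, idif, t_star_min=10)
print(f"true Ki = {kp.ki_voi:.4f}, fitted Ki = {fit.ki:.4f} +/- {fit.se_ki:.5f}, "
      f"V0 = {fit.v0:.3f}, R^2 = {fit.r_squared:.5f}, reliable = {fit.reliable}")
```

prints

```
true Ki = 0.0600, fitted Ki = 0.0599 +/- 0.00001, V0 = 0.155, R^2 = 1.00000, reliable = True
```

i.e. the Patlak slope recovers the simulated VOI-level clearance of
0.060 mL/min/mL to 0.2 %, with a tight slope standard error (well inside
the 10 % reliability criterion) and an apparent distribution volume V₀ of
0.155 mL/mL.

Run the full shortened-scan study on a noisy 42-scan cohort:

```python
from nafpatlak import StudyConfig, run_truncation_study

result = run_truncation_study(StudyConfig(seed=1))
cols = ["region", "duration_min", "rs", "icc", "ba_bias"]
print(result.agreement[cols].round(3).to_string(index=False))
```

```
region  duration_min     rs    icc  ba_bias
lumbar            15  0.029  0.011    0.012
lumbar            30  0.781  0.668    0.003
lumbar            45  0.881  0.884    0.002
 iliac            15 -0.117 -0.181   -0.004
 iliac            30  0.795  0.758    0.001
 iliac            45  0.923  0.937    0.000
```

Each row compares K_i from a truncated scan against the routine 60-min
scan across the cohort: at the default noise level (calibrated so the
30-min agreement is strong but imperfect), 15 minutes is far too short,
while 30 and 45 minutes track the routine measurement increasingly well —
the pattern that motivates a 30-min clinical protocol.  The same study
object carries per-scan fits, turnover classifications, and
classification-concordance tables.

The same study is available from the shell:

```sh
nafpatlak simulate --n 42 --counts 33,4,5 --seed 1 --out cohort/
nafpatlak study --out results_study/   # default configuration
```

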