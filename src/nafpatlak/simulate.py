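"""Synthetic dynamic 18F-NaF cohort with known ground-truth kinetics.

No public dynamic NaF dataset accompanies the study design this package
implements, so every downstream stage is exercised on simulated scans with
known truth.  A scan consists of

* an arterial input function: a Feng-style tri-exponential bolus
  ``C_p(t) = (A1*t - A2 - A3) e^{-l1 t} + A2 e^{-l2 t} + A3 e^{-l3 t}``
  evaluated on a fine time grid and averaged over acquisition frames, and
* one bone TAC per skeletal region, generated from an irreversible
  two-tissue compartment model (rate constants K1, k2, k3; k4 = 0) whose
  macro-parameter ``K_i = K1*k3/(k2+k3)`` is the net plasma-to-bone
  clearance.  The measured VOI value mixes tissue and blood:
  ``(1-vb)*C_tissue + vb*C_blood``.

The ground truth recorded per scan is the VOI-level clearance
``(1-vb)*K1*k3/(k2+k3)`` -- the asymptotic Patlak slope of the noiseless
measured curve -- drawn from a three-category bone-turnover mixture
(low/normal/high) and hit exactly by back-solving k3 at fixed K1 and k2.

Two forward models are available:

``two-tissue``
    Full compartmental convolution.  The Patlak plot is linear only after
    the free pool equilibrates with plasma, so estimates carry a small,
    window-dependent equilibration bias -- as real data do.
``patlak-linear``
    Frame-level graphical model: bone frames are constructed to satisfy
    ``C_bone = (Ki * stretched_time + V0) * C_blood`` exactly at the
    analysis quadrature.  Estimation is then exact for every fit window,
    which isolates the truncation/fit/agreement plumbing from kinetics.

Noise emulates reconstruction counting statistics: independent Gaussian
per frame with SD ``alpha * sqrt(value / frame_duration_min)``, i.e.
variance inversely proportional to frame duration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import lfilter
from scipy.stats import truncnorm

from .frames import (
    FrameSchedule,
    TimeActivityCurve,
    cumulative_midtime_integral,
    write_tacs,
)

__all__ = [
    "InputFunctionParams",
    "KineticParameters",
    "CategoryModel",
    "CohortScan",
    "DEFAULT_IDIF",
    "TURNOVER_MODELS",
    "feng_input",
    "feng_fine_curve",
    "frame_average",
    "simulate_bone_tac",
    "patlak_linear_tac",
    "solve_k3",
    "add_noise",
    "generate_cohort",
    "write_cohort",
]

IDIF_REGION = "aorta_IDIF"
BONE_REGIONS = ("lumbar", "iliac")


@dataclass(frozen=True)
class InputFunctionParams:
    """Feng tri-exponential bolus parameters (time in minutes)."""

    A1: float = 800.0  # kBq/mL/min
    A2: float = 20.0  # kBq/mL
    A3: float = 15.0  # kBq/mL
    lambda1: float = 4.0  # 1/min
    lambda2: float = 0.5  # 1/min
    lambda3: float = 0.008  # 1/min

    def __post_init__(self) -> None:
        if not (self.lambda1 > self.lambda2 > self.lambda3 > 0):
            raise ValueError("require lambda1 > lambda2 > lambda3 > 0")
        if self.A1 < 0 or self.A2 < 0 or self.A3 < 0:
            raise ValueError("amplitudes must be non-negative")
        if self.A1 == 0 and (self.A2 > 0 or self.A3 > 0):
            # A1 = 0 is only meaningful for the all-zero curve
            raise ValueError("A1 must be positive unless all amplitudes are zero")

    def scaled(self, factor: float) -> "InputFunctionParams":
        return InputFunctionParams(
            self.A1 * factor, self.A2 * factor, self.A3 * factor,
            self.lambda1, self.lambda2, self.lambda3,
        )


DEFAULT_IDIF = InputFunctionParams()


@dataclass(frozen=True)
class KineticParameters:
    """Two-tissue irreversible-trapping rate constants.

    K1 [mL/min/mL] is plasma-to-free-pool delivery, k2 and k3 [1/min] are
    efflux and binding, k4 is release from the bound pool (0 for the
    irreversible regime), vb is the fractional blood volume of the VOI.
    """

    K1: float
    k2: float
    k3: float
    k4: float = 0.0
    vb: float = 0.05

    def __post_init__(self) -> None:
        for name in ("K1", "k2", "k3", "k4"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0 <= self.vb < 1:
            raise ValueError("vb must lie in [0, 1)")

    @property
    def ki_macro(self) -> float:
        """Tissue-level net clearance K1*k3/(k2+k3) (0 when nothing enters)."""
        if self.K1 == 0:
            return 0.0
        if self.k2 + self.k3 == 0:
            raise ValueError("degenerate compartment: k2 + k3 = 0 with K1 > 0")
        return self.K1 * self.k3 / (self.k2 + self.k3)

    @property
    def ki_voi(self) -> float:
        """VOI-level clearance (1-vb)*Ki: asymptotic Patlak slope of the VOI curve."""
        return (1.0 - self.vb) * self.ki_macro


def solve_k3(ki_voi: float, K1: float = 0.12, k2: float = 0.24, vb: float = 0.05) -> float:
    """k3 that makes the VOI-level clearance equal ``ki_voi`` at fixed K1, k2, vb."""
    if ki_voi < 0:
        raise ValueError("ki_voi must be non-negative")
    q = ki_voi / (1.0 - vb)
    if q >= K1:
        raise ValueError(
            f"infeasible K_i: {ki_voi} requires tissue clearance {q:.4f} >= K1={K1}"
        )
    return k2 * q / (K1 - q)


def feng_input(params: InputFunctionParams, times_min: np.ndarray) -> np.ndarray:
    """Evaluate the bolus model; negative lobes of the early term are clipped to 0."""
    t = np.asarray(times_min, dtype=float)
    if np.any(t < 0):
        raise ValueError("times must be non-negative")
    c = (
        (params.A1 * t - params.A2 - params.A3) * np.exp(-params.lambda1 * t)
        + params.A2 * np.exp(-params.lambda2 * t)
        + params.A3 * np.exp(-params.lambda3 * t)
    )
    return np.clip(c, 0.0, None)


@dataclass(frozen=True)
class FineCurve:
    """Uniform fine-grid curve from t=0, for forward simulation."""

    t_min: np.ndarray
    values: np.ndarray

    @property
    def dt_min(self) -> float:
        return float(self.t_min[1] - self.t_min[0])


def feng_fine_curve(
    params: InputFunctionParams, schedule: FrameSchedule, dt_s: float = 0.1
) -> FineCurve:
    """Sample the bolus model on a uniform grid covering the schedule span."""
    n = int(round(schedule.span_s / dt_s))
    t_min = np.arange(n + 1) * (dt_s / 60.0)
    return FineCurve(t_min, feng_input(params, t_min))


def frame_average(fine: FineCurve, schedule: FrameSchedule) -> np.ndarray:
    """Time-average of a fine-grid curve over each frame window."""
    dt_s = fine.dt_min * 60.0
    out = np.empty(schedule.n_frames)
    for k, (s, e) in enumerate(schedule.frames):
        i0, i1 = int(round(s / dt_s)), int(round(e / dt_s))
        out[k] = fine.values[i0 : i1 + 1].mean()
    return out


def _free_pool(kp: KineticParameters, fine: FineCurve) -> np.ndarray:
    """Free compartment K1 * e^{-(k2+k3)t} (x) C_p via an exact exponential step.

    The plasma curve is taken piecewise-linear between grid points, for
    which the convolution update is an IIR filter with analytic weights.
    """
    lam = kp.k2 + kp.k3
    h = fine.dt_min
    if lam > 0:
        d = math.exp(-lam * h)
        c1 = (1.0 - d) / lam
        c0 = (d - 1.0 + lam * h) / (lam * lam * h)
        b = np.array([kp.K1 * c0, kp.K1 * (c1 - c0)])
        a = np.array([1.0, -d])
    else:
        b = np.array([kp.K1 * h / 2.0, kp.K1 * h / 2.0])
        a = np.array([1.0, -1.0])
    return lfilter(b, a, fine.values)


def simulate_bone_tac(
    kp: KineticParameters,
    idif_fine: FineCurve,
    schedule: FrameSchedule,
    region: str = "bone",
) -> TimeActivityCurve:
    """Noiseless bone VOI TAC from the irreversible two-tissue model.

    The tissue curve is ``C = C_free + C_bound`` with
    ``C_free = K1 e^{-(k2+k3)t} (x) C_p`` and ``C_bound = k3 * int C_free``;
    the measured VOI value is ``(1-vb) C + vb C_p``, time-averaged over
    each frame window.
    """
    if kp.k4 != 0:
        raise ValueError("only irreversible trapping (k4 = 0) is simulated")
    if kp.K1 > 0 and kp.k2 + kp.k3 == 0:
        raise ValueError("degenerate compartment: k2 + k3 = 0 with K1 > 0")
    free = _free_pool(kp, idif_fine)
    h = idif_fine.dt_min
    bound = np.concatenate([[0.0], np.cumsum(kp.k3 * 0.5 * (free[1:] + free[:-1]) * h)])
    measured = (1.0 - kp.vb) * (free + bound) + kp.vb * idif_fine.values
    values = frame_average(FineCurve(idif_fine.t_min, measured), schedule)
    return TimeActivityCurve(schedule, values, region)


def patlak_linear_tac(
    kp: KineticParameters,
    idif_tac: TimeActivityCurve,
    region: str = "bone",
) -> TimeActivityCurve:
    """Bone TAC satisfying the Patlak graphical model exactly at frame level.

    Frame values are ``(Ki * x_k + V0) * C_blood(t_k)`` with ``x_k`` the
    midtime-trapezoid stretched time of the supplied blood TAC and
    ``V0 = (1-vb) K1/(k2+k3) + vb`` (the equilibrium intercept).  Every fit
    window then recovers the VOI-level Ki exactly, which makes this the
    reference regime for verifying truncation invariance of the pipeline.
    """
    lam = kp.k2 + kp.k3
    if lam == 0:
        raise ValueError("degenerate compartment: k2 + k3 = 0")
    x_min = cumulative_midtime_integral(idif_tac) / 60.0 / idif_tac.values
    v0 = (1.0 - kp.vb) * kp.K1 / lam + kp.vb
    values = (kp.ki_voi * x_min + v0) * idif_tac.values
    return TimeActivityCurve(idif_tac.schedule, values, region)


NOISE_FLOOR_KBQ = 1e-3


def add_noise(
    tac: TimeActivityCurve, alpha: float, seed: int | np.random.Generator
) -> TimeActivityCurve:
    """Gaussian count-statistics noise, SD = alpha*sqrt(max(v, eps)/frame_min).

    Deterministic for a given seed; alpha = 0 returns the TAC unchanged.
    """
    if alpha < 0:
        raise ValueError("alpha must be non-negative")
    if alpha == 0:
        return tac
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    width_min = (tac.schedule.end_s - tac.schedule.start_s) / 60.0
    sd = alpha * np.sqrt(np.maximum(tac.values, NOISE_FLOOR_KBQ) / width_min)
    noisy = tac.values + rng.normal(0.0, 1.0, tac.n_frames) * sd
    return TimeActivityCurve(
        tac.schedule, noisy, tac.region, tac.decay_corrected, noise_contaminated=True
    )


@dataclass(frozen=True)
class CategoryModel:
    """Truncated-normal K_i distribution for one turnover category (mL/min/mL)."""

    mean: float
    sd: float
    lo: float
    hi: float

    def sample(self, rng: np.random.Generator) -> float:
        a = (self.lo - self.mean) / self.sd
        b = (self.hi - self.mean) / self.sd
        return float(truncnorm.rvs(a, b, loc=self.mean, scale=self.sd, random_state=rng))


# Category calibration: means/SDs follow the lumbar-spine turnover summary
# of the hemodialysis cohort this design emulates; the support of each
# category is its cutoff interval (0.038 / 0.055 mL/min/mL), capped at
# 0.11 so the back-solved k3 stays finite below K1 = 0.12.
TURNOVER_MODELS: dict[str, CategoryModel] = {
    "high": CategoryModel(mean=0.076, sd=0.018, lo=0.0551, hi=0.110),
    "normal": CategoryModel(mean=0.045, sd=0.003, lo=0.038, hi=0.055),
    "low": CategoryModel(mean=0.038, sd=0.007, lo=0.015, hi=0.0379),
}

DEFAULT_CATEGORY_COUNTS = (33, 4, 5)  # (high, normal, low) scans out of 42
ILIAC_JITTER_SIGMA = 0.15  # lognormal sigma linking iliac to lumbar truth


@dataclass
class CohortScan:
    """One synthetic scan: shared IDIF plus per-region bone TACs and truth."""

    scan_id: str
    true_category: str
    params: dict[str, KineticParameters]
    true_ki: dict[str, float]
    idif: TimeActivityCurve
    btacs: dict[str, TimeActivityCurve] = field(default_factory=dict)


def _jitter_into_category(
    ki: float, model: CategoryModel, rng: np.random.Generator, max_tries: int = 200
) -> float:
    """Lognormal jitter of ``ki`` rejected into the category interval.

    Rejection (rather than clipping) keeps the per-region truths distinct:
    clipping would pile several scans onto the interval boundary, creating
    exact ties.  If the jitter repeatedly escapes the interval the value is
    redrawn from the category model itself.
    """
    for _ in range(max_tries):
        cand = ki * float(np.exp(rng.normal(0.0, ILIAC_JITTER_SIGMA)))
        if model.lo <= cand <= model.hi:
            return cand
    return model.sample(rng)


def generate_cohort(
    n_scans: int = 42,
    category_counts: tuple[int, int, int] = DEFAULT_CATEGORY_COUNTS,
    schedule: FrameSchedule | None = None,
    alpha: float = 0.0,
    seed: int = 0,
    model: str = "two-tissue",
    K1: float = 0.12,
    k2: float = 0.24,
    vb: float = 0.05,
    idif_params: InputFunctionParams = DEFAULT_IDIF,
    dt_s: float = 0.1,
) -> list[CohortScan]:
    """Simulate a turnover-mixture cohort with known per-region K_i.

    ``category_counts`` is (high, normal, low) and must sum to ``n_scans``.
    Lumbar K_i is drawn from the category's truncated normal; iliac K_i is
    the lumbar value under a lognormal(0, 0.15) jitter, rejection-sampled
    into the category interval so true categories agree across regions.  Noise
    (``alpha``) is applied to the IDIF and every bone TAC.  Fully
    deterministic for a given ``seed``.
    """
    if sum(category_counts) != n_scans:
        raise ValueError(
            f"category_counts {category_counts} must sum to n_scans={n_scans}"
        )
    if model not in ("two-tissue", "patlak-linear"):
        raise ValueError(f"unknown forward model {model!r}")
    if schedule is None:
        from .frames import schedule_60min

        schedule = schedule_60min()
    rng = np.random.default_rng(seed)
    categories = [
        cat
        for cat, cnt in zip(("high", "normal", "low"), category_counts)
        for _ in range(cnt)
    ]
    scans: list[CohortScan] = []
    for i, cat in enumerate(categories):
        cat_model = TURNOVER_MODELS[cat]
        ki_lumbar = cat_model.sample(rng)
        ki_iliac = _jitter_into_category(ki_lumbar, cat_model, rng)
        scan_idif_params = idif_params.scaled(float(np.exp(rng.normal(0.0, 0.15))))
        fine = feng_fine_curve(scan_idif_params, schedule, dt_s)
        idif = TimeActivityCurve(
            schedule, frame_average(fine, schedule), IDIF_REGION
        )
        params: dict[str, KineticParameters] = {}
        true_ki = {"lumbar": ki_lumbar, "iliac": ki_iliac}
        btacs: dict[str, TimeActivityCurve] = {}
        for region in BONE_REGIONS:
            kp = KineticParameters(K1, k2, solve_k3(true_ki[region], K1, k2, vb), 0.0, vb)
            params[region] = kp
            if model == "two-tissue":
                btac = simulate_bone_tac(kp, fine, schedule, region)
            else:
                btac = patlak_linear_tac(kp, idif, region)
            btacs[region] = add_noise(btac, alpha, rng)
        scans.append(
            CohortScan(
                scan_id=f"scan{i + 1:03d}",
                true_category=cat,
                params=params,
                true_ki=true_ki,
                idif=add_noise(idif, alpha, rng),
                btacs=btacs,
            )
        )
    return scans


def write_cohort(cohort: list[CohortScan], outdir, seed: int | None = None) -> pd.DataFrame:
    """Write one TAC CSV per scan plus ``cohort_manifest.csv``; return the manifest."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for scan in cohort:
        write_tacs(outdir / f"{scan.scan_id}_tacs.csv", [scan.idif, *scan.btacs.values()])
        for region in scan.btacs:
            rows.append(
                {
                    "scan_id": scan.scan_id,
                    "region": region,
                    "true_Ki": scan.true_ki[region],
                    "true_category": scan.true_category,
                    "seed": seed if seed is not None else "",
                }
            )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(outdir / "cohort_manifest.csv", index=False)
    return manifest
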