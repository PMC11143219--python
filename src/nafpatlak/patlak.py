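"""Patlak graphical estimation of the bone plasma clearance K_i.

For an irreversibly trapped tracer the tissue curve obeys

    C_bone(T) = K_i * int_0^T C_blood(t) dt + V0 * C_blood(T)

once the free pool has equilibrated with plasma.  Dividing by C_blood(T)
gives a line in "stretched time" x(T) = int_0^T C_blood / C_blood(T):
slope K_i (mL/min/mL, the net plasma-to-bone clearance) and intercept V0
(mL/mL, apparent distribution volume of unbound tracer).  The fit is an
ordinary least-squares line through the points at frame midtimes >= t*,
the start of the linear regime; a fit is flagged unreliable when the
relative standard error of the slope exceeds 10%.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .frames import (
    TimeActivityCurve,
    cumulative_midtime_integral,
    truncate_tac,
)

__all__ = [
    "PatlakFit",
    "PatlakError",
    "patlak_points",
    "fit_patlak",
    "ki_at_durations",
    "RELIABILITY_MAX_RELATIVE_SE",
]

logger = logging.getLogger(__name__)

RELIABILITY_MAX_RELATIVE_SE = 0.10


class PatlakError(ValueError):
    """Raised when a Patlak transform or fit cannot be computed."""


@dataclass(frozen=True)
class PatlakFit:
    """Result of one Patlak regression."""

    ki: float  # slope, mL/min/mL
    v0: float  # intercept, mL/mL
    se_ki: float  # standard error of the slope
    r_squared: float
    n_points: int
    t_star_min: float
    reliable: bool
    n_excluded: int = 0  # frames dropped for non-positive blood activity


def patlak_points(
    btac: TimeActivityCurve, idif: TimeActivityCurve
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Patlak coordinates per frame: (x [min], y [unitless], midtimes [min]).

    x_k = int_0^{t_k} C_blood dt / C_blood(t_k)  (midtime-trapezoid integral),
    y_k = C_bone(t_k) / C_blood(t_k).

    Frames with non-positive blood activity (possible in noisy data) are
    excluded and logged.
    """
    if btac.schedule != idif.schedule:
        raise PatlakError("bone and blood TACs must share the same frame schedule")
    blood = idif.values
    valid = blood > 0
    n_excl = int(np.sum(~valid))
    if n_excl:
        logger.warning(
            "excluding %d frame(s) with non-positive blood activity in region %s",
            n_excl,
            btac.region,
        )
    if np.sum(valid) < 3:
        raise PatlakError("fewer than 3 frames with positive blood activity")
    cum_min = cumulative_midtime_integral(idif) / 60.0  # kBq*min/mL
    x = cum_min[valid] / blood[valid]
    y = btac.values[valid] / blood[valid]
    t_min = idif.schedule.mid_s[valid] / 60.0
    return x, y, t_min


def fit_patlak(
    btac: TimeActivityCurve,
    idif: TimeActivityCurve,
    t_star_min: float = 10.0,
    weights: str = "uniform",
) -> PatlakFit:
    """Least-squares Patlak line through the frames at or after t*.

    ``weights='uniform'`` is the default; ``'frame-duration'`` weights each
    point by its frame length (longer frames average more counts).  The
    slope standard error follows standard linear-regression theory; with
    non-uniform weights it is the weighted-least-squares analogue.
    """
    if not 0 <= t_star_min <= 60:
        raise PatlakError("t_star_min must lie in [0, 60] minutes")
    x, y, t_min = patlak_points(btac, idif)
    n_excluded = idif.n_frames - x.size
    late = t_min >= t_star_min - 1e-9
    n = int(np.sum(late))
    if n < 3:
        raise PatlakError(
            f"insufficient late frames: {n} point(s) at or after t*={t_star_min} min"
        )
    x, y = x[late], y[late]
    if np.ptp(x) <= 0:
        raise PatlakError("degenerate design: all stretched-time values identical")
    if weights == "uniform":
        res = stats.linregress(x, y)
        ki, v0, se = float(res.slope), float(res.intercept), float(res.stderr)
        r2 = float(res.rvalue**2)
    elif weights == "frame-duration":
        w = (btac.schedule.end_s - btac.schedule.start_s)[idif.values > 0][late] / 60.0
        ki, v0, se, r2 = _wls_line(x, y, w)
    else:
        raise PatlakError(f"unknown weighting scheme {weights!r}")
    reliable = bool(ki > 0 and se / ki <= RELIABILITY_MAX_RELATIVE_SE)
    return PatlakFit(ki, v0, se, r2, n, t_star_min, reliable, n_excluded)


def _wls_line(
    x: np.ndarray, y: np.ndarray, w: np.ndarray
) -> tuple[float, float, float, float]:
    sw = w.sum()
    xb, yb = np.sum(w * x) / sw, np.sum(w * y) / sw
    sxx = np.sum(w * (x - xb) ** 2)
    slope = np.sum(w * (x - xb) * (y - yb)) / sxx
    intercept = yb - slope * xb
    resid = y - intercept - slope * x
    dof = x.size - 2
    sigma2 = np.sum(w * resid**2) / dof if dof > 0 else np.nan
    se = float(np.sqrt(sigma2 / sxx))
    syy = np.sum(w * (y - yb) ** 2)
    r2 = float(1.0 - np.sum(w * resid**2) / syy) if syy > 0 else np.nan
    return float(slope), float(intercept), se, r2


def ki_at_durations(
    btac: TimeActivityCurve,
    idif: TimeActivityCurve,
    durations_min: tuple[float, ...] = (15, 30, 45, 60),
    t_star_min: float = 10.0,
    weights: str = "uniform",
) -> dict[float, PatlakFit]:
    """Fit K_i after truncating both curves to each 0--duration window.

    Durations exceeding the scan length are skipped with a warning; fit
    errors for a usable duration propagate to the caller.
    """
    scan_end_min = btac.schedule.span_s / 60.0
    out: dict[float, PatlakFit] = {}
    for dur in durations_min:
        if dur > scan_end_min + 1e-9:
            logger.warning(
                "skipping duration %s min: exceeds %s-min scan", dur, scan_end_min
            )
            continue
        out[dur] = fit_patlak(
            truncate_tac(btac, dur), truncate_tac(idif, dur), t_star_min, weights
        )
    return out


def fits_to_frame(rows: list[dict]) -> pd.DataFrame:
    """Assemble per-scan fit records into the fit-results table."""
    cols = [
        "scan_id", "region", "duration_min", "t_star_min",
        "Ki", "V0", "se_Ki", "r_squared", "n_points", "reliable",
    ]
    return pd.DataFrame(rows, columns=cols)
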