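"""Acquisition frame schedules and time-activity curves.

Dynamic PET list-mode data are re-binned into a sequence of timeframes
(e.g. ``12 x 5 s, 6 x 10 s, ...``).  A :class:`FrameSchedule` records the
``(start, end)`` window of every frame in seconds; gaps between frames
(scanner pauses) are allowed but frames never overlap.  A
:class:`TimeActivityCurve` (TAC) attaches one mean activity concentration
per frame, in kBq/mL, for a named region -- either a vascular region
providing the image-derived input function (IDIF) or a bone volume of
interest (VOI).

The continuous tracer concentration underlying a TAC is represented by its
frame-midtime samples, anchored at ``(t=0, value=0)`` (no tracer before
injection); integrals are trapezoidal on that polyline, which also bridges
pauses by linear interpolation.  All TACs are assumed to be decay-corrected
to injection time upstream; the ``decay_corrected`` flag is carried as
metadata only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "FrameSchedule",
    "TimeActivityCurve",
    "schedule_90min",
    "schedule_60min",
    "frame_midtimes",
    "truncate_tac",
    "integrate_tac",
    "voi_mean_tac",
    "load_nifti_tac",
    "write_tacs",
    "read_tacs",
]

TAC_CSV_COLUMNS = ["frame_start_s", "frame_end_s", "region", "activity_kBq_per_mL"]


@dataclass(frozen=True)
class FrameSchedule:
    """Ordered, non-overlapping acquisition frames in seconds."""

    frames: np.ndarray  # shape (n, 2): [start_s, end_s]
    label: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.frames, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] == 0:
            raise ValueError("frames must be a non-empty (n, 2) array of [start_s, end_s]")
        if np.any(arr[:, 1] <= arr[:, 0]):
            raise ValueError("every frame must satisfy end_s > start_s")
        if np.any(arr[1:, 0] < arr[:-1, 1]):
            raise ValueError("frames must be non-overlapping and strictly increasing")
        if arr[0, 0] < 0:
            raise ValueError("frames must not start before t=0")
        arr.setflags(write=False)
        object.__setattr__(self, "frames", arr)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def start_s(self) -> np.ndarray:
        return self.frames[:, 0]

    @property
    def end_s(self) -> np.ndarray:
        return self.frames[:, 1]

    @property
    def mid_s(self) -> np.ndarray:
        """Frame midtimes (start+end)/2 in seconds."""
        return self.frames.mean(axis=1)

    @property
    def total_covered_s(self) -> float:
        """Total acquisition time, excluding pauses."""
        return float(np.sum(self.frames[:, 1] - self.frames[:, 0]))

    @property
    def span_s(self) -> float:
        """End of the last frame (includes pauses)."""
        return float(self.frames[-1, 1])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FrameSchedule):
            return NotImplemented
        return self.label == other.label and np.array_equal(self.frames, other.frames)


@dataclass
class TimeActivityCurve:
    """Per-frame mean activity concentration (kBq/mL) for one region."""

    schedule: FrameSchedule
    values: np.ndarray
    region: str
    decay_corrected: bool = True
    noise_contaminated: bool = field(default=False)

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 1 or vals.size != self.schedule.n_frames:
            raise ValueError(
                f"values length {vals.size} does not match "
                f"{self.schedule.n_frames} frames in schedule"
            )
        if not np.all(np.isfinite(vals)):
            raise ValueError("TAC values must be finite")
        if not self.noise_contaminated and np.any(vals < 0):
            raise ValueError(
                "negative activity requires noise_contaminated=True (simulator output)"
            )
        self.values = vals

    @property
    def n_frames(self) -> int:
        return self.schedule.n_frames


def _expand_scheme(scheme: list[tuple[float, int]], t0: float = 0.0) -> list[tuple[float, float]]:
    frames = []
    t = t0
    for width, count in scheme:
        for _ in range(count):
            frames.append((t, t + width))
            t += width
    return frames


def schedule_90min() -> FrameSchedule:
    """42-frame 90-min protocol: 12x5 s, 6x10 s, 8x30 s, 4-min pause, 16x300 s.

    The pause separates the initial single-bed bolus acquisition from the
    multi-pass whole-body passes; frames resume at 600 s and end at 5400 s.
    """
    early = _expand_scheme([(5, 12), (10, 6), (30, 8)])
    late = _expand_scheme([(300, 16)], t0=600.0)
    return FrameSchedule(np.array(early + late), label="90min")


def schedule_60min() -> FrameSchedule:
    """35-frame contiguous 60-min protocol: 12x5 s, 6x10 s, 6x30 s, 11x300 s."""
    frames = _expand_scheme([(5, 12), (10, 6), (30, 6), (300, 11)])
    return FrameSchedule(np.array(frames), label="60min")


def frame_midtimes(schedule: FrameSchedule) -> np.ndarray:
    """Midtime (start+end)/2 of each frame, seconds."""
    return schedule.mid_s


def truncate_tac(tac: TimeActivityCurve, duration_min: float) -> TimeActivityCurve:
    """Restrict a TAC to the frames ending within ``duration_min`` minutes.

    A frame belongs to the 0--``duration_min`` window iff its end time is
    <= ``duration_min * 60`` s (closed boundary, matching the "0-30 min"
    window naming).
    """
    if duration_min <= 0:
        raise ValueError("duration_min must be positive")
    limit_s = duration_min * 60.0
    keep = tac.schedule.end_s <= limit_s + 1e-9
    if not np.any(keep):
        raise ValueError(
            f"empty truncation: no frame ends within {duration_min} min"
        )
    n = int(np.sum(keep))  # frames are ordered, so `keep` is a prefix
    schedule = FrameSchedule(tac.schedule.frames[:n], label=tac.schedule.label)
    return replace(tac, schedule=schedule, values=tac.values[:n])


def _midtime_polyline(tac: TimeActivityCurve) -> tuple[np.ndarray, np.ndarray]:
    """Sample points (t_s, value) of the TAC polyline, anchored at (0, 0)."""
    t = np.concatenate([[0.0], tac.schedule.mid_s])
    v = np.concatenate([[0.0], tac.values])
    return t, v


def integrate_tac(tac: TimeActivityCurve, upto_s: float) -> float:
    """Trapezoidal integral of the TAC polyline from 0 to ``upto_s`` (kBq*s/mL).

    The curve is sampled at frame midtimes, anchored with value 0 at
    injection time, and linearly interpolated between samples (including
    across acquisition pauses).  Integration beyond the last midtime would
    extrapolate and is refused.
    """
    t, v = _midtime_polyline(tac)
    if upto_s < t[1]:
        raise ValueError("upto_s must be at or after the first frame midtime")
    if upto_s > t[-1] + 1e-9:
        raise ValueError(
            f"extrapolation refused: upto_s={upto_s} s beyond last midtime {t[-1]} s"
        )
    upto_s = min(upto_s, t[-1])
    k = int(np.searchsorted(t, upto_s, side="right")) - 1
    full = np.trapezoid(v[: k + 1], t[: k + 1])
    if upto_s > t[k]:
        v_at = v[k] + (v[k + 1] - v[k]) * (upto_s - t[k]) / (t[k + 1] - t[k])
        full += 0.5 * (v[k] + v_at) * (upto_s - t[k])
    return float(full)


def cumulative_midtime_integral(tac: TimeActivityCurve) -> np.ndarray:
    """Integral of the TAC polyline from 0 to each frame midtime (kBq*s/mL)."""
    t, v = _midtime_polyline(tac)
    return np.cumsum(0.5 * (v[1:] + v[:-1]) * np.diff(t))


def voi_mean_tac(
    image4d: np.ndarray,
    mask: np.ndarray,
    schedule: FrameSchedule,
    region: str,
) -> TimeActivityCurve:
    """Mean activity inside a VOI mask, per frame.

    The same 3-D mask is applied to every frame of the 4-D image (frame
    axis first), mirroring a VOI duplicated across all PET timeframes.
    """
    image4d = np.asarray(image4d, dtype=float)
    mask = np.asarray(mask).astype(bool)
    if image4d.ndim != 4:
        raise ValueError("image4d must be 4-D (frame, z, y, x)")
    if mask.shape != image4d.shape[1:]:
        raise ValueError("mask shape must match the spatial shape of image4d")
    if image4d.shape[0] != schedule.n_frames:
        raise ValueError("frame count of image4d must match the schedule")
    if not mask.any():
        raise ValueError("empty VOI: mask selects no voxels")
    values = image4d[:, mask].mean(axis=1)
    return TimeActivityCurve(schedule, values, region)


def load_nifti_tac(
    image_path: str, mask_path: str, schedule: FrameSchedule, region: str
) -> TimeActivityCurve:
    """Extract a VOI-mean TAC from a 4-D NIfTI volume and a 3-D NIfTI mask.

    NIfTI stores the time axis last; it is moved in front of the spatial
    axes before extraction.
    """
    import nibabel as nib

    img = np.asanyarray(nib.load(image_path).dataobj)
    msk = np.asanyarray(nib.load(mask_path).dataobj)
    if img.ndim != 4:
        raise ValueError(f"{image_path}: expected a 4-D image, got {img.ndim}-D")
    return voi_mean_tac(np.moveaxis(img, -1, 0), msk > 0, schedule, region)


def write_tacs(path, tacs: list[TimeActivityCurve]) -> None:
    """Write TACs to CSV (columns frame_start_s,frame_end_s,region,activity_kBq_per_mL)."""
    rows = []
    for tac in tacs:
        for (s, e), v in zip(tac.schedule.frames, tac.values):
            rows.append((s, e, tac.region, v))
    df = pd.DataFrame(rows, columns=TAC_CSV_COLUMNS)
    df.to_csv(path, index=False)


def read_tacs(path, schedule_label: str = "") -> dict[str, TimeActivityCurve]:
    """Read a TAC CSV back into one TAC per region.

    Negative activities are accepted (noisy simulator output) and flagged.
    """
    # round_trip parsing: the default fast parser can be 1 ULP off, which
    # breaks bit-identical write/read/write cycles
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(TAC_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing TAC CSV columns {sorted(missing)}")
    out: dict[str, TimeActivityCurve] = {}
    for region, grp in df.groupby("region", sort=False):
        schedule = FrameSchedule(
            grp[["frame_start_s", "frame_end_s"]].to_numpy(float), label=schedule_label
        )
        values = grp["activity_kBq_per_mL"].to_numpy(float)
        out[str(region)] = TimeActivityCurve(
            schedule, values, str(region), noise_contaminated=bool(np.any(values < 0))
        )
    return out
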