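"""Eye-trace processing: differentiation, saccade detection and removal,
trial-averaged velocity, behavioral readouts, and pupil-based drift correction.

The detection rule follows the thresholds used for the recordings: a sample is
saccadic when the acceleration magnitude exceeds 1000 deg/s^2 anywhere, when
speed crosses 15 deg/s during fixation, or when speed crosses 50 deg/s while
the target moves.  Detected saccades are excised and treated as missing data
before trial averaging.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .data_model import (
    AnalysisParams,
    EyeTrace,
    SaccadeEvent,
    Session,
    TaskConfig,
    Trial,
    select_trials,
)

__all__ = [
    "VelocityTrace",
    "SaccadeEvent",
    "gaussian_kernel",
    "smooth",
    "differentiate",
    "detect_saccades",
    "saccade_mask",
    "trial_speed_traces",
    "average_velocity",
    "session_mean_speed",
    "pupil_drift_correction",
    "drift_segments",
    "nearest_task_direction",
]


@dataclass
class VelocityTrace:
    """Velocity/acceleration on the eye-trace grid with a missing-data mask."""

    time: np.ndarray  # ms, session clock
    vh: np.ndarray  # deg/s
    vv: np.ndarray
    speed: np.ndarray  # Euclidean norm of (vh, vv)
    accel: np.ndarray  # norm of component accelerations, deg/s^2
    valid: np.ndarray  # bool; False where excised or undefined


def gaussian_kernel(sd_ms: float, truncate_sds: float = 6.0) -> np.ndarray:
    """Unit-mass Gaussian kernel on the 1 ms grid, truncated and renormalized."""
    half = int(math.ceil(truncate_sds * sd_ms))
    x = np.arange(-half, half + 1, dtype=float)
    k = np.exp(-0.5 * (x / sd_ms) ** 2)
    return k / k.sum()


def smooth(x: np.ndarray, sd_ms: float, truncate_sds: float = 6.0) -> np.ndarray:
    """Gaussian smoothing with reflective edges (trace must exceed the kernel)."""
    k = gaussian_kernel(sd_ms, truncate_sds)
    if x.size < k.size:
        raise ValueError(
            f"trace of {x.size} samples is shorter than the {k.size}-sample kernel"
        )
    xp = np.pad(x, k.size // 2, mode="reflect")
    return np.convolve(xp, k, mode="valid")


def differentiate(eye: EyeTrace, params: AnalysisParams = AnalysisParams()) -> VelocityTrace:
    """Velocity and acceleration from position.

    Position is smoothed with a 5 ms SD Gaussian, then differentiated with
    central differences (one-sided at the edges); acceleration is the same
    operation applied to the component velocities.  Units deg/s and deg/s^2.
    """
    h = smooth(eye.h_position, params.velocity_smooth_sd, params.kernel_truncation_sds)
    v = smooth(eye.v_position, params.velocity_smooth_sd, params.kernel_truncation_sds)
    vh = np.gradient(h) * 1000.0  # per-sample step is 1 ms
    vv = np.gradient(v) * 1000.0
    ah = np.gradient(vh) * 1000.0
    av = np.gradient(vv) * 1000.0
    speed = np.hypot(vh, vv)
    accel = np.hypot(ah, av)
    return VelocityTrace(
        time=eye.time.copy(),
        vh=vh,
        vv=vv,
        speed=speed,
        accel=accel,
        valid=eye.valid_mask.copy(),
    )


def _pursuit_epoch_mask(
    time: np.ndarray,
    trials: Sequence[Trial],
    task: TaskConfig,
    pad: int,
) -> np.ndarray:
    """True while the target moves (plus a short pad for pursuit offset decay)."""
    mask = np.zeros(time.size, dtype=bool)
    t0 = int(time[0])
    for tr in trials:
        a = max(tr.motion_onset - t0, 0)
        b = min(tr.motion_onset + task.motion_duration + pad - t0, time.size)
        if b > a:
            mask[a:b] = True
    return mask


def detect_saccades(
    eye: EyeTrace,
    trials: Sequence[Trial],
    task: TaskConfig,
    params: AnalysisParams = AnalysisParams(),
    vel: Optional[VelocityTrace] = None,
) -> list[SaccadeEvent]:
    """Threshold-based saccade detection.

    Contiguous saccadic samples are merged into events and events separated by
    less than ``params.saccade_merge_gap`` ms are fused.  Each event reports
    its peak speed and the epoch (fixation or pursuit) of its onset sample.
    """
    vel = vel or differentiate(eye, params)
    pursuit = _pursuit_epoch_mask(eye.time, trials, task, params.pursuit_epoch_pad)
    sacc = (
        (vel.accel > params.saccade_accel_threshold)
        | (~pursuit & (vel.speed > params.saccade_fixation_speed))
        | (pursuit & (vel.speed > params.saccade_pursuit_speed))
    )
    # ignore the one-sided derivative samples at the very edges
    sacc[:2] = False
    sacc[-2:] = False
    if not sacc.any():
        return []
    d = np.diff(sacc.astype(np.int8))
    starts = np.nonzero(d == 1)[0] + 1
    ends = np.nonzero(d == -1)[0] + 1  # exclusive
    if sacc[0]:
        starts = np.r_[0, starts]
    if sacc[-1]:
        ends = np.r_[ends, sacc.size]
    # fuse events separated by less than the merge gap
    fused = [[int(starts[0]), int(ends[0])]]
    for s, e in zip(starts[1:], ends[1:]):
        if s - fused[-1][1] < params.saccade_merge_gap:
            fused[-1][1] = int(e)
        else:
            fused.append([int(s), int(e)])
    t0 = int(eye.time[0])
    events = []
    for s, e in fused:
        events.append(
            SaccadeEvent(
                onset_ms=t0 + s,
                offset_ms=t0 + e - 1,
                peak_velocity=float(vel.speed[s:e].max()),
                epoch="pursuit" if pursuit[s] else "fixation",
            )
        )
    return events


def saccade_mask(
    time: np.ndarray, events: Sequence[SaccadeEvent], pad: int = 5
) -> np.ndarray:
    """True at samples to excise: each event padded by ``pad`` ms on each side."""
    mask = np.zeros(time.size, dtype=bool)
    t0 = int(time[0])
    for ev in events:
        a = max(ev.onset_ms - pad - t0, 0)
        b = min(ev.offset_ms + pad + 1 - t0, time.size)
        if b > a:
            mask[a:b] = True
    return mask


def trial_speed_traces(
    vel: VelocityTrace,
    trials: Sequence[Trial],
    align: str,
    window: tuple[int, int],
    events: Sequence[SaccadeEvent] = (),
    params: AnalysisParams = AnalysisParams(),
    task: Optional[TaskConfig] = None,
) -> np.ndarray:
    """Per-trial de-saccaded speed, aligned and cut to ``window`` (NaN = missing)."""
    excise = saccade_mask(vel.time, events, params.saccade_pad)
    t0 = int(vel.time[0])
    w0, w1 = window
    out = np.full((len(trials), w1 - w0), np.nan)
    for i, tr in enumerate(trials):
        a = _align_time(tr, align, task)
        lo = a + w0 - t0
        hi = a + w1 - t0
        if lo < 0 or hi > vel.speed.size:
            continue
        seg = vel.speed[lo:hi].copy()
        bad = excise[lo:hi] | ~vel.valid[lo:hi]
        seg[bad] = np.nan
        out[i] = seg
    return out


def _align_time(trial: Trial, align: str, task: Optional[TaskConfig] = None) -> int:
    if align == "cue":
        return trial.cue_onset
    if align == "motion":
        return trial.motion_onset
    if align == "reward":
        if trial.reward_time is None:
            raise ValueError(f"trial {trial.trial_id} has no reward time")
        return trial.reward_time
    raise ValueError(f"unknown alignment event {align!r}")


def average_velocity(
    traces: np.ndarray,
    params: AnalysisParams = AnalysisParams(),
) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise mean of per-trial traces, ignoring missing samples.

    Returns (mean trace smoothed with a 5 ms SD Gaussian, per-timepoint count
    of contributing trials).  Timepoints with no valid trial stay NaN.
    """
    traces = np.atleast_2d(np.asarray(traces, dtype=float))
    if traces.shape[0] < 1:
        raise ValueError("need at least one trial trace")
    n = np.sum(np.isfinite(traces), axis=0)
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(traces, axis=0)
    # normalized convolution so gaps do not bleed zeros into the average
    k = gaussian_kernel(params.velocity_smooth_sd, params.kernel_truncation_sds)
    filled = np.where(np.isfinite(mean), mean, 0.0)
    w = np.isfinite(mean).astype(float)
    num = np.convolve(filled, k, mode="same")
    den = np.convolve(w, k, mode="same")
    with np.errstate(invalid="ignore", divide="ignore"):
        sm = num / den
    sm[n == 0] = np.nan
    return sm, n


def session_mean_speed(
    session: Session,
    reward: str,
    t_offset: Optional[int] = None,
    params: AnalysisParams = AnalysisParams(),
    events: Optional[Sequence[SaccadeEvent]] = None,
    vel: Optional[VelocityTrace] = None,
) -> float:
    """De-saccaded mean eye speed ``t_offset`` ms after target motion onset.

    The behavioral readout: pursuit initiation speed per reward condition,
    read from the condition's trial-averaged speed trace.
    """
    t_offset = params.behavior_readout_time if t_offset is None else t_offset
    trials = select_trials(session, reward=reward)
    if not trials:
        raise ValueError(f"no successful {reward!r} trials in session")
    vel = vel or differentiate(session.eye, params)
    if events is None:
        events = detect_saccades(session.eye, session.trials, session.task, params, vel)
    window = (-100, t_offset + 150)
    traces = trial_speed_traces(
        vel, trials, "motion", window, events, params, session.task
    )
    mean, _ = average_velocity(traces, params)
    return float(mean[t_offset - window[0]])


def pupil_drift_correction(
    eye: EyeTrace,
    trials: Optional[Sequence[Trial]] = None,
    align: str = "cue",
    window: tuple[int, int] = (-400, 800),
) -> tuple[EyeTrace, dict]:
    """Remove the pupil-predicted component of eye position.

    An ordinary-least-squares model ``position ~ pupil`` is fitted per axis.
    When ``trials`` is given the fit uses the session-average traces aligned to
    the cue (position and pupil averaged across trials on a common grid);
    otherwise it uses the raw trace.  The prediction is subtracted from every
    sample, so ``corrected + predicted`` reconstructs the original exactly.

    Returns the corrected trace and a dict with per-axis slope, intercept and
    R^2 of the fit.
    """
    pupil = eye.pupil
    if np.ptp(pupil[eye.valid_mask]) == 0:
        raise ValueError("pupil size is constant; the drift fit is undefined")
    if trials:
        t0 = int(eye.time[0])
        w0, w1 = window
        cols = []
        for tr in trials:
            a = tr.cue_onset if align == "cue" else _align_time(tr, align)
            lo, hi = a + w0 - t0, a + w1 - t0
            if lo < 0 or hi > len(eye):
                continue
            cols.append((eye.h_position[lo:hi], eye.v_position[lo:hi], pupil[lo:hi]))
        if not cols:
            raise ValueError("no trial fits inside the eye trace")
        h_fit = np.mean([c[0] for c in cols], axis=0)
        v_fit = np.mean([c[1] for c in cols], axis=0)
        p_fit = np.mean([c[2] for c in cols], axis=0)
    else:
        ok = eye.valid_mask
        h_fit, v_fit, p_fit = eye.h_position[ok], eye.v_position[ok], pupil[ok]
    stats = {}
    corrected = {}
    for axis, y_fit, y_full in (
        ("h", h_fit, eye.h_position),
        ("v", v_fit, eye.v_position),
    ):
        X = np.column_stack([np.ones_like(p_fit), p_fit])
        beta, *_ = np.linalg.lstsq(X, y_fit, rcond=None)
        resid = y_fit - X @ beta
        sst = float(np.sum((y_fit - y_fit.mean()) ** 2))
        r2 = 1.0 - float(np.sum(resid**2)) / sst if sst > 0 else 0.0
        stats[axis] = {"intercept": float(beta[0]), "slope": float(beta[1]), "r2": r2}
        corrected[axis] = y_full - (beta[0] + beta[1] * pupil)
    out = EyeTrace(
        time=eye.time.copy(),
        h_position=corrected["h"],
        v_position=corrected["v"],
        pupil=pupil.copy(),
        valid_mask=eye.valid_mask.copy(),
    )
    return out, stats


def nearest_task_direction(angle_deg: float, directions: Sequence[float]) -> float:
    """Task direction with minimal circular distance; ties go to the smaller angle."""
    best = None
    best_d = None
    for d in sorted(float(x) for x in directions):
        dist = abs((angle_deg - d + 180.0) % 360.0 - 180.0)
        if best_d is None or dist < best_d - 1e-12:
            best, best_d = d, dist
    return float(best)


def drift_segments(
    eye: EyeTrace,
    trials: Sequence[Trial],
    task: TaskConfig,
    events: Sequence[SaccadeEvent] = (),
    epoch: str = "post_cue",
    params: AnalysisParams = AnalysisParams(),
) -> list[dict]:
    """Per-trial net fixational drift during the post-cue epoch.

    Saccade samples (padded) are excluded: the displacement sums position
    increments over sample pairs that are both valid.  Each trial's drift is
    also labeled with the nearest of the task's directions.
    """
    excise = saccade_mask(eye.time, events, params.saccade_pad)
    t0 = int(eye.time[0])
    out = []
    for tr in trials:
        if epoch == "post_cue":
            lo, hi = tr.cue_onset - t0, tr.motion_onset - t0
        else:
            raise ValueError(f"unknown epoch {epoch!r}")
        lo, hi = max(lo, 0), min(hi, len(eye))
        if hi - lo < 2:
            continue
        ok = eye.valid_mask[lo:hi] & ~excise[lo:hi]
        pair = ok[1:] & ok[:-1]
        dx = float(np.sum(np.diff(eye.h_position[lo:hi])[pair]))
        dy = float(np.sum(np.diff(eye.v_position[lo:hi])[pair]))
        dur_s = max(int(pair.sum()), 1) / 1000.0
        disp = math.hypot(dx, dy)
        angle = math.degrees(math.atan2(dy, dx)) % 360.0
        out.append(
            {
                "trial_id": tr.trial_id,
                "dx_deg": dx,
                "dy_deg": dy,
                "displacement_deg": disp,
                "mean_speed_dps": disp / dur_s,
                "angle_deg": angle,
                "nearest_direction": nearest_task_direction(angle, task.directions),
            }
        )
    return out
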