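"""Synthetic session generator.

Emulates the reward-cued pursuit task end to end: trial schedules with the
task's timing, step-ramp target kinematics, eye traces with pupil-coupled
fixational drift, microsaccades and catch-up saccades, lick trains, and
Purkinje-cell spike trains sampled from an additive inhomogeneous-Poisson
rate model (baseline + cue transient + circular direction tuning +
lick-locked bumps), with a post-complex-spike pause imposed on the simple
spikes.

Everything is driven by a single master seed; each stage and each cell gets
its own counter-derived child stream, so adding a cell never perturbs the
draws of the others.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence, Union

import numpy as np

from .data_model import (
    CSPK,
    REWARD_CONDITIONS,
    REWARD_LARGE,
    REWARD_SMALL,
    SSPK,
    CellRecording,
    EyeTrace,
    SaccadeEvent,
    Session,
    SpikeTrain,
    TaskConfig,
    Trial,
    ValidationError,
    validate_session,
)

logger = logging.getLogger(__name__)

__all__ = [
    "CellParams",
    "KinematicsParams",
    "SimConfig",
    "simulate_session",
    "draw_trial_schedule",
    "target_trajectory",
    "eye_trajectory",
    "build_rate_profile",
    "sample_inhomogeneous_poisson",
    "impose_post_cspk_pause",
    "make_paper_like_cells",
    "paper_like_config",
    "null_config",
    "child_rng",
]


def child_rng(master_seed: int, *key: int) -> np.random.Generator:
    """Deterministic child stream: master seed plus a counter-based spawn key."""
    ss = np.random.SeedSequence(entropy=int(master_seed), spawn_key=tuple(int(k) for k in key))
    return np.random.default_rng(ss)


# ---------------------------------------------------------------------------
# parameters

@dataclass(frozen=True)
class CellParams:
    """Phenomenological rate model of one Purkinje cell.

    Rates are additive components in spikes/s on a 1 ms grid:

    * complex spikes: low baseline (~1/s) with an optional condition-dependent
      cue transient inside ``cspk_cue_window`` and von-Mises direction tuning
      ``gain * exp(kappa * (cos(dir - pd) - 1))`` during target motion;
    * simple spikes: high baseline (~50/s) with a signed condition-dependent
      cue transient and its own direction tuning;
    * optional lick-locked bumps on the complex-spike rate;
    * a hard post-Cspk pause removing simple spikes after each complex spike.

    ``direction_reward_gain`` multiplies the motion-epoch direction term per
    reward condition (1.0 in both conditions means reward-invariant tuning,
    the configuration the recorded population exhibited).
    """

    cspk_baseline: float = 1.0
    cspk_cue_amplitude: Mapping[str, float] = field(
        default_factory=lambda: {REWARD_LARGE: 2.0, REWARD_SMALL: 0.0}
    )
    cspk_cue_window: tuple[int, int] = (100, 300)
    cspk_direction_gain: float = 2.0
    cspk_pd: float = 0.0
    cspk_kappa: float = 2.0
    sspk_baseline: float = 50.0
    sspk_cue_amplitude: Mapping[str, float] = field(
        default_factory=lambda: {REWARD_LARGE: 0.0, REWARD_SMALL: 0.0}
    )
    sspk_cue_window: tuple[int, int] = (100, 300)
    sspk_direction_gain: float = 20.0
    sspk_pd: float = 0.0
    sspk_kappa: float = 2.0
    direction_reward_gain: Mapping[str, float] = field(
        default_factory=lambda: {REWARD_LARGE: 1.0, REWARD_SMALL: 1.0}
    )
    lick_locked_amplitude: float = 0.0
    lick_locked_window: tuple[int, int] = (0, 150)
    post_cspk_pause: int = 15


@dataclass(frozen=True)
class KinematicsParams:
    """Eye- and lick-behavior parameters.

    Pursuit velocity rises exponentially (time constant ``pursuit_tau``) after
    ``pursuit_latency`` toward ``gain * target speed`` and decays after the
    target stops.  Fixational position is pupil-coupled drift
    (``intercept + slope * pupil``) plus white measurement noise; the vertical
    axis gets strong pupil coupling and the horizontal axis weak coupling.
    Saccades are injected as Gaussian velocity pulses; their ground-truth
    onsets/offsets (center ± 3.5 sigma, covering >99.9% of the displacement)
    are returned alongside the trace.  Licks are a renewal process whose rate
    dips after the cue and surges after reward delivery.
    """

    pursuit_gain: Mapping[str, float] = field(
        default_factory=lambda: {REWARD_LARGE: 0.95, REWARD_SMALL: 0.85}
    )
    pursuit_latency: int = 100
    pursuit_tau: float = 45.0
    catchup_saccade_rate: float = 0.4  # events/s during target motion
    fixation_microsaccade_rate: float = 0.2  # events/s outside pursuit
    drift_pupil_slope: tuple[float, float] = (0.1, 1.0)  # deg per pupil unit (h, v)
    drift_pupil_intercept: tuple[float, float] = (0.0, 0.0)
    position_noise_sd: float = 0.01  # deg, per-sample white noise
    pupil_mean: float = 1.0
    pupil_sd: float = 0.2
    pupil_ar1: float = 0.9995  # per-ms AR(1) coefficient (slow process)
    microsaccade_peak_range: tuple[float, float] = (60.0, 180.0)
    microsaccade_sigma: float = 5.0  # ms
    catchup_peak_range: tuple[float, float] = (80.0, 200.0)
    catchup_sigma: float = 6.0
    return_saccade_sigma: float = 8.0
    lick_base_rate: float = 1.5  # licks/s
    lick_cue_dip: float = 0.3  # multiplicative rate factor after cue
    lick_cue_dip_duration: int = 600
    lick_reward_surge: float = 4.0
    lick_reward_surge_duration: int = 800
    lick_duration: int = 150


@dataclass(frozen=True)
class SimConfig:
    """Full study configuration: task, behavior, cells and the master seed."""

    task: TaskConfig = field(default_factory=TaskConfig)
    kin: KinematicsParams = field(default_factory=KinematicsParams)
    cells: tuple[CellParams, ...] = ()
    n_trials: int = 10  # per condition x direction x speed
    master_seed: int = 0
    failure_rate: float = 0.05
    iti_range: tuple[int, int] = (400, 800)
    monkey_id: str = "S"


# ---------------------------------------------------------------------------
# schedule and target kinematics

def draw_trial_schedule(task: TaskConfig, rng: np.random.Generator) -> dict:
    """Event times of one trial relative to fixation onset.

    Fixation lasts ``task.fixation_duration``; the cue-to-motion delay is
    uniform on ``cue_delay_range`` (inclusive); the target moves for
    ``motion_duration`` and stands still for a uniform draw from
    ``post_motion_range`` before the trial ends (= reward time on success).
    """
    cue = int(task.fixation_duration)
    delay = int(rng.integers(task.cue_delay_range[0], task.cue_delay_range[1] + 1))
    motion = cue + delay
    motion_end = motion + int(task.motion_duration)
    post = int(rng.integers(task.post_motion_range[0], task.post_motion_range[1] + 1))
    end = motion_end + post
    return {"cue": cue, "motion": motion, "motion_end": motion_end, "end": end}


def target_trajectory(trial: Trial, task: TaskConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Step-ramp target position from fixation onset to trial end.

    At motion onset the target jumps by the step size opposite the motion
    direction, then ramps at the trial's speed along it, re-crossing the
    screen center ``step/speed`` seconds later.  Returns (t_ms on the session
    clock, horizontal deg, vertical deg).
    """
    step = float(task.step_sizes[float(trial.speed)])
    t0 = trial.start(task)
    t1 = trial.end(task)
    t = np.arange(t0, t1, dtype=np.int64)
    h = np.zeros(t.size)
    v = np.zeros(t.size)
    th = math.radians(trial.direction)
    ux, uy = math.cos(th), math.sin(th)
    m = trial.motion_onset - t0
    me = min(m + task.motion_duration, t.size)
    rel = (t[m:me] - trial.motion_onset) / 1000.0  # s since motion onset
    radial = -step + trial.speed * rel
    h[m:me] = radial * ux
    v[m:me] = radial * uy
    if me < t.size:
        h[me:] = h[me - 1]
        v[me:] = v[me - 1]
    return t, h, v


# ---------------------------------------------------------------------------
# eye trace

def _inject_saccade(h, v, t0, center, sigma, angle_rad, v_peak):
    """Add a Gaussian velocity pulse; returns the (dx, dy) displacement added."""
    lo = max(0, int(center - t0 - 5 * sigma))
    hi = min(h.size, int(center - t0 + 5 * sigma) + 1)
    if hi <= lo:
        return 0.0, 0.0
    t = np.arange(lo, hi)
    prof = v_peak * np.exp(-0.5 * ((t - (center - t0)) / sigma) ** 2) / 1000.0  # deg/ms
    disp = np.cumsum(prof)
    dx, dy = disp[-1] * math.cos(angle_rad), disp[-1] * math.sin(angle_rad)
    h[lo:hi] += disp * math.cos(angle_rad)
    v[lo:hi] += disp * math.sin(angle_rad)
    h[hi:] += dx
    v[hi:] += dy
    return dx, dy


def _pupil_trace(n: int, kin: KinematicsParams, rng: np.random.Generator) -> np.ndarray:
    """Slow AR(1) pupil process with the configured stationary mean and sd."""
    from scipy.signal import lfilter

    phi = kin.pupil_ar1
    eps_sd = kin.pupil_sd * math.sqrt(max(1.0 - phi * phi, 1e-12))
    eps = rng.normal(0.0, eps_sd, size=n)
    x0 = rng.normal(0.0, kin.pupil_sd)  # stationary start
    x = lfilter([1.0], [1.0, -phi], eps) + x0 * phi ** np.arange(n)
    return kin.pupil_mean + x


def _simulate_eye(
    task: TaskConfig,
    trials: Sequence[Trial],
    kin: KinematicsParams,
    rng: np.random.Generator,
    t0: int,
    t1: int,
) -> tuple[EyeTrace, list[SaccadeEvent]]:
    n = int(t1 - t0)
    time = np.arange(t0, t1, dtype=np.int64)
    pupil = _pupil_trace(n, kin, rng)
    h = (
        kin.drift_pupil_intercept[0]
        + kin.drift_pupil_slope[0] * pupil
        + rng.normal(0.0, kin.position_noise_sd, size=n)
    )
    v = (
        kin.drift_pupil_intercept[1]
        + kin.drift_pupil_slope[1] * pupil
        + rng.normal(0.0, kin.position_noise_sd, size=n)
    )
    truth: list[SaccadeEvent] = []
    pursuit_spans = []  # for labeling / microsaccade exclusion

    for tr in trials:
        m = int(tr.motion_onset)
        me = m + int(task.motion_duration)
        end = tr.end(task)
        gain = kin.pursuit_gain[tr.reward]
        lat, tau = int(kin.pursuit_latency), float(kin.pursuit_tau)
        th = math.radians(tr.direction)
        span = np.arange(m, end) - t0
        rel = np.arange(span.size, dtype=float)
        vel = np.zeros(span.size)
        rise = rel >= lat
        vel[rise] = gain * tr.speed * (1.0 - np.exp(-(rel[rise] - lat) / tau))
        stop = me - m
        if stop < span.size:
            v_stop = gain * tr.speed * (1.0 - math.exp(-(stop - lat) / tau))
            vel[stop:] = v_stop * np.exp(-(rel[stop:] - stop) / tau)
        disp = np.cumsum(vel) / 1000.0
        lo, hi = span[0], span[-1] + 1
        h[lo:hi] += disp * math.cos(th)
        v[lo:hi] += disp * math.sin(th)
        h[hi:] += disp[-1] * math.cos(th)
        v[hi:] += disp[-1] * math.sin(th)
        pursuit_total = (disp[-1] * math.cos(th), disp[-1] * math.sin(th))
        pursuit_spans.append((m, me + 200))

        # catch-up saccades along the target direction during motion
        dur_s = max(me - (m + lat + 80), 0) / 1000.0
        n_cu = rng.poisson(kin.catchup_saccade_rate * dur_s)
        cu_disp = [0.0, 0.0]
        for _ in range(n_cu):
            c = int(rng.integers(m + lat + 80, me - 40))
            vp = rng.uniform(*kin.catchup_peak_range)
            dx, dy = _inject_saccade(h, v, t0, c, kin.catchup_sigma, th, vp)
            cu_disp[0] += dx
            cu_disp[1] += dy
            s = kin.catchup_sigma
            truth.append(
                SaccadeEvent(int(c - 3.5 * s), int(c + 3.5 * s), vp, "pursuit")
            )
        # return saccade back to the fixation point after the target stops
        ret = me + 150
        if ret + 60 < end:
            amp_x = -(pursuit_total[0] + cu_disp[0])
            amp_y = -(pursuit_total[1] + cu_disp[1])
            amp = math.hypot(amp_x, amp_y)
            if amp > 0.2:
                s = kin.return_saccade_sigma
                vp = amp * 1000.0 / (s * math.sqrt(2.0 * math.pi))
                ang = math.atan2(amp_y, amp_x)
                _inject_saccade(h, v, t0, ret, s, ang, vp)
                truth.append(SaccadeEvent(int(ret - 3.5 * s), int(ret + 3.5 * s), vp, "pursuit"))

    # fixational microsaccades anywhere outside (padded) pursuit epochs
    n_ms = rng.poisson(kin.fixation_microsaccade_rate * n / 1000.0)
    centers = np.sort(rng.integers(t0 + 50, t1 - 50, size=n_ms))
    for c in centers:
        c = int(c)
        if any(m - 100 <= c <= pe + 100 for m, pe in pursuit_spans):
            continue
        if truth and c - truth[-1].offset_ms < 80:
            continue  # keep injected events separable
        vp = rng.uniform(*kin.microsaccade_peak_range)
        ang = rng.uniform(0.0, 2.0 * math.pi)
        s = kin.microsaccade_sigma
        _inject_saccade(h, v, t0, c, s, ang, vp)
        truth.append(SaccadeEvent(int(c - 3.5 * s), int(c + 3.5 * s), vp, "fixation"))

    truth.sort(key=lambda e: e.onset_ms)
    eye = EyeTrace(time, h, v, pupil, np.ones(n, dtype=bool))
    return eye, truth


def eye_trajectory(
    trial: Trial,
    kin: KinematicsParams,
    rng: np.random.Generator,
    task: Optional[TaskConfig] = None,
) -> tuple[EyeTrace, list[SaccadeEvent]]:
    """Eye trace for a single trial (plus 200 ms margin on each side)."""
    task = task or TaskConfig()
    t0 = trial.start(task) - 200
    t1 = trial.end(task) + 200
    return _simulate_eye(task, [trial], kin, rng, t0, t1)


# ---------------------------------------------------------------------------
# licks

def _simulate_licks(
    trials: Sequence[Trial],
    kin: KinematicsParams,
    rng: np.random.Generator,
    t0: int,
    t1: int,
) -> np.ndarray:
    n = int(t1 - t0)
    rate = np.full(n, kin.lick_base_rate)
    for tr in trials:
        c = tr.cue_onset - t0
        rate[c : c + kin.lick_cue_dip_duration] *= kin.lick_cue_dip
        if tr.reward_time is not None:
            r = tr.reward_time - t0
            rate[r : r + kin.lick_reward_surge_duration] *= kin.lick_reward_surge
    cand = sample_inhomogeneous_poisson(rate, (t0, t1), rng).timestamps
    onsets = []
    last_off = -(10**9)
    gap = kin.lick_duration + 50  # refractory renewal: no overlapping licks
    for c in cand:
        if c >= last_off + 50:
            onsets.append(int(c))
            last_off = int(c) + kin.lick_duration
    if not onsets:
        return np.empty((0, 2), dtype=np.int64)
    on = np.asarray(onsets, dtype=np.int64)
    return np.stack([on, on + kin.lick_duration], axis=1)


# ---------------------------------------------------------------------------
# spike rates and sampling

def _von_mises_term(direction: float, pd: float, kappa: float) -> float:
    return math.exp(kappa * (math.cos(math.radians(direction - pd)) - 1.0))


def _add_trial_components(
    rate: np.ndarray,
    t0: int,
    cell: CellParams,
    trial: Trial,
    task: TaskConfig,
    spike_class: str,
) -> None:
    if spike_class == CSPK:
        amp = cell.cspk_cue_amplitude.get(trial.reward, 0.0)
        w = cell.cspk_cue_window
        gain, pd, kappa = cell.cspk_direction_gain, cell.cspk_pd, cell.cspk_kappa
    else:
        amp = cell.sspk_cue_amplitude.get(trial.reward, 0.0)
        w = cell.sspk_cue_window
        gain, pd, kappa = cell.sspk_direction_gain, cell.sspk_pd, cell.sspk_kappa
    c = trial.cue_onset - t0
    rate[max(c + w[0], 0) : max(c + w[1], 0)] += amp
    m = trial.motion_onset - t0
    me = m + task.motion_duration
    rg = cell.direction_reward_gain.get(trial.reward, 1.0)
    rate[max(m, 0) : max(me, 0)] += rg * gain * _von_mises_term(trial.direction, pd, kappa)


def _add_lick_components(rate, t0, cell: CellParams, licks: np.ndarray) -> None:
    if cell.lick_locked_amplitude == 0.0 or licks.size == 0:
        return
    w0, w1 = cell.lick_locked_window
    for onset in licks[:, 0]:
        a = int(onset) - t0 + w0
        b = int(onset) - t0 + w1
        if b <= 0 or a >= rate.size:
            continue
        rate[max(a, 0) : min(b, rate.size)] += cell.lick_locked_amplitude


def build_rate_profile(
    cell: CellParams,
    trial: Trial,
    task: TaskConfig,
    licks: Optional[np.ndarray] = None,
    spike_class: str = CSPK,
) -> np.ndarray:
    """Rate (spikes/s, 1 ms grid) over one trial: baseline + cue transient +
    direction tuning during motion + lick-locked bumps, clipped at zero."""
    t0 = trial.start(task)
    n = trial.end(task) - t0
    base = cell.cspk_baseline if spike_class == CSPK else cell.sspk_baseline
    rate = np.full(n, float(base))
    _add_trial_components(rate, t0, cell, trial, task, spike_class)
    if licks is not None:
        _add_lick_components(rate, t0, cell, np.asarray(licks).reshape(-1, 2))
    return _clip_rate(rate, "trial profile")


def _clip_rate(rate: np.ndarray, label: str) -> np.ndarray:
    neg = rate < 0
    if neg.any():
        frac = float(neg.mean())
        if frac > 0.2:
            raise ValueError(
                f"infeasible rate for {label}: {frac:.0%} of samples negative"
            )
        logger.info("clipped %d negative rate samples (%s)", int(neg.sum()), label)
        rate = np.where(neg, 0.0, rate)
    return rate


def sample_inhomogeneous_poisson(
    rate: Union[np.ndarray, Callable[[np.ndarray], np.ndarray]],
    span: tuple[int, int],
    rng: np.random.Generator,
    spike_class: str = CSPK,
) -> SpikeTrain:
    """Sample spikes by thinning against the rate supremum.

    ``rate`` is spikes/s, either an array on the 1 ms grid of ``span`` or a
    callable evaluated on it.  Timestamps are rounded to integer ms; a rounding
    collision keeps the earlier spike (refractory-like) and drops the later.
    """
    t0, t1 = int(span[0]), int(span[1])
    grid = np.arange(t0, t1, dtype=np.int64)
    r = rate(grid) if callable(rate) else np.asarray(rate, dtype=float)
    if r.size != grid.size:
        raise ValueError("rate array does not match span")
    if not np.all(np.isfinite(r)):
        raise ValueError("rate must be bounded (finite) for thinning")
    rmax = float(r.max(initial=0.0))
    if rmax <= 0.0:
        return SpikeTrain(np.empty(0, dtype=np.int64), spike_class)
    dur_s = (t1 - t0) / 1000.0
    n = rng.poisson(rmax * dur_s)
    times = rng.uniform(t0, t1, size=n)
    idx = np.minimum((times - t0).astype(np.int64), r.size - 1)
    keep = rng.uniform(0.0, rmax, size=n) < r[idx]
    ts = np.unique(np.floor(times[keep]).astype(np.int64))
    dropped = int(keep.sum()) - int(ts.size)
    if dropped:
        logger.debug("dropped %d ms-rounding spike collisions", dropped)
    return SpikeTrain(ts, spike_class)


def impose_post_cspk_pause(
    sspk: SpikeTrain, cspk: SpikeTrain, pause: int
) -> SpikeTrain:
    """Remove simple spikes within [0, pause] ms after each complex spike."""
    if pause <= 0 or len(cspk) == 0 or len(sspk) == 0:
        return sspk
    s = sspk.timestamps
    c = cspk.timestamps
    # latest Cspk at or before each Sspk
    idx = np.searchsorted(c, s, side="right") - 1
    has = idx >= 0
    gap = np.where(has, s - c[np.clip(idx, 0, None)], np.iinfo(np.int64).max)
    return SpikeTrain(s[gap > pause], sspk.spike_class)


# ---------------------------------------------------------------------------
# full session

def simulate_session(cfg: SimConfig) -> Session:
    """Generate a full session; identical configs give identical sessions."""
    task = cfg.task
    rng_sched = child_rng(cfg.master_seed, 0)
    labels = [
        (cond, d, s)
        for cond in REWARD_CONDITIONS
        for d in task.directions
        for s in task.target_speeds
        for _ in range(cfg.n_trials)
    ]
    order = rng_sched.permutation(len(labels))
    t = 100
    trials: list[Trial] = []
    for k, j in enumerate(order):
        cond, d, s = labels[j]
        sched = draw_trial_schedule(task, rng_sched)
        success = bool(rng_sched.random() >= cfg.failure_rate)
        end = t + sched["end"]
        trials.append(
            Trial(
                trial_id=k,
                reward=cond,
                direction=float(d),
                speed=float(s),
                cue_onset=t + sched["cue"],
                motion_onset=t + sched["motion"],
                reward_time=end if success else None,
                success=success,
                trial_end=end,
            )
        )
        t = end + int(rng_sched.integers(cfg.iti_range[0], cfg.iti_range[1] + 1))
    t1 = t + 400

    eye, truth = _simulate_eye(task, trials, cfg.kin, child_rng(cfg.master_seed, 1), 0, t1)
    licks = _simulate_licks(trials, cfg.kin, child_rng(cfg.master_seed, 2), 0, t1)

    cells: list[CellRecording] = []
    for i, cp in enumerate(cfg.cells):
        rng_c = child_rng(cfg.master_seed, 3, i)
        trains = {}
        for cls in (CSPK, SSPK):
            base = cp.cspk_baseline if cls == CSPK else cp.sspk_baseline
            rate = np.full(t1, float(base))
            for tr in trials:
                _add_trial_components(rate, 0, cp, tr, task, cls)
            if cls == CSPK:
                _add_lick_components(rate, 0, cp, licks)
            try:
                rate = _clip_rate(rate, f"cell c{i:02d} {cls}")
            except ValueError as exc:
                raise ValueError(f"cell c{i:02d}: {exc}") from exc
            trains[cls] = sample_inhomogeneous_poisson(rate, (0, t1), rng_c, cls)
        sspk = impose_post_cspk_pause(trains[SSPK], trains[CSPK], cp.post_cspk_pause)
        cells.append(
            CellRecording(
                cell_id=f"c{i:02d}",
                monkey_id=cfg.monkey_id,
                cspk=trains[CSPK],
                sspk=sspk,
                trial_ids=tuple(tr.trial_id for tr in trials),
                recording_bounds=(0, t1),
            )
        )

    session = Session(task, trials, cells, eye, licks, saccades=truth)
    violations = validate_session(session)
    if violations:
        raise ValidationError(violations)
    return session


# ---------------------------------------------------------------------------
# study populations

def make_paper_like_cells(
    n_cells: int,
    rng: np.random.Generator,
    cue_frac: float = 0.2,
    tuned_frac: float = 0.4,
    cue_delta: float = 2.0,
    weak_cue_delta: float = 0.3,
) -> tuple[CellParams, ...]:
    """Heterogeneous population mirroring the recorded sample's structure.

    A fraction of cells carry a strong large-reward-only Cspk cue transient;
    the rest carry a weak one (most cells sat slightly below the identity line
    when comparing large- against small-reward cue rates, with only a subset
    individually significant).  A fraction are directionally tuned with the
    Cspk preferred direction anti-phase to the Sspk preferred direction (the
    movement-epoch signal anticorrelation); Sspk cue responses are
    heterogeneous in sign so the population-average Sspk reward difference
    washes out.  Reward never modulates the direction tuning itself.
    """
    cells = []
    for _ in range(n_cells):
        cue_resp = rng.random() < cue_frac
        tuned = rng.random() < tuned_frac
        sspk_pd = float(rng.uniform(0.0, 360.0))
        # Sspk cue responses: a per-cell change common to both reward
        # conditions (many cells changed rate after the cue without
        # differentiating reward) plus a signed reward difference in a subset,
        # so the population-average difference washes out
        common = float(rng.normal(2.0, 5.0))
        u = rng.random()
        if u < 0.3:
            sdiff = float(rng.uniform(2.0, 6.0))
        elif u < 0.5:
            sdiff = -float(rng.uniform(2.0, 6.0))
        else:
            sdiff = 0.0
        cells.append(
            CellParams(
                cspk_baseline=float(rng.uniform(0.7, 1.3)),
                cspk_cue_amplitude={
                    REWARD_LARGE: cue_delta
                    if cue_resp
                    else float(rng.uniform(0.0, weak_cue_delta)),
                    REWARD_SMALL: 0.0,
                },
                cspk_direction_gain=float(rng.uniform(1.5, 3.0)) if tuned else 0.0,
                cspk_pd=(sspk_pd + 180.0) % 360.0,
                cspk_kappa=2.0,
                sspk_baseline=float(rng.uniform(40.0, 70.0)),
                sspk_cue_amplitude={
                    REWARD_LARGE: common + sdiff / 2.0,
                    REWARD_SMALL: common - sdiff / 2.0,
                },
                sspk_direction_gain=float(rng.uniform(15.0, 25.0)) if tuned else 0.0,
                sspk_pd=sspk_pd,
                sspk_kappa=2.0,
                lick_locked_amplitude=0.3,
            )
        )
    return tuple(cells)


def paper_like_config(
    n_cells: int = 40, n_trials: int = 15, master_seed: int = 0, **kwargs
) -> SimConfig:
    """Default study conditions: direction task, heterogeneous population."""
    cells = make_paper_like_cells(n_cells, child_rng(master_seed, 9))
    return SimConfig(cells=cells, n_trials=n_trials, master_seed=master_seed, **kwargs)


def null_config(n_cells: int = 30, n_trials: int = 10, master_seed: int = 0, **kwargs) -> SimConfig:
    """Population with no reward effects anywhere (type-I error checks)."""
    rng = child_rng(master_seed, 9)
    cells = []
    for _ in range(n_cells):
        pd = float(rng.uniform(0, 360))
        cells.append(
            CellParams(
                cspk_cue_amplitude={REWARD_LARGE: 0.0, REWARD_SMALL: 0.0},
                sspk_cue_amplitude={REWARD_LARGE: 0.0, REWARD_SMALL: 0.0},
                cspk_pd=(pd + 180.0) % 360.0,
                sspk_pd=pd,
            )
        )
    kin = KinematicsParams(pursuit_gain={REWARD_LARGE: 0.9, REWARD_SMALL: 0.9})
    return SimConfig(
        cells=tuple(cells), kin=kin, n_trials=n_trials, master_seed=master_seed, **kwargs
    )
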