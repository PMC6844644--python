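"""Eye-trace processing: differentiation, saccade detection, averaging, drift."""

import math

import numpy as np
import pytest

from pursuitcspk.data_model import AnalysisParams, EyeTrace, TaskConfig, Trial
from pursuitcspk.kinematics import (
    average_velocity,
    detect_saccades,
    differentiate,
    drift_segments,
    nearest_task_direction,
    pupil_drift_correction,
    saccade_mask,
    session_mean_speed,
    trial_speed_traces,
)
from pursuitcspk.synthetic import child_rng, paper_like_config, simulate_session

TASK = TaskConfig()


def _eye(h, v=None, pupil=None, t0=0):
    n = len(h)
    return EyeTrace(
        time=np.arange(t0, t0 + n),
        h_position=np.asarray(h, float),
        v_position=np.zeros(n) if v is None else np.asarray(v, float),
        pupil=np.ones(n) if pupil is None else np.asarray(pupil, float),
        valid_mask=np.ones(n, bool),
    )


# ---------------------------------------------------------------------------
# differentiation

def test_differentiate_ramp_and_constant():
    t = np.arange(2000)
    vel = differentiate(_eye(20.0 * t / 1000.0))  # 20 deg/s ramp
    core = slice(100, -100)
    assert np.allclose(vel.vh[core], 20.0, atol=1e-6)
    assert np.allclose(vel.accel[core], 0.0, atol=1e-6)
    vel0 = differentiate(_eye(np.full(2000, 3.3)))
    assert np.allclose(vel0.speed[core], 0.0, atol=1e-9)


def test_differentiate_matches_analytic_sinusoid():
    t = np.arange(4000)
    f = 2.0  # Hz
    amp = 1.0
    w = 2 * math.pi * f
    pos = amp * np.sin(w * t / 1000.0)
    vel = differentiate(_eye(pos))
    true_v = amp * w * np.cos(w * t / 1000.0)
    # 5 ms Gaussian smoothing attenuates by exp(-(w*sd)^2/2); correct for it
    atten = math.exp(-0.5 * (w * 0.005) ** 2)
    core = slice(200, -200)
    err = np.max(np.abs(vel.vh[core] - atten * true_v[core]))
    assert err < 0.01 * amp * w


def test_differentiate_short_trace_errors():
    with pytest.raises(ValueError, match="shorter"):
        differentiate(_eye(np.zeros(10)))


# ---------------------------------------------------------------------------
# saccade detection

def _quiet_trial(t0=1000):
    motion = t0 + 1500
    return Trial(0, "large", 0.0, 20.0, t0 + 500, motion, motion + 1350, True, motion + 1350)


def test_no_detections_on_flat_trace():
    tr = _quiet_trial()
    eye = _eye(np.zeros(5000))
    assert detect_saccades(eye, [tr], TASK) == []


def test_single_injected_saccade_onset_accuracy():
    tr = _quiet_trial()
    t = np.arange(5000, dtype=float)
    center, sigma, vpeak = 1200.0, 5.0, 200.0
    pos = np.cumsum(vpeak * np.exp(-0.5 * ((t - center) / sigma) ** 2) / 1000.0)
    events = detect_saccades(_eye(pos), [tr], TASK)
    assert len(events) == 1
    truth_onset = center - 3.5 * sigma
    assert abs(events[0].onset_ms - truth_onset) <= 5
    assert events[0].epoch == "fixation"
    assert events[0].peak_velocity > 100


def test_steady_pursuit_below_threshold_not_saccadic():
    # 19 deg/s during target motion: under the 50 deg/s pursuit threshold
    tr = _quiet_trial()
    t = np.arange(5000)
    m, me = tr.motion_onset, tr.motion_onset + TASK.motion_duration
    pos = np.clip(t - m, 0, me - m) * 19.0 / 1000.0  # tracks only while target moves
    # soften the velocity steps so acceleration stays physiological
    from pursuitcspk.kinematics import smooth

    pos = smooth(pos, 30.0)
    events = detect_saccades(_eye(pos), [tr], TASK)
    assert events == []


def test_detection_on_simulated_ground_truth():
    s = simulate_session(paper_like_config(n_cells=0, n_trials=4, master_seed=21))
    det = detect_saccades(s.eye, s.trials, s.task)
    truth = s.saccades
    hits, errs, used = 0, [], set()
    for tv in truth:
        best, bd = None, None
        for i, d in enumerate(det):
            if i in used:
                continue
            if d.offset_ms >= tv.onset_ms - 20 and d.onset_ms <= tv.offset_ms + 20:
                e = abs(d.onset_ms - tv.onset_ms)
                if bd is None or e < bd:
                    best, bd = i, e
        if best is not None:
            used.add(best)
            hits += 1
            errs.append(bd)
    assert hits / len(truth) >= 0.95
    assert len(used) / len(det) >= 0.95
    assert max(errs) <= 5


# ---------------------------------------------------------------------------
# averaging and behavior readout

def test_average_velocity_identical_and_masked():
    base = np.full(500, 12.0)
    mean, n = average_velocity(np.vstack([base, base, base]))
    assert np.allclose(mean, 12.0, atol=1e-9)
    assert np.all(n == 3)
    masked = base.copy()
    masked[:100] = np.nan
    other = np.full(500, 8.0)
    mean, n = average_velocity(np.vstack([masked, other]))
    # smoothing kernel halfwidth is 30 ms; check outside the transition band
    assert np.allclose(mean[:65], 8.0, atol=1e-6)  # only the unmasked trace
    assert np.allclose(mean[135:], 10.0, atol=1e-6)
    assert n[0] == 1 and n[-1] == 2


def test_average_velocity_order_and_duplication_invariant(rng):
    traces = rng.normal(10, 1, size=(6, 300))
    traces[rng.random(traces.shape) < 0.1] = np.nan
    m1, _ = average_velocity(traces)
    m2, _ = average_velocity(traces[::-1])
    m3, _ = average_velocity(np.vstack([traces, traces]))
    assert np.allclose(m1, m2, equal_nan=True)
    assert np.allclose(m1, m3, equal_nan=True)


def test_session_mean_speed_constant_velocity():
    # one trial whose eye moves at a constant 10 deg/s: readout must be 10
    tr = _quiet_trial(t0=1000)
    n = 6000
    t = np.arange(n, dtype=float)
    pos = 10.0 * t / 1000.0
    eye = _eye(pos)
    from pursuitcspk.data_model import Session

    s = Session(TASK, [tr], [], eye, np.empty((0, 2), int))
    v = session_mean_speed(s, "large")
    assert v == pytest.approx(10.0, abs=0.05)


def test_session_mean_speed_orders_reward_conditions():
    s = simulate_session(paper_like_config(n_cells=0, n_trials=5, master_seed=22))
    large = session_mean_speed(s, "large")
    small = session_mean_speed(s, "small")
    # analytic plateau: gain * 20 * (1 - exp(-150/tau)), tau = 45 ms
    expect_large = 0.95 * 20 * (1 - math.exp(-150 / 45))
    expect_small = 0.85 * 20 * (1 - math.exp(-150 / 45))
    assert large > small
    assert large == pytest.approx(expect_large, abs=1.0)
    assert small == pytest.approx(expect_small, abs=1.0)


# ---------------------------------------------------------------------------
# pupil drift correction

def test_drift_correction_null_coupling(rng):
    n = 20000
    pupil = 1.0 + 0.2 * np.sin(np.arange(n) / 3000.0)
    h = rng.normal(0, 0.01, n)
    eye = _eye(h, pupil=pupil)
    corrected, fit = pupil_drift_correction(eye)
    assert abs(fit["h"]["slope"]) < 0.05
    assert fit["h"]["r2"] < 0.05
    assert np.allclose(corrected.h_position, eye.h_position - fit["h"]["intercept"]
                       - fit["h"]["slope"] * pupil, atol=1e-12)


def test_drift_correction_recovers_planted_r2(rng):
    n = 50000
    pupil = 1.0 + 0.2 * np.sin(np.arange(n) / 2000.0) + rng.normal(0, 0.02, n)
    signal = 2.0 * pupil
    noise_sd = signal.std() * math.sqrt(1 / 0.9 - 1)  # true R^2 = 0.9
    v = 0.5 + signal + rng.normal(0, noise_sd, n)
    eye = _eye(np.zeros(n), v=v, pupil=pupil)
    corrected, fit = pupil_drift_correction(eye)
    assert abs(fit["v"]["r2"] - 0.9) < 0.05
    r = np.corrcoef(corrected.v_position, pupil)[0, 1]
    assert abs(r) < 0.05
    # reconstruction: corrected + prediction == original exactly
    pred = fit["v"]["intercept"] + fit["v"]["slope"] * pupil
    assert np.allclose(corrected.v_position + pred, v, atol=1e-12)


def test_drift_correction_matches_normal_equations(rng):
    n = 5000
    pupil = rng.normal(1.0, 0.2, n)
    v = 0.3 + 1.7 * pupil + rng.normal(0, 0.1, n)
    eye = _eye(np.zeros(n), v=v, pupil=pupil)
    _, fit = pupil_drift_correction(eye)
    # closed-form simple-regression solution
    sxx = np.sum((pupil - pupil.mean()) ** 2)
    slope = np.sum((pupil - pupil.mean()) * (v - v.mean())) / sxx
    intercept = v.mean() - slope * pupil.mean()
    assert fit["v"]["slope"] == pytest.approx(slope, rel=1e-9)
    assert fit["v"]["intercept"] == pytest.approx(intercept, rel=1e-9)


def test_drift_correction_constant_pupil_errors():
    eye = _eye(np.zeros(1000))
    with pytest.raises(ValueError, match="constant"):
        pupil_drift_correction(eye)


# ---------------------------------------------------------------------------
# drift segments

def test_drift_segments_zero_and_planted():
    tr = _quiet_trial(t0=1000)
    n = 6000
    zero = drift_segments(_eye(np.zeros(n)), [tr], TASK)
    assert zero[0]["displacement_deg"] == pytest.approx(0.0, abs=1e-12)
    # constant drift 0.5 deg/s for the 1000 ms cue->motion epoch along 0 deg
    pos = np.zeros(n)
    a, b = tr.cue_onset, tr.motion_onset
    pos[a:b] = 0.5 * np.arange(b - a) / 1000.0
    pos[b:] = pos[b - 1]
    segs = drift_segments(_eye(pos), [tr], TASK)
    assert segs[0]["dx_deg"] == pytest.approx(0.5 * (b - a) / 1000.0, rel=0.02)
    assert segs[0]["nearest_direction"] == 0.0


def test_nearest_direction_rule():
    assert nearest_task_direction(30.0, TASK.directions) == 45.0
    assert nearest_task_direction(350.0, TASK.directions) == 0.0
    # exact tie 22.5 goes to the smaller angle
    assert nearest_task_direction(22.5, TASK.directions) == 0.0
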