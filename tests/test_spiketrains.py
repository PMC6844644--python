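"""PSTH/PETH estimation, window counts, event-contribution reconstruction, CCG."""

import math

import numpy as np
import pytest

from pursuitcspk.data_model import AnalysisParams, SpikeTrain, TaskConfig, Trial
from pursuitcspk.spiketrains import (
    count_fractions,
    cspk_triggered_ccg,
    event_contribution_psth,
    peth,
    population_psth,
    psth,
    window_counts,
)
from pursuitcspk.synthetic import child_rng, sample_inhomogeneous_poisson

P = AnalysisParams()
TASK = TaskConfig()


def _trials(n, spacing=4000, cue=1000, delay=1000):
    out = []
    for i in range(n):
        t0 = i * spacing
        motion = t0 + cue + delay
        end = motion + 1350
        out.append(Trial(i, "large" if i % 2 == 0 else "small", 0.0, 20.0,
                         t0 + cue, motion, end, True, end))
    return out


# ---------------------------------------------------------------------------
# psth

def test_psth_empty_train_is_zero():
    rt = psth(SpikeTrain(np.array([], int), "Cspk"), [1000, 2000], (-100, 100), P)
    assert np.all(rt.rate == 0)


def test_psth_single_spike_peak_closed_form():
    aligns = np.arange(9) * 3000 + 500
    train = SpikeTrain(aligns.copy(), "Cspk")
    rt = psth(train, aligns, (-200, 200), P)
    peak = rt.at(0)
    assert peak == pytest.approx(1.0 / (0.010 * math.sqrt(2 * math.pi)), abs=1e-6)
    # peak independent of trial count
    rt1 = psth(SpikeTrain(aligns[:1].copy(), "Cspk"), aligns[:1], (-200, 200), P)
    assert rt1.at(0) == pytest.approx(peak, abs=1e-9)


def test_psth_integral_identity_and_linearity(rng):
    ts = np.unique(rng.integers(0, 60_000, 1500))
    train = SpikeTrain(ts, "Sspk")
    a1 = [5000, 15_000, 25_000]
    a2 = [35_000, 45_000, 55_000, 58_000]
    w = (-400, 600)
    r1 = psth(train, a1, w, P, smooth=False)
    r2 = psth(train, a2, w, P, smooth=False)
    r12 = psth(train, a1 + a2, w, P, smooth=False)
    # integral identity: sum(rate)*n*bin == total spike count in the window
    total = sum(((ts >= a + w[0]) & (ts < a + w[1])).sum() for a in a1)
    assert r1.rate.sum() * len(a1) * 0.001 == pytest.approx(total, abs=1e-9)
    # linearity: union PSTH is the trial-count-weighted mean
    want = (r1.rate * len(a1) + r2.rate * len(a2)) / (len(a1) + len(a2))
    assert np.allclose(r12.rate, want, atol=1e-9)
    # linearity survives smoothing (convolution is linear)
    s1 = psth(train, a1, w, P).rate
    s2 = psth(train, a2, w, P).rate
    s12 = psth(train, a1 + a2, w, P).rate
    assert np.allclose(s12, (s1 * 3 + s2 * 4) / 7, atol=1e-9)


def test_psth_smoothing_preserves_interior_integral(rng):
    # all spikes at least one kernel halfwidth inside the window: smoothing
    # must redistribute mass without losing any
    aligns = np.arange(20) * 2000
    offs = rng.integers(-300, 500, size=200)  # window (-400, 600), margin 100
    ts = np.sort(np.concatenate([aligns + o for o in offs]))
    train = SpikeTrain(np.unique(ts), "Sspk")
    raw = psth(train, aligns, (-400, 600), P, smooth=False)
    sm = psth(train, aligns, (-400, 600), P, smooth=True)
    assert sm.rate.sum() == pytest.approx(raw.rate.sum(), abs=1e-6 * max(raw.rate.sum(), 1))


def test_psth_recovers_homogeneous_rate(rng):
    T = 400_000
    train = sample_inhomogeneous_poisson(np.full(T, 20.0), (0, T), rng, "Sspk")
    aligns = np.arange(200) * 2000 + 500
    rt = psth(train, aligns, (-400, 600), P, smooth=False)
    est = rt.rate.mean()
    n_ms = 200 * 1000
    se = math.sqrt(20.0 * 1000.0 / n_ms)
    assert abs(est - 20.0) < 3 * se + 0.025 * 20.0  # ms-rounding collision slack


# ---------------------------------------------------------------------------
# counts

def test_window_counts_half_open_convention():
    trials = _trials(1)
    cue = trials[0].cue_onset
    ts = np.array([cue + 99, cue + 100, cue + 299, cue + 300])
    df = window_counts(SpikeTrain(ts, "Cspk"), trials, "cue", (100, 300), P)
    assert df["count"].tolist() == [2]


def test_window_counts_matches_bruteforce(rng):
    trials = _trials(30)
    ts = np.unique(rng.integers(0, 30 * 4000, 3000))
    train = SpikeTrain(ts, "Sspk")
    for align, get in (("cue", lambda t: t.cue_onset), ("motion", lambda t: t.motion_onset)):
        df = window_counts(train, trials, align, (100, 300), P)
        want = [
            int(np.sum((ts >= get(t) + 100) & (ts < get(t) + 300))) for t in trials
        ]
        assert df["count"].tolist() == want


def test_window_counts_skips_failed_trials_at_reward():
    trials = _trials(4)
    import dataclasses

    trials[1] = dataclasses.replace(trials[1], reward_time=None, success=False)
    df = window_counts(SpikeTrain(np.array([], int), "Cspk"), trials, "reward", (100, 300), P)
    assert len(df) == 3


def test_count_fractions_arithmetic_and_pmf(rng):
    import pandas as pd

    df = pd.DataFrame({"count": [0, 1, 1, 2], "reward": ["large"] * 4})
    f = count_fractions(df)
    assert f == {0: 0.25, 1: 0.5, 2: 0.25, "3+": 0.0}
    assert sum(f.values()) == pytest.approx(1.0)
    # Poisson(0.4) simulation matches the pmf within 3 SE
    n = 4000
    lam = 0.4
    sim = pd.DataFrame({"count": rng.poisson(lam, n), "reward": ["large"] * n})
    fs = count_fractions(sim)
    for k in (0, 1, 2):
        pk = math.exp(-lam) * lam**k / math.factorial(k)
        se = math.sqrt(pk * (1 - pk) / n)
        assert abs(fs[k] - pk) < 3 * se


# ---------------------------------------------------------------------------
# peth and event contributions

def test_peth_equals_psth_on_cue_alignment(rng):
    trials = _trials(10)
    ts = np.unique(rng.integers(0, 40_000, 800))
    train = SpikeTrain(ts, "Sspk")
    cues = [t.cue_onset for t in trials]
    a = peth(train, cues, 300, P)
    b = psth(train, cues, (-300, 301), P)
    assert np.array_equal(a.time, b.time)
    assert np.allclose(a.rate, b.rate)


def test_peth_shows_event_locked_bump(rng):
    # +5 spikes/s on [0,100] ms after each event over a 10 spikes/s baseline
    T = 1_500_000
    events = np.arange(1000, T - 1000, 1500)
    rate = np.full(T, 10.0)
    for e in events:
        rate[e : e + 100] += 5.0
    train = sample_inhomogeneous_poisson(rate, (0, T), rng, "Sspk")
    rt = peth(train, events, 300, P)
    bump = rt.rate[(rt.time >= 20) & (rt.time <= 80)].mean()
    base = rt.rate[(rt.time >= -250) & (rt.time <= -50)].mean()
    assert bump - base == pytest.approx(5.0, abs=1.5)


def test_event_contribution_trivial_cases():
    trials = _trials(5)
    grid = np.arange(-300, 301)
    from pursuitcspk.spiketrains import RateTrace

    flat = RateTrace(grid, np.full(grid.size, 7.0), np.full(grid.size, 5))
    # no events anywhere: fully missing prediction
    out = event_contribution_psth(trials, {}, flat, "cue", (-200, 400), P)
    for cond, rt in out.items():
        assert np.all(np.isnan(rt.rate))
    # flat PETH with full coverage: prediction == the flat rate
    events = {t.trial_id: [t.cue_onset - 200, t.cue_onset + 200] for t in trials}
    out = event_contribution_psth(trials, events, flat, "cue", (-200, 400), P)
    for cond, rt in out.items():
        assert np.allclose(rt.rate, 7.0)


def test_event_contribution_translation_oracle(rng):
    # one event per trial at a fixed latency L: prediction is the PETH shifted by L
    trials = _trials(8)
    grid = np.arange(-300, 301)
    from pursuitcspk.spiketrains import RateTrace

    shape = 10.0 + 5.0 * np.exp(-0.5 * ((grid - 40) / 30.0) ** 2)
    pe = RateTrace(grid, shape, np.full(grid.size, 8))
    L = 150
    events = {t.trial_id: [t.cue_onset + L] for t in trials}
    out = event_contribution_psth(trials, events, pe, "cue", (-200, 500), P)
    for cond, rt in out.items():
        core = (rt.time >= L - 300) & (rt.time <= L + 300)
        src = rt.time[core] - L - grid[0]
        assert np.allclose(rt.rate[core], shape[src.astype(int)])
        assert np.all(np.isnan(rt.rate[rt.time < L - 300]))


# ---------------------------------------------------------------------------
# population psth

def test_population_psth_identity_and_mean_subtraction(rng):
    grid = np.arange(-100, 100)
    from pursuitcspk.spiketrains import RateTrace

    base = 5.0 + np.sin(grid / 20.0)
    cells = [RateTrace(grid, base.copy(), np.full(grid.size, 10)) for _ in range(4)]
    pop = population_psth(cells)
    assert np.allclose(pop.rate, base)
    assert np.allclose(pop.sem, 0.0)
    # constant traces with subtraction vanish
    consts = [RateTrace(grid, np.full(grid.size, float(k)), np.full(grid.size, 10)) for k in range(4)]
    pop0 = population_psth(consts, subtract_cell_mean=True)
    assert np.allclose(pop0.rate, 0.0, atol=1e-12)
    # random offsets removed: equals direct computation
    offs = rng.normal(0, 3, 5)
    cells = [RateTrace(grid, base + o, np.full(grid.size, 10)) for o in offs]
    pop = population_psth(cells, subtract_cell_mean=True)
    want = np.mean([base + o - (base + o).mean() for o in offs], axis=0)
    assert np.allclose(pop.rate, want, atol=1e-9)


def test_population_psth_single_cell_warns():
    grid = np.arange(10)
    from pursuitcspk.spiketrains import RateTrace

    with pytest.warns(UserWarning, match="SEM"):
        population_psth([RateTrace(grid, np.ones(10), np.ones(10, int))])


# ---------------------------------------------------------------------------
# cross-correlogram

def test_ccg_edge_and_blank_rules():
    bounds = [(0, 1000)]
    # Cspk 50 ms into the trial: too close to the edge, not a trigger
    cspk = SpikeTrain(np.array([50, 500]), "Cspk")
    sspk = SpikeTrain(np.array([400, 501, 502, 503, 600]), "Sspk")
    rt = cspk_triggered_ccg(cspk, sspk, bounds, 100, P)
    # only trigger is 500; spikes at 501/502 fall in the [-1,+2] blank window
    assert rt.n_trials[0] == 1
    assert rt.at(1) == 0.0 and rt.at(2) == 0.0
    assert rt.at(3) == 1000.0  # spike at 503 survives: 1 spike / 1 trigger / 1 ms
    assert rt.at(-100) == 1000.0  # spike at 400
    with pytest.raises(ValueError, match="trigger"):
        cspk_triggered_ccg(SpikeTrain(np.array([50]), "Cspk"), sspk, bounds, 100, P)


def test_ccg_planted_pause_and_independence(rng):
    from pursuitcspk.synthetic import impose_post_cspk_pause

    T = 400_000
    cspk = sample_inhomogeneous_poisson(np.full(T, 1.2), (0, T), rng, "Cspk")
    sspk = sample_inhomogeneous_poisson(np.full(T, 50.0), (0, T), rng, "Sspk")
    bounds = [(i * 2500, i * 2500 + 2400) for i in range(T // 2500)]
    # independent trains: CCG flat at the Sspk mean rate within 3 SE
    rt = cspk_triggered_ccg(cspk, sspk, bounds, 100, P)
    out = (rt.time < -5) | (rt.time > 5)
    n_trig = rt.n_trials[0]
    mean_rate = rt.rate[out].mean()
    se = math.sqrt(mean_rate * 1000.0 / (n_trig * out.sum()))
    assert abs(mean_rate - 50.0) < 3 * se + 0.03 * 50.0  # rounding-collision slack
    # planted 15 ms pause: exact silence on (2,15], recovery after
    paused = impose_post_cspk_pause(sspk, cspk, 15)
    rt2 = cspk_triggered_ccg(cspk, paused, bounds, 100, P)
    inpause = (rt2.time > 2) & (rt2.time <= 15)
    assert np.all(rt2.rate[inpause] == 0.0)
    after = rt2.time > 25
    assert rt2.rate[after].mean() > 40.0
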