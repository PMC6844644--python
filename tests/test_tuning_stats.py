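"""Rank tests, tuning curves, preferred directions, permutation and shuffles."""

import itertools
import math

import numpy as np
import pytest

from pursuitcspk.data_model import AnalysisParams, SpikeTrain, TaskConfig, Trial
from pursuitcspk.synthetic import child_rng
from pursuitcspk.tuning_stats import (
    TuningCurve,
    align_population_tuning,
    direction_tuning,
    is_directionally_tuned,
    modulation_correlation,
    preferred_direction,
    rank_sum_test,
    reward_tuning_permutation_test,
    rotate_to_pd,
    shuffle_controls,
    signal_correlation,
)

P = AnalysisParams()
DIRS = np.arange(8) * 45.0


def exact_ranksum_p(x, y, tail):
    """Independent oracle: enumerate every assignment of ranks to the x-sample."""
    x, y = list(x), list(y)
    combined = sorted(x + y)
    nx = len(x)
    obs = sum(combined.index(v) + 1 for v in x)  # rank sum of x (no ties)
    stats = []
    for comb in itertools.combinations(range(1, len(combined) + 1), nx):
        stats.append(sum(comb))
    stats = np.array(stats)
    if tail == "right":
        return float(np.mean(stats >= obs))
    if tail == "left":
        return float(np.mean(stats <= obs))
    lo = min(np.mean(stats >= obs), np.mean(stats <= obs))
    return float(min(1.0, 2 * lo))


def test_rank_sum_worked_example():
    res = rank_sum_test([1, 2, 3], [4, 5, 6], tail="two")
    assert res.p_value == pytest.approx(0.1)
    one = rank_sum_test([4, 5, 6], [1, 2, 3], tail="right")
    assert one.p_value == pytest.approx(0.05)  # 1 / C(6,3)


def test_rank_sum_matches_enumeration_oracle(rng):
    for nx in range(1, 6):
        for ny in range(1, 6):
            if nx + ny > 10:
                continue
            vals = rng.permutation(np.arange(1.0, 20.0))[: nx + ny]
            x, y = vals[:nx], vals[nx:]
            for tail in ("two", "left", "right"):
                got = rank_sum_test(x, y, tail).p_value
                want = exact_ranksum_p(x, y, tail)
                assert got == pytest.approx(want, abs=1e-12), (nx, ny, tail)


def test_rank_sum_identical_samples_and_errors():
    res = rank_sum_test([1, 2, 2, 3], [1, 2, 2, 3], tail="two")
    assert res.p_value > 0.95
    with pytest.raises(ValueError):
        rank_sum_test([], [1.0])


# ---------------------------------------------------------------------------
# tuning curves and PD

def _counts_session(rng, pd_deg=90.0, gain=20.0, base=1.0, kappa=2.0, n_per_dir=40):
    """Trials plus a spike train whose motion response is von-Mises tuned."""
    trials, spikes = [], []
    t = 0
    i = 0
    for d in DIRS:
        lam = base + gain * math.exp(kappa * (math.cos(math.radians(d - pd_deg)) - 1))
        for _ in range(n_per_dir):
            cue = t + 500
            motion = cue + 1000
            end = motion + 1350
            trials.append(Trial(i, "large", float(d), 20.0, cue, motion, end, True, end))
            n = rng.poisson(lam * 0.2)
            if n:
                spikes.extend(rng.integers(motion + 100, motion + 300, n))
            t = end + 500
            i += 1
    ts = np.unique(np.asarray(sorted(spikes), dtype=np.int64))
    return trials, SpikeTrain(ts, "Cspk")


def test_direction_tuning_recovers_generative_curve(rng):
    trials, train = _counts_session(rng, pd_deg=90.0, gain=20.0, base=1.0)
    curve = direction_tuning(train, trials, params=P)
    assert np.array_equal(curve.levels, DIRS)
    for d, m, n in zip(curve.levels, curve.mean_rate, curve.n_trials):
        lam = 1.0 + 20.0 * math.exp(2.0 * (math.cos(math.radians(d - 90.0)) - 1))
        se = math.sqrt(lam / (0.2 * n))  # Poisson SE of the rate estimate
        assert abs(m - lam) < 3 * se + 0.03 * lam
    assert preferred_direction(curve) == 90.0


def test_preferred_direction_worked_examples():
    single = TuningCurve(DIRS, np.array([0, 0, 5, 0, 0, 0, 0, 0.0]), np.ones(8, int), (100, 300))
    assert preferred_direction(single) == 90.0
    sym = TuningCurve(DIRS, np.array([2, 1, 0, 0, 0, 0, 0, 1.0]), np.ones(8, int), (100, 300))
    assert preferred_direction(sym) == 0.0  # the 45/315 pair cancels
    flat = TuningCurve(DIRS, np.ones(8), np.ones(8, int), (100, 300))
    with pytest.raises(ValueError, match="undefined"):
        preferred_direction(flat)


def test_preferred_direction_matches_bruteforce_oracle(rng):
    for _ in range(1000):
        rates = rng.uniform(0, 10, 8)
        curve = TuningCurve(DIRS, rates, np.ones(8, int), (100, 300))
        th = np.radians(DIRS)
        vx, vy = np.sum(rates * np.cos(th)), np.sum(rates * np.sin(th))
        if math.hypot(vx, vy) < 1e-9:
            continue
        ang = math.degrees(math.atan2(vy, vx)) % 360.0
        dists = np.abs((ang - DIRS + 180.0) % 360.0 - 180.0)
        want = DIRS[int(np.argmin(dists))]  # argmin takes the smaller angle on ties
        assert preferred_direction(curve) == want


def test_preferred_direction_equivariance(rng):
    rates = rng.uniform(0, 10, 8)
    c1 = TuningCurve(DIRS, rates, np.ones(8, int), (100, 300))
    c2 = TuningCurve(DIRS, np.roll(rates, 1), np.ones(8, int), (100, 300))  # rotate +45
    assert preferred_direction(c2) == (preferred_direction(c1) + 45.0) % 360.0


def test_directional_tuning_test_cases(rng):
    # two identical groups: no effect
    res = is_directionally_tuned({0.0: np.array([1, 2, 3.0]), 180.0: np.array([1, 2, 3.0])})
    assert res.p_value > 0.95
    # strongly tuned cell is detected
    counts = {
        float(d): rng.poisson(1 + 20 * math.exp(2 * (math.cos(math.radians(d - 90)) - 1)) * 0.2, 40)
        for d in DIRS
    }
    assert is_directionally_tuned(counts).p_value < 0.05
    # untuned cell: type-I at the nominal level over repetitions
    rej = 0
    n_rep = 400
    for _ in range(n_rep):
        counts = {float(d): rng.poisson(2.0, 20) for d in DIRS}
        if is_directionally_tuned(counts).p_value < 0.05:
            rej += 1
    se = math.sqrt(0.05 * 0.95 / n_rep)
    assert abs(rej / n_rep - 0.05) < 4 * se


# ---------------------------------------------------------------------------
# population alignment

def test_population_alignment_rotation():
    rates = np.array([1, 2, 3, 4, 5, 6, 7, 8.0])
    c = TuningCurve(DIRS, rates, np.ones(8, int), (100, 300))
    assert np.allclose(rotate_to_pd(c, 0.0), rates)  # identity at PD 0
    rot = rotate_to_pd(c, 90.0)
    assert rot[0] == rates[2]  # the 90 deg response lands at relative 0
    assert rot[6] == rates[0]  # 90 + 270 = 0 (mod 360)


def test_antiphase_population_minimum_at_zero(rng):
    # Cspk curves generated anti-phase to Sspk: aligned to the Sspk PD, the
    # Cspk population dips at relative 0
    curves, pds = {}, {}
    for k in range(20):
        pd_deg = float(DIRS[rng.integers(0, 8)])
        sspk = 50 + 20 * np.exp(2 * (np.cos(np.radians(DIRS - pd_deg)) - 1))
        cspk = 4 - 0.05 * sspk + rng.normal(0, 0.1, 8)
        curves[f"c{k}"] = TuningCurve(DIRS, cspk, np.ones(8, int), (100, 300))
        pds[f"c{k}"] = pd_deg
    rel, mean, sem = align_population_tuning(curves, pds)
    assert rel[int(np.argmin(mean))] == 0.0


# ---------------------------------------------------------------------------
# permutation test

def test_permutation_identical_curves_gives_p_one(rng):
    L = rng.uniform(1, 5, (10, 8))
    res = reward_tuning_permutation_test(L, L.copy(), n_perm=500, rng=rng)
    assert res.statistic == 0.0
    assert res.p_value == 1.0


def test_permutation_pvalue_never_zero_and_detects_effect(rng):
    L = rng.uniform(1, 5, (20, 8)) + 3.0
    S = rng.uniform(1, 5, (20, 8))
    res = reward_tuning_permutation_test(L, S, n_perm=400, rng=rng)
    assert res.p_value >= 1.0 / 401.0
    assert res.p_value < 0.05


def test_permutation_missing_levels_never_swapped(rng):
    L = rng.uniform(1, 5, (6, 8))
    S = rng.uniform(1, 5, (6, 8))
    L[0, 3] = np.nan  # cell 0 lacks a level in one condition
    res = reward_tuning_permutation_test(L, S, n_perm=200, rng=rng)
    assert 0 < res.p_value <= 1


# ---------------------------------------------------------------------------
# signal correlation and shuffles

def test_signal_correlation_affine_and_degenerate(rng):
    base = rng.uniform(1, 5, 8)
    a = TuningCurve(DIRS, base, np.ones(8, int), (100, 300))
    b = TuningCurve(DIRS, 3.0 - 2.0 * base, np.ones(8, int), (100, 300))
    assert signal_correlation(a, b) == pytest.approx(-1.0)
    const = TuningCurve(DIRS, np.full(8, 2.0), np.ones(8, int), (100, 300))
    assert math.isnan(signal_correlation(a, const))
    # positive affine rescaling invariance
    b2 = TuningCurve(DIRS, 0.5 + 2.0 * base, np.ones(8, int), (100, 300))
    assert signal_correlation(a, b2) == pytest.approx(1.0)
    # matches the textbook formula on random curves
    x, y = rng.uniform(0, 1, 8), rng.uniform(0, 1, 8)
    cx, cy = x - x.mean(), y - y.mean()
    want = float(np.sum(cx * cy) / math.sqrt(np.sum(cx**2) * np.sum(cy**2)))
    got = signal_correlation(
        TuningCurve(DIRS, x, np.ones(8, int), (100, 300)),
        TuningCurve(DIRS, y, np.ones(8, int), (100, 300)),
    )
    assert got == pytest.approx(want, abs=1e-12)


def test_shuffles_preserve_multiset_and_are_seeded(rng):
    mat = rng.uniform(0, 1, (5, 8))
    for mode in ("phase", "direction"):
        sh = shuffle_controls(mat, mode, child_rng(0, 77))
        sh2 = shuffle_controls(mat, mode, child_rng(0, 77))
        assert np.array_equal(sh, sh2)
        for i in range(5):
            assert sorted(sh[i]) == pytest.approx(sorted(mat[i]))
    # phase shuffle preserves circular order
    sh = shuffle_controls(mat, "phase", rng)
    for i in range(5):
        k = int(np.argmax(np.isclose(sh[i], mat[i, 0])))
        assert np.allclose(np.roll(mat[i], k), sh[i])


# ---------------------------------------------------------------------------
# modulation correlation

def test_modulation_correlation_worked_examples(rng):
    mono = modulation_correlation([1, 2, 3, 4], np.exp([1, 2, 3, 4]))
    assert mono.statistic == pytest.approx(1.0)
    hand = modulation_correlation([1, 2, 3, 4], [2, 1, 4, 3])
    assert hand.statistic == pytest.approx(0.6)  # 1 - 6*4/(4*15)
    x = rng.normal(size=200)
    y = rng.normal(size=200)
    res = modulation_correlation(x, y)
    assert abs(res.statistic) < 0.2
    with pytest.raises(ValueError):
        modulation_correlation([1, 2], [3, 4])
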