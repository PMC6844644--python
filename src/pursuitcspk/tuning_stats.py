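"""Inferential statistics: reward discrimination, direction/speed tuning,
preferred directions, the reward-label permutation test, signal correlations
with shuffle controls, and the time-resolved fraction of discriminating cells.

All criteria use alpha = 0.05 with no multiple-comparison correction: tests
applied per cell serve only to classify cells into subpopulations, and
population-level conclusions rest on a small number of tests.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .data_model import (
    AnalysisParams,
    CellRecording,
    REWARD_LARGE,
    REWARD_SMALL,
    SpikeTrain,
    Trial,
)
from .spiketrains import window_counts

__all__ = [
    "TuningCurve",
    "TestResult",
    "CellClassification",
    "rank_sum_test",
    "classify_cue_discrimination",
    "direction_tuning",
    "preferred_direction",
    "is_directionally_tuned",
    "align_population_tuning",
    "rotate_to_pd",
    "reward_tuning_permutation_test",
    "signal_correlation",
    "shuffle_controls",
    "discrimination_timecourse",
    "modulation_correlation",
]


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    n: int
    tail: str  # {"two", "left", "right"}
    method: str


@dataclass
class TuningCurve:
    """Mean firing rate per stimulus level in a fixed analysis window."""

    levels: np.ndarray  # directions (deg) or speeds (deg/s), ordered
    mean_rate: np.ndarray  # spikes/s
    n_trials: np.ndarray
    window: tuple[int, int]

    def __post_init__(self):
        self.levels = np.asarray(self.levels, dtype=float)
        self.mean_rate = np.asarray(self.mean_rate, dtype=float)
        self.n_trials = np.asarray(self.n_trials, dtype=int)


@dataclass
class CellClassification:
    cell_id: str
    cue_discriminating: bool = False
    cue_sign: Optional[str] = None  # "large>small" or "small>large"
    cue_p: Optional[float] = None
    directionally_tuned: bool = False
    pd: Optional[float] = None
    tuned_p: Optional[float] = None
    excluded_reason: Optional[str] = None


# ---------------------------------------------------------------------------
# rank tests

_EXACT_MAX_N = 12


def rank_sum_test(x, y, tail: str = "two") -> TestResult:
    """Wilcoxon-Mann-Whitney rank-sum test.

    The p-value is exact (full enumeration of rank assignments) when the
    combined sample has at most 12 observations and no ties; otherwise it uses
    mid-ranks with the tie-corrected normal approximation.  ``tail='right'``
    tests whether x tends larger than y.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("rank_sum_test requires two nonempty samples")
    alternative = {"two": "two-sided", "left": "less", "right": "greater"}[tail]
    combined = np.concatenate([x, y])
    exact = combined.size <= _EXACT_MAX_N and np.unique(combined).size == combined.size
    res = sps.mannwhitneyu(
        x, y, alternative=alternative, method="exact" if exact else "asymptotic"
    )
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        n=int(combined.size),
        tail=tail,
        method="rank-sum (exact)" if exact else "rank-sum (normal approx.)",
    )


def classify_cue_discrimination(
    cell: CellRecording,
    trials: Sequence[Trial],
    params: AnalysisParams = AnalysisParams(),
    align: str = "cue",
    spike_class: str = "cspk",
) -> CellClassification:
    """Rank-sum comparison of 100-300 ms post-cue spike counts by reward size.

    Cells with fewer than ``params.min_trials_reward`` trials are excluded
    with a reason rather than tested.
    """
    cls = CellClassification(cell_id=cell.cell_id)
    if len(trials) < params.min_trials_reward:
        cls.excluded_reason = (
            f"{len(trials)} trials < minimum {params.min_trials_reward}"
        )
        return cls
    train = cell.cspk if spike_class == "cspk" else cell.sspk
    counts = window_counts(train, trials, align=align, window=params.count_window, params=params)
    large = counts.loc[counts.reward == REWARD_LARGE, "count"].to_numpy()
    small = counts.loc[counts.reward == REWARD_SMALL, "count"].to_numpy()
    if large.size == 0 or small.size == 0:
        cls.excluded_reason = "a reward condition has no trials"
        return cls
    res = rank_sum_test(large, small, tail="two")
    cls.cue_p = res.p_value
    cls.cue_discriminating = res.p_value < params.alpha
    if cls.cue_discriminating:
        cls.cue_sign = (
            "large>small" if large.mean() > small.mean() else "small>large"
        )
    return cls


# ---------------------------------------------------------------------------
# tuning

def direction_tuning(
    train: SpikeTrain,
    trials: Sequence[Trial],
    window: Optional[tuple[int, int]] = None,
    params: AnalysisParams = AnalysisParams(),
    by: str = "direction",
) -> TuningCurve:
    """Tuning curve: mean window count / window duration per level.

    The window defaults to the first 100-300 ms of target motion.  Levels with
    no trials are dropped with a warning.
    """
    w = window if window is not None else params.count_window
    counts = window_counts(train, trials, align="motion", window=w, params=params)
    if counts.empty:
        raise ValueError("no trials for tuning curve")
    dur_s = (w[1] - w[0]) / 1000.0
    grouped = counts.groupby(by)["count"]
    levels = np.array(sorted(grouped.groups.keys()), dtype=float)
    mean_rate = np.array([grouped.get_group(l).mean() / dur_s for l in levels])
    n = np.array([len(grouped.get_group(l)) for l in levels])
    return TuningCurve(levels=levels, mean_rate=mean_rate, n_trials=n, window=tuple(w))


def preferred_direction(curve: TuningCurve) -> float:
    """Direction of the tuning curve's center of mass, snapped to a task level.

    The vector average is sum_d rate_d * (cos d, sin d); the preferred
    direction is the curve level nearest (circularly) to its angle, ties going
    to the smaller angle.  A zero-length vector leaves the PD undefined.
    """
    if curve.levels.size < 2:
        raise ValueError("preferred direction needs at least two levels")
    th = np.radians(curve.levels)
    vx = float(np.sum(curve.mean_rate * np.cos(th)))
    vy = float(np.sum(curve.mean_rate * np.sin(th)))
    norm = math.hypot(vx, vy)
    scale = float(np.max(np.abs(curve.mean_rate))) or 1.0
    if norm < 1e-9 * scale or norm == 0.0:
        raise ValueError("tuning-curve vector average is zero; PD undefined")
    ang = math.degrees(math.atan2(vy, vx)) % 360.0
    best, best_d = None, None
    for d in sorted(float(l) for l in curve.levels):
        dist = abs((ang - d + 180.0) % 360.0 - 180.0)
        if best_d is None or dist < best_d - 1e-12:
            best, best_d = d, dist
    return float(best)


def is_directionally_tuned(
    counts_by_level: Mapping[float, np.ndarray],
    params: AnalysisParams = AnalysisParams(),
) -> TestResult:
    """Kruskal-Wallis across >=3 levels (tie-corrected chi-square), rank-sum for 2."""
    levels = sorted(counts_by_level.keys())
    if len(levels) < 2:
        raise ValueError("tuning test needs at least two levels")
    groups = [np.asarray(counts_by_level[l], dtype=float) for l in levels]
    for l, g in zip(levels, groups):
        if g.size < 2:
            warnings.warn(f"direction {l} has fewer than 2 trials")
    n = int(sum(g.size for g in groups))
    if len(groups) == 2:
        res = rank_sum_test(groups[0], groups[1], tail="two")
        return TestResult(res.statistic, res.p_value, n, "two", res.method)
    allv = np.concatenate(groups)
    if np.ptp(allv) == 0:  # all counts identical: no effect by construction
        return TestResult(0.0, 1.0, n, "two", "kruskal-wallis")
    h, p = sps.kruskal(*groups)
    return TestResult(float(h), float(p), n, "two", "kruskal-wallis")


def tuning_counts_by_level(
    train: SpikeTrain,
    trials: Sequence[Trial],
    params: AnalysisParams = AnalysisParams(),
    by: str = "direction",
    window: Optional[tuple[int, int]] = None,
) -> dict[float, np.ndarray]:
    """Per-level arrays of per-trial motion-window counts (helper for tests)."""
    w = window if window is not None else params.count_window
    counts = window_counts(train, trials, align="motion", window=w, params=params)
    return {
        float(l): g["count"].to_numpy(dtype=float)
        for l, g in counts.groupby(by)
    }


def rotate_to_pd(curve: TuningCurve, pd_deg: float) -> np.ndarray:
    """Rates re-indexed on relative levels so the reference PD sits at 0 deg.

    Entry k of the result is the response at absolute direction
    ``(pd + relative_level_k) mod 360``; relative levels are the curve's own
    level grid.
    """
    rel = curve.levels
    out = np.full(rel.size, np.nan)
    for i, r in enumerate(rel):
        target = (pd_deg + r) % 360.0
        j = np.nonzero(np.isclose(curve.levels % 360.0, target))[0]
        if j.size:
            out[i] = curve.mean_rate[j[0]]
    return out


def align_population_tuning(
    curves: Mapping[str, TuningCurve],
    pds: Mapping[str, float],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Population tuning on relative directions after per-cell PD alignment.

    Cells lacking a reference PD are excluded.  Returns (relative levels,
    mean across cells, SEM).
    """
    rows = []
    rel = None
    for cid, curve in curves.items():
        if cid not in pds or pds[cid] is None:
            continue
        if rel is None:
            rel = curve.levels
        rows.append(rotate_to_pd(curve, pds[cid]))
    if not rows:
        raise ValueError("no cells with a reference preferred direction")
    mat = np.vstack(rows)
    mean = np.nanmean(mat, axis=0)
    nn = np.sum(np.isfinite(mat), axis=0)
    sd = np.nanstd(mat, axis=0, ddof=1) if mat.shape[0] > 1 else np.full(rel.size, np.nan)
    sem = sd / np.sqrt(np.maximum(nn, 1))
    return rel, mean, sem


# ---------------------------------------------------------------------------
# permutation test on reward-split tuning

def reward_tuning_permutation_test(
    large: np.ndarray,
    small: np.ndarray,
    n_perm: int = 2000,
    rng: Optional[np.random.Generator] = None,
    swap_prob: float = 0.5,
) -> TestResult:
    """Permutation test for a reward effect on population tuning curves.

    ``large`` and ``small`` are (cells x levels) matrices of per-condition
    responses on a common relative-level grid (PD-aligned directions, or
    direction x speed combinations flattened).  The statistic is the mean
    square distance between the two population curves.  Under the null, each
    (cell, level) pair's condition labels are swapped independently with
    probability ``swap_prob``; pairs with a missing condition are never
    swapped.  The p-value uses the add-one estimator, so it is never zero.
    """
    rng = rng or np.random.default_rng()
    L = np.asarray(large, dtype=float)
    S = np.asarray(small, dtype=float)
    if L.shape != S.shape:
        raise ValueError("condition matrices must have equal shape")
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is small; permutation p-value is coarse")
    swappable = np.isfinite(L) & np.isfinite(S)
    d = np.where(swappable, L - S, 0.0)  # missing pairs contribute no distance
    n_per_level = swappable.sum(axis=0)
    if np.any(n_per_level == 0):
        raise ValueError("a level has no cell with both conditions")

    def stat(diff):
        return float(np.mean((diff.sum(axis=0) / n_per_level) ** 2))

    t_obs = stat(d)
    flips = np.where(
        swappable[None, :, :] & (rng.random((n_perm,) + L.shape) < swap_prob),
        -1.0,
        1.0,
    )
    pop_diff = (flips * d[None, :, :]).sum(axis=1) / n_per_level[None, :]
    t_perm = np.mean(pop_diff**2, axis=1)
    p = (1.0 + float(np.sum(t_perm >= t_obs))) / (1.0 + n_perm)
    return TestResult(
        statistic=t_obs,
        p_value=p,
        n=int(L.shape[0]),
        tail="right",
        method=f"reward-label permutation ({n_perm} perms)",
    )


# ---------------------------------------------------------------------------
# Cspk/Sspk interaction

def signal_correlation(cspk_curve: TuningCurve, sspk_curve: TuningCurve) -> float:
    """Pearson correlation of the two spike classes' tuning curves.

    Returns NaN when either curve is constant (correlation undefined).
    """
    if not np.array_equal(cspk_curve.levels, sspk_curve.levels):
        raise ValueError("tuning curves must share levels in the same order")
    a, b = cspk_curve.mean_rate, sspk_curve.mean_rate
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def shuffle_controls(
    curves: np.ndarray, mode: str, rng: np.random.Generator
) -> np.ndarray:
    """Destroy curve alignment while keeping per-cell response distributions.

    ``phase``: circular rotation of each cell's curve by a uniformly drawn
    number of level steps (order preserved).  ``direction``: uniform random
    permutation of level labels per cell.
    """
    mat = np.asarray(curves, dtype=float)
    out = np.empty_like(mat)
    k = mat.shape[1]
    for i in range(mat.shape[0]):
        if mode == "phase":
            out[i] = np.roll(mat[i], int(rng.integers(0, k)))
        elif mode == "direction":
            out[i] = mat[i, rng.permutation(k)]
        else:
            raise ValueError(f"unknown shuffle mode {mode!r}")
    return out


def modulation_correlation(x, y) -> TestResult:
    """Spearman rank correlation (mid-ranks for ties) between per-cell
    modulation measures, e.g. Cspk vs Sspk reward differences after the cue."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("modulation correlation needs >=3 paired cells")
    r, p = sps.spearmanr(x, y)
    return TestResult(float(r), float(p), int(x.size), "two", "spearman")


# ---------------------------------------------------------------------------
# time-resolved discrimination

def discrimination_timecourse(
    cells: Sequence[CellRecording],
    trials: Sequence[Trial],
    times: Sequence[int],
    align: str = "cue",
    params: AnalysisParams = AnalysisParams(),
    spike_class: str = "sspk",
) -> pd.DataFrame:
    """Fraction of cells preferring each reward condition, over time.

    At each time point t, per-trial spike counts are taken in the 200 ms bin
    [t-100, t+100) and compared between reward conditions with left- and
    right-tailed rank-sum tests at alpha; each cell is classified RL>RS,
    RS>RL, or neither.  Cells with too few trials are skipped.  The returned
    frame carries the two fractions and the alpha chance line.
    """
    half = params.moving_bin // 2
    times = np.asarray(times, dtype=int)
    n_rl = np.zeros(times.size)
    n_rs = np.zeros(times.size)
    n_cells = 0
    for cell in cells:
        if len(trials) < params.min_trials_reward:
            continue
        train = cell.sspk if spike_class == "sspk" else cell.cspk
        counts_all = []
        for i, t in enumerate(times):
            df = window_counts(
                train, trials, align=align, window=(int(t) - half, int(t) + half), params=params
            )
            counts_all.append(df)
        n_cells += 1
        for i, df in enumerate(counts_all):
            large = df.loc[df.reward == REWARD_LARGE, "count"].to_numpy()
            small = df.loc[df.reward == REWARD_SMALL, "count"].to_numpy()
            if large.size == 0 or small.size == 0:
                continue
            if rank_sum_test(large, small, tail="right").p_value < params.alpha:
                n_rl[i] += 1
            elif rank_sum_test(large, small, tail="left").p_value < params.alpha:
                n_rs[i] += 1
    if n_cells == 0:
        raise ValueError("no cell had enough trials for the timecourse")
    return pd.DataFrame(
        {
            "t_ms": times,
            "frac_large_gt_small": n_rl / n_cells,
            "frac_small_gt_large": n_rs / n_cells,
            "chance_level": params.alpha,
            "n_cells": n_cells,
        }
    )
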