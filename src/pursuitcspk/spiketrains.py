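"""Rate estimation and event-conditioned spike statistics.

PSTHs are computed at 1 ms resolution and smoothed with a 10 ms SD Gaussian;
the smoothing window is computed on a trace extended by at least 100 ms on
each side and trimmed back, so edge effects never reach the displayed span.
Count windows are half-open ``[start, end)`` in ms relative to the alignment
event, so adjacent windows partition time.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .data_model import AnalysisParams, SpikeTrain, Trial
from .kinematics import gaussian_kernel

__all__ = [
    "RateTrace",
    "psth",
    "population_psth",
    "window_counts",
    "count_fractions",
    "peth",
    "event_contribution_psth",
    "cspk_triggered_ccg",
]


@dataclass
class RateTrace:
    """Trial-averaged firing rate on a 1 ms grid relative to an event."""

    time: np.ndarray  # ms relative to alignment event
    rate: np.ndarray  # spikes/s; NaN where undefined
    n_trials: np.ndarray  # per-timepoint contributing trials
    sem: Optional[np.ndarray] = None

    def at(self, t_ms: int) -> float:
        return float(self.rate[int(t_ms - self.time[0])])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t_ms": self.time, "rate": self.rate})


def _binned_counts(
    timestamps: np.ndarray, align_times: np.ndarray, lo: int, hi: int
) -> np.ndarray:
    """Sum over alignment events of 1 ms spike counts on offsets [lo, hi)."""
    counts = np.zeros(hi - lo, dtype=np.int64)
    for a in align_times:
        i0 = np.searchsorted(timestamps, a + lo, side="left")
        i1 = np.searchsorted(timestamps, a + hi, side="left")
        offs = timestamps[i0:i1] - a - lo
        np.add.at(counts, offs.astype(np.intp), 1)
    return counts


def psth(
    train: SpikeTrain,
    align_times: Sequence[int],
    window: tuple[int, int],
    params: AnalysisParams = AnalysisParams(),
    smooth: bool = True,
) -> RateTrace:
    """Peri-stimulus time histogram.

    Spikes are binned at 1 ms relative to each alignment time; the per-bin
    rate is ``count / (n_trials * 0.001 s)``.  Smoothing uses a 10 ms SD
    Gaussian computed on a window extended by ``max(edge_trim, kernel half
    width)`` on each side and trimmed back to ``window``, which preserves the
    integral over the display to <1e-6.
    """
    align = np.asarray(align_times, dtype=np.int64)
    if align.size == 0:
        raise ValueError("psth requires at least one alignment time")
    w0, w1 = int(window[0]), int(window[1])
    if w1 <= w0:
        raise ValueError("empty psth window")
    pad = max(
        params.edge_trim,
        int(math.ceil(params.kernel_truncation_sds * params.psth_smooth_sd)),
    )
    counts = _binned_counts(train.timestamps, align, w0 - pad, w1 + pad)
    rate = counts * (1000.0 / align.size)
    if smooth:
        k = gaussian_kernel(params.psth_smooth_sd, params.kernel_truncation_sds)
        rate = np.convolve(rate, k, mode="same")
    rate = rate[pad : pad + (w1 - w0)]
    return RateTrace(
        time=np.arange(w0, w1, dtype=np.int64),
        rate=rate,
        n_trials=np.full(w1 - w0, align.size, dtype=np.int64),
    )


def population_psth(
    traces: Sequence[RateTrace], subtract_cell_mean: bool = False
) -> RateTrace:
    """Across-cell mean rate (and SEM) on a common grid.

    With ``subtract_cell_mean`` each cell's mean rate over the displayed
    window is removed first (the convention for displaying heterogeneous
    simple-spike populations around a common baseline).
    """
    if not traces:
        raise ValueError("population_psth needs at least one cell")
    grid = traces[0].time
    for tr in traces[1:]:
        if not np.array_equal(tr.time, grid):
            raise ValueError("cell rate traces are not on a common grid")
    mat = np.vstack([tr.rate for tr in traces]).astype(float)
    if subtract_cell_mean:
        mat = mat - np.nanmean(mat, axis=1, keepdims=True)
    mean = np.nanmean(mat, axis=0)
    if mat.shape[0] >= 2:
        sem = np.nanstd(mat, axis=0, ddof=1) / math.sqrt(mat.shape[0])
    else:
        warnings.warn("population SEM undefined with fewer than 2 cells")
        sem = np.full(grid.size, np.nan)
    return RateTrace(
        time=grid.copy(),
        rate=mean,
        n_trials=np.full(grid.size, mat.shape[0], dtype=np.int64),
        sem=sem,
    )


def window_counts(
    train: SpikeTrain,
    trials: Sequence[Trial],
    align: str = "cue",
    window: Optional[tuple[int, int]] = None,
    params: AnalysisParams = AnalysisParams(),
) -> pd.DataFrame:
    """Per-trial spike counts in a half-open window around an alignment event.

    Returns a frame with trial_id, reward, direction, speed and count.  Trials
    lacking the alignment event (e.g. failed trials aligned to reward) are
    skipped.
    """
    w0, w1 = window if window is not None else params.count_window
    ts = train.timestamps
    rows = {"trial_id": [], "reward": [], "direction": [], "speed": [], "count": []}
    for tr in trials:
        if align == "cue":
            a = tr.cue_onset
        elif align == "motion":
            a = tr.motion_onset
        elif align == "reward":
            if tr.reward_time is None:
                continue
            a = tr.reward_time
        else:
            raise ValueError(f"unknown alignment event {align!r}")
        c = int(
            np.searchsorted(ts, a + w1, side="left")
            - np.searchsorted(ts, a + w0, side="left")
        )
        rows["trial_id"].append(tr.trial_id)
        rows["reward"].append(tr.reward)
        rows["direction"].append(tr.direction)
        rows["speed"].append(tr.speed)
        rows["count"].append(c)
    return pd.DataFrame(rows)


def count_fractions(
    counts: pd.DataFrame, condition: Optional[str] = None
) -> dict:
    """Fraction of trials with exactly 0, 1, 2 or >=3 spikes in the window."""
    df = counts if condition is None else counts[counts["reward"] == condition]
    if len(df) == 0:
        raise ValueError("no trials for count fractions")
    c = df["count"].to_numpy()
    n = c.size
    return {
        0: float(np.mean(c == 0)),
        1: float(np.mean(c == 1)),
        2: float(np.mean(c == 2)),
        "3+": float(np.mean(c >= 3)),
    }


def peth(
    train: SpikeTrain,
    event_times: Sequence[int],
    halfwidth: Optional[int] = None,
    params: AnalysisParams = AnalysisParams(),
    smooth: bool = True,
) -> RateTrace:
    """Peri-event time histogram: PSTH semantics aligned to behavioral events,
    on the symmetric window [-halfwidth, +halfwidth]."""
    hw = params.peth_halfwidth if halfwidth is None else int(halfwidth)
    return psth(train, event_times, (-hw, hw + 1), params, smooth=smooth)


def event_contribution_psth(
    trials: Sequence[Trial],
    events_per_trial: Mapping[int, Sequence[int]],
    peth_trace: RateTrace,
    align: str = "cue",
    window: tuple[int, int] = (-400, 800),
    params: AnalysisParams = AnalysisParams(),
) -> dict[str, RateTrace]:
    """Predicted event-locked contribution to the aligned PSTH.

    For every trial a synthetic rate trace is built in which the rate around
    each event equals the event-triggered average (``peth_trace``, computed
    without separating reward conditions); times outside the PETH's span are
    missing.  Overlapping event copies are averaged, keeping the prediction in
    rate units.  The per-condition prediction is the missing-data-aware mean
    across trials, aligned to ``align``.
    """
    w0, w1 = window
    grid = np.arange(w0, w1)
    p0 = int(peth_trace.time[0])
    plen = peth_trace.time.size
    preds: dict[str, list[np.ndarray]] = {}
    for tr in trials:
        if align == "cue":
            a = tr.cue_onset
        elif align == "motion":
            a = tr.motion_onset
        elif align == "reward":
            if tr.reward_time is None:
                continue
            a = tr.reward_time
        else:
            raise ValueError(f"unknown alignment event {align!r}")
        acc = np.zeros(grid.size)
        cnt = np.zeros(grid.size)
        for ev in events_per_trial.get(tr.trial_id, ()):
            rel = int(ev) - a  # event time relative to alignment
            lo = max(rel + p0, w0)
            hi = min(rel + p0 + plen, w1)
            if hi <= lo:
                continue
            src0 = lo - (rel + p0)
            acc[lo - w0 : hi - w0] += peth_trace.rate[src0 : src0 + (hi - lo)]
            cnt[lo - w0 : hi - w0] += 1.0
        with np.errstate(invalid="ignore", divide="ignore"):
            pred = acc / cnt
        pred[cnt == 0] = np.nan
        preds.setdefault(tr.reward, []).append(pred)
    out = {}
    for cond, mats in preds.items():
        m = np.vstack(mats)
        n = np.sum(np.isfinite(m), axis=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mean = np.nanmean(m, axis=0)
        mean[n == 0] = np.nan
        out[cond] = RateTrace(time=grid.copy(), rate=mean, n_trials=n)
    return out


def cspk_triggered_ccg(
    cspk: SpikeTrain,
    sspk: SpikeTrain,
    trial_bounds: Sequence[tuple[int, int]],
    halfwidth: int = 100,
    params: AnalysisParams = AnalysisParams(),
    smooth: bool = False,
) -> RateTrace:
    """Simple-spike rate aligned to complex-spike events.

    Triggers are complex spikes at least ``params.ccg_edge_exclusion`` ms away
    from both edges of a trial; inter-trial complex spikes never trigger.
    Simple spikes within ``params.ccg_blank`` (default [-1, +2]) ms of any
    complex spike are excluded before alignment, mirroring the removal of
    spikelet contamination.  Returned unsmoothed by default so the blanking
    window and any post-complex-spike pause stay visible at 1 ms resolution.
    """
    c = cspk.timestamps
    ex = int(params.ccg_edge_exclusion)
    trig_mask = np.zeros(c.size, dtype=bool)
    for lo, hi in trial_bounds:
        trig_mask |= (c >= lo + ex) & (c <= hi - ex)
    triggers = c[trig_mask]
    if triggers.size == 0:
        raise ValueError("no valid CCG triggers inside trial bounds")
    s = sspk.timestamps
    b0, b1 = params.ccg_blank
    # distance from each Sspk to the surrounding Cspks
    idx = np.searchsorted(c, s)
    prev = np.where(idx > 0, s - c[np.clip(idx - 1, 0, None)], np.iinfo(np.int64).max)
    nxt = np.where(idx < c.size, c[np.clip(idx, None, c.size - 1)] - s, np.iinfo(np.int64).max)
    # blank s if s - c in [b0, b1] for some c:  prev in [0, b1]  or  nxt in [0, -b0]
    blanked = (prev <= b1) | (nxt <= -b0)
    clean = SpikeTrain(s[~blanked], sspk.spike_class)
    return psth(clean, triggers, (-halfwidth, halfwidth + 1), params, smooth=smooth)
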