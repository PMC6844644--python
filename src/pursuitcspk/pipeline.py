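"""End-to-end orchestration: simulate or load a session, run the behavioral
and spike-train analyses in the order of the study (behavior, cue, delivery,
tuning, Cspk/Sspk interaction), and write a reproducible report.

The report is deterministic given the configuration and master seed: every
stochastic step (simulation, permutation test, shuffles) draws from a named
child stream of the master seed, and no timestamps enter the output.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import __version__
from .data_model import (
    AnalysisParams,
    REWARD_LARGE,
    REWARD_SMALL,
    Session,
    read_session,
    select_trials,
    validate_session,
    write_session,
)
from .kinematics import detect_saccades, differentiate, pupil_drift_correction, session_mean_speed
from .spiketrains import window_counts
from .synthetic import SimConfig, child_rng, simulate_session
from .tuning_stats import (
    CellClassification,
    classify_cue_discrimination,
    direction_tuning,
    discrimination_timecourse,
    is_directionally_tuned,
    modulation_correlation,
    preferred_direction,
    reward_tuning_permutation_test,
    rotate_to_pd,
    shuffle_controls,
    signal_correlation,
    tuning_counts_by_level,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "AnalysisReport", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Exactly one of ``input_path`` (a stored session) or ``sim`` is given."""

    input_path: Optional[str] = None
    input_format: str = "tabular"
    sim: Optional[SimConfig] = None
    params: AnalysisParams = field(default_factory=AnalysisParams)
    out_dir: Optional[str] = None
    master_seed: int = 0
    n_perm: int = 2000
    figures: bool = False
    timecourse_step: int = 100
    timecourse_span: tuple[int, int] = (-400, 800)

    def validate(self):
        if (self.input_path is None) == (self.sim is None):
            raise ValueError("give exactly one of input_path or sim")


@dataclass
class AnalysisReport:
    cells: pd.DataFrame
    population: dict
    behavior: dict
    timecourse: pd.DataFrame
    provenance: dict

    def to_dict(self) -> dict:
        return {
            "behavior": self.behavior,
            "population": self.population,
            "provenance": self.provenance,
        }


def _config_hash(cfg: PipelineConfig) -> str:
    def default(o):
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        if isinstance(o, (np.integer, np.floating)):
            return float(o)
        if isinstance(o, tuple):
            return list(o)
        return str(o)

    d = dataclasses.asdict(cfg)
    for key in ("out_dir", "figures"):  # output destination does not change results
        d.pop(key, None)
    blob = json.dumps(d, default=default, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _mean_rate(counts: pd.DataFrame, reward: str, window) -> float:
    sub = counts.loc[counts.reward == reward, "count"]
    if len(sub) == 0:
        return float("nan")
    return float(sub.mean() * 1000.0 / (window[1] - window[0]))


def run_pipeline(cfg: PipelineConfig) -> AnalysisReport:
    cfg.validate()
    params = cfg.params
    # ---- stage: data -----------------------------------------------------
    try:
        if cfg.sim is not None:
            session = simulate_session(cfg.sim)
        else:
            session = read_session(cfg.input_path, format=cfg.input_format)
    except Exception as exc:
        raise RuntimeError(f"stage 'data' failed: {exc}") from exc
    problems = validate_session(session)
    if problems:
        raise RuntimeError(f"stage 'data' failed: invalid session: {problems[:3]}")
    trials = select_trials(session)  # successful trials only
    n_excluded = len(session.trials) - len(trials)
    logger.info("stage=data trials=%d excluded_failed=%d cells=%d",
                len(trials), n_excluded, len(session.cells))

    # ---- stage: behavior ---------------------------------------------------
    try:
        vel = differentiate(session.eye, params)
        saccades = detect_saccades(session.eye, session.trials, session.task, params, vel)
        behavior = {}
        for cond in (REWARD_LARGE, REWARD_SMALL):
            behavior[f"mean_speed_{cond}_dps"] = session_mean_speed(
                session, cond, params=params, events=saccades, vel=vel
            )
        _, drift_fit = pupil_drift_correction(session.eye, trials)
        behavior["drift_r2_h"] = drift_fit["h"]["r2"]
        behavior["drift_r2_v"] = drift_fit["v"]["r2"]
        behavior["n_saccades_detected"] = len(saccades)
    except Exception as exc:
        raise RuntimeError(f"stage 'behavior' failed: {exc}") from exc

    # ---- stage: per-cell statistics ---------------------------------------
    try:
        rows = []
        cspk_curves_by_cond: dict[str, dict[str, np.ndarray]] = {"large": {}, "small": {}}
        cspk_pds: dict[str, float] = {}
        sig_corrs: dict[str, float] = {}
        cspk_curves_for_shuffle = {}
        sspk_aligned = {}
        for cell in session.cells:
            cue_cls = classify_cue_discrimination(cell, trials, params)
            cue_counts = window_counts(cell.cspk, trials, "cue", params.count_window, params)
            del_counts = window_counts(cell.cspk, trials, "reward", params.count_window, params)
            sspk_cue = window_counts(cell.sspk, trials, "cue", params.count_window, params)
            sspk_pre = window_counts(
                cell.sspk, trials, "cue",
                (-params.count_window[1], -params.count_window[0]), params,
            )
            w = params.count_window
            row = {
                "cell_id": cell.cell_id,
                "cue_p": cue_cls.cue_p,
                "cue_sign": cue_cls.cue_sign,
                "cue_discriminating": cue_cls.cue_discriminating,
                "excluded_reason": cue_cls.excluded_reason,
                "cspk_cue_rate_large": _mean_rate(cue_counts, REWARD_LARGE, w),
                "cspk_cue_rate_small": _mean_rate(cue_counts, REWARD_SMALL, w),
                "cspk_delivery_rate_large": _mean_rate(del_counts, REWARD_LARGE, w),
                "cspk_delivery_rate_small": _mean_rate(del_counts, REWARD_SMALL, w),
                "sspk_cue_rate_large": _mean_rate(sspk_cue, REWARD_LARGE, w),
                "sspk_cue_rate_small": _mean_rate(sspk_cue, REWARD_SMALL, w),
                "sspk_precue_rate": float(
                    sspk_pre["count"].mean() * 1000.0 / (w[1] - w[0])
                ) if len(sspk_pre) else float("nan"),
            }
            # delivery discrimination (same rank-sum criterion at reward time)
            dl = del_counts.loc[del_counts.reward == REWARD_LARGE, "count"].to_numpy()
            ds = del_counts.loc[del_counts.reward == REWARD_SMALL, "count"].to_numpy()
            if dl.size and ds.size and len(trials) >= params.min_trials_reward:
                from .tuning_stats import rank_sum_test

                row["delivery_p"] = rank_sum_test(dl, ds).p_value
            else:
                row["delivery_p"] = float("nan")

            # direction tuning of both spike classes
            if len(trials) >= params.min_trials_factorial:
                for label, train in (("cspk", cell.cspk), ("sspk", cell.sspk)):
                    by_level = tuning_counts_by_level(train, trials, params)
                    test = is_directionally_tuned(by_level, params)
                    curve = direction_tuning(train, trials, params=params)
                    row[f"{label}_tuned_p"] = test.p_value
                    tuned = test.p_value < params.alpha
                    row[f"{label}_tuned"] = tuned
                    if tuned:
                        try:
                            row[f"{label}_pd"] = preferred_direction(curve)
                        except ValueError:
                            row[f"{label}_pd"] = float("nan")
                    if label == "cspk":
                        cspk_curve_all = curve
                    else:
                        sspk_curve_all = curve
                # reward-split Cspk curves for the permutation test (tuned cells)
                if row.get("cspk_tuned") and np.isfinite(row.get("cspk_pd", np.nan)):
                    pd_deg = row["cspk_pd"]
                    cspk_pds[cell.cell_id] = pd_deg
                    for cond, key in ((REWARD_LARGE, "large"), (REWARD_SMALL, "small")):
                        ctr = [t for t in trials if t.reward == cond]
                        curve_c = direction_tuning(cell.cspk, ctr, params=params)
                        cspk_curves_by_cond[key][cell.cell_id] = rotate_to_pd(curve_c, pd_deg)
                # Cspk/Sspk signal correlation for Sspk-tuned cells
                if row.get("sspk_tuned") and np.isfinite(row.get("sspk_pd", np.nan)):
                    r = signal_correlation(cspk_curve_all, sspk_curve_all)
                    if np.isfinite(r):
                        sig_corrs[cell.cell_id] = r
                        cspk_curves_for_shuffle[cell.cell_id] = cspk_curve_all.mean_rate
                        sspk_aligned[cell.cell_id] = rotate_to_pd(
                            sspk_curve_all, row["sspk_pd"]
                        )
            rows.append(row)
        cells_df = pd.DataFrame(rows)
    except Exception as exc:
        raise RuntimeError(f"stage 'cells' failed: {exc}") from exc

    # ---- stage: population statistics -------------------------------------
    try:
        population: dict = {"n_cells": len(session.cells)}
        ok = cells_df[cells_df["excluded_reason"].isna()]
        population["n_cells_included"] = int(len(ok))
        population["n_cue_discriminating"] = int(ok["cue_discriminating"].sum())
        population["frac_cue_discriminating"] = (
            float(ok["cue_discriminating"].mean()) if len(ok) else float("nan")
        )
        signs = ok.loc[ok.cue_discriminating, "cue_sign"]
        population["n_cue_large_gt_small"] = int((signs == "large>small").sum())

        def paired_p(a, b):
            d = ok[a].to_numpy() - ok[b].to_numpy()
            d = d[np.isfinite(d)]
            if d.size < 6 or np.all(d == 0):
                return float("nan")
            return float(sps.wilcoxon(d).pvalue)

        population["cue_effect_p"] = paired_p("cspk_cue_rate_large", "cspk_cue_rate_small")
        population["delivery_effect_p"] = paired_p(
            "cspk_delivery_rate_large", "cspk_delivery_rate_small"
        )

        # reward effect on direction tuning: label permutation on tuned cells
        ids = sorted(cspk_curves_by_cond["large"].keys())
        if len(ids) >= 3:
            L = np.vstack([cspk_curves_by_cond["large"][i] for i in ids])
            S = np.vstack([cspk_curves_by_cond["small"][i] for i in ids])
            perm = reward_tuning_permutation_test(
                L, S, n_perm=cfg.n_perm, rng=child_rng(cfg.master_seed, 20)
            )
            population["tuning_permutation_p"] = perm.p_value
            population["tuning_permutation_stat"] = perm.statistic
            population["n_cspk_tuned"] = len(ids)
        else:
            population["tuning_permutation_p"] = float("nan")
            population["n_cspk_tuned"] = len(ids)

        # movement-epoch signal correlations and shuffle controls
        rs = np.array([sig_corrs[i] for i in sorted(sig_corrs)])
        population["n_signal_correlation"] = int(rs.size)
        population["median_signal_correlation"] = (
            float(np.median(rs)) if rs.size else float("nan")
        )
        if len(cspk_curves_for_shuffle) >= 3:
            ids2 = sorted(cspk_curves_for_shuffle)
            cmat = np.vstack([cspk_curves_for_shuffle[i] for i in ids2])
            smat = np.vstack([sspk_aligned[i] for i in ids2])  # fixed Sspk side
            rng_sh = child_rng(cfg.master_seed, 21)
            for mode in ("phase", "direction"):
                sh = shuffle_controls(cmat, mode, rng_sh)
                rr = []
                for i in range(sh.shape[0]):
                    a, b = sh[i], smat[i]
                    if np.ptp(a) > 0 and np.ptp(b) > 0:
                        rr.append(np.corrcoef(a, b)[0, 1])
                population[f"median_signal_correlation_{mode}_shuffle"] = (
                    float(np.median(rr)) if rr else float("nan")
                )

        # cue-period Cspk vs Sspk modulation correlations
        dx = ok["cspk_cue_rate_large"].to_numpy() - ok["cspk_cue_rate_small"].to_numpy()
        dy = ok["sspk_cue_rate_large"].to_numpy() - ok["sspk_cue_rate_small"].to_numpy()
        sspk_post = 0.5 * (
            ok["sspk_cue_rate_large"].to_numpy() + ok["sspk_cue_rate_small"].to_numpy()
        )
        dz = sspk_post - ok["sspk_precue_rate"].to_numpy()
        disc = ok["cue_discriminating"].to_numpy(dtype=bool)
        for name, yv in (("sspk_reward_diff", dy), ("sspk_cue_change", dz)):
            m = np.isfinite(dx) & np.isfinite(yv)
            if m.sum() >= 3:
                res = modulation_correlation(dx[m], yv[m])
                population[f"modulation_corr_{name}_r"] = res.statistic
                population[f"modulation_corr_{name}_p"] = res.p_value
            md = m & disc
            if md.sum() >= 3:
                res = modulation_correlation(dx[md], yv[md])
                population[f"modulation_corr_{name}_disc_r"] = res.statistic
                population[f"modulation_corr_{name}_disc_p"] = res.p_value
    except Exception as exc:
        raise RuntimeError(f"stage 'population' failed: {exc}") from exc

    # ---- stage: Sspk discrimination timecourse -----------------------------
    try:
        t0, t1 = cfg.timecourse_span
        times = np.arange(t0, t1 + 1, cfg.timecourse_step)
        timecourse = discrimination_timecourse(
            session.cells, trials, times, align="cue", params=params
        )
    except Exception as exc:
        raise RuntimeError(f"stage 'timecourse' failed: {exc}") from exc

    provenance = {
        "package_version": __version__,
        "master_seed": cfg.master_seed,
        "n_perm": cfg.n_perm,
        "config_hash": _config_hash(cfg),
        "n_trials_total": len(session.trials),
        "n_trials_successful": len(trials),
    }
    report = AnalysisReport(
        cells=cells_df,
        population=population,
        behavior=behavior,
        timecourse=timecourse,
        provenance=provenance,
    )
    if cfg.out_dir is not None:
        _write_report(report, Path(cfg.out_dir), cfg, session)
    return report


def _round_floats(obj, ndigits=10):
    if isinstance(obj, float):
        return None if np.isnan(obj) else round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def _write_report(report: AnalysisReport, out: Path, cfg: PipelineConfig, session: Session):
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "report.json", "w") as fh:
        json.dump(_round_floats(report.to_dict()), fh, indent=2, sort_keys=True,
                  default=lambda o: None if (isinstance(o, float) and np.isnan(o)) else str(o))
        fh.write("\n")
    report.cells.to_csv(out / "cells.csv", index=False)
    report.timecourse.to_csv(out / "timecourse.csv", index=False)
    if cfg.figures:
        _write_figures(report, out, session, cfg.params)


def _write_figures(report: AnalysisReport, out: Path, session: Session, params: AnalysisParams):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .spiketrains import population_psth, psth
    from .data_model import select_trials

    trials = select_trials(session)
    fig, axes = plt.subplots(1, 3, figsize=(13, 3.5))
    for cond, color in ((REWARD_LARGE, "tab:blue"), (REWARD_SMALL, "tab:red")):
        sub = [t.cue_onset for t in trials if t.reward == cond]
        traces = [psth(c.cspk, sub, (-400, 800), params) for c in session.cells]
        pop = population_psth(traces)
        axes[0].plot(pop.time, pop.rate, color=color, label=cond)
        dsub = [t.reward_time for t in trials if t.reward == cond and t.reward_time]
        traces = [psth(c.cspk, dsub, (-400, 800), params) for c in session.cells]
        pop = population_psth(traces)
        axes[1].plot(pop.time, pop.rate, color=color, label=cond)
    axes[0].set_title("Cspk population PSTH at cue")
    axes[1].set_title("Cspk population PSTH at delivery")
    for ax in axes[:2]:
        ax.set_xlabel("time (ms)")
        ax.set_ylabel("rate (spikes/s)")
        ax.legend()
    tc = report.timecourse
    axes[2].plot(tc.t_ms, tc.frac_large_gt_small, "tab:blue", label="RL>RS")
    axes[2].plot(tc.t_ms, tc.frac_small_gt_large, "tab:red", label="RS>RL")
    axes[2].axhline(float(tc.chance_level.iloc[0]), ls="--", c="k")
    axes[2].set_title("Sspk discrimination timecourse")
    axes[2].set_xlabel("time from cue (ms)")
    axes[2].legend()
    fig.tight_layout()
    fig.savefig(out / "summary.png", dpi=110)
    plt.close(fig)
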