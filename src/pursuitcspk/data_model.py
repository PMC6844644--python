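"""Domain types and session I/O for reward-cued smooth-pursuit recordings.

A *session* is one recording day: a sequence of trials of the direction (or
speed) task, one or more simultaneously recorded Purkinje cells with separate
complex-spike (Cspk) and simple-spike (Sspk) timestamp trains, a 1 kHz eye
trace with pupil size, and lick events.

All times live on a single session clock in integer milliseconds; per-trial
analyses re-align by subtracting the alignment event time.  Trials carry
absolute event times rather than pre-cut spike segments so that analyses that
span trial boundaries (cross-correlograms, event-triggered averages) can see
the raw trains.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "TaskConfig",
    "Trial",
    "SpikeTrain",
    "EyeTrace",
    "CellRecording",
    "SaccadeEvent",
    "Session",
    "AnalysisParams",
    "ValidationError",
    "read_session",
    "write_session",
    "validate_session",
    "select_trials",
    "sessions_equal",
]

REWARD_LARGE = "large"
REWARD_SMALL = "small"
REWARD_CONDITIONS = (REWARD_LARGE, REWARD_SMALL)

CSPK = "Cspk"
SSPK = "Sspk"
SPIKE_CLASSES = (CSPK, SSPK)


class ValidationError(ValueError):
    """Raised when a session (or file) violates the documented invariants."""

    def __init__(self, violations: Sequence[str]):
        self.violations = list(violations)
        super().__init__("; ".join(self.violations))


@dataclass(frozen=True)
class TaskConfig:
    """Timing and geometry of the step-ramp pursuit task.

    Defaults describe the direction task: eight target directions, 20 °/s
    ramps preceded by a 4° step opposite the motion direction, 500 ms
    fixation, a variable 800-1200 ms cue delay, 750 ms of target motion and a
    500-700 ms still period before reward.  The speed task keeps the same
    temporal structure with speeds {5, 10, 20} °/s and steps chosen so the
    ramp re-crosses the center 200 ms after motion onset (1°, 2°, 4°).
    """

    directions: tuple[float, ...] = (0.0, 45.0, 90.0, 135.0, 180.0, 225.0, 270.0, 315.0)
    target_speeds: tuple[float, ...] = (20.0,)
    step_sizes: Mapping[float, float] = field(
        default_factory=lambda: {20.0: 4.0, 10.0: 2.0, 5.0: 1.0}
    )
    fixation_duration: int = 500
    cue_delay_range: tuple[int, int] = (800, 1200)
    motion_duration: int = 750
    post_motion_range: tuple[int, int] = (500, 700)
    reward_sizes: Mapping[str, float] = field(
        default_factory=lambda: {REWARD_LARGE: 0.2, REWARD_SMALL: 0.05}
    )
    # Cue-color mapping is metadata only; analyses never read it.
    reward_colors: Mapping[str, str] = field(
        default_factory=lambda: {REWARD_LARGE: "blue", REWARD_SMALL: "red"}
    )
    eye_sample_rate: int = 1000

    def validate(self) -> list[str]:
        out = []
        dirs = list(self.directions)
        if len(set(dirs)) != len(dirs):
            out.append("task.directions contains duplicates")
        for d in dirs:
            if not (0.0 <= d < 360.0):
                out.append(f"task.direction {d} outside [0, 360)")
        if self.cue_delay_range[1] < self.cue_delay_range[0]:
            out.append("task.cue_delay_range empty")
        if self.post_motion_range[1] < self.post_motion_range[0]:
            out.append("task.post_motion_range empty")
        for s in self.target_speeds:
            if s not in self.step_sizes:
                out.append(f"task.target_speed {s} has no step size")
        return out


@dataclass(frozen=True)
class Trial:
    """One trial: reward condition, target kinematics and aligned event times.

    ``reward_time`` is absent (None) on failed trials; ``trial_end`` marks the
    end of the post-motion still period and doubles as the trial boundary for
    analyses that need one (e.g. cross-correlogram trigger exclusion).
    """

    trial_id: int
    reward: str
    direction: float
    speed: float
    cue_onset: int
    motion_onset: int
    reward_time: Optional[int]
    success: bool
    trial_end: Optional[int] = None

    def end(self, task: TaskConfig) -> int:
        if self.trial_end is not None:
            return int(self.trial_end)
        if self.reward_time is not None:
            return int(self.reward_time)
        return int(self.motion_onset + task.motion_duration + task.post_motion_range[1])

    def start(self, task: TaskConfig) -> int:
        """Fixation onset (trial start) on the session clock."""
        return int(self.cue_onset - task.fixation_duration)


@dataclass(frozen=True)
class SpikeTrain:
    """Strictly increasing integer-millisecond timestamps of one spike class."""

    timestamps: np.ndarray  # int64, ms on the session clock
    spike_class: str

    def __post_init__(self):
        object.__setattr__(
            self, "timestamps", np.asarray(self.timestamps, dtype=np.int64)
        )

    def __len__(self) -> int:
        return int(self.timestamps.size)


@dataclass
class EyeTrace:
    """1 kHz eye position (degrees), pupil size and a per-sample validity mask."""

    time: np.ndarray  # int64 ms, uniform 1 ms grid
    h_position: np.ndarray
    v_position: np.ndarray
    pupil: np.ndarray
    valid_mask: np.ndarray  # bool

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=np.int64)
        self.h_position = np.asarray(self.h_position, dtype=np.float64)
        self.v_position = np.asarray(self.v_position, dtype=np.float64)
        self.pupil = np.asarray(self.pupil, dtype=np.float64)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)

    def __len__(self) -> int:
        return int(self.time.size)

    def index_of(self, t_ms: int) -> int:
        return int(t_ms - self.time[0])


@dataclass
class CellRecording:
    """Cspk and Sspk trains of one Purkinje cell over its recording span."""

    cell_id: str
    monkey_id: str
    cspk: SpikeTrain
    sspk: SpikeTrain
    trial_ids: tuple[int, ...]
    recording_bounds: tuple[int, int]


@dataclass(frozen=True)
class SaccadeEvent:
    """A saccade (or microsaccade): onset/offset on the session clock."""

    onset_ms: int
    offset_ms: int
    peak_velocity: float
    epoch: str  # {"fixation", "pursuit"}


@dataclass
class Session:
    """One recording day: task, trials, cells, eye trace and lick events."""

    task: TaskConfig
    trials: list[Trial]
    cells: list[CellRecording]
    eye: EyeTrace
    licks: np.ndarray  # (n, 2) int64 onset/offset ms; may be empty
    saccades: Optional[list[SaccadeEvent]] = None

    def __post_init__(self):
        self.licks = np.asarray(self.licks, dtype=np.int64).reshape(-1, 2)

    def cell(self, cell_id: str) -> CellRecording:
        for c in self.cells:
            if c.cell_id == cell_id:
                return c
        raise KeyError(f"no cell {cell_id!r} in session")


@dataclass(frozen=True)
class AnalysisParams:
    """Analysis constants: window edges, kernel widths, trial-count floors.

    Windows are half-open ``[start, end)`` in ms relative to the alignment
    event.  ``count_window`` is the 100-300 ms post-event window used both for
    cue/delivery spike counts and for tuning curves after motion onset.
    """

    count_window: tuple[int, int] = (100, 300)
    psth_bin: int = 1
    psth_smooth_sd: float = 10.0
    edge_trim: int = 100
    velocity_smooth_sd: float = 5.0
    moving_bin: int = 200
    peth_halfwidth: int = 300
    ccg_edge_exclusion: int = 100
    ccg_blank: tuple[int, int] = (-1, 2)
    alpha: float = 0.05
    min_trials_reward: int = 20
    min_trials_factorial: int = 50
    behavior_readout_time: int = 250
    kernel_truncation_sds: float = 6.0
    saccade_accel_threshold: float = 1000.0
    saccade_fixation_speed: float = 15.0
    saccade_pursuit_speed: float = 50.0
    saccade_merge_gap: int = 10
    saccade_pad: int = 5
    pursuit_epoch_pad: int = 200

    def validate(self) -> list[str]:
        out = []
        for name in ("psth_bin", "psth_smooth_sd", "edge_trim", "moving_bin",
                     "peth_halfwidth", "ccg_edge_exclusion"):
            if getattr(self, name) <= 0:
                out.append(f"params.{name} must be positive")
        if self.count_window[1] <= self.count_window[0]:
            out.append("params.count_window empty")
        return out


# ---------------------------------------------------------------------------
# validation

def validate_session(session: Session) -> list[str]:
    """Check every documented invariant; return all violations, never raise."""
    out: list[str] = []
    try:
        out.extend(session.task.validate())
        dirs = set(float(d) for d in session.task.directions)
        seen_ids = set()
        for tr in session.trials:
            if tr.trial_id in seen_ids:
                out.append(f"trial {tr.trial_id}: duplicate trial_id")
            seen_ids.add(tr.trial_id)
            if tr.reward not in REWARD_CONDITIONS:
                out.append(f"trial {tr.trial_id}: unknown reward {tr.reward!r}")
            if float(tr.direction) not in dirs:
                out.append(
                    f"trial {tr.trial_id}: direction {tr.direction} not a task direction"
                )
            if not (tr.cue_onset < tr.motion_onset):
                out.append(f"trial {tr.trial_id}: cue_onset >= motion_onset")
            if tr.reward_time is not None and not (tr.motion_onset < tr.reward_time):
                out.append(f"trial {tr.trial_id}: motion_onset >= reward_time")
            if session.eye is not None and len(session.eye):
                t0, t1 = int(session.eye.time[0]), int(session.eye.time[-1])
                end = tr.end(session.task)
                if tr.start(session.task) < t0 or end > t1:
                    out.append(
                        f"trial {tr.trial_id}: events outside eye-trace span"
                    )
        if session.eye is not None and len(session.eye):
            e = session.eye
            n = len(e.time)
            for name in ("h_position", "v_position", "pupil", "valid_mask"):
                if len(getattr(e, name)) != n:
                    out.append(f"eye.{name} length differs from eye.time")
            if n > 1 and not np.all(np.diff(e.time) == 1):
                out.append("eye.time is not a uniform 1 ms grid")
        for cell in session.cells:
            for train in (cell.cspk, cell.sspk):
                ts = train.timestamps
                if ts.size:
                    bad = np.nonzero(np.diff(ts) <= 0)[0]
                    for i in bad[:5]:
                        out.append(
                            f"cell {cell.cell_id} {train.spike_class}: timestamps not "
                            f"strictly increasing at index {int(i) + 1}"
                        )
                    lo, hi = cell.recording_bounds
                    if ts[0] < lo or ts[-1] > hi:
                        out.append(
                            f"cell {cell.cell_id} {train.spike_class}: spikes outside "
                            "recording bounds"
                        )
        if session.licks.size:
            if np.any(session.licks[:, 1] < session.licks[:, 0]):
                out.append("lick offset precedes onset")
    except Exception as exc:  # totality: malformed input reports, never raises
        out.append(f"validation aborted: {exc!r}")
    return out


def select_trials(
    session: Session,
    reward: Optional[str] = None,
    direction: Optional[float] = None,
    speed: Optional[float] = None,
    success_only: bool = True,
) -> list[Trial]:
    """Order-preserving conjunction of trial filters.

    Failed trials are excluded by default; reward delivery is undefined on
    them, so only analyses that explicitly opt in see them.
    """
    if reward is not None and reward not in REWARD_CONDITIONS:
        raise ValueError(f"unknown reward condition {reward!r}")
    if direction is not None and float(direction) not in {
        float(d) for d in session.task.directions
    }:
        raise ValueError(f"unknown direction {direction!r}")
    if speed is not None and float(speed) not in {
        float(s) for s in session.task.target_speeds
    }:
        raise ValueError(f"unknown speed {speed!r}")
    out = []
    for tr in session.trials:
        if success_only and not tr.success:
            continue
        if reward is not None and tr.reward != reward:
            continue
        if direction is not None and float(tr.direction) != float(direction):
            continue
        if speed is not None and float(tr.speed) != float(speed):
            continue
        out.append(tr)
    return out


# ---------------------------------------------------------------------------
# on-disk layouts
#
# Tabular: a directory of plain-text files
#   trials.csv   trial_id, reward, direction_deg, speed_dps, cue_on_ms,
#                motion_on_ms, reward_ms, success, trial_end_ms
#   spikes_<cell>_<class>.csv   timestamp_ms
#   eye.csv      t_ms, h_deg, v_deg, pupil, valid
#   licks.csv    onset_ms, offset_ms
#   saccades.csv onset_ms, offset_ms, peak_velocity, epoch     (optional)
#   task.yaml    TaskConfig fields plus per-cell metadata
#
# HDF: one .h5 file with the same field names under /trials, /cells/<id>,
# /eye, /licks and task attributes.

def _task_to_dict(task: TaskConfig) -> dict:
    return {
        "directions": [float(d) for d in task.directions],
        "target_speeds": [float(s) for s in task.target_speeds],
        "step_sizes": {float(k): float(v) for k, v in task.step_sizes.items()},
        "fixation_duration": int(task.fixation_duration),
        "cue_delay_range": [int(task.cue_delay_range[0]), int(task.cue_delay_range[1])],
        "motion_duration": int(task.motion_duration),
        "post_motion_range": [
            int(task.post_motion_range[0]),
            int(task.post_motion_range[1]),
        ],
        "reward_sizes": {str(k): float(v) for k, v in task.reward_sizes.items()},
        "reward_colors": {str(k): str(v) for k, v in task.reward_colors.items()},
        "eye_sample_rate": int(task.eye_sample_rate),
    }


def _task_from_dict(d: dict) -> TaskConfig:
    return TaskConfig(
        directions=tuple(float(x) for x in d["directions"]),
        target_speeds=tuple(float(x) for x in d["target_speeds"]),
        step_sizes={float(k): float(v) for k, v in d["step_sizes"].items()},
        fixation_duration=int(d["fixation_duration"]),
        cue_delay_range=tuple(int(x) for x in d["cue_delay_range"]),
        motion_duration=int(d["motion_duration"]),
        post_motion_range=tuple(int(x) for x in d["post_motion_range"]),
        reward_sizes={str(k): float(v) for k, v in d["reward_sizes"].items()},
        reward_colors={str(k): str(v) for k, v in d.get("reward_colors", {}).items()}
        or {REWARD_LARGE: "blue", REWARD_SMALL: "red"},
        eye_sample_rate=int(d["eye_sample_rate"]),
    )


def _trials_frame(trials: Sequence[Trial]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "trial_id": [t.trial_id for t in trials],
            "reward": [t.reward for t in trials],
            "direction_deg": [t.direction for t in trials],
            "speed_dps": [t.speed for t in trials],
            "cue_on_ms": [t.cue_onset for t in trials],
            "motion_on_ms": [t.motion_onset for t in trials],
            "reward_ms": [
                (np.nan if t.reward_time is None else t.reward_time) for t in trials
            ],
            "success": [int(t.success) for t in trials],
            "trial_end_ms": [
                (np.nan if t.trial_end is None else t.trial_end) for t in trials
            ],
        }
    )


def _trials_from_frame(df: pd.DataFrame) -> list[Trial]:
    out = []
    for row in df.itertuples(index=False):
        out.append(
            Trial(
                trial_id=int(row.trial_id),
                reward=str(row.reward),
                direction=float(row.direction_deg),
                speed=float(row.speed_dps),
                cue_onset=int(row.cue_on_ms),
                motion_onset=int(row.motion_on_ms),
                reward_time=None if pd.isna(row.reward_ms) else int(row.reward_ms),
                success=bool(int(row.success)),
                trial_end=None if pd.isna(row.trial_end_ms) else int(row.trial_end_ms),
            )
        )
    return out


def write_session(session: Session, path, format: str = "tabular") -> None:
    """Write a session in the tabular (directory of CSVs) or hdf layout."""
    path = Path(path)
    if format == "tabular":
        path.mkdir(parents=True, exist_ok=True)
        _trials_frame(session.trials).to_csv(path / "trials.csv", index=False)
        meta = _task_to_dict(session.task)
        meta["cells"] = [
            {
                "cell_id": c.cell_id,
                "monkey_id": c.monkey_id,
                "trial_ids": [int(i) for i in c.trial_ids],
                "recording_bounds": [int(c.recording_bounds[0]), int(c.recording_bounds[1])],
            }
            for c in session.cells
        ]
        with open(path / "task.yaml", "w") as fh:
            yaml.safe_dump(meta, fh, sort_keys=False)
        for c in session.cells:
            for train in (c.cspk, c.sspk):
                pd.DataFrame({"timestamp_ms": train.timestamps}).to_csv(
                    path / f"spikes_{c.cell_id}_{train.spike_class}.csv", index=False
                )
        e = session.eye
        pd.DataFrame(
            {
                "t_ms": e.time,
                "h_deg": e.h_position,
                "v_deg": e.v_position,
                "pupil": e.pupil,
                "valid": e.valid_mask.astype(int),
            }
        ).to_csv(path / "eye.csv", index=False, float_format="%.17g")
        pd.DataFrame(
            {"onset_ms": session.licks[:, 0], "offset_ms": session.licks[:, 1]}
        ).to_csv(path / "licks.csv", index=False)
        if session.saccades is not None:
            pd.DataFrame(
                {
                    "onset_ms": [s.onset_ms for s in session.saccades],
                    "offset_ms": [s.offset_ms for s in session.saccades],
                    "peak_velocity": [s.peak_velocity for s in session.saccades],
                    "epoch": [s.epoch for s in session.saccades],
                }
            ).to_csv(path / "saccades.csv", index=False, float_format="%.17g")
    elif format == "hdf":
        import h5py

        with h5py.File(path, "w") as f:
            f.attrs["task"] = yaml.safe_dump(_task_to_dict(session.task))
            tg = f.create_group("trials")
            df = _trials_frame(session.trials)
            for col in df.columns:
                if col == "reward":
                    tg.create_dataset(
                        col, data=np.array(df[col], dtype=h5py.string_dtype())
                    )
                else:
                    tg.create_dataset(col, data=df[col].to_numpy())
            cg = f.create_group("cells")
            for c in session.cells:
                g = cg.create_group(c.cell_id)
                g.attrs["monkey_id"] = c.monkey_id
                g.attrs["recording_bounds"] = list(c.recording_bounds)
                g.create_dataset("trial_ids", data=np.asarray(c.trial_ids, dtype=np.int64))
                g.create_dataset("cspk", data=c.cspk.timestamps)
                g.create_dataset("sspk", data=c.sspk.timestamps)
            eg = f.create_group("eye")
            eg.create_dataset("t_ms", data=session.eye.time)
            eg.create_dataset("h_deg", data=session.eye.h_position)
            eg.create_dataset("v_deg", data=session.eye.v_position)
            eg.create_dataset("pupil", data=session.eye.pupil)
            eg.create_dataset("valid", data=session.eye.valid_mask)
            f.create_dataset("licks", data=session.licks)
            if session.saccades is not None:
                sg = f.create_group("saccades")
                sg.create_dataset(
                    "onset_ms", data=np.array([s.onset_ms for s in session.saccades])
                )
                sg.create_dataset(
                    "offset_ms", data=np.array([s.offset_ms for s in session.saccades])
                )
                sg.create_dataset(
                    "peak_velocity",
                    data=np.array([s.peak_velocity for s in session.saccades]),
                )
                sg.create_dataset(
                    "epoch",
                    data=np.array(
                        [s.epoch for s in session.saccades], dtype=h5py.string_dtype()
                    ),
                )
    else:
        raise ValueError(f"unknown format {format!r}")


def read_session(path, format: str = "tabular") -> Session:
    """Read a session; raises on missing files or invariant violations."""
    path = Path(path)
    if format == "tabular":
        for fname in ("trials.csv", "eye.csv", "licks.csv", "task.yaml"):
            if not (path / fname).exists():
                raise FileNotFoundError(f"missing session file: {path / fname}")
        with open(path / "task.yaml") as fh:
            meta = yaml.safe_load(fh)
        task = _task_from_dict(meta)
        trials = _trials_from_frame(pd.read_csv(path / "trials.csv"))
        cells = []
        for cm in meta.get("cells", []):
            cid = cm["cell_id"]
            trains = {}
            for cls in SPIKE_CLASSES:
                fname = path / f"spikes_{cid}_{cls}.csv"
                if not fname.exists():
                    raise FileNotFoundError(f"missing session file: {fname}")
                ts = pd.read_csv(fname)["timestamp_ms"].to_numpy(dtype=np.int64)
                trains[cls] = SpikeTrain(ts, cls)
            cells.append(
                CellRecording(
                    cell_id=cid,
                    monkey_id=cm["monkey_id"],
                    cspk=trains[CSPK],
                    sspk=trains[SSPK],
                    trial_ids=tuple(int(i) for i in cm["trial_ids"]),
                    recording_bounds=tuple(int(x) for x in cm["recording_bounds"]),
                )
            )
        edf = pd.read_csv(path / "eye.csv", float_precision="round_trip")
        eye = EyeTrace(
            time=edf["t_ms"].to_numpy(np.int64),
            h_position=edf["h_deg"].to_numpy(float),
            v_position=edf["v_deg"].to_numpy(float),
            pupil=edf["pupil"].to_numpy(float),
            valid_mask=edf["valid"].to_numpy(bool),
        )
        ldf = pd.read_csv(path / "licks.csv")
        licks = ldf[["onset_ms", "offset_ms"]].to_numpy(np.int64)
        saccades = None
        if (path / "saccades.csv").exists():
            sdf = pd.read_csv(path / "saccades.csv", float_precision="round_trip")
            saccades = [
                SaccadeEvent(int(r.onset_ms), int(r.offset_ms), float(r.peak_velocity), str(r.epoch))
                for r in sdf.itertuples(index=False)
            ]
        session = Session(task, trials, cells, eye, licks, saccades)
    elif format == "hdf":
        import h5py

        if not Path(path).exists():
            raise FileNotFoundError(f"missing session file: {path}")
        with h5py.File(path, "r") as f:
            task = _task_from_dict(yaml.safe_load(f.attrs["task"]))
            tg = f["trials"]
            df = pd.DataFrame(
                {
                    "trial_id": tg["trial_id"][:],
                    "reward": [s.decode() for s in tg["reward"][:]],
                    "direction_deg": tg["direction_deg"][:],
                    "speed_dps": tg["speed_dps"][:],
                    "cue_on_ms": tg["cue_on_ms"][:],
                    "motion_on_ms": tg["motion_on_ms"][:],
                    "reward_ms": tg["reward_ms"][:],
                    "success": tg["success"][:],
                    "trial_end_ms": tg["trial_end_ms"][:],
                }
            )
            trials = _trials_from_frame(df)
            cells = []
            for cid in f["cells"]:
                g = f["cells"][cid]
                cells.append(
                    CellRecording(
                        cell_id=str(cid),
                        monkey_id=str(g.attrs["monkey_id"]),
                        cspk=SpikeTrain(g["cspk"][:], CSPK),
                        sspk=SpikeTrain(g["sspk"][:], SSPK),
                        trial_ids=tuple(int(i) for i in g["trial_ids"][:]),
                        recording_bounds=tuple(int(x) for x in g.attrs["recording_bounds"]),
                    )
                )
            eg = f["eye"]
            eye = EyeTrace(
                time=eg["t_ms"][:],
                h_position=eg["h_deg"][:],
                v_position=eg["v_deg"][:],
                pupil=eg["pupil"][:],
                valid_mask=eg["valid"][:],
            )
            licks = f["licks"][:].reshape(-1, 2)
            saccades = None
            if "saccades" in f:
                sg = f["saccades"]
                saccades = [
                    SaccadeEvent(int(a), int(b), float(v), e.decode())
                    for a, b, v, e in zip(
                        sg["onset_ms"][:],
                        sg["offset_ms"][:],
                        sg["peak_velocity"][:],
                        sg["epoch"][:],
                    )
                ]
        session = Session(task, trials, cells, eye, licks, saccades)
    else:
        raise ValueError(f"unknown format {format!r}")
    violations = validate_session(session)
    if violations:
        raise ValidationError(violations)
    return session


def sessions_equal(a: Session, b: Session) -> bool:
    """Field-by-field equality (exact on timestamps, bit-exact on floats)."""
    if _task_to_dict(a.task) != _task_to_dict(b.task):
        return False
    if a.trials != b.trials:
        return False
    if len(a.cells) != len(b.cells):
        return False
    for ca, cb in zip(a.cells, b.cells):
        if (
            ca.cell_id != cb.cell_id
            or ca.monkey_id != cb.monkey_id
            or ca.trial_ids != cb.trial_ids
            or tuple(ca.recording_bounds) != tuple(cb.recording_bounds)
            or not np.array_equal(ca.cspk.timestamps, cb.cspk.timestamps)
            or not np.array_equal(ca.sspk.timestamps, cb.sspk.timestamps)
        ):
            return False
    for name in ("time", "h_position", "v_position", "pupil", "valid_mask"):
        if not np.array_equal(getattr(a.eye, name), getattr(b.eye, name)):
            return False
    if not np.array_equal(a.licks, b.licks):
        return False
    if (a.saccades is None) != (b.saccades is None):
        return False
    if a.saccades is not None and list(a.saccades) != list(b.saccades):
        return False
    return True
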