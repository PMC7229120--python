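"""Behavioral alignment and trial parsing for the figure-8 alternation task.

The maze is a figure-8: a central stem flanked by two return arms.  A trial
is one full traversal base -> stem -> choice -> entry -> return arm ->
approach.  Reward follows the continuous-alternation rule: a trial is correct
when the turn is opposite to the previous trial's turn (the first free trial
is correct by convention).

A :class:`BehaviorTrace` is a pandas DataFrame with one row per imaging frame
and columns ``time, x, y, speed, valid`` (plus ``section`` and
``lateral_position`` once :func:`label_sections` has run).  Coordinates are
maze-aligned cm with the stem midline at x = 0 running from y = stem_y[0]
(base end) to y = stem_y[1] (choice end).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import (AlignmentError, ConfigurationError, UndefinedPerformanceError)

logger = logging.getLogger(__name__)

SECTIONS = ("base", "stem", "choice", "entry", "return_arm", "approach")


@dataclass(frozen=True)
class MazeGeometry:
    """Section boundaries of the maze, in maze-aligned cm.

    ``stem_restrict_frac`` trims the stem to its central portion before any
    tuning-curve analysis, excluding the ends where left/right trajectories
    diverge toward the arms (default: central 80%). An explicit
    ``stem_restrict`` span overrides the fraction.
    """

    stem_y: tuple = (0.0, 64.0)
    half_width_cm: float = 3.75        # stem corridor half width
    arm_x_cm: float = 18.0             # |x| of return-arm centrelines
    stem_restrict_frac: float = 0.8
    stem_restrict: tuple | None = None

    def __post_init__(self):
        if self.stem_y[1] <= self.stem_y[0]:
            raise ConfigurationError("stem_y: upper bound must exceed lower bound")
        if not (0 < self.stem_restrict_frac <= 1):
            raise ConfigurationError("stem_restrict_frac: must lie in (0, 1]")
        if self.half_width_cm <= 0:
            raise ConfigurationError("half_width_cm: must be positive")

    @property
    def stem_length_cm(self) -> float:
        return self.stem_y[1] - self.stem_y[0]

    def restricted_stem(self) -> tuple:
        """(lo, hi) of the restricted stem span along y."""
        if self.stem_restrict is not None:
            return tuple(self.stem_restrict)
        margin = 0.5 * (1.0 - self.stem_restrict_frac) * self.stem_length_cm
        return (self.stem_y[0] + margin, self.stem_y[1] - margin)

    def section_of(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Vectorized section label per (x, y) sample."""
        x = np.asarray(x)
        y = np.asarray(y)
        on_corridor = np.abs(x) <= self.half_width_cm
        lo, hi = self.stem_y
        out = np.empty(x.shape, dtype=object)
        out[...] = "return_arm"
        out[on_corridor & (y >= lo) & (y <= hi)] = "stem"
        out[on_corridor & (y < lo)] = "base"
        out[on_corridor & (y > hi)] = "choice"
        out[~on_corridor & (y > hi)] = "entry"
        out[~on_corridor & (y < lo)] = "approach"
        return out


def align_behavior_to_imaging(raw_positions: pd.DataFrame,
                              frame_times: np.ndarray) -> pd.DataFrame:
    """Interpolate raw tracking onto imaging frame times.

    Position is linearly interpolated; speed comes from forward finite
    differences (the last frame repeats the previous speed).  Frames outside
    the tracking time range are flagged ``valid = False``.
    """
    t_raw = np.asarray(raw_positions["time"], dtype=float)
    frame_times = np.asarray(frame_times, dtype=float)
    if t_raw.size < 2:
        raise AlignmentError("need at least two tracking samples")
    if frame_times[0] > t_raw[-1] or frame_times[-1] < t_raw[0]:
        raise AlignmentError("tracking and imaging time ranges do not overlap")

    x = np.interp(frame_times, t_raw, np.asarray(raw_positions["x"], dtype=float))
    y = np.interp(frame_times, t_raw, np.asarray(raw_positions["y"], dtype=float))
    valid = (frame_times >= t_raw[0]) & (frame_times <= t_raw[-1])

    speed = np.zeros(frame_times.size)
    if frame_times.size > 1:
        dt = np.diff(frame_times)
        step = np.hypot(np.diff(x), np.diff(y))
        speed[:-1] = step / dt
        speed[-1] = speed[-2]
    return pd.DataFrame({"time": frame_times, "x": x, "y": y,
                         "speed": speed, "valid": valid})


def smooth_speed(trace: pd.DataFrame, boxcar_frames: int = 5) -> pd.DataFrame:
    """Optional boxcar smoothing of the speed column (off by default)."""
    out = trace.copy()
    kernel = np.ones(boxcar_frames) / boxcar_frames
    out["speed"] = np.convolve(trace["speed"].to_numpy(), kernel, mode="same")
    return out


def label_sections(trace: pd.DataFrame, geometry: MazeGeometry) -> pd.DataFrame:
    """Attach ``section`` and ``lateral_position`` columns to a trace."""
    out = trace.copy()
    out["section"] = geometry.section_of(trace["x"].to_numpy(), trace["y"].to_numpy())
    out["lateral_position"] = trace["x"].to_numpy()   # signed offset from stem midline
    return out


def parse_trials(trace: pd.DataFrame, geometry: MazeGeometry | None = None,
                 forced_trials=()) -> pd.DataFrame:
    """Parse a labeled trace into a trial table.

    Returns a DataFrame with one row per complete traversal: frame spans
    (``start``/``end`` and per-section ``<section>_start``/``<section>_end``),
    ``turn`` (L/R), ``correct`` and ``forced`` flags.  Incomplete traversals
    (a stem run never followed by an arm entry) are dropped and logged.
    A trace that never enters the stem yields an empty table.
    """
    geometry = geometry or MazeGeometry()
    if "section" not in trace.columns:
        trace = label_sections(trace, geometry)
    sec = trace["section"].to_numpy()
    x = trace["x"].to_numpy()
    y = trace["y"].to_numpy()
    n = len(trace)

    stem = sec == "stem"
    starts = np.flatnonzero(stem & ~np.r_[False, stem[:-1]])
    ends = np.flatnonzero(stem & ~np.r_[stem[1:], False])   # inclusive run ends

    records = []
    dropped = 0
    for k, (s0, s1) in enumerate(zip(starts, ends)):
        # require an actual base-to-choice traversal, not a flicker
        if (y[s1] - y[s0]) < 0.5 * geometry.stem_length_cm:
            continue
        next_start = starts[k + 1] if k + 1 < starts.size else n
        # turn: side of the first arm-entry frame after the stem run
        post = np.arange(s1 + 1, next_start)
        arm = post[np.isin(sec[post], ("entry", "return_arm"))]
        if arm.size == 0:
            dropped += 1
            continue
        turn = "L" if x[arm[0]] < 0 else "R"
        # trial starts at the contiguous base period preceding the stem run
        t0 = s0
        while t0 > 0 and sec[t0 - 1] == "base":
            t0 -= 1
        t1 = next_start - 1
        rec = {"start": int(t0), "end": int(t1), "turn": turn,
               "stem_start": int(s0), "stem_end": int(s1)}
        span = sec[t0:t1 + 1]
        for name in SECTIONS:
            idx = np.flatnonzero(span == name)
            rec[f"{name}_start"] = int(t0 + idx[0]) if idx.size else -1
            rec[f"{name}_end"] = int(t0 + idx[-1]) if idx.size else -1
        records.append(rec)
    if dropped:
        logger.info("parse_trials: dropped %d incomplete traversal(s)", dropped)

    trials = pd.DataFrame(records)
    if trials.empty:
        return trials
    trials.insert(0, "trial", np.arange(len(trials)))
    turns = trials["turn"].to_numpy()
    correct = np.ones(len(trials), dtype=bool)
    correct[1:] = turns[1:] != turns[:-1]
    trials["correct"] = correct
    forced = np.zeros(len(trials), dtype=bool)
    forced[[i for i in forced_trials if i < len(trials)]] = True
    trials["forced"] = forced
    return trials


def free_correct_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """Correct, non-forced trials — the selection all tuning analyses use."""
    return trials[trials["correct"] & ~trials["forced"]]


def session_performance(trials: pd.DataFrame) -> float:
    """Fraction of free trials that were correct."""
    free = trials[~trials["forced"]] if len(trials) else trials
    if len(free) == 0:
        raise UndefinedPerformanceError("no free trials in session")
    return float(free["correct"].mean())


def acquisition_session(performances, criterion: float = 0.70,
                        run_length: int = 3):
    """Index of the session completing the first `run_length`-long run at or
    above criterion (the task-acquisition session); None if never achieved."""
    run = 0
    for i, p in enumerate(performances):
        run = run + 1 if p >= criterion else 0
        if run >= run_length:
            return i
    return None
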