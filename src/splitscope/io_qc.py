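"""Session file formats and calcium-trace quality control.

A *session bundle* is a directory of small delimited-text files:

``behavior.csv``
    Raw overhead-tracking samples, header ``time,x,y`` (seconds, maze cm).
``events.csv``
    Sparse long-format event raster, header ``neuron_id,frame,value``.
    Only active frames (value 1) need to be listed; values must be 0/1.
``roi.csv``
    One row per active neuron, header ``neuron_id,x_um,y_um,orientation_deg``
    (ROI centroid in micrometres, major-axis orientation in degrees mod 180).
``meta.json``
    Frame rate, frame count, identifiers and the neuron-id order of the raster.

Frames are 0-based; bin intervals are half-open [lo, hi); maze coordinates
are in cm after alignment; orientations are degrees in [0, 180).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from ._util import FormatError, count_events

logger = logging.getLogger(__name__)

BEHAVIOR_COLUMNS = ("time", "x", "y")
ROI_COLUMNS = ("neuron_id", "x_um", "y_um", "orientation_deg")


@dataclass
class EventRaster:
    """Binary calcium-event activity, neurons x frames.

    ``events[i, t]`` is 1 while neuron ``i`` is within the rising-phase epoch
    of a calcium transient at frame ``t``.  Event *counts* are rising edges
    (one per transient); see :func:`splitscope._util.count_events`.
    """

    events: np.ndarray                  # (n_neurons, n_frames) uint8 in {0,1}
    frame_times: np.ndarray             # (n_frames,) seconds, strictly increasing
    frame_rate_hz: float
    neuron_ids: np.ndarray = None       # global ids, defaults to 0..n-1
    session_id: str = ""
    mouse_id: str = ""
    day: int = 0

    def __post_init__(self):
        self.events = np.ascontiguousarray(self.events, dtype=np.uint8)
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if self.events.ndim != 2:
            raise FormatError("events must be 2-D (neurons x frames)")
        if self.events.shape[1] != self.frame_times.size:
            raise FormatError("frame_times length does not match raster width")
        if self.frame_times.size > 1 and not np.all(np.diff(self.frame_times) > 0):
            raise FormatError("frame times must be strictly increasing")
        if self.events.size and self.events.max() > 1:
            raise FormatError("event values must be binary (0/1)")
        if self.neuron_ids is None:
            self.neuron_ids = np.arange(self.events.shape[0])
        else:
            self.neuron_ids = np.asarray(self.neuron_ids, dtype=int)
            if self.neuron_ids.size != self.events.shape[0]:
                raise FormatError("neuron_ids length does not match raster height")

    @property
    def n_neurons(self) -> int:
        return self.events.shape[0]

    @property
    def n_frames(self) -> int:
        return self.events.shape[1]

    def event_counts(self) -> np.ndarray:
        """Events (transients) per neuron."""
        return count_events(self.events, axis=1)


@dataclass
class TraceQcResult:
    half_decay_s: np.ndarray            # NaN where unfittable
    excluded: np.ndarray                # bool
    exclusion_reason: list


# ---------------------------------------------------------------------------
# session bundle I/O


def write_session_bundle(directory, raster: EventRaster, behavior: pd.DataFrame,
                         roi: pd.DataFrame, extra_meta: dict | None = None) -> dict:
    """Write a session bundle; returns a manifest of the files written."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    behavior = behavior.loc[:, list(BEHAVIOR_COLUMNS)]
    behavior.to_csv(directory / "behavior.csv", index=False, float_format="%.6g")

    neuron_idx, frames = np.nonzero(raster.events)
    ev = pd.DataFrame({
        "neuron_id": raster.neuron_ids[neuron_idx],
        "frame": frames,
        "value": np.ones(frames.size, dtype=int),
    })
    ev.to_csv(directory / "events.csv", index=False)

    roi = roi.loc[:, list(ROI_COLUMNS)]
    roi.to_csv(directory / "roi.csv", index=False, float_format="%.6g")

    meta = {
        "frame_rate_hz": raster.frame_rate_hz,
        "n_frames": int(raster.n_frames),
        "frame_time0": float(raster.frame_times[0]) if raster.n_frames else 0.0,
        "neuron_ids": [int(i) for i in raster.neuron_ids],
        "session_id": raster.session_id,
        "mouse_id": raster.mouse_id,
        "day": int(raster.day),
    }
    if extra_meta:
        meta.update(extra_meta)
    with open(directory / "meta.json", "w") as fh:
        json.dump(meta, fh, indent=1)

    manifest = {name: str(directory / f"{name}.csv") for name in ("behavior", "events", "roi")}
    manifest["meta"] = str(directory / "meta.json")
    return manifest


def read_session_bundle(directory):
    """Read a session bundle.

    Returns ``(raster, behavior, roi, meta)``.  Schema violations raise
    :class:`FormatError` naming the offending file and row.
    """
    directory = Path(directory)
    with open(directory / "meta.json") as fh:
        meta = json.load(fh)

    behavior = pd.read_csv(directory / "behavior.csv")
    _require_columns(behavior, BEHAVIOR_COLUMNS, directory / "behavior.csv")
    t = behavior["time"].to_numpy()
    if t.size > 1:
        bad = np.flatnonzero(np.diff(t) <= 0)
        if bad.size:
            raise FormatError(
                f"{directory / 'behavior.csv'}: time not strictly increasing at row {bad[0] + 2}")

    neuron_ids = np.asarray(meta["neuron_ids"], dtype=int)
    n_frames = int(meta["n_frames"])
    fps = float(meta["frame_rate_hz"])
    events = np.zeros((neuron_ids.size, n_frames), dtype=np.uint8)
    ev = pd.read_csv(directory / "events.csv")
    _require_columns(ev, ("neuron_id", "frame", "value"), directory / "events.csv")
    if len(ev):
        vals = ev["value"].to_numpy()
        bad = np.flatnonzero(~np.isin(vals, (0, 1)))
        if bad.size:
            raise FormatError(
                f"{directory / 'events.csv'}: non-binary event value at row {bad[0] + 2}")
        id_to_row = {int(g): i for i, g in enumerate(neuron_ids)}
        rows = ev["neuron_id"].map(id_to_row)
        if rows.isna().any():
            bad = int(np.flatnonzero(rows.isna().to_numpy())[0])
            raise FormatError(
                f"{directory / 'events.csv'}: unknown neuron_id at row {bad + 2}")
        frames = ev["frame"].to_numpy(dtype=int)
        if frames.size and (frames.min() < 0 or frames.max() >= n_frames):
            raise FormatError(f"{directory / 'events.csv'}: frame index out of range")
        events[rows.to_numpy(dtype=int), frames] = vals.astype(np.uint8)

    roi = pd.read_csv(directory / "roi.csv")
    _require_columns(roi, ROI_COLUMNS, directory / "roi.csv")

    frame_times = meta.get("frame_time0", 0.0) + np.arange(n_frames) / fps
    raster = EventRaster(events, frame_times, fps, neuron_ids=neuron_ids,
                         session_id=meta.get("session_id", ""),
                         mouse_id=meta.get("mouse_id", ""), day=meta.get("day", 0))
    return raster, behavior, roi, meta


def _require_columns(df: pd.DataFrame, columns, path):
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")


# ---------------------------------------------------------------------------
# trace quality control


def fit_transient_half_life(times: np.ndarray, fluorescence: np.ndarray) -> float:
    """Half-life (s) of a single-exponential fit to a decaying trace segment.

    The segment should begin at a transient peak.  Returns NaN (unfittable
    sentinel) if fewer than 5 samples are supplied or the least-squares fit
    does not decay.
    """
    t = np.asarray(times, dtype=float)
    f = np.asarray(fluorescence, dtype=float)
    if t.size < 5 or f.size != t.size:
        return float("nan")
    t = t - t[0]

    def model(tt, a, lam):
        return a * np.exp(-lam * tt)

    a0 = max(f[0], 1e-9)
    # log-linear start point where the trace is positive
    pos = f > 0
    lam0 = 1.0
    if pos.sum() >= 2:
        slope = np.polyfit(t[pos], np.log(f[pos]), 1)[0]
        if slope < 0:
            lam0 = -slope
    try:
        popt, _ = curve_fit(model, t, f, p0=(a0, lam0), maxfev=2000)
    except RuntimeError:
        return float("nan")
    lam = popt[1]
    if lam <= 0:
        return float("nan")
    return float(np.log(2) / lam)


def transient_decay_qc(fluor: np.ndarray, raster: EventRaster,
                       max_half_life_s: float = 2.0,
                       contamination_half_life_s: float = 7.0) -> TraceQcResult:
    """Per-neuron half-decay QC on fluorescence traces.

    For each neuron the decaying portion of the *last* transient is fitted
    with a single exponential.  A fitted half-life above
    ``contamination_half_life_s`` is taken as contamination by a neighbouring
    ROI and the previous transient is tried instead, iterating backwards.
    Neurons whose accepted half-life exceeds ``max_half_life_s`` (or that have
    no fittable transient) are excluded.
    """
    fluor = np.atleast_2d(np.asarray(fluor, dtype=float))
    if fluor.shape != raster.events.shape:
        raise FormatError("fluorescence matrix shape does not match raster")
    n = fluor.shape[0]
    half = np.full(n, np.nan)
    excluded = np.zeros(n, dtype=bool)
    reasons: list = [None] * n

    for i in range(n):
        segs = _decay_segments(raster.events[i], fluor.shape[1])
        accepted = float("nan")
        for lo, hi in reversed(segs):      # last transient first
            h = fit_transient_half_life(raster.frame_times[lo:hi], fluor[i, lo:hi])
            if np.isnan(h):
                continue
            if h > contamination_half_life_s:
                logger.debug("neuron %d: half-life %.2fs > %.1fs, trying previous transient",
                             i, h, contamination_half_life_s)
                continue
            accepted = h
            break
        half[i] = accepted
        if np.isnan(accepted):
            excluded[i] = True
            reasons[i] = "unfittable"
        elif accepted > max_half_life_s:
            excluded[i] = True
            reasons[i] = "slow_decay"
    return TraceQcResult(half, excluded, reasons)


def _decay_segments(activity: np.ndarray, n_frames: int) -> list:
    """(start, stop) frame spans of the decay following each transient."""
    act = np.asarray(activity).astype(bool)
    # falling edges: last active frame of each epoch = start of decay
    falling = np.flatnonzero(np.diff(act.astype(np.int8)) == -1)
    if act.size and act[-1]:
        falling = np.concatenate((falling, [act.size - 1]))
    rising = np.flatnonzero(np.diff(act.astype(np.int8)) == 1) + 1
    if act.size and act[0]:
        rising = np.concatenate(([0], rising))
    segs = []
    for k, start in enumerate(falling):
        stop = rising[k + 1] if k + 1 < rising.size else n_frames
        if stop - start >= 5:
            segs.append((int(start), int(stop)))
    return segs


def synthetic_transient_trace(onset_frames, half_lives_s, n_frames: int,
                              frame_rate_hz: float, amplitude: float = 1.0,
                              noise_sd: float = 0.0,
                              rng: np.random.Generator | None = None) -> np.ndarray:
    """Synthetic fluorescence trace: instant rise, exponential decay per transient.

    Fixture generator for the half-life QC; this is a stand-in signal, not a
    biophysical calcium model.
    """
    onset_frames = np.asarray(onset_frames, dtype=int)
    half_lives_s = np.broadcast_to(np.asarray(half_lives_s, dtype=float), onset_frames.shape)
    t = np.arange(n_frames) / frame_rate_hz
    f = np.zeros(n_frames)
    for o, h in zip(onset_frames, half_lives_s):
        lam = np.log(2) / h
        f[o:] += amplitude * np.exp(-lam * (t[o:] - t[o]))
    if noise_sd > 0:
        rng = rng or np.random.default_rng()
        f = f + rng.normal(0.0, noise_sd, n_frames)
    return f


def neuron_activity_filter(raster: EventRaster, min_events: int = 4) -> np.ndarray:
    """Boolean mask of neurons considered active this session (>= min_events)."""
    return raster.event_counts() >= min_events
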