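"""End-to-end orchestration: session analysis and multi-session experiments.

Glues the stage modules together in the order a real dataset flows:
behavior alignment -> trial parsing -> QC filters -> splitter and place-cell
classification -> functional labels, then (for experiments) registration,
stay-active probabilities, cross-session spatial correlations and onsets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import behavior as beh
from . import decoder as dec
from . import longitudinal as lng
from . import ontogeny as ont
from . import placecells as pc
from . import splitters as spl
from ._util import derive_rng, count_events
from .behavior import MazeGeometry
from .io_qc import EventRaster, neuron_activity_filter
from .synthdata import SessionBundle

logger = logging.getLogger(__name__)


@dataclass
class AnalysisParams:
    """Thresholds and shuffle counts used throughout the pipeline.

    Defaults are the study constants: 1000 shuffles at alpha 0.05, >= 3
    significant ~1 cm bins and stem activity on >= 5 trials for a splitter,
    >= 5 transients for a place cell, >= 4 events to count as active,
    1 cm/s running-speed threshold, 5 µm registration ceiling.
    """

    bin_cm: float = 1.0
    n_shuffles: int = 1000
    alpha: float = 0.05
    min_sig_bins: int = 3
    min_stem_event_trials: int = 5
    min_transients: int = 5
    min_active_events: int = 4
    speed_min_cm_s: float = 1.0
    pc_bin_cm: float = 4.0
    smooth_bin_cm: float = 1.0
    smooth_sigma_cm: float = 2.5
    decoder_bin_cm: float = 3.3
    decoder_repeats: int = 1000
    max_reg_dist_um: float = 5.0
    run_anova: bool = True
    stay_min_cells: int = 4
    stay_min_events: int = 5
    n_lags: int = 15


@dataclass
class SessionResult:
    session_index: int
    day: int
    trace: pd.DataFrame
    trials: pd.DataFrame
    performance: float
    splitter_df: pd.DataFrame
    pc_df: pd.DataFrame
    labels: pd.Series                   # per raster row
    run_event_counts: np.ndarray        # events while running, per raster row
    event_rate_per_min: np.ndarray      # events/min while running
    active_mask: np.ndarray             # >= min_active_events
    raster: EventRaster
    roi: pd.DataFrame
    smoothed_maps: dict = field(default_factory=dict)


def analyze_session(bundle: SessionBundle, params: AnalysisParams | None = None,
                    geometry: MazeGeometry | None = None, seed: int = 0,
                    compute_maps: bool = True) -> SessionResult:
    """Run the full single-session pipeline on one bundle."""
    params = params or AnalysisParams()
    geometry = geometry or MazeGeometry()
    raster = bundle.raster

    trace = beh.align_behavior_to_imaging(bundle.behavior, raster.frame_times)
    trace = beh.label_sections(trace, geometry)
    trials = beh.parse_trials(trace, geometry, forced_trials=bundle.forced_trials)
    performance = beh.session_performance(trials) if len(trials) else float("nan")

    active = neuron_activity_filter(raster, params.min_active_events)

    split_df, _ = spl.analyze_splitters(
        raster, trace, trials, bin_cm=params.bin_cm,
        n_shuffles=params.n_shuffles, alpha=params.alpha,
        min_sig_bins=params.min_sig_bins,
        min_stem_event_trials=params.min_stem_event_trials,
        seed=derive_rng(seed, 13, bundle.session_index).integers(2 ** 31),
        run_anova=params.run_anova, geometry=geometry)

    pc_df = pc.place_cell_table(
        raster, trace, n_shuffles=params.n_shuffles,
        seed=int(derive_rng(seed, 17, bundle.session_index).integers(2 ** 31)),
        bin_cm=params.pc_bin_cm, speed_min=params.speed_min_cm_s,
        min_transients=params.min_transients)

    # events while running and event rate (events/min running)
    running = (trace["speed"].to_numpy() > params.speed_min_cm_s)
    run_events = count_events(raster.events[:, running], axis=1)
    run_minutes = running.sum() / raster.frame_rate_hz / 60.0
    rate_per_min = run_events / run_minutes if run_minutes > 0 else np.zeros(raster.n_neurons)

    labels = lng.assign_coding_labels(
        split_df["is_splitter"], pc_df["is_place_cell"], split_df["stem_active"])
    labels[~active] = "inactive"

    maps = {}
    if compute_maps:
        for i in range(raster.n_neurons):
            maps[i] = pc.smoothed_rate_map(
                raster.events[i], trace, bin_cm=params.smooth_bin_cm,
                sigma_cm=params.smooth_sigma_cm,
                speed_min=params.speed_min_cm_s,
                extent=_maze_extent(geometry))

    return SessionResult(bundle.session_index, bundle.day, trace, trials,
                         performance, split_df, pc_df, labels, run_events,
                         rate_per_min, active, raster, bundle.roi, maps)


def _maze_extent(geometry: MazeGeometry):
    # fixed extent so every session's smoothed maps share a grid
    m = geometry.arm_x_cm + geometry.half_width_cm
    return (-m, m, -8.0, geometry.stem_y[1] + 6.0)


def decode_session(result: SessionResult, params: AnalysisParams | None = None,
                   seed: int = 0, n_repeats: int | None = None,
                   geometry: MazeGeometry | None = None):
    """Turn-direction decoding + chance for an analyzed session."""
    params = params or AnalysisParams()
    reps = n_repeats or params.decoder_repeats
    res = dec.lda_turn_decoder(result.raster, result.trace, result.trials,
                               n_repeats=reps, bin_cm=params.decoder_bin_cm,
                               seed=int(derive_rng(seed, 19).integers(2 ** 31)),
                               geometry=geometry)
    chance = dec.decoder_chance(result.raster, result.trace, result.trials,
                                n_repeats=reps, bin_cm=params.decoder_bin_cm,
                                seed=int(derive_rng(seed, 23).integers(2 ** 31)),
                                geometry=geometry)
    return res, chance


@dataclass
class ExperimentResult:
    sessions: list
    pair_registries: dict               # (i, j) -> NeuronRegistry (QC'd)
    stay_tables: pd.DataFrame           # per pair x class rows
    chain: pd.DataFrame                 # uid x session local indices
    splitter_flags: pd.DataFrame        # uid x session (NaN where absent)
    place_flags: pd.DataFrame
    extent: pd.DataFrame                # uid x session splitting extent
    session_days: np.ndarray


def analyze_experiment(bundles, params: AnalysisParams | None = None,
                       geometry: MazeGeometry | None = None, seed: int = 0,
                       compute_maps: bool = False,
                       pair_blacklist=()) -> ExperimentResult:
    """Run all sessions, register them, and build the longitudinal tables.

    ``pair_blacklist`` is a set of (i, j) session-index pairs excluded from
    registration-based analyses (the registration-epoch exclusion mechanism).
    """
    params = params or AnalysisParams()
    geometry = geometry or MazeGeometry()
    sessions = [analyze_session(b, params, geometry, seed=seed,
                                compute_maps=compute_maps) for b in bundles]
    days = np.array([s.day for s in sessions])

    registries = {}
    stay_rows = []
    blacklist = {tuple(p) for p in pair_blacklist}
    for i in range(len(sessions)):
        for j in range(i + 1, len(sessions)):
            if (i, j) in blacklist:
                continue
            lag = int(days[j] - days[i])
            if lag == 0:
                continue        # same-day pairs excluded from lag analyses
            reg = lng.register_sessions(sessions[i].roi, sessions[j].roi,
                                        max_dist_um=params.max_reg_dist_um)
            reg = lng.registration_qc(
                reg, sessions[i].roi, sessions[j].roi,
                n_shuffles=min(params.n_shuffles, 200),
                seed=int(derive_rng(seed, 29, i, j).integers(2 ** 31)))
            registries[(i, j)] = reg
            if reg.qc_verdict == "fail":
                continue
            st = lng.stay_active_probability(
                reg, sessions[i].labels, sessions[i].run_event_counts,
                day_lag=lag, min_cells=params.stay_min_cells,
                min_events=params.stay_min_events)
            st["session_i"], st["session_j"] = i, j
            stay_rows.append(st)
    stay = pd.concat(stay_rows, ignore_index=True) if stay_rows else pd.DataFrame()

    consecutive = []
    for s in range(len(sessions) - 1):
        reg = registries.get((s, s + 1))
        if reg is None:
            reg = lng.register_sessions(sessions[s].roi, sessions[s + 1].roi,
                                        max_dist_um=params.max_reg_dist_um)
        consecutive.append(reg)
    chain = ont.chain_registrations(consecutive,
                                    [len(s.roi) for s in sessions])

    def per_uid(column, frame):
        out = np.full(chain.shape, np.nan)
        for s, sess in enumerate(sessions):
            vals = getattr(sess, frame)[column].to_numpy()
            local = chain[f"session_{s}"].to_numpy()
            ok = local >= 0
            out[ok, s] = vals[local[ok]].astype(float)
        return pd.DataFrame(out, index=chain.index, columns=chain.columns)

    splitter_flags = per_uid("is_splitter", "splitter_df")
    place_flags = per_uid("is_place_cell", "pc_df")
    extent = per_uid("splitting_extent", "splitter_df")

    return ExperimentResult(sessions, registries, stay, chain,
                            splitter_flags, place_flags, extent, days)


def stay_pair_table(stay: pd.DataFrame, class_a: str = "splitter",
                    class_b: str = "arm_pc") -> pd.DataFrame:
    """Pivot stay-active rows into per-pair (a, b) value columns for lag tests."""
    if stay.empty:
        return pd.DataFrame(columns=["day_lag", "splitter_value", "other_value"])
    rows = []
    for (i, j), grp in stay.groupby(["session_i", "session_j"]):
        ga = grp[(grp["class"] == class_a) & grp["included"]]
        gb = grp[(grp["class"] == class_b) & grp["included"]]
        if len(ga) and len(gb):
            rows.append({"day_lag": int(grp["day_lag"].iloc[0]),
                         "splitter_value": float(ga["probability"].iloc[0]),
                         "other_value": float(gb["probability"].iloc[0])})
    return pd.DataFrame(rows, columns=["day_lag", "splitter_value", "other_value"])
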