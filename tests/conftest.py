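import numpy as np
import pandas as pd
import pytest

import splitscope as sc
from splitscope import behavior as beh

try:
    from hypothesis import settings
    settings.register_profile("ci", derandomize=True, max_examples=50)
    settings.load_profile("ci")
except ImportError:
    pass


@pytest.fixture(scope="session")
def geometry():
    return sc.MazeGeometry()


@pytest.fixture(scope="session")
def default_session(geometry):
    """One generated session with the default mixed population, analyzed
    through alignment and trial parsing (shared by several modules)."""
    cfg = sc.SynthConfig(n_neurons=40, n_trials=40, seed=101)
    (bundle,), truth = sc.generate_experiment(cfg)
    trace = beh.align_behavior_to_imaging(bundle.behavior, bundle.raster.frame_times)
    trace = beh.label_sections(trace, geometry)
    trials = beh.parse_trials(trace, geometry)
    return {"config": cfg, "bundle": bundle, "truth": truth,
            "trace": trace, "trials": trials}


def make_stem_session(per_trial_counts, turns, occupancy_frames=1, fps=20.0,
                      n_bins=None):
    """Hand-built minimal stem-only session for arithmetic-level tests.

    ``per_trial_counts``: (n_neurons, n_trials, n_bins) event counts; each
    trial visits every bin for ``occupancy_frames`` frames (scalar or
    (n_trials, n_bins) array).  Event counts beyond the occupancy are capped.
    Returns (raster, trace, trials, geometry) with a geometry whose
    restricted stem spans exactly the n_bins 1-cm bins.
    """
    counts = np.asarray(per_trial_counts)
    n_neurons, n_trials, nb = counts.shape
    n_bins = n_bins or nb
    occ = np.broadcast_to(np.asarray(occupancy_frames), (n_trials, nb)).astype(int)

    geometry = sc.MazeGeometry(stem_y=(0.0, float(n_bins)),
                               stem_restrict=(0.0, float(n_bins)))
    rows = []
    events = []
    trial_rows = []
    frame = 0
    for t in range(n_trials):
        start = frame
        for b in range(nb):
            for k in range(occ[t, b]):
                rows.append({"time": frame / fps, "x": 0.0, "y": b + 0.5,
                             "speed": 10.0, "valid": True, "section": "stem",
                             "lateral_position": 0.0})
                ev = np.zeros(n_neurons, dtype=np.uint8)
                if k == 0:
                    ev[:] = 0
                for n in range(n_neurons):
                    ev[n] = 1 if k < counts[n, t, b] else 0
                events.append(ev)
                frame += 1
        # one non-stem frame between trials so epochs do not merge
        rows.append({"time": frame / fps, "x": 10.0, "y": b + 0.5,
                     "speed": 10.0, "valid": True, "section": "return_arm",
                     "lateral_position": 10.0})
        events.append(np.zeros(n_neurons, dtype=np.uint8))
        sep = frame
        frame += 1
        trial_rows.append({"trial": t, "start": start, "end": sep,
                           "stem_start": start, "stem_end": sep - 1,
                           "turn": turns[t], "correct": True, "forced": False})
    trace = pd.DataFrame(rows)
    trials = pd.DataFrame(trial_rows)
    raster = sc.EventRaster(np.array(events).T, trace["time"].to_numpy(), fps)
    return raster, trace, trials, geometry
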