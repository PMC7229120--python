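"""Multi-session synthetic behavior + calcium data with known ground truth.

The generator emulates the study design every downstream stage expects:
figure-8 continuous alternation (correct = turn opposite the previous trial),
ballistic stem traversals with speed and lateral-position jitter, calcium
transients whose rising-phase epochs are drawn from a refractory Bernoulli
onset process shaped by a spatial Gaussian field and (for splitters) a
left/right rate modulation on the stem, multi-session turnover with
class-dependent persistence, and ROI centroid/orientation jitter across
sessions for registration testing.

Five ground-truth coding classes mirror the functional designation rules:

``splitter``
    Stem field whose onset rate is ``base_event_rate_hz * modulation_ratio``
    on preferred-turn trials and ``base_event_rate_hz`` otherwise.
``stem_pc`` / ``arm_pc``
    Pure place cells with a Gaussian field on the stem / a return arm
    (arm cells are gated off the stem so they produce no stem activity).
``stem_npc`` / ``arm_npc``
    Spatially untuned cells firing uniformly everywhere / off-stem only.

Every random draw is keyed by ``(seed, session_index, neuron_index)`` so
adding neurons or sessions never reshuffles existing ones.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from ._util import ConfigurationError, derive_rng
from .behavior import MazeGeometry
from .io_qc import EventRaster, write_session_bundle, read_session_bundle

logger = logging.getLogger(__name__)

CLASSES = ("splitter", "stem_pc", "arm_pc", "stem_npc", "arm_npc")

_BEHAVIOR_KEY = 2 ** 20          # rng key offsets so streams never collide
_TRUTH_KEY = 2 ** 21
_ROI_KEY = 2 ** 22


@dataclass
class SynthConfig:
    """Generator parameters. Defaults are the study conditions the package
    is tested under; see docs/methods.md for the reasoning behind each."""

    n_neurons: int = 100
    frac_splitter: float = 0.15
    frac_stem_pc: float = 0.20
    frac_arm_pc: float = 0.35
    npc_stem_frac: float = 0.5          # split of the non-place remainder
    n_trials: int = 40
    n_sessions: int = 1
    frame_rate_hz: float = 20.0
    stem_length_cm: float = 64.0
    modulation_ratio: float = 3.0       # preferred:non-preferred onset-rate ratio
    base_event_rate_hz: float = 0.5     # non-preferred in-field transient onset rate
    npc_rate_hz: float = 0.2            # uniform rate of non-place cells
    event_duration_s: float = 0.4       # rising-phase epoch length
    field_width_cm: float = 8.0         # place-field s.d.
    error_rate: float = 0.15            # probability a free trial repeats the previous turn
    n_forced_trials: int = 0
    persist_prob: dict = field(default_factory=lambda: {
        "splitter": 0.85, "stem_pc": 0.85, "arm_pc": 0.65,
        "stem_npc": 0.50, "arm_npc": 0.50})
    rejoin_prob: float = 0.25           # inactive -> active per session
    splitter_onset_sessions: tuple | None = None   # uniform range; None = active from session 0
    field_shift_mode: bool = False      # Fig. 2a phenotype: L/R fields offset along the stem
    field_shift_cm: float = 10.0
    stem_speed_cm_s: float = 20.0
    speed_jitter_cm_s: float = 3.0
    lateral_sd_cm: float = 1.0          # smooth lateral wander on the stem
    lateral_turn_bias_cm: float = 0.0   # systematic lateral offset toward the upcoming turn
    roi_jitter_um: float = 1.0
    orientation_jitter_deg: float = 3.0
    fov_um: float = 600.0
    sessions_per_day: int = 1
    seed: int = 0

    def __post_init__(self):
        fr = self.frac_splitter + self.frac_stem_pc + self.frac_arm_pc
        for name in ("frac_splitter", "frac_stem_pc", "frac_arm_pc", "npc_stem_frac"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigurationError(f"{name}: must lie in [0, 1]")
        if fr > 1.0 + 1e-12:
            raise ConfigurationError(
                "frac_splitter + frac_stem_pc + frac_arm_pc: must not exceed 1")
        for name in ("n_neurons", "n_trials", "n_sessions"):
            if getattr(self, name) < (1 if name != "n_neurons" else 0):
                raise ConfigurationError(f"{name}: must be positive")
        for name in ("frame_rate_hz", "stem_length_cm", "base_event_rate_hz",
                     "npc_rate_hz", "event_duration_s", "field_width_cm",
                     "stem_speed_cm_s", "fov_um"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name}: must be strictly positive")
        if self.modulation_ratio < 1:
            raise ConfigurationError("modulation_ratio: must be >= 1")
        if not (0.0 <= self.error_rate <= 1.0):
            raise ConfigurationError("error_rate: must lie in [0, 1]")
        if isinstance(self.persist_prob, (int, float)):
            self.persist_prob = {c: float(self.persist_prob) for c in CLASSES}
        for c in CLASSES:
            p = self.persist_prob.get(c, None)
            if p is None or not (0.0 <= p <= 1.0):
                raise ConfigurationError(f"persist_prob[{c}]: must lie in [0, 1]")

    def geometry(self) -> MazeGeometry:
        return MazeGeometry(stem_y=(0.0, self.stem_length_cm))


@dataclass
class GroundTruth:
    """Per-neuron generative truth (fixed across sessions for an identity)."""

    true_class: np.ndarray              # (n,) str
    field_center: np.ndarray            # (n, 2) cm; NaN for non-place cells
    preferred_turn: np.ndarray          # (n,) 'L'/'R'/'' (splitters only)
    modulation_ratio: np.ndarray        # (n,)
    true_onset_session: np.ndarray      # (n,) int; session splitting turns on
    active: np.ndarray                  # (n, n_sessions) bool
    roi_center_um: np.ndarray           # (n, 2)
    roi_orientation_deg: np.ndarray     # (n,)

    @property
    def n_neurons(self) -> int:
        return self.true_class.size

    def active_sessions(self, neuron: int) -> set:
        return set(np.flatnonzero(self.active[neuron]).tolist())

    def to_json(self) -> str:
        d = {
            "true_class": self.true_class.tolist(),
            "field_center": self.field_center.tolist(),
            "preferred_turn": self.preferred_turn.tolist(),
            "modulation_ratio": self.modulation_ratio.tolist(),
            "true_onset_session": self.true_onset_session.tolist(),
            "active": self.active.astype(int).tolist(),
            "roi_center_um": self.roi_center_um.tolist(),
            "roi_orientation_deg": self.roi_orientation_deg.tolist(),
        }
        return json.dumps(d, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        return cls(
            true_class=np.asarray(d["true_class"], dtype=object),
            field_center=np.asarray(d["field_center"], dtype=float),
            preferred_turn=np.asarray(d["preferred_turn"], dtype=object),
            modulation_ratio=np.asarray(d["modulation_ratio"], dtype=float),
            true_onset_session=np.asarray(d["true_onset_session"], dtype=int),
            active=np.asarray(d["active"], dtype=bool),
            roi_center_um=np.asarray(d["roi_center_um"], dtype=float),
            roi_orientation_deg=np.asarray(d["roi_orientation_deg"], dtype=float),
        )


@dataclass
class SessionBundle:
    """One generated session: raw tracking, event raster, ROI table."""

    behavior: pd.DataFrame              # raw 30 Hz tracking: time, x, y
    raster: EventRaster                 # active neurons only; neuron_ids are global
    roi: pd.DataFrame                   # neuron_id, x_um, y_um, orientation_deg
    day: int
    session_index: int
    forced_trials: tuple = ()


# ---------------------------------------------------------------------------
# ground truth


def generate_ground_truth(config: SynthConfig) -> GroundTruth:
    """Draw per-neuron classes, fields, persistence chains and base ROIs."""
    rng = derive_rng(config.seed, _TRUTH_KEY)
    n = config.n_neurons
    geom = config.geometry()

    n_split = int(round(config.frac_splitter * n))
    n_stem = int(round(config.frac_stem_pc * n))
    n_arm = int(round(config.frac_arm_pc * n))
    n_rest = n - n_split - n_stem - n_arm
    if n_rest < 0:       # rounding overflow
        n_arm += n_rest
        n_rest = 0
    n_snpc = int(round(config.npc_stem_frac * n_rest))
    classes = np.array(
        ["splitter"] * n_split + ["stem_pc"] * n_stem + ["arm_pc"] * n_arm
        + ["stem_npc"] * n_snpc + ["arm_npc"] * (n_rest - n_snpc), dtype=object)

    lo, hi = geom.restricted_stem()
    field_center = np.full((n, 2), np.nan)
    preferred = np.array([""] * n, dtype=object)
    for i, c in enumerate(classes):
        if c in ("splitter", "stem_pc"):
            field_center[i] = (0.0, rng.uniform(lo + 4, hi - 4))
        elif c == "arm_pc":
            side = rng.choice([-1.0, 1.0])
            field_center[i] = (side * geom.arm_x_cm,
                               rng.uniform(5.0, config.stem_length_cm - 5.0))
        if c == "splitter":
            preferred[i] = rng.choice(["L", "R"])

    mod = np.where(classes == "splitter", config.modulation_ratio, 1.0)

    onset = np.zeros(n, dtype=int)
    if config.splitter_onset_sessions is not None:
        a, b = config.splitter_onset_sessions
        onset = np.where(classes == "splitter",
                         rng.integers(a, b + 1, size=n), 0)

    active = np.zeros((n, config.n_sessions), dtype=bool)
    active[:, 0] = True
    for s in range(1, config.n_sessions):
        p_stay = np.array([config.persist_prob[c] for c in classes])
        u = rng.random(n)
        active[:, s] = np.where(active[:, s - 1], u < p_stay, u < config.rejoin_prob)

    roi_center = rng.uniform(0.0, config.fov_um, size=(n, 2))
    roi_orient = rng.uniform(0.0, 180.0, size=n)

    return GroundTruth(classes, field_center, preferred, mod, onset,
                       active, roi_center, roi_orient)


# ---------------------------------------------------------------------------
# behavior synthesis


def _turn_sequence(config: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    turns = np.empty(config.n_trials, dtype=object)
    turns[0] = rng.choice(["L", "R"])
    for t in range(1, config.n_trials):
        forced = t < config.n_forced_trials
        if forced or rng.random() >= config.error_rate:
            turns[t] = "L" if turns[t - 1] == "R" else "R"
        else:
            turns[t] = turns[t - 1]   # alternation error: repeat
    return turns


def _session_path(config: SynthConfig, turns: np.ndarray,
                  rng: np.random.Generator):
    """Frame-resolution (x, y) path plus per-frame trial index and turn."""
    geom = config.geometry()
    fps = config.frame_rate_hz
    hw = geom.half_width_cm
    top = config.stem_length_cm
    arm = geom.arm_x_cm
    xs, ys, trial_of_frame = [], [], []

    def seg(p0, p1, speed, lateral=None):
        p0 = np.asarray(p0, dtype=float)
        p1 = np.asarray(p1, dtype=float)
        length = np.linalg.norm(p1 - p0)
        nf = max(int(round(length / speed * fps)), 2)
        frac = np.arange(nf) / nf
        pts = p0 + frac[:, None] * (p1 - p0)
        if lateral is not None:
            pts[:, 0] += lateral(nf)
        return pts

    for t, turn in enumerate(turns):
        s = -1.0 if turn == "L" else 1.0
        speed = max(config.stem_speed_cm_s
                    + rng.normal(0.0, config.speed_jitter_cm_s), 5.0)
        bias = s * config.lateral_turn_bias_cm

        def stem_lateral(nf, _bias=bias):
            # AR(1) wander, clipped to the corridor
            e = rng.normal(0.0, config.lateral_sd_cm * 0.4, nf)
            w = np.empty(nf)
            w[0] = rng.normal(0.0, config.lateral_sd_cm * 0.5)
            for k in range(1, nf):
                w[k] = 0.9 * w[k - 1] + e[k]
            return np.clip(w + _bias, -hw + 0.3, hw - 0.3)

        parts = [
            seg((0.0, -6.0), (0.0, -0.01), speed),                      # base
            seg((0.0, 0.0), (0.0, top), speed, lateral=stem_lateral),   # stem
            seg((0.0, top + 0.01), (s * (hw + 0.2), top + 4.0), speed), # choice
            seg((s * (hw + 0.3), top + 4.0), (s * arm, top + 4.0), speed),  # entry
            seg((s * arm, top + 4.0), (s * arm, 0.01), speed),          # return arm
            seg((s * arm, -0.01), (0.0, -6.0), speed),                  # approach -> base
        ]
        pts = np.concatenate(parts, axis=0)
        xs.append(pts[:, 0])
        ys.append(pts[:, 1])
        trial_of_frame.append(np.full(pts.shape[0], t))

    x = np.concatenate(xs)
    y = np.concatenate(ys)
    trial_of_frame = np.concatenate(trial_of_frame)
    turn_of_frame = turns[trial_of_frame]
    on_stem = (np.abs(x) <= hw) & (y >= 0.0) & (y <= top)
    return x, y, trial_of_frame, turn_of_frame, on_stem


# ---------------------------------------------------------------------------
# events


def _refractory_onsets(p_onset: np.ndarray, refractory_frames: int,
                       rng: np.random.Generator) -> np.ndarray:
    """Onset frames from per-frame Bernoulli hazards with a refractory gap.

    The gap (epoch length + 1 frame) guarantees a silent frame between
    consecutive epochs, so rising-edge counting recovers onsets exactly.
    """
    cand = np.flatnonzero(rng.random(p_onset.size) < p_onset)
    onsets = []
    last = -10 ** 9
    for f in cand:
        if f - last > refractory_frames:
            onsets.append(f)
            last = f
    return np.asarray(onsets, dtype=int)


def _neuron_rate(config: SynthConfig, truth: GroundTruth, i: int,
                 session_index: int, x, y, turn_of_frame, on_stem) -> np.ndarray:
    """Per-frame transient onset rate (Hz) for neuron i."""
    c = truth.true_class[i]
    sig2 = 2.0 * config.field_width_cm ** 2
    if c == "stem_npc":
        return np.full(x.size, config.npc_rate_hz)
    if c == "arm_npc":
        return np.where(on_stem, 0.0, config.npc_rate_hz)

    cx, cy = truth.field_center[i]
    if c == "splitter" and config.field_shift_mode \
            and session_index >= truth.true_onset_session[i]:
        pref = truth.preferred_turn[i]
        shift = np.where(turn_of_frame == pref,
                         0.5 * config.field_shift_cm, -0.5 * config.field_shift_cm)
        d2 = (x - cx) ** 2 + (y - (cy + shift)) ** 2
        return config.base_event_rate_hz * config.modulation_ratio * np.exp(-d2 / sig2)

    d2 = (x - cx) ** 2 + (y - cy) ** 2
    rate = config.base_event_rate_hz * np.exp(-d2 / sig2)
    if c == "arm_pc":
        rate = np.where(on_stem, 0.0, rate)
    elif c == "splitter" and session_index >= truth.true_onset_session[i]:
        pref = truth.preferred_turn[i]
        gain = np.where(on_stem & (turn_of_frame == pref),
                        truth.modulation_ratio[i], 1.0)
        rate = rate * gain
    return rate


def generate_session(config: SynthConfig, session_index: int,
                     truth: GroundTruth) -> SessionBundle:
    """Generate one session (deterministic given ``(config.seed, session_index)``)."""
    if truth.n_neurons != config.n_neurons or truth.active.shape[1] < config.n_sessions:
        raise ConfigurationError("truth: inconsistent with config")
    rng_beh = derive_rng(config.seed, session_index, _BEHAVIOR_KEY)
    turns = _turn_sequence(config, rng_beh)
    x, y, trial_of_frame, turn_of_frame, on_stem = _session_path(config, turns, rng_beh)

    fps = config.frame_rate_hz
    n_frames = x.size
    frame_times = np.arange(n_frames) / fps

    # raw 30 Hz tracking with small camera noise; downstream re-interpolates
    t_raw = np.arange(0.0, frame_times[-1] + 1e-9, 1.0 / 30.0)
    x_raw = np.interp(t_raw, frame_times, x) + rng_beh.normal(0.0, 0.15, t_raw.size)
    y_raw = np.interp(t_raw, frame_times, y) + rng_beh.normal(0.0, 0.15, t_raw.size)
    behavior = pd.DataFrame({"time": t_raw, "x": x_raw, "y": y_raw})

    dur_frames = max(int(round(config.event_duration_s * fps)), 1)
    refr = dur_frames + 1

    active_ids = np.flatnonzero(truth.active[:, session_index])
    events = np.zeros((active_ids.size, n_frames), dtype=np.uint8)
    for row, i in enumerate(active_ids):
        rng_i = derive_rng(config.seed, session_index, int(i))
        rate = _neuron_rate(config, truth, int(i), session_index,
                            x, y, turn_of_frame, on_stem)
        # hazard compensation: steady-state onset rate == configured rate
        # despite the refractory gap (duty = rate * epoch length)
        loss = np.minimum(rate * refr / fps, 0.8)
        p = np.minimum(rate / (1.0 - loss) / fps, 0.95)
        onsets = _refractory_onsets(p, refr, rng_i)
        for o in onsets:
            events[row, o:o + dur_frames] = 1

    rng_roi = derive_rng(config.seed, session_index, _ROI_KEY)
    jitter = rng_roi.normal(0.0, config.roi_jitter_um, size=(active_ids.size, 2))
    dori = rng_roi.normal(0.0, config.orientation_jitter_deg, size=active_ids.size)
    roi = pd.DataFrame({
        "neuron_id": active_ids,
        "x_um": truth.roi_center_um[active_ids, 0] + jitter[:, 0],
        "y_um": truth.roi_center_um[active_ids, 1] + jitter[:, 1],
        "orientation_deg": np.mod(truth.roi_orientation_deg[active_ids] + dori, 180.0),
    })

    day = session_index // config.sessions_per_day
    raster = EventRaster(events, frame_times, fps, neuron_ids=active_ids,
                         session_id=f"s{session_index:03d}", mouse_id="synth",
                         day=day)
    forced = tuple(range(config.n_forced_trials))
    return SessionBundle(behavior, raster, roi, day, session_index, forced)


def generate_experiment(config: SynthConfig):
    """All sessions plus the ground truth. Deterministic given config.seed."""
    truth = generate_ground_truth(config)
    sessions = [generate_session(config, s, truth) for s in range(config.n_sessions)]
    return sessions, truth


# ---------------------------------------------------------------------------
# fixtures on disk


def write_fixtures(sessions, truth: GroundTruth, directory,
                   config: SynthConfig | None = None) -> dict:
    """Write an experiment as session-bundle directories + ground-truth JSON.

    Round-trips losslessly through :func:`splitscope.io_qc.read_session_bundle`.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {"sessions": [], "truth": str(directory / "truth.json")}
    for bundle in sessions:
        sub = directory / f"session_{bundle.session_index:03d}"
        m = write_session_bundle(
            sub, bundle.raster, bundle.behavior, bundle.roi,
            extra_meta={"forced_trials": list(bundle.forced_trials),
                        "session_index": bundle.session_index})
        m["directory"] = str(sub)
        manifest["sessions"].append(m)
    (directory / "truth.json").write_text(truth.to_json())
    if config is not None:
        cfg = asdict(config)
        cfg["splitter_onset_sessions"] = (
            list(config.splitter_onset_sessions)
            if config.splitter_onset_sessions is not None else None)
        (directory / "config.json").write_text(json.dumps(cfg, indent=1))
        manifest["config"] = str(directory / "config.json")
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def read_fixtures(directory):
    """Load an experiment written by :func:`write_fixtures`."""
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    truth = GroundTruth.from_json((directory / "truth.json").read_text())
    sessions = []
    for entry in manifest["sessions"]:
        raster, behavior, roi, meta = read_session_bundle(entry["directory"])
        sessions.append(SessionBundle(
            behavior, raster, roi, day=meta.get("day", 0),
            session_index=meta.get("session_index", 0),
            forced_trials=tuple(meta.get("forced_trials", ()))))
    return sessions, truth
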