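"""Place-cell identification via spatial information and a timestamp-shuffle null.

Spatial information (SI) is the mutual information between the binary
calcium-event indicator k (0/1 per frame) and binned position:

    I_pos(x_i) = sum_{k in {0,1}} P(k|x_i) log2( P(k|x_i) / P_k )
    SI         = sum_i P(x_i) I_pos(x_i)

with 0 * log(0/.) terms defined as 0.  Only frames when the animal moves
faster than 1 cm/s enter the maps.  A neuron is a place cell when it has at
least five transients in the session and its SI strictly exceeds 95% of 1000
SIs recomputed after shuffling event timestamps (default: circular shift of
the activity train, which preserves event count and inter-event structure).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from ._util import EmptyMapError, count_events, derive_rng
from .io_qc import EventRaster

logger = logging.getLogger(__name__)


@dataclass
class SpatialMap:
    """Occupancy and event-probability maps on a 2-D grid (cm bins)."""

    bin_cm: float
    x_edges: np.ndarray
    y_edges: np.ndarray
    occupancy_s: np.ndarray             # (ny, nx)
    frames_per_bin: np.ndarray          # (ny, nx)
    event_count: np.ndarray             # (ny, nx) active frames per bin
    P_x: np.ndarray                     # occupancy probability (sums to 1)
    P_k1: float                         # marginal P(k = 1)
    P_k1_given_x: np.ndarray            # (ny, nx)
    valid: np.ndarray                   # occupied bins


@dataclass
class SpatialInfoResult:
    si: float
    shuffle_sis: np.ndarray
    p_rank: float                       # proportion of shuffles >= real SI
    is_place_cell: bool
    n_transients: int
    reason: str = ""


@dataclass
class SmoothedMap:
    rate: np.ndarray                    # (ny, nx) events/s, Gaussian-smoothed
    visited: np.ndarray
    bin_cm: float
    x_edges: np.ndarray
    y_edges: np.ndarray


@dataclass
class PlaceField:
    field_mask: np.ndarray              # connected component containing the peak
    field_area_cm2: float
    field_length_cm: float              # area / corridor width
    peak_rate: float


def _included_frames(trace: pd.DataFrame, speed_min: float):
    speed = trace["speed"].to_numpy()
    valid = trace["valid"].to_numpy() if "valid" in trace.columns else np.ones(len(trace), bool)
    return np.flatnonzero((speed > speed_min) & valid)


def _grid(trace, frames, bin_cm, extent=None):
    x = trace["x"].to_numpy()[frames]
    y = trace["y"].to_numpy()[frames]
    if extent is None:
        extent = (x.min(), x.max(), y.min(), y.max())
    x0, x1, y0, y1 = extent
    nx = max(int(np.ceil((x1 - x0) / bin_cm)), 1)
    ny = max(int(np.ceil((y1 - y0) / bin_cm)), 1)
    ix = np.clip(((x - x0) / bin_cm).astype(int), 0, nx - 1)
    iy = np.clip(((y - y0) / bin_cm).astype(int), 0, ny - 1)
    x_edges = x0 + bin_cm * np.arange(nx + 1)
    y_edges = y0 + bin_cm * np.arange(ny + 1)
    return ix, iy, nx, ny, x_edges, y_edges


def spatial_event_map(events_row: np.ndarray, trace: pd.DataFrame,
                      bin_cm: float = 4.0, speed_min: float = 1.0,
                      extent=None) -> SpatialMap:
    """Occupancy and per-bin event-probability maps for one neuron."""
    frames = _included_frames(trace, speed_min)
    if frames.size == 0:
        raise EmptyMapError("no frames above the speed threshold")
    ix, iy, nx, ny, x_edges, y_edges = _grid(trace, frames, bin_cm, extent)

    flat = iy * nx + ix
    frames_per_bin = np.bincount(flat, minlength=ny * nx).reshape(ny, nx).astype(float)
    ev = np.asarray(events_row, dtype=float)[frames]
    event_count = np.bincount(flat, weights=ev, minlength=ny * nx).reshape(ny, nx)

    valid = frames_per_bin > 0
    P_x = frames_per_bin / frames.size
    with np.errstate(invalid="ignore", divide="ignore"):
        P_k1_given_x = np.where(valid, event_count / frames_per_bin, 0.0)
    P_k1 = float(ev.mean())
    # frame time is uniform, so occupancy seconds = frames / rate; the frame
    # rate is recoverable from trace times
    dt = np.median(np.diff(trace["time"].to_numpy())) if len(trace) > 1 else 1.0
    return SpatialMap(bin_cm, x_edges, y_edges, frames_per_bin * dt,
                      frames_per_bin, event_count, P_x, P_k1, P_k1_given_x, valid)


def spatial_information(smap: SpatialMap, log_base: float = 2.0) -> float:
    """SI in bits (default) from a spatial map; always >= 0."""
    return _si_from_counts(smap.event_count[smap.valid][None, :],
                           smap.frames_per_bin[smap.valid],
                           log_base=log_base)[0]


def _si_from_counts(counts: np.ndarray, frames_per_bin: np.ndarray,
                    log_base: float = 2.0) -> np.ndarray:
    """Vectorized SI for (S, B) event counts over B occupied bins."""
    n_total = frames_per_bin.sum()
    P_x = frames_per_bin / n_total
    p1 = counts.sum(axis=1, keepdims=True) / n_total          # (S, 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p1x = counts / frames_per_bin[None, :]                # (S, B)
        p0x = 1.0 - p1x
        t1 = np.where(p1x > 0, p1x * np.log(p1x / p1), 0.0)
        t0 = np.where(p0x > 0, p0x * np.log(p0x / (1.0 - p1)), 0.0)
    si = (P_x[None, :] * (t1 + t0)).sum(axis=1) / np.log(log_base)
    return np.maximum(si, 0.0)


def place_cell_test(events_row: np.ndarray, trace: pd.DataFrame,
                    n_shuffles: int = 1000, seed: int = 0,
                    rng: np.random.Generator | None = None,
                    bin_cm: float = 4.0, speed_min: float = 1.0,
                    min_transients: int = 5,
                    method: str = "circular") -> SpatialInfoResult:
    """Shuffle test of spatial information for one neuron.

    ``method="circular"`` shifts the activity train by a uniform random
    offset within the speed-filtered frame sequence (preserves event count
    and inter-event structure); ``"permute"`` randomly permutes the activity
    frames instead.  Classification requires >= ``min_transients`` transients
    and the real SI to strictly exceed 95% of the shuffled SIs.
    """
    if rng is None:
        rng = derive_rng(seed, 5)
    n_tr = int(count_events(np.asarray(events_row)))
    frames = _included_frames(trace, speed_min)
    if frames.size == 0:
        raise EmptyMapError("no frames above the speed threshold")
    ix, iy, nx, ny, _, _ = _grid(trace, frames, bin_cm)
    flat = iy * nx + ix
    frames_per_bin = np.bincount(flat, minlength=ny * nx).astype(float)
    occupied = frames_per_bin > 0
    bin_of_frame = flat
    act = np.asarray(events_row, dtype=np.int8)[frames]

    real_counts = np.bincount(bin_of_frame, weights=act.astype(float),
                              minlength=ny * nx)[occupied]
    si = _si_from_counts(real_counts[None, :], frames_per_bin[occupied])[0]

    n = frames.size
    active_pos = np.flatnonzero(act)
    if method == "circular":
        offsets = rng.integers(1, n, size=n_shuffles)
        shifted = (active_pos[None, :] + offsets[:, None]) % n     # (S, A)
    elif method == "permute":
        shifted = np.empty((n_shuffles, active_pos.size), dtype=int)
        for s in range(n_shuffles):
            shifted[s] = rng.choice(n, size=active_pos.size, replace=False)
    else:
        raise ValueError(f"unknown shuffle method {method!r}")

    bins_all = np.searchsorted(np.flatnonzero(occupied),
                               bin_of_frame)                       # compact bin ids
    B = int(occupied.sum())
    sh_bins = bins_all[shifted]                                    # (S, A)
    offset_ids = (np.arange(n_shuffles)[:, None] * B + sh_bins).ravel()
    sh_counts = np.bincount(offset_ids, minlength=n_shuffles * B).reshape(n_shuffles, B)
    shuffle_sis = _si_from_counts(sh_counts.astype(float), frames_per_bin[occupied])

    exceeds = float((si > shuffle_sis).mean())
    p_rank = float((shuffle_sis >= si).mean())
    is_pc = (n_tr >= min_transients) and (exceeds >= 0.95)
    reason = "" if n_tr >= min_transients else f"only {n_tr} transients"
    return SpatialInfoResult(float(si), shuffle_sis, p_rank, bool(is_pc), n_tr, reason)


def place_cell_table(raster: EventRaster, trace: pd.DataFrame,
                     n_shuffles: int = 1000, seed: int = 0, **kwargs) -> pd.DataFrame:
    """Run the place-cell test for every neuron in a raster."""
    rows = []
    for i in range(raster.n_neurons):
        rng = derive_rng(seed, 5, int(raster.neuron_ids[i]))
        res = place_cell_test(raster.events[i], trace, n_shuffles=n_shuffles,
                              rng=rng, **kwargs)
        rows.append({"neuron_id": raster.neuron_ids[i], "si": res.si,
                     "p_rank": res.p_rank, "is_place_cell": res.is_place_cell,
                     "n_transients": res.n_transients})
    return pd.DataFrame(rows)


def smoothed_rate_map(events_row: np.ndarray, trace: pd.DataFrame,
                      bin_cm: float = 1.0, sigma_cm: float = 2.5,
                      speed_min: float = 1.0, extent=None) -> SmoothedMap:
    """Occupancy-normalized event-rate map smoothed with a Gaussian kernel.

    Event-count and occupancy maps are smoothed separately and then divided,
    which preserves total rate mass over interior bins; unvisited bins are
    masked (``visited``) and must be excluded from any correlation use.
    """
    frames = _included_frames(trace, speed_min)
    if frames.size == 0:
        raise EmptyMapError("no frames above the speed threshold")
    ix, iy, nx, ny, x_edges, y_edges = _grid(trace, frames, bin_cm, extent)
    flat = iy * nx + ix
    occ = np.bincount(flat, minlength=ny * nx).reshape(ny, nx).astype(float)
    ev = np.asarray(events_row, dtype=float)[frames]
    cnt = np.bincount(flat, weights=ev, minlength=ny * nx).reshape(ny, nx)
    dt = np.median(np.diff(trace["time"].to_numpy())) if len(trace) > 1 else 1.0

    sigma_bins = sigma_cm / bin_cm
    if sigma_bins > 0:
        cnt_s = ndimage.gaussian_filter(cnt, sigma_bins)
        occ_s = ndimage.gaussian_filter(occ, sigma_bins)
    else:
        cnt_s, occ_s = cnt, occ
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = np.where(occ_s > 1e-12, cnt_s / (occ_s * dt), 0.0)
    return SmoothedMap(rate, occ > 0, bin_cm, x_edges, y_edges)


def extract_place_field(smap: SmoothedMap,
                        corridor_width_cm: float = 5.0) -> PlaceField | None:
    """Field = connected bins (4-neighbor) above half the peak rate,
    containing the peak; length = area / corridor width.  Returns None
    (no-field sentinel) for an all-zero map."""
    rate = np.where(smap.visited, smap.rate, 0.0)
    peak = rate.max()
    if peak <= 0:
        return None
    above = rate > 0.5 * peak
    structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    labels, _ = ndimage.label(above, structure=structure)
    peak_idx = np.unravel_index(np.argmax(rate), rate.shape)
    mask = labels == labels[peak_idx]
    area = float(mask.sum()) * smap.bin_cm ** 2
    return PlaceField(mask, area, area / corridor_width_cm, float(peak))
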