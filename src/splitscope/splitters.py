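"""Trajectory-dependent (splitter) cell identification and metrics.

For each neuron, occupancy-normalized activity-rate tuning curves are built
along the restricted central stem in ~1 cm bins, separately for left-turn and
right-turn correct trials.  Trajectory dependence is assessed per bin with a
trial-label permutation test: the per-bin statistic is the absolute
difference of the left/right curves, and the null is generated by permuting
turn labels among correct trials (left/right counts preserved), one label
permutation evaluated at all bins so the spatial correlation of the null is
retained.  A neuron is a splitter when at least ``min_sig_bins`` bins exceed
95% of the shuffled differences, it produced stem activity on at least
``min_stem_event_trials`` trials, and an ANOVA confirms the turn effect
after accounting for running speed and lateral stem position.

Derived metrics:

discriminability
    sum |tc_L - tc_R| / sum (tc_L + tc_R) over valid stem bins, in [0, 1].
reliability
    per bin, the proportion of shuffles the real difference exceeds; the
    mean (and peak) of this proportion along the stem.
1 - rho
    one minus the Spearman correlation of the unsmoothed curves.
splitting extent
    proportion of valid stem bins with a significant left/right difference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._util import InsufficientDataError, InsufficientTrialsError, derive_rng
from .behavior import MazeGeometry, free_correct_trials
from .io_qc import EventRaster

logger = logging.getLogger(__name__)


@dataclass
class StemTuning:
    """Per-neuron left/right stem tuning curves plus the per-trial matrices
    the permutation test reuses.

    Curves are occupancy-normalized activity rates (active frames / s).
    ``tc_left``/``tc_right`` have shape (n_neurons, n_bins); bins never
    occupied in one direction are masked invalid.
    """

    bin_edges: np.ndarray               # (B+1,) cm along the stem axis
    tc_left: np.ndarray                 # (N, B)
    tc_right: np.ndarray                # (N, B)
    occupancy_left: np.ndarray          # (B,) total s over left trials
    occupancy_right: np.ndarray         # (B,)
    n_trials_left: int
    n_trials_right: int
    n_stem_event_trials: np.ndarray     # (N,)
    valid: np.ndarray                   # (B,) bool
    counts: np.ndarray                  # (N, T, B) active-frame counts per trial
    occupancy_trials: np.ndarray        # (T, B) seconds per trial
    is_left: np.ndarray                 # (T,) bool
    neuron_ids: np.ndarray = None

    @property
    def n_neurons(self) -> int:
        return self.counts.shape[0]

    @property
    def n_bins(self) -> int:
        return self.counts.shape[2]


def stem_tuning_curves(raster: EventRaster, trace: pd.DataFrame,
                       trials: pd.DataFrame, bin_cm: float = 1.0,
                       correct_only: bool = True,
                       geometry: MazeGeometry | None = None,
                       normalization: str = "pooled") -> StemTuning:
    """Build left/right stem tuning curves for every neuron.

    ``normalization="pooled"`` divides the mean per-trial count by the mean
    per-trial occupancy; ``"per_trial"`` averages per-trial rates instead
    (each trial's count / occupancy, zero-occupancy trials skipped).
    """
    geometry = geometry or MazeGeometry()
    use = free_correct_trials(trials) if correct_only else trials[~trials["forced"]]
    is_left = (use["turn"] == "L").to_numpy()
    if is_left.sum() == 0 or (~is_left).sum() == 0:
        raise InsufficientTrialsError("need at least one correct trial per direction")

    lo, hi = geometry.restricted_stem()
    n_bins = max(int(round((hi - lo) / bin_cm)), 1)
    edges = np.linspace(lo, hi, n_bins + 1)
    binw = (hi - lo) / n_bins
    fps = raster.frame_rate_hz

    y = trace["y"].to_numpy()
    sec = trace["section"].to_numpy()
    ev = raster.events
    T = len(use)
    counts = np.zeros((raster.n_neurons, T, n_bins))
    occ = np.zeros((T, n_bins))
    n_stem_event = np.zeros(raster.n_neurons, dtype=int)

    for t_idx, (_, row) in enumerate(use.iterrows()):
        s0, s1 = int(row["stem_start"]), int(row["stem_end"])
        frames = np.arange(s0, s1 + 1)
        frames = frames[sec[frames] == "stem"]
        # any stem activity this trial (full stem section, pre-restriction)
        n_stem_event += ev[:, frames].any(axis=1)
        yy = y[frames]
        inside = (yy >= lo) & (yy < hi)
        frames = frames[inside]
        b = np.minimum(((yy[inside] - lo) / binw).astype(int), n_bins - 1)
        np.add.at(occ[t_idx], b, 1.0 / fps)
        onehot = np.zeros((frames.size, n_bins))
        onehot[np.arange(frames.size), b] = 1.0
        counts[:, t_idx, :] = ev[:, frames].astype(np.float64) @ onehot

    tc_left, occ_left = _direction_curve(counts, occ, is_left, normalization)
    tc_right, occ_right = _direction_curve(counts, occ, ~is_left, normalization)
    valid = (occ[is_left].sum(axis=0) > 0) & (occ[~is_left].sum(axis=0) > 0)

    return StemTuning(edges, tc_left, tc_right,
                      occ[is_left].sum(axis=0), occ[~is_left].sum(axis=0),
                      int(is_left.sum()), int((~is_left).sum()),
                      n_stem_event, valid, counts, occ, is_left,
                      neuron_ids=raster.neuron_ids)


def _direction_curve(counts, occ, mask, normalization):
    occ_d = occ[mask]
    c_d = counts[:, mask, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        if normalization == "pooled":
            tc = c_d.mean(axis=1) / occ_d.mean(axis=0)[None, :]
        elif normalization == "per_trial":
            rate = np.where(occ_d[None, :, :] > 0, c_d / occ_d[None, :, :], np.nan)
            tc = np.nanmean(rate, axis=1)
        else:
            raise ValueError(f"unknown normalization {normalization!r}")
    return np.nan_to_num(tc), occ_d.sum(axis=0)


# ---------------------------------------------------------------------------
# permutation test


def permutation_test(tuning: StemTuning, n_shuffles: int = 1000,
                     alpha: float = 0.05, seed: int = 0,
                     rng: np.random.Generator | None = None):
    """Trial-label permutation test per stem bin, for every neuron.

    Returns ``(sig_bin_mask, rel_per_bin)``, both (n_neurons, n_bins).
    ``rel_per_bin`` is the proportion of shuffles whose curve difference the
    real difference *strictly* exceeds (ties count against significance);
    a bin is significant when that proportion is at least ``1 - alpha``
    (at defaults: the real difference exceeds 950 of 1000 shuffled values).
    Invalid bins carry rel 0 and are never significant.
    """
    is_left = tuning.is_left
    nL, nR = int(is_left.sum()), int((~is_left).sum())
    if nL < 2 or nR < 2:
        raise InsufficientTrialsError("need at least two correct trials per direction")
    if rng is None:
        rng = derive_rng(seed, 3)

    real = np.abs(tuning.tc_left - tuning.tc_right)          # (N, B)
    T = is_left.size
    base = np.tile(is_left, (n_shuffles, 1))

    rel = np.zeros_like(real)
    for n in range(tuning.n_neurons):
        labels = rng.permuted(base, axis=1)                  # (S, T) bool
        diffs = _shuffled_differences(tuning.counts[n], tuning.occupancy_trials,
                                      labels, nL, nR)        # (S, B)
        rel[n] = (real[n][None, :] > diffs).mean(axis=0)
    rel[:, ~tuning.valid] = 0.0
    sig = rel >= (1.0 - alpha) - 1e-12
    sig[:, ~tuning.valid] = False
    return sig, rel


def _shuffled_differences(counts_t, occ_t, labels, nL, nR):
    """|tc_L - tc_R| for each label permutation. counts_t: (T, B); labels (S, T)."""
    L = labels.astype(np.float64)
    R = 1.0 - L
    with np.errstate(invalid="ignore", divide="ignore"):
        tcL = (L @ counts_t / nL) / (L @ occ_t / nL)
        tcR = (R @ counts_t / nR) / (R @ occ_t / nR)
    return np.abs(np.nan_to_num(tcL) - np.nan_to_num(tcR))


def exhaustive_permutation_reliability(tuning: StemTuning, neuron: int = 0):
    """Exact per-bin exceedance proportion over *all* label assignments.

    Brute-force oracle for small trial counts: enumerates every way of
    assigning nL of the trials to 'left' and computes the proportion of
    assignments whose |tc_L - tc_R| the real difference strictly exceeds.
    """
    from itertools import combinations

    is_left = tuning.is_left
    T = is_left.size
    nL, nR = int(is_left.sum()), T - int(is_left.sum())
    assignments = list(combinations(range(T), nL))
    labels = np.zeros((len(assignments), T), dtype=bool)
    for k, combo in enumerate(assignments):
        labels[k, list(combo)] = True
    diffs = _shuffled_differences(tuning.counts[neuron], tuning.occupancy_trials,
                                  labels, nL, nR)
    real = np.abs(tuning.tc_left[neuron] - tuning.tc_right[neuron])
    rel = (real[None, :] > diffs).mean(axis=0)
    rel[~tuning.valid] = 0.0
    return rel


# ---------------------------------------------------------------------------
# metrics


def classify_splitter(sig_bin_mask, n_stem_event_trials,
                      min_sig_bins: int = 3, min_stem_event_trials: int = 5):
    """Threshold rule: >= min_sig_bins significant bins and stem activity on
    >= min_stem_event_trials trials (ANOVA confirmation applied separately)."""
    sig_bin_mask = np.atleast_2d(sig_bin_mask)
    n_sig = sig_bin_mask.sum(axis=1)
    flag = (n_sig >= min_sig_bins) & (np.asarray(n_stem_event_trials) >= min_stem_event_trials)
    return flag if flag.size > 1 else bool(flag[0])


def discriminability(tc_left, tc_right, valid=None):
    """sum|L-R| / sum(L+R) over valid bins; NaN sentinel for all-zero curves."""
    tc_left = np.atleast_2d(np.asarray(tc_left, dtype=float))
    tc_right = np.atleast_2d(np.asarray(tc_right, dtype=float))
    if valid is None:
        valid = np.ones(tc_left.shape[1], dtype=bool)
    num = np.abs(tc_left - tc_right)[:, valid].sum(axis=1)
    den = (tc_left + tc_right)[:, valid].sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(den > 0, num / den, np.nan)
    return d if d.size > 1 else float(d[0])


def reliability_summary(rel_per_bin, valid=None):
    """(mean, peak) of the per-bin exceedance proportion over valid bins."""
    rel = np.atleast_2d(np.asarray(rel_per_bin, dtype=float))
    if valid is None:
        valid = np.ones(rel.shape[1], dtype=bool)
    mean = rel[:, valid].mean(axis=1)
    peak = rel[:, valid].max(axis=1)
    if mean.size == 1:
        return float(mean[0]), float(peak[0])
    return mean, peak


def tuning_correlation_metric(tc_left, tc_right, valid=None):
    """1 - Spearman rho of the unsmoothed curves; NaN if a curve is constant."""
    tc_left = np.atleast_2d(np.asarray(tc_left, dtype=float))
    tc_right = np.atleast_2d(np.asarray(tc_right, dtype=float))
    if valid is None:
        valid = np.ones(tc_left.shape[1], dtype=bool)
    out = np.full(tc_left.shape[0], np.nan)
    for i in range(tc_left.shape[0]):
        a, b = tc_left[i, valid], tc_right[i, valid]
        if np.ptp(a) == 0 or np.ptp(b) == 0:
            continue
        rho = stats.spearmanr(a, b).statistic
        out[i] = 1.0 - rho
    return out if out.size > 1 else float(out[0])


def splitting_extent(sig_bin_mask, valid=None):
    """Proportion of valid stem bins flagged significant."""
    sig = np.atleast_2d(sig_bin_mask)
    if valid is None:
        valid = np.ones(sig.shape[1], dtype=bool)
    ext = sig[:, valid].sum(axis=1) / max(int(valid.sum()), 1)
    return ext if ext.size > 1 else float(ext[0])


# ---------------------------------------------------------------------------
# ANOVA covariate check


def anova_covariate_check(events_row: np.ndarray, trace: pd.DataFrame,
                          trials: pd.DataFrame, frame_rate_hz: float,
                          n_lengthwise_bins: int = 5, alpha: float = 0.05,
                          geometry: MazeGeometry | None = None):
    """Confirm a splitter candidate against speed/lateral-position confounds.

    The stem is divided lengthwise into ``n_lengthwise_bins`` bins; the
    response is the occupancy-normalized transient probability per (trial,
    bin), modelled on trial type, stem bin and their interaction
    (categorical) plus running speed and lateral position (continuous).
    Confirmed iff the trial-type main effect or the type x bin interaction is
    significant at ``alpha``.  Covariates with (near-)zero variance are
    dropped with a logged warning.

    Returns ``(confirmed, anova_table, dropped_covariates)``.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    geometry = geometry or MazeGeometry()
    use = free_correct_trials(trials)
    lo, hi = geometry.restricted_stem()
    binw = (hi - lo) / n_lengthwise_bins
    y = trace["y"].to_numpy()
    sec = trace["section"].to_numpy()
    speed = trace["speed"].to_numpy()
    lateral = trace["lateral_position"].to_numpy()
    ev = np.asarray(events_row)

    rows = []
    for _, tr in use.iterrows():
        frames = np.arange(int(tr["stem_start"]), int(tr["stem_end"]) + 1)
        frames = frames[sec[frames] == "stem"]
        yy = y[frames]
        inside = (yy >= lo) & (yy < hi)
        frames, yy = frames[inside], yy[inside]
        b = np.minimum(((yy - lo) / binw).astype(int), n_lengthwise_bins - 1)
        for bb in range(n_lengthwise_bins):
            sel = frames[b == bb]
            if sel.size == 0:
                continue
            occ_s = sel.size / frame_rate_hz
            rows.append({
                "rate": ev[sel].sum() / occ_s,
                "turn": tr["turn"],
                "stem_bin": bb,
                "speed": speed[sel].mean(),
                "lateral": lateral[sel].mean(),
            })
    df = pd.DataFrame(rows)
    if df.empty or df["turn"].nunique() < 2:
        raise InsufficientTrialsError("ANOVA check needs trials in both directions")

    dropped = []
    terms = ["C(turn)", "C(stem_bin)", "C(turn):C(stem_bin)"]
    for cov in ("speed", "lateral"):
        if np.std(df[cov].to_numpy()) < 1e-9:
            dropped.append(cov)
            logger.warning("anova_covariate_check: dropping constant covariate %r", cov)
        else:
            terms.append(cov)
    model = smf.ols("rate ~ " + " + ".join(terms), data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)

    p_turn = table.loc["C(turn)", "PR(>F)"] if "C(turn)" in table.index else 1.0
    p_int = (table.loc["C(turn):C(stem_bin)", "PR(>F)"]
             if "C(turn):C(stem_bin)" in table.index else 1.0)
    confirmed = bool((p_turn < alpha) or (p_int < alpha))
    return confirmed, table, dropped


# ---------------------------------------------------------------------------
# session-level analysis and performance correlation


def analyze_splitters(raster: EventRaster, trace: pd.DataFrame,
                      trials: pd.DataFrame, bin_cm: float = 1.0,
                      n_shuffles: int = 1000, alpha: float = 0.05,
                      min_sig_bins: int = 3, min_stem_event_trials: int = 5,
                      seed: int = 0, run_anova: bool = True,
                      geometry: MazeGeometry | None = None):
    """Full splitter classification for one session.

    Returns ``(results_df, tuning)`` where ``results_df`` has one row per
    neuron: counts, all trajectory metrics, the permutation-criterion flag,
    ANOVA confirmation (run only on candidates) and the final splitter flag.
    """
    geometry = geometry or MazeGeometry()
    tuning = stem_tuning_curves(raster, trace, trials, bin_cm=bin_cm,
                                geometry=geometry)
    sig, rel = permutation_test(tuning, n_shuffles=n_shuffles, alpha=alpha,
                                seed=seed)
    n_sig = sig.sum(axis=1)
    passes = (n_sig >= min_sig_bins) & (tuning.n_stem_event_trials >= min_stem_event_trials)

    rel_mean, rel_peak = reliability_summary(rel, tuning.valid)
    disc = discriminability(tuning.tc_left, tuning.tc_right, tuning.valid)
    omr = tuning_correlation_metric(tuning.tc_left, tuning.tc_right, tuning.valid)
    extent = splitting_extent(sig, tuning.valid)

    anova_ok = np.zeros(tuning.n_neurons, dtype=bool)
    if run_anova:
        for i in np.flatnonzero(passes):
            try:
                ok, _, _ = anova_covariate_check(
                    raster.events[i], trace, trials, raster.frame_rate_hz,
                    alpha=alpha, geometry=geometry)
            except InsufficientTrialsError:
                ok = False
            anova_ok[i] = ok
    else:
        anova_ok[:] = passes

    df = pd.DataFrame({
        "neuron_id": tuning.neuron_ids,
        "n_sig_bins": n_sig,
        "n_stem_event_trials": tuning.n_stem_event_trials,
        "stem_active": tuning.counts.sum(axis=(1, 2)) > 0,
        "splitting_extent": np.atleast_1d(extent),
        "reliability_mean": np.atleast_1d(rel_mean),
        "reliability_peak": np.atleast_1d(rel_peak),
        "discriminability": np.atleast_1d(disc),
        "one_minus_rho": np.atleast_1d(omr),
        "passes_permutation": passes,
        "anova_confirmed": anova_ok,
        "is_splitter": passes & anova_ok,
    })
    return df, (tuning, sig, rel)


def correlate_metric_with_performance(metric_means, performances,
                                      mouse_ids=None, level: str = "sessions"):
    """Pearson correlation between session metric means and performance.

    ``level="sessions"`` correlates across all sessions; ``"mice"`` first
    averages metric and performance within each mouse.  Needs >= 3 pairs.
    """
    m = np.asarray(metric_means, dtype=float)
    p = np.asarray(performances, dtype=float)
    keep = np.isfinite(m) & np.isfinite(p)
    m, p = m[keep], p[keep]
    if level == "mice":
        if mouse_ids is None:
            raise InsufficientDataError("per-mouse correlation requires mouse_ids")
        ids = np.asarray(mouse_ids)[keep]
        mice = pd.unique(ids)
        m = np.array([m[ids == mm].mean() for mm in mice])
        p = np.array([p[ids == mm].mean() for mm in mice])
    if m.size < 3:
        raise InsufficientDataError("need at least 3 paired observations")
    r, pval = stats.pearsonr(m, p)
    return float(r), float(pval)
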