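"""Coding ontogeny: onsets, onset-aligned metric series and recruitment.

A neuron's onset for a coding class is the first session, among the sessions
where it is registered, in which it passes that class's statistical
criteria.  Metrics (splitting extent, peak reliability, peak
discriminability, spatial information) can be re-indexed by day relative to
onset and compared pre vs post; splitter and place-cell onset-day
distributions are compared with a one-sided Kolmogorov–Smirnov test and the
per-neuron onset-day difference against a symmetric-about-zero null with a
chi-square goodness-of-fit test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._util import InsufficientDataError, count_events
from .io_qc import EventRaster
from .longitudinal import NeuronRegistry

logger = logging.getLogger(__name__)


def chain_registrations(registries, n_per_session) -> pd.DataFrame:
    """Global neuron identities from consecutive-session registries.

    ``registries[k]`` links session k to session k+1.  Returns a DataFrame
    indexed by a global neuron uid with one column per session holding the
    local neuron index (-1 where the neuron is absent).
    """
    n_sessions = len(n_per_session)
    uid_of = {}          # (session, local) -> uid
    next_uid = 0
    for s in range(n_sessions):
        for i in range(n_per_session[s]):
            if (s, i) not in uid_of:
                uid_of[(s, i)] = next_uid
                next_uid += 1
        if s + 1 < n_sessions:
            for _, m in registries[s].matches.iterrows():
                uid_of[(s + 1, int(m["idx_b"]))] = uid_of[(s, int(m["idx_a"]))]
    table = np.full((next_uid, n_sessions), -1, dtype=int)
    for (s, i), u in uid_of.items():
        table[u, s] = i
    # renumber uids densely in first-appearance order
    present = (table >= 0).any(axis=1)
    return pd.DataFrame(table[present],
                        columns=[f"session_{s}" for s in range(n_sessions)])


def onset_sessions(class_flags: pd.DataFrame) -> pd.Series:
    """First session where each tracked neuron passes a class criterion.

    ``class_flags`` is uid x session; entries are True/False where the neuron
    is registered and NaN where absent.  Returns the onset session index per
    uid (NaN if the neuron never qualifies).
    """
    arr = class_flags.to_numpy(dtype=float)          # NaN-safe
    hit = arr == 1.0
    any_hit = hit.any(axis=1)
    onset = np.where(any_hit, hit.argmax(axis=1), np.nan)
    return pd.Series(onset, index=class_flags.index, name="onset_session")


def onset_table(splitter_flags: pd.DataFrame,
                place_flags: pd.DataFrame) -> pd.DataFrame:
    """Per-neuron splitter and place onsets plus their difference (sessions)."""
    so = onset_sessions(splitter_flags)
    po = onset_sessions(place_flags)
    return pd.DataFrame({"splitter_onset": so, "place_onset": po,
                         "onset_difference": so - po})


def aligned_metric_series(metric: pd.DataFrame, onsets: pd.Series,
                          session_days, window: int = 10) -> pd.DataFrame:
    """Re-index a per-neuron, per-session metric by day relative to onset.

    ``metric`` is uid x session; ``session_days`` gives each session's
    calendar day.  When several sessions share a day, the earliest defines
    that day's metric and the rest are excluded.  Neurons without an onset
    are skipped; relative days beyond ±``window`` are excluded.  Returns a
    long DataFrame (uid, rel_day, value).
    """
    session_days = np.asarray(session_days)
    n_sessions = metric.shape[1]
    first_of_day = {}
    for s in range(n_sessions):
        first_of_day.setdefault(int(session_days[s]), s)
    keep_sessions = set(first_of_day.values())

    rows = []
    vals = metric.to_numpy(dtype=float)
    for uid in range(metric.shape[0]):
        o = onsets.iloc[uid] if isinstance(onsets, pd.Series) else onsets[uid]
        if not np.isfinite(o):
            continue
        day0 = session_days[int(o)]
        for s in range(n_sessions):
            if s not in keep_sessions or not np.isfinite(vals[uid, s]):
                continue
            rel = int(session_days[s] - day0)
            if abs(rel) <= window:
                rows.append({"uid": metric.index[uid], "rel_day": rel,
                             "value": vals[uid, s]})
    return pd.DataFrame(rows, columns=["uid", "rel_day", "value"])


@dataclass
class OnsetComparison:
    ks_stat: float
    ks_p: float
    chi2: float
    chi2_p: float
    mean_difference: float
    median_difference: float
    n_differences: int


def onset_comparison(splitter_onset_days, place_onset_days,
                     differences=None, min_onsets: int = 10) -> OnsetComparison:
    """Compare splitter vs place onset-day distributions.

    One-sided two-sample KS test of the hypothesis that place onsets are
    stochastically earlier than splitter onsets, plus a chi-square
    goodness-of-fit of the per-neuron onset-day difference distribution
    against a symmetric-around-zero null (the expectation under randomly
    swapping each neuron's class labels).
    """
    a = np.asarray(splitter_onset_days, dtype=float)
    b = np.asarray(place_onset_days, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if a.size < min_onsets or b.size < min_onsets:
        raise InsufficientDataError("need at least %d onsets per class" % min_onsets)
    # 'less' tests CDF(splitter) < CDF(place): splitter onsets later
    ks = stats.ks_2samp(a, b, alternative="less")

    chi2 = chi2_p = np.nan
    mean_d = med_d = np.nan
    n_d = 0
    if differences is not None:
        d = np.asarray(differences, dtype=float)
        d = d[np.isfinite(d)]
        n_d = d.size
        if n_d:
            mean_d, med_d = float(d.mean()), float(np.median(d))
            lim = int(max(np.abs(d).max(), 1))
            edges = np.arange(-lim - 0.5, lim + 1.5)
            obs, _ = np.histogram(d, bins=edges)
            expected = 0.5 * (obs + obs[::-1])     # label-swap symmetrized
            keep = expected > 0
            chi2_stat = ((obs[keep] - expected[keep]) ** 2 / expected[keep]).sum()
            # symmetrization fixes half the cells; dof = number of strictly
            # positive-lag cells with support
            dof = max(int(keep.sum() - 1) // 2, 1)
            chi2 = float(chi2_stat)
            chi2_p = float(stats.chi2.sf(chi2_stat, dof))
    return OnsetComparison(float(ks.statistic), float(ks.pvalue), chi2, chi2_p,
                           mean_d, med_d, n_d)


def recruitment_within_session(raster: EventRaster, trace: pd.DataFrame,
                               trials: pd.DataFrame,
                               labels: pd.Series) -> pd.DataFrame:
    """First-activity time and trial for every neuron active in a session.

    The recruitment time is the clock time of the first calcium event; the
    recruitment trial is the 1-based trial whose span contains it (events
    before the first trial count as trial 1).  Silent neurons are excluded.
    """
    starts = trials["start"].to_numpy() if len(trials) else np.array([0])
    rows = []
    for i in range(raster.n_neurons):
        ev = raster.events[i]
        if not ev.any():
            continue
        f = int(np.argmax(ev))
        trial = int(np.searchsorted(starts, f, side="right"))
        rows.append({"neuron_id": raster.neuron_ids[i],
                     "first_time_s": float(raster.frame_times[f]),
                     "first_trial": max(trial, 1),
                     "class": labels.iloc[i]})
    return pd.DataFrame(rows, columns=["neuron_id", "first_time_s",
                                       "first_trial", "class"])


def recruitment_comparison(recruit: pd.DataFrame, class_a: str = "splitter",
                           class_b: str = "place",
                           column: str = "first_time_s"):
    """One-sided KS test that class_a is recruited earlier than class_b.

    ``class_b="place"`` pools stem and arm place cells.
    """
    sel_a = recruit["class"] == class_a
    if class_b == "place":
        sel_b = recruit["class"].isin(("stem_pc", "arm_pc"))
    else:
        sel_b = recruit["class"] == class_b
    a = recruit.loc[sel_a, column].to_numpy(dtype=float)
    b = recruit.loc[sel_b, column].to_numpy(dtype=float)
    if a.size < 2 or b.size < 2:
        raise InsufficientDataError("need at least 2 recruited neurons per class")
    # 'greater' tests CDF(a) > CDF(b): a stochastically smaller (earlier)
    res = stats.ks_2samp(a, b, alternative="greater")
    return float(res.statistic), float(res.pvalue)
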