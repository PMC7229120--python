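"""Cross-session neuron registration, functional coding labels and stability.

Registration matches ROI centroids between two sessions by mutual nearest
neighbours within a distance ceiling, with a shuffle-based QC on the change
of each ROI's major-axis orientation: a genuine registration concentrates
orientation changes near zero relative to an identity-shuffled null.

Functional coding types per session (mutually exclusive, exhaustive over
maze-active neurons):

    splitter   — meets the full splitter criteria
    stem_pc    — stem-active place cell failing the splitter criteria
    arm_pc     — place cell with no stem activity
    stem_npc   — stem-active, neither place cell nor splitter
    arm_npc    — not stem-active, not a place cell

Stay-active probabilities per class and session pair, optional event-rate
matching, cross-session spatial correlations of smoothed maps, and lag-wise
one-sided tests with Holm–Bonferroni correction mirror the longitudinal
stability analyses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree
from statsmodels.stats.multitest import multipletests

from ._util import RegistrationError, derive_rng

logger = logging.getLogger(__name__)

LABELS = ("splitter", "stem_pc", "arm_pc", "stem_npc", "arm_npc")


@dataclass
class NeuronRegistry:
    """One-to-one mapping between the neurons of two sessions."""

    matches: pd.DataFrame       # columns: idx_a, idx_b, distance_um, d_orientation_deg
    n_a: int
    n_b: int
    qc_verdict: str = "untested"        # untested | pass | fail | indeterminate
    qc_report: dict = field(default_factory=dict)

    def mapping(self) -> dict:
        return dict(zip(self.matches["idx_a"], self.matches["idx_b"]))


def _orientation_change(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Absolute axial (mod 180) orientation difference, in [0, 90]."""
    d = np.abs(np.mod(a - b, 180.0))
    return np.minimum(d, 180.0 - d)


def register_sessions(roi_a: pd.DataFrame, roi_b: pd.DataFrame,
                      max_dist_um: float = 5.0) -> NeuronRegistry:
    """Mutual-nearest-neighbour centroid matching within ``max_dist_um``.

    Row indices of the input tables are the per-session neuron indices; the
    match table is guaranteed one-to-one.  Tables carrying a ``scale``
    attribute must agree on it.
    """
    sa = roi_a.attrs.get("scale", None)
    sb = roi_b.attrs.get("scale", None)
    if sa is not None and sb is not None and sa != sb:
        raise RegistrationError(f"spatial scale mismatch: {sa!r} vs {sb!r}")

    pa = roi_a[["x_um", "y_um"]].to_numpy(dtype=float)
    pb = roi_b[["x_um", "y_um"]].to_numpy(dtype=float)
    if pa.size == 0 or pb.size == 0:
        empty = pd.DataFrame(columns=["idx_a", "idx_b", "distance_um",
                                      "d_orientation_deg"])
        return NeuronRegistry(empty, len(roi_a), len(roi_b))

    tree_b = cKDTree(pb)
    dist_ab, nn_ab = tree_b.query(pa)
    tree_a = cKDTree(pa)
    _, nn_ba = tree_a.query(pb)

    ia = np.arange(len(pa))
    mutual = (nn_ba[nn_ab] == ia) & (dist_ab <= max_dist_um)
    idx_a = ia[mutual]
    idx_b = nn_ab[mutual]
    d_ori = _orientation_change(
        roi_a["orientation_deg"].to_numpy(dtype=float)[idx_a],
        roi_b["orientation_deg"].to_numpy(dtype=float)[idx_b])
    matches = pd.DataFrame({"idx_a": idx_a, "idx_b": idx_b,
                            "distance_um": dist_ab[mutual],
                            "d_orientation_deg": d_ori})
    return NeuronRegistry(matches, len(roi_a), len(roi_b))


def registration_qc(registry: NeuronRegistry, roi_a: pd.DataFrame,
                    roi_b: pd.DataFrame, n_shuffles: int = 1000,
                    seed: int = 0, alpha: float = 0.05,
                    min_matches: int = 10) -> NeuronRegistry:
    """Orientation-change QC against an identity-shuffled null.

    The mean |orientation change| of the real matches is compared with the
    distribution of means obtained after shuffling the session-b identities
    of the matched neurons ``n_shuffles`` times; the pair passes when the
    real mean is significantly smaller (permutation p < alpha).  Fewer than
    ``min_matches`` matches yield an indeterminate verdict.
    """
    m = registry.matches
    if len(m) < min_matches:
        registry.qc_verdict = "indeterminate"
        registry.qc_report = {"reason": f"only {len(m)} matches"}
        return registry
    rng = derive_rng(seed, 11)
    ori_a = roi_a["orientation_deg"].to_numpy(dtype=float)[m["idx_a"].to_numpy()]
    ori_b = roi_b["orientation_deg"].to_numpy(dtype=float)[m["idx_b"].to_numpy()]
    real_mean = _orientation_change(ori_a, ori_b).mean()

    null_means = np.empty(n_shuffles)
    for s in range(n_shuffles):
        null_means[s] = _orientation_change(ori_a, rng.permutation(ori_b)).mean()
    p = (1.0 + np.sum(null_means <= real_mean)) / (n_shuffles + 1.0)
    registry.qc_verdict = "pass" if p < alpha else "fail"
    registry.qc_report = {"real_mean_deg": float(real_mean),
                          "null_mean_deg": float(null_means.mean()),
                          "p": float(p), "n_matches": int(len(m))}
    return registry


# ---------------------------------------------------------------------------
# functional coding designation


def assign_coding_labels(splitter_flags, place_flags, stem_active) -> pd.Series:
    """Deterministic per-neuron functional label (rule order matters):
    splitter beats everything; then place cells split by stem activity;
    remaining neurons split into stem/arm non-place cells."""
    splitter_flags = np.asarray(splitter_flags, dtype=bool)
    place_flags = np.asarray(place_flags, dtype=bool)
    stem_active = np.asarray(stem_active, dtype=bool)
    out = np.where(splitter_flags, "splitter",
                   np.where(place_flags & stem_active, "stem_pc",
                            np.where(place_flags, "arm_pc",
                                     np.where(stem_active, "stem_npc", "arm_npc"))))
    return pd.Series(out)


def stay_active_probability(registry: NeuronRegistry, labels_a: pd.Series,
                            run_events_a: np.ndarray, day_lag: int,
                            min_cells: int = 4, min_events: int = 5) -> pd.DataFrame:
    """Per-class probability of staying active into the later session.

    The base population of a class is its session-a neurons with at least
    ``min_events`` calcium events while running; a neuron stays active when
    the registry matches it to a session-b neuron.  Classes with fewer than
    ``min_cells`` base neurons are excluded (``included=False`` rows).
    """
    run_events_a = np.asarray(run_events_a)
    matched_a = set(registry.matches["idx_a"].tolist())
    rows = []
    for cls in LABELS:
        idx = np.flatnonzero((labels_a.to_numpy() == cls) & (run_events_a >= min_events))
        n_base = idx.size
        n_stay = int(np.isin(idx, list(matched_a)).sum())
        rows.append({
            "class": cls, "day_lag": day_lag, "n_class_session1": n_base,
            "n_still_active": n_stay,
            "probability": n_stay / n_base if n_base else np.nan,
            "included": n_base >= min_cells,
        })
    return pd.DataFrame(rows)


def event_rate_match(rates_by_class: dict, reference_class: str = "splitter"):
    """Match mean event rates to the reference class by dropping low-rate cells.

    For each non-reference class, iteratively removes the lowest-rate cell
    until the class mean reaches the reference mean.  A class whose mean is
    already at or above the reference loses no cells; a class that empties
    before matching is excluded (mask of all False).  Returns
    ``{class: keep_mask}``; the reference class is always fully kept.
    """
    ref = np.asarray(rates_by_class[reference_class], dtype=float)
    ref_mean = ref.mean() if ref.size else np.nan
    out = {}
    for cls, rates in rates_by_class.items():
        rates = np.asarray(rates, dtype=float)
        keep = np.ones(rates.size, dtype=bool)
        if cls == reference_class or not np.isfinite(ref_mean):
            out[cls] = keep
            continue
        order = np.argsort(rates, kind="stable")
        k = 0
        while keep.any() and rates[keep].mean() < ref_mean:
            keep[order[k]] = False
            k += 1
        if not keep.any():
            logger.info("event_rate_match: class %r empties before matching", cls)
        out[cls] = keep
    return out


def spatial_correlation_across_sessions(maps_a, maps_b, registry: NeuronRegistry,
                                        labels_a: pd.Series | None = None,
                                        min_bins: int = 10) -> pd.DataFrame:
    """Spearman correlation of smoothed rate maps for every matched neuron.

    ``maps_a``/``maps_b`` map the per-session neuron index to a
    :class:`~splitscope.placecells.SmoothedMap`.  Correlations use only bins
    visited in both sessions; neurons with fewer than ``min_bins`` mutually
    visited bins are skipped with a reason.
    """
    rows = []
    for _, m in registry.matches.iterrows():
        ia, ib = int(m["idx_a"]), int(m["idx_b"])
        if ia not in maps_a or ib not in maps_b:
            continue
        ma, mb = maps_a[ia], maps_b[ib]
        if ma.rate.shape != mb.rate.shape:
            rows.append({"idx_a": ia, "idx_b": ib, "rho": np.nan,
                         "n_bins": 0, "reason": "grid mismatch"})
            continue
        both = ma.visited & mb.visited
        n = int(both.sum())
        if n < min_bins:
            rows.append({"idx_a": ia, "idx_b": ib, "rho": np.nan,
                         "n_bins": n, "reason": "too few mutually visited bins"})
            continue
        rho = stats.spearmanr(ma.rate[both], mb.rate[both]).statistic
        rows.append({"idx_a": ia, "idx_b": ib, "rho": float(rho),
                     "n_bins": n, "reason": ""})
    df = pd.DataFrame(rows, columns=["idx_a", "idx_b", "rho", "n_bins", "reason"])
    if labels_a is not None and len(df):
        df["class"] = labels_a.to_numpy()[df["idx_a"].to_numpy(dtype=int)]
    return df


def lag_comparison_test(pair_stats: pd.DataFrame, value_a: str = "splitter_value",
                        value_b: str = "other_value", n_lags: int = 15,
                        min_pairs: int = 5, alpha: float = 0.05,
                        test: str = "signed_rank") -> pd.DataFrame:
    """One-sided paired test (a > b) per day lag, Holm–Bonferroni corrected.

    ``pair_stats`` has one row per session pair with columns ``day_lag``,
    ``value_a`` and ``value_b``.  Lags above ``n_lags`` or with fewer than
    ``min_pairs`` pairs are not tested; the correction family is the set of
    tested lags.  ``test`` selects the one-sided Wilcoxon signed-rank test
    (default, as in the figure captions) or the sign test.
    """
    rows = []
    for lag, grp in pair_stats.groupby("day_lag"):
        a = grp[value_a].to_numpy(dtype=float)
        b = grp[value_b].to_numpy(dtype=float)
        keep = np.isfinite(a) & np.isfinite(b)
        a, b = a[keep], b[keep]
        n = a.size
        testable = (1 <= lag <= n_lags) and n >= min_pairs
        p = np.nan
        if testable:
            d = a - b
            if np.all(d == 0):
                p = 1.0
            elif test == "signed_rank":
                p = stats.wilcoxon(a, b, alternative="greater",
                                   zero_method="wilcox").pvalue
            elif test == "sign":
                nz = d[d != 0]
                p = stats.binomtest(int((nz > 0).sum()), nz.size,
                                    alternative="greater").pvalue
            else:
                raise ValueError(f"unknown test {test!r}")
        rows.append({"day_lag": lag, "n_pairs": n, "tested": testable,
                     "p": float(p) if np.isfinite(p) else np.nan})
    df = pd.DataFrame(rows)
    df["significant"] = False
    tested = df["tested"] & df["p"].notna()
    if tested.any():
        rej, _, _, _ = multipletests(df.loc[tested, "p"], alpha=alpha,
                                     method="holm")
        df.loc[tested, "significant"] = rej
    return df
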