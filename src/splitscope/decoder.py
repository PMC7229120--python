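"""Linear-discriminant decoding of the upcoming turn from stem population activity.

Each stem time point is a sample: the feature vector is the population's
binary event activity at that frame and the label is the trial's upcoming
turn.  Per repeat, a random half of the correct trials (stratified by
direction) trains the discriminant and the held-out half is predicted;
accuracy is aggregated per ~3.3 cm spatial bin along the stem and then
averaged over bins.  The default discriminant uses a diagonal pooled
covariance (time points far outnumber trials, so a full pooled covariance is
singular); a full-covariance variant (scikit-learn's shrinkage LDA) is
available.  Chance level is measured by the identical pipeline after
shuffling trial labels; it is reported alongside accuracy, never subtracted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._util import InsufficientTrialsError, derive_rng
from .behavior import MazeGeometry, free_correct_trials
from .io_qc import EventRaster

logger = logging.getLogger(__name__)


@dataclass
class DecodeResult:
    bin_edges: np.ndarray
    bin_accuracy: np.ndarray            # per spatial bin, NaN where untested
    mean_accuracy: float                # mean over tested bins
    trial_accuracy: float               # majority vote per held-out trial
    n_repeats: int
    shuffled_labels: bool = False


class _DiagonalLDA:
    """Two-class linear discriminant with diagonal pooled covariance."""

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        mus, priors, var = [], [], np.zeros(X.shape[1])
        for c in self.classes_:
            Xc = X[y == c]
            mus.append(Xc.mean(axis=0))
            priors.append(Xc.shape[0] / X.shape[0])
            var += ((Xc - Xc.mean(axis=0)) ** 2).sum(axis=0)
        var = var / max(X.shape[0] - len(self.classes_), 1) + 1e-6
        mu0, mu1 = mus
        self.w_ = (mu1 - mu0) / var
        self.b_ = (-0.5 * ((mu1 ** 2 - mu0 ** 2) / var).sum()
                   + np.log(priors[1] / priors[0]))
        return self

    def predict(self, X):
        score = np.asarray(X, dtype=float) @ self.w_ + self.b_
        return np.where(score > 0, self.classes_[1], self.classes_[0])


def _stem_samples(raster: EventRaster, trace: pd.DataFrame, trials: pd.DataFrame,
                  geometry: MazeGeometry, bin_cm: float):
    use = free_correct_trials(trials)
    lo, hi = geometry.restricted_stem()
    n_bins = max(int(round((hi - lo) / bin_cm)), 1)
    binw = (hi - lo) / n_bins
    y = trace["y"].to_numpy()
    sec = trace["section"].to_numpy()

    frames, trial_ids, ybins, labels = [], [], [], []
    for _, tr in use.iterrows():
        f = np.arange(int(tr["stem_start"]), int(tr["stem_end"]) + 1)
        f = f[sec[f] == "stem"]
        yy = y[f]
        inside = (yy >= lo) & (yy < hi)
        f, yy = f[inside], yy[inside]
        frames.append(f)
        trial_ids.append(np.full(f.size, int(tr["trial"])))
        ybins.append(np.minimum(((yy - lo) / binw).astype(int), n_bins - 1))
        labels.append(np.full(f.size, tr["turn"]))
    frames = np.concatenate(frames)
    X = raster.events[:, frames].T.astype(float)       # (F, N)
    return (X, np.concatenate(trial_ids), np.concatenate(ybins),
            np.concatenate(labels), use, n_bins,
            lo + binw * (np.arange(n_bins + 1)))


def lda_turn_decoder(raster: EventRaster, trace: pd.DataFrame,
                     trials: pd.DataFrame, train_frac: float = 0.5,
                     n_repeats: int = 1000, bin_cm: float = 3.3,
                     seed: int = 0, rng: np.random.Generator | None = None,
                     covariance: str = "diagonal",
                     geometry: MazeGeometry | None = None,
                     shuffle_labels: bool = False) -> DecodeResult:
    """Train/test LDA decoders over ``n_repeats`` random 50/50 trial splits.

    Splits are stratified by turn direction; if a training split ever lacks a
    class it is resampled (logged).  With ``shuffle_labels=True`` the trial
    labels are permuted before each split — the chance pipeline.
    """
    geometry = geometry or MazeGeometry()
    if rng is None:
        rng = derive_rng(seed, 7)
    X, trial_ids, ybins, frame_labels, use, n_bins, edges = _stem_samples(
        raster, trace, trials, geometry, bin_cm)

    uniq_trials = use["trial"].to_numpy()
    turn_of_trial = dict(zip(use["trial"], use["turn"]))
    left_trials = np.array([t for t in uniq_trials if turn_of_trial[t] == "L"])
    right_trials = np.array([t for t in uniq_trials if turn_of_trial[t] == "R"])
    if left_trials.size < 2 or right_trials.size < 2:
        raise InsufficientTrialsError("need at least two correct trials per direction")

    if covariance == "diagonal":
        make = _DiagonalLDA
    elif covariance == "full":
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        def make():
            return LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
    else:
        raise ValueError(f"unknown covariance {covariance!r}")

    correct_bin = np.zeros(n_bins)
    total_bin = np.zeros(n_bins)
    trial_hits = 0
    trial_total = 0

    for _ in range(n_repeats):
        labels = dict(turn_of_trial)
        if shuffle_labels:
            vals = rng.permutation([turn_of_trial[t] for t in uniq_trials])
            labels = dict(zip(uniq_trials, vals))
        for _attempt in range(10):
            train = np.concatenate([
                rng.permutation(left_trials)[: max(int(train_frac * left_trials.size), 1)],
                rng.permutation(right_trials)[: max(int(train_frac * right_trials.size), 1)],
            ])
            train_set = set(train.tolist())
            y_train = np.array([labels[t] for t in trial_ids if t in train_set])
            if np.unique(y_train).size == 2:
                break
            logger.info("decoder: resampling a split missing one class")
        in_train = np.isin(trial_ids, train)
        y_all = np.array([labels[t] for t in trial_ids])
        model = make() if covariance == "diagonal" else make()
        model.fit(X[in_train], y_all[in_train])
        pred = model.predict(X[~in_train])
        ok = pred == y_all[~in_train]
        np.add.at(correct_bin, ybins[~in_train], ok)
        np.add.at(total_bin, ybins[~in_train], 1.0)
        # per-trial majority vote
        test_trials = np.setdiff1d(uniq_trials, train)
        tid_test = trial_ids[~in_train]
        for t in test_trials:
            sel = tid_test == t
            if not sel.any():
                continue
            vote = pd.Series(pred[sel]).mode().iloc[0]
            trial_hits += int(vote == labels[t])
            trial_total += 1

    with np.errstate(invalid="ignore", divide="ignore"):
        bin_acc = np.where(total_bin > 0, correct_bin / total_bin, np.nan)
    mean_acc = float(np.nanmean(bin_acc)) if np.isfinite(bin_acc).any() else float("nan")
    trial_acc = trial_hits / trial_total if trial_total else float("nan")
    return DecodeResult(edges, bin_acc, mean_acc, float(trial_acc),
                        n_repeats, shuffled_labels=shuffle_labels)


def decoder_chance(raster: EventRaster, trace: pd.DataFrame,
                   trials: pd.DataFrame, seed: int = 0, **kwargs) -> DecodeResult:
    """Chance accuracy: the identical pipeline with trial labels shuffled."""
    return lda_turn_decoder(raster, trace, trials, seed=seed,
                            shuffle_labels=True, **kwargs)
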