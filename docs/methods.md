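# Methods

This note documents the statistical procedures `splitscope` implements, the
synthetic-data model used to exercise them, the defaults and their units,
and the numerical choices made where the design was genuinely open.

## Task and data model

The task is figure-8 continuous spatial alternation: the animal runs from a
base section up a central stem (64 cm by default), chooses left or right at
the top, returns along the corresponding arm, and is rewarded only when the
turn is opposite to the previous trial's turn (the first free trial counts
as correct by convention; forced trials are flagged and excluded from every
downstream selection). Behavior is an overhead-tracking stream
(`time, x, y` at ~30 Hz) interpolated linearly onto imaging frame times
(20 Hz by default); speed comes from forward finite differences. The maze
is partitioned geometrically into six sections (base, stem, choice, entry,
return arm, approach); a trial is one complete base→approach traversal, and
incomplete traversals are dropped with a log message (how the original
hardware handled blocked mid-stem passes is unknowable from our side, so we
take the conservative option).

Neural data is a binary event raster, neurons × frames. The indicator
marks the **rising-phase epoch** of each calcium transient, not a single
frame: transient onsets are instantaneous but the inferred spiking epoch of
a GCaMP6f transient spans several frames, and all event *counts* (activity
filters, transient-count thresholds) are rising edges, one per transient.
Tuning curves and spatial maps are built from active *frames*, so they
estimate the probability of calcium activity per unit time — the quantity a
calcium tuning curve actually measures.

The stem is restricted to its central 80% before any tuning analysis
(configurable, `MazeGeometry.stem_restrict`), standing in for the manual
exclusion of the divergence zones near the choice point and base.

## Splitter identification

For each neuron, per-trial event counts and occupancy are accumulated in
1 cm bins along the restricted stem, separately for left- and right-turn
**correct free** trials. The tuning curve is mean per-trial count divided by
mean per-trial occupancy (`normalization="pooled"`; the alternative —
mean of per-trial rates — is exposed as `"per_trial"` because the verbal
description of occupancy normalization admits both readings).

Per-bin statistic: |tc_L − tc_R| (absolute value makes the per-bin test
two-sided on magnitude). Null: turn labels permuted among correct trials
with left/right counts preserved (exchangeability under the null); one
permutation is evaluated at all bins, preserving the spatial correlation of
the null. With 1000 shuffles, a bin is significant when the real statistic
strictly exceeds at least 950 shuffled values — ties count against
significance, which makes the test conservative on sparse data. The
per-bin exceedance proportion is the *reliability* of that bin; its mean
and max over valid bins summarize the neuron. Zero-occupancy bins are
masked invalid and excluded from all counts and denominators.

A neuron is a splitter when (1) ≥ 3 bins are significant, (2) it produced
stem activity on ≥ 5 trials, and (3) an ANOVA on per-(trial × lengthwise
fifth-of-stem) occupancy-normalized transient probability — categorical
turn, stem bin and turn × bin, continuous speed and lateral position —
shows a significant turn or turn × bin effect at α = 0.05. Covariates with
zero variance are dropped with a warning. The ANOVA is run only on neurons
passing (1) and (2), mirroring the screening order. Note that per-bin
significance on one neuron shares trials across bins, so the *neuron-level*
false-positive rate among stem-active cells exceeds the 5% per-bin level;
only the per-bin rate is controlled.

Derived metrics: discriminability Σ|tc_L − tc_R| / Σ(tc_L + tc_R) (scale
invariant, in [0, 1]; undefined-metric NaN when both curves are zero),
1 − Spearman ρ of the unsmoothed curves (NaN when a curve is constant),
and splitting extent = significant bins / valid bins. Session means for
performance correlations (Pearson, session level or per-mouse means)
exclude NaN sentinels.

## Place-cell identification

Frames with speed ≤ 1 cm/s are excluded. Position is binned at 4 cm;
spatial information is the mutual information between the binary event
indicator and the occupied bin, in bits (the base is configurable; base 2
is the field's convention for Skaggs-style information), with
0·log(0/·) ≡ 0. The null shuffles event timestamps: a circular shift of the
activity train within the speed-filtered frame sequence by a uniform random
offset (preserves event count and inter-event/epoch structure); a full
random permutation is available (`method="permute"`) since the original
shuffle's granularity is not recoverable. A neuron is a place cell with
≥ 5 transients and SI strictly above 95% of 1000 shuffled SIs; ties count
against classification.

Smoothed rate maps use 1 cm bins and a Gaussian kernel (σ = 2.5 cm),
smoothing event-count and occupancy maps separately before dividing (this
preserves total rate mass over interior bins); unvisited bins are masked
and excluded from any correlation. A place field is the 4-connected
component of bins above half the peak smoothed rate that contains the peak;
field length = field area / 5 cm (the effective corridor width).

## Decoding

Features are the population's binary activity at each stem frame of correct
free trials; the label is the trial's upcoming turn. Each of 1000 repeats
trains on a random half of trials (stratified by direction — an empty-class
training split cannot otherwise be ruled out) and predicts the held-out
half; accuracy is aggregated in 3.3 cm stem bins and averaged over bins,
with a per-trial majority vote also reported. The default discriminant
pools a **diagonal** covariance: stem frames far outnumber trials, so a
full pooled covariance estimated from binary features is singular;
scikit-learn's shrinkage LDA is available via `covariance="full"`. Chance
is the identical pipeline after permuting trial labels and is reported
alongside accuracy, never subtracted. With unbalanced labels the chance
pipeline converges to majority-class behavior rather than 0.5.

## Longitudinal analysis

Registration matches ROI centroids between sessions by mutual nearest
neighbour within 5 µm (configurable; the original threshold lives in prior
methods work and is not recoverable, 5 µm is a few-pixel radius at
~1.2 µm/px). QC compares the mean absolute change of ROI major-axis
orientation (axial, mod 180°) against 1000 identity-shuffled nulls; a pair
passes when the real mean is smaller than the null at p < 0.05 — an
automated version of what is otherwise a visual check. Pairs failing QC and
session pairs on a blacklist (the registration-epoch exclusion mechanism)
are dropped from longitudinal statistics; same-day pairs are excluded from
lag analyses.

Functional classes are assigned in rule order: splitter; else place cell
with/without stem activity → stem/arm place cell; else stem/arm non-place
cell by stem activity. Stay-active probability per class and session pair
is (class members with ≥ 5 running events in the first session that are
registered in the second) / (class members with ≥ 5 running events);
classes with < 4 base cells are excluded. A separate ≥ 4-event threshold
defines "active in a session" — both thresholds exist in the protocol and
are applied where each belongs. Event-rate matching iteratively drops the
lowest-rate cells of a class until its mean reaches the splitter mean
(never dropping splitters; a class already at or above loses nothing).
Cross-session spatial correlations are Spearman over bins visited in both
sessions (≥ 10 mutual bins). Lag-wise comparisons use a one-sided Wilcoxon
signed-rank test per day lag (the sign test is available — the protocol's
two descriptions disagree, and the figure-level description names
signed-rank), Holm–Bonferroni corrected over the tested lags (≤ 15; a lag
is tested with ≥ 5 pairs).

## Ontogeny

Onset = first session, among registered sessions, passing the class
criteria (consecutive-session registries are chained into global
identities). Metrics are re-indexed by day relative to onset within
± 10 days; when two sessions share a day the earlier defines that day.
Onset-day distributions are compared by one-sided two-sample KS; the
per-neuron splitter-minus-place onset difference is tested by χ²
goodness-of-fit against the symmetrized observed histogram — the
expectation under randomly swapping each neuron's two onset labels, our
choice of null since none is prescribed — with degrees of freedom counted
over the symmetry-free half of the support. Recruitment is each neuron's
first event time/trial within a session, compared between classes by
one-sided KS.

## Trace quality control

Fluorescence traces are synthesized (or supplied) per neuron; the decaying
portion of the last transient is fitted with a single exponential
(half-life = ln 2 / λ). A fit above 7 s is treated as contamination by a
neighbouring ROI and the previous transient is tried instead; neurons with
accepted half-life > 2 s, or no fittable transient, are excluded. Neurons
need ≥ 4 events to count as active in a session.

## Synthetic-data generator

The generator is the package's test bed and defines the conditions all
calibration figures refer to. Defaults (all configurable in `SynthConfig`):

| parameter | default | meaning |
|---|---|---|
| `frame_rate_hz` | 20 | imaging frame rate |
| `stem_length_cm` | 64 | central stem length |
| `stem_speed_cm_s` | 20 ± 3 | ballistic stem running speed (per-trial jitter) |
| `base_event_rate_hz` | 0.5 | in-field transient onset rate (non-preferred) |
| `modulation_ratio` | 3 | preferred : non-preferred stem rate ratio |
| `event_duration_s` | 0.4 | rising-phase epoch length |
| `field_width_cm` | 8 | place-field Gaussian s.d. |
| `error_rate` | 0.15 | probability a free trial repeats the previous turn |
| `n_trials` | 40 | trials per session |
| `persist_prob` | 0.85/0.85/0.65/0.5/0.5 | per-class per-session stay-active probability (splitter/stem PC/arm PC/stem nPC/arm nPC) |
| `roi_jitter_um` | 1 | per-session centroid jitter s.d. (sub-pixel at ~1.2 µm/px) |
| `fov_um` | 600 | field-of-view side |

Behavior: piecewise-linear traversals through the six sections with
Gaussian per-trial speed jitter and AR(1) lateral wander on the stem
(optionally biased toward the upcoming turn, `lateral_turn_bias_cm`, to
construct lateral-position confounds). Raw tracking is emitted at 30 Hz
with 0.15 cm camera noise so the alignment stage is exercised.

Events: transient onsets are a per-frame Bernoulli process with a
refractory gap of one epoch plus one frame (two transients cannot overlap,
and rising-edge counting recovers onsets exactly); the hazard is
compensated for the refractory loss so the measured onset rate equals the
configured rate (verified to < 10% relative error). The epoch length and
running speed jointly set the per-bin statistical power of the permutation
test; with instantaneous single-frame events the per-bin counts at 1 cm
bins and ballistic speeds would be far too sparse for any realistic
modulation to reach the ≥ 3-significant-bin criterion, which is why the
generator models the epoch explicitly. Rates: place-type cells have a 2-D
Gaussian field (splitters and stem place cells on the stem, arm place
cells on an arm and gated off the stem so they produce no stem activity);
splitters scale their stem rate by `modulation_ratio` on preferred-turn
trials (rate-remapping phenotype; `field_shift_mode` instead offsets the
L/R field centers). Non-place cells fire uniformly (stem nPC everywhere,
arm nPC off-stem). Multi-session turnover is a per-class Markov chain
(stay with `persist_prob`, rejoin with `rejoin_prob`); splitter modulation
can be switched on at a planted onset session
(`splitter_onset_sessions`), before which the cell behaves as a stem place
cell. All draws are keyed by `(seed, session, neuron)`, so growing the
population or the experiment never reshuffles existing entities.

What the generator does **not** emulate: fluorescence dynamics and event
inference noise (events are clean), within-session place-field drift,
remapping of field locations between sessions (a persisting neuron keeps
its field exactly, so cross-session map correlations are optimistic),
overdispersed trial-to-trial excitability, and anatomically realistic ROI
shapes. Passing tests therefore establish the *statistical* correctness
and calibration of the pipeline under the stated model, not performance on
real recordings.

## Problem sizes and numerical choices

Calibration checks run at desk scale chosen for stable statistics: 200
neurons for the permutation-test level and place-cell specificity (1000
shuffles each), 60 neurons for splitter sensitivity at the stated
conditions (ratio ≥ 3, ≥ 40 correct trials, 0.5 Hz), a 500-neuron ×
4-session experiment for persistence recovery, and ~100-neuron × 7–8
session experiments for the longitudinal and ontogeny phenotypes. The
persistence check compares the generator's realized Markov chain against
`persist_prob` with family-wise 95% binomial coverage (Bonferroni over the
five classes) and separately bounds the registration-induced bias (< 3%
absolute), since per-class 95% intervals over five classes would
false-fail about a quarter of runs by construction.

Ties always count against significance (permutation, SI shuffle, QC).
Divisions guard zero occupancy with masks, not epsilons; undefined metrics
are NaN sentinels excluded from session means. The diagonal LDA adds 1e-6
to pooled variances. Degenerate inputs (no trials in a direction, no
frames above the speed floor, < 3 correlation pairs, empty classes) raise
typed errors or produce flagged exclusion rows rather than silent numbers.
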