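"""Shared plumbing: errors, RNG derivation, event counting."""

from __future__ import annotations

import numpy as np


class SplitscopeError(Exception):
    """Base class for all package errors."""


class ConfigurationError(SplitscopeError):
    """A configuration value is invalid; the message names the offending field."""


class AlignmentError(SplitscopeError):
    """Behavior and imaging streams cannot be aligned (e.g. no temporal overlap)."""


class InsufficientTrialsError(SplitscopeError):
    """Too few trials of a required kind to run an analysis."""


class InsufficientDataError(SplitscopeError):
    """Too few observations for a statistical comparison."""


class UndefinedPerformanceError(SplitscopeError):
    """Session performance requested with zero free trials."""


class EmptyMapError(SplitscopeError):
    """No frames survive filtering when building a spatial map."""


class FormatError(SplitscopeError):
    """A file violates the documented dialect; message carries the location."""


class RegistrationError(SplitscopeError):
    """ROI tables cannot be registered (e.g. declared scale mismatch)."""


def derive_rng(seed, *keys) -> np.random.Generator:
    """Independent generator keyed by (seed, *keys).

    Streams keyed by (seed, session, neuron) are stable under changes to the
    number of neurons or sessions: adding entities never reshuffles others.
    """
    entropy = [int(seed)] + [int(k) for k in keys]
    return np.random.default_rng(np.random.SeedSequence(entropy))


def count_events(activity: np.ndarray, axis: int = -1) -> np.ndarray:
    """Number of calcium events (rising edges) in a binary activity array.

    A calcium event is one transient; its indicator spans the rising-phase
    epoch, so events are counted as 0->1 transitions (the first frame counts
    if the trace starts active).
    """
    activity = np.asarray(activity)
    act = activity.astype(bool)
    first = np.take(act, [0], axis=axis)
    rising = np.diff(act.astype(np.int8), axis=axis) == 1
    return first.sum(axis=axis) + rising.sum(axis=axis)


def event_onset_frames(activity: np.ndarray) -> np.ndarray:
    """Frame indices of event onsets (rising edges) for a 1-D activity vector."""
    act = np.asarray(activity).astype(bool)
    on = np.flatnonzero(np.diff(act.astype(np.int8)) == 1) + 1
    if act.size and act[0]:
        on = np.concatenate(([0], on))
    return on
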