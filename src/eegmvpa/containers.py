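"""Core in-memory containers for epoched EEG data.

An :class:`EpochSet` holds raw (or preprocessed) voltage epochs in microvolts;
a :class:`FeatureSet` holds per-trial baseline-normalized z-scores that serve
as classifier features.  Both carry the trial labels, time axis and validity
mask needed by every downstream stage.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = ["EpochSet", "FeatureSet", "time_mask"]


def time_mask(times: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    """Boolean mask selecting samples with ``window[0] <= t < window[1]`` (ms).

    Half-open on the right so that adjacent windows tile the epoch without
    double-counting samples.
    """
    lo, hi = window
    if not hi > lo:
        raise ValueError(f"empty time window {window!r}")
    mask = (times >= lo) & (times < hi)
    if not mask.any():
        raise ValueError(f"window {window!r} contains no samples")
    return mask


@dataclass
class EpochSet:
    """Epoched multichannel EEG: trials x channels x timepoints, in microvolts.

    Parameters
    ----------
    data:
        Array of shape ``(n_trials, n_channels, n_times)`` in μV.
    times:
        Time axis in ms, aligned so stimulus onset is at 0; strictly increasing.
    labels:
        Integer condition id per trial.
    channel_names:
        One name per channel.
    sampling_rate:
        Sampling rate in Hz.
    valid_mask:
        Per-trial boolean; ``False`` marks trials excluded by artifact
        rejection or other preprocessing.  Defaults to all-valid.
    """

    data: np.ndarray
    times: np.ndarray
    labels: np.ndarray
    channel_names: list[str]
    sampling_rate: float
    subject_id: str = ""
    valid_mask: np.ndarray | None = None
    units: str = "uV"
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.times = np.asarray(self.times, dtype=np.float64)
        self.labels = np.asarray(self.labels)
        self.channel_names = list(self.channel_names)
        if self.data.ndim != 3:
            raise ValueError("data must be (n_trials, n_channels, n_times)")
        n_trials, n_channels, n_times = self.data.shape
        if self.times.shape != (n_times,):
            raise ValueError("times length does not match data")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.labels.shape != (n_trials,):
            raise ValueError("labels length does not match data")
        if len(self.channel_names) != n_channels:
            raise ValueError("channel_names length does not match data")
        if self.valid_mask is None:
            self.valid_mask = np.ones(n_trials, dtype=bool)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.valid_mask.shape != (n_trials,):
            raise ValueError("valid_mask length does not match data")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_times(self) -> int:
        return self.data.shape[2]

    @property
    def conditions(self) -> np.ndarray:
        """Sorted unique condition ids present in the labels."""
        return np.unique(self.labels)

    def replace(self, **changes: Any) -> "EpochSet":
        """Return a copy with the given fields replaced."""
        return dataclasses.replace(self, **changes)

    def channel_index(self, names: list[str]) -> np.ndarray:
        idx = []
        for name in names:
            if name not in self.channel_names:
                raise KeyError(f"unknown channel {name!r}")
            idx.append(self.channel_names.index(name))
        return np.asarray(idx, dtype=int)

    def valid_trials(self, condition: int | None = None) -> np.ndarray:
        """Indices of valid trials, optionally restricted to one condition."""
        mask = self.valid_mask.copy()
        if condition is not None:
            mask &= self.labels == condition
        return np.flatnonzero(mask)


@dataclass
class FeatureSet:
    """Per-trial baseline-normalized z-score features (unitless).

    Same layout as :class:`EpochSet` but the amplitudes have been z-scored
    against each trial's own baseline period, per channel, so values are in
    z-units rather than μV.  ``provenance`` records the preprocessing
    parameters that produced the features.
    """

    data: np.ndarray
    times: np.ndarray
    labels: np.ndarray
    channel_names: list[str]
    sampling_rate: float
    subject_id: str = ""
    valid_mask: np.ndarray | None = None
    units: str = "z"
    provenance: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        # identical structural checks as EpochSet
        EpochSet.__post_init__(self)  # type: ignore[arg-type]

    n_trials = EpochSet.n_trials
    n_channels = EpochSet.n_channels
    n_times = EpochSet.n_times
    conditions = EpochSet.conditions
    channel_index = EpochSet.channel_index
    valid_trials = EpochSet.valid_trials

    def replace(self, **changes: Any) -> "FeatureSet":
        return dataclasses.replace(self, **changes)
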