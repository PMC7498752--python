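"""Epoch-level preprocessing: smoothing, baseline correction, artifact
rejection, channel selection, baseline z-scoring and participant inclusion.

The canonical stage order is smooth -> baseline-correct -> reject ->
select channels -> z-score; :func:`preprocess_epochs` applies it in one call.
All window arguments are half-open ms intervals ``[lo, hi)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import EpochSet, FeatureSet, time_mask

__all__ = [
    "PreprocessParams",
    "smooth_running_average",
    "baseline_correct",
    "reject_artifacts",
    "select_channels",
    "zscore_to_baseline",
    "include_participant",
    "subsample_trials",
    "preprocess_epochs",
]


@dataclass
class PreprocessParams:
    """Preprocessing settings.

    ``rejection_threshold`` is the scalp-wide absolute-amplitude cutoff in μV
    (150 is a typical infant setting, 80 an adult one).  ``channel_thresholds``
    maps individual channel names to stricter cutoffs (e.g. frontopolar
    channels for blink artifacts, horizontal EOG for eye movements); these are
    applied before ``excluded_channels`` are dropped, so EOG channels can veto
    trials and then be removed from the feature set.
    """

    smoothing_window: float = 20.0  # ms
    baseline_window: tuple[float, float] = (-50.0, 0.0)
    rejection_threshold: float = 150.0  # μV
    channel_thresholds: dict[str, float] = field(default_factory=dict)
    excluded_channels: list[str] = field(default_factory=list)
    inclusion_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.smoothing_window <= 0:
            raise ValueError("smoothing_window must be positive")
        if self.rejection_threshold <= 0:
            raise ValueError("rejection_threshold must be positive")
        if not (0.0 < self.inclusion_fraction <= 1.0):
            raise ValueError("inclusion_fraction must be in (0, 1]")
        for name, thr in self.channel_thresholds.items():
            if thr <= 0:
                raise ValueError(f"threshold for channel {name!r} must be positive")


def smooth_running_average(epochs: EpochSet, window_ms: float) -> EpochSet:
    """Centered running-average smoothing of each channel timeseries.

    The window shrinks at the epoch edges (no padding), so no data are
    fabricated outside the recorded epoch.  Timeseries length is preserved.
    """
    n_samples = int(round(window_ms * epochs.sampling_rate / 1000.0))
    n_samples = max(n_samples, 1)
    n_times = epochs.n_times
    if n_samples > n_times:
        raise ValueError(
            f"smoothing window of {n_samples} samples exceeds epoch length {n_times}"
        )
    if n_samples == 1:
        return epochs.replace(data=epochs.data.copy())
    half_left = (n_samples - 1) // 2
    half_right = n_samples // 2
    # cumulative sum along time gives O(1) window means
    csum = np.cumsum(epochs.data, axis=-1)
    csum = np.concatenate([np.zeros_like(csum[..., :1]), csum], axis=-1)
    idx = np.arange(n_times)
    lo = np.clip(idx - half_left, 0, n_times)
    hi = np.clip(idx + half_right + 1, 0, n_times)
    smoothed = (csum[..., hi] - csum[..., lo]) / (hi - lo)
    return epochs.replace(data=smoothed)


def baseline_correct(
    epochs: EpochSet, baseline_window: tuple[float, float] = (-50.0, 0.0)
) -> EpochSet:
    """Subtract each trial's per-channel mean over the baseline window."""
    mask = time_mask(epochs.times, baseline_window)
    baseline_mean = epochs.data[..., mask].mean(axis=-1, keepdims=True)
    return epochs.replace(data=epochs.data - baseline_mean)


def reject_artifacts(
    epochs: EpochSet,
    threshold: float,
    channel_thresholds: dict[str, float] | None = None,
) -> tuple[EpochSet, pd.DataFrame]:
    """Mark trials invalid whose amplitude strictly exceeds ±threshold.

    A sample exactly at the threshold is kept ("exceeded" read as strict
    inequality).  ``channel_thresholds`` adds per-channel cutoffs on top of
    the scalp-wide one.  Returns the epochs with an updated ``valid_mask``
    plus a rejection log (one row per newly rejected trial: worst channel
    and its peak absolute amplitude).
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    abs_peak = np.abs(epochs.data).max(axis=-1)  # (trials, channels)
    limits = np.full(epochs.n_channels, float(threshold))
    for name, thr in (channel_thresholds or {}).items():
        limits[epochs.channel_index([name])[0]] = min(thr, limits[epochs.channel_index([name])[0]])
    exceeded = abs_peak > limits[None, :]
    bad = exceeded.any(axis=1)
    rows = []
    for tr in np.flatnonzero(bad & epochs.valid_mask):
        ratio = abs_peak[tr] / limits
        worst = int(np.argmax(ratio))
        rows.append(
            {
                "trial": int(tr),
                "reason": "amplitude",
                "worst_channel": epochs.channel_names[worst],
                "amplitude_uv": float(abs_peak[tr, worst]),
                "threshold_uv": float(limits[worst]),
            }
        )
    log = pd.DataFrame(
        rows, columns=["trial", "reason", "worst_channel", "amplitude_uv", "threshold_uv"]
    )
    return epochs.replace(valid_mask=epochs.valid_mask & ~bad), log


def select_channels(epochs: EpochSet, excluded: list[str]) -> EpochSet:
    """Drop the named channels (e.g. the outer rim of a high-density net)."""
    if not excluded:
        return epochs.replace(data=epochs.data.copy())
    drop = set(epochs.channel_index(list(excluded)))
    keep = [i for i in range(epochs.n_channels) if i not in drop]
    if not keep:
        raise ValueError("cannot exclude every channel")
    return epochs.replace(
        data=epochs.data[:, keep, :],
        channel_names=[epochs.channel_names[i] for i in keep],
    )


def zscore_to_baseline(
    epochs: EpochSet, baseline_window: tuple[float, float] = (-50.0, 0.0)
) -> tuple[FeatureSet, pd.DataFrame]:
    """Z-score each trial and channel against its own baseline period.

    ``z = (x - baseline mean) / baseline sd`` with the sample (ddof=1)
    standard deviation.  Trials where any channel has zero baseline sd are
    marked invalid (logged) rather than producing non-finite features.
    """
    mask = time_mask(epochs.times, baseline_window)
    if mask.sum() < 2:
        raise ValueError("baseline window must contain at least 2 samples")
    base = epochs.data[..., mask]
    mean = base.mean(axis=-1, keepdims=True)
    sd = base.std(axis=-1, ddof=1, keepdims=True)
    # a railed/flat channel yields sd ~ 1e-15 * mean, not exactly 0
    tol = 1e-10 * np.maximum(1.0, np.abs(mean[..., 0]))
    flat = sd[..., 0] <= tol
    degenerate = flat.any(axis=1)
    safe_sd = np.where(flat[..., None], 1.0, sd)
    z = (epochs.data - mean) / safe_sd
    rows = [
        {"trial": int(tr), "reason": "zero_baseline_sd"}
        for tr in np.flatnonzero(degenerate & epochs.valid_mask)
    ]
    log = pd.DataFrame(rows, columns=["trial", "reason"])
    features = FeatureSet(
        data=z,
        times=epochs.times.copy(),
        labels=epochs.labels.copy(),
        channel_names=list(epochs.channel_names),
        sampling_rate=epochs.sampling_rate,
        subject_id=epochs.subject_id,
        valid_mask=epochs.valid_mask & ~degenerate,
        provenance={"baseline_window": tuple(baseline_window), "source_units": epochs.units},
    )
    return features, log


def include_participant(valid_trials: int, max_trials: int, fraction: float = 0.5) -> bool:
    """Inclusion rule: at least ``fraction`` of the maximum possible trials valid."""
    if max_trials <= 0:
        raise ValueError("max_trials must be positive")
    if not (0 <= valid_trials <= max_trials):
        raise ValueError("valid_trials must lie in [0, max_trials]")
    return valid_trials >= fraction * max_trials


def subsample_trials(
    epochs: EpochSet, target_counts: dict[int, int], seed: int
) -> EpochSet:
    """Randomly keep a fixed number of valid trials per condition.

    Used to yoke one group's trial counts to another's.  Non-selected trials
    are marked invalid (data are retained).  Uniform sampling without
    replacement, deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    keep = np.zeros(epochs.n_trials, dtype=bool)
    for cond in epochs.conditions:
        cond = int(cond)
        avail = epochs.valid_trials(cond)
        target = target_counts.get(cond, avail.size)
        if target > avail.size:
            raise ValueError(
                f"condition {cond}: requested {target} trials, only {avail.size} available"
            )
        keep[rng.choice(avail, size=target, replace=False)] = True
    return epochs.replace(valid_mask=epochs.valid_mask & keep)


def preprocess_epochs(
    epochs: EpochSet, params: PreprocessParams
) -> tuple[FeatureSet, EpochSet, pd.DataFrame]:
    """Run the full epoch-level preprocessing chain.

    Returns the classifier-ready :class:`FeatureSet`, the preprocessed (but
    non-z-scored, μV) epochs for univariate ERP analysis, and the combined
    rejection log.
    """
    out = smooth_running_average(epochs, params.smoothing_window)
    out = baseline_correct(out, params.baseline_window)
    out, reject_log = reject_artifacts(
        out, params.rejection_threshold, params.channel_thresholds
    )
    out = select_channels(out, params.excluded_channels)
    features, zscore_log = zscore_to_baseline(out, params.baseline_window)
    log = pd.concat([reject_log, zscore_log], ignore_index=True)
    return features, out, log
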