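"""Synthetic epoched-EEG generator with controllable representational geometry.

The generator emulates a passive-viewing visual paradigm: 8 stimulus
conditions split into 2 categorical domains (e.g. animals vs body parts),
each eliciting a condition-specific spatial pattern over channels that is
idiosyncratic per subject.  Signal is embedded in temporally autocorrelated,
spatially correlated noise, with occasional large-amplitude artifact trials.
Everything is deterministic given the configuration seed.

Also provides synthetic stimulus images (for the SSIM control model) and
synthetic model-activation vectors with a prescribed representational
similarity structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .containers import EpochSet

__all__ = [
    "SimulationConfig",
    "ImageSet",
    "ActivationSet",
    "default_domain_map",
    "simulate_epochs",
    "simulate_stimulus_images",
    "simulate_model_activations",
    "ground_truth_pattern_rdm",
]

#: Standard deviation of the stationary background noise, in μV.  Scalp EEG
#: after average-referencing typically fluctuates on the order of 10 μV;
#: the snr parameter is expressed relative to this scale.
NOISE_SD_UV = 10.0


def default_domain_map(n_conditions: int = 8) -> dict[int, str]:
    """First half of the conditions labelled ``animal``, second half ``body``."""
    half = n_conditions // 2
    return {c: ("animal" if c < half else "body") for c in range(n_conditions)}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic EEG experiment.

    ``snr`` is the ratio of the norm of the condition-specific spatial
    pattern (at envelope peak) to the noise standard deviation; ``snr=0``
    produces label-free null data.  ``within_domain_similarity`` and
    ``across_domain_similarity`` set the target correlation between spatial
    patterns of conditions in the same / different domains, which is what
    makes across-domain pairs easier to decode than within-domain pairs.
    """

    n_subjects: int = 10
    n_conditions: int = 8
    domain_map: Mapping[int, str] | None = None
    n_trials_per_condition: int = 16
    n_channels: int = 32
    sampling_rate: float = 1000.0
    epoch_window: tuple[float, float] = (-50.0, 500.0)
    signal_window: tuple[float, float] = (80.0, 400.0)
    snr: float = 1.0
    within_domain_similarity: float = 0.5
    across_domain_similarity: float = 0.2
    noise_ar_coefficient: float = 0.9
    spatial_noise_correlation: float = 0.3
    artifact_probability: float = 0.05
    artifact_amplitude: float = 200.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.domain_map is None:
            self.domain_map = default_domain_map(self.n_conditions)
        if self.n_conditions < 2:
            raise ValueError("need at least 2 conditions")
        if set(self.domain_map) != set(range(self.n_conditions)):
            raise ValueError("domain_map must cover conditions 0..n_conditions-1")
        if self.n_trials_per_condition < 4:
            raise ValueError("need at least 4 trials per condition")
        if self.n_channels < 2:
            raise ValueError("need at least 2 channels")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        e0, e1 = self.epoch_window
        s0, s1 = self.signal_window
        if not (e0 < e1):
            raise ValueError("empty epoch_window")
        if not (e0 <= s0 < s1 <= e1):
            raise ValueError("signal_window must lie within epoch_window")
        if self.snr < 0:
            raise ValueError("snr must be non-negative")
        for name in (
            "within_domain_similarity",
            "across_domain_similarity",
            "noise_ar_coefficient",
            "spatial_noise_correlation",
        ):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise ValueError(f"{name} must be in [0, 1)")
        if not (0.0 <= self.artifact_probability <= 1.0):
            raise ValueError("artifact_probability must be in [0, 1]")
        if self.artifact_amplitude <= 0:
            raise ValueError("artifact_amplitude must be positive")
        if self.seed < 0:
            raise ValueError("seed must be non-negative")

    @property
    def times(self) -> np.ndarray:
        """Epoch time axis in ms (onset at 0, half-open on the right)."""
        step = 1000.0 / self.sampling_rate
        e0, e1 = self.epoch_window
        n = int(round((e1 - e0) / step))
        return e0 + step * np.arange(n)


@dataclass
class ImageSet:
    """Small intensity rasters standing in for the photographic stimuli."""

    images: np.ndarray  # (n, height, width), values in [0, dynamic_range]
    condition_ids: np.ndarray
    dynamic_range: float = 1.0

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images, dtype=np.float64)
        self.condition_ids = np.asarray(self.condition_ids)
        if self.images.ndim != 3:
            raise ValueError("images must be (n, height, width)")
        if len(self.condition_ids) != len(self.images):
            raise ValueError("one condition id per image required")
        if self.images.min() < 0 or self.images.max() > self.dynamic_range:
            raise ValueError("image intensities must lie in [0, dynamic_range]")


@dataclass
class ActivationSet:
    """Per-condition activation vectors of a vision model (one row each)."""

    activations: np.ndarray  # (n_conditions, n_features)
    condition_ids: np.ndarray
    model_name: str = "model"

    def __post_init__(self) -> None:
        self.activations = np.asarray(self.activations, dtype=np.float64)
        self.condition_ids = np.asarray(self.condition_ids)
        if self.activations.ndim != 2:
            raise ValueError("activations must be (n_conditions, n_features)")
        if len(self.condition_ids) != len(self.activations):
            raise ValueError("one activation vector per condition required")


def _condition_correlation_matrix(config: SimulationConfig) -> np.ndarray:
    """Target correlation matrix between condition spatial patterns."""
    n = config.n_conditions
    domains = [config.domain_map[c] for c in range(n)]
    corr = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                corr[i, j] = 1.0
            elif domains[i] == domains[j]:
                corr[i, j] = config.within_domain_similarity
            else:
                corr[i, j] = config.across_domain_similarity
    return corr


def _psd_factor(corr: np.ndarray) -> np.ndarray:
    """Return L with L @ L.T = corr, tolerating tiny negative eigenvalues."""
    w, v = np.linalg.eigh(corr)
    if w.min() < -1e-8:
        raise ValueError("target correlation matrix is not positive semidefinite")
    return v * np.sqrt(np.clip(w, 0.0, None))


def _base_patterns(config: SimulationConfig) -> np.ndarray:
    """Unit-norm condition spatial patterns with the target correlations.

    Drawn once per configuration (not per subject): subjects receive
    orthogonally rotated copies, which preserves all pairwise geometry.
    """
    rng = np.random.default_rng([config.seed, 2**20])
    factor = _psd_factor(_condition_correlation_matrix(config))
    raw = factor @ rng.standard_normal((config.n_conditions, config.n_channels))
    return raw / np.linalg.norm(raw, axis=1, keepdims=True)


def _temporal_envelope(config: SimulationConfig) -> np.ndarray:
    """Raised-cosine envelope, 1 at signal-window midpoint, 0 outside."""
    times = config.times
    s0, s1 = config.signal_window
    env = np.zeros_like(times)
    inside = (times >= s0) & (times < s1)
    phase = (times[inside] - s0) / (s1 - s0)
    env[inside] = 0.5 * (1.0 - np.cos(2.0 * np.pi * phase))
    return env


def _ar1_noise(
    rng: np.random.Generator, n_trials: int, n_channels: int, n_times: int,
    ar: float, spatial_corr: float,
) -> np.ndarray:
    """Stationary unit-variance AR(1) noise with uniformly correlated channels."""
    spatial_cov = np.full((n_channels, n_channels), spatial_corr)
    np.fill_diagonal(spatial_cov, 1.0)
    ls = np.linalg.cholesky(spatial_cov)
    innov = rng.standard_normal((n_trials, n_times, n_channels)) @ ls.T
    innov = innov.transpose(0, 2, 1)  # (trials, channels, times)
    noise = np.empty_like(innov)
    noise[..., 0] = innov[..., 0]
    scale = np.sqrt(1.0 - ar**2)
    for t in range(1, n_times):
        noise[..., t] = ar * noise[..., t - 1] + scale * innov[..., t]
    return noise


def simulate_epochs(config: SimulationConfig, subject_index: int = 0) -> EpochSet:
    """Simulate one subject's epoched EEG.

    The subject's condition patterns are the configuration-level base
    patterns rotated by a subject-specific random orthogonal map, so each
    subject expresses the same representational geometry through an
    idiosyncratic channel topography — the regime that motivates
    within-subject (rather than cross-subject) classification.

    Deterministic given ``(config.seed, subject_index)``.
    """
    if subject_index < 0:
        raise ValueError("subject_index must be non-negative")
    rng = np.random.default_rng([config.seed, subject_index])
    times = config.times
    n_times = times.size
    n_cond = config.n_conditions
    n_trials = n_cond * config.n_trials_per_condition

    # subject-specific orthogonal rotation of the shared geometry
    gauss = rng.standard_normal((config.n_channels, config.n_channels))
    q, r = np.linalg.qr(gauss)
    q *= np.sign(np.diag(r))  # unique Q, Haar-distributed
    patterns = _base_patterns(config) @ q.T

    labels = rng.permutation(np.repeat(np.arange(n_cond), config.n_trials_per_condition))
    noise = NOISE_SD_UV * _ar1_noise(
        rng, n_trials, config.n_channels, n_times,
        config.noise_ar_coefficient, config.spatial_noise_correlation,
    )
    envelope = _temporal_envelope(config)
    signal_scale = config.snr * NOISE_SD_UV
    data = noise + signal_scale * patterns[labels][:, :, None] * envelope[None, None, :]

    # occasional artifact trials: one channel driven beyond artifact_amplitude
    artifact_trials = np.flatnonzero(rng.random(n_trials) < config.artifact_probability)
    pulse_len = max(1, int(round(20.0 * config.sampling_rate / 1000.0)))
    for tr in artifact_trials:
        ch = rng.integers(config.n_channels)
        start = rng.integers(max(1, n_times - pulse_len + 1))
        sign = 1.0 if rng.random() < 0.5 else -1.0
        magnitude = config.artifact_amplitude * (1.2 + 0.3 * rng.random())
        data[tr, ch, start : start + pulse_len] += sign * magnitude

    return EpochSet(
        data=data,
        times=times,
        labels=labels,
        channel_names=[f"E{i + 1}" for i in range(config.n_channels)],
        sampling_rate=config.sampling_rate,
        subject_id=f"sub-{subject_index:02d}",
        units="uV",
        meta={
            "seed": config.seed,
            "subject_index": subject_index,
            "snr": config.snr,
            "n_artifact_trials": int(artifact_trials.size),
        },
    )


def ground_truth_pattern_rdm(config: SimulationConfig) -> np.ndarray:
    """Euclidean distances between the generator's condition patterns.

    Orthogonal rotations preserve distances, so this one matrix is the
    ground-truth representational geometry shared by every simulated
    subject.  Diagonal is 0.
    """
    patterns = _base_patterns(config)
    diff = patterns[:, None, :] - patterns[None, :, :]
    return np.linalg.norm(diff, axis=-1)


def simulate_stimulus_images(
    n: int,
    shape: tuple[int, int] = (64, 64),
    seed: int = 0,
    variation: float = 0.5,
) -> ImageSet:
    """Synthetic stimulus rasters: shared smooth background + per-condition blob.

    ``variation`` scales the condition-specific component; small values give
    highly similar images (pairwise SSIM near 1), large values dissimilar
    ones.  Intensities are normalized to [0, 1].
    """
    if n < 2:
        raise ValueError("need at least 2 images")
    h, w = shape
    if h < 8 or w < 8:
        raise ValueError(f"degenerate image shape {shape!r}")
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:h, 0:w]

    # shared low-frequency background: sum of a few broad Gaussians
    background = np.zeros((h, w))
    for _ in range(4):
        cy, cx = rng.uniform(0, h), rng.uniform(0, w)
        s = rng.uniform(0.2, 0.5) * min(h, w)
        background += rng.uniform(0.3, 1.0) * np.exp(
            -((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * s**2)
        )

    images = np.empty((n, h, w))
    for i in range(n):
        cy, cx = rng.uniform(h * 0.2, h * 0.8), rng.uniform(w * 0.2, w * 0.8)
        s = rng.uniform(0.06, 0.15) * min(h, w)
        blob = np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * s**2))
        images[i] = background + variation * blob
    images -= images.min()
    peak = images.max()
    if peak > 0:
        images /= peak
    return ImageSet(images=images, condition_ids=np.arange(n), dynamic_range=1.0)


def simulate_model_activations(
    target_rsm: np.ndarray,
    n_features: int = 10_000,
    seed: int = 0,
    model_name: str = "synthetic-model",
) -> ActivationSet:
    """Activation vectors whose pairwise Pearson correlations approximate a target.

    The target representational similarity matrix must be symmetric positive
    semidefinite with unit diagonal.  Realized correlations deviate from the
    target by sampling error of order ``1/sqrt(n_features)``.
    """
    target_rsm = np.asarray(target_rsm, dtype=np.float64)
    n = target_rsm.shape[0]
    if target_rsm.shape != (n, n) or not np.allclose(target_rsm, target_rsm.T):
        raise ValueError("target RSM must be square and symmetric")
    if not np.allclose(np.diag(target_rsm), 1.0):
        raise ValueError("target RSM must have unit diagonal")
    if n_features < 2:
        raise ValueError("need at least 2 features")
    factor = _psd_factor(target_rsm)  # raises if not PSD
    rng = np.random.default_rng(seed)
    acts = factor @ rng.standard_normal((n, n_features))
    return ActivationSet(
        activations=acts, condition_ids=np.arange(n), model_name=model_name
    )
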