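"""Within-subject time-resolved decoding with pseudo-trial averaging.

For each pair of stimulus conditions and each timepoint, a linear
soft-margin SVM (C = 1) is trained on pseudo-trials — averages of randomly
partitioned single trials — and tested on the held-out pseudo-trial fold.
The randomize/partition/train/test procedure is repeated many times and
accuracies averaged, which stabilizes the estimate.  Also provides
one-vs-one multiclass decoding, temporal generalization (train at one time,
test at all others), and conversion of classifier weights to interpretable
activation patterns via the feature covariance (the Haufe transform).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Any, Sequence

import numpy as np
import pandas as pd

from .containers import FeatureSet, time_mask
from .svm import decision_function, fit_linear_svm_batch

__all__ = [
    "DecodeParams",
    "PairwiseDecodingResult",
    "TemporalGeneralizationMatrix",
    "ActivationPattern",
    "make_pseudotrials",
    "decode_pair_timecourse",
    "decode_all_pairs",
    "decode_multiclass_timecourse",
    "temporal_generalization",
    "weights_to_activation_pattern",
    "average_absolute_patterns",
]

CHANCE_PAIRWISE = 50.0  # % — theoretical chance for two balanced classes


@dataclass
class DecodeParams:
    """Cross-validated decoding settings.

    ``fold_rotation=True`` tests every fold in turn within each repeat
    (lower-variance); ``False`` holds out only the last fold per repeat,
    the literal single-test-fold scheme.  Both are unbiased because fold
    membership is re-randomized every repeat.
    """

    n_folds: int = 4
    n_repeats: int = 200
    C: float = 1.0
    seed: int = 0
    fold_rotation: bool = True

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be at least 2")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be at least 1")
        if self.C <= 0:
            raise ValueError("C must be positive")


@dataclass
class PairwiseDecodingResult:
    """Per-pair accuracy timecourses (%) for one subject."""

    accuracies: np.ndarray  # (n_pairs, n_times), in %
    pairs: list[tuple[int, int]]
    times: np.ndarray  # ms
    subject_id: str = ""
    params: dict[str, Any] = field(default_factory=dict)

    def mean_timecourse(self) -> np.ndarray:
        """Accuracy averaged over pairs, per timepoint."""
        return self.accuracies.mean(axis=0)

    def pair_index(self, pair: tuple[int, int]) -> int:
        key = (min(pair), max(pair))
        return self.pairs.index(key)

    def to_frame(self) -> pd.DataFrame:
        """Tidy table: subject, pair, time_ms, accuracy_pct."""
        rows = []
        for (a, b), acc in zip(self.pairs, self.accuracies):
            for t, v in zip(self.times, acc):
                rows.append((self.subject_id, a, b, t, v))
        return pd.DataFrame(
            rows, columns=["subject", "cond_a", "cond_b", "time_ms", "accuracy_pct"]
        )


@dataclass
class TemporalGeneralizationMatrix:
    """Train-time x test-time accuracy (%) for one pair (or pair average)."""

    accuracy: np.ndarray  # (n_times, n_times), rows = training time
    times: np.ndarray
    pair: tuple[int, int] | str = "average"
    subject_id: str = ""

    def diagonal(self) -> np.ndarray:
        return np.diag(self.accuracy)


@dataclass
class ActivationPattern:
    """Channel-space pattern reconstructed from classifier weights."""

    values: np.ndarray  # (n_channels,)
    time_ms: float
    pair: tuple[int, int] | str = "average"


def _rng_for(seed: int, *stream: int) -> np.random.Generator:
    """Independent, reproducible stream for (seed, pair, repeat, ...)."""
    return np.random.default_rng([int(seed)] + [int(s) for s in stream])


def make_pseudotrials(
    trials_a: np.ndarray,
    trials_b: np.ndarray,
    n_folds: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Randomly partition each condition's trials into folds and average.

    Returns exactly ``n_folds`` pseudo-trials per condition (fold sizes
    differ by at most one trial).  The two conditions are partitioned
    independently, so pseudo-trials may average different trial counts when
    the conditions have unequal numbers of trials.
    """
    return (
        _pseudotrial_folds(trials_a, n_folds, rng, "A"),
        _pseudotrial_folds(trials_b, n_folds, rng, "B"),
    )


def _pseudotrial_folds(
    trials: np.ndarray, n_folds: int, rng: np.random.Generator, name: str = ""
) -> np.ndarray:
    n = trials.shape[0]
    if n < n_folds:
        raise ValueError(
            f"condition {name or '?'} has {n} trials, fewer than {n_folds} folds"
        )
    order = rng.permutation(n)
    return np.stack(
        [trials[idx].mean(axis=0) for idx in np.array_split(order, n_folds)]
    )


def _condition_features(features: FeatureSet, cond: int) -> np.ndarray:
    idx = features.valid_trials(int(cond))
    X = features.data[idx]
    if not np.isfinite(X).all():
        raise ValueError(f"non-finite features in condition {cond}")
    return X


_TRAIN_LABELS_CACHE: dict[int, np.ndarray] = {}


def _train_labels(n_folds: int) -> np.ndarray:
    if n_folds not in _TRAIN_LABELS_CACHE:
        k = n_folds - 1
        _TRAIN_LABELS_CACHE[n_folds] = np.concatenate(
            [-np.ones(k), np.ones(k)]
        )
    return _TRAIN_LABELS_CACHE[n_folds]


def decode_pair_timecourse(
    features: FeatureSet,
    cond_a: int,
    cond_b: int,
    params: DecodeParams,
    return_patterns: bool = False,
) -> np.ndarray | tuple[np.ndarray, np.ndarray]:
    """Accuracy timecourse (%) for one condition pair.

    Features are the channel z-scores at each timepoint.  Deterministic
    given ``params.seed``; the random stream is derived from
    ``(seed, cond_a, cond_b, repeat)`` so each pair and repeat is
    independent and reproducible.

    With ``return_patterns=True`` also returns the repeat-averaged Haufe
    activation pattern per timepoint, shape ``(n_times, n_channels)``.
    """
    cond_a, cond_b = sorted((int(cond_a), int(cond_b)))
    Xa = _condition_features(features, cond_a)
    Xb = _condition_features(features, cond_b)
    k = params.n_folds
    T = features.n_times
    test_folds = list(range(k)) if params.fold_rotation else [k - 1]
    y = _train_labels(k)

    correct = np.zeros(T)
    total = 0
    pattern_sum = np.zeros((T, features.n_channels)) if return_patterns else None
    n_patterns = 0
    for r in range(params.n_repeats):
        rng = _rng_for(params.seed, cond_a, cond_b, r)
        ps_a, ps_b = make_pseudotrials(Xa, Xb, k, rng)
        X_train, X_test = _fold_problems(ps_a, ps_b, test_folds)
        w, b = fit_linear_svm_batch(X_train, y, C=params.C)
        dec = decision_function(w, b, X_test).reshape(len(test_folds), T, 2)
        correct += ((dec[..., 0] < 0).sum(axis=0) + (dec[..., 1] >= 0).sum(axis=0))
        total += 2 * len(test_folds)
        if return_patterns:
            pattern_sum += _haufe_patterns(X_train, w).reshape(
                len(test_folds), T, -1
            ).sum(axis=0)
            n_patterns += len(test_folds)
    accuracy = 100.0 * correct / total
    if return_patterns:
        return accuracy, pattern_sum / n_patterns
    return accuracy


def _fold_problems(
    ps_a: np.ndarray, ps_b: np.ndarray, test_folds: list[int]
) -> tuple[np.ndarray, np.ndarray]:
    """Stack (fold, time) training and test sets for the batched solver.

    ``ps_a``/``ps_b``: (n_folds, n_channels, n_times) pseudo-trials.
    Returns X_train (F*T, n_train, C) and X_test (F*T, 2, C).
    """
    k, n_ch, T = ps_a.shape
    trains, tests = [], []
    for f in test_folds:
        keep = [g for g in range(k) if g != f]
        train = np.concatenate([ps_a[keep], ps_b[keep]])  # (2k-2, C, T)
        trains.append(train.transpose(2, 0, 1))  # (T, n, C)
        tests.append(np.stack([ps_a[f], ps_b[f]]).transpose(2, 0, 1))  # (T, 2, C)
    return np.concatenate(trains), np.concatenate(tests)


def _haufe_patterns(X_train: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Batched Haufe transform: pattern = training-feature covariance @ w."""
    centered = X_train - X_train.mean(axis=1, keepdims=True)
    n = X_train.shape[1]
    cov = np.einsum("bnc,bnd->bcd", centered, centered) / (n - 1)
    return np.einsum("bcd,bd->bc", cov, weights)


def decode_all_pairs(
    features: FeatureSet,
    params: DecodeParams,
    conditions: Sequence[int] | None = None,
) -> PairwiseDecodingResult:
    """Accuracy timecourses for every unordered condition pair.

    Pairs are ordered lexicographically by condition id.
    """
    conds = sorted(int(c) for c in (conditions if conditions is not None else features.conditions))
    pairs = list(combinations(conds, 2))
    acc = np.stack(
        [decode_pair_timecourse(features, a, b, params) for a, b in pairs]
    )
    return PairwiseDecodingResult(
        accuracies=acc,
        pairs=pairs,
        times=features.times.copy(),
        subject_id=features.subject_id,
        params={
            "n_folds": params.n_folds,
            "n_repeats": params.n_repeats,
            "seed": params.seed,
            "fold_rotation": params.fold_rotation,
        },
    )


def decode_multiclass_timecourse(
    features: FeatureSet,
    params: DecodeParams,
    conditions: Sequence[int] | None = None,
) -> np.ndarray:
    """Multiclass accuracy timecourse (%) via one-vs-one voting.

    All pairwise classifiers vote on each held-out pseudo-trial; ties go to
    the lowest condition id.  Chance is ``100 / n_conditions`` %.
    """
    conds = sorted(int(c) for c in (conditions if conditions is not None else features.conditions))
    n_cond = len(conds)
    if n_cond < 2:
        raise ValueError("need at least 2 conditions")
    X_by_cond = [_condition_features(features, c) for c in conds]
    k = params.n_folds
    T = features.n_times
    pairs = list(combinations(range(n_cond), 2))
    test_folds = list(range(k)) if params.fold_rotation else [k - 1]
    y = _train_labels(k)

    correct = np.zeros(T)
    total = 0
    for r in range(params.n_repeats):
        rng = _rng_for(params.seed, 10_000, r)
        ps = [_pseudotrial_folds(X, k, rng, str(c)) for X, c in zip(X_by_cond, conds)]
        for f in test_folds:
            keep = [g for g in range(k) if g != f]
            trains = []
            for a, b in pairs:
                train = np.concatenate([ps[a][keep], ps[b][keep]])
                trains.append(train.transpose(2, 0, 1))
            X_train = np.concatenate(trains)  # (P*T, n, C)
            w, b_ = fit_linear_svm_batch(X_train, y, C=params.C)
            # every pair classifier scores all n_cond held-out pseudo-trials
            test = np.stack([ps[c][f] for c in range(n_cond)])  # (n_cond, C, T)
            test = test.transpose(2, 0, 1)  # (T, n_cond, C)
            X_test = np.tile(test, (len(pairs), 1, 1))
            dec = decision_function(w, b_, X_test).reshape(len(pairs), T, n_cond)
            votes = np.zeros((T, n_cond, n_cond))
            for p, (a, b) in enumerate(pairs):
                votes[:, :, a] += dec[p] < 0
                votes[:, :, b] += dec[p] >= 0
            pred = votes.argmax(axis=-1)  # (T, n_cond) — ties -> lowest id
            correct += (pred == np.arange(n_cond)[None, :]).sum(axis=1)
            total += n_cond
    return 100.0 * correct / total


def temporal_generalization(
    features: FeatureSet,
    cond_a: int,
    cond_b: int,
    params: DecodeParams,
) -> TemporalGeneralizationMatrix:
    """Train at each timepoint, test at every timepoint (one condition pair).

    Within a repeat the same fold partition is reused for all training and
    test times, so the matrix diagonal reproduces the standard timecourse
    procedure (up to Monte-Carlo noise when seeds differ).
    """
    cond_a, cond_b = sorted((int(cond_a), int(cond_b)))
    Xa = _condition_features(features, cond_a)
    Xb = _condition_features(features, cond_b)
    k = params.n_folds
    T = features.n_times
    test_folds = list(range(k)) if params.fold_rotation else [k - 1]
    y = _train_labels(k)

    correct = np.zeros((T, T))
    total = 0
    for r in range(params.n_repeats):
        rng = _rng_for(params.seed, cond_a, cond_b, r)
        ps_a, ps_b = make_pseudotrials(Xa, Xb, k, rng)
        for f in test_folds:
            keep = [g for g in range(k) if g != f]
            train = np.concatenate([ps_a[keep], ps_b[keep]]).transpose(2, 0, 1)
            w, b = fit_linear_svm_batch(train, y, C=params.C)  # (T, ...)
            # test both held-out pseudo-trials at all test times at once
            test = np.stack([ps_a[f], ps_b[f]])  # (2, C, T)
            flat = test.transpose(2, 0, 1).reshape(2 * T, -1)  # (T_test*2, C)
            X_test = np.broadcast_to(flat, (T, 2 * T, flat.shape[1]))
            dec = decision_function(w, b, X_test).reshape(T, T, 2)
            correct += (dec[..., 0] < 0).astype(np.int64) + (dec[..., 1] >= 0)
            total += 2
    return TemporalGeneralizationMatrix(
        accuracy=100.0 * correct / total,
        times=features.times.copy(),
        pair=(cond_a, cond_b),
        subject_id=features.subject_id,
    )


def weights_to_activation_pattern(
    weights: np.ndarray,
    feature_covariance: np.ndarray,
    time_ms: float = float("nan"),
    pair: tuple[int, int] | str = "average",
) -> ActivationPattern:
    """Haufe transform of linear classifier weights: pattern = Σ @ w.

    For a linear two-class model the product of the feature covariance and
    the weight vector recovers the activation pattern actually expressed in
    the data, which — unlike raw weights — is interpretable channel-wise
    (suppressor channels get near-zero pattern loadings).
    """
    w = np.asarray(weights, dtype=np.float64)
    cov = np.asarray(feature_covariance, dtype=np.float64)
    if w.ndim != 1:
        raise ValueError("weights must be a vector")
    if cov.shape != (w.size, w.size):
        raise ValueError(
            f"covariance shape {cov.shape} incompatible with {w.size} weights"
        )
    return ActivationPattern(values=cov @ w, time_ms=time_ms, pair=pair)


def average_absolute_patterns(patterns: Sequence[np.ndarray]) -> np.ndarray:
    """Mean absolute activation pattern over pairs and/or timepoints.

    Accepts any sequence of equal-length channel patterns (or stacked
    arrays whose last axis is channels).
    """
    arrays = [np.atleast_2d(np.asarray(p, dtype=np.float64)) for p in patterns]
    if not arrays:
        raise ValueError("no patterns given")
    stacked = np.concatenate([a.reshape(-1, a.shape[-1]) for a in arrays])
    return np.abs(stacked).mean(axis=0)


def window_mean_accuracy(
    result: PairwiseDecodingResult, window: tuple[float, float]
) -> np.ndarray:
    """Per-pair accuracy averaged over a half-open ms window."""
    mask = time_mask(result.times, window)
    return result.accuracies[:, mask].mean(axis=1)
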