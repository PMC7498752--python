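"""Group-level nonparametric inference for decoding timecourses.

Implements sign-permutation tests with cluster-based correction for
multiple comparisons over timepoints (1D) or train-time x test-time grids
(2D, 4-neighborhood connectivity).  The permutation scheme flips the sign
of each subject's entire (null-centered) series, which is exact under the
null hypothesis that each subject's effect is symmetric around the null
value.  When the group is small enough, all 2^n sign assignments are
enumerated; otherwise a seeded random subset is drawn.  Cluster p-values
use the add-one rule, guaranteeing validity under sampling.

Also provides Benjamini-Hochberg FDR correction and add-one empirical
p-values for externally supplied null distributions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any, Literal

import numpy as np
import pandas as pd
from scipy import ndimage
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ClusterTestParams",
    "ClusterTestResult",
    "sign_permutation_cluster_test_1d",
    "sign_permutation_cluster_test_2d",
    "paired_difference_series",
    "fdr_correct",
    "empirical_pvalue",
    "cluster_report",
]


@dataclass
class ClusterTestParams:
    """Settings of the cluster-corrected sign permutation test.

    ``null_value`` is subtracted from every series before testing (50 for
    accuracies against chance, 0 for paired differences).  The cluster
    statistic is the cluster mass (sum of point statistics) by default;
    ``cluster_statistic="extent"`` uses the number of supra-threshold
    points instead.
    """

    tail: Literal["right", "two-sided"] = "right"
    cluster_alpha: float = 0.05
    alpha: float = 0.05
    marginal_alpha: float = 0.10
    n_permutations: int = 10_000
    null_value: float = 0.0
    cluster_statistic: Literal["mass", "extent"] = "mass"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("cluster_alpha", "alpha", "marginal_alpha"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must be in (0, 1)")
        if self.alpha > self.marginal_alpha:
            raise ValueError("alpha must not exceed marginal_alpha")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be positive")
        if self.cluster_statistic not in ("mass", "extent"):
            raise ValueError("cluster_statistic must be 'mass' or 'extent'")
        if self.tail not in ("right", "two-sided"):
            raise ValueError("tail must be 'right' or 'two-sided'")


@dataclass
class ClusterTestResult:
    """Point statistics, clusters and permutation p-values of one test."""

    point_stat: np.ndarray  # mean effect (original scale minus null_value)
    pointwise_p: np.ndarray
    clusters: list[np.ndarray]  # boolean masks, one per cluster
    cluster_stats: np.ndarray
    cluster_pvalues: np.ndarray
    significant: np.ndarray  # bool per cluster, p <= alpha
    marginal: np.ndarray  # bool per cluster, alpha < p <= marginal_alpha
    n_permutations: int
    exhaustive: bool
    params: dict[str, Any] = field(default_factory=dict)

    @property
    def any_significant(self) -> bool:
        return bool(self.significant.any())

    def significant_mask(self) -> np.ndarray:
        """Union of all significant clusters as a boolean map."""
        mask = np.zeros_like(self.point_stat, dtype=bool)
        for cl, sig in zip(self.clusters, self.significant):
            if sig:
                mask |= cl
        return mask


def _sign_matrix(
    n_subjects: int, n_permutations: int, seed: int
) -> tuple[np.ndarray, bool]:
    """All (or a random subset of) +-1 sign assignments, one row per permutation."""
    if n_subjects <= 30 and 2**n_subjects <= n_permutations:
        grid = np.arange(2**n_subjects, dtype=np.int64)
        signs = ((grid[:, None] >> np.arange(n_subjects)) & 1) * 2.0 - 1.0
        return signs, True
    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_permutations, n_subjects))
    return signs, False


def _max_run_stat_1d(vals: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Per-row maximum of contiguous-run sums of ``vals`` where ``mask``.

    Vectorized over rows; rows without any run return 0.
    """
    P, T = mask.shape
    padded_mask = np.concatenate([mask, np.zeros((P, 1), dtype=bool)], axis=1).ravel()
    padded_vals = np.concatenate([vals * mask, np.zeros((P, 1))], axis=1).ravel()
    prev = np.concatenate([[False], padded_mask[:-1]])
    starts = np.flatnonzero(padded_mask & ~prev)
    if starts.size == 0:
        return np.zeros(P)
    nxt = np.concatenate([padded_mask[1:], [False]])
    ends = np.flatnonzero(padded_mask & ~nxt)
    csum = np.concatenate([[0.0], np.cumsum(padded_vals)])
    masses = csum[ends + 1] - csum[starts]
    rows = starts // (T + 1)
    out = np.zeros(P)
    np.maximum.at(out, rows, masses)
    return out


def _pointwise_threshold(perm_vals: np.ndarray, cluster_alpha: float) -> np.ndarray:
    """Per-position critical value: v is supra-threshold iff v > threshold.

    Chosen so that the add-one permutation p-value of v is <= cluster_alpha.
    """
    P = perm_vals.shape[0]
    m = int(np.floor(cluster_alpha * (P + 1) - 1))
    if m < 0:
        return np.full(perm_vals.shape[1], np.inf)
    return -np.partition(-perm_vals, m, axis=0)[m]


def _cluster_test(
    data: np.ndarray, params: ClusterTestParams, shape: tuple[int, ...]
) -> ClusterTestResult:
    """Shared engine for the 1D and 2D tests; ``data`` is (subjects, positions)."""
    S = data.shape[0]
    if S < 2:
        raise ValueError("sign permutation test requires at least 2 subjects")
    centered = data - params.null_value
    if np.allclose(centered.std(axis=0), 0.0):
        warnings.warn(
            "all subjects identical: permutation distribution is degenerate",
            RuntimeWarning,
            stacklevel=3,
        )
    signs, exhaustive = _sign_matrix(S, params.n_permutations, params.seed)
    P = signs.shape[0]
    perm_means = signs @ centered / S  # (P, K)
    observed = centered.mean(axis=0)

    if params.tail == "two-sided":
        perm_vals, obs_vals = np.abs(perm_means), np.abs(observed)
    else:
        perm_vals, obs_vals = perm_means, observed

    # tolerance so the identity assignment (whose statistic equals the
    # observed one up to summation-order rounding) always counts
    tol = 1e-9 * (1.0 + np.abs(obs_vals))
    pointwise_p = (1 + (perm_vals >= (obs_vals - tol)[None, :]).sum(axis=0)) / (1 + P)
    thr = _pointwise_threshold(perm_vals, params.cluster_alpha)
    obs_mask = obs_vals > thr
    perm_mask = perm_vals > thr[None, :]
    mass_vals_perm = perm_vals if params.cluster_statistic == "mass" else np.ones_like(perm_vals)
    mass_vals_obs = obs_vals if params.cluster_statistic == "mass" else np.ones_like(obs_vals)

    if len(shape) == 1:
        null_max = _max_run_stat_1d(mass_vals_perm, perm_mask)
    else:
        null_max = np.zeros(P)
        for p in range(P):
            null_max[p] = _max_cluster_stat_2d(
                mass_vals_perm[p].reshape(shape), perm_mask[p].reshape(shape)
            )

    clusters, stats = _observed_clusters(mass_vals_obs, obs_mask, shape)
    pvals = np.array(
        [(1 + (null_max >= s - 1e-9 * (1.0 + abs(s))).sum()) / (1 + P) for s in stats]
    )
    return ClusterTestResult(
        point_stat=observed.reshape(shape),
        pointwise_p=pointwise_p.reshape(shape),
        clusters=[c.reshape(shape) for c in clusters],
        cluster_stats=stats,
        cluster_pvalues=pvals,
        significant=pvals <= params.alpha if pvals.size else np.zeros(0, bool),
        marginal=(pvals > params.alpha) & (pvals <= params.marginal_alpha)
        if pvals.size
        else np.zeros(0, bool),
        n_permutations=P,
        exhaustive=exhaustive,
        params={
            "tail": params.tail,
            "cluster_alpha": params.cluster_alpha,
            "alpha": params.alpha,
            "marginal_alpha": params.marginal_alpha,
            "null_value": params.null_value,
            "cluster_statistic": params.cluster_statistic,
            "seed": params.seed,
        },
    )


def _observed_clusters(
    vals: np.ndarray, mask: np.ndarray, shape: tuple[int, ...]
) -> tuple[list[np.ndarray], np.ndarray]:
    """Connected supra-threshold components and their statistics."""
    labelled, n = ndimage.label(mask.reshape(shape))  # 4-neighborhood in 2D
    labelled = labelled.ravel()
    clusters, stats = [], []
    for lab in range(1, n + 1):
        cl = labelled == lab
        clusters.append(cl)
        stats.append(vals[cl].sum())
    return clusters, np.asarray(stats, dtype=np.float64)


def _max_cluster_stat_2d(vals: np.ndarray, mask: np.ndarray) -> float:
    labelled, n = ndimage.label(mask)
    if n == 0:
        return 0.0
    return float(
        ndimage.sum_labels(vals, labelled, index=np.arange(1, n + 1)).max()
    )


def sign_permutation_cluster_test_1d(
    subject_series: np.ndarray, params: ClusterTestParams
) -> ClusterTestResult:
    """Cluster-corrected sign permutation test on subject timecourses.

    ``subject_series`` has shape ``(n_subjects, n_times)``; typical uses
    are accuracy timecourses against ``null_value=50`` (right tail) and
    paired accuracy differences against ``null_value=0`` (two-sided).
    """
    data = np.asarray(subject_series, dtype=np.float64)
    if data.ndim != 2:
        raise ValueError("subject_series must be (n_subjects, n_times)")
    return _cluster_test(data, params, (data.shape[1],))


def sign_permutation_cluster_test_2d(
    subject_matrices: np.ndarray, params: ClusterTestParams
) -> ClusterTestResult:
    """As the 1D test, on train-time x test-time generalization matrices.

    Clusters are 4-connected components of the supra-threshold grid.
    """
    data = np.asarray(subject_matrices, dtype=np.float64)
    if data.ndim != 3:
        raise ValueError("subject_matrices must be (n_subjects, T1, T2)")
    S, T1, T2 = data.shape
    return _cluster_test(data.reshape(S, T1 * T2), params, (T1, T2))


def paired_difference_series(
    series_a: np.ndarray, series_b: np.ndarray
) -> np.ndarray:
    """Per-subject difference (a - b), ready for a two-sided test against 0."""
    a = np.asarray(series_a, dtype=np.float64)
    b = np.asarray(series_b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return a - b


def fdr_correct(
    p_values: np.ndarray, q: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjustment.

    Returns (adjusted p-values, rejection flags at level q).
    """
    p = np.asarray(p_values, dtype=np.float64)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if p.size == 0:
        return np.zeros(0), np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, adjusted, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return adjusted, reject


def empirical_pvalue(
    observed: float,
    null_samples: np.ndarray,
    tail: Literal["right", "left"] = "right",
) -> float:
    """Add-one empirical p-value against a sampled null distribution.

    Right tail: ``p = (1 + #{null >= observed}) / (1 + N)``; never 0.
    """
    nulls = np.asarray(null_samples, dtype=np.float64)
    if nulls.size == 0:
        raise ValueError("null_samples must be non-empty")
    if tail == "right":
        count = (nulls >= observed).sum()
    elif tail == "left":
        count = (nulls <= observed).sum()
    else:
        raise ValueError("tail must be 'right' or 'left'")
    return float((1 + count) / (1 + nulls.size))


def cluster_report(
    result: ClusterTestResult, times: np.ndarray | None = None
) -> pd.DataFrame:
    """Cluster table: extent (or bounding box), statistic, p-value and flag."""
    rows = []
    for i, (cl, stat, p, sig, marg) in enumerate(
        zip(
            result.clusters,
            result.cluster_stats,
            result.cluster_pvalues,
            result.significant,
            result.marginal,
        )
    ):
        idx = np.argwhere(cl)
        if cl.ndim == 1:
            lo, hi = idx.min(), idx.max()
            span = (
                f"{times[lo]:g}-{times[hi]:g} ms" if times is not None else f"{lo}-{hi}"
            )
        else:
            span = (
                f"rows {idx[:, 0].min()}-{idx[:, 0].max()}, "
                f"cols {idx[:, 1].min()}-{idx[:, 1].max()}"
            )
        flag = "significant" if sig else ("marginal" if marg else "ns")
        rows.append(
            {
                "cluster": i,
                "extent": span,
                "n_points": int(cl.sum()),
                "statistic": float(stat),
                "p_value": float(p),
                "flag": flag,
            }
        )
    return pd.DataFrame(
        rows, columns=["cluster", "extent", "n_points", "statistic", "p_value", "flag"]
    )
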