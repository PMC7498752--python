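"""Representational similarity analysis on decoding-derived RDMs.

A representational dissimilarity matrix (RDM) summarizes pairwise decoding
accuracy (or model dissimilarity) for every pair of stimulus conditions
within a time window.  This module builds decoding RDMs, model RDMs from
activation vectors (1 - Pearson r) and from images (1 - SSIM), estimates
split-half noise ceilings with permutation nulls, correlates RDMs within
and between groups and against model RDMs, and tests across- vs
within-domain dissimilarity contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Any, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from skimage.metrics import structural_similarity

from .decode import PairwiseDecodingResult, window_mean_accuracy
from .permstats import empirical_pvalue, fdr_correct
from .simulate import ActivationSet, ImageSet

__all__ = [
    "RDM",
    "NoiseCeilingEstimate",
    "build_rdm",
    "subject_rdm_stack",
    "rdm_from_activations",
    "ssim",
    "ssim_rdm",
    "split_half_noise_ceiling",
    "noise_ceiling_null",
    "correlate_rdms",
    "group_rdm_similarity_matrix",
    "model_comparison",
    "domain_contrast_rdm",
    "INFANT_WINDOWS",
    "ADULT_WINDOWS",
]

#: Default a-priori analysis windows (ms, half-open) per age group.
INFANT_WINDOWS: dict[str, tuple[float, float]] = {
    "100-190ms": (100.0, 190.0),
    "200-300ms": (200.0, 300.0),
    "300-500ms": (300.0, 500.0),
}
ADULT_WINDOWS: dict[str, tuple[float, float]] = {
    "80-120ms": (80.0, 120.0),
    "150-190ms": (150.0, 190.0),
    "250-400ms": (250.0, 400.0),
}


@dataclass
class RDM:
    """Symmetric condition x condition dissimilarity matrix.

    Decoding RDMs store NaN on the diagonal (self-dissimilarity is not an
    accuracy); model RDMs store 0.  All comparisons between RDMs use only
    the strictly upper triangle.
    """

    values: np.ndarray
    units: str  # "accuracy %", "1 - Pearson r" or "1 - SSIM"
    condition_ids: np.ndarray
    provenance: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.condition_ids = np.asarray(self.condition_ids)
        n = len(self.condition_ids)
        if self.values.shape != (n, n):
            raise ValueError("RDM must be square with one row per condition")
        off = ~np.eye(n, dtype=bool)
        if not np.isfinite(self.values[off]).all():
            raise ValueError("off-diagonal dissimilarities must be finite")
        if not np.allclose(self.values[off], self.values.T[off]):
            raise ValueError("RDM must be symmetric")

    @property
    def n_conditions(self) -> int:
        return len(self.condition_ids)

    def upper_tri(self) -> np.ndarray:
        """Strictly-upper-triangle dissimilarities as a flat vector."""
        return upper_tri(self.values)


def upper_tri(matrix: np.ndarray) -> np.ndarray:
    matrix = np.asarray(matrix)
    iu = np.triu_indices(matrix.shape[0], k=1)
    return matrix[iu]


def _fill_symmetric(vec: np.ndarray, n: int, diagonal: float) -> np.ndarray:
    out = np.full((n, n), diagonal)
    iu = np.triu_indices(n, k=1)
    out[iu] = vec
    out.T[iu] = vec
    return out


def build_rdm(
    results: PairwiseDecodingResult | Sequence[PairwiseDecodingResult],
    window: tuple[float, float],
    provenance: dict[str, Any] | None = None,
) -> RDM:
    """Decoding RDM: window-averaged pairwise accuracy, per subject or group.

    Given several subjects' results, the group RDM is the mean of the
    subject RDMs (equivalently, the mean over subjects of window-averaged
    accuracies).  Diagonal is NaN.
    """
    if isinstance(results, PairwiseDecodingResult):
        results = [results]
    if not results:
        raise ValueError("no decoding results given")
    first = results[0]
    for r in results[1:]:
        if r.pairs != first.pairs:
            raise ValueError("all subjects must share the same condition pairs")
    conds = sorted({c for pair in first.pairs for c in pair})
    vecs = np.stack([window_mean_accuracy(r, window) for r in results])
    values = _fill_symmetric(vecs.mean(axis=0), len(conds), np.nan)
    prov = {"window_ms": tuple(window), "n_subjects": len(results)}
    prov.update(provenance or {})
    return RDM(
        values=values,
        units="accuracy %",
        condition_ids=np.asarray(conds),
        provenance=prov,
    )


def subject_rdm_stack(
    results: Sequence[PairwiseDecodingResult], window: tuple[float, float]
) -> np.ndarray:
    """Stack of per-subject RDM matrices, shape (n_subjects, n_cond, n_cond)."""
    return np.stack([build_rdm(r, window).values for r in results])


def rdm_from_activations(acts: ActivationSet) -> RDM:
    """Model RDM = 1 - Pearson correlation of per-condition activations."""
    X = acts.activations
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need at least 2 conditions and 2 features")
    if np.any(X.std(axis=1) == 0):
        raise ValueError("zero-variance activation vector: correlation undefined")
    rdm = 1.0 - np.corrcoef(X)
    np.fill_diagonal(rdm, 0.0)
    return RDM(
        values=rdm,
        units="1 - Pearson r",
        condition_ids=acts.condition_ids.copy(),
        provenance={"model": acts.model_name},
    )


def ssim(
    image_a: np.ndarray,
    image_b: np.ndarray,
    data_range: float = 1.0,
) -> float:
    """Structural similarity index between two images, in [-1, 1].

    Mean local luminance/contrast/structure similarity over an 11x11
    Gaussian-weighted sliding window (sigma 1.5), stabilization constants
    K1=0.01 and K2=0.03 — the canonical published parameterization.
    Equals 1 iff the images are identical.
    """
    a = np.asarray(image_a, dtype=np.float64)
    b = np.asarray(image_b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"image shapes differ: {a.shape} vs {b.shape}")
    if a.ndim == 3:  # color planes -> luminance
        a = a.mean(axis=-1)
        b = b.mean(axis=-1)
    return float(
        structural_similarity(
            a,
            b,
            data_range=data_range,
            gaussian_weights=True,
            sigma=1.5,
            win_size=11,
            use_sample_covariance=False,
            K1=0.01,
            K2=0.03,
        )
    )


def ssim_rdm(images: ImageSet) -> RDM:
    """Low-level control RDM: entry (i, j) = 1 - SSIM(image_i, image_j)."""
    n = len(images.images)
    if n < 2:
        raise ValueError("need at least 2 images")
    vec = np.array(
        [
            1.0 - ssim(images.images[i], images.images[j], images.dynamic_range)
            for i, j in combinations(range(n), 2)
        ]
    )
    return RDM(
        values=_fill_symmetric(vec, n, 0.0),
        units="1 - SSIM",
        condition_ids=images.condition_ids.copy(),
        provenance={"model": "ssim-control"},
    )


@dataclass
class NoiseCeilingEstimate:
    """Spearman-Brown-corrected split-half reliability of a group RDM."""

    ceiling: float  # in [0, 1]
    per_split: np.ndarray
    n_splits: int
    null_distribution: np.ndarray | None = None
    p_value: float | None = None


def _as_subject_vectors(subject_rdms: np.ndarray | Sequence[np.ndarray]) -> np.ndarray:
    arr = np.stack([np.asarray(m, dtype=np.float64) for m in subject_rdms])
    if arr.ndim != 3 or arr.shape[1] != arr.shape[2]:
        raise ValueError("subject RDMs must be a stack of square matrices")
    if arr.shape[0] < 2:
        raise ValueError("need at least 2 subjects")
    iu = np.triu_indices(arr.shape[1], k=1)
    return arr[:, iu[0], iu[1]]


def _rowwise_pearson(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    uc = u - u.mean(axis=1, keepdims=True)
    vc = v - v.mean(axis=1, keepdims=True)
    denom = np.linalg.norm(uc, axis=1) * np.linalg.norm(vc, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (uc * vc).sum(axis=1) / denom
    return np.where(np.isfinite(r), r, 0.0)


def _spearman_brown_floor(r: np.ndarray) -> np.ndarray:
    """sqrt(2r / (1+r)) for positive split-half r, floored at 0 otherwise.

    The square root maps full-group reliability back to the correlation
    scale of a single half; negative correlations are defined as 0 (chance).
    """
    out = np.zeros_like(r)
    pos = r > 0
    out[pos] = np.sqrt(2.0 * r[pos] / (1.0 + r[pos]))
    return out


def _split_half_values(
    vecs: np.ndarray,
    n_splits: int,
    rng: np.random.Generator,
    scramble: bool = False,
) -> np.ndarray:
    """Corrected split-half correlations for ``n_splits`` random half-splits.

    With ``scramble=True`` the first half's group RDM has its dissimilarity
    entries randomly permuted before correlating (the null procedure).
    """
    S, m = vecs.shape
    half = S // 2
    u = np.empty((n_splits, m))
    v = np.empty((n_splits, m))
    for s in range(n_splits):
        order = rng.permutation(S)
        u[s] = vecs[order[:half]].mean(axis=0)
        v[s] = vecs[order[half:]].mean(axis=0)
    if scramble:
        u = rng.permuted(u, axis=1)
    return _spearman_brown_floor(_rowwise_pearson(u, v))


def split_half_noise_ceiling(
    subject_rdms: np.ndarray | Sequence[np.ndarray],
    n_splits: int = 100,
    seed: int = 0,
) -> NoiseCeilingEstimate:
    """Estimate the noise ceiling of a group-average RDM.

    For each random half-split of the subjects the two half-group RDMs are
    Pearson-correlated over their upper triangles, corrected with the
    square root of the Spearman-Brown formula (and floored at zero), and
    the corrected values averaged over splits.
    """
    vecs = _as_subject_vectors(subject_rdms)
    rng = np.random.default_rng(seed)
    per_split = _split_half_values(vecs, n_splits, rng)
    return NoiseCeilingEstimate(
        ceiling=float(per_split.mean()), per_split=per_split, n_splits=n_splits
    )


def noise_ceiling_null(
    subject_rdms: np.ndarray | Sequence[np.ndarray],
    n_null: int = 10_000,
    n_splits: int = 100,
    seed: int = 0,
) -> NoiseCeilingEstimate:
    """Noise ceiling with an empirical significance test against scrambling.

    Each null estimate repeats the full split-half procedure with one
    half's group RDM scrambled in every split; the p-value is the add-one
    right-tail proportion of null estimates reaching the observed ceiling.
    """
    vecs = _as_subject_vectors(subject_rdms)
    rng = np.random.default_rng(seed)
    observed = _split_half_values(vecs, n_splits, rng).mean()
    nulls = np.empty(n_null)
    for i in range(n_null):
        nulls[i] = _split_half_values(vecs, n_splits, rng, scramble=True).mean()
    p = empirical_pvalue(observed, nulls, tail="right")
    return NoiseCeilingEstimate(
        ceiling=float(observed),
        per_split=np.array([]),
        n_splits=n_splits,
        null_distribution=nulls,
        p_value=p,
    )


def correlate_rdms(
    rdm_a: RDM | np.ndarray,
    rdm_b: RDM | np.ndarray,
    method: Literal["pearson", "spearman"] = "pearson",
) -> tuple[float, float]:
    """Correlation of two RDMs over their strictly-upper triangles.

    Pearson for same-scale comparisons; Spearman when only a monotone
    relation can be assumed (e.g. decoding RDM vs model RDM).  P-values are
    two-sided parametric.
    """
    a = rdm_a.upper_tri() if isinstance(rdm_a, RDM) else upper_tri(rdm_a)
    b = rdm_b.upper_tri() if isinstance(rdm_b, RDM) else upper_tri(rdm_b)
    if a.shape != b.shape:
        raise ValueError("RDMs have different numbers of conditions")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("constant RDM: correlation undefined")
    if method == "pearson":
        res = sps.pearsonr(a, b)
    elif method == "spearman":
        res = sps.spearmanr(a, b)
    else:
        raise ValueError("method must be 'pearson' or 'spearman'")
    return float(res.statistic), float(res.pvalue)


@dataclass
class GroupSimilarityResult:
    """All-pairs group-RDM correlations with noise ceilings on the diagonal."""

    names: list[str]
    matrix: np.ndarray  # correlations off-diagonal, ceilings on diagonal
    p_values: pd.DataFrame  # tidy: kind, name_a, name_b, p, p_fdr, significant
    fdr_family_size: int


def group_rdm_similarity_matrix(
    subject_rdm_stacks: Mapping[str, np.ndarray],
    n_splits: int = 100,
    n_null: int = 10_000,
    seed: int = 0,
    q: float = 0.05,
) -> GroupSimilarityResult:
    """Pairwise Pearson similarity of group RDMs plus per-RDM noise ceilings.

    The FDR family is the union of all between-RDM correlation p-values and
    all noise-ceiling p-values (``k*(k-1)/2 + k`` tests for k RDMs).
    """
    names = list(subject_rdm_stacks)
    if len(names) < 2:
        raise ValueError("need at least 2 group RDMs")
    shapes = {np.asarray(subject_rdm_stacks[n]).shape[1:] for n in names}
    if len(shapes) != 1:
        raise ValueError("all RDM stacks must share the same condition set")
    k = len(names)
    group_means = {
        n: np.stack(list(subject_rdm_stacks[n])).mean(axis=0) for n in names
    }
    matrix = np.full((k, k), np.nan)
    rows = []
    for i, j in combinations(range(k), 2):
        coef, p = correlate_rdms(
            group_means[names[i]], group_means[names[j]], method="pearson"
        )
        matrix[i, j] = matrix[j, i] = coef
        rows.append(("correlation", names[i], names[j], coef, p))
    for i, name in enumerate(names):
        est = noise_ceiling_null(
            subject_rdm_stacks[name], n_null=n_null, n_splits=n_splits,
            seed=seed + i,
        )
        matrix[i, i] = est.ceiling
        rows.append(("noise_ceiling", name, name, est.ceiling, est.p_value))
    table = pd.DataFrame(
        rows, columns=["kind", "name_a", "name_b", "value", "p_value"]
    )
    adjusted, reject = fdr_correct(table["p_value"].to_numpy(), q=q)
    table["p_fdr"] = adjusted
    table["significant"] = reject
    return GroupSimilarityResult(
        names=names, matrix=matrix, p_values=table, fdr_family_size=len(table)
    )


def model_comparison(
    group_rdms: Mapping[str, RDM | np.ndarray],
    model_rdms: Mapping[str, RDM | np.ndarray],
    q: float = 0.05,
) -> pd.DataFrame:
    """Spearman correlation of every group RDM with every model RDM.

    Rank correlation because a linear relation between neural and model
    dissimilarities cannot be assumed.  FDR is applied over the full
    ``n_groups * n_models`` family.
    """
    rows = []
    for gname, g in group_rdms.items():
        for mname, m in model_rdms.items():
            coef, p = correlate_rdms(g, m, method="spearman")
            rows.append((gname, mname, coef, p))
    table = pd.DataFrame(rows, columns=["group_rdm", "model_rdm", "spearman_r", "p_value"])
    adjusted, reject = fdr_correct(table["p_value"].to_numpy(), q=q)
    table["p_fdr"] = adjusted
    table["significant"] = reject
    return table


def _domain_pair_masks(
    condition_ids: np.ndarray, domain_map: Mapping[int, str]
) -> tuple[np.ndarray, np.ndarray]:
    """Boolean masks over the upper-triangle pair vector: across / within domain."""
    domains = [domain_map[int(c)] for c in condition_ids]
    counts: dict[str, int] = {}
    for d in domains:
        counts[d] = counts.get(d, 0) + 1
    if len(counts) < 2:
        raise ValueError("need at least 2 domains for a contrast")
    if min(counts.values()) < 2:
        raise ValueError("every domain needs >= 2 conditions (no within pairs otherwise)")
    pairs = list(combinations(range(len(condition_ids)), 2))
    across = np.array([domains[i] != domains[j] for i, j in pairs])
    return across, ~across


def domain_contrast_rdm(
    subject_rdm_stacks: Mapping[str, np.ndarray],
    domain_map: Mapping[int, str],
    condition_ids: np.ndarray | None = None,
    q: float = 0.05,
) -> pd.DataFrame:
    """Across- minus within-domain dissimilarity, tested per time window.

    For each subject and window: mean of across-domain RDM entries minus
    mean of within-domain entries; a two-sided paired t-test across
    subjects per window; BH-FDR over windows.
    """
    rows = []
    for window, stack in subject_rdm_stacks.items():
        vecs = _as_subject_vectors(stack)
        n_cond = np.stack(list(stack)).shape[1]
        ids = (
            np.asarray(condition_ids)
            if condition_ids is not None
            else np.arange(n_cond)
        )
        across, within = _domain_pair_masks(ids, domain_map)
        diffs = vecs[:, across].mean(axis=1) - vecs[:, within].mean(axis=1)
        t, p = sps.ttest_1samp(diffs, 0.0)
        rows.append(
            (window, float(diffs.mean()), float(t), len(diffs) - 1, float(p))
        )
    table = pd.DataFrame(
        rows, columns=["window", "mean_difference", "t", "df", "p_value"]
    )
    adjusted, reject = fdr_correct(table["p_value"].to_numpy(), q=q)
    table["p_fdr"] = adjusted
    table["significant"] = reject
    return table
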