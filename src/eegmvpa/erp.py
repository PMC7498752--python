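"""Univariate event-related potential (ERP) analysis.

Operates on baseline-corrected, artifact-rejected epochs in μV (not the
z-scored classifier features): region-of-interest averaging, component
window amplitudes (e.g. infant N290/P400/NC, adult N170), a paired domain
contrast on component amplitudes, and cluster-corrected waveform
comparisons delegated to the sign-permutation machinery.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .containers import EpochSet, time_mask
from .permstats import (
    ClusterTestParams,
    ClusterTestResult,
    sign_permutation_cluster_test_1d,
)

__all__ = [
    "ComponentSpec",
    "roi_average",
    "component_amplitude",
    "domain_effect_test",
    "compare_waveforms_cluster",
    "component_table",
]


@dataclass
class ComponentSpec:
    """An ERP component: named channel ROI and measurement window (ms)."""

    name: str
    channels: list[str]
    window: tuple[float, float]
    group: str = ""

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("component needs at least one channel")
        if not self.window[1] > self.window[0]:
            raise ValueError("empty component window")


def roi_average(epochs: EpochSet, channels: Sequence[str]) -> np.ndarray:
    """Mean waveform over the ROI channels, per trial: (n_trials, n_times) μV."""
    idx = epochs.channel_index(list(channels))
    return epochs.data[:, idx, :].mean(axis=1)


def component_amplitude(
    waveforms: np.ndarray, times: np.ndarray, window: tuple[float, float]
) -> np.ndarray:
    """Mean amplitude over the component window, per trial (μV)."""
    mask = time_mask(times, window)
    return np.asarray(waveforms)[..., mask].mean(axis=-1)


def component_table(
    epochs_by_subject: Mapping[str, EpochSet],
    component: ComponentSpec,
    domain_map: Mapping[int, str],
) -> pd.DataFrame:
    """Per-subject, per-domain mean component amplitude (valid trials only)."""
    rows = []
    for subject, epochs in epochs_by_subject.items():
        wave = roi_average(epochs, component.channels)
        amp = component_amplitude(wave, epochs.times, component.window)
        for domain in sorted(set(domain_map.values())):
            conds = [c for c, d in domain_map.items() if d == domain]
            sel = epochs.valid_mask & np.isin(epochs.labels, conds)
            if not sel.any():
                raise ValueError(
                    f"subject {subject}: no valid trials for domain {domain!r}"
                )
            rows.append((subject, component.name, domain, float(amp[sel].mean())))
    return pd.DataFrame(
        rows, columns=["subject", "component", "domain", "amplitude_uv"]
    )


def domain_effect_test(amplitudes: pd.DataFrame) -> dict[str, float]:
    """Effect of domain on component amplitude, within subjects.

    Expects the output of :func:`component_table` with exactly two domains.
    The contrast is a paired comparison of per-subject domain means,
    reported as F = t² with (1, n-1) degrees of freedom, a two-sided p and
    Cohen's d of the paired differences.
    """
    domains = sorted(amplitudes["domain"].unique())
    if len(domains) != 2:
        raise ValueError(f"need exactly 2 domains, got {domains}")
    wide = amplitudes.pivot_table(
        index="subject", columns="domain", values="amplitude_uv"
    )
    if wide.isna().any().any():
        raise ValueError("every subject needs an amplitude for both domains")
    if len(wide) < 2:
        raise ValueError("need at least 2 subjects")
    diff = (wide[domains[0]] - wide[domains[1]]).to_numpy()
    n = diff.size
    if diff.std(ddof=1) == 0:
        t = 0.0 if diff.mean() == 0 else np.inf
        p = 1.0 if diff.mean() == 0 else 0.0
    else:
        t, p = sps.ttest_1samp(diff, 0.0)
    sd = diff.std(ddof=1)
    d = float(diff.mean() / sd) if sd > 0 else np.nan
    return {
        "F": float(t) ** 2,
        "df1": 1,
        "df2": n - 1,
        "t": float(t),
        "p": float(p),
        "cohens_d": d,
        "mean_difference_uv": float(diff.mean()),
    }


def compare_waveforms_cluster(
    subject_difference_waveforms: np.ndarray,
    params: ClusterTestParams | None = None,
) -> ClusterTestResult:
    """Cluster-corrected test of condition-difference waveforms against 0.

    ``subject_difference_waveforms``: (n_subjects, n_times) per-subject ROI
    difference waveforms (e.g. animal minus body).  Two-sided by default.
    """
    if params is None:
        params = ClusterTestParams(tail="two-sided", null_value=0.0)
    return sign_permutation_cluster_test_1d(subject_difference_waveforms, params)
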