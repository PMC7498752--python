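"""End-to-end orchestration: simulate -> preprocess -> decode -> stats -> rsa.

Each stage persists its artifacts as flat delimited tables (plus the HDF5
epochs container), so a run directory is self-documenting and a rerun with
the same configuration and seed reproduces every numeric output.  Stage
dependencies are resolved in memory when possible and re-loaded from the
run directory otherwise; a missing dependency raises
:class:`PipelineError` naming the absent artifact.
"""

from __future__ import annotations

import time
from dataclasses import replace
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import decode as dec
from . import rsa as rsa_mod
from .containers import FeatureSet
from .io import PipelineConfig, read_epochs, write_epochs
from .permstats import ClusterTestParams, cluster_report, sign_permutation_cluster_test_1d
from .preprocess import preprocess_epochs
from .simulate import simulate_epochs, simulate_model_activations, simulate_stimulus_images

__all__ = ["PipelineError", "run_pipeline", "STAGES"]

STAGES = ("simulate", "preprocess", "decode", "stats", "rsa", "report")


class PipelineError(RuntimeError):
    pass


def subject_seed(master_seed: int, subject_index: int) -> int:
    """Independent reproducible per-subject seed below 2^31."""
    return int(
        np.random.SeedSequence([int(master_seed), int(subject_index)]).generate_state(1)[0]
        % 2**31
    )


def _provenance_header(config: PipelineConfig) -> str:
    return (
        f"# seed={config.seed} n_repeats={config.decode.n_repeats} "
        f"n_permutations={config.stats.n_permutations}\n"
    )


def _write_table(df: pd.DataFrame, path: Path, header: str = "") -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as f:
        if header:
            f.write(header)
        df.to_csv(f, sep="\t", index=False)


def run_pipeline(
    config: PipelineConfig,
    stages: list[str] | tuple[str, ...] = STAGES,
    out_dir: str | Path = "eegmvpa-run",
) -> dict[str, Any]:
    """Execute the requested stages in canonical order.

    Returns a dict of in-memory artifacts (epochs, features, decoding
    results, cluster tests, RDM tables) and writes every table under
    ``out_dir``.
    """
    for s in stages:
        if s not in STAGES:
            raise PipelineError(f"unknown stage {s!r}; valid stages: {STAGES}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Any] = {}
    timings: list[tuple[str, float]] = []
    header = _provenance_header(config)

    for stage in STAGES:
        if stage not in stages:
            continue
        t0 = time.perf_counter()
        if stage == "simulate":
            _stage_simulate(config, out, artifacts)
        elif stage == "preprocess":
            _stage_preprocess(config, out, artifacts)
        elif stage == "decode":
            _stage_decode(config, out, artifacts, header)
        elif stage == "stats":
            _stage_stats(config, out, artifacts, header)
        elif stage == "rsa":
            _stage_rsa(config, out, artifacts, header)
        elif stage == "report":
            _stage_report(config, out, artifacts, timings)
        timings.append((stage, time.perf_counter() - t0))

    log = pd.DataFrame(timings, columns=["stage", "seconds"])
    _write_table(log, out / "run_log.tsv", header)
    return artifacts


def _stage_simulate(config: PipelineConfig, out: Path, artifacts: dict) -> None:
    sim = replace(config.simulation, seed=config.seed)
    epochs = [simulate_epochs(sim, i) for i in range(sim.n_subjects)]
    for ep in epochs:
        write_epochs(ep, out / "epochs" / f"{ep.subject_id}.h5")
    artifacts["epochs"] = epochs
    artifacts["simulation_config"] = sim


def _load_epochs(out: Path) -> list:
    paths = sorted((out / "epochs").glob("*.h5")) if (out / "epochs").exists() else []
    return [read_epochs(p) for p in paths]


def _stage_preprocess(config: PipelineConfig, out: Path, artifacts: dict) -> None:
    epochs = artifacts.get("epochs") or _load_epochs(out)
    if not epochs:
        raise PipelineError("preprocess requires epochs (run 'simulate' or provide epochs/*.h5)")
    features, erp_epochs, logs = [], [], []
    for ep in epochs:
        feats, erp_ep, log = preprocess_epochs(ep, config.preprocess)
        features.append(feats)
        erp_epochs.append(erp_ep)
        log.insert(0, "subject", ep.subject_id)
        logs.append(log)
    artifacts["features"] = features
    artifacts["erp_epochs"] = erp_epochs
    _write_table(pd.concat(logs, ignore_index=True), out / "preprocess" / "rejection_log.tsv")


def _stage_decode(
    config: PipelineConfig, out: Path, artifacts: dict, header: str
) -> None:
    features: list[FeatureSet] | None = artifacts.get("features")
    if not features:
        raise PipelineError("decode requires features (run 'preprocess' first)")
    results = []
    for i, feats in enumerate(features):
        params = replace(config.decode, seed=subject_seed(config.seed, i))
        res = dec.decode_all_pairs(feats, params)
        results.append(res)
        _write_table(res.to_frame(), out / "decode" / f"{feats.subject_id}_pairwise.tsv", header)
    artifacts["decoding"] = results
    mean_df = pd.DataFrame(
        {
            "time_ms": results[0].times,
            **{r.subject_id: r.mean_timecourse() for r in results},
        }
    )
    _write_table(mean_df, out / "decode" / "mean_accuracy_by_subject.tsv", header)


def _load_decoding(out: Path) -> list[dec.PairwiseDecodingResult]:
    paths = sorted((out / "decode").glob("*_pairwise.tsv")) if (out / "decode").exists() else []
    results = []
    for p in paths:
        df = pd.read_csv(p, sep="\t", comment="#")
        pairs = sorted(
            {(int(a), int(b)) for a, b in zip(df["cond_a"], df["cond_b"])}
        )
        times = np.sort(df["time_ms"].unique())
        acc = np.stack(
            [
                df[(df.cond_a == a) & (df.cond_b == b)]
                .sort_values("time_ms")["accuracy_pct"]
                .to_numpy()
                for a, b in pairs
            ]
        )
        results.append(
            dec.PairwiseDecodingResult(
                accuracies=acc,
                pairs=pairs,
                times=times,
                subject_id=str(df["subject"].iloc[0]),
            )
        )
    return results


def _stage_stats(
    config: PipelineConfig, out: Path, artifacts: dict, header: str
) -> None:
    results = artifacts.get("decoding") or _load_decoding(out)
    if not results:
        raise PipelineError("stats requires decoding results (run 'decode' first)")
    artifacts["decoding"] = results
    series = np.stack([r.mean_timecourse() for r in results])
    params = replace(
        config.stats, tail="right", null_value=dec.CHANCE_PAIRWISE, seed=config.seed
    )
    test = sign_permutation_cluster_test_1d(series, params)
    artifacts["cluster_test"] = test
    _write_table(
        cluster_report(test, results[0].times),
        out / "stats" / "clusters_mean_accuracy.tsv",
        header,
    )


def _stage_rsa(
    config: PipelineConfig, out: Path, artifacts: dict, header: str
) -> None:
    results = artifacts.get("decoding") or _load_decoding(out)
    if not results:
        raise PipelineError("rsa requires decoding results (run 'decode' first)")
    sim = artifacts.get("simulation_config") or config.simulation
    rsa_p = config.rsa
    stacks = {
        name: rsa_mod.subject_rdm_stack(results, window)
        for name, window in rsa_p.windows.items()
    }
    for name, window in rsa_p.windows.items():
        rdm = rsa_mod.build_rdm(results, window)
        pd.DataFrame(
            rdm.values, index=rdm.condition_ids, columns=rdm.condition_ids
        ).to_csv(_ensure(out / "rsa" / f"rdm_{name}.csv"))
    sim_result = rsa_mod.group_rdm_similarity_matrix(
        stacks, n_splits=rsa_p.n_splits, n_null=rsa_p.n_null, seed=config.seed
    )
    artifacts["rdm_similarity"] = sim_result
    _write_table(sim_result.p_values, out / "rsa" / "group_similarity.tsv", header)

    contrast = rsa_mod.domain_contrast_rdm(stacks, sim.domain_map)
    artifacts["domain_contrast"] = contrast
    _write_table(contrast, out / "rsa" / "domain_contrast.tsv", header)

    # model comparison against synthetic stand-in models + SSIM control
    n_cond = sim.n_conditions
    group_rdms = {
        name: rsa_mod.build_rdm(results, window)
        for name, window in rsa_p.windows.items()
    }
    rng_seed = config.seed
    target = np.full((n_cond, n_cond), 0.3)
    np.fill_diagonal(target, 1.0)
    acts = simulate_model_activations(
        target, n_features=rsa_p.n_model_features, seed=rng_seed, model_name="synthetic-cnn"
    )
    images = simulate_stimulus_images(n_cond, seed=rng_seed)
    model_rdms = {
        "synthetic-cnn": rsa_mod.rdm_from_activations(acts),
        "ssim-control": rsa_mod.ssim_rdm(images),
    }
    comparison = rsa_mod.model_comparison(group_rdms, model_rdms)
    artifacts["model_comparison"] = comparison
    _write_table(comparison, out / "rsa" / "model_comparison.tsv", header)


def _stage_report(
    config: PipelineConfig, out: Path, artifacts: dict, timings: list
) -> None:
    lines = ["# eegmvpa run report", ""]
    lines.append(f"master seed: {config.seed}")
    if "decoding" in artifacts:
        results = artifacts["decoding"]
        grand = float(np.mean([r.mean_timecourse() for r in results]))
        lines.append(f"subjects decoded: {len(results)}")
        lines.append(f"grand-mean pairwise accuracy: {grand:.2f} %")
    if "cluster_test" in artifacts:
        test = artifacts["cluster_test"]
        lines.append(
            f"significant clusters vs chance: {int(test.significant.sum())}"
        )
    if "rdm_similarity" in artifacts:
        lines.append(
            f"RDM similarity FDR family size: {artifacts['rdm_similarity'].fdr_family_size}"
        )
    for stage, seconds in timings:
        lines.append(f"stage {stage}: {seconds:.2f} s")
    (out / "report.md").write_text("\n".join(lines) + "\n")


def _ensure(path: Path) -> Path:
    path.parent.mkdir(parents=True, exist_ok=True)
    return path
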