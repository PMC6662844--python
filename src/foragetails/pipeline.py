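"""End-to-end orchestration: simulate/load -> distances -> summaries ->
fits -> sweeps -> cluster tests -> exploration indices -> report.

Configured by a versioned YAML schema; every stochastic stage derives its
seed from the single top-level seed, so a run is bit-reproducible from
its manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import warnings
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import (
    Group,
    Task,
    apply_exclusion_rule,
    cohort_median,
    median_split,
    read_cohort,
    read_paths,
    write_cohort,
    write_paths,
)
from .distances import euclidean_path_distances, semantic_path_distances, write_distances
from .embeddings import load_embeddings, save_embeddings
from .regression import fit_ols, fit_poisson, fit_random_intercept, summarize_child
from .simulate import ForagingParams, packaged_embeddings, simulate_cohort
from .tails import cluster_null_test, exploration_index, index_correlation, quantile_regression_sweep

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Configuration schema violation; message lists every problem found."""


_ANALYSIS_DEFAULTS: dict[str, Any] = {
    "poisson_levels": [0.50, 0.99, 0.01],
    "quantreg_levels": [0.50, 0.95, 0.05],
    "alpha_cluster": 0.05,
    "alpha_family": 0.05,
    "n_resamples": 1000,
    "resample": "permutation",
    "mass": "count",
    "n_boot": 200,
    "index": "child_quantile",
    "sd_reference": "teacher",
}


@dataclasses.dataclass
class RunConfig:
    seed: int = 0
    tasks: tuple[str, ...] = ("visual", "semantic")
    simulate: dict | None = None  # {"n_children": int, "params": {...}}
    inputs: dict | None = None  # {"cohort": path, "paths": path, "embeddings": path}
    analysis: dict = dataclasses.field(default_factory=lambda: dict(_ANALYSIS_DEFAULTS))
    plots: bool = True
    version: int = 1

    def canonical(self) -> dict:
        return dataclasses.asdict(self)


def load_config(source: str | Path | dict) -> RunConfig:
    """Validate a YAML file or dict against the schema; unknown keys rejected."""
    raw = source if isinstance(source, dict) else yaml.safe_load(Path(source).read_text())
    raw = dict(raw or {})
    problems: list[str] = []
    known = {"seed", "tasks", "simulate", "inputs", "analysis", "plots", "version"}
    for k in set(raw) - known:
        problems.append(f"unknown key {k!r}")
    if raw.get("version", 1) != 1:
        problems.append(f"unsupported config version {raw.get('version')}")
    if raw.get("simulate") is not None and raw.get("inputs") is not None:
        problems.append("'simulate' and 'inputs' are mutually exclusive")
    tasks = tuple(raw.get("tasks", ("visual", "semantic")))
    for t in tasks:
        if t not in ("visual", "semantic"):
            problems.append(f"unknown task {t!r}")
    analysis = dict(_ANALYSIS_DEFAULTS)
    for k, v in dict(raw.get("analysis") or {}).items():
        if k not in _ANALYSIS_DEFAULTS:
            problems.append(f"unknown analysis key {k!r}")
        else:
            analysis[k] = v
    sim = raw.get("simulate")
    if sim is not None:
        for k in set(sim) - {"n_children", "params"}:
            problems.append(f"unknown simulate key {k!r}")
        bad = set(dict(sim.get("params") or {})) - {
            f.name for f in dataclasses.fields(ForagingParams)
        }
        for k in bad:
            problems.append(f"unknown foraging parameter {k!r}")
    if problems:
        raise ConfigError("invalid config: " + "; ".join(problems))
    return RunConfig(
        seed=int(raw.get("seed", 0)),
        tasks=tasks,
        simulate=sim,
        inputs=raw.get("inputs"),
        analysis=analysis,
        plots=bool(raw.get("plots", True)),
    )


def _level_grid(spec) -> np.ndarray:
    lo, hi, step = spec
    n = int(round((hi - lo) / step))
    return np.round(lo + step * np.arange(n + 1), 10)


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        obj = obj.item()
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def _dump_json(data, path: Path) -> None:
    path.write_text(json.dumps(_jsonable(data), indent=2, sort_keys=True, allow_nan=False) + "\n")


def _plot_densities(series, groups, cluster_result, task: str, out: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from scipy.stats import gaussian_kde

    pooled = {g: np.concatenate([s.distances for s, gg in zip(series, groups) if gg == g])
              for g in ("low", "high")}
    fig, ax = plt.subplots(figsize=(6, 4))
    xs = np.linspace(0, max(p.max() for p in pooled.values()) * 1.05, 400)
    for g, style in (("high", "-"), ("low", ":")):
        ax.plot(xs, gaussian_kde(pooled[g])(xs), style, label=f"{g} trait group")
    y0 = ax.get_ylim()[1] * 0.05
    for c, sig in zip(cluster_result.clusters, cluster_result.significant):
        if sig:
            lo = cluster_result.sweep.thresholds[c.start_idx]
            hi = cluster_result.sweep.thresholds[c.end_idx]
            ax.hlines(y0, lo, hi, lw=4, color="black")
    ax.set_xlabel("transition distance" + (" (mm)" if task == "visual" else " (1 - cos)"))
    ax.set_ylabel("density")
    ax.set_title(f"{task} search: pooled distance distributions")
    ax.legend()
    fig.tight_layout()
    fig.savefig(out, dpi=120)
    plt.close(fig)


def run_pipeline(config: RunConfig | dict | str | Path, outdir: str | Path) -> Path:
    """Run the full analysis; returns the run directory.

    Emits cohort/path/distance CSVs, the per-child summary table, model
    reports (JSON + text), sweep and cluster results, one density figure
    per task, a structured log and a manifest with content hashes.
    """
    cfg = config if isinstance(config, RunConfig) else load_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    log_lines: list[str] = []

    def stage(msg: str) -> None:
        line = f"[{time.time() - t0:8.2f}s] {msg}"
        log_lines.append(line)
        logger.info(msg)

    ss = np.random.SeedSequence(cfg.seed)
    sim_seed, analysis_seed = (int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2))

    # --- inputs ------------------------------------------------------------
    if cfg.inputs is not None:
        cohort = read_cohort(cfg.inputs["cohort"])
        all_paths = read_paths(cfg.inputs["paths"])
        table = (
            load_embeddings(cfg.inputs["embeddings"])
            if cfg.inputs.get("embeddings")
            else packaged_embeddings()
        )
        visual_paths = [p for p in all_paths if p.task is Task.VISUAL]
        semantic_paths = [p for p in all_paths if p.task is Task.SEMANTIC]
        stage(f"loaded cohort n={len(cohort)} and {len(all_paths)} paths")
    else:
        sim_cfg = cfg.simulate or {"n_children": 84}
        params = ForagingParams(**dict(sim_cfg.get("params") or {}))
        sim = simulate_cohort(int(sim_cfg.get("n_children", 84)), params, seed=sim_seed)
        cohort, visual_paths, semantic_paths, table = (
            sim.cohort, sim.visual_paths, sim.semantic_paths, sim.embeddings,
        )
        write_cohort(cohort, outdir / "cohort.csv", seed=sim_seed)
        write_paths(visual_paths + semantic_paths, outdir / "paths.csv", seed=sim_seed)
        save_embeddings(table, outdir / "embeddings.txt")
        stage(f"simulated cohort n={len(cohort)} (seed={sim_seed})")

    # --- exclusion + split --------------------------------------------------
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        apply_exclusion_rule(cohort, sd_reference=cfg.analysis["sd_reference"])
    median = cohort_median(cohort)
    median_split(cohort)
    kept = {p.id for p in cohort if p.included}
    stage(f"exclusion + median split: retained {len(kept)}/{len(cohort)}, median={median}")

    by_id = {p.id: p for p in cohort}
    visual_paths = [p for p in visual_paths if p.participant_id in kept]
    semantic_paths = [p for p in semantic_paths if p.participant_id in kept]

    # --- distances + summaries ----------------------------------------------
    results: dict[str, Any] = {"median": median, "n_retained": len(kept)}
    fits: dict[str, Any] = {}
    summaries = []
    task_series: dict[str, list] = {}
    task_paths = {"visual": visual_paths, "semantic": semantic_paths}
    for task in cfg.tasks:
        paths = task_paths[task]
        if task == "visual":
            series = [euclidean_path_distances(p) for p in paths]
        else:
            series = [semantic_path_distances(p, table) for p in paths]
        keep = [i for i, s in enumerate(series) if len(s) > 0]
        series = [series[i] for i in keep]
        paths = [paths[i] for i in keep]
        task_paths[task] = paths
        task_series[task] = series
        write_distances(series, outdir / f"distances_{task}.csv", seed=cfg.seed)
        summaries += [summarize_child(s, p) for s, p in zip(series, paths)]
        stage(f"{task}: {len(series)} distance series")

    summary_df = pd.DataFrame([dataclasses.asdict(s) for s in summaries])
    summary_df["task"] = [s.task.value for s in summaries]
    summary_df.to_csv(outdir / "child_summaries.csv", index=False)

    # --- per-child regressions ----------------------------------------------
    for task in cfg.tasks:
        sub = summary_df[summary_df["task"] == task].reset_index(drop=True)
        score = np.array([by_id[p].teacher_score for p in sub["participant_id"]], dtype=float)
        design = {"intercept": np.ones(len(sub)), "score": score}
        fits[f"{task}_mean_distance_ols"] = fit_ols(sub["mean_distance"].to_numpy(), design)
        fits[f"{task}_sd_distance_ols"] = fit_ols(sub["sd_distance"].to_numpy(), design)
        fits[f"{task}_production_poisson"] = fit_poisson(sub["n_items"].to_numpy(), design)
        if task == "semantic":
            fits["semantic_performance_poisson"] = fit_poisson(sub["n_unique"].to_numpy(), design)
            design_rep = dict(design, performance=sub["n_unique"].to_numpy(dtype=float))
            fits["semantic_repetition_poisson"] = fit_poisson(
                sub["immediate_repetitions"].to_numpy(), design_rep
            )
            # IRT ~ semantic distance with participant random intercepts
            y = np.concatenate([s.irts for s in task_series[task] if s.irts is not None])
            x = np.concatenate([s.distances for s in task_series[task] if s.irts is not None])
            ids = np.concatenate(
                [np.full(len(s), s.participant_id) for s in task_series[task] if s.irts is not None]
            )
            if len(y):
                fits["semantic_irt_mixed"] = fit_random_intercept(y, x, ids)
        stage(f"{task}: per-child regressions done")

    # --- sweeps + cluster tests ----------------------------------------------
    a = cfg.analysis
    ss_analysis = np.random.SeedSequence(analysis_seed)
    sweep_seeds = ss_analysis.generate_state(2 * len(cfg.tasks)) % (2**31)
    indices: dict[str, np.ndarray] = {}
    index_ids: dict[str, list[str]] = {}
    for k, task in enumerate(cfg.tasks):
        series = task_series[task]
        groups = [by_id[s.participant_id].group.value for s in series]
        scores = [by_id[s.participant_id].teacher_score for s in series]

        cres = cluster_null_test(
            series, groups,
            levels=_level_grid(a["poisson_levels"]),
            n_resamples=int(a["n_resamples"]),
            alpha_cluster=float(a["alpha_cluster"]),
            alpha_family=float(a["alpha_family"]),
            seed=int(sweep_seeds[2 * k]),
            resample=a["resample"],
            mass=a["mass"],
            task=task,
        )
        cres.sweep.to_frame().to_csv(outdir / f"sweep_poisson_{task}.csv", index=False)
        _dump_json(cres.to_dict(), outdir / f"clusters_{task}.json")
        stage(f"{task}: exceedance sweep + cluster test "
              f"({len(cres.significant_clusters)} significant clusters)")

        qres = quantile_regression_sweep(
            series, scores,
            levels=_level_grid(a["quantreg_levels"]),
            n_boot=int(a["n_boot"]),
            seed=int(sweep_seeds[2 * k + 1]),
            task=task,
        )
        qres.to_frame().to_csv(outdir / f"sweep_quantreg_{task}.csv", index=False)
        stage(f"{task}: quantile-regression sweep done")

        sig_levels = qres.significant_levels(float(a["alpha_cluster"]))
        indices[task] = np.array(
            [exploration_index(s, sig_levels, interpretation=a["index"]) for s in series]
        )
        index_ids[task] = [s.participant_id for s in series]

        if cfg.plots:
            _plot_densities(series, groups, cres, task, outdir / f"density_{task}.png")
        results[f"{task}_cluster"] = cres.to_dict()
        results[f"{task}_quantreg_significant_levels"] = sig_levels.tolist()

    if set(cfg.tasks) == {"visual", "semantic"}:
        common = sorted(set(index_ids["visual"]) & set(index_ids["semantic"]))
        vi = dict(zip(index_ids["visual"], indices["visual"]))
        si = dict(zip(index_ids["semantic"], indices["semantic"]))
        vi_arr = np.array([vi[c] for c in common])
        si_arr = np.array([si[c] for c in common])
        if np.ptp(vi_arr) > 0 and np.ptp(si_arr) > 0:
            fits["index_correlation_ols"] = index_correlation(
                vi_arr, si_arr, [by_id[c].teacher_score for c in common]
            )
        else:
            results["index_correlation_skipped"] = "constant index (no significant levels)"
            stage("index correlation skipped: constant index")
        pd.DataFrame(
            {"participant_id": common,
             "visual_index": [vi[c] for c in common],
             "semantic_index": [si[c] for c in common]}
        ).to_csv(outdir / "exploration_indices.csv", index=False)
        stage("cross-task index correlation done")

    # --- reports --------------------------------------------------------------
    _dump_json({k: v.to_dict() for k, v in fits.items()}, outdir / "fits.json")
    (outdir / "fits.txt").write_text(
        "\n\n".join(f"== {k} ==\n{v.summary()}" for k, v in fits.items()) + "\n"
    )
    _dump_json(results, outdir / "results.json")

    hashed = sorted(p.name for p in outdir.iterdir() if p.suffix in {".csv", ".json", ".txt"}
                    if p.name != "manifest.json")
    manifest = {
        "package": "foragetails",
        "version": __version__,
        "seed": cfg.seed,
        "config": cfg.canonical(),
        "config_hash": hashlib.sha256(
            json.dumps(_jsonable(cfg.canonical()), sort_keys=True).encode()
        ).hexdigest(),
        "files": {name: hashlib.sha256((outdir / name).read_bytes()).hexdigest()
                  for name in hashed if name != "run.log"},
    }
    _dump_json(manifest, outdir / "manifest.json")
    (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
    stage("pipeline complete")
    return outdir
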