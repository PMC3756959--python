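"""End-to-end orchestration: cohort -> QC -> connectivity -> networks -> stats.

The pipeline mirrors the analysis flow: motion QC and dummy-volume
discarding, per-subject partial correlation, the group-mean connectivity
map, degree-targeted thresholding (K = 48 by default, 2160 edges on 90
nodes), per-subject network measures, degree-matched null ensembles with
small-world statistics, the hierarchy fit, and the swallowing-ROI versus
whole-brain sweep comparison.  Every stage writes plain tabular files under
the output directory, and a manifest JSON records the configuration, seeds,
QC exclusions and timing, so a run is reproducible bit-for-bit from its
config.
"""

from __future__ import annotations

import dataclasses
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as snio
from .atlas import load_region_table, region_labels, swallowing_nodes
from .connectivity import group_mean_matrix, partial_correlation
from .construction import STUDY_MEAN_DEGREE, sweep_grid, threshold_to_mean_degree
from .metrics import network_summary
from .nulls import null_ensemble, small_worldness
from .plotting import plot_connectivity_matrix, plot_sweep_comparison
from .preprocess import discard_initial_volumes, motion_magnitude, qc_exclude
from .stats import compare_scopes, metric_sweep
from .synthetic import CohortSpec, generate_cohort

__all__ = ["RunConfig", "run_pipeline", "load_config", "save_config"]


@dataclass(frozen=True)
class RunConfig:
    """Fully serializable description of one pipeline run."""

    cohort: CohortSpec = field(default_factory=CohortSpec)
    input_dir: str | None = None  # if set, read TSV cohort instead of simulating
    out_dir: str = "swallownet_run"
    n_discard: int = 10
    qc_limit_mm: float = 4.0
    K: int = STUDY_MEAN_DEGREE
    sweep_start: float = 0.0
    sweep_stop: float = 1.0
    sweep_step: float = 0.05
    n_random: int = 100
    swaps_per_edge: int = 10
    null_seed: int = 0
    lp_kind: str = "harmonic"
    make_plots: bool = True


def save_config(config: RunConfig, path: str | Path) -> Path:
    path = Path(path)
    payload = dataclasses.asdict(config)
    path.write_text(yaml.safe_dump(payload, sort_keys=False))
    return path


def load_config(path: str | Path) -> RunConfig:
    payload = yaml.safe_load(Path(path).read_text())
    cohort = CohortSpec(**payload.pop("cohort", {}))
    return RunConfig(cohort=cohort, **payload)


def _load_cohort(config: RunConfig):
    if config.input_dir is None:
        return generate_cohort(config.cohort)
    root = Path(config.input_dir)
    manifest = yaml.safe_load((root / "manifest.json").read_text())
    cohort = []
    for entry in manifest["subjects"]:
        ts = snio.read_series_tsv(root / entry["series"], subject_id=entry["subject_id"])
        motion = snio.read_motion_tsv(root / entry["motion"])
        cohort.append((ts, motion))
    return cohort


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and return the run manifest (also written to disk)."""
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table = load_region_table()
    labels = region_labels(table)
    roi = swallowing_nodes(table)

    cohort = _load_cohort(config)
    qc_rows, kept = [], []
    for ts, motion in cohort:
        trans_mag, rot_mag = motion_magnitude(motion)
        excluded = qc_exclude(motion, limit_mm=config.qc_limit_mm)
        qc_rows.append(
            {
                "subject_id": ts.subject_id,
                "mean_translation_mm": trans_mag,
                "mean_rotation_deg": rot_mag,
                "excluded": excluded,
            }
        )
        if not excluded:
            kept.append(discard_initial_volumes(ts, config.n_discard))
    qc_df = pd.DataFrame(qc_rows)
    qc_df.to_csv(out / "qc.csv", index=False)
    if not kept:
        raise RuntimeError("QC excluded every subject; nothing to analyze")

    matrices = [partial_correlation(ts) for ts in kept]
    mean_matrix = group_mean_matrix(matrices)
    snio.write_matrix_tsv(out / "group_mean_connectivity.tsv", mean_matrix, labels)

    # degree-targeted networks and per-subject measures
    summary_rows, sw_rows = [], []
    null_root = np.random.SeedSequence(config.null_seed)
    null_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in null_root.spawn(len(kept))]
    for ts, C, nseed in zip(kept, matrices, null_seeds):
        binary, weighted = threshold_to_mean_degree(C, K=config.K, labels=tuple(labels))
        for net, mode in ((binary, "binary"), (weighted, "weighted")):
            s = network_summary(net, lp_kind=config.lp_kind)
            summary_rows.append({"subject_id": ts.subject_id, "mode": mode, **s.as_dict()})
        ens = null_ensemble(
            binary, n_random=config.n_random, seed=nseed,
            swaps_per_edge=config.swaps_per_edge,
        )
        sw = small_worldness(network_summary(binary, lp_kind="harmonic"), ens)
        sw_rows.append(
            {
                "subject_id": ts.subject_id,
                "Crand_mean": ens.Crand_mean,
                "Lrand_mean": ens.Lrand_mean,
                "gamma": sw.gamma,
                "lambda": sw.lam,
                "sigma": sw.sigma,
                "is_small_world": sw.is_small_world,
            }
        )
    summary_df = pd.DataFrame(summary_rows)
    summary_df.to_csv(out / "network_summaries.csv", index=False)
    sw_df = pd.DataFrame(sw_rows)
    sw_df.to_csv(out / "small_world.csv", index=False)

    grid = sweep_grid(config.sweep_start, config.sweep_stop, config.sweep_step)
    sweep_whole = metric_sweep(matrices, "whole_brain", grid)
    sweep_roi = metric_sweep(matrices, "swallowing_roi", grid, roi_nodes=roi)
    sweep_whole.table.to_csv(out / "sweep_whole_brain.csv", index=False)
    sweep_roi.table.to_csv(out / "sweep_swallowing_roi.csv", index=False)
    comparison = compare_scopes(sweep_roi, sweep_whole)
    comparison.to_csv(out / "scope_comparison.csv", index=False)

    if config.make_plots:
        plot_connectivity_matrix(mean_matrix, labels, out / "group_mean_connectivity.png")
        plot_sweep_comparison(sweep_roi, sweep_whole, comparison, out / "sweep_comparison.png")

    manifest = {
        "config": dataclasses.asdict(config),
        "n_subjects_input": len(cohort),
        "n_subjects_excluded": int(qc_df["excluded"].sum()),
        "n_subjects_analyzed": len(kept),
        "n_timepoints": int(kept[0].n_timepoints),
        "n_regions": int(kept[0].n_regions),
        "n_edges_per_network": int(config.K * kept[0].n_regions // 2),
        "n_sweep_thresholds": int(grid.size),
        "n_roi_nodes": len(roi),
        "null_seeds": null_seeds,
        "mean_sigma": float(sw_df["sigma"].mean()),
        "elapsed_seconds": round(time.time() - t0, 2),
    }
    snio.write_json(out / "manifest.json", manifest)
    return manifest
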