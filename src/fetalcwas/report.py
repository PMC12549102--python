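"""End-to-end pipeline orchestration and report tables.

Runs simulate -> motion QC -> connectomes -> MDMR -> community detection ->
enrichment -> summary tables, writing every stage's output (CSV/TSV plus a
JSON manifest with versions, seeds and parameters) into one directory.
Identical config and seed give byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

import fetalcwas
from fetalcwas import communities, connectome, enrichment, mdmr, motion, synthetic
from fetalcwas.exceptions import InputError, PipelineError

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Every knob of one pipeline run; mirrors the CLI flags."""

    output_dir: str = "cwas_output"
    input_dir: str | None = None  # existing cohort directory; None -> simulate
    # simulation
    n_subjects: int = 59
    n_rois: int = 100
    n_modules: int = 14
    n_volumes: int = 110
    tr_seconds: float = 3.0
    within_module_r: float = 0.4
    between_module_r: float = 0.05
    motion_spike_prob: float = 0.05
    # motion QC
    trans_thresh_mm: float = 1.0
    rot_thresh_deg: float = 1.5
    mad_voxel_frac: float = 0.10
    mad_k: float = 3.0
    min_minutes: float = 4.0
    apply_bandpass: bool = False
    # statistics
    factors: tuple[str, ...] = ("retained_volumes", "ssai", "stai")
    behavior_factors: tuple[str, ...] = ("stai", "ssai")
    mdmr_mode: str = "whole_connectome"
    mdmr_permutations: int = 999
    enrich_permutations: int = 1000
    alpha: float = 0.05
    resolution: float = 1.5
    consensus_runs: int = 100
    top_k: int = 10
    seed: int = 0


def summarize_associations(stats_table: pd.DataFrame, total_edges: int | None = None) -> dict:
    """Counts of significant positive/negative edges with percentages.

    Percentages are recomputed from the counts against the total edge count
    and rounded to one decimal.
    """
    if total_edges is None:
        total_edges = len(stats_table)
    if len(stats_table) == 0:
        return {
            "total_edges": total_edges,
            "significant_total": 0,
            "significant_positive": 0,
            "significant_negative": 0,
            "percent_positive": 0.0,
            "percent_negative": 0.0,
        }
    sig = stats_table["significant"].to_numpy(dtype=bool)
    pos = int((sig & (stats_table["r"].to_numpy() > 0)).sum())
    neg = int((sig & (stats_table["r"].to_numpy() < 0)).sum())
    return {
        "total_edges": int(total_edges),
        "significant_total": pos + neg,
        "significant_positive": pos,
        "significant_negative": neg,
        "percent_positive": round(100.0 * pos / total_edges, 1),
        "percent_negative": round(100.0 * neg / total_edges, 1),
    }


def enriched_share(
    stats_table: pd.DataFrame,
    enrich_table: pd.DataFrame,
    partition: communities.ModulePartition,
    roi_labels: list[str],
    alpha: float = 0.05,
) -> dict:
    """How many significant edges fall inside the enriched network pairs.

    Returns the count, the percentage of all significant edges (rounded to
    the nearest integer, as conventionally reported), and the share of
    those in-pair edges with positive direction.
    """
    edge_index = list(zip(stats_table["roi_i"], stats_table["roi_j"]))
    ids, _ = enrichment.edge_pair_ids(edge_index, partition, roi_labels)
    called = (enrich_table["p_perm"] < alpha) & enrich_table["enriched"]
    called_ids = set(np.flatnonzero(called.to_numpy()))
    sig = stats_table["significant"].to_numpy(dtype=bool)
    in_pair = np.array([i in called_ids for i in ids])
    n_sig = int(sig.sum())
    n_in = int((sig & in_pair).sum())
    pos_in = int((sig & in_pair & (stats_table["r"].to_numpy() > 0)).sum())
    return {
        "significant_total": n_sig,
        "in_enriched_pairs": n_in,
        "percent_of_significant": round(100.0 * n_in / n_sig) if n_sig else 0,
        "positive_in_enriched": pos_in,
        "n_enriched_pairs": int(called.sum()),
    }


def top_edges(stats_table: pd.DataFrame, k: int = 10) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Top-k positive and top-k negative edges ranked by |r|.

    Ties break deterministically on (roi_i, roi_j) label order; fewer than
    k rows are returned when fewer exist.
    """
    if k < 0:
        raise InputError("k must be nonnegative")
    df = stats_table.copy()
    df["abs_r"] = df["r"].abs()
    pos = (
        df[df["r"] > 0]
        .sort_values(["abs_r", "roi_i", "roi_j"], ascending=[False, True, True])
        .head(k)
        .drop(columns="abs_r")
        .reset_index(drop=True)
    )
    neg = (
        df[df["r"] < 0]
        .sort_values(["abs_r", "roi_i", "roi_j"], ascending=[False, True, True])
        .head(k)
        .drop(columns="abs_r")
        .reset_index(drop=True)
    )
    pos.index += 1
    neg.index += 1
    return pos, neg


def _qc_stage(cohort: synthetic.Cohort, config: RunConfig) -> list[motion.SubjectScan]:
    included = []
    for scan in cohort.scans:
        motion.censor_motion(scan, config.trans_thresh_mm, config.rot_thresh_deg)
        motion.censor_mad(scan, config.mad_voxel_frac, config.mad_k)
        if config.apply_bandpass:
            motion.bandpass_filter(scan)
        if motion.check_inclusion(scan, config.min_minutes):
            included.append(scan)
    return included


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full analysis; returns the output directory.

    Stage order: simulate (or load) -> motion QC and inclusion -> connectome
    construction -> covariate-adjusted MDMR -> community detection on the
    group connectome -> per-behavior enrichment -> summary report. Any
    stage failure aborts with a stage-labelled error.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "fetalcwas",
        "version": fetalcwas.__version__,
        "config": {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(config).items()},
        "stages": {},
    }
    log_lines: list[str] = []
    current_stage = "simulate"

    def _stage(name: str):
        nonlocal current_stage
        current_stage = name
        t0 = time.perf_counter()

        def _done():
            dt = time.perf_counter() - t0
            manifest["stages"][name] = round(dt, 3)
            log_lines.append(f"{name}: {dt:.3f}s")
            logger.info("stage %s finished in %.3fs", name, dt)

        return _done

    try:
        done = _stage("simulate")
        if config.input_dir is not None:
            cohort = synthetic.read_cohort(config.input_dir, config.tr_seconds)
        else:
            spec = synthetic.CohortSpec(
                n_subjects=config.n_subjects,
                n_rois=config.n_rois,
                n_modules=config.n_modules,
                n_volumes=config.n_volumes,
                tr_seconds=config.tr_seconds,
                within_module_r=config.within_module_r,
                between_module_r=config.between_module_r,
                motion_spike_prob=config.motion_spike_prob,
                seed=config.seed,
            )
            cohort = synthetic.generate_cohort(spec)
        labels = synthetic.roi_labels(cohort.spec.n_rois)
        done()

        done = _stage("qc")
        included = _qc_stage(cohort, config)
        if len(included) < 2:
            raise InputError(
                f"only {len(included)} scan(s) pass inclusion; "
                "the cwas stage needs at least 2"
            )
        ids = [s.scan_id for s in included]
        cov = cohort.covariates.set_index("scan_id").loc[ids].reset_index()
        cov["retained_volumes"] = [s.retained_volumes for s in included]
        cov.to_csv(out / "covariates_included.csv", index=False)
        done()

        done = _stage("connectome")
        cons = [
            connectome.build_connectome(
                s.timeseries, labels, s.keep_mask, scan_id=s.scan_id
            )
            for s in included
        ]
        edge_vectors = [connectome.vectorize_edges(c) for c in cons]
        edge_matrix = np.stack([v.values for v in edge_vectors])
        edge_index = edge_vectors[0].edge_index
        pd.DataFrame(
            edge_matrix, index=ids, columns=[f"{a}|{b}" for a, b in edge_index]
        ).to_csv(out / "edge_matrix.csv")
        done()

        done = _stage("mdmr")
        x = mdmr.design_matrix(cov, list(config.factors))
        mdmr_table = mdmr.cwas_scan(
            edge_matrix,
            x,
            mode=config.mdmr_mode,
            permutations=config.mdmr_permutations,
            seed=config.seed,
            roi_labels=labels,
        )
        mdmr_table.to_csv(out / "mdmr_results.tsv", sep="\t", index=False)
        done()

        done = _stage("communities")
        group_z = communities.group_connectome(cons)
        partition = communities.detect_modules(
            group_z,
            resolution=config.resolution,
            seed=config.seed,
            consensus_runs=config.consensus_runs,
        )
        partition.to_frame(labels).to_csv(out / "modules.tsv", sep="\t", index=False)
        manifest["n_modules"] = partition.n_modules
        manifest["modularity_q"] = round(partition.modularity_q, 6)
        done()

        done = _stage("enrichment")
        summary: dict = {}
        for behavior in config.behavior_factors:
            scores = cov[behavior].to_numpy(dtype=float)
            stats_table = enrichment.edge_behavior_correlations(
                edge_matrix, scores, edge_index, config.alpha
            )
            stats_table.to_csv(out / f"edge_stats_{behavior}.csv", index=False)
            enrich_table = enrichment.enrichment_permutation(
                edge_matrix,
                scores,
                partition,
                edge_index,
                labels,
                permutations=config.enrich_permutations,
                alpha=config.alpha,
                seed=config.seed,
            )
            enrich_table.to_csv(out / f"enrichment_{behavior}.tsv", sep="\t", index=False)
            pos, neg = top_edges(stats_table, config.top_k)
            pos.to_csv(out / f"top_positive_{behavior}.csv")
            neg.to_csv(out / f"top_negative_{behavior}.csv")
            summary[behavior] = {
                "associations": summarize_associations(stats_table),
                "enrichment": enriched_share(
                    stats_table, enrich_table, partition, labels, config.alpha
                ),
            }
        done()

        manifest["summary"] = summary
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        (out / "run.log").write_text("\n".join(log_lines) + "\n")
    except Exception as exc:
        raise PipelineError(f"stage '{current_stage}' failed: {exc}") from exc
    return out
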