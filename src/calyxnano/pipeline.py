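"""End-to-end orchestration and cohort-level summaries.

A pipeline run executes generate -> detect -> align -> simulate from a
single seeded configuration and stamps every artifact with the config hash,
seed and package version.  The summary layer is purely descriptive
(medians, means, standard errors, empirical CDFs); hypothesis testing is
left to downstream tools on the exported tidy tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .alignment import average_profiles, cross_enrichment_profile, en_face_project
from .clusters import cluster_report, detect_nanoclusters, make_synaptic_cluster, nanocluster_table, reports_to_frame
from .localizations import write_channels
from .sim import SimConfig, average_traces
from .sim.metrics import metrics_of
from .synth import PairedChannelSpec, SyntheticClusterSpec, generate_paired_channels

log = logging.getLogger("calyxnano.pipeline")


@dataclass
class PipelineConfig:
    """One reproducible end-to-end run.

    ``groups`` maps a group label (e.g. control / ko_like) to the
    localization-generator spec and simulator settings of that condition.
    """

    seed: int
    output_dir: str
    n_synapses_per_group: int = 8
    groups: dict = field(default_factory=dict)
    sim_config: SimConfig = field(default_factory=SimConfig)
    sim_runs: int = 20
    stages: tuple = ("generate", "detect", "align", "simulate")
    log_level: str = "INFO"

    def validate(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if not self.groups:
            raise ValueError("at least one group required")
        unknown = set(self.stages) - {"generate", "detect", "align", "simulate"}
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}")

    def config_hash(self) -> str:
        blob = json.dumps(
            {
                "seed": self.seed,
                "n": self.n_synapses_per_group,
                "groups": {k: v.reference.to_dict() if isinstance(v, PairedChannelSpec) else v.to_dict() for k, v in self.groups.items()},
                "sim": self.sim_config.to_dict(),
                "runs": self.sim_runs,
            },
            sort_keys=True,
            default=str,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def default_pipeline_config(seed: int, output_dir: str, n_synapses_per_group: int = 8) -> PipelineConfig:
    control = PairedChannelSpec(
        reference=SyntheticClusterSpec(n_localizations=1500, nanocluster_centers=((-60.0, 0.0), (60.0, 40.0)), seed=seed),
        target=SyntheticClusterSpec(n_localizations=1500, seed=seed + 1),
        alignment_mode="aligned",
        cross_enrichment=3.0,
    )
    ko_like = replace(
        control,
        cross_enrichment=1.5,
        reference=replace(control.reference, enrichment_factor=3.0, nanocluster_radius=55.0),
    )
    return PipelineConfig(
        seed=seed,
        output_dir=output_dir,
        n_synapses_per_group=n_synapses_per_group,
        groups={"control": control, "ko_like": ko_like},
    )


@dataclass
class CohortSummary:
    per_synapse: pd.DataFrame
    per_metric: pd.DataFrame
    trace_metrics: pd.DataFrame | None = None


def summarize_cohort(reports: pd.DataFrame, group_col: str = "group") -> pd.DataFrame:
    """Median, mean, SE and n per numeric metric per group."""
    if reports.empty:
        raise ValueError("empty cohort")
    num = reports.select_dtypes(include=[np.number]).columns
    rows = []
    for (g,), sub in reports.groupby([group_col]):
        if len(sub) == 0:
            raise ValueError(f"empty group {g}")
        for c in num:
            v = sub[c].dropna().to_numpy(float)
            if len(v) == 0:
                continue
            rows.append(
                {
                    "group": g,
                    "metric": c,
                    "n": len(v),
                    "mean": v.mean(),
                    "median": float(np.median(v)),
                    "se": v.std(ddof=1) / np.sqrt(len(v)) if len(v) > 1 else 0.0,
                }
            )
    return pd.DataFrame(rows)


def empirical_cdfs(reports: pd.DataFrame, group_col: str = "group") -> pd.DataFrame:
    num = reports.select_dtypes(include=[np.number]).columns
    rows = []
    for (g,), sub in reports.groupby([group_col]):
        for c in num:
            v = np.sort(sub[c].dropna().to_numpy(float))
            for i, x in enumerate(v):
                rows.append({"group": g, "metric": c, "value": x, "cdf": (i + 1) / len(v)})
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> CohortSummary:
    """Execute the configured stages and write all artifacts to disk."""
    config.validate()
    logging.basicConfig(level=config.log_level)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = {"config_hash": config.config_hash(), "seed": config.seed, "version": __version__}
    (out / "provenance.json").write_text(json.dumps(stamp, indent=2))

    rng = np.random.default_rng(config.seed)
    all_reports = []
    profiles = {}
    nc_tables = []
    try:
        for group, spec in config.groups.items():
            group_profiles = []
            for k in range(config.n_synapses_per_group):
                syn_seed = int(rng.integers(2**31 - 1))
                pcs = replace(
                    spec,
                    reference=replace(spec.reference, seed=syn_seed),
                    target=replace(spec.target, seed=syn_seed + 1),
                )
                ref, tgt = generate_paired_channels(pcs)
                sid = f"{group}_{k:03d}"
                if "generate" in config.stages:
                    write_channels(out / f"locs_{sid}.csv", [ref, tgt])
                if "detect" not in config.stages:
                    continue
                cluster = make_synaptic_cluster(ref)
                ncs = detect_nanoclusters(cluster, seed=syn_seed)
                rep = cluster_report(cluster, ncs, synapse_id=sid)
                row = rep.to_row()
                row["group"] = group
                all_reports.append(row)
                nc_tables.append((rep, ncs))
                if "align" in config.stages and ncs:
                    frame, _ = en_face_project(cluster.locs)
                    peaks2d = frame.project(np.vstack([nc.peak for nc in ncs]))
                    tgt_clean = make_synaptic_cluster(tgt)
                    group_profiles.append(
                        cross_enrichment_profile(peaks2d, frame.project(tgt_clean.locs.xyz))
                    )
            if group_profiles:
                profiles[group] = average_profiles(group_profiles)
    except Exception as exc:  # pragma: no cover - error path
        raise RuntimeError(f"pipeline stage failed for group processing: {exc}") from exc

    per_synapse = pd.DataFrame(all_reports)
    if not per_synapse.empty:
        per_synapse.to_csv(out / "cluster_reports.csv", index=False)
        nanocluster_table(nc_tables).to_csv(out / "nanoclusters.csv", index=False)
    for group, prof in profiles.items():
        prof.to_frame().to_csv(out / f"enrichment_profile_{group}.csv", index=False)

    tm = None
    if "simulate" in config.stages:
        trace, per_run = average_traces(config.sim_config, n_runs=config.sim_runs, seed=config.seed)
        m = metrics_of(trace)
        tm = pd.DataFrame([{**m.to_row(), "group": "simulated"}])
        trace.to_frame(stride=config.sim_config.record_stride).to_csv(out / "mean_trace.csv", index=False)
        per_run.to_csv(out / "per_run_metrics.csv", index=False)
        tm.to_csv(out / "trace_metrics.csv", index=False)

    per_metric = summarize_cohort(per_synapse) if not per_synapse.empty else pd.DataFrame()
    if not per_metric.empty:
        per_metric.to_csv(out / "cohort_summary.csv", index=False)
        empirical_cdfs(per_synapse).to_csv(out / "cohort_cdfs.csv", index=False)
    log.info("pipeline done: %s", stamp)
    return CohortSummary(per_synapse, per_metric, tm)
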