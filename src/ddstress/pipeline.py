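"""End-to-end orchestration: DGE -> trajectory clustering -> enrichment,
plus the optional flow-kinetics and cell-cycle stages, with a reproducibility
manifest.

A run is fully determined by (input files, config, seed); the manifest
records the config snapshot, seed, input checksums, output list and per-stage
wall time so a deterministic rerun can be verified bit for bit.
"""

from __future__ import annotations

import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, dge, enrich, flow, gating, io, trajectories


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """All paths and analysis constants of one run.

    The defaults are the study's fixed constants: fold-change threshold 1.4,
    BH alpha 0.01, k=2 medoid partition, 3 sub-clusters per set, top 10%
    most-variable genes for PCA, 1000 permutations with weight 1 for GSEA.
    """

    counts: str | None = None
    metadata: str | None = None
    gmt: str | None = None
    flow_events: str | None = None
    cell_events: str | None = None
    out_dir: str = "ddstress_out"

    fc_threshold: float = 1.4
    alpha: float = 0.01
    k: int = 2
    subclusters: int = 3
    top_fraction: float = 0.10
    n_perm: int = 1000
    gsea_weight: float = 1.0
    gsea_timepoints: tuple[float, ...] | None = None  # default: all t > 0
    partition_representation: str = "cross_condition"
    min_set_size: int = 5
    max_set_size: int = 500
    seed: int = 0

    stages: tuple[str, ...] = ("dge", "clustering", "enrichment", "kinetics", "gating")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise io.ValidationError(f"unknown config keys: {sorted(unknown)}")
        for key in ("gsea_timepoints", "stages"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def validate_paths(self) -> None:
        for name in ("counts", "metadata", "gmt", "flow_events", "cell_events"):
            value = getattr(self, name)
            if value is not None and not Path(value).exists():
                raise io.ValidationError(f"config path {name} does not exist: {value}")


@dataclass
class RunManifest:
    config: dict
    seed: int
    version: str
    input_checksums: dict[str, str] = field(default_factory=dict)
    outputs: list[str] = field(default_factory=list)
    wall_time_s: dict[str, float] = field(default_factory=dict)


def run_all(config: PipelineConfig) -> RunManifest:
    """Execute every configured stage and write outputs plus manifest.json.

    Stage order: dge -> clustering -> enrichment (ORA per cluster + GSEA per
    condition/timepoint) and, when flow inputs are present, kinetics and
    gating.  Any stage failure raises :class:`PipelineError` naming the
    stage; outputs of completed stages are retained.
    """
    config.validate_paths()
    if config.counts is None or config.metadata is None:
        raise io.ValidationError("config must provide counts and metadata paths")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=asdict(config), seed=config.seed, version=__version__)
    for name in ("counts", "metadata", "gmt", "flow_events", "cell_events"):
        value = getattr(config, name)
        if value is not None:
            manifest.input_checksums[name] = io.sha256(value)

    def emit(df, rel, index=True):
        p = io.write_table(df, out / rel, index=index)
        manifest.outputs.append(str(p.relative_to(out)))

    counts = io.read_counts(config.counts)
    meta = io.read_metadata(config.metadata, counts)

    # ----- differential expression -------------------------------------
    t0 = time.perf_counter()
    try:
        results = dge.run_contrasts(counts, meta)
        called = dge.call_degs(results, config.fc_threshold, config.alpha)
        # nuclear condition first: channel 0 drives distinct-set cluster naming
        conditions = sorted(
            meta["condition"].unique(),
            key=lambda c: (0 if "nuc" in c.lower() else 1, c),
        )
        per_cond = {c: called[called["condition"] == c] for c in conditions}
        classified = dge.classify_common_distinct(per_cond[conditions[0]], per_cond[conditions[1]])
        class_counts = dge.classification_counts(classified)
        factors = dge.size_factors(counts.loc[results.index.unique()])
        norm = dge.normalized_counts(counts.loc[results.index.unique()], factors)
        pca_coords, pca_var = dge.pca_samples(norm, config.top_fraction)
        emit(results, "de_results.tsv")
        emit(called[called["deg"]], "deg_table.tsv")
        emit(classified, "common_distinct.tsv", index=False)
        emit(class_counts, "common_distinct_counts.tsv", index=False)
        emit(pca_coords, "pca_samples.tsv")
    except Exception as exc:
        raise PipelineError("dge", exc) from exc
    manifest.wall_time_s["dge"] = time.perf_counter() - t0

    deg_genes = sorted(called.index[called["deg"]].unique())

    # ----- trajectory clustering ----------------------------------------
    t0 = time.perf_counter()
    partition = traj = None
    cluster_names = pd.Series(dtype=object)
    if "clustering" in config.stages and len(deg_genes) >= max(config.k, 2):
        try:
            traj = trajectories.build_trajectories(results, deg_genes, tuple(conditions))
            dist = trajectories.pairwise_dtw(traj, config.partition_representation)
            partition = trajectories.pam(dist, k=config.k, seed=config.seed)
            partition = trajectories.orient_partition(partition, traj)
            cluster_names, dendros = trajectories.subcluster_sets(traj, partition, config.subclusters)
            sets = trajectories.gene_sets(partition, traj)
            assign = pd.DataFrame(
                {
                    "set": [partition.set_labels[int(c)] for c in partition.labels],
                    "cluster": cluster_names.reindex(traj.genes).to_numpy(),
                },
                index=pd.Index(traj.genes, name="gene"),
            )
            emit(assign, "trajectory_clusters.tsv")
            for label, dendro in dendros.items():
                p = out / f"dendrogram_{label}.nwk"
                p.write_text(trajectories.to_newick(dendro) + "\n")
                manifest.outputs.append(p.name)
        except Exception as exc:
            raise PipelineError("clustering", exc) from exc
    manifest.wall_time_s["clustering"] = time.perf_counter() - t0

    # ----- enrichment ----------------------------------------------------
    t0 = time.perf_counter()
    if "enrichment" in config.stages and config.gmt is not None:
        try:
            coll = enrich.read_gmt(config.gmt)
            background = list(results.index.unique())
            if not cluster_names.empty:
                ora_frames = []
                for cname in sorted(cluster_names.unique()):
                    members = list(cluster_names.index[cluster_names == cname])
                    res = enrich.ora(members, background, coll,
                                     config.min_set_size, config.max_set_size)
                    res.insert(0, "cluster", cname)
                    ora_frames.append(res)
                emit(pd.concat(ora_frames, ignore_index=True), "ora_clusters.tsv", index=False)
            gsea_tps = config.gsea_timepoints
            if gsea_tps is None:
                gsea_tps = tuple(sorted(t for t in meta["timepoint_min"].unique() if t > 0))
            summaries = {}
            for cond in conditions:
                by_tp = {}
                for t in gsea_tps:
                    ranked = enrich.rank_genes(results, cond, t)
                    by_tp[float(t)] = enrich.gsea_preranked(
                        ranked, coll, weight=config.gsea_weight, n_perm=config.n_perm,
                        seed=config.seed, min_size=config.min_set_size,
                        max_size=config.max_set_size,
                    )
                    frame = by_tp[float(t)].copy()
                    frame.insert(0, "timepoint_min", float(t))
                    frame.insert(0, "condition", cond)
                    emit(frame, f"gsea_{cond}_t{int(t)}.tsv", index=False)
                late = [t for t in enrich.LATE_TIMEPOINTS if t in by_tp]
                summaries[cond] = enrich.summarize_nes(by_tp, late_timepoints=late)
                emit(summaries[cond], f"nes_summary_{cond}.tsv", index=False)
        except Exception as exc:
            raise PipelineError("enrichment", exc) from exc
    manifest.wall_time_s["enrichment"] = time.perf_counter() - t0

    # ----- flow kinetics -------------------------------------------------
    t0 = time.perf_counter()
    if "kinetics" in config.stages and config.flow_events is not None:
        try:
            events = io.read_flow_events(config.flow_events)
            rows = []
            for (construct, channel), _ in events.groupby(["construct", "channel"]):
                series = flow.summarize_flow(events, construct, channel)
                fit = flow.fit_first_order_decay(series)
                act = flow.proteasome_activity(series)
                rows.append(
                    {
                        "construct": construct, "channel": channel,
                        "t_half_min": fit.t_half, "k_per_min": fit.k,
                        "f0": fit.f0, "baseline": fit.baseline,
                        "converged": fit.converged,
                        "min_activity": float(act.activity.min()),
                        "t_min_activity": float(act.timepoints[act.activity.argmin()]),
                    }
                )
            emit(pd.DataFrame(rows), "flow_kinetics.tsv", index=False)
        except Exception as exc:
            raise PipelineError("kinetics", exc) from exc
    manifest.wall_time_s["kinetics"] = time.perf_counter() - t0

    # ----- cell-cycle gating ---------------------------------------------
    t0 = time.perf_counter()
    if "gating" in config.stages and config.cell_events is not None:
        try:
            cells = io.read_cell_events(config.cell_events)
            ann_cols = [c for c in ("construct", "genotype", "duration_min") if c in cells.columns]
            groups = cells.groupby(ann_cols) if ann_cols else [(("all",), cells)]
            per_sample = {}
            labels_frames = []
            for key, grp in groups:
                key = key if isinstance(key, tuple) else (key,)
                model = gating.fit_gates(grp)
                labels = gating.assign_phases(grp, model)
                pf = gating.phase_fractions(labels)
                sample_id = "_".join(str(k) for k in key)
                per_sample[sample_id] = (pf, dict(zip(ann_cols, key)))
                lf = grp[["event_id"]].copy() if "event_id" in grp else pd.DataFrame(index=grp.index)
                lf["phase"] = labels.to_numpy()
                lf["sample_id"] = sample_id
                labels_frames.append(lf)
            table = gating.fractions_table(per_sample)
            emit(pd.concat(labels_frames, ignore_index=True), "cellcycle_labels.csv", index=False)
            emit(table, "cellcycle_fractions.tsv", index=False)
            if {"construct", "duration_min"} <= set(ann_cols):
                emit(gating.compare_conditions(table), "cellcycle_comparison.tsv", index=False)
        except Exception as exc:
            raise PipelineError("gating", exc) from exc
    manifest.wall_time_s["gating"] = time.perf_counter() - t0

    manifest.outputs.append("manifest.json")
    io.write_json(asdict(manifest), out / "manifest.json")
    return manifest
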