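"""Shared fixtures: the study-scale synthetic run is generated once per
session and reused by the unit and acceptance tests."""

from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from ddstress import dge, enrich, simulate, trajectories

STUDY_SEED = 1


@pytest.fixture(scope="session")
def standard_sim():
    """The standard planted design: 5000 genes, 6 timepoints x 2 conditions
    x 5 replicates, modules common_up/common_down/distinct_nuc_up."""
    cfg = simulate.SimConfig(seed=STUDY_SEED)
    counts, meta, truth = simulate.generate_timecourse_counts(cfg)
    return cfg, counts, meta, truth


@pytest.fixture(scope="session")
def standard_dge(standard_sim):
    _cfg, counts, meta, _truth = standard_sim
    results = dge.run_contrasts(counts, meta)
    called = dge.call_degs(results)
    return results, called


@pytest.fixture(scope="session")
def standard_partition(standard_sim, standard_dge):
    results, called = standard_dge
    deg_genes = sorted(called.index[called["deg"]].unique())
    traj = trajectories.build_trajectories(results, deg_genes, ("NucDD", "CytoDD"))
    dist = trajectories.pairwise_dtw(traj, "cross_condition")
    partition = trajectories.orient_partition(trajectories.pam(dist, k=2), traj)
    return traj, partition


@pytest.fixture(scope="session")
def planted_collection(standard_sim):
    """Gene-set collection holding the planted modules plus random decoys."""
    _cfg, _counts, _meta, truth = standard_sim
    rng = np.random.default_rng(7)
    coll = enrich.GeneSetCollection()
    for module in ("common_up", "common_down", "distinct_nuc_up"):
        name = f"{module}_set"
        coll.sets[name] = list(truth.genes_in(module))
        coll.descriptions[name] = "planted module"
    all_genes = list(truth.labels.index)
    for i in range(20):
        size = int(rng.integers(20, 200))
        coll.sets[f"random_{i:02d}"] = list(rng.choice(all_genes, size=size, replace=False))
        coll.descriptions[f"random_{i:02d}"] = "random decoy"
    return coll
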