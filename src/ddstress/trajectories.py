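"""Fold-change trajectory clustering: DTW distances, a k-medoids
common/distinct partition, and Ward sub-clustering.

The two-step scheme reduces the three-way relationship between compartment,
expression change, and time: step one partitions DEGs into a "common" set
(similar response in both cell lines) and a "distinct" set (compartment-
specific response); step two cuts each set into expression-pattern clusters
(C1..C3 / D1..D3) by Ward's method on gene-gene DTW distances.

Two gene representations are available for the pairwise distances:

``bivariate``
    each gene is a 2-channel series (Z-scored NucDD and CytoDD trajectories)
    and D(i, j) is the multivariate DTW distance between genes — a pattern
    similarity.  This is the substrate for Ward sub-clustering.

``cross_condition``
    each gene is summarized by its concordance score delta = univariate DTW
    between its own NucDD and CytoDD Z-series, and D(i, j) = |delta_i -
    delta_j|.  This is the default substrate for the k=2 partition, because a
    pattern distance cannot express "responds the same way in both lines"
    when the common set mixes up- and down-regulated genes: after row
    Z-normalization an up gene and a down gene are mirror images with a large
    mutual DTW distance, so a k=2 pattern clustering splits up from down
    rather than common from distinct.  The concordance representation makes
    the partition measure exactly the property that defines the sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform


@dataclass
class TrajectoryMatrix:
    """Per-gene log2FC-vs-t0 series for both conditions plus a row-Z copy.

    ``raw`` and ``z`` have shape (n_genes, n_conditions, n_timepoints); the
    Z-normalization is per gene over the concatenated values of both
    conditions (constant rows normalize to all zeros).
    """

    genes: list[str]
    conditions: tuple[str, ...]
    timepoints: np.ndarray
    raw: np.ndarray
    z: np.ndarray

    @property
    def n_genes(self) -> int:
        return len(self.genes)


@dataclass
class Partition:
    medoids: list[int]  # indices into the distance matrix
    labels: np.ndarray  # gene -> cluster index (0..k-1)
    objective: float  # sum of distances to assigned medoids
    set_labels: dict[int, str] = field(default_factory=dict)  # cluster -> common/distinct


@dataclass
class Dendrogram:
    linkage: np.ndarray  # scipy linkage matrix (Ward.D2 convention)
    leaves: list[str]  # gene ids in input order

    def cut(self, n_clusters: int) -> np.ndarray:
        if n_clusters > len(self.leaves):
            raise ValueError("n_clusters exceeds number of leaves")
        return hierarchy.fcluster(self.linkage, t=n_clusters, criterion="maxclust")


def build_trajectories(
    results: pd.DataFrame,
    deg_genes,
    conditions: tuple[str, str] = ("NucDD", "CytoDD"),
) -> TrajectoryMatrix:
    """Assemble per-gene log2FC series (0 prepended at t=0) and Z-normalize.

    ``results`` holds the per-contrast test rows (gene index, condition,
    timepoint_min, log2fc); every requested gene must be tested at every
    (condition, timepoint).
    """
    deg_genes = list(deg_genes)
    tested_tps = sorted(results["timepoint_min"].unique())
    timepoints = np.array([0.0] + [t for t in tested_tps if t > 0])
    n_t = len(timepoints)
    raw = np.zeros((len(deg_genes), len(conditions), n_t))
    for ci, cond in enumerate(conditions):
        sub = results[results["condition"] == cond]
        wide = sub.pivot_table(index=sub.index, columns="timepoint_min", values="log2fc")
        missing = set(deg_genes) - set(wide.index)
        if missing:
            raise ValueError(f"missing trajectory entries for genes: {sorted(missing)[:5]} ...")
        wide = wide.reindex(deg_genes)
        if wide.isna().any().any():
            raise ValueError("missing (gene, condition, timepoint) log2FC entries")
        raw[:, ci, 1:] = wide[[t for t in timepoints[1:]]].to_numpy()

    flat = raw.reshape(len(deg_genes), -1)
    mu = flat.mean(axis=1, keepdims=True)
    sd = flat.std(axis=1, ddof=0, keepdims=True)
    z = np.where(sd > 0, (flat - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    return TrajectoryMatrix(
        genes=deg_genes,
        conditions=tuple(conditions),
        timepoints=timepoints,
        raw=raw,
        z=z.reshape(raw.shape),
    )


# ---------------------------------------------------------------------------
# dynamic time warping
# ---------------------------------------------------------------------------

def dtw_distance(a: np.ndarray, b: np.ndarray) -> float:
    """DTW distance with steps {(1,0),(0,1),(1,1)}, unit step weights, and
    Euclidean local cost; no window constraint, no path normalization.

    Inputs are (T,) univariate or (T, C) multivariate series sharing C.
    """
    a = np.atleast_2d(np.asarray(a, dtype=float).T).T
    b = np.atleast_2d(np.asarray(b, dtype=float).T).T
    if a.ndim == 1:
        a = a[:, None]
    if b.ndim == 1:
        b = b[:, None]
    if a.shape[0] == 0 or b.shape[0] == 0:
        raise ValueError("empty series")
    if a.shape[1] != b.shape[1]:
        raise ValueError("channel mismatch between series")
    diff = a[:, None, :] - b[None, :, :]
    cost = np.sqrt((diff**2).sum(axis=2))
    n, m = cost.shape
    acc = np.full((n, m), np.inf)
    acc[0, 0] = cost[0, 0]
    for i in range(n):
        for j in range(m):
            if i == 0 and j == 0:
                continue
            best = np.inf
            if i > 0:
                best = min(best, acc[i - 1, j])
            if j > 0:
                best = min(best, acc[i, j - 1])
            if i > 0 and j > 0:
                best = min(best, acc[i - 1, j - 1])
            acc[i, j] = cost[i, j] + best
    return float(acc[n - 1, m - 1])


def cross_condition_delta(traj: TrajectoryMatrix) -> np.ndarray:
    """Per-gene concordance score: univariate DTW between the gene's own
    NucDD and CytoDD Z-series (0 for a perfectly concordant gene)."""
    return np.array(
        [dtw_distance(traj.z[g, 0, :], traj.z[g, 1, :]) for g in range(traj.n_genes)]
    )


def _pairwise_dtw_bivariate(z: np.ndarray) -> np.ndarray:
    """Vectorized multivariate DTW over all gene pairs.

    ``z`` has shape (n, C, T).  For each anchor gene the 6x6 DP recursion is
    run simultaneously against all other genes, which keeps the inner loop in
    numpy; identical in value to :func:`dtw_distance` per pair.
    """
    n, _c, t = z.shape
    d = np.zeros((n, n))
    series = np.transpose(z, (0, 2, 1))  # (n, T, C)
    for p in range(n - 1):
        others = series[p + 1:]  # (q, T, C)
        diff = series[p][None, :, None, :] - others[:, None, :, :]  # (q, Ta, Tb, C)
        cost = np.sqrt((diff**2).sum(axis=3))
        acc = np.full_like(cost, np.inf)
        acc[:, 0, 0] = cost[:, 0, 0]
        for i in range(t):
            for j in range(t):
                if i == 0 and j == 0:
                    continue
                best = np.full(cost.shape[0], np.inf)
                if i > 0:
                    best = np.minimum(best, acc[:, i - 1, j])
                if j > 0:
                    best = np.minimum(best, acc[:, i, j - 1])
                if i > 0 and j > 0:
                    best = np.minimum(best, acc[:, i - 1, j - 1])
                acc[:, i, j] = cost[:, i, j] + best
        d[p, p + 1:] = acc[:, t - 1, t - 1]
        d[p + 1:, p] = d[p, p + 1:]
    return d


def pairwise_dtw(traj: TrajectoryMatrix, representation: str = "bivariate") -> np.ndarray:
    """Symmetric gene-gene distance matrix under the chosen representation."""
    if traj.n_genes < 2:
        raise ValueError("need at least 2 genes")
    if representation == "bivariate":
        return _pairwise_dtw_bivariate(traj.z)
    if representation == "cross_condition":
        delta = cross_condition_delta(traj)
        return np.abs(delta[:, None] - delta[None, :])
    raise ValueError(f"unknown representation {representation!r}")


# ---------------------------------------------------------------------------
# partitioning around medoids (BUILD + SWAP)
# ---------------------------------------------------------------------------

import math as _math


def _exact_medoids_k2(d: np.ndarray) -> list[int]:
    """Globally optimal medoid pair for k=2 (chunked vectorized scan)."""
    n = d.shape[0]
    best_obj, best = np.inf, (0, 1)
    for i in range(n - 1):
        objs = np.minimum(d[i][None, :], d[i + 1:, :]).sum(axis=1)
        j = int(np.argmin(objs))
        if objs[j] < best_obj - 1e-15:
            best_obj, best = float(objs[j]), (i, i + 1 + j)
    return list(best)


def pam(
    dist: np.ndarray,
    k: int = 2,
    seed: int | None = None,
    max_exhaustive: int = 200_000,
) -> Partition:
    """k-medoids on a precomputed distance matrix.

    When the medoid-subset space is small (``C(n, k) <= max_exhaustive``,
    which covers the pipeline's own k=2 partitions) the globally optimal
    medoid set is found by direct enumeration; otherwise classic PAM
    (greedy BUILD followed by best-improvement SWAP to convergence) is used.
    SWAP is a local search and can stop short of the global optimum — the
    reference PAM implementations share this property — hence the exact path
    whenever it is affordable.  Fully deterministic (ties break toward the
    lowest index); ``seed`` is accepted for interface symmetry but unused.
    """
    d = np.asarray(dist, dtype=float)
    n = d.shape[0]
    if k < 1 or k > n:
        raise ValueError("k must satisfy 1 <= k <= n")

    if k == 2 and n >= 2 and _math.comb(n, 2) <= max_exhaustive:
        medoids = _exact_medoids_k2(d)
        labels = np.argmin(d[:, medoids], axis=1)
        return Partition(
            medoids=medoids, labels=labels,
            objective=float(d[:, medoids].min(axis=1).sum()),
        )
    if k != 2 and _math.comb(n, k) <= max_exhaustive:
        import itertools

        best_obj, best = np.inf, None
        for meds in itertools.combinations(range(n), k):
            obj = float(d[:, meds].min(axis=1).sum())
            if obj < best_obj - 1e-15:
                best_obj, best = obj, list(meds)
        labels = np.argmin(d[:, best], axis=1)
        return Partition(medoids=best, labels=labels, objective=best_obj)

    # BUILD
    medoids = [int(np.argmin(d.sum(axis=1)))]
    while len(medoids) < k:
        current = d[:, medoids].min(axis=1)
        gains = np.maximum(current[None, :] - d, 0.0).sum(axis=1)
        gains[medoids] = -np.inf
        medoids.append(int(np.argmax(gains)))

    def objective(meds: list[int]) -> float:
        return float(d[:, meds].min(axis=1).sum())

    best_obj = objective(medoids)
    improved = True
    while improved:
        improved = False
        best_swap, best_swap_obj = None, best_obj
        for mi, m in enumerate(medoids):
            for h in range(n):
                if h in medoids:
                    continue
                trial = medoids.copy()
                trial[mi] = h
                obj = objective(trial)
                if obj < best_swap_obj - 1e-12:
                    best_swap_obj, best_swap = obj, (mi, h)
        if best_swap is not None:
            mi, h = best_swap
            medoids[mi] = h
            best_obj = best_swap_obj
            improved = True

    medoids = sorted(medoids)
    labels = np.argmin(d[:, medoids], axis=1)
    return Partition(medoids=medoids, labels=labels, objective=objective(medoids))


def orient_partition(partition: Partition, traj: TrajectoryMatrix) -> Partition:
    """Label the k=2 clusters common/distinct by cross-condition concordance.

    The cluster whose genes have the lower median delta (NucDD-vs-CytoDD
    DTW) is the common set.  Invariant to the arbitrary cluster indexing.
    """
    if len(partition.medoids) != 2:
        raise ValueError("orientation requires a k=2 partition")
    delta = cross_condition_delta(traj)
    medians = {}
    for c in (0, 1):
        members = partition.labels == c
        if not members.any():
            raise ValueError("degenerate partition: empty cluster")
        medians[c] = float(np.median(delta[members]))
    common = min((0, 1), key=lambda c: (medians[c], c))
    partition.set_labels = {common: "common", 1 - common: "distinct"}
    return partition


def gene_sets(partition: Partition, traj: TrajectoryMatrix) -> dict[str, list[str]]:
    """Common/distinct gene lists from an oriented partition."""
    if not partition.set_labels:
        raise ValueError("partition is not oriented; call orient_partition first")
    out: dict[str, list[str]] = {"common": [], "distinct": []}
    for idx, gene in enumerate(traj.genes):
        out[partition.set_labels[int(partition.labels[idx])]].append(gene)
    return out


# ---------------------------------------------------------------------------
# Ward sub-clustering
# ---------------------------------------------------------------------------

def ward_linkage(dist: np.ndarray, members: list[str]) -> Dendrogram:
    """Agglomerative Ward clustering (Ward.D2 Lance-Williams update on
    squared distances) over a gene subset.

    DTW distances are not Euclidean, so Ward here is the usual pragmatic
    heuristic: the recurrence is applied to the distances as given.
    """
    d = np.asarray(dist, dtype=float)
    if d.shape[0] != len(members):
        raise ValueError("distance matrix does not match members")
    if len(members) < 2:
        raise ValueError("need at least 2 members")
    z = hierarchy.linkage(squareform(d, checks=False), method="ward")
    return Dendrogram(linkage=z, leaves=list(members))


def cut_and_name(
    dendrogram: Dendrogram,
    n_clusters: int,
    traj: TrajectoryMatrix,
    set_label: str,
) -> pd.Series:
    """Cut a set's dendrogram and name clusters C1..Cn / D1..Dn.

    Within a set, clusters are ordered by descending mean Z-scored fold
    change over the final two timepoints (averaged across conditions for the
    common set; NucDD-only for the distinct set), so C1/D1 is the strongest
    late up-regulation pattern.  The naming is invariant to leaf input order.
    """
    assignments = dendrogram.cut(n_clusters)
    prefix = "C" if set_label == "common" else "D"
    gene_pos = {g: i for i, g in enumerate(traj.genes)}
    idx = np.array([gene_pos[g] for g in dendrogram.leaves])
    if set_label == "common":
        late = traj.z[idx][:, :, -2:].mean(axis=(1, 2))
    else:
        late = traj.z[idx][:, 0, -2:].mean(axis=1)
    scores = {}
    for c in np.unique(assignments):
        scores[c] = float(late[assignments == c].mean())
    ordered = sorted(scores, key=lambda c: (-scores[c], c))
    names = {c: f"{prefix}{rank + 1}" for rank, c in enumerate(ordered)}
    return pd.Series(
        [names[c] for c in assignments], index=pd.Index(dendrogram.leaves, name="gene"),
        name="cluster",
    )


def to_newick(dendrogram: Dendrogram) -> str:
    """Newick export of a dendrogram (branch lengths from merge heights)."""
    tree = hierarchy.to_tree(dendrogram.linkage)
    leaves = dendrogram.leaves

    def rec(node, parent_height: float) -> str:
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{leaves[node.id]}:{length:.6g}"
        left = rec(node.left, node.dist)
        right = rec(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return rec(tree, tree.dist) + ";"


def subcluster_sets(
    traj: TrajectoryMatrix,
    partition: Partition,
    n_clusters: int = 3,
) -> tuple[pd.Series, dict[str, Dendrogram]]:
    """Ward sub-clustering of the common and distinct sets.

    Returns a gene -> cluster-name series (C1..Cn, D1..Dn) and the per-set
    dendrograms.  Pattern (bivariate DTW) distances are used within each set.
    """
    sets = gene_sets(partition, traj)
    full_d = pairwise_dtw(traj, representation="bivariate")
    pos = {g: i for i, g in enumerate(traj.genes)}
    named = []
    dendros: dict[str, Dendrogram] = {}
    for set_label, members in sets.items():
        if len(members) < 2:
            raise ValueError(f"{set_label} set has fewer than 2 genes")
        idx = np.array([pos[g] for g in members])
        sub_d = full_d[np.ix_(idx, idx)]
        dendro = ward_linkage(sub_d, members)
        dendros[set_label] = dendro
        k = min(n_clusters, len(members))
        named.append(cut_and_name(dendro, k, traj, set_label))
    return pd.concat(named), dendros


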