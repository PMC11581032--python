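"""Pathway enrichment: hypergeometric overrepresentation and preranked GSEA.

ORA tests a query gene list (e.g. one expression cluster) against gene sets
within a background universe of all detected genes; sets are ranked by fold
enrichment (k/n)/(K/N).  Preranked GSEA walks a Wald-statistic-ranked gene
list with the classic weighted running sum; the enrichment score ES is the
signed maximum deviation, normalized to NES against a gene-sampling
permutation null.  Pathway-level summaries follow the study's two rankings:
median NES across timepoints and the sum of NES over the late (60/120/240
min) timepoints.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .dge import bh_adjust

LATE_TIMEPOINTS = (60.0, 120.0, 240.0)


@dataclass
class GeneSetCollection:
    sets: dict[str, list[str]] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)

    def items(self):
        return self.sets.items()


class GmtError(ValueError):
    pass


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file (name TAB description TAB member...)."""
    coll = GeneSetCollection()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GmtError(f"{path}: malformed GMT line {lineno} (need >= 3 fields)")
            name, desc, *members = fields
            seen: list[str] = []
            for m in members:
                if m and m not in seen:
                    seen.append(m)
            coll.sets[name] = seen
            coll.descriptions[name] = desc
    if not coll.sets:
        warnings.warn(f"{path}: empty GMT collection", stacklevel=2)
    return coll


def write_gmt(coll: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, members in coll.sets.items():
            desc = coll.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *members]) + "\n")


def ora(
    query,
    background,
    sets: GeneSetCollection,
    min_size: int = 5,
    max_size: int = 500,
) -> pd.DataFrame:
    """Hypergeometric overrepresentation of each gene set in a query list.

    p = P(X >= k) with population N = |background|, K successes (set members
    in the background), n draws (query size); BH across retained sets; rows
    sorted by descending fold enrichment.
    """
    query_set = set(query)
    bg_set = set(background)
    if not query_set:
        raise ValueError("empty query")
    if not query_set <= bg_set:
        raise ValueError("query genes must be contained in the background")
    n, n_bg = len(query_set), len(bg_set)
    rows = []
    for name, members in sets.items():
        in_bg = set(members) & bg_set
        big_k = len(in_bg)
        if not (min_size <= big_k <= max_size):
            continue
        k = len(in_bg & query_set)
        fe = (k / n) / (big_k / n_bg)
        p = float(stats.hypergeom.sf(k - 1, n_bg, big_k, n))
        rows.append({"set": name, "k": k, "K": big_k, "n": n, "N": n_bg,
                     "fold_enrichment": fe, "pvalue": p})
    result = pd.DataFrame(rows, columns=["set", "k", "K", "n", "N", "fold_enrichment", "pvalue"])
    if len(result):
        result["padj"] = bh_adjust(result["pvalue"].to_numpy())
        result = result.sort_values(
            ["fold_enrichment", "pvalue", "set"], ascending=[False, True, True]
        ).reset_index(drop=True)
    else:
        result["padj"] = []
    return result


def rank_genes(results: pd.DataFrame, condition: str, timepoint: float) -> pd.DataFrame:
    """Wald-statistic preranking for one contrast (descending z, ties by gene
    ID; untested genes excluded)."""
    sub = results[
        (results["condition"] == condition) & (results["timepoint_min"] == timepoint)
    ]
    if sub.empty:
        raise ValueError(f"unknown contrast ({condition}, {timepoint})")
    sub = sub[np.isfinite(sub["stat"])]
    ranked = sub.reset_index()[["gene", "stat"]]
    ranked = ranked.sort_values(["stat", "gene"], ascending=[False, True], kind="stable")
    return ranked.reset_index(drop=True)


# ---------------------------------------------------------------------------
# enrichment score machinery
# ---------------------------------------------------------------------------

def _es_from_positions(pos: np.ndarray, w: np.ndarray, n_list: int) -> np.ndarray:
    """Vectorized ES for one or more hit-position sets.

    ``pos`` (m, K) are 0-based hit positions sorted ascending per row; ``w``
    the matching hit weights (|stat|**weight).  The running sum only changes
    slope at hits, so its extremes occur immediately after a hit (maximum
    candidates) or immediately before one (minimum candidates); the final
    value is 0 by normalization.  ES is the extreme of larger magnitude
    (ties resolve positive).
    """
    m, k = pos.shape
    miss_step = 1.0 / (n_list - k)
    w_total = w.sum(axis=1, keepdims=True)
    # guard all-zero weights (flat statistics): hits contribute equally
    flat = (w_total == 0).ravel()
    if flat.any():
        w = w.copy()
        w[flat] = 1.0
        w_total = w.sum(axis=1, keepdims=True)
    hit_cum = np.cumsum(w, axis=1) / w_total
    i = np.arange(1, k + 1)
    after = hit_cum - (pos + 1 - i) * miss_step
    before = (hit_cum - w / w_total) - (pos - (i - 1)) * miss_step
    max_dev = np.maximum(after.max(axis=1), 0.0)
    min_dev = np.minimum(before.min(axis=1), 0.0)
    # ties (|max| == |min| up to float noise) resolve to the positive extreme
    return np.where(max_dev >= -min_dev - 1e-12, max_dev, min_dev)


def enrichment_score(stats_ranked: np.ndarray, hit_mask: np.ndarray, weight: float = 1.0):
    """ES and running sum for one set on a ranked statistic vector.

    Kept O(N) and explicit (hits add |stat|**weight normalized by the set
    total; misses subtract 1/(N-K)); the permutation path uses the
    positions-based equivalent.
    """
    stats_ranked = np.asarray(stats_ranked, dtype=float)
    hit_mask = np.asarray(hit_mask, dtype=bool)
    n = stats_ranked.size
    k = int(hit_mask.sum())
    if k == 0 or k == n:
        raise ValueError("set must be a proper non-empty subset of the list")
    w = np.abs(stats_ranked) ** weight
    w_hits = np.where(hit_mask, w, 0.0)
    total = w_hits.sum()
    if total == 0:
        w_hits = hit_mask.astype(float)
        total = float(k)
    steps = np.where(hit_mask, w_hits / total, -1.0 / (n - k))
    running = np.cumsum(steps)
    i_max = int(np.argmax(running))
    i_min = int(np.argmin(running))
    max_dev = max(running[i_max], 0.0)
    min_dev = min(running[i_min], 0.0)
    # ties resolve to the positive extreme (tolerance absorbs float noise)
    es = max_dev if max_dev >= -min_dev - 1e-12 else min_dev
    return float(es), running


def _leading_edge(genes: np.ndarray, running: np.ndarray, hit_mask: np.ndarray, es: float) -> list[str]:
    if es >= 0:
        upto = int(np.argmax(running))
        sel = hit_mask[: upto + 1]
        return list(genes[: upto + 1][sel])
    frm = int(np.argmin(running))
    sel = hit_mask[frm:]
    return list(genes[frm:][sel])


def gsea_preranked(
    ranked: pd.DataFrame,
    sets: GeneSetCollection,
    weight: float = 1.0,
    n_perm: int = 1000,
    seed: int = 0,
    min_size: int = 5,
    max_size: int = 500,
) -> pd.DataFrame:
    """Preranked GSEA for one contrast.

    The null is gene-sampling: ``n_perm`` random same-size draws from the
    ranked list.  NES = ES / mean(|null ES| of the same sign); the empirical
    p uses (k+1)/(n+1) smoothing against the same-sign null; BH across sets.
    ``sig`` flags raw p < 0.05 (the display criterion); padj is reported
    alongside.
    """
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives unstable NES/p estimates", stacklevel=2)
    genes = ranked["gene"].to_numpy()
    stat = ranked["stat"].to_numpy(dtype=float)
    if len(np.unique(genes)) != len(genes):
        raise ValueError("ranked list must have unique genes")
    if not np.all(np.isfinite(stat)):
        raise ValueError("ranking statistics must be finite")
    n = genes.size
    pos_of = {g: i for i, g in enumerate(genes)}
    rng = np.random.default_rng(seed)
    absw = np.abs(stat) ** weight

    rows = []
    for name, members in sets.items():
        hit_idx = np.array(sorted(pos_of[g] for g in members if g in pos_of), dtype=int)
        k = hit_idx.size
        if not (min_size <= k <= max_size) or k == n:
            continue
        hit_mask = np.zeros(n, dtype=bool)
        hit_mask[hit_idx] = True
        es, running = enrichment_score(stat, hit_mask, weight)

        # same-size random gene draws
        draws = np.argpartition(rng.random((n_perm, n)), k - 1, axis=1)[:, :k]
        draws.sort(axis=1)
        null_es = _es_from_positions(draws, absw[draws], n)
        same_sign = null_es >= 0 if es >= 0 else null_es < 0
        null_same = np.abs(null_es[same_sign])
        if null_same.size == 0:
            nes, p = np.nan, 1.0
        else:
            denom = null_same.mean()
            nes = es / denom if denom > 0 else np.nan
            p = (1.0 + float((null_same >= abs(es)).sum())) / (1.0 + null_same.size)
        rows.append(
            {
                "set": name,
                "size": k,
                "es": es,
                "nes": nes,
                "pvalue": p,
                "lead_genes": ",".join(_leading_edge(genes, running, hit_mask, es)),
            }
        )
    result = pd.DataFrame(rows, columns=["set", "size", "es", "nes", "pvalue", "lead_genes"])
    if len(result):
        result["padj"] = bh_adjust(result["pvalue"].to_numpy())
        result["sig"] = result["pvalue"] < 0.05
    else:
        result["padj"] = []
        result["sig"] = []
    return result


def summarize_nes(
    results_by_timepoint: dict[float, pd.DataFrame],
    late_timepoints=LATE_TIMEPOINTS,
) -> pd.DataFrame:
    """Pathway ranking summaries across timepoints.

    Per set: median NES across all supplied timepoints (non-significant
    timepoints still contribute their NES; significance only flags display)
    and the sum of NES over the late subset.  Both rank orderings are
    emitted as columns.
    """
    if not results_by_timepoint:
        raise ValueError("no GSEA results supplied")
    late = [float(t) for t in late_timepoints]
    missing = [t for t in late if t not in {float(x) for x in results_by_timepoint}]
    if missing:
        raise ValueError(f"requested summary timepoints absent from results: {missing}")
    frames = []
    for t, df in results_by_timepoint.items():
        sub = df[["set", "nes", "sig"]].copy()
        sub["timepoint_min"] = float(t)
        frames.append(sub)
    long = pd.concat(frames)
    rows = []
    for name, grp in long.groupby("set"):
        late_grp = grp[grp["timepoint_min"].isin(late)]
        rows.append(
            {
                "set": name,
                "median_nes": float(grp["nes"].median()),
                "late_nes_sum": float(late_grp["nes"].sum()),
                "n_timepoints": len(grp),
                "n_sig_timepoints": int(grp["sig"].sum()),
            }
        )
    out = pd.DataFrame(rows)
    out["rank_by_median"] = out["median_nes"].rank(ascending=False, method="min").astype(int)
    out["rank_by_late_sum"] = out["late_nes_sum"].rank(ascending=False, method="min").astype(int)
    return out.sort_values("late_nes_sum", ascending=False).reset_index(drop=True)
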