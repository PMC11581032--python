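"""Time-course differential expression with a simplified NB Wald test.

Each post-withdrawal timepoint is tested against the 0-min sample of the same
cell line.  Counts are normalized with median-of-ratios size factors; per-gene
negative-binomial dispersions (Var = mu + alpha mu^2) are estimated by moments
and shrunk toward a fitted 1/mu mean-dispersion trend; the test statistic is
the Wald z = log2FC / SE with a delta-method standard error and a two-sided
normal p-value, BH-adjusted within each contrast.  DESeq2's exact shrinkage
machinery is deliberately not reproduced — the pipeline needs the statistic's
semantics (a signed, SE-scaled fold change), not a bit-identical replica.

DEG calling uses the study's thresholds: |fold change| > 1.4 and BH-adjusted
p < 0.01.  Per timepoint, genes passing in both cell lines are "common",
in exactly one "distinct".
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_FC_THRESHOLD = 1.4
DEFAULT_ALPHA = 0.01

# strength of shrinkage toward the mean-dispersion trend, in pseudo-degrees of
# freedom; with 5v5 replicates (8 residual df) the trend dominates, which is
# what keeps the normal-tail Wald p calibrated at small n
_DISPERSION_PRIOR_DF = 20.0
_MIN_DISPERSION = 1e-8
_PSEUDO_MEAN = 0.5  # stabilizer added to group means before taking log2


class DesignError(ValueError):
    pass


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    factor_s = median over genes (expressed in all samples) of
    counts_gs / geometric-mean_g.  Genes with a zero in any sample are
    excluded from the reference, as in the standard median-of-ratios scheme.
    """
    mat = counts.to_numpy(dtype=float)
    usable = (mat > 0).all(axis=1)
    if not usable.any():
        raise DesignError("no gene expressed in all samples; cannot normalize")
    logs = np.log(mat[usable])
    log_gm = logs.mean(axis=1, keepdims=True)
    factors = np.exp(np.median(logs - log_gm, axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def normalized_counts(counts: pd.DataFrame, factors: pd.Series) -> pd.DataFrame:
    if (factors <= 0).any():
        raise DesignError("size factors must be positive")
    return counts / factors.reindex(counts.columns)


def detected_genes(counts: pd.DataFrame, meta: pd.DataFrame) -> pd.Index:
    """Universe filter: genes with nonzero total count in every
    (condition, timepoint) group — the in-silico analogue of "transcripts
    detected in both cell lines across all timepoints"."""
    keep = np.ones(len(counts), dtype=bool)
    for _, grp in meta.groupby(["condition", "timepoint_min"]):
        keep &= counts[grp["sample_id"]].sum(axis=1).to_numpy() > 0
    return counts.index[keep]


def validate_design(meta: pd.DataFrame) -> None:
    required = {"sample_id", "condition", "timepoint_min", "replicate"}
    missing = required - set(meta.columns)
    if missing:
        raise DesignError(f"metadata missing columns: {sorted(missing)}")
    for cond, grp in meta.groupby("condition"):
        if 0 not in set(grp["timepoint_min"]):
            raise DesignError(f"condition {cond!r} lacks a 0-min reference group")
        sizes = grp.groupby("timepoint_min").size()
        if (sizes < 2).any():
            bad = sizes[sizes < 2].index.tolist()
            raise DesignError(f"condition {cond!r} has <2 replicates at timepoints {bad}")


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, order-preserving, capped at 1.

    NaN entries are passed through and excluded from the number of tests m.
    """
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    vals = p[mask]
    if np.any((vals < 0) | (vals > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = vals.size
    if m == 0:
        return out
    order = np.argsort(vals, kind="stable")
    ranked = vals[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.empty(m)
    adjusted[order] = np.minimum(adj, 1.0)
    out[mask] = adjusted
    return out


def _dispersion_trend(mean: np.ndarray, disp: np.ndarray) -> np.ndarray:
    """Fit alpha(mu) = a0 + a1/mu by least squares over well-measured genes
    and return the per-gene trend values (floored)."""
    ok = (mean > 5) & np.isfinite(disp)
    if ok.sum() < 10:
        a0, a1 = max(np.nanmedian(disp), _MIN_DISPERSION), 0.0
    else:
        x = np.column_stack([np.ones(ok.sum()), 1.0 / mean[ok]])
        coef, *_ = np.linalg.lstsq(x, disp[ok], rcond=None)
        a0, a1 = max(coef[0], 0.0), max(coef[1], 0.0)
        if a0 == 0.0 and a1 == 0.0:
            a0 = max(np.nanmedian(disp), _MIN_DISPERSION)
    return np.maximum(a0 + a1 / np.maximum(mean, 1e-8), _MIN_DISPERSION)


def test_timepoint(
    counts: pd.DataFrame,
    meta: pd.DataFrame,
    condition: str,
    timepoint: float,
    factors: pd.Series | None = None,
) -> pd.DataFrame:
    """NB Wald test of one (condition, timepoint) contrast against t=0.

    Returns one row per gene with columns condition, timepoint_min, base_mean,
    log2fc, se, stat, pvalue, padj.  Genes with all-zero counts in both groups
    get NaN p-values and are excluded from the BH test count.
    """
    validate_design(meta)
    if factors is None:
        factors = size_factors(counts)
    sub = meta[meta["condition"] == condition]
    s_t = sub.loc[sub["timepoint_min"] == timepoint, "sample_id"].tolist()
    s_0 = sub.loc[sub["timepoint_min"] == 0, "sample_id"].tolist()
    if len(s_t) < 2 or len(s_0) < 2:
        raise DesignError(
            f"contrast ({condition}, {timepoint} min) needs >=2 replicates in both groups"
        )

    norm = normalized_counts(counts, factors)
    a = norm[s_t].to_numpy(dtype=float)
    b = norm[s_0].to_numpy(dtype=float)
    n_a, n_b = a.shape[1], b.shape[1]
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    var_a = a.var(axis=1, ddof=1)
    var_b = b.var(axis=1, ddof=1)
    inv_s_a = (1.0 / factors[s_t]).mean()
    inv_s_b = (1.0 / factors[s_0]).mean()

    # moment estimate of NB dispersion on the normalized scale, pooled over
    # both groups, then shrunk toward a fitted 1/mu trend
    with np.errstate(divide="ignore", invalid="ignore"):
        disp_a = (var_a - mean_a * inv_s_a) / mean_a**2
        disp_b = (var_b - mean_b * inv_s_b) / mean_b**2
    df_a, df_b = n_a - 1, n_b - 1
    disp_raw = (df_a * disp_a + df_b * disp_b) / (df_a + df_b)
    disp_raw = np.clip(disp_raw, 0.0, 10.0)
    base_mean = (mean_a * n_a + mean_b * n_b) / (n_a + n_b)
    trend = _dispersion_trend(base_mean, disp_raw)
    df = float(df_a + df_b)
    alpha = (df * disp_raw + _DISPERSION_PRIOR_DF * trend) / (df + _DISPERSION_PRIOR_DF)
    alpha = np.maximum(alpha, _MIN_DISPERSION)

    m_a = mean_a + _PSEUDO_MEAN
    m_b = mean_b + _PSEUDO_MEAN
    log2fc = np.log2(m_a / m_b)
    # delta method: Var(log2 mean) = Var(mean) / (mean ln2)^2 with
    # Var(mean_group) = (mu * mean(1/s) + alpha mu^2) / n
    var_mean_a = (m_a * inv_s_a + alpha * m_a**2) / n_a
    var_mean_b = (m_b * inv_s_b + alpha * m_b**2) / n_b
    se = np.sqrt(var_mean_a / m_a**2 + var_mean_b / m_b**2) / np.log(2.0)

    untested = (a.sum(axis=1) == 0) & (b.sum(axis=1) == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = log2fc / se
    pvalue = 2.0 * stats.norm.sf(np.abs(z))
    pvalue[untested] = np.nan
    z = np.where(untested, np.nan, z)

    res = pd.DataFrame(
        {
            "condition": condition,
            "timepoint_min": float(timepoint),
            "base_mean": base_mean,
            "log2fc": log2fc,
            "se": se,
            "stat": z,
            "pvalue": pvalue,
            "padj": bh_adjust(pvalue),
        },
        index=counts.index,
    )
    res.index.name = "gene"
    return res


def run_contrasts(
    counts: pd.DataFrame,
    meta: pd.DataFrame,
    conditions: list[str] | None = None,
    timepoints: list[float] | None = None,
    filter_detected: bool = True,
) -> pd.DataFrame:
    """All (condition, timepoint > 0) contrasts, concatenated.

    With ``filter_detected`` the gene universe is restricted to genes detected
    in every condition-timepoint group before testing.
    """
    validate_design(meta)
    if filter_detected:
        counts = counts.loc[detected_genes(counts, meta)]
    factors = size_factors(counts)
    if conditions is None:
        conditions = sorted(meta["condition"].unique())
    results = []
    for cond in conditions:
        tps = timepoints
        if tps is None:
            tps = sorted(t for t in meta.loc[meta["condition"] == cond, "timepoint_min"].unique() if t > 0)
        for t in tps:
            results.append(test_timepoint(counts, meta, cond, t, factors=factors))
    return pd.concat(results)


def call_degs(
    results: pd.DataFrame,
    fc_threshold: float = DEFAULT_FC_THRESHOLD,
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """Flag DEGs: |fold change| > fc_threshold and padj < alpha.

    The threshold applies to the unshrunk fold-change estimate on the linear
    scale (2**|log2fc| > fc_threshold).  Direction is the sign of log2fc.
    """
    if fc_threshold <= 0:
        raise ValueError("fc_threshold must be positive")
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    out = results.copy()
    passes_fc = np.exp2(np.abs(out["log2fc"])) > fc_threshold
    passes_p = out["padj"] < alpha
    out["deg"] = (passes_fc & passes_p).fillna(False)
    out["direction"] = np.where(out["log2fc"] > 0, "up", "down")
    out.loc[~out["deg"], "direction"] = "none"
    return out


def classify_common_distinct(deg_nuc: pd.DataFrame, deg_cyto: pd.DataFrame) -> pd.DataFrame:
    """Per-(gene, timepoint) class: common (DEG in both cell lines),
    distinct (DEG in exactly one), none."""
    key = ["timepoint_min"]
    n = deg_nuc.reset_index().set_index(["gene"] + key)
    c = deg_cyto.reset_index().set_index(["gene"] + key)
    if set(n.index) != set(c.index):
        raise DesignError("gene/timepoint universes differ between the two DEG tables")
    merged = pd.DataFrame(
        {
            "nuc_deg": n["deg"],
            "cyto_deg": c["deg"].reindex(n.index),
            "nuc_direction": n["direction"],
            "cyto_direction": c["direction"].reindex(n.index),
        }
    )
    both = merged["nuc_deg"] & merged["cyto_deg"]
    one = merged["nuc_deg"] ^ merged["cyto_deg"]
    merged["klass"] = np.where(both, "common", np.where(one, "distinct", "none"))
    return merged.reset_index()


def classification_counts(classified: pd.DataFrame) -> pd.DataFrame:
    """Per-timepoint DEG counts by class and direction (the bar-plot numbers)."""
    rows = []
    for t, grp in classified.groupby("timepoint_min"):
        for klass in ("common", "distinct"):
            sub = grp[grp["klass"] == klass]
            direction = sub["nuc_direction"].where(sub["nuc_direction"] != "none", sub["cyto_direction"])
            rows.append(
                {
                    "timepoint_min": t,
                    "klass": klass,
                    "n_genes": len(sub),
                    "n_up": int((direction == "up").sum()),
                    "n_down": int((direction == "down").sum()),
                }
            )
    return pd.DataFrame(rows)


def pca_samples(
    normalized: pd.DataFrame, top_fraction: float = 0.10, n_components: int = 2
) -> tuple[pd.DataFrame, np.ndarray]:
    """Sample PCA on the most variable genes.

    Genes are ranked by variance of log2(normalized + 1); the top
    ``top_fraction`` are retained; samples are projected onto the principal
    components of the gene-centered matrix.  Returns (coordinates indexed by
    sample, variance-explained fractions).
    """
    if normalized.shape[1] < 3:
        raise DesignError("PCA needs at least 3 samples")
    logx = np.log2(normalized.to_numpy(dtype=float) + 1.0)
    n_top = int(np.ceil(top_fraction * logx.shape[0]))
    if n_top < 1:
        raise DesignError("top gene set is empty")
    variances = logx.var(axis=1)
    top = np.argsort(-variances, kind="stable")[:n_top]
    x = logx[top]  # genes x samples
    x = x - x.mean(axis=1, keepdims=True)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    coords = (vt[:n_components].T * s[:n_components])
    explained = (s**2) / (s**2).sum()
    cols = [f"PC{i+1}" for i in range(n_components)]
    return pd.DataFrame(coords, index=normalized.columns, columns=cols), explained[:n_components]
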