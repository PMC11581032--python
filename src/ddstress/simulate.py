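"""Synthetic inputs with planted ground truth.

Every generator mirrors one arm of the experimental design: bulk RNA-seq
counts over a ligand-withdrawal time course (6 timepoints x 2 cell lines x
5 replicates), flow-cytometry decay of the DD-sfGFP fusion after ligand
withdrawal, degron-reporter accumulation/recovery, and bivariate DNA/EdU
cell-cycle event clouds.  All generators are deterministic given a single
integer seed; per-generator substreams are derived by fixed offsets so adding
one generator never perturbs another's stream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

DEFAULT_TIMEPOINTS = (0, 15, 30, 60, 120, 240)
DEFAULT_CONDITIONS = ("NucDD", "CytoDD")

# fixed substream offsets (never reorder: seeds are part of the contract)
_STREAM_OFFSETS = {
    "counts": 11,
    "decay": 23,
    "reporter": 37,
    "cellcycle": 53,
}

CELL_CYCLE_PHASES = ("G1", "early_S", "late_S", "G2M")


def substream(seed: int, name: str) -> np.random.Generator:
    """Independent RNG substream for one generator, derived from the global seed."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), _STREAM_OFFSETS[name]]))


@dataclass(frozen=True)
class ModuleSpec:
    """A planted gene module: a name, a size, and one log2FC-vs-t0 trajectory
    per condition (zero at t=0 by construction)."""

    name: str
    n_genes: int
    log2fc: Mapping[str, Sequence[float]]  # condition -> trajectory over timepoints


def default_module_specs(
    timepoints: Sequence[int] = DEFAULT_TIMEPOINTS,
) -> tuple[ModuleSpec, ...]:
    """The standard planted design.

    ``common_up``/``common_down`` respond identically in both cell lines with
    late (120-240 min) induction/repression; ``distinct_nuc_up`` is a stronger,
    nucleus-only late induction emulating the p53-program-like response that
    only nuclear unfolded protein elicits.
    """
    if tuple(timepoints) != DEFAULT_TIMEPOINTS:
        raise ValueError("default module specs are defined on the standard 6-timepoint grid")
    up = (0.0, 0.0, 0.0, 0.2, 0.5, 1.0)
    down = tuple(-v for v in up)
    nuc_only = (0.0, 0.0, 0.0, 0.3, 1.0, 1.5)
    flat = (0.0,) * 6
    return (
        ModuleSpec("common_up", 150, {"NucDD": up, "CytoDD": up}),
        ModuleSpec("common_down", 100, {"NucDD": down, "CytoDD": down}),
        ModuleSpec("distinct_nuc_up", 120, {"NucDD": nuc_only, "CytoDD": flat}),
    )


@dataclass
class SimConfig:
    """Configuration of the RNA-seq count simulator.

    Negative-binomial counts with Var = mu + dispersion * mu^2; per-gene
    baseline means are log-normal; per-sample depth factors are uniform in
    ``library_size_range``.
    """

    n_genes: int = 5000
    timepoints: tuple[int, ...] = DEFAULT_TIMEPOINTS
    n_replicates: int = 5
    conditions: tuple[str, ...] = DEFAULT_CONDITIONS
    module_specs: tuple[ModuleSpec, ...] = field(default_factory=default_module_specs)
    baseline_mean_log_params: tuple[float, float] = (4.0, 1.5)  # ln-scale loc/scale
    dispersion: float | np.ndarray = 0.05
    library_size_range: tuple[float, float] = (0.7, 1.3)
    seed: int = 0

    def validate(self) -> None:
        tps = np.asarray(self.timepoints)
        if tps[0] != 0 or np.any(np.diff(tps) <= 0):
            raise ValueError("timepoints must be strictly increasing and start at 0")
        if self.n_replicates < 2:
            raise ValueError("need >= 2 replicates per condition-timepoint")
        total = sum(m.n_genes for m in self.module_specs)
        if total > self.n_genes:
            raise ValueError(
                f"module gene counts ({total}) exceed n_genes ({self.n_genes})"
            )
        disp = np.asarray(self.dispersion, dtype=float)
        if np.any(disp <= 0):
            raise ValueError("dispersion must be > 0")
        for m in self.module_specs:
            for cond in self.conditions:
                traj = np.asarray(m.log2fc[cond], dtype=float)
                if traj.shape != tps.shape:
                    raise ValueError(f"module {m.name}: trajectory length mismatch")
                if traj[0] != 0:
                    raise ValueError(f"module {m.name}: trajectory must be 0 at t=0")
        lo, hi = self.library_size_range
        if not (0 < lo <= hi):
            raise ValueError("library_size_range must be positive and ordered")


@dataclass
class SimTruth:
    """Planted ground truth: per-gene module label, per-gene true log2FC
    trajectory per condition, per-sample true depth factor."""

    labels: pd.Series  # gene -> module name ('null' for unplanted genes)
    log2fc: dict[str, pd.DataFrame]  # condition -> genes x timepoints
    depth: pd.Series  # sample -> depth factor
    baseline_mean: pd.Series  # gene -> mu_g

    def genes_in(self, module: str) -> pd.Index:
        return self.labels.index[self.labels == module]


def generate_timecourse_counts(
    config: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, SimTruth]:
    """Simulate the full count matrix, sample metadata, and ground truth.

    Counts for gene g in sample s (condition c, time t) are NB with mean
    ``mu_g * 2**FC_{g,c}(t) * depth_s`` and dispersion ``alpha_g``.
    """
    config.validate()
    rng = substream(config.seed, "counts")
    n_genes = config.n_genes
    tps = list(config.timepoints)

    genes = pd.Index([f"g{i:05d}" for i in range(n_genes)], name="gene")
    labels = pd.Series("null", index=genes, name="module")
    fc = {c: np.zeros((n_genes, len(tps))) for c in config.conditions}
    start = 0
    for m in config.module_specs:
        sl = slice(start, start + m.n_genes)
        labels.iloc[sl] = m.name
        for c in config.conditions:
            fc[c][sl, :] = np.asarray(m.log2fc[c], dtype=float)
        start += m.n_genes

    loc, scale = config.baseline_mean_log_params
    mu = rng.lognormal(mean=loc, sigma=scale, size=n_genes)
    alpha = np.broadcast_to(np.asarray(config.dispersion, dtype=float), (n_genes,))

    rows = []
    for c in config.conditions:
        for t in tps:
            for r in range(1, config.n_replicates + 1):
                rows.append((f"{c}_t{t:03d}_r{r}", c, t, r))
    meta = pd.DataFrame(rows, columns=["sample_id", "condition", "timepoint_min", "replicate"])
    depth = pd.Series(
        rng.uniform(*config.library_size_range, size=len(meta)),
        index=meta["sample_id"].values,
        name="depth",
    )

    counts = np.empty((n_genes, len(meta)), dtype=np.int64)
    nb_n = 1.0 / alpha  # NB shape so that Var = mu + alpha mu^2
    for j, (sid, c, t, _r) in enumerate(meta.itertuples(index=False)):
        ti = tps.index(t)
        mean_j = mu * np.exp2(fc[c][:, ti]) * depth.loc[sid]
        p = nb_n / (nb_n + mean_j)
        counts[:, j] = rng.negative_binomial(nb_n, p)

    counts_df = pd.DataFrame(counts, index=genes, columns=meta["sample_id"].values)
    truth = SimTruth(
        labels=labels,
        log2fc={c: pd.DataFrame(fc[c], index=genes, columns=tps) for c in config.conditions},
        depth=depth,
        baseline_mean=pd.Series(mu, index=genes, name="baseline_mean"),
    )
    return counts_df, meta, truth


# ---------------------------------------------------------------------------
# flow-cytometry event generators
# ---------------------------------------------------------------------------

def _lognormal_events(rng: np.random.Generator, mean: float, cv: float, n: int) -> np.ndarray:
    """Log-normal draws with arithmetic mean ``mean`` and coefficient of
    variation ``cv`` (degenerate at cv=0)."""
    if mean < 0:
        raise ValueError("negative intensities requested")
    if cv == 0:
        return np.full(n, float(mean))
    sigma2 = math.log1p(cv * cv)
    mu = math.log(mean) - sigma2 / 2.0
    return rng.lognormal(mean=mu, sigma=math.sqrt(sigma2), size=n)


def _events_frame(records: list[tuple]) -> pd.DataFrame:
    df = pd.DataFrame(records, columns=["construct", "timepoint_min", "channel", "intensity"])
    df.insert(0, "event_id", np.arange(len(df)))
    return df


def generate_decay_events(
    t_half: float,
    f0: float,
    baseline: float = 0.0,
    cv: float = 0.3,
    n_events_per_timepoint: int = 20_000,
    timepoints: Sequence[float] = DEFAULT_TIMEPOINTS,
    seed: int = 0,
    construct: str = "DD-sfGFP",
    channel: str = "GFP",
) -> pd.DataFrame:
    """First-order fluorescence decay after ligand withdrawal.

    Per-event intensity is log-normal around
    ``F(t) = baseline + (f0 - baseline) * exp(-t ln2 / t_half)`` with the
    requested coefficient of variation.
    """
    if t_half <= 0:
        raise ValueError("t_half must be > 0")
    if n_events_per_timepoint < 1:
        raise ValueError("need >= 1 event per timepoint")
    if f0 < 0 or baseline < 0:
        raise ValueError("negative intensities requested")
    rng = substream(seed, "decay")
    k = math.log(2.0) / t_half
    records: list[tuple] = []
    for t in timepoints:
        mean = baseline + (f0 - baseline) * math.exp(-k * t)
        vals = _lognormal_events(rng, mean, cv, n_events_per_timepoint)
        records.extend((construct, float(t), channel, v) for v in vals)
    return _events_frame(records)


def generate_reporter_events(
    activity_profile: Mapping[float, float],
    f0: float,
    cv: float = 0.3,
    n_events: int = 20_000,
    seed: int = 0,
    construct: str = "UbG76V-mCh",
    channel: str = "mCh",
) -> pd.DataFrame:
    """Degron-reporter events whose mean intensity is ``f0 / activity(t)``.

    The planted relative proteasome activity must equal 1 at t=0 (the
    unstressed reference) and be strictly positive everywhere.
    """
    tps = sorted(activity_profile)
    if not tps or tps[0] != 0:
        raise ValueError("activity profile must include t=0")
    if activity_profile[tps[0]] != 1:
        raise ValueError("activity at t=0 must equal 1")
    if any(activity_profile[t] <= 0 for t in tps):
        raise ValueError("activity values must be > 0")
    rng = substream(seed, "reporter")
    records: list[tuple] = []
    for t in tps:
        mean = f0 / activity_profile[t]
        vals = _lognormal_events(rng, mean, cv, n_events)
        records.extend((construct, float(t), channel, v) for v in vals)
    return _events_frame(records)


def generate_cellcycle_events(
    phase_fractions: Sequence[float] = (0.5, 0.2, 0.2, 0.1),
    dna_peaks: tuple[float, float, float] = (100.0, 200.0, 0.05),
    edu_levels: tuple[float, float, float] = (10.0, 1000.0, 0.05),
    n_events: int = 50_000,
    seed: int = 0,
    construct: str = "NucDD",
    genotype: str = "p53wt",
    duration_min: float = 0.0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Bivariate DNA/EdU event cloud with known phase labels.

    G1 sits at the 2N DNA peak (EdU-negative), G2/M at the 4N peak
    (EdU-negative); S-phase events are EdU-positive with DNA content uniform
    over the lower (early S) or upper (late S) half of the 2N-4N interval.
    Event counts per phase are multinomial over ``phase_fractions``
    (order G1, early S, late S, G2/M).
    """
    frac = np.asarray(phase_fractions, dtype=float)
    if frac.shape != (4,) or np.any(frac < 0) or np.any(frac > 1):
        raise ValueError("phase_fractions must be 4 values in [0, 1]")
    if abs(frac.sum() - 1.0) > 1e-9:
        raise ValueError("phase fractions must sum to 1")
    mu_2n, mu_4n, dna_cv = dna_peaks
    mu_neg, mu_pos, edu_cv = edu_levels
    if not (0 < mu_2n < mu_4n):
        raise ValueError("require 0 < mu_2N < mu_4N")
    if not (0 < mu_neg < mu_pos):
        raise ValueError("require 0 < mu_neg < mu_pos")

    rng = substream(seed, "cellcycle")
    counts = rng.multinomial(n_events, frac)
    mid = (mu_2n + mu_4n) / 2.0

    dna_parts, edu_parts, labels = [], [], []
    for phase, n in zip(CELL_CYCLE_PHASES, counts):
        if n == 0:
            continue
        if phase == "G1":
            dna = _lognormal_events(rng, mu_2n, dna_cv, n)
            edu = _lognormal_events(rng, mu_neg, edu_cv, n)
        elif phase == "early_S":
            dna = rng.uniform(mu_2n, mid, size=n) * _lognormal_events(rng, 1.0, dna_cv, n)
            edu = _lognormal_events(rng, mu_pos, edu_cv, n)
        elif phase == "late_S":
            dna = rng.uniform(mid, mu_4n, size=n) * _lognormal_events(rng, 1.0, dna_cv, n)
            edu = _lognormal_events(rng, mu_pos, edu_cv, n)
        else:  # G2M
            dna = _lognormal_events(rng, mu_4n, dna_cv, n)
            edu = _lognormal_events(rng, mu_neg, edu_cv, n)
        dna_parts.append(dna)
        edu_parts.append(edu)
        labels.extend([phase] * n)

    events = pd.DataFrame(
        {
            "event_id": np.arange(n_events),
            "dna": np.concatenate(dna_parts),
            "edu": np.concatenate(edu_parts),
            "construct": construct,
            "genotype": genotype,
            "duration_min": float(duration_min),
        }
    )
    truth = pd.Series(labels, name="truth_phase")
    return events, truth
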