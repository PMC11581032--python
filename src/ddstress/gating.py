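"""Automated cell-cycle gating from DNA-content and EdU intensities.

A one-hour EdU pulse marks replicating (S-phase) cells; total DNA stain
separates 2N (G1) from 4N (G2/M) content.  Gates are derived from the data
itself: a two-component mixture on linear DNA locates the 2N and 4N peaks, a
two-component mixture on log EdU yields the positivity threshold at equal
posterior probability, and phases follow from the standard box scheme —
EdU-negative cells inside the 2N (G1) or 4N (G2/M) window, EdU-positive
cells split into early/late S at the 2N-4N midpoint.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from sklearn.mixture import GaussianMixture

from .simulate import CELL_CYCLE_PHASES

PHASE_LABELS = CELL_CYCLE_PHASES + ("unassigned",)


class GatingError(ValueError):
    pass


@dataclass
class GateModel:
    """Fitted gate geometry.

    DNA windows are peak +/- ``n_sigma`` component widths; the S-phase split
    sits at the arithmetic 2N-4N midpoint; ``edu_threshold`` is on the
    original (linear) intensity scale.
    """

    mu_2n: float
    sigma_2n: float
    mu_4n: float
    sigma_4n: float
    w_2n: float
    w_4n: float
    edu_threshold: float
    n_sigma: float = 2.5

    @property
    def midpoint(self) -> float:
        return (self.mu_2n + self.mu_4n) / 2.0

    @property
    def g1_window(self) -> tuple[float, float]:
        return (self.mu_2n - self.n_sigma * self.sigma_2n,
                self.mu_2n + self.n_sigma * self.sigma_2n)

    @property
    def g2m_window(self) -> tuple[float, float]:
        return (self.mu_4n - self.n_sigma * self.sigma_4n,
                self.mu_4n + self.n_sigma * self.sigma_4n)


@dataclass
class PhaseFractions:
    fractions: dict[str, float]
    counts: dict[str, int]
    n_events: int

    def as_series(self) -> pd.Series:
        return pd.Series(self.fractions, name="fraction")


def _fit_two_gaussians(x: np.ndarray, init_means: np.ndarray) -> GaussianMixture:
    gm = GaussianMixture(
        n_components=2,
        covariance_type="full",
        means_init=init_means.reshape(-1, 1),
        random_state=0,
        max_iter=500,
        n_init=1,
        reg_covar=1e-10 * max(float(np.var(x)), 1e-12),
    )
    gm.fit(x.reshape(-1, 1))
    if not gm.converged_:
        raise GatingError("mixture fit did not converge")
    return gm


def _equal_posterior_threshold(gm: GaussianMixture) -> float:
    """Point between the two component means where posteriors are equal."""
    means = gm.means_.ravel()
    order = np.argsort(means)
    lo, hi = means[order]
    sds = np.sqrt(gm.covariances_.reshape(-1))[order]
    ws = gm.weights_[order]

    def diff(x):
        l1 = np.log(ws[0]) - 0.5 * ((x - lo) / sds[0]) ** 2 - np.log(sds[0])
        l2 = np.log(ws[1]) - 0.5 * ((x - hi) / sds[1]) ** 2 - np.log(sds[1])
        return l1 - l2

    if diff(lo) * diff(hi) < 0:
        return float(optimize.brentq(diff, lo, hi))
    return float((lo + hi) / 2.0)


def fit_gates(events: pd.DataFrame, n_sigma: float = 2.5, min_events: int = 1000) -> GateModel:
    """Fit the gate model from event DNA/EdU intensities.

    The EdU positivity threshold is fit first (two-component mixture on log
    EdU, cut at equal posterior); the DNA mixture is then fit on the
    EdU-negative events only, so that S-phase cells — whose DNA content fills
    the 2N-4N interval — do not drag the peak estimates inward.  The DNA
    mixture is initialized at (m, 2m) with m a low-quartile location,
    encoding the expectation that the 4N peak sits at twice the 2N content.
    If the fitted components are not consistent with DNA doubling (peak ratio
    < 1.5) the data are treated as single-peaked: the 4N peak is placed at
    twice the 2N estimate and its weight reported from the upper tail, with a
    warning (degenerate but usable, e.g. an all-G1 sample).
    """
    if len(events) < min_events:
        raise GatingError(f"need >= {min_events} events to fit gates, got {len(events)}")
    dna = events["dna"].to_numpy(dtype=float)
    edu = events["edu"].to_numpy(dtype=float)
    if np.any(dna < 0) or np.any(edu < 0):
        raise GatingError("negative intensities in events")

    log_edu = np.log(np.clip(edu, 1e-12, None))
    q25, q75 = np.percentile(log_edu, [25, 75])
    gm_edu = _fit_two_gaussians(log_edu, np.array([q25, q75]))
    e_means = np.sort(gm_edu.means_.ravel())
    edu_separable = e_means[1] - e_means[0] >= 0.5
    if edu_separable:
        thr = float(np.exp(_equal_posterior_threshold(gm_edu)))
        if not (np.exp(e_means[0]) <= thr <= np.exp(e_means[1])):
            raise GatingError("EdU threshold fell outside the component means")
    else:
        # no separable EdU-positive population: threshold above the cloud
        thr = float(np.exp(log_edu.mean() + 3.0 * log_edu.std()))
        warnings.warn("EdU distribution has no separable positive population", stacklevel=2)

    dna_neg = dna[edu <= thr]
    if dna_neg.size < max(200, min_events // 10):
        dna_neg = dna  # nearly everything cycling: fall back to all events

    m0 = float(np.percentile(dna_neg, 25))
    gm_dna = _fit_two_gaussians(dna_neg, np.array([m0, 2.0 * m0]))
    means = gm_dna.means_.ravel()
    order = np.argsort(means)
    mu_lo, mu_hi = means[order]
    sd_lo, sd_hi = np.sqrt(gm_dna.covariances_.reshape(-1))[order]
    w_lo, w_hi = gm_dna.weights_[order]
    if mu_hi <= 0:
        raise GatingError(f"DNA peak order violation: mu_4N={mu_hi:.3g}")

    if mu_lo <= 0 or mu_hi / mu_lo < 1.5:
        # single dominant peak; synthesize the 4N gate at doubled content
        mu_2n = float(np.median(dna_neg))
        sigma_2n = float(1.4826 * np.median(np.abs(dna_neg - mu_2n)))
        mu_4n = 2.0 * mu_2n
        sigma_4n = 2.0 * sigma_2n
        w_4n = float(np.mean(dna_neg > 1.5 * mu_2n))
        warnings.warn(
            "DNA distribution is effectively single-peaked; 4N gate placed at "
            f"2x the 2N peak (4N weight {w_4n:.3f})",
            stacklevel=2,
        )
        w_2n = 1.0 - w_4n
    else:
        mu_2n, sigma_2n, w_2n = float(mu_lo), float(sd_lo), float(w_lo)
        mu_4n, sigma_4n, w_4n = float(mu_hi), float(sd_hi), float(w_hi)
        if w_4n < 0.05:
            warnings.warn(f"4N component weight is small ({w_4n:.3f})", stacklevel=2)

    return GateModel(
        mu_2n=mu_2n, sigma_2n=sigma_2n, mu_4n=mu_4n, sigma_4n=sigma_4n,
        w_2n=w_2n, w_4n=w_4n, edu_threshold=thr, n_sigma=n_sigma,
    )


def assign_phases(events: pd.DataFrame, model: GateModel) -> pd.Series:
    """Per-event phase labels under the box-gate scheme.

    EdU-positive events are S phase, split early/late at the DNA midpoint
    (events exactly at the midpoint are late S); EdU-negative events must
    fall in the G1 or G2/M DNA window, otherwise they are unassigned.
    """
    dna = events["dna"].to_numpy(dtype=float)
    edu = events["edu"].to_numpy(dtype=float)
    edu_pos = edu > model.edu_threshold
    g1_lo, g1_hi = model.g1_window
    g2_lo, g2_hi = model.g2m_window
    labels = np.full(len(events), "unassigned", dtype=object)
    labels[edu_pos & (dna < model.midpoint)] = "early_S"
    labels[edu_pos & (dna >= model.midpoint)] = "late_S"
    in_g1 = ~edu_pos & (dna >= g1_lo) & (dna <= g1_hi)
    in_g2m = ~edu_pos & (dna >= g2_lo) & (dna <= g2_hi)
    # if the windows overlap, the nearer peak wins
    both = in_g1 & in_g2m
    labels[in_g1 & ~both] = "G1"
    labels[in_g2m & ~both] = "G2M"
    if both.any():
        nearer_g1 = np.abs(dna - model.mu_2n) <= np.abs(dna - model.mu_4n)
        labels[both & nearer_g1] = "G1"
        labels[both & ~nearer_g1] = "G2M"
    return pd.Series(labels, index=events.index, name="phase")


def phase_fractions(labels: pd.Series) -> PhaseFractions:
    if len(labels) == 0:
        raise GatingError("no labeled events")
    counts = {p: int((labels == p).sum()) for p in PHASE_LABELS}
    n = len(labels)
    return PhaseFractions(
        fractions={p: c / n for p, c in counts.items()},
        counts=counts,
        n_events=n,
    )


def fractions_table(per_sample: dict[str, tuple[PhaseFractions, dict]]) -> pd.DataFrame:
    """Tidy per-sample phase-fraction table.

    ``per_sample`` maps sample id to (fractions, annotations) where the
    annotations carry construct/genotype/duration_min.
    """
    rows = []
    for sample_id, (pf, ann) in per_sample.items():
        for phase, frac in pf.fractions.items():
            rows.append({"sample_id": sample_id, **ann, "phase": phase, "fraction": frac})
    return pd.DataFrame(rows)


def compare_conditions(
    table: pd.DataFrame, grouping: tuple[str, ...] = ("construct", "duration_min")
) -> pd.DataFrame:
    """Group-mean phase fractions with differences against the 0-min group.

    Emits per (group, phase): mean fraction, n samples, and — when
    ``duration_min`` is part of the grouping — the difference to the matched
    0-min group (same values of the remaining keys).
    """
    for key in grouping:
        if key not in table.columns:
            raise GatingError(f"unknown grouping key {key!r}")
    agg = (
        table.groupby([*grouping, "phase"], sort=True)["fraction"]
        .agg(["mean", "count"])
        .reset_index()
        .rename(columns={"mean": "mean_fraction", "count": "n_samples"})
    )
    if "duration_min" in grouping:
        others = [k for k in grouping if k != "duration_min"]
        base = agg[agg["duration_min"] == 0]
        key_cols = [*others, "phase"]
        base_map = base.set_index(key_cols)["mean_fraction"]
        idx = pd.MultiIndex.from_frame(agg[key_cols]) if len(key_cols) > 1 else agg[key_cols[0]]
        agg["delta_vs_0min"] = agg["mean_fraction"].to_numpy() - base_map.reindex(idx).to_numpy()
    return agg
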