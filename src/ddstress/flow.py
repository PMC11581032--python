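"""Degradation kinetics and proteasome-activity readouts from flow events.

A destabilizing-domain (DD) fusion is degraded after ligand withdrawal; its
mean fluorescence over time follows first-order decay and its half-life is
the headline kinetic readout.  Proteasome activity is quantified as the
inverse of degron-reporter fluorescence relative to the unstressed (0 min)
state: A(t) = F(0)/F(t), so accumulating reporter (rising F) reads out as
falling activity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize


@dataclass
class MeanFluorescenceSeries:
    construct: str
    channel: str
    timepoints: np.ndarray  # minutes, strictly increasing, first = 0
    mean: np.ndarray  # arithmetic mean intensity per timepoint (au)
    n_events: np.ndarray

    def __post_init__(self) -> None:
        self.timepoints = np.asarray(self.timepoints, dtype=float)
        self.mean = np.asarray(self.mean, dtype=float)
        self.n_events = np.asarray(self.n_events, dtype=int)
        if self.timepoints[0] != 0 or np.any(np.diff(self.timepoints) <= 0):
            raise ValueError("timepoints must start at 0 and increase strictly")
        if np.any(self.mean <= 0):
            raise ValueError("mean fluorescence must be positive")


@dataclass
class DecayFit:
    """First-order decay fit F(t) = baseline + (f0 - baseline) exp(-k t)."""

    f0: float
    baseline: float
    k: float  # per minute; > 0 on success
    t_half: float  # ln2 / k
    residual_norm: float
    converged: bool
    message: str = ""


@dataclass
class ActivitySeries:
    """Relative proteasome activity A(t) = F(0)/F(t); A(0) = 1 exactly."""

    reporter: str
    timepoints: np.ndarray
    activity: np.ndarray


class FlowError(ValueError):
    pass


def summarize_flow(
    dataset: pd.DataFrame,
    construct: str,
    channel: str,
    min_events: int = 1000,
) -> MeanFluorescenceSeries:
    """Arithmetic mean intensity per timepoint for one (construct, channel).

    Raises :class:`FlowError` naming the offending timepoint when a group is
    missing or smaller than ``min_events``.
    """
    sub = dataset[(dataset["construct"] == construct) & (dataset["channel"] == channel)]
    if sub.empty:
        raise FlowError(f"no events for construct={construct!r} channel={channel!r}")
    tps, means, ns = [], [], []
    for t, grp in sub.groupby("timepoint_min", sort=True):
        if len(grp) < min_events:
            raise FlowError(
                f"timepoint {t} min has {len(grp)} events (< min_events={min_events})"
            )
        tps.append(float(t))
        means.append(float(grp["intensity"].mean()))
        ns.append(len(grp))
    return MeanFluorescenceSeries(construct, channel, np.array(tps), np.array(means), np.array(ns))


def fit_first_order_decay(
    series: MeanFluorescenceSeries, fit_baseline: bool = True
) -> DecayFit:
    """Least-squares first-order decay fit of a mean-fluorescence series.

    An additive baseline is fit by default because decaying reporters
    typically level off at a dark-cell floor; disable with
    ``fit_baseline=False`` to force decay to zero.  A non-decreasing series
    has no positive decay rate and returns ``converged=False``.
    """
    t = series.timepoints
    f = series.mean
    if len(t) < 4:
        raise FlowError("need >= 4 timepoints for a decay fit")
    if f[-1] >= f[0]:
        return DecayFit(
            f0=float(f[0]), baseline=float(f.min()), k=float("nan"),
            t_half=float("nan"), residual_norm=float("nan"), converged=False,
            message="series is not decreasing; first-order decay not applicable",
        )

    # init from a log-linear regression of (F - floor) on t
    floor0 = 0.9 * f.min() if fit_baseline else 0.0
    resid0 = np.clip(f - floor0, 1e-12 * f[0], None)
    slope, intercept = np.polyfit(t, np.log(resid0), 1)
    k0 = max(-slope, 1e-6)
    f00 = float(np.exp(intercept) + floor0)

    if fit_baseline:
        def model(tt, f0, baseline, k):
            return baseline + (f0 - baseline) * np.exp(-k * tt)

        p0 = [f00, floor0, k0]
        bounds = ([0.0, 0.0, 1e-9], [np.inf, np.inf, np.inf])
    else:
        def model(tt, f0, k):
            return f0 * np.exp(-k * tt)

        p0 = [f00, k0]
        bounds = ([0.0, 1e-9], [np.inf, np.inf])

    try:
        popt, _ = optimize.curve_fit(
            model, t, f, p0=p0, bounds=bounds, xtol=1e-8, ftol=1e-10, maxfev=20000
        )
    except (RuntimeError, optimize.OptimizeWarning) as exc:  # pragma: no cover - rare
        return DecayFit(
            f0=float(f[0]), baseline=0.0, k=float("nan"), t_half=float("nan"),
            residual_norm=float("nan"), converged=False, message=str(exc),
        )
    if fit_baseline:
        f0_hat, baseline_hat, k_hat = popt
    else:
        (f0_hat, k_hat), baseline_hat = popt, 0.0
    resid = f - model(t, *popt)
    return DecayFit(
        f0=float(f0_hat),
        baseline=float(baseline_hat),
        k=float(k_hat),
        t_half=math.log(2.0) / float(k_hat),
        residual_norm=float(np.linalg.norm(resid)),
        converged=True,
    )


def proteasome_activity(series: MeanFluorescenceSeries, reporter: str | None = None) -> ActivitySeries:
    """Relative proteasome activity A(t) = F(0)/F(t) (A(0) = 1 exactly)."""
    f = series.mean
    if f[0] <= 0:
        raise FlowError("F(0) must be positive")
    if np.any(f == 0):
        raise FlowError("zero fluorescence encountered; activity undefined")
    a = f[0] / f
    a[0] = 1.0  # exact by definition
    return ActivitySeries(
        reporter=reporter or series.construct,
        timepoints=series.timepoints.copy(),
        activity=a,
    )


_COMPARTMENT_KEYS = (("nuc", "nuclear"), ("cyto", "cytosolic"))


def _compartment(label: str) -> str:
    low = label.lower()
    for key, name in _COMPARTMENT_KEYS:
        if key in low:
            return name
    return "global"


def compare_compartment_activity(
    activity_by_pair: dict[tuple[str, str], ActivitySeries],
) -> pd.DataFrame:
    """Tidy per-(DD construct, reporter) comparison of activity minima.

    Emits the minimum activity and its timepoint for every pair plus a
    cis/trans flag (DD and reporter in the same vs different compartment) —
    the readout behind the observation that unfolded protein primarily
    attenuates proteasome capacity within its own compartment.
    """
    if not activity_by_pair:
        raise FlowError("no activity series supplied")
    grids = {tuple(s.timepoints) for s in activity_by_pair.values()}
    if len(grids) != 1:
        raise FlowError("all activity series must share the same timepoint grid")
    rows = []
    for (dd, reporter), series in activity_by_pair.items():
        i = int(np.argmin(series.activity))
        dd_comp, rep_comp = _compartment(dd), _compartment(reporter)
        rows.append(
            {
                "dd_construct": dd,
                "reporter": reporter,
                "dd_compartment": dd_comp,
                "reporter_compartment": rep_comp,
                "cis": dd_comp == rep_comp and dd_comp != "global",
                "min_activity": float(series.activity[i]),
                "t_min": float(series.timepoints[i]),
            }
        )
    return pd.DataFrame(rows)
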