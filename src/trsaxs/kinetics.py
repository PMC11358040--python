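"""Single-exponential kinetics of V_R and I(0) time series.

A responsive well's V_R-to-dimer trace decays toward a plateau as the
monomer pool converts; fitting V(t) = C + A exp(-k t) gives the apparent
first-order transition rate k_VR.  Rising observables (I(0), Rg) use the
mirrored model y(t) = C - A exp(-k t); time-to-95% of the plateau is 3/k.
The plateau C is a free parameter so partial converters are fit without
assuming they reach the dimer benchmark level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import DataError, FitError
from .cluster import ClusterAssignment, elbow_select_k, kmeans_cluster, kmeans_wss
from .similarity import VRTrace

__all__ = [
    "ExponentialFit",
    "fit_exponential_decay",
    "fit_exponential_rise",
    "rank_and_cluster_kvr",
]

#: below this rate (s^-1) a fitted trace is treated as non-transitioning
K_MIN_TRANSITIONING = 1e-3


@dataclass(frozen=True)
class ExponentialFit:
    label: str
    k: float              # first-order rate constant, s^-1
    amplitude: float      # A, trace units (>= 0)
    plateau: float        # C, trace units
    direction: str        # 'decay' or 'rise'
    sse: float
    k_err: float
    amplitude_err: float
    plateau_err: float
    converged: bool
    transitioning: bool

    @property
    def time_to_95(self) -> float:
        """Time to reach 95% of the total change: 3/k."""
        if self.k <= 0:
            return float("inf")
        return 3.0 / self.k


def _fit_single_exponential(times, values, sign: float, label: str, direction: str,
                            weights=None) -> ExponentialFit:
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.size < 4:
        raise DataError("need >= 4 time points for an exponential fit")
    if np.any(np.diff(t) <= 0):
        raise DataError("times must be strictly increasing")
    if not (np.all(np.isfinite(t)) and np.all(np.isfinite(v))):
        raise DataError("non-finite values in trace")

    def model(tt, k, a, c):
        return c + sign * a * np.exp(-k * tt)

    # initialization: plateau from the tail, amplitude from the total change,
    # k from log-linearizing the plateau-subtracted trace
    c0 = v[-1]
    a0 = max(sign * (v[0] - v[-1]), 1e-12)
    resid0 = sign * (v - c0)
    usable = resid0 > 0
    if np.count_nonzero(usable) >= 2:
        slope = np.polyfit(t[usable], np.log(resid0[usable]), 1)[0]
        k0 = max(-slope, K_MIN_TRANSITIONING)
    else:
        k0 = 1.0 / (t[-1] - t[0])
    sigma = None if weights is None else 1.0 / np.asarray(weights, dtype=float)
    try:
        popt, pcov = curve_fit(
            model, t, v, p0=[k0, a0, c0],
            bounds=([0.0, 0.0, -np.inf], [np.inf, np.inf, np.inf]),
            sigma=sigma, maxfev=20000,
        )
    except RuntimeError as e:
        raise FitError(f"exponential fit failed for {label!r}: {e}") from e
    k, a, c = (float(x) for x in popt)
    perr = np.sqrt(np.clip(np.diag(pcov), 0.0, np.inf))
    sse = float(np.sum((v - model(t, *popt)) ** 2))
    transitioning = bool(a >= 2.0 * perr[1] and k >= K_MIN_TRANSITIONING)
    return ExponentialFit(
        label=label, k=k, amplitude=a, plateau=c, direction=direction, sse=sse,
        k_err=float(perr[0]), amplitude_err=float(perr[1]), plateau_err=float(perr[2]),
        converged=True, transitioning=transitioning,
    )


def fit_exponential_decay(trace: VRTrace | tuple, weights=None) -> ExponentialFit:
    """Fit V(t) = C + A exp(-k t), A >= 0, k >= 0 (unweighted SSE by default)."""
    if isinstance(trace, VRTrace):
        t, v, label = trace.times, trace.values, trace.label
    else:
        t, v = trace
        label = ""
    return _fit_single_exponential(t, v, sign=+1.0, label=label, direction="decay",
                                   weights=weights)


def fit_exponential_rise(trace: VRTrace | tuple, weights=None) -> ExponentialFit:
    """Fit y(t) = C - A exp(-k t), A >= 0, k >= 0 (e.g. I(0) build-up)."""
    if isinstance(trace, VRTrace):
        t, v, label = trace.times, trace.values, trace.label
    else:
        t, v = trace
        label = ""
    return _fit_single_exponential(t, v, sign=-1.0, label=label, direction="rise",
                                   weights=weights)


def rank_and_cluster_kvr(
    fits: list[ExponentialFit], kmax: int = 6, restarts: int = 50, seed: int = 0
) -> tuple[pd.DataFrame, ClusterAssignment | None]:
    """Rank transitioning samples by k_VR and cluster the 1-D rates.

    Descending by k; ties broken by larger amplitude, then label order.
    Cluster number for the k-means step is elbow-selected from the W_k
    scan.  Non-transitioning fits are listed with rank/cluster = NA.
    """
    trans = [f for f in fits if f.transitioning]
    rest = [f for f in fits if not f.transitioning]
    if len(trans) < 2:
        rows = [
            {"label": f.label, "k_vr": f.k, "k_se": f.k_err, "A": f.amplitude,
             "C": f.plateau, "sse": f.sse, "transitioning": f.transitioning,
             "rank": pd.NA, "cluster": pd.NA}
            for f in fits
        ]
        return pd.DataFrame(rows), None
    order = sorted(trans, key=lambda f: (-f.k, -f.amplitude, f.label))
    ks = np.asarray([f.k for f in order])
    labels = [f.label for f in order]
    kmax_eff = int(min(kmax, len(order) - 1))
    if kmax_eff >= 3:
        wss = kmeans_wss(ks, kmax_eff, restarts=restarts, seed=seed)
        k_sel = elbow_select_k(wss)
    else:
        k_sel = min(2, len(order))
    assign = kmeans_cluster(ks, k_sel, restarts=restarts, seed=seed, labels=labels)
    rows = []
    for rank, f in enumerate(order, start=1):
        rows.append({"label": f.label, "k_vr": f.k, "k_se": f.k_err, "A": f.amplitude,
                     "C": f.plateau, "sse": f.sse, "transitioning": True,
                     "rank": rank, "cluster": assign.assignment[f.label]})
    for f in sorted(rest, key=lambda f: f.label):
        rows.append({"label": f.label, "k_vr": f.k, "k_se": f.k_err, "A": f.amplitude,
                     "C": f.plateau, "sse": f.sse, "transitioning": False,
                     "rank": pd.NA, "cluster": pd.NA})
    return pd.DataFrame(rows), assign
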