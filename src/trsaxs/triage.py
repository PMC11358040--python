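"""Orthogonal-assay triage: DSF thermal shifts and MST amplitudes.

Differential scanning fluorimetry (DSF) melt curves are fit with the
Boltzmann sigmoid F(T) = B + (P - B) / (1 + exp((Tm - T)/a)); ligand
effects are read as dTm against the DMSO reference mean, with hit calls
at k standard deviations of the reference spread (3 s.d. by default).
Microscale thermophoresis (MST) traces are scored as time-averaged
normalized amplitudes inside a fixed window of the infrared-excitation
phase, with the same k-sigma calling and an optional one-site binding fit
R(c) = R0 + dR * c / (Kd + c) for titrations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import DataError, FitError

__all__ = [
    "MeltCurve",
    "TmFit",
    "MstTrace",
    "BindingFit",
    "MST_PHASES",
    "fit_boltzmann_tm",
    "qc_melt_curve",
    "threshold_call",
    "mst_amplitude",
    "one_site_fit",
]

#: MST phase boundaries in seconds: equilibration, infrared excitation, recovery
MST_PHASES = {"equilibration": (0.0, 3.0), "excitation": (3.0, 23.0), "recovery": (23.0, 24.0)}


@dataclass(frozen=True)
class MeltCurve:
    temperature: np.ndarray  # deg C, strictly increasing
    fluorescence: np.ndarray
    well: str = ""
    compound: str = ""

    def __post_init__(self):
        t = np.asarray(self.temperature, dtype=float)
        f = np.asarray(self.fluorescence, dtype=float)
        object.__setattr__(self, "temperature", t)
        object.__setattr__(self, "fluorescence", f)
        if t.size < 10 or t.shape != f.shape:
            raise DataError("melt curve needs >= 10 matched (T, F) points")
        if np.any(np.diff(t) <= 0):
            raise DataError("temperatures must be strictly increasing")


@dataclass(frozen=True)
class TmFit:
    tm: float          # deg C
    slope: float       # a, deg C (> 0)
    baseline: float    # B
    plateau: float     # P
    window: tuple[float, float]
    r2: float
    tm_err: float
    determinate: bool
    qc: str = ""


@dataclass(frozen=True)
class MstTrace:
    time: np.ndarray   # s
    fluorescence: np.ndarray
    scan: int = 0

    def __post_init__(self):
        t = np.asarray(self.time, dtype=float)
        f = np.asarray(self.fluorescence, dtype=float)
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "fluorescence", f)
        if t.shape != f.shape or t.size < 10:
            raise DataError("MST trace needs matched time/fluorescence arrays")


@dataclass(frozen=True)
class BindingFit:
    kd: float
    r0: float
    dr: float
    kd_err: float
    dr_err: float
    determinate: bool


def _boltzmann(T, tm, a, B, P):
    z = np.clip((tm - T) / a, -700.0, 700.0)
    return B + (P - B) / (1.0 + np.exp(z))


def fit_boltzmann_tm(melt: MeltCurve) -> TmFit:
    """Boltzmann Tm fit on the window up to the global maximum + 2 deg C.

    SYPRO-type dyes lose signal after the unfolding peak, so the post-peak
    decay is excluded before fitting.  Indeterminate when the curve shows
    no significant sigmoidal rise.
    """
    T, F = melt.temperature, melt.fluorescence
    i_max = int(np.argmax(F))
    t_hi = T[i_max] + 2.0
    mask = T <= t_hi
    Tw, Fw = T[mask], F[mask]
    window = (float(Tw[0]), float(Tw[-1]))
    span = float(Fw.max() - Fw.min())
    if Tw.size < 6 or span <= 0 or i_max == 0:
        return TmFit(np.nan, np.nan, np.nan, np.nan, window, 0.0, np.nan,
                     determinate=False, qc="no sigmoidal rise")
    p0 = [Tw[int(np.argmin(np.abs(Fw - (Fw.min() + span / 2))))], 1.5, Fw.min(), Fw.max()]
    try:
        popt, pcov = curve_fit(
            _boltzmann, Tw, Fw, p0=p0,
            bounds=([Tw[0] - 20, 1e-3, -np.inf, -np.inf], [Tw[-1] + 20, 50.0, np.inf, np.inf]),
            maxfev=20000,
        )
    except RuntimeError:
        return TmFit(np.nan, np.nan, np.nan, np.nan, window, 0.0, np.nan,
                     determinate=False, qc="fit did not converge")
    tm, a, B, P = (float(x) for x in popt)
    perr = np.sqrt(np.clip(np.diag(pcov), 0, np.inf))
    resid = Fw - _boltzmann(Tw, *popt)
    ss_tot = float(np.sum((Fw - Fw.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    rise = P - B
    determinate = bool(rise > 0 and rise > 2.0 * np.sqrt(perr[2] ** 2 + perr[3] ** 2)
                       and window[0] <= tm <= window[1])
    return TmFit(tm=tm, slope=a, baseline=B, plateau=P, window=window, r2=r2,
                 tm_err=float(perr[0]), determinate=determinate,
                 qc="" if determinate else "no significant rise or Tm outside window")


def qc_melt_curve(melt: MeltCurve, fit: TmFit | None = None, r2_min: float = 0.95):
    """Pass/fail QC mirroring the interference/aggregation exclusions.

    Fails when the curve starts above 50% of its maximum (pre-aggregated
    or fluorescent interference), when no maximum occurs before the last
    3 points (no transition), or when the post-fit R^2 is below
    ``r2_min``.  Returns (passed, reason).
    """
    F = melt.fluorescence
    fmax = float(F.max())
    if fmax <= 0:
        return False, "non-positive fluorescence"
    if F[0] > 0.5 * fmax:
        return False, "pre-aggregated (initial fluorescence > 50% of max)"
    if int(np.argmax(F)) >= F.size - 3:
        return False, "no transition (no maximum before the last 3 points)"
    if fit is not None and (not fit.determinate or fit.r2 < r2_min):
        return False, f"poor Boltzmann fit (R^2 = {fit.r2:.3f} < {r2_min})"
    return True, "pass"


def threshold_call(
    values, reference_values, k: float = 3.0, sense: str = "two-sided", labels=None
) -> tuple[pd.DataFrame, dict]:
    """k-sigma hit calls against a reference replicate group.

    The cutoff is k times the unrounded sample SD of ``reference_values``
    about their mean.  ``sense`` is 'two-sided', 'greater' or 'less'.
    Each call is labeled elevating/lowering relative to the reference
    mean; the summary counts calls by class.
    """
    x = np.asarray(values, dtype=float)
    ref = np.asarray(reference_values, dtype=float)
    if ref.size < 2:
        raise DataError("need >= 2 reference values")
    if sense not in ("two-sided", "greater", "less"):
        raise DataError("sense must be 'two-sided', 'greater' or 'less'")
    mu = float(ref.mean())
    sd = float(ref.std(ddof=1))
    cutoff = k * sd
    delta = x - mu
    if sd == 0.0:
        if np.any(delta != 0):
            warnings.warn("reference SD is zero; every deviation is a hit", UserWarning)
        hit = delta != 0 if sense == "two-sided" else (
            delta > 0 if sense == "greater" else delta < 0)
    elif sense == "two-sided":
        hit = np.abs(delta) > cutoff
    elif sense == "greater":
        hit = delta > cutoff
    else:
        hit = -delta > cutoff
    if labels is None:
        labels = [str(i) for i in range(x.size)]
    direction = np.where(delta > 0, "elevating", np.where(delta < 0, "lowering", "none"))
    table = pd.DataFrame({
        "label": list(labels), "value": x, "delta": delta,
        "hit": hit, "direction": direction,
    })
    summary = {
        "reference_mean": mu, "reference_sd": sd, "cutoff": cutoff, "k": k, "sense": sense,
        "n_hits": int(hit.sum()),
        "n_elevating_hits": int((hit & (delta > 0)).sum()),
        "n_lowering_hits": int((hit & (delta < 0)).sum()),
    }
    return table, summary


def mst_amplitude(
    traces: list[MstTrace], window: tuple[float, float] = (4.0, 5.0)
) -> float:
    """Time-averaged normalized MST amplitude over ``window`` seconds.

    Each scan is normalized to its pre-excitation baseline mean x 1000;
    the per-scan window means of the last three consecutive scans are
    averaged to the final amplitude.  The window must lie inside the
    excitation phase.
    """
    lo, hi = window
    exc_lo, exc_hi = MST_PHASES["excitation"]
    if lo < exc_lo or hi > exc_hi:
        raise DataError(f"window {window} is outside the excitation phase {MST_PHASES['excitation']}")
    if len(traces) < 3:
        raise DataError("need >= 3 scans for amplitude averaging")
    eq_lo, eq_hi = MST_PHASES["equilibration"]
    per_scan = []
    for tr in traces[-3:]:
        base_mask = (tr.time >= eq_lo) & (tr.time < eq_hi)
        if not np.any(base_mask):
            raise DataError("scan lacks pre-excitation baseline samples")
        baseline = float(tr.fluorescence[base_mask].mean())
        if baseline <= 0:
            raise DataError("non-positive baseline fluorescence")
        win_mask = (tr.time >= lo) & (tr.time <= hi)
        if not np.any(win_mask):
            raise DataError("scan lacks samples inside the amplitude window")
        per_scan.append(float(tr.fluorescence[win_mask].mean()) / baseline * 1000.0)
    return float(np.mean(per_scan))


def one_site_fit(concentrations, responses) -> BindingFit:
    """One-site binding fit R(c) = R0 + dR * c / (Kd + c).

    Indeterminate (ND) when the span dR is not significant or the fitted
    Kd exceeds the top concentration more than tenfold (curve not
    saturating inside the titration).
    """
    c = np.asarray(concentrations, dtype=float)
    r = np.asarray(responses, dtype=float)
    if np.any(c <= 0):
        raise DataError("concentrations must be positive")
    if c.size < 6:
        raise DataError("need >= 6 titration points")
    if np.log10(c.max() / c.min()) < 2.0:
        raise DataError("titration must span >= 2 orders of magnitude")

    def model(cc, kd, r0, dr):
        return r0 + dr * cc / (kd + cc)

    order = np.argsort(c)
    p0 = [float(np.median(c)), float(r[order[0]]), float(r[order[-1]] - r[order[0]])]
    try:
        popt, pcov = curve_fit(
            model, c, r, p0=p0,
            bounds=([1e-12, -np.inf, -np.inf], [np.inf, np.inf, np.inf]),
            maxfev=20000,
        )
    except RuntimeError as e:
        raise FitError(f"one-site fit failed: {e}") from e
    kd, r0, dr = (float(x) for x in popt)
    perr = np.sqrt(np.clip(np.diag(pcov), 0, np.inf))
    determinate = bool(abs(dr) > 2.0 * perr[2] and kd <= 10.0 * c.max())
    return BindingFit(kd=kd, r0=r0, dr=dr, kd_err=float(perr[0]), dr_err=float(perr[2]),
                      determinate=determinate)
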