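"""Guinier analysis, aggregation checks, normalized Kratky transform and
Z-factor assay statistics.

The Guinier approximation ln I(q) = ln I(0) - q^2 Rg^2 / 3 holds at low q
(qmax * Rg <= ~1.3 for globular particles); fitting its linear form gives
the radius of gyration Rg and forward scattering I(0), the two per-frame
metrics the time-resolved screen tracks.  The Z-factor
Z = 1 - 3 (sigma_p + sigma_n) / |mu_p - mu_n| quantifies how well
replicate monomer and dimer controls are resolved; 0.5-1.0 marks an
assay window good enough for single-well hit calling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DataError, FitError
from .io import ScatteringCurve

__all__ = [
    "GuinierFit",
    "AssayQuality",
    "AggregationReport",
    "guinier_fit",
    "aggregation_check",
    "kratky_normalized",
    "z_factor",
]


@dataclass(frozen=True)
class GuinierFit:
    rg: float            # radius of gyration, A
    i0: float            # extrapolated zero-angle intensity, arbitrary units
    qmin: float
    qmax: float
    n_points: int
    r2: float
    qmax_rg: float
    rg_err: float
    i0_err: float

    def __post_init__(self):
        if not (self.rg > 0 and self.i0 > 0):
            raise FitError(f"non-physical Guinier result rg={self.rg}, i0={self.i0}")


@dataclass(frozen=True)
class AssayQuality:
    z: float
    mu_p: float
    mu_n: float
    sd_p: float
    sd_n: float
    metric: str = ""


@dataclass(frozen=True)
class AggregationReport:
    flagged: bool
    indeterminate: bool
    reason: str
    rg_low_half: float | None = None
    rg_high_half: float | None = None


def _wls_line(x: np.ndarray, y: np.ndarray, w: np.ndarray):
    """Weighted least squares y = a + b x; returns a, b, SE(a), SE(b), R^2."""
    W = np.sum(w)
    xm = np.sum(w * x) / W
    ym = np.sum(w * y) / W
    sxx = np.sum(w * (x - xm) ** 2)
    if sxx <= 0:
        raise FitError("degenerate abscissa in linear fit")
    b = np.sum(w * (x - xm) * (y - ym)) / sxx
    a = ym - b * xm
    resid = y - (a + b * x)
    n = x.size
    dof = max(n - 2, 1)
    s2 = np.sum(w * resid**2) / dof
    se_b = np.sqrt(s2 / sxx)
    se_a = np.sqrt(s2 * (1.0 / W + xm**2 / sxx))
    ss_tot = np.sum(w * (y - ym) ** 2)
    r2 = 1.0 - np.sum(w * resid**2) / ss_tot if ss_tot > 0 else 1.0
    return a, b, se_a, se_b, r2


def _guinier_window(curve: ScatteringCurve, qmin: float | None):
    i = curve.intensity
    q = curve.q
    pos = i > 0
    if qmin is not None:
        pos &= q >= qmin
    if not np.any(pos):
        raise DataError("no positive intensities in candidate Guinier window")
    start = int(np.argmax(pos))
    # contiguous positive block from the first usable point
    stop = start
    while stop < len(q) and pos[stop]:
        stop += 1
    return start, stop


def guinier_fit(
    curve: ScatteringCurve,
    qmax_rg_limit: float = 1.3,
    qmin: float | None = None,
    min_points: int = 5,
    max_iter: int = 100,
) -> GuinierFit:
    """Fit ln I vs q^2, shrinking the window from the high-q side until
    qmax * Rg <= ``qmax_rg_limit`` (fixed point).

    Weighted by sigma when present (sigma_lnI = sigma/I); unweighted
    otherwise.  The low-q start is the first positive-intensity point at
    or after ``qmin``.
    """
    start, stop = _guinier_window(curve, qmin)
    q = curve.q
    if stop - start < min_points:
        raise FitError(f"only {stop - start} usable points, need {min_points}")
    hi = stop
    last = None
    for _ in range(max_iter):
        qs = q[start:hi]
        ys = np.log(curve.intensity[start:hi])
        if curve.sigma is not None:
            w = (curve.intensity[start:hi] / curve.sigma[start:hi]) ** 2
        else:
            w = np.ones_like(qs)
        a, b, se_a, se_b, r2 = _wls_line(qs**2, ys, w)
        if b >= 0:
            # shrink and retry: upturned low-q data cannot give Rg
            hi -= 1
            if hi - start < min_points:
                raise FitError("no convergent Guinier window with a negative slope")
            continue
        rg = float(np.sqrt(-3.0 * b))
        qlim = qmax_rg_limit / rg
        new_hi = start + int(np.searchsorted(q[start:hi], qlim, side="right"))
        if new_hi >= hi:
            # fixed point reached
            rg_err = 3.0 * se_b / (2.0 * rg)
            i0 = float(np.exp(a))
            return GuinierFit(
                rg=rg, i0=i0, qmin=float(q[start]), qmax=float(q[hi - 1]),
                n_points=hi - start, r2=float(r2), qmax_rg=float(q[hi - 1] * rg),
                rg_err=float(rg_err), i0_err=float(i0 * se_a),
            )
        if new_hi - start < min_points:
            raise FitError(
                f"window shrank below {min_points} points before qmax*Rg <= {qmax_rg_limit}"
            )
        if last == new_hi:
            hi = new_hi - 1  # break 2-cycles by forcing one extra shrink
        else:
            hi = new_hi
        last = hi
    raise FitError("Guinier window search did not converge")


def aggregation_check(curve: ScatteringCurve, fit: GuinierFit) -> AggregationReport:
    """Flag upturned low-q behaviour inside the accepted Guinier window.

    The window is split in half and refit; aggregation is flagged when the
    low-half Rg exceeds the high-half Rg by more than 5%, or when the
    lowest-q quartile of residuals shows systematic positive curvature
    (mean > 2x residual SD).  Windows under 10 points are indeterminate.
    """
    mask = (curve.q >= fit.qmin) & (curve.q <= fit.qmax) & (curve.intensity > 0)
    q = curve.q[mask]
    y = np.log(curve.intensity[mask])
    n = q.size
    if n < 10:
        return AggregationReport(False, True, f"window of {n} points too small to split")
    w = ((curve.intensity[mask] / curve.sigma[mask]) ** 2
         if curve.sigma is not None else np.ones(n))
    half = n // 2

    def _rg(sl):
        _, b, _, _, _ = _wls_line(q[sl] ** 2, y[sl], w[sl])
        return float(np.sqrt(-3.0 * b)) if b < 0 else np.nan

    rg_lo = _rg(slice(0, half))
    rg_hi = _rg(slice(half, n))
    split_flag = np.isfinite(rg_lo) and np.isfinite(rg_hi) and rg_lo > 1.05 * rg_hi
    a, b, *_ = _wls_line(q**2, y, w)
    resid = y - (a + b * q**2)
    quart = max(n // 4, 2)
    resid_sd = float(np.std(resid, ddof=1))
    curv_flag = resid_sd > 0 and float(np.mean(resid[:quart])) > 2.0 * resid_sd
    flagged = bool(split_flag or curv_flag)
    reason = []
    if split_flag:
        reason.append(f"low-half Rg {rg_lo:.3g} > 1.05 * high-half Rg {rg_hi:.3g}")
    if curv_flag:
        reason.append("systematic positive low-q residual curvature")
    return AggregationReport(flagged, False, "; ".join(reason) or "clean",
                             rg_low_half=rg_lo, rg_high_half=rg_hi)


def kratky_normalized(curve: ScatteringCurve, fit: GuinierFit):
    """Dimensionless Kratky transform: x = q*Rg, y = (q*Rg)^2 I(q)/I(0).

    A compact globular particle peaks near (sqrt(3), 1.104); flexible or
    unfolded states plateau or rise instead.
    """
    if fit.i0 <= 0:
        raise DataError("I(0) must be positive for the normalized Kratky transform")
    x = curve.q * fit.rg
    y = x**2 * curve.intensity / fit.i0
    return x, y


def z_factor(positive_values, negative_values, metric: str = "") -> AssayQuality:
    """Z = 1 - 3 (sd_p + sd_n) / |mu_p - mu_n| with sample (n-1) SDs."""
    p = np.asarray(positive_values, dtype=float)
    n = np.asarray(negative_values, dtype=float)
    if p.size < 2 or n.size < 2:
        raise DataError("need >= 2 values per control group")
    mu_p, mu_n = float(np.mean(p)), float(np.mean(n))
    if mu_p == mu_n:
        raise DataError("Z-factor undefined: control means are equal")
    sd_p, sd_n = float(np.std(p, ddof=1)), float(np.std(n, ddof=1))
    z = 1.0 - 3.0 * (sd_p + sd_n) / abs(mu_p - mu_n)
    return AssayQuality(z=z, mu_p=mu_p, mu_n=mu_n, sd_p=sd_p, sd_n=sd_n, metric=metric)
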