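"""Replicate averaging, time-matched buffer subtraction and regridding.

Buffer wells are measured in duplicate alongside every plate; each sample
frame has its time-matched buffer frame average subtracted so that slow
drifts in background scattering cancel per frame.  No buffer scale factor
is applied by default (compound-matched buffers are assumed); a
``buffer_scale`` override exists for unmatched backgrounds.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .errors import AlignmentError, GridError, RangeError
from .io import CurveMeta, FrameSeries, ScatteringCurve

__all__ = ["average_curves", "subtract_time_matched", "regrid"]


def _require_common_grid(curves: Sequence[ScatteringCurve]) -> np.ndarray:
    q0 = curves[0].q
    for c in curves[1:]:
        if c.q.shape != q0.shape or not np.allclose(c.q, q0, rtol=1e-12, atol=0.0):
            raise GridError("curves are not on a common q grid")
    return q0


def average_curves(curves: Sequence[ScatteringCurve]) -> ScatteringCurve:
    """Pointwise mean of curves on one grid.

    Propagated sigma is sqrt(sum sigma_i^2)/n when every input carries
    sigma, otherwise the average is returned without uncertainty.
    """
    curves = list(curves)
    if not curves:
        raise ValueError("need at least one curve")
    q = _require_common_grid(curves)
    n = len(curves)
    mean_i = np.mean([c.intensity for c in curves], axis=0)
    sigma = None
    if all(c.sigma is not None for c in curves):
        sigma = np.sqrt(np.sum([c.sigma**2 for c in curves], axis=0)) / n
    meta = curves[0].meta
    return ScatteringCurve(q, mean_i, sigma, CurveMeta(label=f"avg({meta.label})", well=meta.well,
                                                       frame_index=meta.frame_index,
                                                       frame_time=meta.frame_time,
                                                       exposure=meta.exposure))


def subtract_time_matched(
    sample: FrameSeries,
    buffers: Sequence[FrameSeries],
    buffer_scale: float = 1.0,
    time_tol: float = 1e-3,
) -> FrameSeries:
    """Subtract the frame-wise buffer average from a sample series.

    Per frame t: I_sub(q, t) = I_sample(q, t) - scale * mean_b I_buffer(q, t),
    with sigmas combined in quadrature.  Frame times must agree within
    ``time_tol`` seconds (default 1 ms).
    """
    buffers = list(buffers)
    if not buffers:
        raise ValueError("need at least one buffer series")
    ts = sample.times
    for b in buffers:
        if len(b) != len(sample):
            raise AlignmentError(f"buffer {b.label!r} has {len(b)} frames, sample has {len(sample)}")
        if np.any(np.abs(b.times - ts) > time_tol):
            raise AlignmentError(f"frame times of buffer {b.label!r} deviate beyond {time_tol} s")
    out = []
    for k, frame in enumerate(sample):
        bufs = [b.frames[k] for b in buffers]
        _require_common_grid([frame, *bufs])
        bmean = average_curves(bufs)
        inten = frame.intensity - buffer_scale * bmean.intensity
        sigma = None
        if frame.sigma is not None and bmean.sigma is not None:
            sigma = np.sqrt(frame.sigma**2 + (buffer_scale * bmean.sigma) ** 2)
        out.append(ScatteringCurve(frame.q, inten, sigma, frame.meta))
    return FrameSeries(sample.label, tuple(out))


def regrid(curve: ScatteringCurve, target_grid: np.ndarray) -> ScatteringCurve:
    """Linear interpolation of I (and sigma) onto ``target_grid``.

    Interpolation is linear in (q, I) with no smoothing so the noise
    statistics feeding V_R and the fits are preserved.  Extrapolation is
    forbidden.
    """
    target = np.asarray(target_grid, dtype=float)
    if target[0] < curve.q[0] - 1e-15 or target[-1] > curve.q[-1] + 1e-15:
        raise RangeError(
            f"target grid [{target[0]:.6g}, {target[-1]:.6g}] exceeds source "
            f"range [{curve.q[0]:.6g}, {curve.q[-1]:.6g}]"
        )
    inten = np.interp(target, curve.q, curve.intensity)
    sigma = np.interp(target, curve.q, curve.sigma) if curve.sigma is not None else None
    return ScatteringCurve(target, inten, sigma, curve.meta)
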