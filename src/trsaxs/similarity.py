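"""Volatility-of-ratio (V_R) similarity, similarity matrices, time-resolved
V_R traces and replicate-derived significance envelopes.

V_R compares two scattering curves through the *shape* of their intensity
ratio: the ratio is binned over an intermediate q window (default
0.015-0.15 A^-1, 25 equal-width bins) and summed as relative first
differences,

    V_R = sum_i |R_{i+1} - R_i| / ((R_{i+1} + R_i) / 2),

where R_i is the ratio of the in-bin mean intensities.  Identical shapes
give a flat ratio and V_R = 0; V_R is invariant to uniform rescaling of
either curve and exactly symmetric in its arguments (swapping the curves
maps R -> 1/R, which leaves relative differences unchanged).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import AlignmentError, DataError, RatioError, WindowError
from .io import FrameSeries, ScatteringCurve
from .reduction import regrid

__all__ = [
    "VR_WINDOW",
    "VR_NBINS",
    "VRResult",
    "SimilarityMatrix",
    "VRTrace",
    "BenchmarkEnvelope",
    "volatility_of_ratio",
    "similarity_matrix",
    "vr_trace",
    "benchmark_envelope",
    "classify_transition",
]

#: default q window (A^-1) for V_R, covering intermediate-resolution shape
VR_WINDOW = (0.015, 0.15)
#: default number of equal-width ratio bins
VR_NBINS = 25


@dataclass(frozen=True)
class VRResult:
    value: float
    window: tuple[float, float]
    nbins: int
    label_a: str
    label_b: str


@dataclass(frozen=True)
class SimilarityMatrix:
    labels: tuple[str, ...]
    values: np.ndarray
    window: tuple[float, float]
    nbins: int

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        n = len(self.labels)
        if v.shape != (n, n):
            raise DataError("similarity matrix must be square over the labels")
        if np.any(np.abs(v - v.T) > 1e-12):
            raise DataError("similarity matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise DataError("similarity diagonal must be zero")
        if np.any(v < 0):
            raise DataError("V_R values must be non-negative")

    def row(self, label: str) -> np.ndarray:
        return self.values[self.labels.index(label)]


@dataclass(frozen=True)
class VRTrace:
    label: str
    reference: str
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)
        if t.shape != v.shape:
            raise DataError("times and values must have equal length")
        if np.any(np.diff(t) <= 0):
            raise DataError("trace times must be strictly increasing")
        if np.any(v < 0):
            raise DataError("V_R values must be non-negative")


@dataclass(frozen=True)
class BenchmarkEnvelope:
    """Replicate mean +/- k*sigma_bar significance band for one benchmark.

    sigma_bar is the per-time sample SDs averaged across the series (the
    'standard uncertainty' of the benchmark); the threshold runs at
    mean - k*sigma_bar for a departure-toward-similarity benchmark
    (sense='lower', e.g. monomer vs dimer reference) and mean + k*sigma_bar
    for an entry-into-similarity benchmark (sense='upper', dimer self-V_R).
    """

    label: str
    times: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    sigma_bar: float
    k: float
    sense: str  # 'lower' or 'upper'
    n_replicates: int

    @property
    def threshold(self) -> np.ndarray:
        sign = -1.0 if self.sense == "lower" else 1.0
        return self.mean + sign * self.k * self.sigma_bar


def _binned_means(curve: ScatteringCurve, window: tuple[float, float],
                  nbins: int) -> tuple[np.ndarray, np.ndarray]:
    lo, hi = window
    mask = (curve.q >= lo) & (curve.q <= hi)
    if not np.any(mask):
        raise WindowError("curve has no points inside the V_R window")
    q = curve.q[mask]
    i = curve.intensity[mask]
    if np.any(i <= 0):
        raise RatioError(f"non-positive intensity inside V_R window for {curve.meta.label!r}")
    # equal-width bins; the point at q == hi joins the last bin
    width = (hi - lo) / nbins
    idx = np.minimum(((q - lo) / width).astype(int), nbins - 1)
    sums = np.bincount(idx, weights=i, minlength=nbins)
    counts = np.bincount(idx, minlength=nbins)
    keep = counts > 0
    return sums[keep] / counts[keep], keep


def volatility_of_ratio(
    curve_a: ScatteringCurve,
    curve_b: ScatteringCurve,
    window: tuple[float, float] = VR_WINDOW,
    nbins: int = VR_NBINS,
) -> VRResult:
    """V_R between two curves over ``window`` with ``nbins`` ratio bins.

    Curves must cover the window; ``curve_b`` is regridded onto
    ``curve_a``'s grid when the grids differ.  Both curves must be
    strictly positive inside the window.
    """
    lo, hi = window
    for c in (curve_a, curve_b):
        if c.q[0] > lo or c.q[-1] < hi:
            raise WindowError(
                f"curve {c.meta.label!r} does not cover the window [{lo}, {hi}]"
            )
    if not curve_a.same_grid(curve_b):
        sub = curve_a.q[(curve_a.q >= lo) & (curve_a.q <= hi)]
        curve_a = regrid(curve_a, sub)
        curve_b = regrid(curve_b, sub)
    A, keep_a = _binned_means(curve_a, (lo, hi), nbins)
    B, keep_b = _binned_means(curve_b, (lo, hi), nbins)
    if not np.array_equal(keep_a, keep_b):  # identical grids => identical occupancy
        raise WindowError("bin occupancy differs between the two curves")
    if A.size < 2:
        raise WindowError(f"fewer than 2 non-empty bins in [{lo}, {hi}]")
    # summand written symmetrically in (A, B): with R_i = A_i/B_i,
    # |R2 - R1| / ((R2 + R1)/2) == 2|A2*B1 - A1*B2| / (A2*B1 + A1*B2),
    # so swapping the curves is bit-exact.
    num = 2.0 * np.abs(A[1:] * B[:-1] - A[:-1] * B[1:])
    den = A[1:] * B[:-1] + A[:-1] * B[1:]
    value = float(np.sum(num / den))
    return VRResult(value, window, nbins, curve_a.meta.label, curve_b.meta.label)


def similarity_matrix(
    labeled_curves: dict[str, ScatteringCurve] | list[tuple[str, ScatteringCurve]],
    window: tuple[float, float] = VR_WINDOW,
    nbins: int = VR_NBINS,
) -> SimilarityMatrix:
    """All pairwise V_R values; computed once per unordered pair."""
    items = list(labeled_curves.items()) if isinstance(labeled_curves, dict) else list(labeled_curves)
    if len(items) < 2:
        raise DataError("need at least 2 curves for a similarity matrix")
    labels = tuple(lbl for lbl, _ in items)
    n = len(items)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            try:
                v = volatility_of_ratio(items[i][1], items[j][1], window, nbins).value
            except (RatioError, WindowError) as e:
                raise type(e)(f"pair ({labels[i]!r}, {labels[j]!r}): {e}") from e
            m[i, j] = m[j, i] = v
    return SimilarityMatrix(labels, m, window, nbins)


def plot_ssm_heatmap(ssm: SimilarityMatrix, path, dpi: int = 150):
    """Save an SSM heat map (blue = similar/low V_R, red = dissimilar/high).

    Requires matplotlib (the ``plot`` extra).
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = len(ssm.labels)
    fig, ax = plt.subplots(figsize=(max(4, n * 0.35), max(3.5, n * 0.35)))
    im = ax.imshow(ssm.values, cmap="coolwarm", interpolation="nearest")
    ax.set_xticks(range(n), ssm.labels, rotation=90, fontsize=7)
    ax.set_yticks(range(n), ssm.labels, fontsize=7)
    fig.colorbar(im, ax=ax, label="$V_R$")
    lo, hi = ssm.window
    ax.set_title(f"SAXS similarity matrix  (q {lo}-{hi} $\\AA^{{-1}}$, {ssm.nbins} bins)",
                 fontsize=9)
    fig.tight_layout()
    fig.savefig(path, dpi=dpi)
    plt.close(fig)
    return path


def vr_trace(
    series: FrameSeries,
    reference: ScatteringCurve | FrameSeries,
    window: tuple[float, float] = VR_WINDOW,
    nbins: int = VR_NBINS,
) -> VRTrace:
    """One V_R value per frame against a fixed curve or a time-matched series."""
    if isinstance(reference, FrameSeries):
        if len(reference) != len(series):
            raise AlignmentError(
                f"time-matched reference has {len(reference)} frames, sample has {len(series)}"
            )
        refs = list(reference.frames)
        ref_label = f"{reference.label} (time-matched)"
    else:
        refs = [reference] * len(series)
        ref_label = reference.meta.label
    values = [
        volatility_of_ratio(f, r, window, nbins).value for f, r in zip(series.frames, refs)
    ]
    return VRTrace(series.label, ref_label, series.times, np.asarray(values))


def benchmark_envelope(
    replicate_traces: list[VRTrace], k: float = 3.0, sense: str = "lower", label: str = ""
) -> BenchmarkEnvelope:
    """Mean trace and k*sigma_bar significance threshold from replicates.

    Per-time sample SDs (n-1) are averaged across the series to one
    standard uncertainty sigma_bar; the threshold is the mean trace offset
    by k*sigma_bar in the benchmark's sense.
    """
    if len(replicate_traces) < 2:
        raise DataError("need >= 2 replicate traces for an envelope")
    if sense not in ("lower", "upper"):
        raise DataError("sense must be 'lower' or 'upper'")
    t0 = replicate_traces[0].times
    for tr in replicate_traces[1:]:
        if tr.times.shape != t0.shape or np.any(np.abs(tr.times - t0) > 1e-9):
            raise AlignmentError("replicate traces are not on one time grid")
    vals = np.vstack([tr.values for tr in replicate_traces])
    mean = vals.mean(axis=0)
    sd = vals.std(axis=0, ddof=1)
    sigma_bar = float(sd.mean())
    return BenchmarkEnvelope(
        label=label or replicate_traces[0].label,
        times=t0, mean=mean, sd=sd, sigma_bar=sigma_bar, k=float(k), sense=sense,
        n_replicates=len(replicate_traces),
    )


def classify_transition(
    trace: VRTrace, monomer_env: BenchmarkEnvelope, dimer_env: BenchmarkEnvelope
):
    """Label each time point of a sample V_R-to-dimer trace.

    'monomer-like'  : at or above the monomer benchmark threshold
    'significant'   : below the monomer threshold (departure from monomer)
    'dimer-entered' : at or below the dimer self-similarity threshold

    Returns (labels, summary) where summary records first crossing times
    (or 'none').
    """
    for env in (monomer_env, dimer_env):
        if env.times.shape != trace.times.shape or np.any(np.abs(env.times - trace.times) > 1e-9):
            raise AlignmentError("envelope and trace are not on one time grid")
    mono_thr = monomer_env.threshold
    dim_thr = dimer_env.threshold
    labels = []
    for v, mt, dt in zip(trace.values, mono_thr, dim_thr):
        if v <= dt:
            labels.append("dimer-entered")
        elif v < mt:
            labels.append("significant")
        else:
            labels.append("monomer-like")
    def _first(pred):
        for t, lab in zip(trace.times, labels):
            if pred(lab):
                return float(t)
        return "none"

    summary = {
        # a dimer-entered point is by construction past the monomer threshold
        "first_significant": _first(lambda lab: lab != "monomer-like"),
        "first_dimer_entered": _first(lambda lab: lab == "dimer-entered"),
    }
    return labels, summary
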