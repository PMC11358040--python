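"""Synthetic two-state dimerization screen generator.

The generator emulates the statistical structure the analysis assumes: a
monomeric particle converting to a dimer under first-order kinetics
x(t) = x_inf * (1 - exp(-k_true * t)), observed as 300-ms scattering
frames with Gaussian noise, alongside replicate monomer/dimer controls,
duplicate matched buffers, and DSF/MST responses for a planted chemotype
library.

End states are analytic: a uniform sphere of radius R (Rg = sqrt(3/5) R)
and a tangent two-sphere dimer (center spacing 2R, Rg = sqrt(8/5) R)
whose per-particle forward scattering is 4x the monomer's, so at equal
mass concentration (number density halved) I(0) doubles on full
dimerization and I(0, t)/I(0, 0) = 1 + x(t) exactly in the noiseless
limit.  The dimer is the simplest analytic shape with those properties,
not a structural model of any particular protein.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError
from .io import CurveMeta, FrameSeries, SampleSheet, ScatteringCurve, write_dat
from .triage import MeltCurve, MstTrace

__all__ = [
    "ParticleModel",
    "DimerizationKinetics",
    "FragmentEffect",
    "SimConfig",
    "TriageConfig",
    "PlateData",
    "TriageData",
    "default_library",
    "sphere_profile",
    "dimer_profile",
    "simulate_two_state_series",
    "simulate_screen_plate",
    "simulate_triage_assays",
    "draw_tm_values",
    "write_plate",
]

CHEMOTYPES = ("CX1", "CX2", "CX3", "CX4", "inactive")


def _sphere_form_factor(u: np.ndarray) -> np.ndarray:
    """P(u) = [3 (sin u - u cos u) / u^3]^2 with the u -> 0 limit handled."""
    u = np.asarray(u, dtype=float)
    small = np.abs(u) < 1e-4
    us = np.where(small, 1.0, u)
    amp = 3.0 * (np.sin(us) - us * np.cos(us)) / us**3
    amp = np.where(small, 1.0 - u**2 / 10.0, amp)
    return amp**2


def sphere_profile(q_grid, R: float, scale: float = 1.0, label: str = "monomer") -> ScatteringCurve:
    """Uniform-sphere intensity I(q) = scale * V^2 * P(qR)."""
    if R <= 0:
        raise ConfigError("sphere radius must be positive")
    q = np.asarray(q_grid, dtype=float)
    V = 4.0 / 3.0 * np.pi * R**3
    inten = scale * V**2 * _sphere_form_factor(q * R)
    return ScatteringCurve(q, inten, None, CurveMeta(label=label))


def dimer_profile(q_grid, R: float, scale: float = 1.0, label: str = "dimer") -> ScatteringCurve:
    """Orientation-averaged tangent two-sphere intensity (per particle).

    I_dim(q) = 2 * scale * V^2 * P(qR) * [1 + sin(q d)/(q d)], d = 2R.
    """
    if R <= 0:
        raise ConfigError("sphere radius must be positive")
    q = np.asarray(q_grid, dtype=float)
    V = 4.0 / 3.0 * np.pi * R**3
    d = 2.0 * R
    x = q * d
    small = np.abs(x) < 1e-8
    xs = np.where(small, 1.0, x)
    sinc = np.where(small, 1.0 - x**2 / 6.0, np.sin(xs) / xs)
    inten = 2.0 * scale * V**2 * _sphere_form_factor(q * R) * (1.0 + sinc)
    return ScatteringCurve(q, inten, None, CurveMeta(label=label))


@dataclass(frozen=True)
class ParticleModel:
    """Analytic monomer/dimer end states on a common contrast scale."""

    # 25 A keeps the sphere form-factor minimum (u = qR ~ 4.49) outside the
    # 0.015-0.15 A^-1 similarity window; real protein profiles have no deep
    # zero there, so the analytic end states should not either.
    radius: float = 25.0        # sphere radius R, A
    i0_monomer: float = 100.0   # monomer forward scattering, arbitrary units

    @property
    def rg_monomer(self) -> float:
        return float(np.sqrt(3.0 / 5.0) * self.radius)

    @property
    def rg_dimer(self) -> float:
        return float(np.sqrt(8.0 / 5.0) * self.radius)

    @property
    def scale(self) -> float:
        V = 4.0 / 3.0 * np.pi * self.radius**3
        return self.i0_monomer / V**2

    def monomer(self, q_grid) -> ScatteringCurve:
        return sphere_profile(q_grid, self.radius, self.scale, label="monomer")

    def dimer(self, q_grid) -> ScatteringCurve:
        return dimer_profile(q_grid, self.radius, self.scale, label="dimer")


@dataclass(frozen=True)
class DimerizationKinetics:
    """First-order monomer -> dimer conversion."""

    k_true: float        # s^-1
    x_inf: float = 1.0   # final converted monomer fraction

    def __post_init__(self):
        if not (0.0 <= self.x_inf <= 1.0):
            raise ConfigError(f"x_inf = {self.x_inf} outside [0, 1]")
        if self.k_true < 0:
            raise ConfigError("k_true must be >= 0")

    def x(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.x_inf * (1.0 - np.exp(-self.k_true * t))


@dataclass(frozen=True)
class FragmentEffect:
    """Planted ground truth for one library compound."""

    compound_id: str
    chemotype: str
    k_true: float
    x_inf: float
    delta_tm: float      # planted thermal shift, deg C
    mst_shift: float     # planted MST amplitude drop, response units
    kd_uM: float | None  # planted one-site Kd, None = ND

    def __post_init__(self):
        if self.chemotype not in CHEMOTYPES:
            raise ConfigError(f"unknown chemotype {self.chemotype!r}")


def default_library() -> list[FragmentEffect]:
    """The default 12-compound planted chemotype library.

    CX1 converts fully and fastest, CX2 partially at moderate rates, CX3
    weakly, CX4 not at all; thermal shifts and MST drops shadow the
    conversion strength, with one NADH-like strong Tm-lowering compound.
    """
    # (k_true, x_inf) pairs place the four chemotypes at well-separated
    # converted fractions by ~2 s (CX1 ~0.95-0.99, CX2 ~0.50-0.58,
    # CX3 ~0.16-0.22, CX4 0) so the planted groups are distinguishable in
    # similarity space the way the screen assumes distinct scaffold classes are.
    rows = [
        ("F01", "CX1", 2.00, 1.000, -10.8, 20.0, 200.0),
        ("F02", "CX1", 1.70, 1.000, -4.0, 15.0, 350.0),
        ("F03", "CX1", 1.40, 1.000, -3.5, 12.0, 500.0),
        ("F04", "CX2", 0.80, 0.713, -2.5, 10.0, 800.0),
        ("F05", "CX2", 0.60, 0.754, -2.0, 8.0, 1200.0),
        ("F06", "CX2", 0.40, 0.880, -1.5, 7.0, None),
        ("F07", "CX3", 1.20, 0.239, 1.5, 6.0, None),
        ("F08", "CX3", 1.05, 0.214, 1.2, 0.0, None),
        ("F09", "CX3", 0.90, 0.189, 1.0, 0.0, None),
        ("F10", "CX4", 0.00, 0.000, 0.0, 0.0, None),
        ("F11", "CX4", 0.00, 0.000, 0.0, 0.0, None),
        ("F12", "CX4", 0.00, 0.000, 0.0, 0.0, None),
    ]
    return [FragmentEffect(*r) for r in rows]


@dataclass(frozen=True)
class SimConfig:
    """Acquisition geometry, noise and replicate layout for a plate.

    Defaults mirror 300-ms framing over the 0.3-3.0 s analysis span on a
    q grid of 0.01-0.59 A^-1 (256 points).  ``noise`` is the Gaussian
    sigma at q = 0 in intensity units (monomer I(0) = 100); the per-point
    sigma is noise * sqrt(I/I0) with an additive noise/10 floor, i.e.
    counting-statistics-shaped relative error growing as sqrt(I0/I).
    The default keeps the ratio bins near the window's high-q edge (where
    the signal is ~2% of I(0) and this noise model is most punishing)
    quiet enough that similarity clustering and rate ranking remain
    faithful; control Z-factors then sit near the top of the usable
    0.5-1.0 band.
    """

    seed: int
    frame_times: tuple[float, ...] = tuple(np.round(np.arange(1, 11) * 0.3, 10))
    q_min: float = 0.01
    q_max: float = 0.59
    n_q: int = 256
    noise: float = 0.02
    concentration: float = 1.0
    buffer_level: float = 20.0
    n_monomer_controls: int = 2
    n_dimer_controls: int = 3
    n_buffers: int = 2
    model: ParticleModel = field(default_factory=ParticleModel)

    def __post_init__(self):
        if self.seed is None:
            raise ConfigError("a seed is mandatory")
        if self.n_monomer_controls < 2 or self.n_dimer_controls < 2 or self.n_buffers < 2:
            raise ConfigError("replicate counts < 2 make significance envelopes infeasible")
        if np.any(np.diff(self.frame_times) <= 0):
            raise ConfigError("frame times must be strictly increasing")

    @property
    def q_grid(self) -> np.ndarray:
        return np.linspace(self.q_min, self.q_max, self.n_q)


def _noisy(inten: np.ndarray, i0: float, noise: float, rng) -> tuple[np.ndarray, np.ndarray]:
    sigma = noise * np.sqrt(np.clip(inten, 0.0, None) / i0) + noise / 10.0
    return inten + rng.normal(0.0, sigma), sigma


def simulate_two_state_series(
    model: ParticleModel,
    kinetics: DimerizationKinetics,
    config: SimConfig,
    label: str = "sample",
    well: str = "",
    rng: np.random.Generator | None = None,
    noisy: bool = True,
    include_buffer: bool = False,
) -> FrameSeries:
    """Frame series of the number-weighted two-state mixture.

    Per frame t: I(q, t) = c * [(1 - x(t)) I_mon(q) + (x(t)/2) I_dim(q)],
    so I(0, t)/I(0, 0) = 1 + x(t).  Noise follows the SimConfig model and
    is written to the sigma column; ``include_buffer`` adds the flat
    buffer background (for raw, unsubtracted wells).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    q = config.q_grid
    imon = model.monomer(q).intensity
    idim = model.dimer(q).intensity
    frames = []
    for i, t in enumerate(config.frame_times):
        x = float(kinetics.x(t))
        inten = config.concentration * ((1.0 - x) * imon + (x / 2.0) * idim)
        i0 = config.concentration * model.i0_monomer * (1.0 + x)
        if noisy:
            inten, sigma = _noisy(inten, i0, config.noise, rng)
        else:
            sigma = None
        if include_buffer:
            inten = inten + config.buffer_level
        frames.append(ScatteringCurve(
            q, inten, sigma,
            CurveMeta(label=label, well=well, frame_index=i, frame_time=float(t),
                      exposure=float(config.frame_times[0])),
        ))
    return FrameSeries(label=label, frames=tuple(frames))


def _static_series(config, intensity_fn, label, well, rng, i0_ref, noisy=True,
                   include_buffer=True) -> FrameSeries:
    q = config.q_grid
    base = intensity_fn(q)
    frames = []
    for i, t in enumerate(config.frame_times):
        inten = base.copy()
        if noisy:
            inten, sigma = _noisy(inten, i0_ref, config.noise, rng)
        else:
            sigma = None
        if include_buffer:
            inten = inten + config.buffer_level
        frames.append(ScatteringCurve(
            q, inten, sigma,
            CurveMeta(label=label, well=well, frame_index=i, frame_time=float(t),
                      exposure=float(config.frame_times[0])),
        ))
    return FrameSeries(label=label, frames=tuple(frames))


@dataclass(frozen=True)
class PlateData:
    sheet: SampleSheet
    series: dict[str, FrameSeries]   # well -> raw (buffer-containing) series
    truth: pd.DataFrame


def simulate_screen_plate(
    library: Sequence[FragmentEffect] | None = None,
    config: SimConfig | None = None,
    seed: int | None = None,
) -> PlateData:
    """One synthetic 96-well screen plate with planted ground truth.

    Produces one raw series per compound, duplicate monomer controls,
    triplicate dimer controls and duplicate matched buffer wells, all on
    one seeded noise stream, plus the planted-truth table.
    """
    if library is None:
        library = default_library()
    if not library:
        raise ConfigError("library must be non-empty")
    if config is None:
        if seed is None:
            raise ConfigError("provide a SimConfig or a seed")
        config = SimConfig(seed=seed)
    elif seed is not None:
        config = replace(config, seed=seed)
    rng = np.random.default_rng(config.seed)
    model = config.model
    series: dict[str, FrameSeries] = {}
    rows = []

    def _well(prefix, i):
        return f"{prefix}{i + 1}"

    for i, frag in enumerate(library):
        well = _well("A", i)
        kin = DimerizationKinetics(frag.k_true, frag.x_inf)
        series[well] = simulate_two_state_series(
            model, kin, config, label=frag.compound_id, well=well, rng=rng,
            include_buffer=True,
        )
        rows.append({"well": well, "role": "sample", "compound_id": frag.compound_id,
                     "conc_mM": 1.0, "replicate": 1,
                     "path_pattern": f"{well}_{{frame}}.dat"})
    for i in range(config.n_monomer_controls):
        well = _well("M", i)
        series[well] = _static_series(
            config, lambda q: config.concentration * model.monomer(q).intensity,
            label=f"monomer-control-{i + 1}", well=well, rng=rng,
            i0_ref=config.concentration * model.i0_monomer,
        )
        rows.append({"well": well, "role": "monomer-control", "compound_id": "DMSO",
                     "conc_mM": 0.0, "replicate": i + 1,
                     "path_pattern": f"{well}_{{frame}}.dat"})
    for i in range(config.n_dimer_controls):
        well = _well("D", i)
        series[well] = _static_series(
            config, lambda q: config.concentration * 0.5 * model.dimer(q).intensity,
            label=f"dimer-control-{i + 1}", well=well, rng=rng,
            i0_ref=config.concentration * 2.0 * model.i0_monomer,
        )
        rows.append({"well": well, "role": "dimer-control", "compound_id": "NADH-DMSO",
                     "conc_mM": 0.0, "replicate": i + 1,
                     "path_pattern": f"{well}_{{frame}}.dat"})
    for i in range(config.n_buffers):
        well = _well("B", i)
        series[well] = _static_series(
            config, lambda q: np.zeros_like(q),
            label=f"buffer-{i + 1}", well=well, rng=rng,
            i0_ref=config.concentration * model.i0_monomer,
        )
        rows.append({"well": well, "role": "buffer", "compound_id": "buffer",
                     "conc_mM": 0.0, "replicate": i + 1,
                     "path_pattern": f"{well}_{{frame}}.dat"})
    sheet = SampleSheet(pd.DataFrame(rows))
    truth = pd.DataFrame([
        {"compound_id": f.compound_id, "well": _well("A", i), "chemotype": f.chemotype,
         "k_true": f.k_true, "x_inf": f.x_inf, "delta_tm": f.delta_tm,
         "mst_shift": f.mst_shift, "kd_uM": f.kd_uM}
        for i, f in enumerate(library)
    ])
    return PlateData(sheet=sheet, series=series, truth=truth)


def write_plate(plate: PlateData, out_dir: str | Path) -> Path:
    """Write a plate as manifest.csv + per-well per-frame .dat files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for well, ser in plate.series.items():
        for i, frame in enumerate(ser.frames):
            write_dat(frame, out / f"{well}_{i}.dat")
    plate.sheet.table.to_csv(out / "manifest.csv", index=False)
    plate.truth.to_csv(out / "truth.csv", index=False)
    return out / "manifest.csv"


# --------------------------------------------------------------------------
# DSF / MST triage assays


@dataclass(frozen=True)
class TriageConfig:
    """Planted DSF/MST assay conditions.

    DSF: screen-wide reference Tm with per-curve Tm jitter sigma_tm and a
    planted pathological-curve fraction (interference/aggregation-like
    shapes that fail QC).  MST: normalized reference amplitude level with
    per-scan jitter scaled to a reference spread near 1.4 response units.
    """

    seed: int
    tm_reference: float = 65.6       # deg C
    tm_sigma: float = 0.15           # per-curve Tm jitter, deg C
    tm_slope: float = 1.5            # Boltzmann slope a, deg C
    n_reference_melts: int = 216
    pathological_fraction: float = 0.23
    melt_noise: float = 0.008        # fluorescence noise, fraction of span
    t_grid: tuple[float, float, float] = (25.0, 99.0, 1.0)
    mst_level: float = 0.9563        # excitation-phase level / baseline
    mst_scan_sigma: float = 0.0024   # per-scan level jitter
    mst_point_sigma: float = 0.0006
    n_reference_mst: int = 4


@dataclass(frozen=True)
class TriageData:
    melts: dict[str, MeltCurve]            # compound -> melt curve
    reference_melts: list[MeltCurve]
    mst: dict[str, list[MstTrace]]         # compound -> 3 scans
    reference_mst: list[list[MstTrace]]
    truth: pd.DataFrame                    # compound, delta_tm, mst_shift, pathological


def draw_tm_values(rng: np.random.Generator, n: int, delta_tm: float,
                   config: TriageConfig) -> np.ndarray:
    """Sample the planted melt-curve midpoints (reference Tm + shift + jitter)."""
    return config.tm_reference + delta_tm + rng.normal(0.0, config.tm_sigma, size=n)


def _melt_curve(rng, tm, config: TriageConfig, compound="", pathological=None) -> MeltCurve:
    lo, hi, step = config.t_grid
    T = np.arange(lo, hi + step / 2, step)
    if pathological == "pre-aggregated":
        F = 0.95 + rng.normal(0.0, 0.01, T.size)
    elif pathological == "no-transition":
        F = 0.05 + 0.9 / (1.0 + np.exp((hi + 5.0 - T) / 4.0)) + rng.normal(0.0, 0.005, T.size)
    else:
        sig = 0.05 + 0.95 / (1.0 + np.exp((tm - T) / config.tm_slope))
        decay = np.exp(-np.clip(T - (tm + 6.0), 0.0, None) / 15.0)
        F = sig * decay + rng.normal(0.0, config.melt_noise, T.size)
    return MeltCurve(T, F, compound=compound)


def _mst_scans(rng, level: float, config: TriageConfig) -> list[MstTrace]:
    t = np.arange(0.0, 24.0 + 1e-9, 0.1)
    scans = []
    for s in range(3):
        lv = level + rng.normal(0.0, config.mst_scan_sigma)
        F = np.ones_like(t)
        exc = (t >= 3.0) & (t < 23.0)
        F[exc] = lv + (1.0 - lv) * np.exp(-(t[exc] - 3.0) / 0.2)
        rec = t >= 23.0
        F[rec] = lv + (1.0 - lv) * (1.0 - np.exp(-(t[rec] - 23.0) / 0.3))
        F = F + rng.normal(0.0, config.mst_point_sigma, t.size)
        scans.append(MstTrace(t, F, scan=s))
    return scans


def simulate_triage_assays(
    library: Sequence[FragmentEffect] | None = None,
    config: TriageConfig | None = None,
    seed: int | None = None,
) -> TriageData:
    """Seeded DSF melt curves and MST scans for a planted library.

    A ``pathological_fraction`` of compound melt curves (count rounded to
    the nearest integer) is planted with interference/aggregation shapes
    that must fail melt-curve QC; the truth table records which.
    """
    if library is None:
        library = default_library()
    if not library:
        raise ConfigError("library must be non-empty")
    if config is None:
        if seed is None:
            raise ConfigError("provide a TriageConfig or a seed")
        config = TriageConfig(seed=seed)
    elif seed is not None:
        config = replace(config, seed=seed)
    rng = np.random.default_rng(config.seed)
    n = len(library)
    n_path = int(round(config.pathological_fraction * n))
    path_idx = set(rng.choice(n, size=n_path, replace=False).tolist())
    path_kind = {}
    melts = {}
    mst = {}
    rows = []
    for i, frag in enumerate(library):
        kind = None
        if i in path_idx:
            kind = "pre-aggregated" if rng.random() < 0.5 else "no-transition"
            path_kind[frag.compound_id] = kind
        tm = float(draw_tm_values(rng, 1, frag.delta_tm, config)[0])
        melts[frag.compound_id] = _melt_curve(rng, tm, config, compound=frag.compound_id,
                                              pathological=kind)
        level = config.mst_level - frag.mst_shift / 1000.0
        mst[frag.compound_id] = _mst_scans(rng, level, config)
        rows.append({"compound_id": frag.compound_id, "delta_tm": frag.delta_tm,
                     "mst_shift": frag.mst_shift, "pathological": kind or ""})
    reference_melts = [
        _melt_curve(rng, float(draw_tm_values(rng, 1, 0.0, config)[0]), config,
                    compound=f"DMSO-{j + 1}")
        for j in range(config.n_reference_melts)
    ]
    reference_mst = [_mst_scans(rng, config.mst_level, config)
                     for _ in range(config.n_reference_mst)]
    truth = pd.DataFrame(rows)
    return TriageData(melts=melts, reference_melts=reference_melts, mst=mst,
                      reference_mst=reference_mst, truth=truth)
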