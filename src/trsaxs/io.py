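"""Reading and writing 1-D SAXS profiles and plate manifests.

Profiles are plain-text ``.dat`` files: ``#`` comment lines followed by
rows of ``q I(q) [sigma]`` in reciprocal angstroms and arbitrary
intensity units.  A plate manifest is a CSV assigning wells to roles
(sample / buffer / monomer-control / dimer-control), compounds and frame
file patterns, from which time-ordered :class:`FrameSeries` are built.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import AlignmentError, DataError, GridError, ParseError, SchemaError

__all__ = [
    "CurveMeta",
    "ScatteringCurve",
    "FrameSeries",
    "SampleSheet",
    "ROLES",
    "read_dat",
    "write_dat",
    "load_manifest",
]

ROLES = ("sample", "buffer", "monomer-control", "dimer-control")

#: q values above this are almost certainly nm^-1, not A^-1
_Q_UNIT_SUSPECT = 2.0


@dataclass(frozen=True)
class CurveMeta:
    """Provenance attached to one profile.

    ``frame_time`` is the nominal time of the frame within the exposure
    (seconds); by convention frame ``i`` of an ``exposure``-second framing
    is stamped ``(i + 1) * exposure`` so the first 0.3-s frame reads 0.3 s.
    """

    label: str = ""
    well: str = ""
    frame_index: int | None = None
    frame_time: float | None = None
    exposure: float | None = None
    wavelength: float | None = None


@dataclass(frozen=True)
class ScatteringCurve:
    """One 1-D scattering profile I(q) with optional per-point sigma.

    q is the momentum transfer, q = 4*pi*sin(theta)/lambda, in A^-1,
    strictly increasing; sigma (when present) is strictly positive and in
    the same units as the intensity.
    """

    q: np.ndarray
    intensity: np.ndarray
    sigma: np.ndarray | None = None
    meta: CurveMeta = field(default_factory=CurveMeta)

    def __post_init__(self) -> None:
        q = np.asarray(self.q, dtype=float)
        i = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "q", q)
        object.__setattr__(self, "intensity", i)
        if q.ndim != 1 or q.shape != i.shape or q.size < 3:
            raise DataError("q and intensity must be equal-length 1-D arrays (n >= 3)")
        if not np.all(np.isfinite(q)) or np.any(q <= 0):
            raise DataError("q values must be finite and positive")
        if np.any(np.diff(q) <= 0):
            raise DataError("q must be strictly increasing")
        if self.sigma is not None:
            s = np.asarray(self.sigma, dtype=float)
            object.__setattr__(self, "sigma", s)
            if s.shape != q.shape:
                raise DataError("sigma length must match q")
            if not np.all(np.isfinite(s)) or np.any(s <= 0):
                raise DataError("sigma must be finite and strictly positive")
        if q[-1] > _Q_UNIT_SUSPECT:
            warnings.warn(
                f"max q = {q[-1]:.3g} looks like nm^-1; this package expects A^-1",
                UserWarning,
                stacklevel=2,
            )

    def __len__(self) -> int:
        return self.q.size

    def with_meta(self, **kw) -> "ScatteringCurve":
        return replace(self, meta=replace(self.meta, **kw))

    def same_grid(self, other: "ScatteringCurve", rtol: float = 1e-12) -> bool:
        return self.q.shape == other.q.shape and np.allclose(
            self.q, other.q, rtol=rtol, atol=0.0
        )


@dataclass(frozen=True)
class FrameSeries:
    """Time-ordered profiles for one well; the unit of time-resolved analysis."""

    label: str
    frames: tuple[ScatteringCurve, ...]
    common_grid: bool = True

    def __post_init__(self) -> None:
        frames = tuple(self.frames)
        object.__setattr__(self, "frames", frames)
        if not frames:
            raise DataError("FrameSeries needs at least one frame")
        t = self.times
        if np.any(np.diff(t) <= 0):
            raise AlignmentError(f"frame times not strictly increasing for {self.label!r}")
        if self.common_grid:
            q0 = frames[0].q
            for f in frames[1:]:
                if f.q.shape != q0.shape or not np.array_equal(f.q, q0):
                    raise GridError(f"frames of {self.label!r} do not share one q grid")

    @property
    def times(self) -> np.ndarray:
        ts = []
        for i, f in enumerate(self.frames):
            t = f.meta.frame_time
            if t is None:
                exp = f.meta.exposure or 1.0
                idx = f.meta.frame_index if f.meta.frame_index is not None else i
                t = (idx + 1) * exp
            ts.append(t)
        return np.asarray(ts, dtype=float)

    @property
    def q(self) -> np.ndarray:
        return self.frames[0].q

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)

    def map(self, fn) -> "FrameSeries":
        return FrameSeries(self.label, tuple(fn(f) for f in self.frames), self.common_grid)


MANIFEST_COLUMNS = ("well", "role", "compound_id", "conc_mM", "replicate", "path_pattern")


@dataclass(frozen=True)
class SampleSheet:
    """Validated plate manifest rows."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.table
        missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"manifest missing required column(s): {missing}")
        if df["well"].duplicated().any():
            dupes = sorted(df.loc[df["well"].duplicated(), "well"])
            raise SchemaError(f"duplicate well id(s): {dupes}")
        bad = set(df["role"]) - set(ROLES)
        if bad:
            raise SchemaError(f"unknown role(s) {sorted(bad)}; allowed: {ROLES}")
        if (df["role"] == "sample").any() and not (df["role"] == "buffer").any():
            raise SchemaError("manifest has sample rows but no buffer row")

    def rows(self, role: str | None = None) -> pd.DataFrame:
        if role is None:
            return self.table
        return self.table[self.table["role"] == role]

    def wells(self, role: str | None = None) -> list[str]:
        return list(self.rows(role)["well"])


def read_dat(path: str | Path, label: str | None = None) -> ScatteringCurve:
    """Parse a 3-column (or 2-column, sigma-less) SAXS text profile.

    Leading-``#`` lines and blank lines are skipped.  Raises
    :class:`ParseError` naming the offending row for non-numeric tokens or
    non-monotone q.
    """
    path = Path(path)
    q, i, s = [], [], []
    ncols = None
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.strip()
            if not text or text.startswith("#"):
                continue
            parts = text.split()
            if len(parts) not in (2, 3):
                raise ParseError(f"{path}:{lineno}: expected 2 or 3 columns, got {len(parts)}")
            try:
                vals = [float(p) for p in parts]
            except ValueError as e:
                raise ParseError(f"{path}:{lineno}: non-numeric token in {text!r}") from e
            if ncols is None:
                ncols = len(parts)
            elif len(parts) != ncols:
                raise ParseError(f"{path}:{lineno}: inconsistent column count")
            if q and vals[0] <= q[-1]:
                raise ParseError(f"{path}:{lineno}: q not strictly increasing at {vals[0]!r}")
            q.append(vals[0])
            i.append(vals[1])
            if ncols == 3:
                s.append(vals[2])
    if len(q) < 3:
        raise ParseError(f"{path}: fewer than 3 data rows")
    sigma = np.asarray(s) if ncols == 3 else None
    return ScatteringCurve(
        np.asarray(q), np.asarray(i), sigma, CurveMeta(label=label or path.stem)
    )


def write_dat(curve: ScatteringCurve, path: str | Path) -> Path:
    """Write a profile as ``#``-headed text, >= 9 significant digits."""
    path = Path(path)
    m = curve.meta
    lines = [
        f"# label={m.label} well={m.well} frame_index={m.frame_index}"
        f" frame_time={m.frame_time} exposure={m.exposure}",
        "# q(A^-1)  I(q)" + ("  sigma" if curve.sigma is not None else ""),
    ]
    for k in range(len(curve)):
        row = f"{curve.q[k]:.12g} {curve.intensity[k]:.12g}"
        if curve.sigma is not None:
            row += f" {curve.sigma[k]:.12g}"
        lines.append(row)
    path.write_text("\n".join(lines) + "\n")
    return path


def _series_from_files(
    well: str, label: str, files: Mapping[int, Path], exposure: float | None
) -> FrameSeries:
    frames = []
    for idx in sorted(files):
        c = read_dat(files[idx], label=f"{label}[{idx}]")
        t = (idx + 1) * exposure if exposure else None
        frames.append(
            c.with_meta(label=label, well=well, frame_index=idx, frame_time=t, exposure=exposure)
        )
    return FrameSeries(label=label, frames=tuple(frames))


def load_manifest(
    manifest_path: str | Path, exposure: float = 0.3
) -> tuple[SampleSheet, dict[str, FrameSeries], pd.DataFrame]:
    """Load a plate manifest CSV and assemble one FrameSeries per well.

    ``path_pattern`` must contain a ``{frame}`` placeholder; frame indices
    are discovered on disk.  Returns the sheet, a well -> series mapping,
    and a validation report (one row per missing/extra frame) so skipped
    frames are auditable rather than fatal.
    """
    manifest_path = Path(manifest_path)
    sheet = SampleSheet(pd.read_csv(manifest_path))
    base = manifest_path.parent
    series: dict[str, FrameSeries] = {}
    report_rows = []
    for _, row in sheet.table.iterrows():
        pattern = str(row["path_pattern"])
        if "{frame}" not in pattern:
            raise SchemaError(f"path_pattern for well {row['well']!r} lacks {{frame}}")
        found: dict[int, Path] = {}
        # frame indices are discovered by globbing the pattern
        glob_pat = pattern.replace("{frame}", "*")
        prefix, _, suffix = pattern.partition("{frame}")
        for p in sorted(base.glob(glob_pat)):
            stem = str(p.relative_to(base))
            digits = stem[len(prefix) : len(stem) - len(suffix)]
            try:
                found[int(digits)] = p
            except ValueError:
                continue
        if not found:
            raise SchemaError(f"no frames found for well {row['well']!r} ({pattern})")
        idxs = sorted(found)
        for missing in set(range(idxs[0], idxs[-1] + 1)) - set(idxs):
            report_rows.append({"well": row["well"], "frame": missing, "issue": "missing"})
        label = str(row["compound_id"]) if row["role"] == "sample" else f"{row['role']}:{row['well']}"
        series[str(row["well"])] = _series_from_files(str(row["well"]), label, found, exposure)
    report = pd.DataFrame(report_rows, columns=["well", "frame", "issue"])
    return sheet, series, report
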