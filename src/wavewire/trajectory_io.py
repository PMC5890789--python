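"""Trajectory and time-series I/O plus time-domain summaries.

Reads multi-frame XYZ trajectories, extracts internal coordinates
(distances, angles, dihedrals), and provides the elementary time-domain
reductions used to characterise a hydrogen-bond network: excited/ground
difference traces, block averages and value distributions.

Units are fixed throughout the package: Å for distances, degrees for
angles and dihedrals, fs for time.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from MDAnalysis.lib.distances import calc_angles, calc_dihedrals

__all__ = [
    "Trajectory",
    "TimeSeries",
    "InternalCoordinateSpec",
    "Distribution",
    "XYZParseError",
    "read_xyz",
    "write_xyz",
    "extract",
    "difference",
    "block_average",
    "histogram",
    "read_timeseries",
    "write_timeseries",
    "write_distribution",
]


class XYZParseError(ValueError):
    """Raised when a multi-frame XYZ file is malformed."""


@dataclass
class Trajectory:
    """A uniformly sampled trajectory: one atom list, many frames.

    Parameters
    ----------
    element_labels
        Chemical symbols, one per atom, identical across frames.
    coordinates
        Array of shape ``(n_frames, n_atoms, 3)`` in Å.
    dt
        Frame spacing in fs.
    comments
        Optional per-frame comment lines (XYZ second line).
    """

    element_labels: list[str]
    coordinates: np.ndarray
    dt: float
    comments: list[str] | None = None

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise ValueError("coordinates must have shape (n_frames, n_atoms, 3)")
        if self.coordinates.shape[1] != len(self.element_labels):
            raise ValueError("element_labels length does not match coordinates")
        if not self.dt > 0:
            raise ValueError("dt must be positive")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("coordinates contain non-finite values")

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.dt


@dataclass
class TimeSeries:
    """Uniformly sampled scalar signal F(t).

    ``values`` carries the samples (Å or degrees), ``dt`` the spacing in
    fs and ``t0`` the time of the first sample.
    """

    values: np.ndarray
    dt: float
    t0: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.values.size < 1:
            raise ValueError("time series must contain at least one sample")
        if not self.dt > 0:
            raise ValueError("dt must be positive")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("time series contains non-finite values")

    def __len__(self) -> int:
        return self.values.size

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.values.size) * self.dt

    @property
    def duration(self) -> float:
        return (self.values.size - 1) * self.dt


_KIND_ARITY = {"distance": 2, "angle": 3, "dihedral": 4}


@dataclass(frozen=True)
class InternalCoordinateSpec:
    """Selection of one internal coordinate by zero-based atom indices."""

    kind: str
    atom_indices: tuple[int, ...]
    label: str = ""

    def __post_init__(self) -> None:
        if self.kind not in _KIND_ARITY:
            raise ValueError(f"unknown coordinate kind {self.kind!r}")
        idx = tuple(int(i) for i in self.atom_indices)
        object.__setattr__(self, "atom_indices", idx)
        if len(idx) != _KIND_ARITY[self.kind]:
            raise ValueError(
                f"{self.kind} requires {_KIND_ARITY[self.kind]} atom indices, got {len(idx)}"
            )
        if len(set(idx)) != len(idx):
            raise ValueError("atom indices must be distinct")
        if any(i < 0 for i in idx):
            raise ValueError("atom indices must be non-negative")


@dataclass
class Distribution:
    """Histogram of a time series: counts and normalised density."""

    bin_edges: np.ndarray
    counts: np.ndarray
    density: np.ndarray | None = None
    label: str = ""

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.counts = np.asarray(self.counts)
        if self.bin_edges.size != self.counts.size + 1:
            raise ValueError("need one more edge than counts")
        if np.any(np.diff(self.bin_edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def n_samples(self) -> int:
        return int(self.counts.sum())


# ---------------------------------------------------------------------------
# XYZ I/O


def read_xyz(path: str | Path, dt: float) -> Trajectory:
    """Read a standard multi-frame XYZ file.

    Each frame is an atom-count line, a comment line, then ``symbol x y z``
    rows. All frames must share the same atom count and element ordering.
    ``dt`` (fs) is attached as metadata; XYZ itself carries no time axis.
    """
    if not dt > 0:
        raise ValueError("dt must be positive")
    lines = Path(path).read_text().splitlines()
    pos = 0
    n_lines = len(lines)
    labels: list[str] | None = None
    frames: list[np.ndarray] = []
    comments: list[str] = []
    while pos < n_lines and lines[pos].strip() == "" and pos == n_lines - 1:
        break
    while pos < n_lines:
        if lines[pos].strip() == "" and all(l.strip() == "" for l in lines[pos:]):
            break  # trailing blank lines
        frame_idx = len(frames)
        try:
            n_atoms = int(lines[pos].split()[0])
        except (ValueError, IndexError) as exc:
            raise XYZParseError(
                f"frame {frame_idx}: expected atom-count line, got {lines[pos]!r}"
            ) from exc
        if pos + 1 >= n_lines:
            raise XYZParseError(f"frame {frame_idx}: truncated after atom-count line")
        comments.append(lines[pos + 1])
        body = lines[pos + 2 : pos + 2 + n_atoms]
        if len(body) < n_atoms or any(len(l.split()) < 4 for l in body):
            raise XYZParseError(
                f"frame {frame_idx}: expected {n_atoms} coordinate lines"
            )
        frame_labels = [l.split()[0] for l in body]
        try:
            xyz = np.array([[float(v) for v in l.split()[1:4]] for l in body])
        except ValueError as exc:
            raise XYZParseError(
                f"frame {frame_idx}: non-numeric coordinate entry"
            ) from exc
        if labels is None:
            labels = frame_labels
        elif frame_labels != labels:
            raise XYZParseError(
                f"frame {frame_idx}: atom labels/order differ from frame 0"
            )
        frames.append(xyz)
        pos += 2 + n_atoms
    if not frames:
        raise XYZParseError(f"{path}: no frames found")
    return Trajectory(labels, np.stack(frames), dt=dt, comments=comments)


def write_xyz(traj: Trajectory, path: str | Path, fmt: str = "%.8f") -> None:
    """Write a trajectory as multi-frame XYZ (8 decimals by default)."""
    buf = io.StringIO()
    for f in range(traj.n_frames):
        comment = (
            traj.comments[f]
            if traj.comments is not None and f < len(traj.comments)
            else f"frame {f} t= {f * traj.dt:.4f} fs"
        )
        buf.write(f"{traj.n_atoms}\n{comment}\n")
        for sym, (x, y, z) in zip(traj.element_labels, traj.coordinates[f]):
            buf.write(f"{sym} {fmt % x} {fmt % y} {fmt % z}\n")
    Path(path).write_text(buf.getvalue())


# ---------------------------------------------------------------------------
# Internal coordinates


def _check_spec(traj: Trajectory, spec: InternalCoordinateSpec) -> None:
    if max(spec.atom_indices) >= traj.n_atoms:
        raise IndexError(
            f"spec {spec.label or spec.kind}: atom index {max(spec.atom_indices)} "
            f"out of range for {traj.n_atoms} atoms"
        )


def extract(traj: Trajectory, spec: InternalCoordinateSpec) -> TimeSeries:
    """Extract one internal-coordinate time series from a trajectory.

    Distances are Euclidean norms in Å; angles are in [0, 180] degrees;
    dihedrals are signed torsions in (−180, 180] with the IUPAC sign
    convention (looking from the second to the third atom, clockwise
    rotation of the far bond is positive).
    """
    _check_spec(traj, spec)
    pts = [np.ascontiguousarray(traj.coordinates[:, i]) for i in spec.atom_indices]
    label = spec.label or f"{spec.kind}{spec.atom_indices}"
    if spec.kind == "distance":
        vals = np.linalg.norm(pts[0] - pts[1], axis=1)
    elif spec.kind == "angle":
        _fail_on_degenerate_legs(pts, label)
        vals = np.degrees(calc_angles(pts[0], pts[1], pts[2]))
    else:  # dihedral
        _fail_on_collinear(pts, label)
        vals = np.degrees(calc_dihedrals(pts[0], pts[1], pts[2], pts[3]))
        # map -180 -> +180 so the range is (-180, 180]
        vals = np.where(vals <= -180.0, vals + 360.0, vals)
    return TimeSeries(vals, dt=traj.dt, t0=0.0, label=label)


def _fail_on_degenerate_legs(pts: Sequence[np.ndarray], label: str) -> None:
    for a, b in ((0, 1), (1, 2)):
        bad = np.linalg.norm(pts[a] - pts[b], axis=1) < 1e-10
        if bad.any():
            raise ValueError(
                f"{label}: coincident atoms at frame {int(np.flatnonzero(bad)[0])}"
            )


def _fail_on_collinear(pts: Sequence[np.ndarray], label: str) -> None:
    b1 = pts[1] - pts[0]
    b2 = pts[2] - pts[1]
    b3 = pts[3] - pts[2]
    for name, n in (("1-2-3", np.cross(b1, b2)), ("2-3-4", np.cross(b2, b3))):
        bad = np.linalg.norm(n, axis=1) < 1e-10
        if bad.any():
            raise ValueError(
                f"{label}: collinear atoms {name} make the torsion undefined "
                f"at frame {int(np.flatnonzero(bad)[0])}"
            )


# ---------------------------------------------------------------------------
# Time-domain reductions


def difference(a: TimeSeries, b: TimeSeries) -> TimeSeries:
    """Elementwise a − b after truncation to the common span.

    The natural use is an excited-minus-ground (S1 − S0) relative trace of
    the same internal coordinate from two trajectories sharing a time step.
    """
    if not np.isclose(a.dt, b.dt, rtol=1e-9, atol=0.0):
        raise ValueError(f"dt mismatch: {a.dt} vs {b.dt}")
    n = min(len(a), len(b))
    label = f"{a.label or 'a'}-{b.label or 'b'}"
    return TimeSeries(a.values[:n] - b.values[:n], dt=a.dt, t0=a.t0, label=label)


def block_average(ts: TimeSeries, window: int) -> TimeSeries:
    """Average non-overlapping consecutive blocks of ``window`` samples.

    A trailing partial block is averaged over its actual length so the
    smoothed curve keeps the full span. Output spacing is ``window * dt``.
    """
    window = int(window)
    if window < 1:
        raise ValueError("window must be >= 1")
    v = ts.values
    starts = np.arange(0, v.size, window)
    sums = np.add.reduceat(v, starts)
    sizes = np.minimum(starts + window, v.size) - starts
    out = sums / sizes
    return TimeSeries(
        out,
        dt=window * ts.dt,
        t0=ts.t0 + (window - 1) * ts.dt / 2.0,
        label=f"{ts.label} (block {window})".strip(),
    )


def histogram(ts: TimeSeries, bin_width: float) -> Distribution:
    """Time-averaged value distribution with fixed-width bins.

    Edges are aligned to multiples of ``bin_width``; counts conserve the
    sample count and the density integrates to one.
    """
    if not bin_width > 0:
        raise ValueError("bin_width must be positive")
    v = ts.values
    lo = np.floor(v.min() / bin_width) * bin_width
    n_bins = max(1, int(np.ceil((v.max() - lo) / bin_width - 1e-12)))
    edges = lo + bin_width * np.arange(n_bins + 1)
    if edges[-1] < v.max():  # guard against rounding at the top edge
        edges = np.append(edges, edges[-1] + bin_width)
    counts, edges = np.histogram(v, bins=edges)
    density = counts / (v.size * bin_width)
    return Distribution(edges, counts, density, label=ts.label)


# ---------------------------------------------------------------------------
# Delimited text I/O


def write_timeseries(ts: TimeSeries, path: str | Path) -> None:
    """Write ``time_fs,value`` with one header line."""
    df = pd.DataFrame({"time_fs": ts.times, "value": ts.values})
    df.to_csv(path, index=False, float_format="%.10g")


def read_timeseries(path: str | Path, label: str | None = None) -> TimeSeries:
    """Read a two-column ``time_fs,value`` file with one header line."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns time_fs,value")
    t = df.iloc[:, 0].to_numpy(dtype=float)
    v = df.iloc[:, 1].to_numpy(dtype=float)
    if t.size < 2:
        raise ValueError(f"{path}: need at least two samples")
    steps = np.diff(t)
    dt = float(np.median(steps))
    if not np.allclose(steps, dt, rtol=1e-6, atol=1e-9 * max(dt, 1.0)):
        raise ValueError(f"{path}: time column is not uniformly spaced")
    return TimeSeries(v, dt=dt, t0=float(t[0]), label=label or str(path))


def write_distribution(dist: Distribution, path: str | Path) -> None:
    """Write ``bin_left,bin_right,count,density`` rows."""
    density = (
        dist.density
        if dist.density is not None
        else dist.counts / max(1, dist.n_samples) / np.diff(dist.bin_edges)
    )
    df = pd.DataFrame(
        {
            "bin_left": dist.bin_edges[:-1],
            "bin_right": dist.bin_edges[1:],
            "count": dist.counts,
            "density": density,
        }
    )
    df.to_csv(path, index=False, float_format="%.10g")
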