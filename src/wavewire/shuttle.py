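"""Proton-wire characterisation in the time domain.

A proton wire is an ordered chain of hydrogen bonds — in GFP the
chromophore phenol, a crystallographic water, Ser205 and Glu222 — along
which protons shuttle after photoexcitation. This module extracts the
wire's distance and dihedral series from a trajectory, detects transfer
events as persistent donor/acceptor distance crossings, classifies how
concerted the relay is, and monitors wire planarity and the approach of
a hydrogen-bond partner (His148 in GFP) to the donor oxygen.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .trajectory_io import InternalCoordinateSpec, TimeSeries, Trajectory, extract

__all__ = [
    "ProtonWireTopology",
    "TransferEvent",
    "ConcertednessResult",
    "ApproachResult",
    "ShuttleSummary",
    "wire_summary",
    "transfer_time",
    "detect_events",
    "concertedness",
    "planarity_monitor",
    "approach_monitor",
    "write_summary",
    "write_events",
]

#: Concertedness thresholds on the spread (max − min transfer time), fs.
SYNCHRONOUS_SPREAD_FS = 25.0
CONCERTED_SPREAD_FS = 250.0


@dataclass(frozen=True)
class ProtonWireTopology:
    """Atom indices of a donor→acceptor proton wire.

    ``links`` are (donor O, H, acceptor O) triplets ordered along the
    wire; consecutive links share an oxygen. ``oxygen_chain`` lists the
    four wire oxygens in order, ``chromophore_dihedral`` the four atoms
    of the ring–bridge–ring torsion, and ``monitors`` optional extra
    distance pairs (e.g. an H-bond partner proton to the donor oxygen).

    The defaults match the 13-atom toy wire emitted by
    :mod:`wavewire.synthetic`.
    """

    links: tuple[tuple[int, int, int], ...] = ((0, 4, 1), (1, 5, 2), (2, 6, 3))
    oxygen_chain: tuple[int, int, int, int] = (0, 1, 2, 3)
    chromophore_dihedral: tuple[int, int, int, int] = (7, 8, 9, 10)
    monitors: tuple[tuple[int, int], ...] = ((11, 0),)
    link_labels: tuple[str, ...] = ("Otyr->wat", "wat->Ser205", "Ser205->Glu222")
    monitor_labels: tuple[str, ...] = ("Hhis148-Otyr",)

    def __post_init__(self) -> None:
        if len(self.links) != len(self.link_labels):
            raise ValueError("one label per link required")
        chain = self.oxygen_chain
        for k, (d, h, a) in enumerate(self.links):
            if len({d, h, a}) != 3:
                raise ValueError(f"link {k}: indices must be distinct")
            if k < len(chain) - 1 and (d != chain[k] or a != chain[k + 1]):
                raise ValueError(
                    f"link {k}: donor/acceptor oxygens disagree with oxygen_chain"
                )


@dataclass
class TransferEvent:
    """One detected proton hop: link id, time (fs) and the persistence used."""

    link: int
    transfer_time: float
    persistence: float
    label: str = ""


@dataclass
class ConcertednessResult:
    """Spread of transfer times and the resulting mechanism class."""

    spread: float
    classification: str
    ordering: list[int]
    complete: bool


@dataclass
class ApproachResult:
    """Partner-approach summary around a transfer event."""

    below_at_event: bool
    first_sustained_time: float | None
    cutoff: float


@dataclass
class ShuttleSummary:
    """All wire series on a common grid: 9 distances, 2 dihedrals, monitors."""

    donor_h: dict[str, TimeSeries]
    h_acceptor: dict[str, TimeSeries]
    oxygen_oxygen: dict[str, TimeSeries]
    dihedrals: dict[str, TimeSeries]
    monitors: dict[str, TimeSeries]
    dt: float

    def all_series(self) -> dict[str, TimeSeries]:
        out: dict[str, TimeSeries] = {}
        for group in (
            self.donor_h,
            self.h_acceptor,
            self.oxygen_oxygen,
            self.dihedrals,
            self.monitors,
        ):
            out.update(group)
        return out

    def to_frame(self) -> pd.DataFrame:
        series = self.all_series()
        first = next(iter(series.values()))
        data = {"time_fs": first.times}
        data.update({k: v.values for k, v in series.items()})
        return pd.DataFrame(data)


def wire_summary(traj: Trajectory, topo: ProtonWireTopology) -> ShuttleSummary:
    """Extract every wire parameter series from a trajectory.

    Produces per link the donor–H, H–acceptor and O–O distances, plus the
    chromophore and oxygen-chain dihedrals and any monitor distances.
    """
    donor_h, h_acceptor, oo = {}, {}, {}
    for k, ((d, h, a), lab) in enumerate(zip(topo.links, topo.link_labels)):
        donor_h[f"dOH_{lab}"] = extract(
            traj, InternalCoordinateSpec("distance", (d, h), f"dOH_{lab}")
        )
        h_acceptor[f"dHA_{lab}"] = extract(
            traj, InternalCoordinateSpec("distance", (h, a), f"dHA_{lab}")
        )
        oo[f"dOO_{lab}"] = extract(
            traj, InternalCoordinateSpec("distance", (d, a), f"dOO_{lab}")
        )
    dihedrals = {
        "chromophore_NCCC": extract(
            traj,
            InternalCoordinateSpec(
                "dihedral", topo.chromophore_dihedral, "chromophore_NCCC"
            ),
        ),
        "wire_oxygen": extract(
            traj, InternalCoordinateSpec("dihedral", topo.oxygen_chain, "wire_oxygen")
        ),
    }
    monitors = {
        lab: extract(traj, InternalCoordinateSpec("distance", pair, lab))
        for pair, lab in zip(topo.monitors, topo.monitor_labels)
    }
    return ShuttleSummary(donor_h, h_acceptor, oo, dihedrals, monitors, dt=traj.dt)


def _first_sustained(cond: np.ndarray, n_hold: int) -> int | None:
    """First index i with cond[i : i + n_hold] all True and fully in range."""
    if cond.size < n_hold:
        return None
    ok = np.convolve(cond.astype(int), np.ones(n_hold, dtype=int), mode="valid") == n_hold
    hits = np.flatnonzero(ok)
    return int(hits[0]) if hits.size else None


def transfer_time(
    d_donor_h: TimeSeries,
    d_acceptor_h: TimeSeries,
    persistence: float = 10.0,
    link: int = 0,
    label: str = "",
) -> TransferEvent | None:
    """Detect a proton hop as a persistent donor/acceptor distance crossing.

    The event time is the first sample where the H–acceptor distance drops
    below the H–donor distance and stays below for every sample within the
    following ``persistence`` fs (a window that must fit inside the
    trajectory). Returns None when the proton never relocates.
    """
    if len(d_donor_h) != len(d_acceptor_h) or not np.isclose(
        d_donor_h.dt, d_acceptor_h.dt, rtol=1e-9
    ):
        raise ValueError("donor and acceptor series must share one grid")
    dt = d_donor_h.dt
    if persistence < dt:
        raise ValueError("persistence must be at least one time step")
    cond = d_acceptor_h.values < d_donor_h.values
    n_hold = int(round(persistence / dt)) + 1  # samples in [t, t+persistence]
    i = _first_sustained(cond, n_hold)
    if i is None:
        return None
    return TransferEvent(
        link=link,
        transfer_time=float(d_donor_h.t0 + i * dt),
        persistence=float(persistence),
        label=label,
    )


def detect_events(
    summary: ShuttleSummary, persistence: float = 10.0
) -> list[TransferEvent]:
    """Run :func:`transfer_time` on every link of a wire summary."""
    events = []
    for k, ((_, dOH), (_, dHA)) in enumerate(
        zip(summary.donor_h.items(), summary.h_acceptor.items())
    ):
        ev = transfer_time(
            dOH, dHA, persistence=persistence, link=k, label=dOH.label.removeprefix("dOH_")
        )
        if ev is not None:
            events.append(ev)
    return events


def concertedness(
    events: Sequence[TransferEvent], n_links: int | None = None
) -> ConcertednessResult:
    """Classify the relay from the spread of its transfer times.

    spread ≤ 25 fs → concerted-synchronous; ≤ 250 fs →
    concerted-asynchronous; larger → sequential. With events missing on
    some links the classification is reported as partial with a warning.
    """
    if not events:
        raise ValueError("need at least one transfer event")
    times = np.array([e.transfer_time for e in events])
    spread = float(times.max() - times.min())
    if spread <= SYNCHRONOUS_SPREAD_FS:
        cls = "concerted-synchronous"
    elif spread <= CONCERTED_SPREAD_FS:
        cls = "concerted-asynchronous"
    else:
        cls = "sequential"
    ordering = [events[i].link for i in np.argsort(times, kind="stable")]
    complete = n_links is None or len(events) >= n_links
    if not complete:
        warnings.warn(
            f"only {len(events)} of {n_links} links transferred; "
            "classification is partial",
            stacklevel=2,
        )
        cls += " (partial)"
    return ConcertednessResult(
        spread=spread, classification=cls, ordering=ordering, complete=complete
    )


def planarity_monitor(
    dihedral: TimeSeries, threshold: float = 10.0
) -> list[tuple[float, float]]:
    """Maximal contiguous windows (fs) where |dihedral| < threshold degrees."""
    if not threshold > 0:
        raise ValueError("threshold must be positive")
    flat = np.abs(dihedral.values) < threshold
    if not flat.any():
        return []
    edges = np.diff(flat.astype(int))
    starts = list(np.flatnonzero(edges == 1) + 1)
    ends = list(np.flatnonzero(edges == -1))
    if flat[0]:
        starts.insert(0, 0)
    if flat[-1]:
        ends.append(flat.size - 1)
    t = dihedral.times
    return [(float(t[i]), float(t[j])) for i, j in zip(starts, ends)]


def approach_monitor(
    monitor: TimeSeries,
    event: TransferEvent,
    cutoff: float = 2.0,
    sustain: float = 50.0,
) -> ApproachResult:
    """Partner approach relative to a transfer event.

    Reports whether the monitored distance is below ``cutoff`` (Å) at the
    event time, and the earliest time from which it stays below the
    cutoff for at least ``sustain`` fs.
    """
    t = monitor.times
    if not (t[0] - 1e-9 <= event.transfer_time <= t[-1] + 1e-9):
        raise ValueError("monitor series does not span the event time")
    i_event = int(round((event.transfer_time - monitor.t0) / monitor.dt))
    below_at_event = bool(monitor.values[i_event] < cutoff)
    cond = monitor.values < cutoff
    n_hold = int(round(sustain / monitor.dt)) + 1
    i = _first_sustained(cond, n_hold)
    first_time = float(t[i]) if i is not None else None
    return ApproachResult(
        below_at_event=below_at_event, first_sustained_time=first_time, cutoff=cutoff
    )


def write_summary(summary: ShuttleSummary, path: str | Path) -> None:
    """Write the wide table: time plus every wire series."""
    summary.to_frame().to_csv(path, index=False, float_format="%.10g")


def write_events(events: Sequence[TransferEvent], path: str | Path) -> None:
    """Write ``link,label,transfer_time_fs,persistence_fs`` rows."""
    pd.DataFrame(
        {
            "link": [e.link for e in events],
            "label": [e.label for e in events],
            "transfer_time_fs": [e.transfer_time for e in events],
            "persistence_fs": [e.persistence for e in events],
        }
    ).to_csv(path, index=False)
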