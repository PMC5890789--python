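"""Seeded synthetic signals and a toy proton-wire trajectory.

Every generator returns its ground truth (scripted event times,
instantaneous frequencies, modulation phases) so downstream analyses can
be verified end to end without any external data. The toy wire is
geometric, not physical: proton relocation is scripted kinematics whose
extracted internal coordinates reproduce the scripted series — the
object under test is the analysis, not the dynamics.

Default script values mirror the study conditions the package targets:
O–H stretch carriers of 3330/3099/2533 cm⁻¹ in the ground state
red-shifting to 3108/2859/2056 cm⁻¹ upon excitation, a ~120 cm⁻¹
low-frequency pocket mode on the dihedral surrogates, O–O baselines of
2.58 Å, a 0.5 fs time step, a proton transfer on the first link at
720 fs, and a 250 fs amplitude-modulation period for the anti-phase
band pair (carriers 1500/1550 cm⁻¹).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .trajectory_io import TimeSeries, Trajectory
from .wavelet import C_CM_PER_FS, sampling_limit

__all__ = [
    "WireScript",
    "GroundTruth",
    "make_sinusoid",
    "make_chirp",
    "make_antiphase_pair",
    "make_wire_trajectory",
    "write_ground_truth",
]


@dataclass
class GroundTruth:
    """What a generator scripted, for later verification.

    ``event_times`` are scripted proton-transfer times (fs) per link
    label, ``instantaneous_wavenumber`` per-series ν(t) arrays (cm⁻¹),
    ``modulation_phase`` per-series modulation phase arrays (rad), and
    ``meta`` scalar script facts (carriers, periods, crossing times).
    """

    event_times: dict[str, float] = field(default_factory=dict)
    instantaneous_wavenumber: dict[str, np.ndarray] = field(default_factory=dict)
    modulation_phase: dict[str, np.ndarray] = field(default_factory=dict)
    meta: dict[str, object] = field(default_factory=dict)


def write_ground_truth(gt: GroundTruth, path: str | Path) -> None:
    """JSON sidecar: scalar facts plus endpoints of the scripted ν(t)."""
    doc: dict[str, object] = {
        "event_times_fs": gt.event_times,
        "meta": gt.meta,
        "instantaneous_wavenumber_endpoints_cm1": {
            k: [float(v[0]), float(v[-1])] for k, v in gt.instantaneous_wavenumber.items()
        },
    }
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")


def _check_alias(nu: float, dt: float) -> None:
    lim = sampling_limit(dt)
    if nu >= lim:
        raise ValueError(
            f"wavenumber {nu} cm^-1 is at or above the sampling limit "
            f"{lim:.1f} cm^-1 for dt={dt} fs"
        )


def _time_grid(dt: float, duration: float) -> np.ndarray:
    n = int(round(duration / dt)) + 1
    if n < 2:
        raise ValueError("duration must cover at least two samples")
    return np.arange(n) * dt


def make_sinusoid(
    nu: float,
    amplitude: float = 1.0,
    dt: float = 0.5,
    duration: float = 1000.0,
    seed: int | None = None,
    noise_sigma: float = 0.0,
    label: str = "",
) -> TimeSeries:
    """Pure tone at ν cm⁻¹ with optional seeded Gaussian noise."""
    _check_alias(nu, dt)
    t = _time_grid(dt, duration)
    v = amplitude * np.sin(2.0 * np.pi * C_CM_PER_FS * nu * t)
    if noise_sigma > 0.0:
        v = v + np.random.default_rng(seed).normal(0.0, noise_sigma, t.size)
    return TimeSeries(v, dt=dt, t0=0.0, label=label or f"sin_{nu:g}cm1")


def make_chirp(
    nu_start: float,
    nu_end: float,
    dt: float = 0.5,
    duration: float = 1000.0,
    amplitude: float = 1.0,
    hold: float = 0.0,
    seed: int | None = None,
    noise_sigma: float = 0.0,
    label: str = "",
) -> tuple[TimeSeries, GroundTruth]:
    """Linear frequency sweep; phase is the integral of ν(t).

    With ``hold`` > 0 the instantaneous frequency stays at its endpoints
    for ``hold`` fs at each end of the sweep (useful for measuring
    red-shift endpoints free of ramp bias).
    """
    _check_alias(max(nu_start, nu_end), dt)
    if hold < 0 or 2 * hold >= duration:
        raise ValueError("hold must satisfy 0 <= 2*hold < duration")
    t = _time_grid(dt, duration)
    frac = np.clip((t - hold) / (duration - 2.0 * hold), 0.0, 1.0)
    nu_t = nu_start + (nu_end - nu_start) * frac
    phase = 2.0 * np.pi * C_CM_PER_FS * cumulative_trapezoid(nu_t, t, initial=0.0)
    v = amplitude * np.sin(phase)
    if noise_sigma > 0.0:
        v = v + np.random.default_rng(seed).normal(0.0, noise_sigma, t.size)
    ts = TimeSeries(v, dt=dt, t0=0.0, label=label or f"chirp_{nu_start:g}_{nu_end:g}")
    gt = GroundTruth(
        instantaneous_wavenumber={ts.label: nu_t},
        meta={"nu_start_cm1": nu_start, "nu_end_cm1": nu_end, "hold_fs": hold},
    )
    return ts, gt


def make_antiphase_pair(
    carrier_a: float = 1500.0,
    carrier_b: float = 1550.0,
    modulation_period: float = 250.0,
    modulation_depth: float = 0.5,
    dt: float = 0.5,
    duration: float = 2000.0,
    seed: int | None = None,
    noise_sigma: float = 0.0,
) -> tuple[TimeSeries, TimeSeries, GroundTruth]:
    """Two carriers whose amplitudes breathe in anti-phase.

    A is modulated by (1 + m·sin(2πt/T)), B by (1 − m·sin(2πt/T)), so the
    band-power maxima of the two alternate T/2 apart.
    """
    _check_alias(max(carrier_a, carrier_b), dt)
    if not modulation_period > 0:
        raise ValueError("modulation period must be positive")
    if not 0.0 <= modulation_depth <= 1.0:
        raise ValueError("modulation depth must lie in [0, 1]")
    t = _time_grid(dt, duration)
    phase = 2.0 * np.pi * t / modulation_period
    env = modulation_depth * np.sin(phase)
    rng = np.random.default_rng(seed)
    va = (1.0 + env) * np.sin(2.0 * np.pi * C_CM_PER_FS * carrier_a * t)
    vb = (1.0 - env) * np.sin(2.0 * np.pi * C_CM_PER_FS * carrier_b * t)
    if noise_sigma > 0.0:
        va = va + rng.normal(0.0, noise_sigma, t.size)
        vb = vb + rng.normal(0.0, noise_sigma, t.size)
    ts_a = TimeSeries(va, dt=dt, label=f"bandA_{carrier_a:g}cm1")
    ts_b = TimeSeries(vb, dt=dt, label=f"bandB_{carrier_b:g}cm1")
    gt = GroundTruth(
        modulation_phase={ts_a.label: phase, ts_b.label: phase + np.pi},
        meta={
            "carrier_a_cm1": carrier_a,
            "carrier_b_cm1": carrier_b,
            "modulation_period_fs": modulation_period,
            "modulation_depth": modulation_depth,
            "expected_alternation_lag_fs": modulation_period / 2.0,
        },
    )
    return ts_a, ts_b, gt


# ---------------------------------------------------------------------------
# Toy proton wire


@dataclass
class WireScript:
    """Recipe for a 13-atom toy proton-wire trajectory.

    Atom order: O0..O3 (wire oxygens: chromophore phenol, water, Ser205,
    Glu222 surrogates), H4..H6 (wire protons), atoms 7–10 a four-atom
    chromophore-dihedral surrogate (N,C,C,C), atom 11 the His-like
    partner proton, atom 12 its nitrogen. Matches the default
    :class:`wavewire.shuttle.ProtonWireTopology`.
    """

    excited: bool = True
    duration: float | None = None  # fs; 1 ps excited, 7 ps ground
    dt: float = 0.5
    seed: int = 0
    noise_sigma: float = 0.0  # Å on distance drivers

    carriers_s0: tuple[float, float, float] = (3330.0, 3099.0, 2533.0)
    carriers_s1: tuple[float, float, float] = (3108.0, 2859.0, 2056.0)
    oh_equilibrium: float = 1.02  # Å
    oh_amplitude: float = 0.02  # Å

    oo_baseline: float = 2.58  # Å
    oo_mod_amplitude: float = 0.04  # Å, at the pocket wavenumber
    oo_contraction: float = 0.12  # Å reached after excitation
    contraction_tau: float = 150.0  # fs ramp time constant

    pocket_wavenumber: float = 120.0  # cm^-1
    chromo_dihedral_mean: float = -2.0  # degrees
    chromo_dihedral_amplitude: float | None = None  # 3 deg ground, 8 deg excited
    wire_dihedral_mean: float = 2.5  # degrees
    wire_dihedral_amplitude: float = 20.0  # degrees

    transfer_times: tuple[float | None, float | None, float | None] | None = None
    transfer_width: float = 3.0  # fs, sigmoid steepness of the hop

    his_baseline: float = 2.6  # Å
    his_final: float = 1.85  # Å
    his_ramp: float = 250.0  # fs
    his_lead: float = 200.0  # fs before the first transfer

    modulation_period: float = 250.0  # fs, for the anti-phase band pair

    LINK_LABELS = ("Otyr->wat", "wat->Ser205", "Ser205->Glu222")

    def __post_init__(self) -> None:
        if self.duration is None:
            self.duration = 1000.0 if self.excited else 7000.0
        if self.transfer_times is None:
            self.transfer_times = (720.0, 740.0, 760.0) if self.excited else (None,) * 3
        if len(self.transfer_times) != 3:
            raise ValueError("transfer_times needs one entry per link")
        if self.chromo_dihedral_amplitude is None:
            self.chromo_dihedral_amplitude = 8.0 if self.excited else 3.0
        lim = sampling_limit(self.dt)
        for nu in (*self.carriers_s0, *self.carriers_s1, self.pocket_wavenumber):
            if nu >= lim:
                raise ValueError(f"carrier {nu} cm^-1 aliases at dt={self.dt} fs")
        for t_ev in self.transfer_times:
            if t_ev is not None and not (0.0 < t_ev < self.duration):
                raise ValueError(f"transfer time {t_ev} fs outside the trajectory span")
        if self.oh_equilibrium + self.oh_amplitude >= (
            self.oo_baseline - self.oo_mod_amplitude - self.oo_contraction
        ) / 2.0 + 0.5:
            # the proton must sit clearly on one side of the wire link
            raise ValueError("O-H oscillation too large for the O-O baseline")

    @classmethod
    def ground_state(cls, **kw) -> "WireScript":
        kw.setdefault("excited", False)
        return cls(**kw)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60.0, 60.0)))


def _chain4(d12, d23, d34, theta_deg, center, bond_plane_angle=70.0):
    """Place a 4-atom chain with given consecutive distances and dihedral.

    Returns per-frame positions p1..p4, each (n, 3). The dihedral
    1-2-3-4 equals ``theta_deg`` by construction (verified against the
    two-plane-normal definition).
    """
    n = np.broadcast(d12, theta_deg).size
    a = np.radians(bond_plane_angle)
    th = np.radians(np.asarray(theta_deg, dtype=float))
    d12 = np.broadcast_to(np.asarray(d12, dtype=float), (n,))
    d23 = np.broadcast_to(np.asarray(d23, dtype=float), (n,))
    d34 = np.broadcast_to(np.asarray(d34, dtype=float), (n,))
    p2 = np.zeros((n, 3))
    p3 = np.zeros((n, 3))
    p3[:, 0] = d23
    p1 = np.zeros((n, 3))
    p1[:, 0] = -d12 * np.cos(a)
    p1[:, 1] = d12 * np.sin(a)
    p4 = p3.copy()
    p4[:, 0] += -d34 * np.cos(a)
    p4[:, 1] += d34 * np.sin(a) * np.cos(th)
    p4[:, 2] += d34 * np.sin(a) * np.sin(th)
    return [p + np.asarray(center)[None, :] for p in (p1, p2, p3, p4)]


def make_wire_trajectory(script: WireScript) -> tuple[Trajectory, GroundTruth]:
    """Build the toy wire trajectory and its ground truth.

    Extracted internal coordinates reproduce the scripted series: O–H
    distances oscillate about 1.02 Å at the per-link carrier (chirping
    from the ground- to the excited-state value when ``excited``), O–O
    distances breathe about the baseline at the pocket wavenumber and
    contract after excitation, wire protons relocate at the scripted
    transfer times, the dihedral surrogates oscillate at the pocket
    wavenumber, and the His-like proton descends below 2 Å ahead of the
    first transfer. Identical seeds give identical output.
    """
    t = _time_grid(script.dt, script.duration)
    n = t.size
    rng = np.random.default_rng(script.seed)
    two_pi_c = 2.0 * np.pi * C_CM_PER_FS
    gt = GroundTruth(meta={"excited": script.excited, "dt_fs": script.dt, "seed": script.seed})

    # O-O distances per link: baseline + pocket-mode breathing (+ contraction)
    d_oo = []
    for k in range(3):
        mod = script.oo_mod_amplitude * np.sin(
            two_pi_c * script.pocket_wavenumber * t + 0.7 * k
        )
        d = script.oo_baseline + mod
        if script.excited:
            d = d - script.oo_contraction * (1.0 - np.exp(-t / script.contraction_tau))
        if script.noise_sigma > 0:
            d = d + rng.normal(0.0, script.noise_sigma, n)
        d_oo.append(d)

    # O-H oscillation per link; excited state chirps S0 -> S1 carrier
    s_along = []
    for k, label in enumerate(script.LINK_LABELS):
        if script.excited:
            frac = t / script.duration
            nu_t = script.carriers_s0[k] + (script.carriers_s1[k] - script.carriers_s0[k]) * frac
        else:
            nu_t = np.full(n, script.carriers_s0[k])
        gt.instantaneous_wavenumber[f"dOH_{label}"] = nu_t
        phase = two_pi_c * cumulative_trapezoid(nu_t, t, initial=0.0)
        r = script.oh_equilibrium + script.oh_amplitude * np.sin(phase)
        if script.noise_sigma > 0:
            r = r + rng.normal(0.0, script.noise_sigma, n)
        t_ev = script.transfer_times[k]
        if t_ev is None:
            g = np.zeros(n)
        else:
            g = _sigmoid((t - t_ev) / script.transfer_width)
            gt.event_times[label] = float(t_ev)
        # distance from donor oxygen along the link axis; crosses the
        # midpoint exactly at t_ev because donor and acceptor share r(t)
        s_along.append(r + g * (d_oo[k] - 2.0 * r))

    # dihedral surrogates at the pocket wavenumber
    chromo = script.chromo_dihedral_mean + script.chromo_dihedral_amplitude * np.sin(
        two_pi_c * script.pocket_wavenumber * t + 0.3
    )
    wire_dih = script.wire_dihedral_mean + script.wire_dihedral_amplitude * np.sin(
        two_pi_c * script.pocket_wavenumber * t
    )
    gt.meta["pocket_wavenumber_cm1"] = script.pocket_wavenumber

    # His-like partner approach: linear descent crossing 2.0 A his_lead
    # fs before the first transfer
    events = [e for e in script.transfer_times if e is not None]
    if events:
        t_cross = min(events) - script.his_lead
        span = script.his_baseline - script.his_final
        frac_at_cross = (script.his_baseline - 2.0) / span
        t_a = t_cross - frac_at_cross * script.his_ramp
        m = script.his_baseline - span * np.clip((t - t_a) / script.his_ramp, 0.0, 1.0)
        gt.meta["his_crossing_time_fs"] = float(t_cross)
    else:
        m = np.full(n, script.his_baseline)
    m = m + 0.01 * np.sin(two_pi_c * script.pocket_wavenumber * t + 1.1)
    if script.noise_sigma > 0:
        m = m + rng.normal(0.0, script.noise_sigma, n)

    # geometry assembly
    o1, o2, o3, o4 = _chain4(d_oo[0], d_oo[1], d_oo[2], wire_dih, (0.0, 0.0, 0.0))
    coords = np.zeros((n, 13, 3))
    coords[:, 0], coords[:, 1], coords[:, 2], coords[:, 3] = o1, o2, o3, o4
    for k, (dn, ac) in enumerate(((0, 1), (1, 2), (2, 3))):
        axis = coords[:, ac] - coords[:, dn]
        axis /= np.linalg.norm(axis, axis=1, keepdims=True)
        coords[:, 4 + k] = coords[:, dn] + s_along[k][:, None] * axis
    c1, c2, c3, c4 = _chain4(
        np.full(n, 1.4), np.full(n, 1.45), np.full(n, 1.4), chromo, (0.0, 0.0, 8.0)
    )
    coords[:, 7], coords[:, 8], coords[:, 9], coords[:, 10] = c1, c2, c3, c4
    u = coords[:, 0] - coords[:, 1]
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    coords[:, 11] = coords[:, 0] + m[:, None] * u
    coords[:, 12] = coords[:, 11] + 1.0 * u

    labels = ["O", "O", "O", "O", "H", "H", "H", "N", "C", "C", "C", "H", "N"]
    comments = [f"toy proton wire frame {i} t= {ti:.4f} fs" for i, ti in enumerate(t)]
    traj = Trajectory(labels, coords, dt=script.dt, comments=comments)
    gt.meta.update(
        {
            "carriers_s0_cm1": list(script.carriers_s0),
            "carriers_s1_cm1": list(script.carriers_s1),
            "oo_baseline_A": script.oo_baseline,
            "modulation_period_fs": script.modulation_period,
        }
    )
    return traj, gt
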