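# wavewire

Time-resolved vibrational analysis of molecular-dynamics trajectories
with a multiresolution Morlet continuous wavelet transform, plus the
trajectory analyses it drives: proton-transfer event detection, band
ridge/period/phase tracking, and hydrogen-bond-network statistics.

## Who this is for

Simulators studying ultrafast photoreactivity — the motivating case is
the excited-state proton transfer (ESPT) in green fluorescent protein,
where a proton relays chromophore → water → Ser205 → Glu222 within a
picosecond of photoexcitation — who need to ask *when* a vibrational
band shifts, which bands exchange intensity, and how structural
rearrangement times relate to the reaction event. A windowed Fourier
transform fixes one time–frequency trade-off for all bands; the CWT
adapts it per band, resolving slow collective modes to a few cm⁻¹ while
localising O–H stretches to tens of fs.

## The transform

For a uniformly sampled signal F(t) (a distance in Å or a dihedral in
degrees, dt in fs) and the Morlet mother wavelet
Ψ(t) = π^(−1/4) e^{iω₀t} e^{−t²/2} (ω₀ = 6),

    W(a, b) = a^(−1/2) ∫ F(t) Ψ*((t − b)/a) dt

is evaluated on a discretized scale set {aᵢ} built per wavenumber
region — by default grid spacings of ≤ 5, 10 and 20 cm⁻¹ in the
10–1300, 1300–3000 and 3000–4000 cm⁻¹ regions. Scales convert to
wavenumbers through the equivalent Fourier period
λ = 4πa/(ω₀ + √(2 + ω₀²)), ν̃ = 1/(cλ). The power |W(ν, t)|² is the
time-resolved spectrum; a cone-of-influence mask flags edge-affected
cells, and every scale's time–bandwidth product attains the Heisenberg
bound ΔνΔt = 1/(4π). A slow Riemann-sum reference and an FFT fast path
agree to better than 1e-6; see `docs/methods.md` for every numerical
choice.

## Worked example

Everything is testable without external data: the `synthetic` module
scripts a 13-atom toy proton wire whose internal coordinates carry
known frequencies and a scheduled transfer.

```python
import numpy as np
from wavewire import (
    WireScript, make_wire_trajectory, wire_summary, ProtonWireTopology,
    detect_events, concertedness, approach_monitor,
    build_scale_set, cwt_fast, ridge_track, period_to_wavenumber,
)

# a 1 ps excited-state toy wire (dt = 0.5 fs), scripted ESPT at 720 fs
traj, truth = make_wire_trajectory(WireScript(seed=0))
summary = wire_summary(traj, ProtonWireTopology())
events = detect_events(summary, persistence=10.0)
for ev in events:
    print(f"{ev.label:18s} transfer at {ev.transfer_time:6.1f} fs")
relay = concertedness(events, n_links=3)
print(f"mechanism: {relay.classification} (spread {relay.spread:.1f} fs)")

first = min(events, key=lambda e: e.transfer_time)
his = approach_monitor(summary.monitors["Hhis148-Otyr"], first, cutoff=2.0)
print(f"His-H below 2 A from {his.first_sustained_time:.1f} fs "
      f"({first.transfer_time - his.first_sustained_time:.0f} fs before the event)")

# wavelet spectrum of the wire-oxygen dihedral: the ~120 cm^-1 pocket mode
dih = summary.dihedrals["wire_oxygen"]
scales = build_scale_set([(60.0, 250.0, 2.0)], dt=dih.dt)
track = ridge_track(cwt_fast(dih, scales), 60.0, 250.0)
sel = track.valid() & (track.times > 300.0) & (track.times < 700.0)
print(f"pocket-mode ridge: {np.median(track.peak_wavenumber[sel]):.0f} cm^-1")
```

prints

```
Otyr->wat          transfer at  720.5 fs
wat->Ser205        transfer at  740.5 fs
Ser205->Glu222     transfer at  760.5 fs
mechanism: concerted-asynchronous (spread 40.0 fs)
His-H below 2 A from 521.5 fs (199 fs before the event)
pocket-mode ridge: 120 cm^-1
```

The detector recovers each scripted hop within one sample (the
crossing becomes strict half a step after the scheduled time), the
40 fs spread classifies the relay as concerted but slightly
asynchronous, the His-like partner crosses 2 Å ~200 fs ahead of the
event, and the dihedral's wavelet ridge sits on the scripted 120 cm⁻¹
pocket mode.

## Command line

The same workflow is scriptable from a shell; every command validates
its inputs, writes plain delimited outputs and a provenance copy of its
resolved configuration, and exits non-zero on error:

```
wavewire synth   --script script.yaml --seed 1 --out fixture/
wavewire extract --traj fixture/wire.xyz --dt 0.5 --spec coords.yaml --out series/
wavewire cwt     --series series/wire_dih.csv --regions "10:1300:5,1300:3000:10,3000:4000:20" --out spectra/
wavewire ridge   --series series/wire_dih.csv --window 60:250 --out ridge/
wavewire events  --traj fixture/wire.xyz --dt 0.5 --persistence 10 --out events/
```

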