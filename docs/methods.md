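# Methods

## The analysis in one paragraph

`wavewire` analyses structural time series F(t) extracted from
molecular-dynamics trajectories — bond distances, hydrogen-bond
distances, dihedral angles — in the joint time–frequency domain with a
continuous wavelet transform (CWT),

    W(a, b) = a^(-1/2) ∫ F(t) Ψ*((t − b)/a) dt ,

and uses the resulting power maps |W(ν, t)|² to follow vibrational
bands as a reaction unfolds: red shifts of O–H stretches when covalent
bonds weaken in an electronically excited state, the anti-phase
breathing of chromophore marker bands, the low-frequency "pocket" modes
that modulate a proton wire, and the proton-transfer events themselves,
detected in the time domain as persistent donor/acceptor distance
crossings.

## Mother wavelet and scale–wavenumber conversion

The mother wavelet is the Morlet function

    Ψ(t) = π^(-1/4) · exp(i ω₀ t) · exp(−t²/2),   ω₀ = 6 by default.

ω₀ is dimensionless; values ≥ 5 keep the admissibility defect (the
residual mean of this analytic form) below ~1e-6 so the standard
correction term can be dropped; the constructor rejects smaller values.
A scale `a` (in fs) is reported as the wavenumber of the equivalent
Fourier period,

    λ = 4π a / (ω₀ + √(2 + ω₀²)),   ν̃ = 1/(c λ),

with c = 2.99792458×10⁻⁵ cm/fs, giving λ/a ≈ 1.0330 at ω₀ = 6. This
conversion almost exactly cancels the a^(1/2) tilt of the power ridge,
so a pure tone's ridge lands on the grid point nearest its true
frequency (verified to within one grid spacing in every region).

## Multiresolution scale set

Scales are discretized per wavenumber *region*. Each region
(ν_lo, ν_hi, max_spacing) contributes an arithmetic wavenumber grid
whose adjacent gap never exceeds the cap (the span is divided evenly).
The defaults are

| region (cm⁻¹) | grid spacing cap (cm⁻¹) |
|---------------|-------------------------|
| 10 – 1300     | 5                       |
| 1300 – 3000   | 10                      |
| 3000 – 4000   | 20                      |

which resolves low-frequency collective modes to a few cm⁻¹ while
keeping the O–H stretch region affordable. "Resolution" here means the
grid spacing of the discretized scale set; the intrinsic Morlet
bandwidth at each scale is reported separately by
`resolution_report` (Δt = a/√2 fs, Δν = 1/(2π c a √2) cm⁻¹), whose
dimensionless product c·Δν·Δt equals the Heisenberg bound 1/(4π)
because the envelope is Gaussian. Regions must stay below the sampling
limit 1/(2 c dt) ≈ 33 360 cm⁻¹ at dt = 0.5 fs.

## Numerical evaluation

Two evaluation paths share one contract. `cwt_direct` is the literal
Riemann sum of the defining integral, O(n²) per scale, kept as the
readable reference. `cwt_fast` multiplies the FFT of the zero-padded
signal by the analytic Morlet spectrum Ψ̂(ω) = π^(-1/4)√(2π)
exp(−(aω − ω₀)²/2); padding extends to the next power of two past the
widest wavelet support (8·a_max), so circular wrap-around is
negligible and the two paths agree to ~1e-7 relative inside the cone
of influence (tested at 1e-6 on seeded random signals up to 4096
samples).

Signals are mean-removed before transforming (default on, flag to
disable): distance series carry multi-Å offsets that would otherwise
leak spurious low-frequency power. Power is reported in arbitrary
units (signal² · fs²); no spectroscopic cross-section calibration is
attempted.

The cone of influence (COI) marks a time–scale cell unreliable when it
lies closer than √2·a to a signal edge (the e-folding time of the
envelope's power). Two practical consequences, both visible in the
tests: (i) the zero-mean cancellation for constant signals only holds
where the *full* wavelet support (~8a) fits inside the signal, so the
admissibility check uses that deeper margin; (ii) ridge positions in
the last few columns just inside the COI are still edge-biased, so
band statistics trim a small extra margin (~50 fs at stretch
frequencies) and `intensity_maxima` discards maxima within one
`min_separation` of the track ends.

## Band analysis

- **Ridge**: per time column, the in-COI power argmax inside a
  wavenumber window; ties break toward lower wavenumber; columns fully
  outside the COI are missing (NaN). No continuity penalty is applied.
- **Intensity maxima**: `scipy.signal.find_peaks` with a minimum
  spacing (default 100 fs — below the 250–300 fs modulation periods of
  interest, above noise spacing); the mean and std of consecutive gaps
  give the modulation period, undefined (not an error) with fewer than
  two interior maxima.
- **Phase relation**: normalized cross-correlation of the mean-removed
  band-power traces. The zero-lag value classifies the pair
  (≤ −0.2 out-of-phase, ≥ +0.2 in-phase, else uncorrelated — the
  thresholds are package choices, configurable in the dataclass).
  `best_lag` is the lag of the maximum *signed* correlation, i.e. the
  alternation lag that brings the traces into agreement (T/2 for an
  anti-phase pair); the absolute-maximum lag would simply return 0 for
  any strongly anti-correlated pair and carries no information beyond
  the zero-lag value.
- **Periods and wavenumbers** interconvert as ν̃ = 1/(c T): 300 fs ↔
  111.19 cm⁻¹, 260 fs ↔ 128.29 cm⁻¹.
- **Red-shift report**: median in-COI ridge wavenumber per state inside
  a per-mode window, compared against a reference table of harmonic
  frequencies. Two modes closer than the Morlet bandwidth at their
  scale (~19 cm⁻¹ around 160 cm⁻¹) cannot be separated inside one
  series; the report assumes one dominant band per window.

## Proton-wire analysis

The wire is an ordered chain donor → H → acceptor → … (in GFP:
chromophore phenol O, crystallographic water, Ser205, Glu222, with
His148 as an approach monitor). `wire_summary` extracts the nine
distance series (3 donor–H, 3 H–acceptor, 3 O–O), the chromophore
N–C–C–C and wire-oxygen dihedrals, and any monitor distances.

A **transfer event** is the first time the H–acceptor distance drops
below the H–donor distance and stays below for every sample in the
following `persistence` window (default 10 fs; the window must fit
inside the trajectory, so a crossing in the last few fs is not
counted). This crossing rule is an operational interpretation — the
underlying studies identify events by inspection — and the persistence
default rejects sub-vibrational transients (a 4 fs blip is not a
transfer) while accepting any stable relocation.

**Concertedness** classifies the spread (max − min) of the per-link
transfer times: ≤ 25 fs concerted-synchronous, ≤ 250 fs
concerted-asynchronous, larger sequential. The thresholds are package
definitions calibrated to sub-vibrational-period vs sub-modulation-
period spreads; both are configurable. **Planarity** windows are
maximal runs of |dihedral| below a threshold (default 10°).
**Approach monitoring** reports whether a monitor distance is below a
cutoff (default 2.0 Å) at the event time and the earliest sustained
(≥ 50 fs) sub-cutoff time.

Dihedrals use the IUPAC sign convention (looking from atom 2 to atom
3, clockwise rotation of the far bond positive), range (−180°, 180°].
Note the signed torsion is *invariant* under reversing the four-index
order; only improper mirror operations flip its sign. Distances are
plain Euclidean norms — no periodic-boundary handling, appropriate for
protein-interior coordinates.

## Synthetic fixtures and what they do (not) show

`wavewire.synthetic` generates every test input with known ground
truth. Defaults encode the study conditions the package targets: O–H
stretch carriers 3330/3099/2533 cm⁻¹ red-shifting to
3108/2859/2056 cm⁻¹ upon excitation; a 120 cm⁻¹ pocket mode on the
dihedral surrogates (amplitude 20° on the wire-oxygen dihedral, 8°/3°
on the chromophore dihedral in the excited/ground state); O–O
baselines of 2.58 Å with a 0.04 Å breathing amplitude and a 0.12 Å
post-excitation contraction (150 fs ramp); transfers at 720/740/760 fs
(first link at 720 fs, slightly asynchronous); a His-like partner
descending through 2.0 Å 200 fs before the first transfer; a 250 fs
modulation period for the anti-phase band pair at 1500/1550 cm⁻¹
carriers; dt = 0.5 fs; durations of 1 ps (excited) and 7 ps (ground).
O–H oscillation amplitude is 0.02 Å about a 1.02 Å equilibrium,
matching sub-0.03 Å covalent-bond fluctuation scales.

The 13-atom toy wire is geometric, not physical: internal coordinates
are scripted kinematics assembled into Cartesian frames (chain
geometry with prescribed bond lengths and dihedrals; wire protons
placed on the donor–acceptor axis so donor and acceptor distances
cross exactly at the scripted transfer time). Noise is independent
Gaussian per sample, for robustness testing only. Consequently,
passing tests demonstrate that the *analysis* recovers scripted
frequencies, phases and events under realistic magnitudes — they say
nothing about force fields, electronic structure, anharmonic couplings
or the statistical structure of real AIMD noise.

## Problem sizes and numerical choices

Test and acceptance runs use 1–6 ps signals at dt = 0.5 fs
(2 000–12 000 samples) with regional scale subsets, and the full
three-region set (479 scales) where cross-region behaviour matters;
these sizes put every reported quantity well inside its asymptotic
regime while keeping a full run in tens of seconds. Other fixed
choices: ridge ties break toward lower wavenumber; trailing partial
blocks in `block_average` are averaged, not dropped; histogram edges
align to multiples of the bin width; the FFT path clips sigmoid
arguments at ±60 to avoid overflow; scale/wavenumber round-trips are
exact to 1e-12 relative.

## Known limitations

- No inverse CWT, discrete wavelet transforms, or intensity/cross-
  section modelling.
- Per-column argmax ridges can hop between near-degenerate bands; a
  continuity-penalised tracker is out of scope.
- The transfer criterion needs both O–H distance series; it does not
  infer topology or detect back-transfers after the first event.
- XYZ is the only trajectory format (by design); time step must be
  supplied externally since XYZ carries no time axis.
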