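# Methods

## Model overview

The package simulates two trap-free 2DMS geometries with idealized
uniform-field kinematics and closed-form ion optics. Electrode-level field
solving, fringe fields, space charge, detector response and kinetic-energy
release on fragmentation are deliberately out of scope; a small-step
numerical trajectory integrator exists in the test suite as an independent
oracle for the closed forms, never as part of the simulation itself.

### TOF side-kick variant

Axial (detection) and lateral (kick/fragmentation) motions are treated as
independent, which presumes the kicked trajectory is parallel to the
detector — the reason the kick potential (7 V) is kept small against the
repeller (1000 V). The kick is impulsive: it imparts lateral speed
v = √(2e·V_kick/((m/z)·u)) followed by field-free drift. At delay t the ion
sits at d = v·t − zone_start inside a fragmentation zone illuminated with
dual-slit fringes I(d) = cos²(π(d − φ)/Λ); its capture (and hence
fragmentation) probability is I(d) sampled at the start of the
fragmentation period. Stepping the delay by Δt per scan line turns each
precursor's fragment intensities into a sampled cosine at

    f = v/Λ = D/√(m/z),  D = √(2e·V_kick/u)/Λ   (Hz·Th^1/2)

Note the charge state cancels: both the kinetic energy gained and the mass
scale with z, so the law depends only on m/z.

### Electric-sector variant

A deflection field E = V/gap acts for a pulse length stepped by 1 µs per
run. The impulse changes only the orthogonal velocity component,
Δv = eEt/((m/z)·u), so the exit angle is
θ_F = arctan((v_ir + Δv)/v_forward) and the displacement on the
fragmentation axis after drifting X is d = X(tan θ_F − tan θ_i), measured
**relative to the undeflected path** (the other reading of "distance from
the center of deflection" would differ by a constant and cannot produce
the stated scaling). With tangential entry (θ_i = 0) this chain is
*exactly* linear in pulse length — tan θ_F = Δv/v_forward — so the
transient is an unchirped cosine at any deflection angle, and with an
entry speed derived from an acceleration potential the frequency again
obeys f = D_sector/√(m/z) exactly. The impulse approximation (deflection
applied at a point) is the one physical idealization here; the engine
records max |tan θ_F − θ_F|/θ_F per acquisition as a validity diagnostic.

The pass-through-time constraint (the pulse must end before the ions leave
the entrance region) is exposed as an optional validated `zone_pass_time`
field rather than a default: the entrance geometry is not otherwise
modeled, and the reference voltages and pulse schedule would imply an
entrance region many metres long, so no physically meaningful default
exists.

## Pinned defaults and why

| Quantity | Default | Rationale |
| --- | --- | --- |
| Kick / repeller / extractor / lens | 7 / 1000 / 905 / 914 V | reference side-kick operating point |
| Fringe spacing Λ | 0.2 mm | with the 36 mm zone gives 181 maxima (180 fringes) |
| Zone start / length | 5 / 36 mm | exposed in config; zone/Λ sets the fringe count |
| TOF schedule | 2^15 scans, Δt = zone_length/(v(1000 Th)·n_scans), t₀ = zone_start/v | "split evenly across the fragmentation zone": the 1000 Th reference ion traverses the zone exactly once |
| Sector field | 3 V across 10 mm (300 V/m) | stated deflection voltage; gap exposed in config |
| Sector schedule | 2^13 = 8192 runs × 1 µs | full stated acquisition; see below |
| Sector entry | 1000 V potential, θ_i = 0 | entry speed ∝ 1/√(m/z) is required by the calibration law |
| Sector drift X | solved so the 1000 Th ion crosses 2171/8191 fringes per run | realizes the 2172-maxima reference sweep (≈ 25.4 mm) |

The TOF defaults give the 1000 Th ion 180 fringe crossings over the
transient, hence RP_mz ≈ 180/(2×1.2067) ≈ 74.6 at the rectangular-window
line width — the ≈ 75 regime. The sector defaults give 2171 crossings over
8192 runs, i.e. 0.265 cycles/run (safely below the 0.5 cycles/scan Nyquist
limit), hence RP_mz ≈ 900 at 1000 Th and ≈ 900/√2 ≈ 636 at 2000 Th, and a
~12× resolving-power gain over the TOF variant with 4× fewer scans. We
deliberately quote the sector figures over the full 8192-run acquisition:
compressing the same fringe sweep into 4096 runs would push the modulation
to 0.53 cycles/run, above Nyquist, where the folded centroid no longer
reports the true resolving power.

At 2300 Th the same law predicts RP_mz ≈ 46 under the pinned TOF schedule
(the slower ion enters the zone late and sweeps fewer fringes); the
simulator reproduces that value, which is what the inverse-square-root
calibration implies — a substantially lower figure in the low twenties is
not consistent with the law and is not reproduced here.

## Numerical choices

- **Mean (DC) subtraction before the FFT.** The cos² pattern carries a ½
  offset that would otherwise dominate bin 0 and its skirt.
- **Magnitude mode only.** The phase constant C (offset between the ions'
  start point and the first fringe maximum) is stored on the calibration
  model but plays no role outside absorption-mode phasing, which is not
  implemented.
- **Zero-fill ×4, rectangular window by default.** The centroid comes from
  three-point parabolic interpolation and the FWHM from linear
  interpolation of the half-height crossings; at ×2 padding the linear
  crossing biases the FWHM of an unapodized line by up to ~2%, at ×4 the
  bias is under 0.6% everywhere we measured. Resolving powers quoted in
  the m/z domain are exactly half the frequency-domain values (m ∝ f⁻²).
- **Peak-picker guards.** Local maxima closer than 3 natural bins
  (1/n_scans cycles/scan) to a taller peak are treated as sidelobes of
  that peak (the first sidelobes of a rectangular line reach ~22% of its
  height); the first 4 natural bins are excluded entirely, because
  transients gated by zone entry/exit leave a baseline step after mean
  subtraction whose magnitude piles up against DC.
- **Uniform scan axes** are validated to 1e-12 relative on the step plus
  the float64 representation noise of the axis values.
- **Constants pinned**: e = 1.602176634×10⁻¹⁹ C,
  u = 1.66053906660×10⁻²⁷ kg; all internal units SI, m/z in Th at
  interfaces.

## Deterministic and stochastic acquisition

Deterministic mode records exact expected intensities
(abundance × branching × I(d) per fragment channel, abundance × (1 − I)
on a depleted-precursor channel — whether unfragmented survivors are
recorded is an instrument choice; recording them costs nothing here and
both conventions are available by ignoring the precursor channels, which
carry a distinct channel-kind tag). Stochastic mode draws, per scan,
Binomial(n_ions, I(d)) fragmenting ions routed to channels by a
multinomial over branching ratios; it is reproducible given (seed,
n_ions). With n_ions = 10⁴ the binomial error keeps the RMS relative
deviation from the deterministic transient below 5% over scans with
intensity ≥ 0.1 (a per-scan worst-case bound cannot hold over thousands of
scans — at I = 0.1 the per-scan relative standard deviation is already
3%, so the extreme over 10³–10⁴ draws necessarily exceeds 5%).

## Synthetic mixtures

`generate_mixture` emulates the inputs of a desk-scale survey: precursor
m/z uniform in a requested range, rejected unless the modulation frequency
under the active configuration is sub-Nyquist and at least a requested
number of line widths (FWHM = 1.2067/n_scans cycles/scan) from every other
precursor; fragment m/z uniform in (50 Th, precursor); branching ratios a
Dirichlet split of a 0.9 total fragmentation yield; abundances uniform in
[0.2, 1]. It does **not** emulate isotope clusters, charge-state
envelopes, chemical noise, shared fragment m/z between precursors (except
by vanishing-probability coincidence), or peak-height dynamics beyond a
5:1 abundance range — so a 100% fragment-to-parent assignment on these
fixtures demonstrates the correctness of the correlation chain under
resolvable, noiseless conditions, not robustness on real spectra.

## Problem sizes

The reference experiments run the full stated acquisitions (2^15 TOF scan
lines; 2^13 sector runs) — vectorized, they take seconds. Property tests
use 2^9–2^13-scan schedules where the property is scale-free, 10⁴ ions
per precursor for stochastic convergence, and 1000 replicates for the
noisy-calibration recovery; these sizes are the package's own test design
choices.

## Known limitations

- Idealized optics: no fringe fields, no lens aberrations, no space
  charge; the kick and deflection are impulsive.
- Fragments inherit the precursor's velocities exactly (kinetic-energy
  release neglected, as appropriate when it is small against the pusher
  energy); no reflectron correction.
- Magnitude-mode only; absorption mode (which would roughly double
  resolving power and would require the phase constant C) is a metadata
  slot, not an implementation.
- The dual-slit pattern is the ideal equal-spacing cos² law with an
  optional sinc² visibility envelope; physical diffraction optics
  (wavelength/slit geometry → Λ) are not modeled. An idealized sinusoidal
  grating is the same law; measured patterns can be tabulated.
- The magnetic-sector geometry is not implemented.
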