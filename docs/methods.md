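# Methods

`echodome` simulates the ultrasonic echoes that a walking echolocating bat
(*Pipistrellus abramus*) receives from dome-shaped targets whose back
structure is hidden from the front — an occlusion spot — and quantifies how
much echo information those hidden structures carry.  This note records the
models, the numerical choices, and what the synthetic stand-ins do and do
not capture.

## Targets

The behavioural experiments used five 3D-printed dome targets derived from
a scanned paper roost (outer envelope 146 × 98 × 54 mm):

| id | edit | what it probes |
|----|------|----------------|
| T1 | original: two floor-level holes, rough surface (Rz = 3.3 mm) | trained operant stimulus |
| T2 | back half removed | gross occlusion-structure change |
| T3 | back hole plugged | subtle occlusion-structure change |
| T4 | smooth surface (Rz = 0) | texture change, same shape |
| T5 | front hole plugged | interior echo path removed |

The scanned geometry is not available to this package, so `geometry.make_dome`
builds a parametric stand-in: a half **super-ellipsoid** shell (exponent 4 in
the horizontal plane, 2 vertically) with configurable wall thickness (default
3 mm, a typical FDM print) and circular entry/exit holes (default diameter
30 mm, centred on the long axis at floor level).  The horizontal bluntness is
deliberate: a purely quadratic ellipsoid tapers to a point exactly where the
entry arch is cut, and the arch would then shorten the printed 146 mm
envelope by ~7 mm; the blunt profile keeps the bounding box at the printed
envelope.  Hole size, hole position and wall thickness are not reported for
the physical targets and are free parameters here.  Real scanned meshes can
be substituted through `read_stl`.

Surface roughness is realised as a seeded band-limited random displacement
field (random-phase spectral synthesis with an isotropic squared-exponential
spectrum, correlation length 8 mm) applied along outer-surface normals and
rescaled so the realised peak-to-valley height equals Rz exactly.  The field
is a deterministic function of *position*, not of the mesh, so all variants
of one base specification receive the identical texture and variant edits
stay local — T3 and T5 differ from T1 only near the plugged hole.  Because
the displacement is centred, the inward excursion is Rz/2; the
self-intersection guard therefore rejects Rz/2 ≥ wall thickness.

Meshes are extracted from the implicit solid by marching cubes
(default 0.5 mm sampling) and are watertight; the T2 midplane cut is closed
by the cut cross-section, which leaves the occupied solid unchanged.
`geometry.voxelize` rasterises a mesh onto the solver lattice with exact
centre-inside semantics (column-parity ray casting along z), so an
axis-aligned 10 mm cube at dx = 1 mm occupies exactly 1000 voxels and voxel
volume converges to mesh volume as dx shrinks.

## Wave solver

`solver.run_simulation` integrates the scalar wave equation directly
(WE-FDTD): a leapfrog update `p(n+1) = 2p(n) − p(n−1) + χ² L₇[p(n)]` on the
7-point stencil, χ = c·dt/dx, stable in 3D for χ ≤ 1/√3.  The reference
configuration mirrors the echo-simulation conditions of the study:
420 × 220 × 80 mm space, c = 340 m/s, χ = 0.5, 2.65 ms simulated time,
10 mm floor slab with pressure reflection coefficient 0.99, source 14 mm and
receiver 17 mm above the floor.  Production resolution is dx = 0.2 mm
(~9·10⁸ cells); desk-scale analyses here run at dx = 1–2 mm.

* **Obstacles** are rigid (PLA/air impedance mismatch ≫ 1): a mirror ghost
  enforces zero normal derivative on voxel faces.
* **Floor**: solid slab whose surface is a locally reacting impedance
  boundary.  The ghost value uses the time-centred (semi-implicit) form
  `p_ghost − p = −(χ/2ζ)(p(n+1) − p(n−1))`, ζ = (1+R)/(1−R), which makes the
  normal-incidence discrete reflection match R closely near R = 1 (measured
  0.993 at R = 0.99).  The boundary is first-order accurate; at R = 0 a
  broadband residual of order −15 dB remains — adequate for this study,
  where the floor is nearly rigid.
* **PML**: convolutional perfectly matched layer for the second-order wave
  equation with recursive memory variables on collocated first and second
  derivatives (κ = 1, α = 0), quadratic damping profile over 10 cells,
  σ_max from the graded-layer rule −(m+1)·c·ln(R₀)/(2L) with R₀ = 10⁻⁴.
  Measured normal-incidence reflection is below −44 dB for 10–40 kHz tone
  bursts.  With α = 0 the layer does not absorb DC; sources used here
  (impulse and zero-mean bursts) have no DC content.
* **Source/receiver**: omnidirectional point source (soft source added to
  the pressure field) and point receiver sampled every step; no head-related
  transfer function, no binaural separation.  "Impulse" excitation is a
  single-step unit injection.
* Fields are float32 by default (float64 available); a divergence guard
  aborts if |p| exceeds 10⁶ × the source amplitude.

The impulse response of a target is obtained by linearity: simulate the
scene with floor only, then floor plus target, and subtract the receiver
traces (`echo.subtract_baseline`).  The subtraction removes the direct path
and all floor-only reverberation exactly.

### Grid dispersion and arrival timing

A single-step impulse excites wavenumbers up to the lattice Nyquist, where
the leapfrog group velocity falls far below c — on coarse grids the raw
envelope peak of a propagated impulse is *not* at the physical delay.  All
timing measurements therefore band-limit the trace to grid-resolved
frequencies, `timing_band(dx) = c/(20·dx)` by default (17 kHz at dx = 1 mm),
and optionally correlate with the band-limited doublet — the far-field
wavelet of a pressure impulse — before envelope peak-picking
(`detect_arrivals(..., max_frequency=..., matched=True)`).  With this
estimator the free-field arrival error stays within ±2 dt of d/c at dx = 2 mm
over 60–140 mm, and the surface-echo delay of the standard scene lands on
the two-way time of flight within ~0.02 ms at dx = 1 mm.

## FM pulse

The sweep mimics the species' downward FM call.  Instantaneous frequency
(t in ms, output kHz):

    f(t) = f0·f1 / ((f0 − f1)·(a·f1/f0)^t + (1 − a)·f1)

with a = 0.005, f0 = 40, f1 = 80.  This is the unique bracketing of the
typeset source expression that yields a physical downward sweep,
f(0) = f0·f1/(f0 − a·f1) = 80.81 kHz falling to the terminal asymptote
f0·f1/((1−a)·f1) = 40.20 kHz; the literal left-to-right reading multiplies
by f0/(f0−f1) < 0 and produces negative frequencies — it is retained under
`interpretation="literal"` for reference but never used.  The waveform is
`A(t)·sin(2π∫f dτ)` with trapezoid-integrated phase and raised-cosine
onset/offset ramps (default 0.25 ms; the envelope of the natural call is
not specified).  Convolving the impulse response with this pulse
(`convolve_echo`) predicts the observed echo waveform.

## Spectrograms and log-spectral distortion

Spectrograms are Hann-windowed magnitude STFTs, window 1024 samples,
hop 24.  Component LSD between a probe target's impulse response and the
T1 reference (`spectral.component_lsd`) aggregates per-bin log-magnitude
ratios `20·log10((|X|+ε)/(|X̂|+ε))` over a time gate × frequency band:

* **Gates** (delays re emission): SURFACE [0.9, 1.7) ms and OCCLUSION
  [1.7, 2.65) ms, bracketing the ~1.2 ms surface-related and ~2.2 ms
  occlusion-related components of the 204 mm scene.  For moving-bat
  analyses the gates translate with the two-way surface delay 2d/c.
* **Band** 20–120 kHz (biosonar-relevant; resolved on the 0.2 mm
  reference grid).
* **Analysis rate**: impulse responses are resampled to 3.4 MHz — the
  solver rate of the 0.2 mm reference configuration — so the 1024-sample
  window spans ~0.3 ms regardless of the solver dx and the two component
  gates remain separable.  `analysis_rate=None` keeps the native rate.
* **Aggregation**: the literal definition is a *signed sum* over all bins,
  which cancels sign-wise and scales with bin count; the per-target values
  reported for the study (6–35 dB) are consistent with an average, not a
  raw sum over ~10⁵ bins.  The default `mean_abs` therefore averages the
  absolute per-bin terms (scale-consistent: a uniform gain g gives
  |20 log g|); `sum_signed` reproduces the literal formula.  The
  discrepancy is documented rather than silently resolved, and every
  result records gates, band, ε and aggregation.
* **ε-floor**: ε = 10⁻⁶ × max|X̂| guards empty bins; halving it moves
  results by < 0.5 dB on the standard fixtures.

Absolute LSD values of the study are not reproducible here: they require
the authors' scanned geometry and the 0.2 mm production grid.  What is
reproducible at desk scale is the *structure*: the occlusion-component
ordering {T3, T4} < {T2, T5}, which the acceptance suite checks at
dx = 1 mm.  At dx = 2 mm the unresolved dispersive tail of the surface echo
bleeds texture differences into the occlusion gate and can lift T4 above
T2; dx ≤ 1 mm keeps the ordering stable.

## Behavioural fixtures and linkage

The study's video trajectories and trial logs are emulated, not
reproduced.  `fixtures.gen_choice_trials` draws Bernoulli outcomes at the
observed mean accuracies (T2/T5 = 1.0, T3 = 0.557, T4 = 0.68; 15 trials
per condition) with balanced pseudo-random side assignment;
`behavior.summarize_choices` reports per-bat and pooled accuracies with
exact two-sided binomial tests against chance (0.5), raw and
Holm-adjusted (the study reports no tests; four planned comparisons).
`fixtures.gen_trajectories` produces smooth approaches in a two-corridor
arena (100 mm aisles, corridor centres ±60 mm, 600 mm start distance,
walking speed 300 mm/s, pulse emissions every ~80 ms with ±20 ms jitter):
DECISIVE paths commit to the T1 corridor mid-approach, UNSURE paths wander
near the centreline.  Arena depth, wall thickness and gait parameters are
plausible choices, not measurements.

`behavior.pulse_lsd_series` maps each selected pulse to a simulation by its
source–target distance alone (corridor walls are not simulated; the domain
length adapts to the distance and the PML makes the lateral extent
immaterial).  Both targets are simulated at the same distance, gates
translated to the local two-way delay, and the component LSD evaluated per
pulse.  Head direction is carried in the fixtures but unused by the
omnidirectional source, mirroring the reference simulations.

A caveat on the approach trend: at desk-scale grids the occlusion-gate
LSD of a T4-vs-T1 series *decreases* with decreasing distance under the
default ε = 10⁻⁶ (measured 11.1 → 5.1 dB over 400 → 124 mm at dx = 2 mm;
4.5 → 3.6 dB at dx = 1 mm), because the far-range occlusion gate is
dominated by near-empty spectrogram bins whose log ratios are numerically
inflated.  Imposing a finite dynamic range (ε = 10⁻³, i.e. a −60 dB floor
relative to the spectral peak — the order of a real receiver's usable
range) reverses the trend to the expected rise on approach
(3.65 → 4.62 dB at dx = 2 mm).  The defaults are kept as stated and the
sensitivity is reported rather than folded into the defaults.

## Problem sizes used in the test suite

The suite reruns the full pipeline at desk scale: the five-target standard
scene at dx = 1 mm (the binding occlusion-ordering check and the component
delays), solver oracles on small domains at dx = 0.5–2 mm, and a two-pulse
trajectory series at dx = 2 mm.  `scripts/acceptance.py` recomputes the two
component delays at dx = 1 mm.  These sizes were chosen so a complete run
stays within ordinary desk-machine patience; the 0.2 mm production
configuration is supported by the same code path but is cluster-scale.

## Known limitations

* The synthetic dome approximates the scanned roost; absolute echo spectra
  and absolute LSD values differ from the study's.  Arrival *delays* and
  the LSD *ordering* are geometry-robust and are what the tests pin down.
* The floor impedance boundary is first-order accurate; away from R ≈ 1 the
  realised reflection deviates by a few per cent (measured 0.93 at R = 0.9,
  0.67 at R = 0.5 under broadband normal incidence).
* No frequency-dependent air absorption, no directional source/receiver
  patterns, no elastic propagation inside the targets.
* The α = 0 CPML does not absorb DC; zero-mean excitations avoid this.
* The distance-only pulse mapping ignores aspect angle and pulse
  directionality, and single-precision baseline subtraction leaves a
  ~−70 dB leak of the direct blast near zero delay; arrival detection
  therefore starts at the first analysis gate.
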