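# Methods

This note documents the models, parameter choices and known limitations of
the package; everything quantitative below is computed by the test suite or
the example scripts, not asserted from memory.

## Measurement model

A scintillator cube of side 100 mm sits with its centre at the treatment
isocenter; the beam travels vertically downward.  A camera at ~320 mm
records one 16-bit frame per delivery trigger.  Each pulse frame carries two
projections of the scintillation track: the direct view (230 px across one
cube side at the closest face, apparent pixel ≈ 435 µm; column ∝ Y, row ∝
depth) and the mirror view folded in at 45° (167 px, apparent pixel
≈ 600 µm because the folded optical path is longer; column ∝ X).  The
leftmost 30 sensor columns never see scintillation light and serve as a
per-line background probe.  The mirror row and amplitude duplicate the
direct-view row and amplitude and are not computed; the direct view is
preferred for its better signal-to-noise ratio.

Pulse-level characteristics are (X, Y) in mm in the isocenter frame, energy
E in MeV, and intensity I in monitor units (MU).

## Synthetic delivery

The simulator emulates a delivery system that splits each planned PB into
several non-consecutive pulses:

- **pulse count**: n = clip(ceil(I / cap·u), 3..11) with u ~ U(0.6, 1); the
  hard per-pulse cap (default 0.13 MU) always wins over the range, and n is
  reduced so no pulse falls below the minimum deliverable intensity
  (1.5 × 10⁻³ MU). A spot below that minimum is delivered as one pulse.
- **pulse intensities**: Dirichlet(8) weights rescaled to conserve the
  planned intensity exactly (≤10⁻⁹ MU error enforced; excess above the cap
  redistributed).  The true intensity distribution of the physical machine
  is not public; this proxy reproduces its qualitative behaviour (pulses
  confined to ~1.5–150 × 10⁻³ MU, more pulses rather than brighter pulses
  as the planned intensity grows).
- **scheduling**: each energy layer is scanned 3–4 times; a PB's pulses are
  assigned round-robin to the scan passes, so they interleave with other
  spots and are never all consecutive.  Timestamps advance on a 1 ms grid;
  ticks are skipped at the configured dark-trigger rate (default 25 %,
  physical range 10–60 %), and rendering one frame per tick reproduces the
  dark-frame stream of the real acquisition.
- **delivery scatter**: per-pulse Gaussian jitter, 0.15 mm in X/Y and
  0.05 MeV in E by default — the sub-200 µm delivery accuracy scale reported
  for machine logs.

Misalignments are rigid transforms.  Machine-side errors can be applied at
delivery time; *table* positioning errors (the QA use case) are applied at
render time to the scene only, so the log-file stays nominal exactly as a
real log would.  Yaw rotates the scene about the vertical axis; pitch (about
the X axis) mixes Y with the depth coordinate of the Bragg peak, which is
why a pitched table degrades both the Y and E verdicts.

## Optical forward model

Depth of the Bragg peak from energy follows the Bragg–Kleeman power law
range = α·Eᵖ (α = 0.022 mm·MeV⁻¹·⁷⁷, p = 1.77, water-equivalent) minus the
range-shifter water-equivalent thickness (7.4 cm default), so the
calibration energies (~120–156 MeV) land 25–95 mm deep in the cube.  A peak
beyond the cube renders as a shoot-through track (plateau only) and is
flagged in the stack metadata.

The scintillation profile is an entrance plateau (35 % of peak) rising into
a 3-D Gaussian peak (longitudinal sd 4 mm, lateral sd 3.5 mm).  The real
light distribution is never needed downstream: only the peak position and
amplitude are analysed, and the calibration absorbs the profile's exact
shape.  Projection applies a per-view perspective magnification
m = L/(L + d) (distance d of the emission point from the closest face;
mirror path longer by 110 mm), radial vignetting, and mirror reflectivity
0.82.  Amplitude is proportional to pulse MU (3 × 10⁵ counts/MU), with
Poisson shot noise, Gaussian read noise (sd 2), a 100-count pedestal, and
sparse hot pixels (rate 10⁻⁴ per pixel per frame, 10–50× the blob peak,
clipped at 16 bits) emulating scattered radiation hitting the sensor.

What the simulator does **not** model: quenching (Birks), Čerenkov light,
optical diffusion, camera nonlinearity, nozzle-chamber coordinate
conversions, and Monte Carlo transport.  Passing tests therefore demonstrate
the correctness and sensitivity of the *analysis chain* under a smooth,
monotone optical response — not the absolute uncertainties of any physical
detector.

## Preprocessing

- Frame classification: a frame is a pulse frame iff, after subtracting the
  mean dark image, it contains an 8-connected cluster of **strictly more
  than** 50 pixels each above the global dark sd.  Connectivity is
  configurable; "adjacent" is read as 8-connectivity.
- Dark model: bootstrapped from the stack itself — a provisional sd from the
  lowest-variance decile of frames seeds a first classification, and the
  final model uses the frames it labels dark.  The global sd is a scaled
  MAD rather than a plain standard deviation so hot pixels on dark frames
  do not inflate the threshold.  The scheme assumes dark triggers exist in
  the stream, which the physical trigger logic guarantees (10–60 %).
- Hot pixels: a pixel is hot iff its value exceeds 2× the median of its 8
  neighbours **and** its minimum absolute difference to those neighbours
  exceeds 5× the dark sd.  The gradient criterion is the discriminating
  one (an isolated spike exceeds all neighbours); the intensity criterion
  protects genuine peaks, which are smooth at the pixel scale (PSF +
  lateral beam width span several pixels), so a factor 2 is safe and still
  catches spikes landing on blob flanks.  Replacement by the non-hot
  neighbourhood median makes the repair idempotent.
- Background: static mean dark image plus, per sensor line, the mean of the
  leftmost 30 columns (dark margin), broadcast along the row.  The cluster
  threshold is applied to dark-subtracted frames.

## Localization

The likelihood surface is the correlation of a view with a separable
unit-sum Gaussian kernel, sd 6 px at full resolution (scaled with the
sensor so its physical footprint is constant), truncated at ±4 sd,
zero-padded at borders.  Unit normalization makes the maximum of L a
proportional estimator of the peak intensity.  The integer argmax (ties →
smallest (row, col) lexicographically) is refined per axis by a 3-point
parabolic fit, clipped to ±0.5 px; both integer and sub-pixel modes are
available.  A pulse whose amplitude falls below 5× the post-correlation
noise sd (dark sd × kernel L2 norm) is flagged unusable — the signature of
a mis-sorted frame.

## Calibration

Predictors are standardized (training mean/sd) before monomials are built;
degree-5 tensor designs are otherwise catastrophically conditioned.
Candidate bases are full tensor grids: (5+1)³−1 = 215 terms for the three
geometric predictors, (4+1)⁴−1 = 624 with the amplitude added; the
intercept is carried separately and never deleted.  Collinear columns are
dropped up front by pivoted QR and reported.

Selection is greedy backward deletion: with the Gram matrix held fixed, the
RSS increase of deleting term j is βⱼ²/[(XᵀX)⁻¹]ⱼⱼ, so each step evaluates
every deletion exactly and removes the cheapest while
BIC = n·ln(RSS/n) + k·ln(n) (k = terms + intercept + variance) decreases.
Exhaustive subset search over 2²¹⁵ models is infeasible; backward deletion
is the natural reading of a "model deletion" approach.  The RSS is floored
at a data-scaled epsilon so exact interpolation (RSS = 0 to machine
precision) compares as equal rather than as a spurious likelihood gain.
X, Y, E and I are fitted independently.  The default calibration pools two
grid irradiations, at 1 MU and 0.1 MU per spot, to span the full
pulse-intensity range.

Frame/log pairing is greedy nearest-timestamp one-to-one matching within a
tolerance of 0.4 ms (below half the 1 ms frame period); two log entries
within tolerance of one frame raise an ambiguity error rather than guess.

## Verification

Discrepancies are *reference minus measured* (log reference at pulse level,
plan reference at PB level).  Reporting units: position µm, energy keV,
intensity both 10⁻³ MU and percent of the planned PB intensity; the
intensity tolerance band uses the relative scale.  Confidence intervals are
mean ± 3 sd of the pooled discrepancy set (99.7 % coverage for normal
scatter); interval bounds are closed, so boundary items count as inside.
The verdict compares the joint in-CI proportion to a configurable threshold
(default 0.95); per-feature proportions below the threshold name the
offending axis.  Reconstructed PBs absent from the plan are reported as
unplanned and excluded from proportions; planned spots never reconstructed
are reported as missing.

## Problem sizes and numerical choices

The packaged end-to-end runs use a half-resolution sensor (115/84-px views,
128 × 240 frames, pixel scale doubled to ≈ 0.87/1.2 mm) with a 7-layer
5 × 5 calibration grid at (1, 0.1) MU (~2300 matched pulses, comfortably
above the 625-point minimum for the intensity basis) and a 5-layer 6 × 6
verification grid at 0.3 MU — a deliberately scaled-down session that keeps
a full calibrate-and-verify cycle in the low minutes while exercising every
stage at full polynomial degree.  The geometry object scales losslessly
back to the full-size sensor.

Degenerate inputs are handled explicitly: empty stacks, empty views,
all-zero views (flat likelihood), zero-variance discrepancies (degenerate
interval, flagged), rank-deficient designs (dropped and reported), spots
below the minimum pulse intensity (single pulse, no error).

## Known limitations

- The intensity-splitting law and the log-file schema are package
  inventions; only their qualitative envelope is anchored to the physical
  system.
- Calibration is against log-file values; calibrating against planned
  positions (and grouping pulses spatially — a grid-snap fallback exists
  behind a flag) is supported only as an experimental mode.
- No dose, dose-rate or gamma-index computation; the package verifies beam
  *characteristics*, not dose distributions.
- Sub-pixel refinement assumes a locally parabolic likelihood peak; for
  shoot-through pulses the depth feature saturates at the cube exit and the
  energy calibration is not meaningful there (such pulses are flagged).
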