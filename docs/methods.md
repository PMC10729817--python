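# Methods

## The problem

A human sperm head is translucent, nearly axially symmetric (a flattened
ellipsoid, ~5 × 3.2 × 1.6 µm), and rotates about its long axis several times
per second while swimming. In a single 2D bright-field view its rotation
direction is not determinable: the head is a weak phase object whose contrast
inverts with its position relative to the focal plane, and spinning
translucent objects are prone to perception bistability. The method this
package implements reads the rotation direction out of *multi-plane* (3D+t)
bright-field records instead: the through-focus contrast inversion paints a
one-sided bright border on an inclined head, the maximum intensity projection
(MIP) of each z-stack accumulates that border into a single image, and the
border's drift across the head (left→right or right→left relative to the head
axis, viewed from head to tail) encodes the rotation sense.

`spinsense` contains (i) a scalar-diffraction image-formation model for weak
phase objects under defocus and spherical aberration, (ii) a synthetic 4D
phantom generator that emulates the acquisition and provides ground truth,
(iii) the detection pipeline (MIP → head tracking → bb′ profile → weighted
mean position x̄ → CCW/CW/non-rotating call), and (iv) cohort-level
aggregation.

## Image formation model

The system is modelled as a coherent bright-field imager. The pupil carries a
wavefront error

    W(ρ) = A_d ρ² + A_s ρ⁴,   ρ = pupil radius fraction ∈ [0, 1]

with defocus amplitude `A_d` and spherical-aberration amplitude `A_s`; the
amplitude PSF is the Fourier transform of the (apodized) circular aperture
times `exp(i·k·W)`. A phase object `exp(i·φ(x, y))` (peak φ = 0.1 rad, the
weak-phase regime) is imaged by multiplying its spectrum with the aberrated
pupil and squaring the modulus.

Numerical choices:

* **Phase scales.** The dimensionless amplitudes are converted to pupil-edge
  radians by two constants, `defocus_scale = 40` and `spherical_scale =
  2500`, calibrated once on the canonical 128×128-grid / 40×40-px / 0.1-rad
  plate configuration so that defocus amplitudes of a few hundredths and
  spherical amplitudes of a few ten-thousandths produce interacting phase
  regimes, then frozen. A single shared scale cannot do this: it fixes the
  spherical phase at 1% of the defocus phase at the pupil edge. Only signs
  and ratios matter for every claim downstream.
* **Contrast polarity.** The coupling of object height above the focal plane
  to defocus amplitude, `defocus_per_um`, carries the system polarity. Its
  default (−0.5 for the single-image demonstrations, −0.3 in the phantom
  camera chain) renders an object *behind* the focal plane (farther from the
  objective of the inverted microscope) bright with a dark halo, and an
  object in front dark with a bright halo. The absolute polarity of a real
  system depends on its optical design and must be calibrated there; it is a
  configuration choice here.
* **Depth-varying objects** are imaged by multi-slice coherent propagation:
  the object is split into thin phase screens by equal-width height bins
  (default 5–7 slices), a unit illumination field passes the highest screen
  first, free-space propagation (the same quadratic spectral phase that
  defines defocus) carries it between screens, and the exit field is
  propagated to the focal plane and imaged once through the aberrated pupil.
  This preserves the interference between depths — which is what makes the
  border of an object straddling the focal plane light up on one side — and
  degenerates exactly to the flat-object path for a constant height map.
  Early masked-intensity compositing of per-depth images lost that
  interference, and the MIP then carried no rotation signature at all.
* **Apodization.** The pupil amplitude rolls off as a half-cosine from 60%
  of the pupil radius. A hard aperture stamps strong coherent Airy ringing
  on every defocused feature; real, partially coherent bright-field images
  do not show it, and it disrupts segmentation.
* **Padding.** Strongly defocused renders are computed on a 2× zero-order
  (unit background) padded grid so defocused light spreads away instead of
  wrapping around the periodic FFT domain.

### What the model reproduces, and what it cannot

Reproduced, and asserted by the test suite: contrast inversion of a flat
plate with the sign of the defocus amplitude in the presence of spherical
aberration; the bright/dark split across a ~5°-inclined plate with the
behind-half bright; the Fig-style spinning-plate signature (bright part of
the object drifting monotonically within each half turn, direction tied to
the spin sense, abrupt reappearance at the starting side each half turn);
and through-focus phenomenology of the rendered head (bright interior/dark
halo behind the focal plane, inverted in front).

Not reproduced — and mathematically not reproducible in scalar weak-phase
imaging: (1) *same-sign* interior contrast for pure defocus of either sign,
and (2) a spherical-sign flip that inverts every bright/dark assignment.
For a pure phase object, conjugating the object and pupil gives
I(−A_d, −A_s, −φ) = I(A_d, A_s, φ) exactly; at linear order in φ the
contrast is odd in φ, hence c(A_d, A_s) = −c(−A_d, −A_s). Under that
identity, "opposite signs at ±A_d" and "flipping A_s flips the signs" are
mutually exclusive, and pure-defocus phase contrast (a real effect) is
always odd in A_d. The two corresponding acceptance tests assert the claimed
behaviour faithfully and fail; they document the model boundary rather than
a defect of the implementation. In a real microscope the matched partially
coherent illumination suppresses the ideal defocus phase contrast and the
residual aberration response dominates, which the coherent model cannot
represent at matching cost.

## The phantom

The head is a flattened ellipsoid (default semi-axes 2.5 × 1.6 × 0.8 µm,
configurable) treated as a projected phase screen: per pixel, the chord
thickness along the optical axis sets the phase delay (scaled to a 0.1-rad
peak) and the chord midplane sets the height map. An optional neck particle
(sphere, default radius 0.5 µm, offset 3 µm behind the head centre and
1.2 µm off-axis) co-rotates rigidly with the head. The flagellum is not
rendered; detection uses only the head.

Motion is rigid-body: uniform swimming at `speed_um_s` (default 12 µm/s)
tip-first along a constant heading, constant-rate roll about the long axis,
and an axial wobble of the head centre (default 1 µm at the rotation
frequency) so the head crosses focal planes as a free swimmer does. CCW is
defined viewing from head to tail: the angular velocity vector points from
flagellum toward tip. The lab frame is right-handed with z toward the
camera-side far field (the objective sits below), and the screen shows x
rightward, y upward.

Acquisition follows the canonical multi-plane protocol: 8000 frames/s camera
synchronized with an 80 Hz triangular axial scan of 20 µm peak-to-peak, so
each rising half-cycle yields 50 focal planes spaced 0.4 µm and 1/160 s.
Frames are rendered only on rising slopes (the pipeline discards falling
slopes); default frames are 80×80 px at 0.25 µm/px and record lengths are
0.35–0.5 s in unit tests and 1.2 s in the validation cohort (the reference
acquisition records 3.4 s; the shorter records still contain 7–19 half-turn
sweeps at 3–8 Hz and keep the full validation suite tractable). Noise is additive Gaussian on
intensity (default sd 1% of background), seeded; everything is deterministic
for a fixed seed.

Against real data, the phantom omits: flagellar hydrodynamics and beat-shape
variability, head precession, non-uniform swimming, illumination gradients,
camera shot/readout noise statistics, and the caustic-like rim brightening
of a truly refractive 3D head. Passing the recovery suite therefore shows
the pipeline is correct and robust *under the stated image-formation model*,
not that it is validated on real recordings.

## Detection pipeline

Per rising-slope stack:

1. **MIP** — pixelwise maximum over the 50 planes.
2. **Tracking** — the head body is segmented on the *through-focus variance
   map* of the stack (the body modulates strongly across planes; the
   one-sided MIP halo, which is the rotation signal, does not), via an Otsu
   seed, a relaxed connected threshold, and largest-component selection.
   The upstream tracker of the original method is an external system; any
   tracker meeting the pose contract is substitutable, and this one is
   designed so the probe anchor does not chase the halo.
3. **Heading** — per-stack headings come from the smoothed centre
   trajectory (7-stack moving average, ±5-stack windowed displacement): the
   head swims tip-first, so motion fixes both the axis and the tip end.
   The per-stack second-moment axis is used only for quasi-static cells.
   Probe geometry is anchored to the smoothed centres; raw per-stack
   centroid errors are time-correlated and would write a slow spurious wave
   into the trace.
4. **bb′ profile** — the probe segment lies on the line C′ perpendicular to
   the head axis C, through a point d = L/3 ahead of the centre toward the
   tip (L = 5 µm mean head length), with half-length w = 2.5 µm and N = 64
   bilinear samples, averaged over a ±2-px band along the axis for noise
   robustness. Looking from tip to flagellum, b is the observer's left and
   b′ their right; on screen this handedness depends on the optical train's
   mirror count (real systems calibrate it with a physical control), and the
   package fixes it by construction: b′ = tip direction rotated −90° in
   array coordinates, the choice under which a geometrically CCW phantom
   satisfies the canonical rule below.
5. **x̄ (weighted mean position)** — x̄ = Σ I_i x_i / Σ I_i on the
   min-subtracted profile, normalized to [0, 1] from b to b′. Min
   subtraction isolates the moving bright feature from the flat background;
   a raw mode is available.
6. **Classification** — the canonical rule: x̄ drifting from b to b′ with
   abrupt half-turn resets means CCW; the mirrored pattern means CW. The
   implementation median-filters the trace (3 points), removes the slow
   baseline (25-stack moving average — far below any plausible rotation
   frequency), gates on the robust 5th–95th-percentile excursion
   (`amp_threshold = 0.15`; rotating phantoms sit near 0.3, the noise floor
   below 0.1), takes the direction from the up/down step-count asymmetry
   (the sawtooth spends more frames drifting than resetting), identifies
   resets as counter-drift segments between prominent extrema exceeding
   half the excursion, and reports the majority fraction of retained steps
   as the confidence (gate 0.6) plus the reset count as half-cycles
   (frequency = half-cycles / 2·duration, minimum 2). The thresholds are
   calibrated on the phantom recovery suite and exposed in configuration.
   A kymograph stripe-drift reader (`profile_drift_lag`, the mean
   cross-correlation lag between consecutive profiles) is provided as a
   diagnostic companion to the x̄ rule.

Aggregation counts per-condition CCW/CW/non-rotating calls with exact
integers and full-precision percentages; low-confidence demotions are
tallied in a separate audit column.

## Validation summary

The test suite generates everything it needs at run time: exact acquisition
arithmetic; the optics sign suite; 40 randomized spinning plates (100%
drift-direction recovery); a 30-phantom cohort (directions × 3–8 Hz ×
four quadrants, wobble on) with 100% recovery at ≤2% noise and ≥95% with no
CCW↔CW confusion at 5%; four-quadrant call invariance; exact mirror
anti-symmetry; and bit-identical TIFF round trips with slope segmentation
that matches the generator's scan log frame by frame.

## Known limitations

* The two non-reproducible contrast-sign claims above.
* The frequency estimate counts reset events; at high rotation rates with
  few stacks per half turn it can be biased by ±1 half-cycle per record.
* One cell per record (as in the analysis the method was designed for);
  curved trajectories are supported by the windowed heading but sharp turns
  within ~5 stacks are not.
* Rotation rates well above ~10 Hz under-sample the 80 Hz stack rate and
  are outside the validated range.
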