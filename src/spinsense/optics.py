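"""Scalar-diffraction image formation for weak phase objects.

Bright-field images of translucent, weakly scattering objects (phase delay
well below 1 rad) carry almost no contrast at focus.  Out of focus, the
combination of defocus and the objective's residual spherical aberration
produces a characteristic signature: the object's interior appears bright on
one side of the focal plane and dark on the other, and an *inclined* object
shows a bright/dark split across its tilt axis.  This module simulates that
image-formation chain for a coherent system:

* the wavefront error over the pupil is ``W(rho) = A_d rho**2 + A_s rho**4``
  with ``rho`` the normalized pupil radius, ``A_d`` the defocus amplitude and
  ``A_s`` the spherical-aberration amplitude;
* the amplitude point spread function is the Fourier transform of the pupil
  aperture multiplied by ``exp(i * k * W)``;
* a phase object ``exp(i * phi(x, y))`` is imaged coherently through that
  pupil and the squared modulus is recorded.

The amplitude coefficients ``A_d`` and ``A_s`` are dimensionless and their
absolute normalization is not fixed by the wavefront expansion alone;
``defocus_scale`` and ``spherical_scale`` convert one unit of each amplitude
into radians of pupil-edge phase.  Both were calibrated once on the canonical
128x128-grid, 40x40-pixel, 0.1-rad plate configuration so that defocus
amplitudes of a few hundredths and spherical amplitudes of a few
ten-thousandths land in interacting phase regimes, and are then frozen.  Only
signs and ratios of the coefficients matter for every statement this package
makes downstream.

The polarity of the through-focus contrast (which side of the focal plane
renders bright) is carried by the sign of ``defocus_per_um``, the coupling
between an object's height above the focal plane and its defocus amplitude.
The default makes an object *behind* the focal plane (farther from the
objective) render bright with a dark halo, and an object in front dark with
a bright halo; real systems can have either polarity, so it is configurable.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "AberrationModel",
    "PhaseObject",
    "IntensityImage",
    "wave_aberration",
    "psf",
    "defocus_amplitude_sign",
    "image_weak_phase_object",
    "image_inclined_object",
    "render_spinning_sequence",
    "signed_contrast",
    "rect_phase_object",
    "inclined_plate",
    "SpinningPlate",
]

# Radians of pupil-edge phase per unit of aberration amplitude; calibrated
# once on the canonical plate configuration and frozen (see docs/methods.md).
DEFOCUS_PHASE_SCALE = 40.0
SPHERICAL_PHASE_SCALE = 2500.0

# Default height -> defocus coupling (A_d per um of height above the focal
# plane).  Negative: behind the focal plane renders bright in this system.
# Magnitude puts the sub-micron height range of a 5-degree tilted plate into
# the calibrated defocus-amplitude regime where the within-object split is
# clearly resolved.
DEFAULT_DEFOCUS_PER_UM = -0.5


class InvalidModelError(ValueError):
    """Raised for non-physical aberration-model parameters."""


@dataclass(frozen=True)
class AberrationModel:
    """Pupil-plane description of the imaging system.

    Parameters
    ----------
    a_d : float
        Defocus amplitude, coefficient of the normalized pupil radius
        squared.  Positive when the object is farther from the objective
        than the focused object distance.
    a_s : float
        Spherical-aberration amplitude, coefficient of the normalized pupil
        radius to the fourth.  Its sign depends on the optical design and
        decides which side of the focal plane renders bright.
    pupil_radius : float
        Radius of the circular pupil in pupil-plane samples (frequency-grid
        pixels).  Sets the coherent resolution limit on a given grid.
    wavelength_um : float
        Illumination wavelength in micrometres.
    defocus_scale, spherical_scale : float
        Radians of pupil-edge phase per unit of ``a_d`` / ``a_s``.
    defocus_per_um : float
        Defocus amplitude accrued per micrometre of axial offset from the
        focal plane.  Converts an object's height map into per-slice ``a_d``;
        its sign is the system's contrast polarity (the default renders
        objects behind the focal plane bright).
    pupil_taper : float
        Fraction of the pupil radius where a cosine amplitude rolloff
        begins (1.0 = hard aperture).  The soft edge suppresses the strong
        coherent Airy ringing a hard aperture would stamp on every
        defocused feature, which real (partially coherent) bright-field
        images do not show.
    """

    a_d: float = 0.0
    a_s: float = 0.0
    pupil_radius: float = 32.0
    wavelength_um: float = 0.53
    defocus_scale: float = DEFOCUS_PHASE_SCALE
    spherical_scale: float = SPHERICAL_PHASE_SCALE
    defocus_per_um: float = DEFAULT_DEFOCUS_PER_UM
    pupil_taper: float = 0.6

    def __post_init__(self) -> None:
        if self.pupil_radius <= 0:
            raise InvalidModelError("pupil_radius must be positive")
        if self.wavelength_um <= 0:
            raise InvalidModelError("wavelength_um must be positive")

    @property
    def wavenumber(self) -> float:
        """Wavenumber ``k = 2 pi / wavelength`` in rad/um."""
        return 2.0 * np.pi / self.wavelength_um

    def with_defocus(self, a_d: float) -> "AberrationModel":
        return dataclasses.replace(self, a_d=a_d)


@dataclass
class PhaseObject:
    """A translucent object described by its phase delay and axial offset.

    ``phase_map`` is the per-pixel phase delay in radians (weak-phase regime,
    magnitudes well below 1 rad).  ``height_map`` is the signed axial offset
    of the local object surface from the focused object plane, in um;
    positive means farther from the objective ("behind" the focal plane).  A
    scalar height means the object is parallel to the lens.
    """

    phase_map: np.ndarray
    height_map: np.ndarray | float = 0.0
    pixel_pitch: float = 0.25

    def __post_init__(self) -> None:
        self.phase_map = np.asarray(self.phase_map, dtype=float)
        if not np.all(np.isfinite(self.phase_map)):
            raise ValueError("phase_map must be finite")
        if np.ndim(self.height_map) > 0:
            self.height_map = np.asarray(self.height_map, dtype=float)
            if self.height_map.shape != self.phase_map.shape:
                raise ValueError("height_map shape must match phase_map")
            if not np.all(np.isfinite(self.height_map)):
                raise ValueError("height_map must be finite")

    @property
    def footprint(self) -> np.ndarray:
        return np.abs(self.phase_map) > 1e-12

    @property
    def is_flat(self) -> bool:
        if np.ndim(self.height_map) == 0:
            return True
        fp = self.footprint
        if not fp.any():
            return True
        h = self.height_map[fp]
        return bool(np.ptp(h) < 1e-12)


@dataclass
class IntensityImage:
    """Non-negative intensity grid with its pixel pitch in um/px."""

    values: np.ndarray
    pixel_pitch: float = 0.25

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < -1e-9):
            raise ValueError("intensity values must be non-negative")
        self.values = np.clip(self.values, 0.0, None)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


# ---------------------------------------------------------------------------
# pupil / PSF


def _centered_freq_grids(shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Pupil-plane sample coordinates, zero at the grid centre."""
    ny, nx = shape
    y = np.arange(ny) - ny // 2
    x = np.arange(nx) - nx // 2
    return np.meshgrid(y, x, indexing="ij")


def wave_aberration(x, y, model: AberrationModel):
    """Wavefront error ``W = A_d rho**2 + A_s rho**4`` at pupil point (x, y).

    ``rho = sqrt(x**2 + y**2) / pupil_radius`` is the normalized pupil
    radius, so ``W(0, 0) = 0`` and pure defocus reaches ``A_d`` at the pupil
    edge.  The returned value is the optical-path coefficient, not yet
    converted to radians.
    """
    rho2 = (np.asarray(x, dtype=float) ** 2 + np.asarray(y, dtype=float) ** 2) / (
        model.pupil_radius**2
    )
    return model.a_d * rho2 + model.a_s * rho2**2


def _pupil_and_phase(model: AberrationModel, shape: tuple[int, int]):
    yy, xx = _centered_freq_grids(shape)
    rho2 = (xx.astype(float) ** 2 + yy.astype(float) ** 2) / model.pupil_radius**2
    pupil = rho2 <= 1.0
    phase = model.defocus_scale * model.a_d * rho2 + model.spherical_scale * model.a_s * rho2**2
    return pupil, phase


def pupil_function(model: AberrationModel, shape: tuple[int, int]) -> np.ndarray:
    """Complex pupil: (apodized) circular aperture times the aberration phase."""
    pupil, phase = _pupil_and_phase(model, shape)
    amp = pupil.astype(float)
    if model.pupil_taper < 1.0:
        yy, xx = _centered_freq_grids(shape)
        rho = np.sqrt(xx.astype(float) ** 2 + yy.astype(float) ** 2) / model.pupil_radius
        frac = np.clip((rho - model.pupil_taper) / max(1.0 - model.pupil_taper, 1e-9), 0.0, 1.0)
        amp = amp * 0.5 * (1.0 + np.cos(np.pi * frac))
    return amp * np.exp(1j * np.where(pupil, phase, 0.0))


def psf(model: AberrationModel, grid_shape: tuple[int, int]) -> np.ndarray:
    """Amplitude PSF: centred Fourier transform of the aberrated pupil.

    Uses a unitary transform so that the PSF energy equals the pupil energy
    (Parseval).  With ``a_d = a_s = 0`` the modulus is the Airy pattern of
    the circular aperture, peaked at the grid centre.
    """
    ny, nx = grid_shape
    if 2 * model.pupil_radius > min(ny, nx):
        raise InvalidModelError("grid smaller than the pupil support")
    p = pupil_function(model, grid_shape)
    return np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(p), norm="ortho"))


def defocus_amplitude_sign(d0: float, f: float, di: float, gain: float = 1.0) -> float:
    """Signed defocus amplitude from the thin-lens (Gauss) equation.

    ``A_d = 0`` for a focused system (``1/d0 + 1/di = 1/f``); positive when
    the object sits farther from the objective than the focused object
    distance, negative when closer.  ``gain`` sets the (arbitrary) units of
    the returned amplitude.
    """
    if d0 <= 0 or f <= 0 or di <= 0:
        raise ValueError("distances must be positive")
    # 1/f - 1/di is the focused 1/d0; a larger d0 makes 1/d0 smaller.
    return gain * ((1.0 / f - 1.0 / di) - 1.0 / d0)


# ---------------------------------------------------------------------------
# imaging


def _pad_field(field: np.ndarray, pad_factor: int) -> tuple[np.ndarray, tuple[slice, slice]]:
    """Embed the field in a unit background ``pad_factor`` times larger."""
    ny, nx = field.shape
    py, px = ny * pad_factor, nx * pad_factor
    out = np.ones((py, px), dtype=complex)
    oy, ox = (py - ny) // 2, (px - nx) // 2
    out[oy : oy + ny, ox : ox + nx] = field
    return out, (slice(oy, oy + ny), slice(ox, ox + nx))


def _padded_model(model: AberrationModel, pad_factor: int) -> AberrationModel:
    # frequency-pixel spacing shrinks on the padded grid; keep the physical
    # pupil cutoff by scaling the pupil radius with the grid
    if pad_factor == 1:
        return model
    return dataclasses.replace(model, pupil_radius=model.pupil_radius * pad_factor)


def _coherent_image(field: np.ndarray, model: AberrationModel, pad_factor: int = 1) -> np.ndarray:
    """Image a complex object field through the aberrated pupil (coherent).

    ``pad_factor`` > 1 embeds the field in a unit background before the FFT
    so that strongly defocused light spreads away instead of wrapping around
    the periodic grid; the central crop is returned.
    """
    padded, crop = _pad_field(field, pad_factor)
    ctf = np.fft.ifftshift(pupil_function(_padded_model(model, pad_factor), padded.shape))
    out = np.fft.ifft2(np.fft.fft2(padded) * ctf)
    return np.abs(out[crop]) ** 2


def _image_from_spectrum(
    spectrum: np.ndarray, model: AberrationModel, crop: tuple[slice, slice]
) -> np.ndarray:
    """As ``_coherent_image`` but reusing a precomputed padded-field FFT."""
    ctf = np.fft.ifftshift(pupil_function(model, spectrum.shape))
    out = np.fft.ifft2(spectrum * ctf)
    return np.abs(out[crop]) ** 2


def image_weak_phase_object(obj: PhaseObject, model: AberrationModel) -> IntensityImage:
    """Bright-field image of a flat weak phase object.

    The object field is the full ``exp(i phase)`` (at 0.1 rad the linearized
    form differs below any tolerance used here).  A zero phase map yields a
    uniform unit-background image.
    """
    if not obj.is_flat:
        raise ValueError("object has a non-constant height_map; use image_inclined_object")
    field = np.exp(1j * obj.phase_map)
    return IntensityImage(_coherent_image(field, model), obj.pixel_pitch)


def _height_bins(heights: np.ndarray, n_slices: int) -> np.ndarray:
    """Assign each value to one of ``n_slices`` equal-width depth bins."""
    lo, hi = float(heights.min()), float(heights.max())
    if hi - lo < 1e-12:
        return np.zeros(heights.shape, dtype=int)
    edges = np.linspace(lo, hi, n_slices + 1)
    idx = np.searchsorted(edges, heights, side="right") - 1
    return np.clip(idx, 0, n_slices - 1)


def _propagator(model: AberrationModel, shape: tuple[int, int], drop_um: float) -> np.ndarray:
    """Paraxial free-space propagator for a height drop of ``drop_um``.

    Expressed through the same defocus normalization as the pupil: dropping
    an object plane by ``drop_um`` multiplies its spectrum by the quadratic
    phase a plate at that extra height would acquire.  Defined on the full
    frequency grid (no aperture); the aperture and the spherical term are
    applied once, at the final imaging step.
    """
    yy, xx = _centered_freq_grids(shape)
    rho2 = (xx.astype(float) ** 2 + yy.astype(float) ** 2) / model.pupil_radius**2
    return np.exp(1j * model.defocus_scale * model.defocus_per_um * drop_um * rho2)


def image_inclined_object(
    obj: PhaseObject,
    model: AberrationModel,
    n_slices: int = 7,
    pad_factor: int = 1,
) -> IntensityImage:
    """Bright-field image of an object whose height varies across its footprint.

    Multi-slice coherent propagation: the object is decomposed into
    ``n_slices`` thin phase screens by equal-width height bins.  A unit
    illumination field passes the highest screen first, propagates down to
    the next screen, and so on; the exit field is propagated to the focal
    plane (height zero) and imaged through the aberrated pupil.  This keeps
    the interference between depths, which is what makes the border of an
    object *straddling* the focal plane light up on the behind side — the
    signature the rotation detector integrates.  A constant height map
    degenerates exactly to ``image_weak_phase_object`` at that height.
    """
    if n_slices < 2:
        raise ValueError("n_slices must be at least 2")
    fp = obj.footprint
    if not fp.any():
        return IntensityImage(np.ones_like(obj.phase_map), obj.pixel_pitch)

    heights = (
        np.full(obj.phase_map.shape, float(obj.height_map))
        if np.ndim(obj.height_map) == 0
        else obj.height_map
    )
    h_fp = heights[fp]
    bins = _height_bins(h_fp, n_slices)

    ny, nx = obj.phase_map.shape
    shape = (ny * pad_factor, nx * pad_factor)
    oy, ox = (shape[0] - ny) // 2, (shape[1] - nx) // 2
    crop = (slice(oy, oy + ny), slice(ox, ox + nx))
    pmodel = _padded_model(model, pad_factor)

    # per-bin phase screens (padded) and their mean heights, top first
    screens: list[tuple[float, np.ndarray]] = []
    for b in np.unique(bins):
        sel = np.zeros(fp.sum(), dtype=bool)
        sel[bins == b] = True
        mask = np.zeros(obj.phase_map.shape, dtype=bool)
        mask[fp] = sel
        screen = np.zeros(shape)
        screen[crop] = np.where(mask, obj.phase_map, 0.0)
        screens.append((float(h_fp[bins == b].mean()), screen))
    screens.sort(key=lambda hs: -hs[0])

    u = np.ones(shape, dtype=complex)
    h_current = screens[0][0]
    for h_b, screen in screens:
        if h_b < h_current - 1e-12:
            prop = np.fft.ifftshift(_propagator(pmodel, shape, h_current - h_b))
            u = np.fft.ifft2(np.fft.fft2(u) * prop)
            h_current = h_b
        u = u * np.exp(1j * screen)

    # propagate the exit field to the focal plane and image through the pupil
    spectrum = np.fft.fft2(u)
    if abs(h_current) > 1e-12:
        spectrum = spectrum * np.fft.ifftshift(_propagator(pmodel, shape, h_current))
    ctf = np.fft.ifftshift(pupil_function(pmodel.with_defocus(model.a_d), shape))
    out = np.abs(np.fft.ifft2(spectrum * ctf)[crop]) ** 2
    return IntensityImage(out, obj.pixel_pitch)


# ---------------------------------------------------------------------------
# canonical demonstration objects


def rect_phase_object(
    grid: int = 128,
    obj_px: int = 40,
    phase_rad: float = 0.1,
    pixel_pitch: float = 0.25,
) -> PhaseObject:
    """Square weak phase plate (default: central 40x40 px on a 128x128 grid)."""
    phase = np.zeros((grid, grid))
    lo = (grid - obj_px) // 2
    phase[lo : lo + obj_px, lo : lo + obj_px] = phase_rad
    return PhaseObject(phase, 0.0, pixel_pitch)


def inclined_plate(
    angle_deg: float = 5.0,
    grid: int = 128,
    obj_px: int = 40,
    phase_rad: float = 0.1,
    pixel_pitch: float = 0.25,
    tilt_axis: str = "vertical",
) -> PhaseObject:
    """Plate tilted about an in-plane axis, centre in the focal plane.

    With a vertical tilt axis, pixels to the right of centre sit closer to
    the objective (negative height) and pixels to the left sit farther away,
    matching the canonical inclined-object demonstration.
    """
    obj = rect_phase_object(grid, obj_px, phase_rad, pixel_pitch)
    yy, xx = np.meshgrid(np.arange(grid), np.arange(grid), indexing="ij")
    centre = (grid - 1) / 2.0
    along = (xx - centre) if tilt_axis == "vertical" else (yy - centre)
    heights = -along * pixel_pitch * np.tan(np.deg2rad(angle_deg))
    return PhaseObject(obj.phase_map, heights, pixel_pitch)


def signed_contrast(
    image: IntensityImage | np.ndarray,
    footprint: np.ndarray,
    erode_px: int = 2,
    annulus_px: int = 6,
) -> float:
    """Mean interior minus mean exterior intensity.

    Interior is the object footprint eroded by ``erode_px``; exterior an
    ``annulus_px``-wide ring just outside the footprint.  Positive means the
    object interior renders brighter than its surround.
    """
    values = image.values if isinstance(image, IntensityImage) else np.asarray(image)
    interior = ndimage.binary_erosion(footprint, iterations=erode_px)
    exterior = ndimage.binary_dilation(footprint, iterations=annulus_px) & ~footprint
    if not interior.any() or not exterior.any():
        raise ValueError("footprint too small for the contrast statistic")
    return float(values[interior].mean() - values[exterior].mean())


# ---------------------------------------------------------------------------
# spinning plate


@dataclass(frozen=True)
class SpinningPlate:
    """Rigid rectangular plate spinning about its long, in-plane axis.

    The long axis lies along image *y*; the across-plate material coordinate
    projects onto image *x* with a ``cos(theta)`` foreshortening while local
    height varies as ``sin(theta)``.  ``direction`` is judged looking along
    the axis from the top of the image: clockwise spin carries the
    behind-the-focal-plane (bright) side from right to left.
    """

    half_width_um: float = 5.0
    half_length_um: float = 5.0
    phase_rad: float = 0.1
    pixel_pitch: float = 0.25

    def phase_and_height(self, theta: float, grid: int) -> PhaseObject:
        yy, xx = np.meshgrid(np.arange(grid), np.arange(grid), indexing="ij")
        centre = (grid - 1) / 2.0
        x_um = (xx - centre) * self.pixel_pitch
        y_um = (yy - centre) * self.pixel_pitch
        c, s = np.cos(theta), np.sin(theta)
        proj_half = max(abs(c) * self.half_width_um, self.pixel_pitch)
        inside = (np.abs(x_um) <= proj_half) & (np.abs(y_um) <= self.half_length_um)
        phase = np.where(inside, self.phase_rad, 0.0)
        if abs(c) > 1e-6:
            material = np.clip(x_um / c, -self.half_width_um, self.half_width_um)
        else:
            material = np.zeros_like(x_um)
        heights = np.where(inside, material * s, 0.0)
        return PhaseObject(phase, heights, self.pixel_pitch)


def render_spinning_sequence(
    plate: SpinningPlate,
    direction: str,
    n_frames: int = 12,
    n_half_turns: int = 2,
    model: AberrationModel | None = None,
    grid: int = 128,
    theta0: float = 0.0,
    n_slices: int = 7,
) -> tuple[list[IntensityImage], np.ndarray]:
    """Render a plate spinning through ``n_half_turns`` half rotations.

    ``direction`` is "cw" or "ccw" viewed from the top of the image along
    the rotation axis.  Returns the frames and the roll angle per frame.
    The bright-region centroid drifts monotonically within each half turn —
    right-to-left for CW, left-to-right for CCW — and resets at each half
    turn.
    """
    if n_frames < 3:
        raise ValueError("need at least 3 frames to span a half rotation")
    if direction not in ("cw", "ccw"):
        raise ValueError("direction must be 'cw' or 'ccw'")
    if plate.half_width_um <= 0 or plate.half_length_um <= 0:
        raise ValueError("zero-area plate")
    if model is None:
        # spherical amplitude -0.004, peak defocus 0.2 at the plate edge
        model = AberrationModel(a_s=-0.004, defocus_per_um=-0.2 / plate.half_width_um)
    if model.a_s == 0:
        raise ValueError("spinning-plate contrast requires a_s != 0")
    sign = 1.0 if direction == "cw" else -1.0
    thetas = theta0 + sign * np.linspace(0, n_half_turns * np.pi, n_frames, endpoint=False)
    frames = []
    for th in thetas:
        obj = plate.phase_and_height(float(th), grid)
        frames.append(image_inclined_object(obj, model, n_slices=n_slices))
    return frames, thetas


def bright_centroid_x(
    image: IntensityImage, background: float = 1.0, mask: np.ndarray | None = None
) -> float:
    """Centroid (image-x, px) of above-background intensity; NaN if none.

    ``mask`` restricts the centroid to a region of interest — for a spinning
    plate, its footprint, since the claimed drift signature concerns the
    bright part *of* the inclined object, not the exterior halo.
    """
    excess = np.clip(image.values - background, 0.0, None)
    if mask is not None:
        excess = excess * mask
    total = excess.sum()
    if total <= 1e-12:
        return float("nan")
    xx = np.arange(image.values.shape[1])
    return float((excess.sum(axis=0) * xx).sum() / total)


def drift_direction(centroids: np.ndarray, thetas: np.ndarray) -> str:
    """Classify a spinning-plate sequence from its bright-centroid drift.

    Uses the within-half-turn displacements of the bright-region centroid.
    Displacements that span a half-turn boundary (the reset: bright and dark
    regions jump back to their starting side) or that touch a near-flat pose
    (|sin theta| < 0.25, where the tilt signature vanishes) are excluded.
    Returns "cw" for net right-to-left drift, "ccw" for net left-to-right,
    judged looking along the rotation axis from the top of the image.
    """
    centroids = np.asarray(centroids, dtype=float)
    thetas = np.asarray(thetas, dtype=float)
    half_index = np.floor(np.abs(thetas - thetas[0]) / np.pi).astype(int)
    deltas = []
    for i in range(1, len(centroids)):
        if half_index[i] != half_index[i - 1]:
            continue  # reset between half turns
        if min(abs(np.sin(thetas[i])), abs(np.sin(thetas[i - 1]))) < 0.25:
            continue  # near-flat pose: no tilt signature
        if np.isnan(centroids[i]) or np.isnan(centroids[i - 1]):
            continue
        deltas.append(centroids[i] - centroids[i - 1])
    if not deltas:
        raise ValueError("no usable displacements in sequence")
    return "cw" if float(np.median(deltas)) < 0 else "ccw"


def spinning_drift_call(
    plate: SpinningPlate,
    direction: str,
    n_frames: int = 12,
    n_half_turns: int = 2,
    model: AberrationModel | None = None,
    grid: int = 128,
    theta0: float = 0.0,
) -> str:
    """Render a spinning plate and recover its direction from the drift."""
    frames, thetas = render_spinning_sequence(
        plate, direction, n_frames=n_frames, n_half_turns=n_half_turns,
        model=model, grid=grid, theta0=theta0,
    )
    centroids = [
        bright_centroid_x(f, mask=plate.phase_and_height(float(th), grid).footprint)
        for f, th in zip(frames, thetas)
    ]
    return drift_direction(np.asarray(centroids), thetas)
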