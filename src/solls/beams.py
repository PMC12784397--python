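"""Light-sheet construction: slit-mask lattice sheets and Gaussian sheets.

The lattice sheet is generated the way the instrument generates it: a
binary multi-slit photomask of finite optical density, illuminated by
an expanded Gaussian laser spot, is placed conjugate to the back focal
plane of the objective; the objective Fourier-maps the pupil field to
the sample, and a galvo dithers the sheet along its width (y) to
time-average the lattice period into a uniform profile.  The Gaussian
reference sheet is a 1-D focused Gaussian (thin in z, collimated
envelope in y), as produced by a cylindrical lens.

Mask geometry is specified in millimetres (the natural unit at the
pupil) and converted to µm internally.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .fields import (BeamVolume, OpticalTrain, ScalarField, lens_fourier,
                     synthesize_volume)
from .metrics import one_over_e2_radius

__all__ = [
    "MaskSpec",
    "SheetSpec",
    "SteeringState",
    "MirrorSpec",
    "mask_transmission",
    "make_lattice_sheet",
    "make_gaussian_sheet",
    "apply_dither",
    "steer_sheet",
    "reflect_at_mirror",
    "mirror_tilt_deg",
]

MM = 1000.0  # µm per mm


@dataclasses.dataclass
class MaskSpec:
    """Binary slit photomask at the back focal plane.

    Slits are rectangles, narrow along y (width) and long along z
    (length); their y-centres are listed in ``slit_centers``.  Outside
    the slits the chrome transmits ``10**(-OD)`` in intensity.  The
    ``illumination_radius`` is the 1/e² intensity radius of the
    expanded laser spot illuminating the mask — it apodizes the slit
    apertures and is scaled together with the mask geometry.
    """

    slit_centers: tuple[float, ...] = (-1.2, 0.0, 1.2)  # mm
    slit_width: float = 0.08        # mm
    slit_length: float = 2.0        # mm
    optical_density: float = 5.2
    illumination_radius: float = 3.0  # mm, 1/e² intensity radius

    def __post_init__(self) -> None:
        if self.slit_width <= 0 or self.slit_length <= 0:
            raise ValueError("slit dimensions must be positive")
        if self.optical_density < 0:
            raise ValueError("optical density must be >= 0")
        if self.illumination_radius <= 0:
            raise ValueError("illumination radius must be positive")
        c = np.sort(np.asarray(self.slit_centers, float))
        if len(c) > 1 and not np.allclose(c, -c[::-1], atol=1e-9):
            raise ValueError("slit centres must be symmetric about 0")

    @property
    def outer_separation(self) -> float:
        """Distance between the outer slit centres, mm."""
        c = np.asarray(self.slit_centers, float)
        return float(c.max() - c.min())

    def scaled(self, factor: float) -> "MaskSpec":
        """All mask-plane coordinates multiplied by ``factor``."""
        return MaskSpec(tuple(c * factor for c in self.slit_centers),
                        self.slit_width * factor, self.slit_length * factor,
                        self.optical_density,
                        self.illumination_radius * factor)


@dataclasses.dataclass
class SheetSpec:
    """Target light-sheet parameters (1/e² intensity radii, µm)."""

    family: str = "lattice"          # lattice | gaussian
    target_waist_w0: float = 1.8     # µm, focal thickness
    width_target: float = 32.9       # µm, sheet half-width (Gaussian family)
    dither_amplitude_um: float = 3.5  # galvo sine amplitude at the sample

    def __post_init__(self) -> None:
        if self.family not in ("lattice", "gaussian"):
            raise ValueError("family must be 'lattice' or 'gaussian'")
        if self.target_waist_w0 <= 0:
            raise ValueError("target waist must be positive")


@dataclasses.dataclass
class SteeringState:
    """Calibrated linear galvo / tunable-lens steering signals.

    Slopes are the bench calibrations: 0.64 µm axial (z) and 0.35 µm
    in-plane (y) per 0.01 V on the galvos, and 2.41 µm of focus shift
    (x) per 10 mA on the tunable lens.  ``family_multiplier`` rescales
    the galvo slopes per sheet family (the Gaussian path, lacking the
    beam-shrinking relay, responds 2x differently).
    """

    galvo_z_volts: float = 0.0
    galvo_y_volts: float = 0.0
    tunable_lens_mA: float = 0.0
    slope_z_um_per_001V: float = 0.64
    slope_y_um_per_001V: float = 0.35
    slope_x_um_per_10mA: float = 2.41
    family_multiplier: float = 1.0

    def displacement(self) -> tuple[float, float, float]:
        """(Δx, Δy, Δz) in µm for the current signals."""
        for s in (self.slope_z_um_per_001V, self.slope_y_um_per_001V,
                  self.slope_x_um_per_10mA, self.family_multiplier):
            if not np.isfinite(s):
                raise ValueError("calibration slopes must be finite")
        dx = self.tunable_lens_mA / 10.0 * self.slope_x_um_per_10mA
        dy = self.galvo_y_volts / 0.01 * self.slope_y_um_per_001V * self.family_multiplier
        dz = self.galvo_z_volts / 0.01 * self.slope_z_um_per_001V * self.family_multiplier
        return (dx, dy, dz)


@dataclasses.dataclass
class MirrorSpec:
    """Reflective micromirror insert; wall angle relative to the coverslip."""

    wall_angle_deg: float = 39.0

    def __post_init__(self) -> None:
        if not (0.0 < self.wall_angle_deg < 90.0):
            raise ValueError("wall angle must be in (0, 90) degrees")


# ---------------------------------------------------------------------------
# mask and pupil field


def mask_transmission(mask: MaskSpec, train: OpticalTrain, n_grid: int = 1024,
                      extent_mm: float = 12.0) -> ScalarField:
    """Real amplitude transmittance of the slit mask on a BFP grid.

    Amplitude is 1 inside a slit and ``10**(-OD/2)`` outside; slit edges
    are area-weighted over the pixel they cross.  Raises if any slit
    extends beyond the pupil radius NA·f.
    """
    pupil = train.pupil_radius  # µm
    half_len = mask.slit_length * MM / 2.0
    for c in mask.slit_centers:
        edge = np.hypot(abs(c * MM) + mask.slit_width * MM / 2.0, half_len)
        if edge > pupil:
            raise ValueError(
                f"slit at {c} mm extends to {edge / MM:.3f} mm, outside the "
                f"pupil radius {pupil / MM:.3f} mm")
    d = extent_mm * MM / n_grid
    field = ScalarField(np.zeros((n_grid, n_grid)), d, d,
                        train.wavelength_vac, train.sample_index)
    y, z = field.axes()
    t_out = 10.0 ** (-mask.optical_density / 2.0)

    # fractional pixel coverage of the slit rectangle, separable in y and z
    def coverage(coord: np.ndarray, center: float, full: float) -> np.ndarray:
        lo, hi = center - full / 2.0, center + full / 2.0
        return np.clip((np.minimum(coord + d / 2, hi)
                        - np.maximum(coord - d / 2, lo)) / d, 0.0, 1.0)

    cov = np.zeros((n_grid, n_grid))
    cz = coverage(z, 0.0, mask.slit_length * MM)
    for c in mask.slit_centers:
        cy = coverage(y, c * MM, mask.slit_width * MM)
        cov = np.maximum(cov, cy[:, None] * cz[None, :])
    field.amplitude = (t_out + (1.0 - t_out) * cov).astype(complex)
    return field


def _illuminated_mask_field(mask: MaskSpec, train: OpticalTrain,
                            n_grid: int, extent_mm: float) -> ScalarField:
    field = mask_transmission(mask, train, n_grid, extent_mm)
    y, z = field.axes()
    r_i = mask.illumination_radius * MM
    envelope = np.exp(-(y[:, None] ** 2 + z[None, :] ** 2) / r_i**2)
    field.amplitude = field.amplitude * envelope
    return field


def _crop_center(field: ScalarField, ny: int, nz: int) -> ScalarField:
    fy, fz = field.shape
    sy, sz = (fy - ny) // 2, (fz - nz) // 2
    return ScalarField(field.amplitude[sy:sy + ny, sz:sz + nz],
                       field.dy, field.dz, field.wavelength_vac,
                       field.medium_index)


def _dither_average(inten: np.ndarray, dy: float, amplitude_um: float,
                    n_phases: int = 64) -> np.ndarray:
    """Average intensity over whole-voxel sine-dwell y-shifts (axis 0)."""
    if amplitude_um <= 0:
        return inten
    phases = 2.0 * np.pi * (np.arange(n_phases) + 0.5) / n_phases
    shifts = np.round(amplitude_um * np.sin(phases) / dy).astype(int)
    return sum(np.roll(inten, s, axis=0) for s in shifts) / n_phases


def _focal_thickness(focal: ScalarField, dither_amplitude_um: float = 0.0) -> float:
    """Fitted 1/e² z-radius of the (optionally dithered) |E|² at the
    y-centre of mass — the thickness the synthesized sheet will show."""
    inten = _dither_average(np.abs(focal.amplitude) ** 2, focal.dy,
                            dither_amplitude_um)
    ysum = inten.sum(axis=1)
    iy = int(np.round(np.sum(np.arange(len(ysum)) * ysum) / ysum.sum()))
    return one_over_e2_radius(inten[iy], focal.dz)


def lattice_focal_field(mask: MaskSpec, train: OpticalTrain,
                        spec: SheetSpec, n_grid: int = 1024,
                        extent_mm: float = 12.0,
                        crop: tuple[int, int] = (256, 512),
                        max_iter: int = 3, tol: float = 0.02):
    """Focal-plane field of the auto-scaled lattice mask.

    The mask coordinates (and illumination radius) are multiplied by a
    single factor so the fitted focal 1/e² thickness matches
    ``spec.target_waist_w0``; because the lens mapping is an exact
    Fourier transform, focal size scales inversely with mask size, so
    one or two corrections converge.

    Returns ``(field, scaled_mask)``.
    """
    scale = 1.0
    current = mask
    for _ in range(max_iter):
        bfp = _illuminated_mask_field(current, train, n_grid, extent_mm)
        focal = lens_fourier(bfp, train.objective_focal_length)
        focal = _crop_center(focal, *crop)
        w = _focal_thickness(focal, spec.dither_amplitude_um)
        if abs(w - spec.target_waist_w0) <= tol * spec.target_waist_w0:
            return focal, current
        scale = w / spec.target_waist_w0
        current = current.scaled(scale)
        half_len = current.slit_length * MM / 2.0
        outer = max(abs(c) for c in current.slit_centers) * MM
        if np.hypot(outer + current.slit_width * MM / 2, half_len) > train.pupil_radius:
            raise ValueError(
                f"requested waist {spec.target_waist_w0} µm needs mask scale "
                f"{scale:.2f}, pushing slits outside the pupil (NA limit)")
    return focal, current


def make_lattice_sheet(mask: MaskSpec, train: OpticalTrain, spec: SheetSpec,
                       x_span: float = 60.0, n_planes: int = 121,
                       n_grid: int = 1024, extent_mm: float = 12.0,
                       crop: tuple[int, int] = (256, 512),
                       dither: bool = True) -> BeamVolume:
    """Dithered lattice light-sheet intensity volume over x ∈ ±x_span."""
    focal, _ = lattice_focal_field(mask, train, spec, n_grid, extent_mm, crop)
    vol = synthesize_volume(focal, -x_span, x_span, n_planes)
    if dither and spec.dither_amplitude_um > 0:
        vol = apply_dither(vol, "y", spec.dither_amplitude_um)
    return vol


def gaussian_focal_field(spec: SheetSpec, train: OpticalTrain,
                         shape: tuple[int, int] = (256, 512),
                         pitch: float | None = None) -> ScalarField:
    """Focal field of a cylindrical-lens Gaussian sheet.

    Gaussian with 1/e² intensity radius ``target_waist_w0`` along z; a
    flat-topped (10th-order super-Gaussian) collimated envelope of 1/e²
    radius ``width_target`` along y.
    """
    w0 = spec.target_waist_w0
    w_min = train.wavelength_vac / (np.pi * train.NA) * train.sample_index
    if w0 < w_min:
        raise ValueError(f"waist {w0} µm below the diffraction limit {w_min:.3f} µm")
    if pitch is None:
        lam_med = train.wavelength_vac / train.sample_index
        pitch = lam_med * train.objective_focal_length / (12.0 * MM)
    field = ScalarField(np.zeros(shape), pitch, pitch,
                        train.wavelength_vac, train.sample_index)
    y, z = field.axes()
    amp_z = np.exp(-z**2 / w0**2)                      # intensity 1/e² radius w0
    amp_y = np.exp(-((y / spec.width_target) ** 10))   # flat across the window
    field.amplitude = (amp_y[:, None] * amp_z[None, :]).astype(complex)
    return field


def make_gaussian_sheet(spec: SheetSpec, train: OpticalTrain,
                        x_span: float = 60.0, n_planes: int = 121,
                        shape: tuple[int, int] = (256, 512)) -> BeamVolume:
    """Gaussian light-sheet intensity volume over x ∈ ±x_span."""
    focal = gaussian_focal_field(spec, train, shape)
    return synthesize_volume(focal, -x_span, x_span, n_planes)


# ---------------------------------------------------------------------------
# dithering, steering, mirror


def apply_dither(volume: BeamVolume, axis: str = "y",
                 amplitude_um: float = 3.5, n_phases: int = 64) -> BeamVolume:
    """Time-average over one period of sinusoidal lateral dithering.

    The volume is averaged over ``n_phases`` equally spaced phases of a
    sine displacement of the given amplitude (uniform time sampling
    yields the sine-dwell weighting automatically).  Displacements are
    rounded to whole voxels and applied periodically, so the per-plane
    summed intensity is conserved exactly.
    """
    if amplitude_um < 0:
        raise ValueError("dither amplitude must be >= 0")
    if axis != "y":
        raise ValueError("dithering is along the width axis 'y'")
    if amplitude_um == 0:
        return volume.copy()
    phases = 2.0 * np.pi * (np.arange(n_phases) + 0.5) / n_phases
    shifts = np.round(amplitude_um * np.sin(phases) / volume.dy).astype(int)
    acc = np.zeros_like(volume.intensity)
    for s in shifts:
        acc += np.roll(volume.intensity, s, axis=1)
    return BeamVolume(acc / n_phases, volume.dx, volume.dy, volume.dz,
                      volume.origin)


def steer_sheet(volume: BeamVolume, state: SteeringState) -> BeamVolume:
    """Translate the sheet by the calibrated linear response to the signals.

    The translation is applied exactly, by moving the volume's
    sample-frame origin, so composed steers add without resampling loss.
    """
    dx, dy, dz = state.displacement()
    extents = (volume.shape[0] * volume.dx, volume.shape[1] * volume.dy,
               volume.shape[2] * volume.dz)
    for shift, extent, name in zip((dx, dy, dz), extents, "xyz"):
        if abs(shift) > extent:
            raise ValueError(f"steer of {shift:.2f} µm along {name} exceeds "
                             f"the volume extent {extent:.2f} µm")
    origin = (volume.origin[0] + dx, volume.origin[1] + dy, volume.origin[2] + dz)
    return BeamVolume(volume.intensity.copy(), volume.dx, volume.dy,
                      volume.dz, origin)


def mirror_tilt_deg(mirror: MirrorSpec) -> float:
    """Downward tilt of the reflected propagation axis vs the coverslip.

    A vertically launched beam reflected by a wall at ``α`` to the
    coverslip leaves at 2·(45° − α) below horizontal (specular
    reflection); α = 45° sends the sheet exactly horizontally.
    """
    return 2.0 * (45.0 - mirror.wall_angle_deg)


def _shear(vol: np.ndarray, shear_axis: int, coord_axis: int,
           factor: float, pitches: tuple[float, float, float]) -> np.ndarray:
    """Shear: shift along ``shear_axis`` by factor · coordinate(coord_axis).

    Each line is shifted periodically with linear interpolation, which
    conserves the line sum exactly.
    """
    n_shift = vol.shape[shear_axis]
    n_coord = vol.shape[coord_axis]
    coords = (np.arange(n_coord) - n_coord // 2) * pitches[coord_axis]
    shifts = factor * coords / pitches[shear_axis]
    k = np.floor(shifts).astype(int)
    f = shifts - k
    out = np.empty_like(vol)
    idx = [slice(None)] * 3
    for j in range(n_coord):
        idx[coord_axis] = j
        line = vol[tuple(idx)]
        ax = shear_axis if shear_axis < coord_axis else shear_axis - 1
        out[tuple(idx)] = ((1.0 - f[j]) * np.roll(line, k[j], axis=ax)
                           + f[j] * np.roll(line, k[j] + 1, axis=ax))
    return out


def reflect_at_mirror(volume: BeamVolume, mirror: MirrorSpec) -> BeamVolume:
    """Rotate the sheet volume into the sample frame set by the mirror.

    Implemented as a rigid rotation in the (x, z) plane by the specular
    tilt angle, decomposed into three periodic shears so the total
    intensity is conserved to machine precision.  No re-diffraction at
    the mirror is modelled (the mirror is flat and large compared with
    the beam).
    """
    theta = np.deg2rad(mirror_tilt_deg(mirror))
    if theta == 0.0:
        return volume.copy()
    pitches = (volume.dx, volume.dy, volume.dz)
    a = -np.tan(theta / 2.0)
    b = np.sin(theta)
    out = _shear(volume.intensity, 0, 2, a, pitches)
    out = _shear(out, 2, 0, b, pitches)
    out = _shear(out, 0, 2, a, pitches)
    return BeamVolume(out, volume.dx, volume.dy, volume.dz, volume.origin)
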