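"""Scalar Fourier-optics core: fields, propagation, lens mapping, volume synthesis.

All lengths are in micrometres (µm) internally.  The coordinate
convention throughout the package is right-handed with ``x`` the
propagation direction, ``y`` the sheet-width direction and ``z`` the
sheet-thickness direction.  A :class:`ScalarField` lives in one
transverse (y, z) plane; its 2-D amplitude array is indexed
``amplitude[iy, iz]``.
"""

from __future__ import annotations

import dataclasses
import pathlib
import warnings

import numpy as np
import tifffile
import yaml

__all__ = [
    "ScalarField",
    "OpticalTrain",
    "BeamVolume",
    "propagate_angular_spectrum",
    "lens_fourier",
    "synthesize_volume",
    "read_volume",
    "write_volume",
]


@dataclasses.dataclass
class ScalarField:
    """Complex scalar optical field sampled on one transverse plane.

    Parameters
    ----------
    amplitude : ndarray, complex, shape (ny, nz)
        Complex field amplitude; ``|amplitude|**2`` is intensity.
    dy, dz : float
        Grid spacing along the two transverse axes, µm.
    wavelength_vac : float
        Vacuum wavelength, µm.
    medium_index : float
        Refractive index of the propagation medium (>= 1).
    """

    amplitude: np.ndarray
    dy: float
    dz: float
    wavelength_vac: float
    medium_index: float = 1.0

    def __post_init__(self) -> None:
        self.amplitude = np.asarray(self.amplitude, dtype=complex)
        if self.amplitude.ndim != 2:
            raise ValueError("amplitude must be a 2-D array")
        if self.dy <= 0 or self.dz <= 0:
            raise ValueError("grid spacings must be positive")
        if self.wavelength_vac <= 0:
            raise ValueError("wavelength must be positive")
        if self.medium_index < 1:
            raise ValueError("medium_index must be >= 1")

    @property
    def shape(self) -> tuple[int, int]:
        return self.amplitude.shape

    @property
    def wavelength(self) -> float:
        """Wavelength in the medium, µm."""
        return self.wavelength_vac / self.medium_index

    @property
    def wavenumber(self) -> float:
        """Medium wavenumber k·n = 2π n / λ_vac, rad/µm."""
        return 2.0 * np.pi * self.medium_index / self.wavelength_vac

    def power(self) -> float:
        """Total power ∑|E|² dy dz."""
        return float(np.sum(np.abs(self.amplitude) ** 2) * self.dy * self.dz)

    def axes(self) -> tuple[np.ndarray, np.ndarray]:
        """Centred y and z coordinate vectors, µm."""
        ny, nz = self.amplitude.shape
        y = (np.arange(ny) - ny // 2) * self.dy
        z = (np.arange(nz) - nz // 2) * self.dz
        return y, z

    def copy(self) -> "ScalarField":
        return ScalarField(self.amplitude.copy(), self.dy, self.dz,
                           self.wavelength_vac, self.medium_index)


@dataclasses.dataclass
class OpticalTrain:
    """Objective / illumination-train parameters.

    Defaults describe a 100x / NA 1.45 oil-immersion objective used with
    560 nm excitation into an aqueous sample.  The focal length assumes
    the common 180 mm tube-lens standard divided by the magnification;
    it is configurable because it is rig-specific.
    """

    NA: float = 1.45
    objective_focal_length: float = 1800.0  # µm
    immersion_index: float = 1.518
    sample_index: float = 1.33
    wavelength_vac: float = 0.560  # µm

    def __post_init__(self) -> None:
        if not (0 < self.NA <= self.immersion_index):
            raise ValueError("require 0 < NA <= immersion_index")
        if self.objective_focal_length <= 0:
            raise ValueError("focal length must be positive")

    @property
    def pupil_radius(self) -> float:
        """Back-focal-plane pupil radius NA·f, µm."""
        return self.NA * self.objective_focal_length


@dataclasses.dataclass
class BeamVolume:
    """Real-valued 3-D intensity volume.

    ``intensity`` is indexed ``[ix, iy, iz]`` with x the propagation
    axis, y the width axis and z the thickness axis.  ``origin`` gives
    the sample-frame coordinates of voxel (0, 0, 0); voxel centres sit
    at ``origin + index * pitch``.
    """

    intensity: np.ndarray
    dx: float
    dy: float
    dz: float
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim != 3:
            raise ValueError("intensity must be 3-D (x, y, z)")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be non-negative")
        if min(self.dx, self.dy, self.dz) <= 0:
            raise ValueError("voxel pitches must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensity.shape

    def x_positions(self) -> np.ndarray:
        return self.origin[0] + np.arange(self.shape[0]) * self.dx

    def y_positions(self) -> np.ndarray:
        return self.origin[1] + np.arange(self.shape[1]) * self.dy

    def z_positions(self) -> np.ndarray:
        return self.origin[2] + np.arange(self.shape[2]) * self.dz

    def interp_at(self, x: np.ndarray, y: np.ndarray, z: np.ndarray) -> np.ndarray:
        """Trilinear intensity lookup at sample-frame points (0 outside)."""
        from scipy.interpolate import RegularGridInterpolator

        interp = RegularGridInterpolator(
            (self.x_positions(), self.y_positions(), self.z_positions()),
            self.intensity, bounds_error=False, fill_value=0.0)
        pts = np.stack([np.atleast_1d(x), np.atleast_1d(y), np.atleast_1d(z)], axis=-1)
        return interp(pts)

    def copy(self) -> "BeamVolume":
        return BeamVolume(self.intensity.copy(), self.dx, self.dy, self.dz, self.origin)


# ---------------------------------------------------------------------------
# propagation


def _spectrum_padded(field: ScalarField, pad_factor: int = 2):
    """Zero-padded 2-D spectrum and the padded-plane frequency grids."""
    ny, nz = field.shape
    py, pz = ny * pad_factor, nz * pad_factor
    buf = np.zeros((py, pz), dtype=complex)
    buf[:ny, :nz] = field.amplitude
    # roll so the original field is centred in the padded frame: keeps the
    # crop window trivially at the front corner after the inverse roll
    spec = np.fft.fft2(buf)
    ky = 2.0 * np.pi * np.fft.fftfreq(py, field.dy)
    kz = 2.0 * np.pi * np.fft.fftfreq(pz, field.dz)
    return spec, ky[:, None], kz[None, :]


def _check_band_limit(field: ScalarField) -> None:
    kn = field.wavenumber
    ny_y = np.pi / field.dy
    ny_z = np.pi / field.dz
    if kn > np.sqrt(ny_y**2 + ny_z**2):
        raise ValueError(
            "grid too coarse: propagating band limit k·n exceeds grid Nyquist; "
            f"need dy,dz < {np.pi / kn:.4g} µm combined")


def propagate_angular_spectrum(field: ScalarField, distance: float,
                               pad_factor: int = 2) -> ScalarField:
    """Free-space propagation by the angular-spectrum method.

    The 2-D spectrum is multiplied by ``exp(i·d·sqrt(k²n² − ky² − kz²))``;
    evanescent components (ky² + kz² > k²n²) are zeroed.  The field is
    zero-padded by ``pad_factor`` before the spectral multiply to
    suppress periodic wrap-around.

    Power carried by propagating components is conserved exactly
    (the kernel is a pure phase on the propagating band).
    """
    if not np.isfinite(distance):
        raise ValueError("propagation distance must be finite")
    if distance == 0.0:
        return field.copy()
    _check_band_limit(field)
    spec, ky, kz = _spectrum_padded(field, pad_factor)
    kn2 = field.wavenumber**2
    kt2 = ky**2 + kz**2
    kx = np.sqrt(np.maximum(kn2 - kt2, 0.0))
    kernel = np.where(kt2 <= kn2, np.exp(1j * kx * distance), 0.0)
    out = np.fft.ifft2(spec * kernel)
    ny, nz = field.shape
    return ScalarField(out[:ny, :nz], field.dy, field.dz,
                       field.wavelength_vac, field.medium_index)


def lens_fourier(field: ScalarField, focal_length: float) -> ScalarField:
    """Ideal-lens 2f mapping: field in the front focal plane -> back focal plane.

    Implements the exact Fourier relation of an aberration-free thin
    lens, with the output plane sampled at ``λf / (N·d)`` so the DFT is
    unitary and Parseval power equality holds to machine precision.
    The (physically irrelevant) constant phase 1/(iλf) is dropped.
    """
    if focal_length <= 0:
        raise ValueError("focal_length must be positive")
    lam = field.wavelength_vac / field.medium_index
    ny, nz = field.shape
    amp = np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(field.amplitude)))
    # unitary scaling: |out|² du dv  ==  |in|² dy dz
    dy_out = lam * focal_length / (ny * field.dy)
    dz_out = lam * focal_length / (nz * field.dz)
    amp *= field.dy * field.dz / (lam * focal_length)
    return ScalarField(amp, dy_out, dz_out, field.wavelength_vac, field.medium_index)


def synthesize_volume(focal_field: ScalarField, x_min: float, x_max: float,
                      n_planes: int, pad_factor: int = 2) -> BeamVolume:
    """Assemble an intensity volume by propagating a focal field plane by plane.

    Plane ``j`` of the result is ``|propagate(focal_field, x_j)|²`` with
    ``x_j`` uniformly spaced over [x_min, x_max].  The forward FFT is
    computed once and reused for every plane.
    """
    if n_planes < 2:
        raise ValueError("n_planes must be >= 2")
    if not (x_min < x_max):
        raise ValueError("require x_min < x_max")
    _check_band_limit(focal_field)
    spec, ky, kz = _spectrum_padded(focal_field, pad_factor)
    kn2 = focal_field.wavenumber**2
    kt2 = ky**2 + kz**2
    propagating = kt2 <= kn2
    kx = np.sqrt(np.maximum(kn2 - kt2, 0.0))
    xs = np.linspace(x_min, x_max, n_planes)
    ny, nz = focal_field.shape
    vol = np.empty((n_planes, ny, nz))
    for j, x in enumerate(xs):
        if x == 0.0:
            vol[j] = np.abs(focal_field.amplitude) ** 2
            continue
        kernel = np.where(propagating, np.exp(1j * kx * x), 0.0)
        plane = np.fft.ifft2(spec * kernel)[:ny, :nz]
        vol[j] = np.abs(plane) ** 2
    y0, z0 = focal_field.axes()
    return BeamVolume(vol, dx=(x_max - x_min) / (n_planes - 1),
                      dy=focal_field.dy, dz=focal_field.dz,
                      origin=(x_min, y0[0], z0[0]))


# ---------------------------------------------------------------------------
# I/O: multi-page float32 TIFF + YAML sidecar carrying the grid metadata


def write_volume(volume: BeamVolume, path: str | pathlib.Path) -> None:
    """Write a BeamVolume as a multi-page 32-bit float TIFF (one page per
    x-plane) plus a ``<path>.yaml`` sidecar with pitches and origin."""
    path = pathlib.Path(path)
    tifffile.imwrite(path, volume.intensity.astype(np.float32),
                     photometric="minisblack")
    meta = {"dx_um": float(volume.dx), "dy_um": float(volume.dy),
            "dz_um": float(volume.dz),
            "origin_um": [float(v) for v in volume.origin],
            "axes": "x=propagation, y=width, z=thickness"}
    path.with_suffix(path.suffix + ".yaml").write_text(
        yaml.safe_dump(meta, sort_keys=False))


def read_volume(path: str | pathlib.Path) -> BeamVolume:
    """Read a BeamVolume written by :func:`write_volume`."""
    path = pathlib.Path(path)
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    sidecar = path.with_suffix(path.suffix + ".yaml")
    if sidecar.exists():
        meta = yaml.safe_load(sidecar.read_text())
        return BeamVolume(np.asarray(data, float), meta["dx_um"], meta["dy_um"],
                          meta["dz_um"], tuple(meta["origin_um"]))
    warnings.warn(f"no sidecar {sidecar.name}; assuming unit voxel pitch")
    return BeamVolume(np.asarray(data, float), 1.0, 1.0, 1.0)
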