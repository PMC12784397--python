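"""Synthetic single-molecule movies: phantoms, PSF rendering, EMCCD noise.

Emitters blink with per-frame Bernoulli kinetics (a PAINT-like
approximation), are excited in proportion to the local illumination
intensity (a sheet :class:`~solls.fields.BeamVolume`, or uniformly for
epi-illumination), are rendered with a pixel-integrated 2-D Gaussian
or a double-helix (DH) PSF, and are read out through the EMCCD gain
chain: Poisson shot noise → Gamma electron multiplication → Gaussian
read noise → A/D conversion plus a dark offset.
"""

from __future__ import annotations

import dataclasses
import pathlib

import numpy as np
import pandas as pd
import tifffile
import yaml
from scipy.special import erf

from .fields import BeamVolume

__all__ = ["CameraModel", "PSFModel", "EmitterSet", "make_cell_phantom",
           "render_psf", "simulate_frames", "write_movie"]


@dataclasses.dataclass
class CameraModel:
    """EMCCD gain chain and pixel geometry.

    Defaults are bench calibrations of an iXon Ultra 897: EM gain 182,
    4.41 photoelectrons per A/D count, dark level 500 counts, pixel
    pitch 157 nm (horizontal) × 159 nm (vertical) in the sample plane.
    The Gamma-distributed electron-multiplication register doubles the
    shot-noise variance (excess noise factor 2).
    """

    em_gain: float = 182.0
    conversion_gain: float = 4.41     # photoelectrons per A/D count
    dark_level: float = 500.0         # A/D counts
    read_noise: float = 20.0          # electrons rms at the output register
    pixel_size_x: float = 0.157       # µm
    pixel_size_y: float = 0.159       # µm
    excess_noise_factor: float = 2.0

    def __post_init__(self) -> None:
        if min(self.em_gain, self.conversion_gain) <= 0:
            raise ValueError("gains must be positive")
        if min(self.pixel_size_x, self.pixel_size_y) <= 0:
            raise ValueError("pixel sizes must be positive")

    def photons_from_adu(self, adu: np.ndarray) -> np.ndarray:
        """Dark-subtracted A/D counts converted to expected photons."""
        return (np.asarray(adu, float) - self.dark_level) \
            * self.conversion_gain / self.em_gain

    def adu_per_photon(self) -> float:
        return self.em_gain / self.conversion_gain


@dataclasses.dataclass
class PSFModel:
    """Gaussian or double-helix point-spread function.

    The DH-PSF renders two Gaussian lobes separated by
    ``dh_separation`` whose axis rotates linearly with emitter depth,
    θ(z) = θ0 + rate·z; the commercial short- and long-range phase
    masks are represented by the two constructors (their exact
    rotation parameters are not public; these defaults are
    configurable placeholders).
    """

    family: str = "gaussian2d"        # gaussian2d | double_helix
    sigma0: float = 1.05 * 0.157      # µm (1.05 px at 157 nm/px)
    defocus_depth: float = 0.5        # µm: σ(z) = σ0·√(1+(z/depth)²)
    dh_separation: float = 1.0        # µm between lobe centres
    dh_rot_rate: float = 90.0         # degrees per µm of z
    dh_z_range: float = 2.0           # usable |z| span, µm (total)
    theta0_deg: float = 0.0           # lobe-axis angle at z = 0

    def __post_init__(self) -> None:
        if self.family not in ("gaussian2d", "double_helix"):
            raise ValueError("family must be 'gaussian2d' or 'double_helix'")
        if self.family == "double_helix" and self.dh_rot_rate == 0:
            raise ValueError("double-helix rotation rate must be nonzero")
        if self.sigma0 <= 0:
            raise ValueError("sigma0 must be positive")

    @classmethod
    def short_range(cls) -> "PSFModel":
        return cls(family="double_helix", dh_rot_rate=90.0, dh_z_range=2.0)

    @classmethod
    def long_range(cls) -> "PSFModel":
        return cls(family="double_helix", dh_rot_rate=30.0, dh_z_range=6.0)

    def lobe_angle_deg(self, z: float) -> float:
        return self.theta0_deg + self.dh_rot_rate * z

    def z_from_angle_deg(self, theta: float) -> float:
        """Invert θ(z), wrapping the lobe-exchange-degenerate angle to
        (−90°, 90°] about θ0 before dividing by the rotation rate."""
        d = (theta - self.theta0_deg + 90.0) % 180.0 - 90.0
        if d == -90.0:
            d = 90.0
        return d / self.dh_rot_rate


@dataclasses.dataclass
class EmitterSet:
    """Ground-truth emitters: positions (µm), brightness and blinking."""

    positions: np.ndarray             # (n, 3): x, y, z in µm
    photon_rate: np.ndarray           # expected photons/frame when fully lit
    on_probability: np.ndarray        # per-frame Bernoulli on-probability
    fiducial: np.ndarray              # bool per emitter

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, float))
        n = len(self.positions)
        self.photon_rate = np.broadcast_to(
            np.asarray(self.photon_rate, float), (n,)).copy()
        self.on_probability = np.broadcast_to(
            np.asarray(self.on_probability, float), (n,)).copy()
        self.fiducial = np.broadcast_to(
            np.asarray(self.fiducial, bool), (n,)).copy()
        if np.any(self.photon_rate < 0):
            raise ValueError("photon rates must be >= 0")
        if np.any((self.on_probability < 0) | (self.on_probability > 1)):
            raise ValueError("on probabilities must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.positions)

    @staticmethod
    def concatenate(sets: list["EmitterSet"]) -> "EmitterSet":
        return EmitterSet(
            np.concatenate([s.positions for s in sets]),
            np.concatenate([s.photon_rate for s in sets]),
            np.concatenate([s.on_probability for s in sets]),
            np.concatenate([s.fiducial for s in sets]))


# ---------------------------------------------------------------------------
# phantoms


def make_cell_phantom(kind: str, params: dict | None = None,
                      seed: int = 0) -> EmitterSet:
    """Seeded emitter phantom.

    kinds
    -----
    ``nuclear_shell``
        Emitters on an ellipsoidal shell (semi-axes ``radii`` µm,
        Gaussian radial scatter ``shell_thickness``); count is Poisson
        with mean ``density`` (µm⁻²) times the ellipsoid surface area.
    ``mito_network``
        Random straight tubule segments in a box; ``density`` is
        emitters per µm of tubule length.
    ``two_plane``
        Two parallel planes at z = 0 and z = ``separation``; ``density``
        is emitters per µm² per plane.  Used for sheet-vs-epi
        signal-to-background comparisons.
    """
    p = dict(params or {})
    rng = np.random.default_rng(seed)
    photon_rate = p.pop("photon_rate", 4320.0)
    on_prob = p.pop("on_probability", 0.05)

    if kind == "nuclear_shell":
        radii = np.asarray(p.pop("radii", (6.0, 4.5, 3.0)), float)
        thick = p.pop("shell_thickness", 0.1)
        density = p.pop("density", 5.0)
        a, b, c = radii
        # Knud Thomsen approximation of the ellipsoid surface area
        s = 1.6075
        area = 4 * np.pi * ((a**s * b**s + a**s * c**s + b**s * c**s) / 3) ** (1 / s)
        n = rng.poisson(density * area)
        v = rng.standard_normal((n, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        radial = 1.0 + rng.normal(0.0, thick / np.mean(radii), n)
        pos = v * radii * radial[:, None]
    elif kind == "mito_network":
        box = np.asarray(p.pop("box", (15.0, 15.0, 4.0)), float)
        n_seg = p.pop("n_segments", 12)
        seg_len = p.pop("segment_length", 5.0)
        density = p.pop("density", 20.0)
        jitter = p.pop("tubule_radius", 0.1)
        pts = []
        for _ in range(n_seg):
            start = rng.uniform(-box / 2, box / 2)
            direction = rng.standard_normal(3)
            direction /= np.linalg.norm(direction)
            n = rng.poisson(density * seg_len)
            t = rng.uniform(0, seg_len, n)
            pts.append(start + t[:, None] * direction
                       + rng.normal(0, jitter, (n, 3)))
        pos = np.concatenate(pts) if pts else np.empty((0, 3))
        pos = pos[np.all(np.abs(pos) <= box / 2, axis=1)]
    elif kind == "two_plane":
        extent = np.asarray(p.pop("extent", (10.0, 10.0)), float)
        sep = p.pop("separation", 4.0)
        density = p.pop("density", 0.6)
        n = rng.poisson(density * extent[0] * extent[1] * 2)
        xy = rng.uniform(-extent / 2, extent / 2, (n, 2))
        z = np.where(rng.random(n) < 0.5, 0.0, sep)
        pos = np.column_stack([xy, z])
    else:
        raise ValueError(f"unknown phantom kind {kind!r}")
    if p:
        raise ValueError(f"unused phantom parameters: {sorted(p)}")
    n = len(pos)
    return EmitterSet(pos.reshape(n, 3), np.full(n, photon_rate),
                      np.full(n, on_prob), np.zeros(n, bool))


# ---------------------------------------------------------------------------
# PSF rendering


def _pixel_gauss_1d(edges: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    """Integral of a unit Gaussian over the pixel bins given by edges."""
    c = erf((edges - mu) / (np.sqrt(2.0) * sigma))
    return 0.5 * (c[1:] - c[:-1])


def _render_lobes(shape: tuple[int, int], centers_um, weights, sigma: float,
                  camera: CameraModel, photons: float) -> np.ndarray:
    npy, npx = shape
    xe = (np.arange(npx + 1) - npx / 2.0) * camera.pixel_size_x
    ye = (np.arange(npy + 1) - npy / 2.0) * camera.pixel_size_y
    img = np.zeros(shape)
    for (cx, cy), wgt in zip(centers_um, weights):
        gx = _pixel_gauss_1d(xe, cx, sigma)
        gy = _pixel_gauss_1d(ye, cy, sigma)
        img += wgt * np.outer(gy, gx)
    return photons * img


def render_psf(z: float, psf: PSFModel, photons: float,
               camera: CameraModel | None = None,
               shape: tuple[int, int] = (21, 21),
               lateral_offset: tuple[float, float] = (0.0, 0.0)) -> np.ndarray:
    """Expected-photon image patch of one emitter at depth ``z``.

    The patch integrates the PSF over the camera pixels, so it sums to
    ``photons`` up to the tails falling outside the finite window.  For
    the double helix the two lobes carry half the photons each and sit
    at ±separation/2 about the emitter, rotated by θ(z).
    """
    camera = camera or CameraModel()
    ox, oy = lateral_offset
    if psf.family == "gaussian2d":
        # simple defocus model: width grows hyperbolically out of focus
        sigma = psf.sigma0 * np.sqrt(1.0 + (z / psf.defocus_depth) ** 2)
        return _render_lobes(shape, [(ox, oy)], [1.0], sigma, camera, photons)
    else:
        if abs(z) > psf.dh_z_range / 2.0:
            raise ValueError(f"z = {z} µm outside the DH range "
                             f"±{psf.dh_z_range / 2.0} µm")
        th = np.deg2rad(psf.lobe_angle_deg(z))
        dx = psf.dh_separation / 2.0 * np.cos(th)
        dy = psf.dh_separation / 2.0 * np.sin(th)
        centers = [(ox + dx, oy + dy), (ox - dx, oy - dy)]
        return _render_lobes(shape, centers, [0.5, 0.5], psf.sigma0, camera,
                             photons)


# ---------------------------------------------------------------------------
# movie synthesis


def _illumination_weights(emitters: EmitterSet,
                          illumination: BeamVolume | None) -> np.ndarray:
    if illumination is None:  # epi: uniform excitation
        return np.ones(len(emitters))
    vals = illumination.interp_at(emitters.positions[:, 0],
                                  emitters.positions[:, 1],
                                  emitters.positions[:, 2])
    peak = float(illumination.intensity.max())
    return np.asarray(vals, float) / peak


def simulate_frames(emitters: EmitterSet,
                    illumination: BeamVolume | None,
                    psf: PSFModel, camera: CameraModel, n_frames: int,
                    seed: int = 0, fov_px: tuple[int, int] = (64, 64),
                    background_photons: float = 2.0,
                    patch_px: int = 21) -> tuple[np.ndarray, pd.DataFrame]:
    """Simulate an EMCCD single-molecule movie.

    Per frame each emitter turns on with its Bernoulli probability
    (fiducials are always on); its expected signal is
    ``photon_rate × illumination weight`` where the weight is the
    normalized sheet intensity at the emitter's 3-D position (1
    everywhere for epi).  The expected-photon image (plus a uniform
    background) then passes through the EMCCD chain: Poisson →
    Gamma(n, em_gain) → Gaussian read noise → ÷ conversion gain →
    + dark level, quantized to 16-bit counts.

    Returns the movie ``(n_frames, ny, nx)`` uint16 stack and the
    ground-truth table (frame, emitter, x_um, y_um, z_um, photons).
    """
    rng = np.random.default_rng(seed)
    npy, npx = fov_px
    fov_x = npx * camera.pixel_size_x
    fov_y = npy * camera.pixel_size_y
    weights = _illumination_weights(emitters, illumination)
    movie = np.empty((n_frames, npy, npx), dtype=np.uint16)
    px_mean = (camera.pixel_size_x + camera.pixel_size_y) / 2.0

    def emitter_patch_px(z: float) -> int:
        # widen the render window for defocused spots so the haze is kept
        if psf.family == "gaussian2d":
            s = psf.sigma0 * np.sqrt(1.0 + (z / psf.defocus_depth) ** 2)
            need = int(np.ceil(8.0 * s / px_mean)) | 1
            return min(max(patch_px, need), 2 * max(npy, npx) + 1)
        return patch_px

    truth = []
    for f in range(n_frames):
        on = rng.random(len(emitters)) < emitters.on_probability
        on |= emitters.fiducial
        expected = np.full((npy, npx), float(background_photons))
        for i in np.nonzero(on)[0]:
            x, y, z = emitters.positions[i]
            n_exp = emitters.photon_rate[i] * weights[i]
            if n_exp <= 0:
                continue
            ix = x / camera.pixel_size_x + npx / 2.0
            iy = y / camera.pixel_size_y + npy / 2.0
            cx, cy = int(np.round(ix)), int(np.round(iy))
            off = ((ix - cx) * camera.pixel_size_x,
                   (iy - cy) * camera.pixel_size_y)
            pp = emitter_patch_px(z)
            half = pp // 2
            patch = render_psf(z, psf, n_exp, camera, (pp, pp), off)
            x0, x1 = max(cx - half, 0), min(cx + half + 1, npx)
            y0, y1 = max(cy - half, 0), min(cy + half + 1, npy)
            if x0 >= x1 or y0 >= y1:
                continue
            expected[y0:y1, x0:x1] += patch[y0 - (cy - half):y1 - (cy - half),
                                            x0 - (cx - half):x1 - (cx - half)]
            truth.append((f, i, x, y, z, n_exp))
        n_pe = rng.poisson(expected)
        electrons = np.where(
            n_pe > 0, rng.standard_gamma(np.maximum(n_pe, 1)) * camera.em_gain,
            0.0)
        electrons += rng.normal(0.0, camera.read_noise, electrons.shape)
        adu = electrons / camera.conversion_gain + camera.dark_level
        movie[f] = np.clip(np.round(adu), 0, 65535).astype(np.uint16)
    table = pd.DataFrame(truth, columns=["frame", "emitter", "x_um", "y_um",
                                         "z_um", "photons"])
    return movie, table


def write_movie(path: str | pathlib.Path, movie: np.ndarray,
                truth: pd.DataFrame | None = None,
                params: dict | None = None) -> None:
    """Write a movie as 16-bit multi-page TIFF, with optional ground-truth
    CSV and parameter YAML next to it."""
    path = pathlib.Path(path)
    tifffile.imwrite(path, movie.astype(np.uint16))
    if truth is not None:
        truth.to_csv(path.with_suffix(".truth.csv"), index=False)
    if params is not None:
        path.with_suffix(".params.yaml").write_text(
            yaml.safe_dump(params, sort_keys=False))
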