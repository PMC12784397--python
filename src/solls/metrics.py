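"""Light-sheet quantification: 1/e² radii, thickness curves, effective range.

The thickness convention throughout is the 1/e² *intensity* radius of a
Gaussian fitted to the central lobe of the z-profile.  The effective
range of a sheet is the longest contiguous propagation interval,
containing the waist, over which the fitted thickness stays within a
factor of √2 of the waist thickness — the sheet analogue of the
confocal parameter of a Gaussian beam (for an ideal Gaussian sheet it
equals 2·z_R = 2π n w0²/λ).
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy.optimize import curve_fit

from .fields import BeamVolume

__all__ = [
    "ThicknessProfile",
    "LSMetrics",
    "one_over_e2_radius",
    "thickness_curve",
    "effective_range",
    "max_intensity_projection",
    "measure_sheet",
]

SQRT2 = float(np.sqrt(2.0))


@dataclasses.dataclass
class ThicknessProfile:
    """Fitted 1/e² thickness w(x) along the propagation axis."""

    x_positions: np.ndarray      # µm, planes with a successful fit
    w: np.ndarray                # µm, fitted 1/e² radius per plane
    waist_w0: float              # µm, min over fitted w
    waist_position: float        # µm


@dataclasses.dataclass
class LSMetrics:
    """Summary metrics of one light-sheet volume."""

    thickness_w0: float          # µm
    width_1e2: float             # µm
    effective_range: float       # µm
    side: str = "symmetric"      # symmetric | post_focus


def _gauss_offset(r, i0, w, off):
    return i0 * np.exp(-2.0 * r**2 / w**2) + off


def _central_lobe_bounds(profile: np.ndarray, peak: int,
                         drop_fraction: float = 0.5) -> tuple[int, int]:
    """Window between the lobe-bounding local minima.

    A minimum only terminates the window if the profile has also dropped
    below ``drop_fraction`` of the peak; shallow defocus ripples riding
    on the lobe would otherwise truncate the fit window.
    """
    n = len(profile)
    pk = profile[peak]
    lo = peak
    while lo > 0 and not (profile[lo] < profile[lo - 1]
                          and profile[lo] < drop_fraction * pk):
        lo -= 1
    hi = peak
    while hi < n - 1 and not (profile[hi] < profile[hi + 1]
                              and profile[hi] < drop_fraction * pk):
        hi += 1
    return lo, hi


def one_over_e2_radius(profile: np.ndarray, spacing: float,
                       central_lobe: bool = True) -> float:
    """Fit ``I(r) = I0·exp(−2r²/w²) + offset`` and return the 1/e² radius w (µm).

    Parameters
    ----------
    profile : 1-D intensity samples with a single dominant peak.
    spacing : sample spacing, µm.
    central_lobe : restrict the fit window to the central lobe
        (between the minima flanking the peak); side lobes of lattice
        profiles would otherwise bias the fit.
    """
    profile = np.asarray(profile, dtype=float)
    if profile.ndim != 1 or len(profile) < 5:
        raise ValueError("profile must be a 1-D array with >= 5 samples")
    peak = int(np.argmax(profile))
    if central_lobe:
        lo, hi = _central_lobe_bounds(profile, peak)
    else:
        lo, hi = 0, len(profile) - 1
    r = (np.arange(lo, hi + 1) - peak) * spacing
    seg = profile[lo:hi + 1]
    pk = float(profile[peak])
    if pk <= 0:
        raise RuntimeError("profile peak is not positive; cannot fit")
    # moment-based initial guess for w
    wgt = np.clip(seg - seg.min(), 0, None)
    var = float(np.sum(wgt * r**2) / max(np.sum(wgt), 1e-300))
    w_guess = max(2.0 * np.sqrt(max(var, spacing**2 / 12.0)), spacing)
    try:
        popt, _ = curve_fit(_gauss_offset, r, seg, p0=[pk, w_guess, 0.0],
                            maxfev=20000)
    except RuntimeError as err:  # pragma: no cover - diagnostics path
        raise RuntimeError(
            f"1/e² fit failed on {hi - lo + 1}-sample window "
            f"(peak {pk:.3g}, guess w={w_guess:.3g} µm): {err}") from err
    w = abs(float(popt[1]))
    if w <= 0 or not np.isfinite(w):
        raise RuntimeError("1/e² fit returned a non-positive radius")
    return w


def thickness_curve(volume: BeamVolume, y_index: int | None = None,
                    median_window: int = 3) -> ThicknessProfile:
    """Per-plane 1/e² thickness of the z-profile at the beam's y-centre.

    Planes whose fit fails are excluded with a warning.  The fitted
    curve is passed through a short median filter (``median_window``
    planes, identity on monotone segments) so an isolated mis-fit on a
    ratty defocused profile cannot masquerade as the waist.
    """
    nx, ny, nz = volume.shape
    if y_index is None:
        # y-centre of mass of the total intensity
        ysum = volume.intensity.sum(axis=(0, 2))
        y_index = int(np.round(np.sum(np.arange(ny) * ysum) / np.sum(ysum)))
    xs = volume.x_positions()
    fitted_x, fitted_w = [], []
    for j in range(nx):
        prof = volume.intensity[j, y_index, :]
        try:
            w = one_over_e2_radius(prof, volume.dz)
        except RuntimeError as err:
            warnings.warn(f"plane {j} (x={xs[j]:.2f} µm) excluded: {err}")
            continue
        fitted_x.append(xs[j])
        fitted_w.append(w)
    if not fitted_w:
        raise RuntimeError("no plane of the volume could be fitted")
    fitted_x = np.asarray(fitted_x)
    fitted_w = np.asarray(fitted_w)
    if median_window > 1 and len(fitted_w) >= median_window:
        from scipy.signal import medfilt
        fitted_w = medfilt(fitted_w, kernel_size=median_window | 1)
    i0 = int(np.argmin(fitted_w))
    return ThicknessProfile(fitted_x, fitted_w, float(fitted_w[i0]),
                            float(fitted_x[i0]))


def effective_range(profile: ThicknessProfile, side: str = "symmetric") -> float:
    """Length of the contiguous interval around the waist with w(x) ≤ √2·w0.

    The sub-sample crossing of the √2·w0 threshold is located by linear
    interpolation between planes.  In ``post_focus`` mode only the span
    from the waist forward (+x) is counted.
    """
    if side not in ("symmetric", "post_focus"):
        raise ValueError("side must be 'symmetric' or 'post_focus'")
    x, w = profile.x_positions, profile.w
    i0 = int(np.argmin(w))
    thr = SQRT2 * profile.waist_w0

    def cross(i_in: int, i_out: int) -> float:
        # linear interpolation of the threshold crossing between planes
        f = (thr - w[i_in]) / (w[i_out] - w[i_in])
        return x[i_in] + f * (x[i_out] - x[i_in])

    hi = i0
    while hi < len(x) - 1 and w[hi + 1] <= thr:
        hi += 1
    x_hi = cross(hi, hi + 1) if hi < len(x) - 1 else x[-1]
    lo = i0
    while lo > 0 and w[lo - 1] <= thr:
        lo -= 1
    x_lo = cross(lo, lo - 1) if lo > 0 else x[0]
    if side == "post_focus":
        return float(x_hi - profile.waist_position)
    if lo == 0 or hi == len(x) - 1:
        warnings.warn("√2 threshold not crossed inside the measured domain; "
                      "effective range is clipped to the domain")
    return float(x_hi - x_lo)


def max_intensity_projection(volume: BeamVolume, axis: str) -> np.ndarray:
    """Maximum-intensity projection along one of the axes 'x', 'y', 'z'."""
    try:
        ax = {"x": 0, "y": 1, "z": 2}[axis]
    except KeyError:
        raise ValueError("axis must be one of 'x', 'y', 'z'") from None
    return volume.intensity.max(axis=ax)


def measure_sheet(volume: BeamVolume, side: str = "symmetric") -> LSMetrics:
    """Convenience wrapper: thickness curve, width and effective range."""
    prof = thickness_curve(volume)
    # width: 1/e² radius of the y-profile at the waist plane, z-centre
    i_x = int(np.argmin(np.abs(volume.x_positions() - prof.waist_position)))
    plane = volume.intensity[i_x]
    iz = int(np.argmax(plane.max(axis=0)))
    try:
        width = one_over_e2_radius(plane[:, iz], volume.dy, central_lobe=False)
        if width > volume.shape[1] * volume.dy:
            # profile flat across the window: width not resolvable
            width = float("nan")
    except RuntimeError:
        width = float("nan")
    return LSMetrics(thickness_w0=prof.waist_w0, width_1e2=width,
                     effective_range=effective_range(prof, side=side),
                     side=side)
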