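"""Localization and statistics pipeline.

Detection uses B-spline à-trous wavelet filtering with a peak-intensity
threshold; spots are fitted by weighted least squares with a
pixel-integrated 2-D Gaussian (or a double-Gaussian for the
double-helix PSF, whose lobe angle encodes depth); per-localization
precision comes from an EMCCD-specific least-squares formula with the
shot-noise term doubled by the electron-multiplication excess noise.
Post-processing: fiducial drift correction, rule-based filtering,
axial rescaling for index mismatch, region statistics,
signal-to-background ratios and Fourier ring correlation resolution.

Localization tables are plain pandas DataFrames with unit-suffixed
columns (``frame, x_um, y_um, z_um, photons, background, sigma_um,
uncertainty_xy_nm, uncertainty_z_nm``) and round-trip through CSV.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import curve_fit
from scipy.special import erf

from .smlm import CameraModel, PSFModel

__all__ = [
    "detect_candidates", "fit_gaussian2d_wls", "precision_emccd",
    "precision_dh_z", "fit_dh_double_gaussian", "localize_movie",
    "drift_correct", "filter_localizations", "rescale_axial",
    "bin_regions", "RegionStats", "compute_sbr", "sbr_from_line_scan",
    "frc_resolution", "SCATTERING_FILTER_RULES", "TWO_TARGET_FILTER_RULES",
]

log = logging.getLogger(__name__)

# paper-calibrated filtering presets
SCATTERING_FILTER_RULES = {
    "uncertainty_xy_nm": {"max": 100.0},
    "photons": {"max": 1_000_000.0},
}
TWO_TARGET_FILTER_RULES = {
    "uncertainty_xy_nm": {"max": 42.0},
    "uncertainty_z_nm": {"max": 50.0},
    "photons": {"min": 3000.0},
}


# ---------------------------------------------------------------------------
# detection

_B3 = np.array([1.0, 4.0, 6.0, 4.0, 1.0]) / 16.0


def _atrous_smooth(img: np.ndarray, level: int) -> np.ndarray:
    """Separable B3-spline à-trous smoothing at the given level
    (holes of 2**(level-1) − 1 zeros between kernel taps)."""
    step = 2 ** (level - 1)
    kernel = np.zeros(4 * step + 1)
    kernel[::step] = _B3
    out = ndimage.convolve1d(img, kernel, axis=0, mode="reflect")
    return ndimage.convolve1d(out, kernel, axis=1, mode="reflect")


def detect_candidates(frame: np.ndarray, threshold_coeff: float = 2.0
                      ) -> np.ndarray:
    """Spot candidates on a dark-corrected frame.

    The frame is wavelet-filtered (second à-trous B3-spline detail
    plane); 8-connected local maxima above ``threshold_coeff`` times
    the standard deviation of the first detail plane (a noise
    estimate) are returned as an (n, 2) array of (row, col) pixels.
    """
    frame = np.asarray(frame, float)
    v1 = _atrous_smooth(frame, 1)
    v2 = _atrous_smooth(v1, 2)
    w1 = frame - v1          # finest detail plane: noise estimate
    w2 = v1 - v2             # spot-scale detail plane
    threshold = threshold_coeff * w1.std()
    local_max = (w2 == ndimage.maximum_filter(w2, size=3)) & (w2 > threshold)
    # deduplicate plateaus: one candidate per connected component
    labels, n = ndimage.label(local_max, structure=np.ones((3, 3)))
    if n == 0:
        return np.empty((0, 2), dtype=int)
    coords = ndimage.center_of_mass(local_max, labels, range(1, n + 1))
    return np.round(np.asarray(coords)).astype(int)


# ---------------------------------------------------------------------------
# fitting


def _pixel_gauss(edges: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    c = erf((edges - mu) / (np.sqrt(2.0) * sigma))
    return 0.5 * (c[1:] - c[:-1])


@dataclasses.dataclass
class FitResult:
    x_px: float          # within the ROI, pixels (column)
    y_px: float          # within the ROI, pixels (row)
    sigma_um: float
    photons: float
    background: float    # photons per pixel
    z_um: float | None = None


def fit_gaussian2d_wls(roi: np.ndarray, camera: CameraModel,
                       sigma_guess_px: float = 1.05) -> FitResult:
    """Weighted least-squares fit of one spot in a photon-unit ROI.

    Model: symmetric pixel-integrated 2-D Gaussian plus constant
    background, ``N·Gx(x0, σ)·Gy(y0, σ) + b``; weights are the inverse
    of the expected per-pixel variance approximated by the observed
    counts (floored at one photon).
    """
    roi = np.asarray(roi, float)
    npy, npx = roi.shape
    xe = np.arange(npx + 1, dtype=float)
    ye = np.arange(npy + 1, dtype=float)
    b0 = float(np.median(roi))
    n0 = max(float(roi.sum() - b0 * roi.size), 1.0)
    iy, ix = np.unravel_index(np.argmax(roi), roi.shape)
    px_mean = (camera.pixel_size_x + camera.pixel_size_y) / 2.0

    def model(_, x0, y0, s_px, n, b):
        return (n * np.outer(_pixel_gauss(ye, y0, s_px),
                             _pixel_gauss(xe, x0, s_px)) + b).ravel()

    sigma_w = np.sqrt(np.maximum(roi, 1.0)).ravel()
    try:
        popt, _ = curve_fit(
            model, None, roi.ravel(),
            p0=[ix + 0.5, iy + 0.5, sigma_guess_px, n0, b0],
            sigma=sigma_w, absolute_sigma=True, maxfev=20000)
    except RuntimeError as err:
        raise RuntimeError(f"Gaussian fit did not converge: {err}") from err
    x0, y0, s_px, n, b = popt
    if n <= 0:
        raise RuntimeError("Gaussian fit returned non-positive photon count")
    return FitResult(x_px=float(x0), y_px=float(y0),
                     sigma_um=abs(float(s_px)) * px_mean,
                     photons=float(n), background=float(b))


def precision_emccd(N: float, b: float, sigma: float, pixel: float,
                    excess_noise_factor: float = 2.0) -> float:
    """Lateral least-squares localization precision on an EMCCD, in nm.

    Thompson/Mortensen-style least-squares expression with the
    effective PSF variance ``σ_a² = σ² + a²/12`` and the shot-noise
    term multiplied by the electron-multiplication excess noise factor
    (2 for a Gamma EM register)::

        var = F · σ_a²/N · (16/9 + 8π σ_a² b / (N a²))

    with N signal photons, b background photons per pixel, σ the
    fitted PSF sigma and a the pixel size (σ, a in µm).
    """
    if N <= 0:
        raise ValueError("photon count must be positive")
    sa2 = sigma**2 + pixel**2 / 12.0
    var = excess_noise_factor * sa2 / N * (
        16.0 / 9.0 + 8.0 * np.pi * sa2 * b / (N * pixel**2))
    return float(np.sqrt(var) * 1000.0)


def precision_dh_z(N: float, b: float, sigma: float, pixel: float,
                   psf: PSFModel, excess_noise_factor: float = 2.0) -> float:
    """Axial precision of a double-helix fit, in nm.

    Each lobe (N/2 photons) is localized with the EMCCD formula; the
    lobe-pair angle uncertainty σ_θ = √2·σ_lobe/separation maps to
    depth through the rotation rate.
    """
    lobe_nm = precision_emccd(N / 2.0, b, sigma, pixel, excess_noise_factor)
    sigma_theta = np.sqrt(2.0) * (lobe_nm / 1000.0) / psf.dh_separation  # rad
    rate_rad_per_um = np.deg2rad(psf.dh_rot_rate)
    return float(sigma_theta / rate_rad_per_um * 1000.0)


def fit_dh_double_gaussian(roi: np.ndarray, psf: PSFModel,
                           camera: CameraModel) -> FitResult:
    """Double-Gaussian fit of a double-helix spot in a photon-unit ROI.

    Two equal-width Gaussian lobes with free midpoint, separation and
    angle; the emitter is at the lobe midpoint and its depth follows
    from the lobe-axis angle via the inverse rotation model (angle
    wrapped to (−90°, 90°], resolving the lobe-exchange degeneracy).
    Raises if the second lobe cannot be resolved.
    """
    roi = np.asarray(roi, float)
    npy, npx = roi.shape
    xe = np.arange(npx + 1, dtype=float)
    ye = np.arange(npy + 1, dtype=float)
    px = (camera.pixel_size_x + camera.pixel_size_y) / 2.0
    s0 = psf.sigma0 / px
    sep0 = psf.dh_separation / px

    # initial guess: brightest pixel and brightest pixel far from it
    b0 = float(np.median(roi))
    iy1, ix1 = np.unravel_index(np.argmax(roi), roi.shape)
    masked = roi.copy()
    yy, xx = np.mgrid[0:npy, 0:npx]
    masked[(yy - iy1) ** 2 + (xx - ix1) ** 2 < (0.6 * sep0) ** 2] = -np.inf
    if not np.isfinite(masked).any():
        raise RuntimeError("ROI too small to resolve both DH lobes")
    iy2, ix2 = np.unravel_index(np.argmax(masked), roi.shape)
    peak2 = roi[iy2, ix2] - b0
    peak1 = roi[iy1, ix1] - b0
    if peak2 < 0.2 * peak1:
        raise RuntimeError("single-lobe spot: second DH lobe not found")
    xc0, yc0 = (ix1 + ix2) / 2.0 + 0.5, (iy1 + iy2) / 2.0 + 0.5
    th0 = np.arctan2(iy2 - iy1, ix2 - ix1)
    n0 = max(float(roi.sum() - b0 * roi.size), 1.0)

    def model(_, xc, yc, sep, th, s_px, n, b):
        dx, dy = sep / 2.0 * np.cos(th), sep / 2.0 * np.sin(th)
        lobe1 = np.outer(_pixel_gauss(ye, yc + dy, s_px),
                         _pixel_gauss(xe, xc + dx, s_px))
        lobe2 = np.outer(_pixel_gauss(ye, yc - dy, s_px),
                         _pixel_gauss(xe, xc - dx, s_px))
        return (n / 2.0 * (lobe1 + lobe2) + b).ravel()

    sigma_w = np.sqrt(np.maximum(roi, 1.0)).ravel()
    try:
        popt, _ = curve_fit(model, None, roi.ravel(),
                            p0=[xc0, yc0, sep0, th0, s0, n0, b0],
                            sigma=sigma_w, absolute_sigma=True, maxfev=30000)
    except RuntimeError as err:
        raise RuntimeError(f"DH fit did not converge: {err}") from err
    xc, yc, sep, th, s_px, n, b = popt
    if n <= 0 or abs(sep) < 0.3 * sep0:
        raise RuntimeError("DH fit degenerate (lobes collapsed)")
    if sep < 0:
        sep, th = -sep, th + np.pi
    z = psf.z_from_angle_deg(np.rad2deg(th))
    return FitResult(x_px=float(xc), y_px=float(yc),
                     sigma_um=abs(float(s_px)) * px, photons=float(n),
                     background=float(b), z_um=float(z))


# ---------------------------------------------------------------------------
# movie driver


def localize_movie(movie: np.ndarray, camera: CameraModel,
                   psf: PSFModel | None = None,
                   threshold_coeff: float = 2.0,
                   patch_px: int | None = None) -> pd.DataFrame:
    """Detect and fit all frames of a movie (A/D counts in, table out).

    Positions are reported in the centred sample frame used by the
    movie synthesizer (µm, origin at the FOV centre).
    """
    psf = psf or PSFModel()
    dh = psf.family == "double_helix"
    if patch_px is None:
        patch_px = 25 if dh else 15
    half = patch_px // 2
    n_frames, npy, npx = movie.shape
    rows = []
    for f in range(n_frames):
        photons = camera.photons_from_adu(movie[f])
        for row, col in detect_candidates(photons, threshold_coeff):
            y0, x0 = row - half, col - half
            if y0 < 0 or x0 < 0 or y0 + patch_px > npy or x0 + patch_px > npx:
                continue
            roi = photons[y0:y0 + patch_px, x0:x0 + patch_px]
            try:
                if dh:
                    fit = fit_dh_double_gaussian(roi, psf, camera)
                else:
                    fit = fit_gaussian2d_wls(roi, camera)
            except RuntimeError as err:
                log.debug("frame %d (%d,%d): %s", f, row, col, err)
                continue
            # fit coordinates are edge-based (pixel i centre at i + 0.5);
            # image pixel index i sits at (i − n/2)·pitch in the sample frame
            x_um = (x0 + fit.x_px - 0.5 - npx / 2.0) * camera.pixel_size_x
            y_um = (y0 + fit.y_px - 0.5 - npy / 2.0) * camera.pixel_size_y
            px_mean = (camera.pixel_size_x + camera.pixel_size_y) / 2.0
            unc = precision_emccd(fit.photons, max(fit.background, 0.0),
                                  fit.sigma_um, px_mean,
                                  camera.excess_noise_factor)
            rec = {"frame": f, "x_um": x_um, "y_um": y_um,
                   "photons": fit.photons, "background": fit.background,
                   "sigma_um": fit.sigma_um, "uncertainty_xy_nm": unc}
            if dh:
                rec["z_um"] = fit.z_um
                rec["uncertainty_z_nm"] = precision_dh_z(
                    fit.photons, max(fit.background, 0.0), fit.sigma_um,
                    px_mean, psf, camera.excess_noise_factor)
            rows.append(rec)
    df = pd.DataFrame(rows)
    if len(df) > 1:
        # deduplicate double detections of the same spot in a frame
        df = df.sort_values(["frame", "photons"], ascending=[True, False])
        keep = []
        for _, grp in df.groupby("frame"):
            taken: list[tuple[float, float]] = []
            for idx, r in grp.iterrows():
                if all((r.x_um - tx) ** 2 + (r.y_um - ty) ** 2 > 0.25
                       for tx, ty in taken):
                    keep.append(idx)
                    taken.append((r.x_um, r.y_um))
        df = df.loc[keep].sort_index().reset_index(drop=True)
    return df


# ---------------------------------------------------------------------------
# post-processing


def _fiducial_ids(fiducials: pd.DataFrame) -> pd.Series:
    if "fiducial_id" in fiducials.columns:
        return fiducials["fiducial_id"]
    # cluster by first-seen positions (fiducials are bright and sparse)
    refs: list[tuple[float, float]] = []
    ids = np.empty(len(fiducials), dtype=int)
    for i, (x, y) in enumerate(zip(fiducials["x_um"], fiducials["y_um"])):
        for j, (rx, ry) in enumerate(refs):
            if (x - rx) ** 2 + (y - ry) ** 2 < 1.0:
                ids[i] = j
                break
        else:
            ids[i] = len(refs)
            refs.append((x, y))
    return pd.Series(ids, index=fiducials.index)


def drift_correct(locs: pd.DataFrame, fiducials: pd.DataFrame,
                  smoothing_window: int = 50) -> pd.DataFrame:
    """Subtract the smoothed mean fiducial displacement per frame.

    Each fiducial trajectory is referenced to its own mean position;
    per-frame displacements are averaged over fiducials, gaps are
    linearly interpolated, the trace is smoothed with a moving average
    of ``smoothing_window`` frames and subtracted from the table.
    """
    if len(fiducials) == 0:
        raise ValueError("drift correction requires at least one fiducial")
    fid = fiducials.copy()
    fid["_id"] = _fiducial_ids(fiducials)
    axes = [c for c in ("x_um", "y_um", "z_um") if c in locs.columns
            and c in fid.columns]
    frames = np.arange(int(locs["frame"].max()) + 1)
    drift = {}
    for ax in axes:
        fid["_d"] = fid[ax] - fid.groupby("_id")[ax].transform("mean")
        per_frame = fid.groupby("frame")["_d"].mean()
        trace = np.interp(frames, per_frame.index.values, per_frame.values)
        drift[ax] = ndimage.uniform_filter1d(trace, size=smoothing_window,
                                             mode="nearest")
    out = locs.copy()
    idx = out["frame"].astype(int).values
    for ax in axes:
        out[ax] = out[ax] - drift[ax][idx]
    return out


def filter_localizations(locs: pd.DataFrame, rules: dict) -> pd.DataFrame:
    """Drop records failing any rule; removal counts are logged per rule.

    ``rules`` maps a column name to ``{"min": lo}`` and/or
    ``{"max": hi}`` bounds (inclusive).
    """
    keep = pd.Series(True, index=locs.index)
    counts = {}
    for col, bounds in rules.items():
        if col not in locs.columns:
            raise KeyError(f"filter rule on missing column {col!r}")
        ok = pd.Series(True, index=locs.index)
        if "min" in bounds:
            ok &= locs[col] >= bounds["min"]
        if "max" in bounds:
            ok &= locs[col] <= bounds["max"]
        counts[col] = int((~ok).sum())
        keep &= ok
    for col, n in counts.items():
        if n:
            log.info("filter %s removed %d records", col, n)
    out = locs[keep].copy()
    out.attrs["filter_counts"] = counts
    return out


def rescale_axial(locs: pd.DataFrame, factor: float = 0.75) -> pd.DataFrame:
    """Multiply the axial coordinate by ``factor`` (default 0.75,
    compensating refractive-index mismatch between coverslip and
    sample); every other column is untouched."""
    if "z_um" not in locs.columns:
        raise KeyError("axial rescaling requires a z_um column")
    out = locs.copy()
    out["z_um"] = out["z_um"] * factor
    return out


@dataclasses.dataclass
class RegionStats:
    """Per-region localization statistics across the FOV."""

    table: pd.DataFrame   # region, count, norm_count, means and sds
    axis: str
    bounds: tuple[float, float]


def bin_regions(locs: pd.DataFrame, n_regions: int = 5, axis: str = "x",
                bounds: tuple[float, float] | None = None) -> RegionStats:
    """Bin localizations into equal-width regions along one axis.

    Region 1 is nearest the reference (mirror) edge — the low end of
    the axis.  Counts are normalized by region 1; the mean ± sd of the
    ``sbr`` and ``uncertainty_xy_nm`` columns are reported per region
    where present.
    """
    col = f"{axis}_um"
    if col not in locs.columns:
        raise KeyError(f"no column {col!r}")
    vals = locs[col].to_numpy()
    if bounds is None:
        bounds = (float(vals.min()), float(vals.max()))
    edges = np.linspace(bounds[0], bounds[1], n_regions + 1)
    idx = np.clip(np.searchsorted(edges, vals, side="right") - 1,
                  0, n_regions - 1)
    rows = []
    n1 = int(np.sum(idx == 0))
    if n1 == 0:
        warnings.warn("region 1 is empty; normalized counts undefined")
    for r in range(n_regions):
        sel = locs[idx == r]
        row = {"region": r + 1, "count": len(sel),
               "norm_count": len(sel) / n1 if n1 else np.nan}
        for src, name in (("sbr", "sbr"), ("uncertainty_xy_nm", "uncertainty")):
            if src in locs.columns:
                finite = sel[src][np.isfinite(sel[src])]
                row[f"{name}_mean"] = float(finite.mean()) if len(finite) else np.nan
                row[f"{name}_sd"] = float(finite.std(ddof=1)) if len(finite) > 1 else np.nan
        rows.append(row)
    return RegionStats(pd.DataFrame(rows), axis, bounds)


# ---------------------------------------------------------------------------
# SBR


def compute_sbr(locs: pd.DataFrame, camera: CameraModel | None = None
                ) -> pd.Series:
    """Per-localization signal-to-background ratio.

    Peak signal is the expected photon count in the brightest pixel of
    the fitted Gaussian, ``N · a_x a_y / (2π σ²)``; SBR is that over
    the fitted background per pixel.  Zero-background records give
    +inf and are excluded from downstream means.
    """
    camera = camera or CameraModel()
    area = camera.pixel_size_x * camera.pixel_size_y
    peak = locs["photons"] * area / (2.0 * np.pi * locs["sigma_um"] ** 2)
    bg = locs["background"].to_numpy(float)
    with np.errstate(divide="ignore"):
        sbr = np.where(bg > 0, peak / bg, np.inf)
    if np.any(~np.isfinite(sbr)):
        warnings.warn("zero-background localizations give infinite SBR; "
                      "excluded from means")
    return pd.Series(sbr, index=locs.index, name="sbr")


def sbr_from_line_scan(profile: np.ndarray, spacing: float,
                       background_window_um: float = 1.6) -> float:
    """SBR of an intensity line scan across one emitter.

    The background is the mean over a ``background_window_um`` stretch
    taken from the two ends of the scan (where no emitter signal is
    present); SBR is the profile peak over that mean.
    """
    profile = np.asarray(profile, float)
    n_bg = max(int(round(background_window_um / spacing / 2.0)), 1)
    background = float(np.concatenate([profile[:n_bg], profile[-n_bg:]]).mean())
    if background <= 0:
        warnings.warn("non-positive background in line scan; SBR undefined")
        return float("inf")
    return float(profile.max() / background)


# ---------------------------------------------------------------------------
# FRC


def _render_histogram(x: np.ndarray, y: np.ndarray, origin: np.ndarray,
                      n_px: int, px: float) -> np.ndarray:
    edges_x = origin[0] + np.arange(n_px + 1) * px
    edges_y = origin[1] + np.arange(n_px + 1) * px
    img, _, _ = np.histogram2d(y, x, bins=(edges_y, edges_x))
    return img


def frc_resolution(locs: pd.DataFrame, sr_pixel_nm: float = 8.0,
                   seed: int = 0, threshold: float = 1.0 / 7.0,
                   n_splits: int = 1, min_locs: int = 200,
                   halves: tuple[pd.DataFrame, pd.DataFrame] | None = None
                   ) -> float:
    """Fourier-ring-correlation resolution of a localization table, nm.

    The table is randomly split in half (seeded); each half is
    rendered as a 2-D histogram with ``sr_pixel_nm`` pixels; the
    ring-averaged correlation of the two spectra is thresholded at 1/7
    and the first crossing gives the resolution.  If the curve never
    drops below threshold the result is bounded by two render pixels.
    ``n_splits`` > 1 averages the curve over independent splits.
    """
    if halves is None and len(locs) < min_locs:
        raise ValueError(f"too few localizations for FRC ({len(locs)} < {min_locs})")
    px = sr_pixel_nm / 1000.0  # µm
    x = locs["x_um"].to_numpy(float)
    y = locs["y_um"].to_numpy(float)
    extent = max(x.max() - x.min(), y.max() - y.min()) + 4 * px
    n_px = int(2 ** np.ceil(np.log2(extent / px)))
    origin = np.array([(x.min() + x.max()) / 2.0 - n_px * px / 2.0,
                       (y.min() + y.max()) / 2.0 - n_px * px / 2.0])
    rng = np.random.default_rng(seed)

    ky = np.fft.fftfreq(n_px, px)
    kr = np.hypot(ky[:, None], ky[None, :])
    n_rings = n_px // 2
    ring = np.clip((kr * n_px * px).astype(int), 0, n_rings)
    ring_flat = ring.ravel()

    curves = []
    for _ in range(max(n_splits, 1)):
        if halves is not None:
            h1, h2 = halves
        else:
            mask = rng.random(len(locs)) < 0.5
            h1, h2 = locs[mask], locs[~mask]
        f1 = np.fft.fft2(_render_histogram(h1["x_um"].to_numpy(),
                                           h1["y_um"].to_numpy(),
                                           origin, n_px, px))
        f2 = np.fft.fft2(_render_histogram(h2["x_um"].to_numpy(),
                                           h2["y_um"].to_numpy(),
                                           origin, n_px, px))
        num = np.bincount(ring_flat, (f1 * np.conj(f2)).real.ravel(),
                          minlength=n_rings + 1)
        d1 = np.bincount(ring_flat, np.abs(f1).ravel() ** 2,
                         minlength=n_rings + 1)
        d2 = np.bincount(ring_flat, np.abs(f2).ravel() ** 2,
                         minlength=n_rings + 1)
        with np.errstate(invalid="ignore", divide="ignore"):
            curves.append(num / np.sqrt(d1 * d2))
    frc = np.nanmean(curves, axis=0)[:n_rings]
    # light smoothing stabilizes the crossing against ring noise
    frc = ndimage.uniform_filter1d(frc, size=3, mode="nearest")
    freqs = np.arange(n_rings) / (n_px * px)  # cycles/µm

    below = np.nonzero(frc[1:] < threshold)[0]
    if len(below) == 0:
        return float(2.0 * sr_pixel_nm)
    i = below[0] + 1
    # sub-ring linear interpolation of the crossing
    f_lo, f_hi = freqs[i - 1], freqs[i]
    c_lo, c_hi = frc[i - 1], frc[i]
    f_cross = f_lo + (c_lo - threshold) / (c_lo - c_hi) * (f_hi - f_lo)
    return float(1000.0 / f_cross)
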