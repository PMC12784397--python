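"""Localization pipeline: detection, fits, precision, post-processing."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from solls import render_psf
from solls.localize import (SCATTERING_FILTER_RULES, bin_regions, compute_sbr,
                            detect_candidates, drift_correct,
                            filter_localizations, fit_dh_double_gaussian,
                            fit_gaussian2d_wls, frc_resolution,
                            localize_movie, precision_dh_z, precision_emccd,
                            rescale_axial, sbr_from_line_scan)
from solls.smlm import CameraModel, EmitterSet, PSFModel, simulate_frames


class TestDetection:
    def test_blank_frame_yields_nothing(self):
        assert len(detect_candidates(np.zeros((64, 64)))) == 0

    def test_single_emitter_found_at_its_peak(self, camera, psf):
        frame = np.zeros((64, 64))
        patch = render_psf(0.0, psf, 3000.0, camera, (15, 15))
        frame[20:35, 30:45] += patch
        frame += 1.0
        cands = detect_candidates(frame)
        assert len(cands) == 1
        assert tuple(cands[0]) == (27, 37)

    def test_two_well_separated_emitters(self, camera, psf):
        frame = np.full((64, 64), 2.0)
        patch = render_psf(0.0, psf, 3000.0, camera, (15, 15))
        frame[5:20, 5:20] += patch
        frame[40:55, 40:55] += patch     # 35 px ≈ 33σ apart
        cands = detect_candidates(frame)
        assert len(cands) == 2


class TestGaussianFit:
    def test_noiseless_parameters_recovered(self, camera, psf):
        roi = render_psf(0.0, psf, 1000.0, camera, (15, 15)) + 10.0
        fit = fit_gaussian2d_wls(roi, camera)
        assert fit.photons == pytest.approx(1000.0, rel=1e-4)
        assert fit.background == pytest.approx(10.0, rel=1e-4)
        assert fit.sigma_um == pytest.approx(psf.sigma0, rel=1e-4)
        assert fit.x_px == pytest.approx(7.5, abs=1e-4)

    def test_translation_equivariance(self, camera, psf):
        dx = 0.3 * camera.pixel_size_x
        roi = render_psf(0.0, psf, 1000.0, camera, (15, 15),
                         lateral_offset=(dx, 0.0)) + 10.0
        fit = fit_gaussian2d_wls(roi, camera)
        assert fit.x_px - 7.5 == pytest.approx(0.3, abs=1e-3)
        assert fit.y_px == pytest.approx(7.5, abs=1e-3)


class TestPrecisionFormula:
    def test_background_free_limit(self):
        full = precision_emccd(5000, 0.0, 0.165, 0.157)
        sa2 = 0.165**2 + 0.157**2 / 12
        expected = np.sqrt(2 * sa2 / 5000 * 16 / 9) * 1000
        assert full == pytest.approx(expected)

    def test_shot_limited_scaling(self):
        # quadrupling N halves the uncertainty in the shot-limited regime
        lo = precision_emccd(40000, 0.01, 0.165, 0.157)
        hi = precision_emccd(10000, 0.01, 0.165, 0.157)
        assert hi / lo == pytest.approx(2.0, rel=0.05)

    def test_monotone_in_signal_and_background(self):
        ns = np.logspace(2, 5, 12)
        bs = np.linspace(0, 50, 12)
        for b in (0.0, 5.0, 30.0):
            vals = [precision_emccd(n, b, 0.165, 0.157) for n in ns]
            assert np.all(np.diff(vals) < 0)
        for n in (500.0, 5000.0):
            vals = [precision_emccd(n, b, 0.165, 0.157) for b in bs]
            assert np.all(np.diff(vals) > 0)

    def test_zero_photons_rejected(self):
        with pytest.raises(ValueError):
            precision_emccd(0.0, 1.0, 0.165, 0.157)

    def test_monte_carlo_consistency(self, camera, psf):
        """Fit ensemble at the bench point (N=4320, b=16.1 photons/px)
        matches the EMCCD formula within 25%."""
        rng = np.random.default_rng(12)
        xs = []
        for _ in range(250):
            off = (rng.uniform(-0.5, 0.5) * camera.pixel_size_x, 0.0)
            exp_img = render_psf(0.0, psf, 4320.0, camera, (15, 15), off) + 16.1
            n_pe = rng.poisson(exp_img)
            el = np.where(n_pe > 0,
                          rng.standard_gamma(np.maximum(n_pe, 1)) * camera.em_gain,
                          0.0)
            el += rng.normal(0, camera.read_noise, el.shape)
            roi = el / camera.em_gain
            fit = fit_gaussian2d_wls(roi, camera)
            xs.append(fit.x_px * camera.pixel_size_x - off[0])
        mc_nm = np.std(xs, ddof=1) * 1000
        pred = precision_emccd(4320.0, 16.1, psf.sigma0,
                               (camera.pixel_size_x + camera.pixel_size_y) / 2)
        assert mc_nm == pytest.approx(pred, rel=0.25)


class TestDoubleHelixFit:
    def test_in_focus_depth_is_zero(self, camera, dh_psf):
        roi = render_psf(0.0, dh_psf, 5000.0, camera, (25, 25)) + 5.0
        fit = fit_dh_double_gaussian(roi, dh_psf, camera)
        assert abs(fit.z_um) * 1000 < 1.0

    def test_z_scan_round_trip_is_linear(self, camera, dh_psf):
        zs = np.linspace(-0.9, 0.9, 19)
        rec = []
        for z in zs:
            roi = render_psf(z, dh_psf, 5000.0, camera, (25, 25)) + 5.0
            rec.append(fit_dh_double_gaussian(roi, dh_psf, camera).z_um)
        slope, intercept = np.polyfit(zs, rec, 1)
        r2 = np.corrcoef(zs, rec)[0, 1] ** 2
        assert slope == pytest.approx(1.0, rel=0.02)
        assert r2 > 0.999

    def test_lobe_swap_symmetry(self, camera, dh_psf):
        """A 180° rotation of the patch exchanges the two lobes but the
        wrapped angle gives the same localization."""
        roi = render_psf(0.4, dh_psf, 5000.0, camera, (25, 25)) + 5.0
        swapped = roi[::-1, ::-1]
        a = fit_dh_double_gaussian(roi, dh_psf, camera)
        b = fit_dh_double_gaussian(swapped, dh_psf, camera)
        assert a.z_um == pytest.approx(b.z_um, abs=1e-3)

    def test_single_lobe_rejected(self, camera, dh_psf):
        roi = render_psf(0.0, PSFModel(), 5000.0, camera, (25, 25)) + 5.0
        with pytest.raises(RuntimeError):
            fit_dh_double_gaussian(roi, dh_psf, camera)

    def test_dh_z_precision_positive_and_monotone(self, dh_psf):
        a = precision_dh_z(4000, 10, 0.165, 0.157, dh_psf)
        b = precision_dh_z(1000, 10, 0.165, 0.157, dh_psf)
        assert 0 < a < b


class TestDriftCorrection:
    @staticmethod
    def _tables(drift_per_frame, n_frames=1000, noise=0.002, seed=0):
        rng = np.random.default_rng(seed)
        frames = np.arange(n_frames)
        drift = drift_per_frame * frames
        fid = pd.DataFrame({
            "frame": frames,
            "x_um": 3.0 + drift + rng.normal(0, noise, n_frames),
            "y_um": -2.0 + rng.normal(0, noise, n_frames)})
        locs = pd.DataFrame({
            "frame": frames,
            "x_um": drift + rng.normal(0, noise, n_frames),
            "y_um": rng.normal(0, noise, n_frames)})
        return locs, fid

    def test_injected_linear_drift_removed(self):
        # 50 nm over 1000 frames
        locs, fid = self._tables(0.05 / 999)
        corrected = drift_correct(fid, fid)
        span = np.polyfit(corrected["frame"], corrected["x_um"], 1)[0] * 999
        assert abs(span) * 1000 < 5.0

    def test_zero_drift_movie_untouched_within_noise(self):
        locs, fid = self._tables(0.0)
        out = drift_correct(locs, fid)
        assert np.abs(out["x_um"] - locs["x_um"]).max() < 0.005

    def test_fiducial_variance_never_increased(self):
        locs, fid = self._tables(0.05 / 999, noise=0.004, seed=3)
        out = drift_correct(fid, fid)
        for ax in ("x_um", "y_um"):
            assert out[ax].std() <= fid[ax].std() + 1e-12

    def test_no_fiducials_rejected(self):
        locs, _ = self._tables(0.0)
        with pytest.raises(ValueError):
            drift_correct(locs, locs.iloc[0:0])


class TestFilterAndRescale:
    def test_paper_thresholds_on_toy_table(self):
        table = pd.DataFrame({
            "uncertainty_xy_nm": [20.0, 150.0, 60.0, 99.0, 30.0],
            "photons": [5e3, 4e3, 2e6, 8e5, 1e4]})
        out = filter_localizations(table, SCATTERING_FILTER_RULES)
        assert len(out) == 3
        assert out.attrs["filter_counts"] == {"uncertainty_xy_nm": 1,
                                              "photons": 1}

    def test_empty_and_all_pass_tables(self):
        empty = pd.DataFrame({"photons": [], "uncertainty_xy_nm": []})
        assert len(filter_localizations(empty, SCATTERING_FILTER_RULES)) == 0
        ok = pd.DataFrame({"photons": [1.0, 2.0],
                           "uncertainty_xy_nm": [5.0, 6.0]})
        out = filter_localizations(ok, SCATTERING_FILTER_RULES)
        pd.testing.assert_frame_equal(out, ok)

    def test_rule_on_missing_column_rejected(self):
        with pytest.raises(KeyError):
            filter_localizations(pd.DataFrame({"photons": [1.0]}),
                                 {"nope": {"max": 1}})

    def test_axial_rescaling(self):
        t = pd.DataFrame({"z_um": [0.1, -0.2], "x_um": [1.0, 2.0]})
        out = rescale_axial(t, 0.75)
        np.testing.assert_allclose(out["z_um"], [0.075, -0.15])
        assert out["x_um"].equals(t["x_um"])
        assert rescale_axial(t, 1.0)["z_um"].equals(t["z_um"])
        with pytest.raises(KeyError):
            rescale_axial(t.drop(columns="z_um"), 0.75)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.permutations(list(range(8))))
    def test_filter_then_rescale_order_independent(self, order):
        base = pd.DataFrame({
            "z_um": np.linspace(-1, 1, 8),
            "photons": np.linspace(100, 5000, 8),
            "uncertainty_xy_nm": np.linspace(10, 160, 8)})
        shuffled = base.iloc[order].reset_index(drop=True)
        a = rescale_axial(filter_localizations(base, SCATTERING_FILTER_RULES))
        b = rescale_axial(filter_localizations(shuffled,
                                               SCATTERING_FILTER_RULES))
        key = ["photons"]
        pd.testing.assert_frame_equal(
            a.sort_values(key).reset_index(drop=True),
            b.sort_values(key).reset_index(drop=True))


class TestRegions:
    def test_constructed_counts_normalized(self):
        xs = np.concatenate([np.full(n, c) for n, c in
                             zip((10, 8, 6, 4, 2), (1, 3, 5, 7, 9))])
        t = pd.DataFrame({"x_um": xs})
        rs = bin_regions(t, 5, bounds=(0.0, 10.0))
        np.testing.assert_allclose(rs.table["norm_count"],
                                   [1.0, 0.8, 0.6, 0.4, 0.2])
        assert rs.table["count"].sum() == len(t)

    def test_uniform_occupancy(self):
        rng = np.random.default_rng(0)
        t = pd.DataFrame({"x_um": rng.uniform(0, 50, 20000)})
        rs = bin_regions(t, 5, bounds=(0.0, 50.0))
        n = 20000 / 5
        sigma = np.sqrt(n * 0.8)
        assert np.all(np.abs(rs.table["count"] - n) < 3 * sigma)

    def test_matches_bruteforce_assignment(self):
        rng = np.random.default_rng(1)
        t = pd.DataFrame({"x_um": rng.uniform(-3, 7, 500)})
        rs = bin_regions(t, 5, bounds=(-3.0, 7.0))
        edges = np.linspace(-3, 7, 6)
        brute = [int(np.sum((t.x_um >= edges[i])
                            & (t.x_um < edges[i + 1]))) for i in range(5)]
        brute[-1] += int(np.sum(t.x_um == 7.0))
        assert list(rs.table["count"]) == brute

    def test_empty_first_region_flagged(self):
        t = pd.DataFrame({"x_um": np.full(5, 9.0)})
        with pytest.warns(UserWarning, match="region 1"):
            rs = bin_regions(t, 5, bounds=(0.0, 10.0))
        assert np.isnan(rs.table["norm_count"].iloc[0])


class TestSBR:
    def test_definition_and_scale_invariance(self):
        t = pd.DataFrame({"photons": [1000.0], "background": [10.0],
                          "sigma_um": [0.165]})
        cam = CameraModel()
        s1 = compute_sbr(t, cam).iloc[0]
        peak = 1000.0 * cam.pixel_size_x * cam.pixel_size_y \
            / (2 * np.pi * 0.165**2)
        assert s1 == pytest.approx(peak / 10.0)
        t2 = t.assign(photons=t.photons * 2, background=t.background * 2)
        assert compute_sbr(t2, cam).iloc[0] == pytest.approx(s1)

    def test_zero_background_flagged_infinite(self):
        t = pd.DataFrame({"photons": [100.0, 100.0],
                          "background": [0.0, 5.0],
                          "sigma_um": [0.165, 0.165]})
        with pytest.warns(UserWarning, match="infinite"):
            s = compute_sbr(t)
        assert np.isinf(s.iloc[0]) and np.isfinite(s.iloc[1])

    def test_line_scan_mode(self):
        spacing = 0.157
        x = np.arange(41) * spacing
        prof = 10.0 + 90.0 * np.exp(-((x - x[20]) / 0.3) ** 2)
        assert sbr_from_line_scan(prof, spacing) == pytest.approx(10.0,
                                                                  rel=0.01)


class TestFRC:
    @staticmethod
    def _ring_table(sigma_nm, n=15000, seed=4):
        rng = np.random.default_rng(seed)
        th = rng.uniform(0, 2 * np.pi, n)
        return pd.DataFrame({
            "x_um": 2 * np.cos(th) + rng.normal(0, sigma_nm / 1000, n),
            "y_um": 2 * np.sin(th) + rng.normal(0, sigma_nm / 1000, n)})

    def test_identical_halves_bounded_by_two_pixels(self):
        t = self._ring_table(10)
        res = frc_resolution(t, halves=(t, t))
        assert res <= 2 * 8.0

    def test_resolution_degrades_with_localization_error(self):
        r10 = frc_resolution(self._ring_table(10), seed=1)
        r30 = frc_resolution(self._ring_table(30), seed=1)
        assert r30 > r10

    def test_translation_invariance(self):
        t = self._ring_table(15)
        r0 = frc_resolution(t, seed=2)
        # translate by an exact number of render pixels
        shifted = t.assign(x_um=t.x_um + 125 * 0.008,
                           y_um=t.y_um - 50 * 0.008)
        assert frc_resolution(shifted, seed=2) == pytest.approx(r0, rel=1e-9)

    def test_too_few_localizations_rejected(self):
        with pytest.raises(ValueError):
            frc_resolution(self._ring_table(10, n=50))


class TestEndToEnd:
    def test_movie_round_trip_recovers_positions(self, camera, psf):
        em = EmitterSet(np.array([[-1.0, 0.5, 0.0], [1.5, -1.0, 0.0]]),
                        4000.0, 1.0, np.array([False, False]))
        movie, truth = simulate_frames(em, None, psf, camera, 30, seed=4,
                                       fov_px=(48, 48),
                                       background_photons=2.0)
        locs = localize_movie(movie, camera, psf)
        assert len(locs) >= 50
        med = locs.groupby(locs["x_um"].round(0))
        for x, y in [(-1.0, 0.5), (1.5, -1.0)]:
            near = locs[(locs.x_um - x) ** 2 + (locs.y_um - y) ** 2 < 0.04]
            assert len(near) >= 20
            err = np.hypot(near.x_um.median() - x, near.y_um.median() - y)
            pred = near.uncertainty_xy_nm.median() / 1000
            assert err < 5 * pred + 0.01
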