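"""Sheet construction: masks, dithering, steering, mirror reflection."""

import numpy as np
import pytest

from solls import (BeamVolume, MaskSpec, MirrorSpec, OpticalTrain, SheetSpec,
                   SteeringState, apply_dither, make_gaussian_sheet,
                   mask_transmission, mirror_tilt_deg, reflect_at_mirror,
                   steer_sheet)
from solls.beams import gaussian_focal_field
from solls.metrics import one_over_e2_radius, thickness_curve


class TestMaskTransmission:
    def test_outside_amplitude_follows_optical_density(self, train):
        field = mask_transmission(MaskSpec(), train)
        assert field.amplitude.real.min() == pytest.approx(10 ** (-5.2 / 2))
        assert field.amplitude.real.max() == pytest.approx(1.0)

    def test_od_zero_is_fully_transparent(self, train):
        field = mask_transmission(MaskSpec(optical_density=0.0), train)
        np.testing.assert_allclose(field.amplitude.real, 1.0)

    def test_open_area_power_fraction(self, train):
        # grid chosen so slit edges align with pixel boundaries: the
        # transmitted power fraction is exactly the slit-area fraction
        mask = MaskSpec(slit_width=0.09, slit_length=2.01,
                        optical_density=200.0)
        field = mask_transmission(mask, train, n_grid=1200, extent_mm=12.0)
        frac = np.sum(np.abs(field.amplitude) ** 2) / field.amplitude.size
        slit_area = 3 * 0.09 * 2.01
        assert frac == pytest.approx(slit_area / 144.0, rel=1e-9)
        # default mask on an unaligned grid: agreement within edge-pixel error
        field = mask_transmission(MaskSpec(optical_density=200.0), train)
        frac = np.sum(np.abs(field.amplitude) ** 2) / field.amplitude.size
        assert frac == pytest.approx(3 * 0.08 * 2.0 / 144.0, rel=0.07)

    def test_slit_outside_pupil_rejected(self, train):
        with pytest.raises(ValueError, match="pupil"):
            mask_transmission(MaskSpec(slit_centers=(-3.0, 0.0, 3.0)), train)


class TestLatticeSheet:
    def test_focal_z_profile_symmetric(self, lattice_focal):
        inten = np.abs(lattice_focal.amplitude) ** 2
        prof = inten[inten.shape[0] // 2]
        n = len(prof)
        sym = prof[n // 2 + 1:]
        asym = np.abs(sym - prof[1:n // 2][::-1]) / prof.max()
        assert asym.max() <= 1e-6

    def test_focal_thickness_matches_request(self, lattice_sheet):
        prof = thickness_curve(lattice_sheet)
        i0 = np.argmin(np.abs(prof.x_positions))
        assert prof.w[i0] == pytest.approx(1.8, rel=0.05)

    def test_side_lobes_below_single_bessel_sheet(self, lattice_sheet):
        """Dithered lattice keeps less z-energy outside the central lobe
        than an undithered single-Bessel sheet of equal lobe thickness."""
        iy = lattice_sheet.shape[1] // 2
        i0 = lattice_sheet.shape[0] // 2
        prof = lattice_sheet.intensity[i0, iy, :]
        dz = lattice_sheet.dz

        def outside_fraction(p):
            pk = int(np.argmax(p))
            lo = hi = pk
            while lo > 0 and p[lo - 1] < p[lo]:
                lo -= 1
            while hi < len(p) - 1 and p[hi + 1] < p[hi]:
                hi += 1
            return 1.0 - p[lo:hi + 1].sum() / p.sum()

        # cosine sheet (two interfering plane waves = single-Bessel z
        # cross-section) with its central lobe fitted to the same 1/e² radius
        w_lat = one_over_e2_radius(prof, dz)
        kz0 = 1.1938 / w_lat  # cos² falls to 1/e² at kz0·z = 1.1938
        z = (np.arange(len(prof)) - len(prof) // 2) * dz
        bessel = np.cos(kz0 * z) ** 2 * np.exp(-(z / (len(prof) * dz / 3)) ** 2)
        assert outside_fraction(prof) < outside_fraction(bessel)


class TestGaussianSheet:
    def test_waist_within_one_percent(self, gaussian_sheet):
        prof = thickness_curve(gaussian_sheet)
        assert prof.waist_w0 == pytest.approx(1.8, rel=0.01)

    def test_uniform_along_width(self, gaussian_focal):
        inten = np.abs(gaussian_focal.amplitude) ** 2
        iz = inten.shape[1] // 2
        y, _ = gaussian_focal.axes()
        central = inten[np.abs(y) <= 32.9 / 2, iz]
        assert np.ptp(central) / central.max() <= 0.01

    def test_waist_below_diffraction_limit_rejected(self, train):
        with pytest.raises(ValueError, match="diffraction"):
            gaussian_focal_field(SheetSpec(family="gaussian",
                                           target_waist_w0=0.05), train)


class TestDither:
    def test_zero_amplitude_is_identity(self, gaussian_sheet):
        out = apply_dither(gaussian_sheet, "y", 0.0)
        np.testing.assert_array_equal(out.intensity, gaussian_sheet.intensity)

    def test_per_plane_energy_conserved(self, lattice_sheet):
        out = apply_dither(lattice_sheet, "y", 2.2)
        before = lattice_sheet.intensity.sum(axis=(1, 2))
        after = out.intensity.sum(axis=(1, 2))
        np.testing.assert_allclose(after, before, rtol=1e-6)

    @staticmethod
    def _ripple(p, amp, dy=0.06):
        y = np.arange(512) * dy
        plane = 1.0 + np.cos(2 * np.pi * y / p)
        vol = BeamVolume(np.tile(plane[None, :, None], (3, 1, 8)),
                         1.0, dy, 0.1)
        out = apply_dither(vol, "y", amp)
        prof = out.intensity[1, :, 4]
        m = int(np.ceil(amp / dy)) + 2   # skip the periodic wrap seam
        prof = prof[m:-m]
        return (prof.max() - prof.min()) / (2 * prof.mean())

    def test_ripple_matches_sine_dwell_average_oracle(self):
        # independent oracle: the time-average of cos(2π(y+A·sinφ)/p)
        # keeps a residual fundamental of amplitude |∮cos(2πA·sinφ/p)dφ|/2π
        p, amp = 3.79, 3.5
        phi = np.linspace(0, 2 * np.pi, 20001)
        residual = abs(np.trapezoid(np.cos(2 * np.pi * amp * np.sin(phi) / p),
                                    phi)) / (2 * np.pi)
        assert self._ripple(p, amp) == pytest.approx(residual, abs=0.01)

    def test_fundamental_nulling_amplitude_flattens_below_5pct(self):
        # smallest amplitude ≥ p that nulls the residual fundamental
        # (first zero of the dwell average beyond 2πA/p = 2π)
        p = 3.79
        amp = 8.6537 / (2 * np.pi) * p
        assert amp >= p
        assert self._ripple(p, amp) <= 0.05

    def test_negative_amplitude_rejected(self, gaussian_sheet):
        with pytest.raises(ValueError):
            apply_dither(gaussian_sheet, "y", -1.0)


class TestSteering:
    def test_calibrated_displacements(self):
        assert SteeringState(galvo_z_volts=0.01).displacement() == \
            pytest.approx((0.0, 0.0, 0.64))
        assert SteeringState(galvo_z_volts=0.05).displacement() == \
            pytest.approx((0.0, 0.0, 3.20))
        assert SteeringState(galvo_y_volts=0.01).displacement() == \
            pytest.approx((0.0, 0.35, 0.0))
        assert SteeringState(tunable_lens_mA=10.0).displacement() == \
            pytest.approx((2.41, 0.0, 0.0))

    def test_gaussian_family_multiplier(self):
        s = SteeringState(galvo_z_volts=0.01, family_multiplier=2.0)
        assert s.displacement()[2] == pytest.approx(1.28)

    def test_composition_is_exactly_linear(self, gaussian_sheet):
        a = SteeringState(galvo_z_volts=0.02, galvo_y_volts=0.01)
        b = SteeringState(galvo_z_volts=-0.01, tunable_lens_mA=5.0)
        both = SteeringState(galvo_z_volts=0.01, galvo_y_volts=0.01,
                             tunable_lens_mA=5.0)
        two_step = steer_sheet(steer_sheet(gaussian_sheet, a), b)
        one_step = steer_sheet(gaussian_sheet, both)
        assert two_step.origin == pytest.approx(one_step.origin)
        np.testing.assert_array_equal(two_step.intensity, one_step.intensity)

    def test_shift_beyond_extent_rejected(self, gaussian_sheet):
        with pytest.raises(ValueError, match="exceeds"):
            steer_sheet(gaussian_sheet, SteeringState(galvo_z_volts=10.0))


class TestMirror:
    def _blob(self):
        x = np.linspace(-10, 10, 41)
        z = np.linspace(-5, 5, 41)
        inten = np.exp(-((x[:, None] / 6) ** 2) - (z[None, :] / 1.5) ** 2)
        return BeamVolume(np.tile(inten[:, None, :], (1, 5, 1)),
                          0.5, 0.5, 0.25, (-10, -1.25, -5))

    def test_45_degree_wall_gives_horizontal_sheet(self):
        assert mirror_tilt_deg(MirrorSpec(wall_angle_deg=45.0)) == 0.0
        vol = self._blob()
        out = reflect_at_mirror(vol, MirrorSpec(wall_angle_deg=45.0))
        np.testing.assert_array_equal(out.intensity, vol.intensity)

    def test_39_degree_wall_tilts_12_degrees(self):
        mirror = MirrorSpec(wall_angle_deg=39.0)
        assert mirror_tilt_deg(mirror) == pytest.approx(12.0)
        vol = self._blob()
        out = reflect_at_mirror(vol, mirror)
        # slope of the z-centroid along x measures the beam-axis tilt
        xs = vol.x_positions()
        zs = vol.z_positions()
        prof = out.intensity.sum(axis=1)
        sel = prof.sum(axis=1) > 0.1 * prof.sum(axis=1).max()
        zc = prof @ zs / prof.sum(axis=1)
        slope = np.polyfit(xs[sel], zc[sel], 1)[0]
        assert np.rad2deg(np.arctan(abs(slope))) == pytest.approx(12.0, abs=1.0)

    def test_reflection_conserves_total_intensity(self):
        vol = self._blob()
        out = reflect_at_mirror(vol, MirrorSpec(wall_angle_deg=39.0))
        assert out.intensity.sum() == pytest.approx(vol.intensity.sum(),
                                                    rel=1e-6)

    def test_invalid_wall_angle_rejected(self):
        with pytest.raises(ValueError):
            MirrorSpec(wall_angle_deg=95.0)
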