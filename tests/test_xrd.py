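"""XRD strain analysis: masking, integration, peak fits, Bragg, strain."""

import math

import numpy as np
import pytest

from bonerad import (
    DetectorGeometry,
    PeakFitResult,
    RadialProfile,
    azimuthal_integration,
    build_detector_mask,
    c_to_two_theta,
    fit_voigt_linear,
    strain_series,
    subtract_empty_beam,
    two_theta_to_c,
)
from bonerad.synthetic import SyntheticScenario, gen_diffraction_sequence
from scipy.special import voigt_profile

GEOM = DetectorGeometry(50.0, 100.0, (127.0, 127.0), 18.0)


def ring_frame(radius_px=40.0, width_px=1.5, shape=(255, 255), amplitude=1000.0):
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    r = np.hypot(xx - GEOM.beam_center_px[0], yy - GEOM.beam_center_px[1])
    return amplitude * np.exp(-((r - radius_px) ** 2) / (2 * width_px**2))


class TestMask:
    def test_no_stripes_all_valid(self):
        assert build_detector_mask((16, 16)).all()

    def test_stripe_pixel_count(self):
        mask = build_detector_mask((100, 80), [("v", 10, 10)])
        assert (~mask).sum() == 10 * 100

    def test_stripe_outside_frame_rejected(self):
        with pytest.raises(ValueError, match="outside frame"):
            build_detector_mask((50, 50), [("h", 45, 10)])

    def test_masked_integration_matches_gap_free(self):
        """Stripes removed by the mask leave the ring profile unchanged."""
        frame = ring_frame()
        gapped = frame.copy()
        gapped[100:110, :] = 0.0
        mask = build_detector_mask(frame.shape, [("h", 100, 10)])
        full = azimuthal_integration(frame, GEOM, n_bins=200)
        masked = azimuthal_integration(gapped, GEOM, mask, n_bins=200)
        sel = full.npix > 0
        np.testing.assert_allclose(masked.intensity[sel], full.intensity[sel],
                                   rtol=0.05, atol=1e-6)


class TestAzimuthalIntegration:
    def test_ring_position_geometry_oracle(self):
        """Peak lands at 2theta = atan(r px / distance), within one bin."""
        profile = azimuthal_integration(ring_frame(), GEOM, n_bins=300)
        peak_tth = profile.two_theta_deg[np.argmax(profile.intensity)]
        expected = math.degrees(math.atan(40.0 * 0.1 / 50.0))
        bin_width = np.diff(profile.two_theta_deg).mean()
        assert abs(peak_tth - expected) <= bin_width

    def test_uniform_frame_flat_profile(self):
        profile = azimuthal_integration(np.full((255, 255), 7.0), GEOM, n_bins=100)
        sel = profile.npix > 0
        np.testing.assert_allclose(profile.intensity[sel], 7.0, rtol=1e-12)

    def test_rotation_invariance_about_beam_center(self):
        frame = ring_frame() + np.linspace(0, 1, 255)[None, :]  # break symmetry
        rotated = np.rot90(frame).copy()
        a = azimuthal_integration(frame, GEOM, n_bins=150)
        b = azimuthal_integration(rotated, GEOM, n_bins=150)
        np.testing.assert_array_equal(a.npix, b.npix)
        np.testing.assert_allclose(a.intensity, b.intensity, rtol=1e-10)

    def test_total_count_conservation(self):
        """sum(mean * npix) equals the summed unmasked pixel counts."""
        rng = np.random.default_rng(2)
        frame = rng.poisson(20.0, (255, 255)).astype(float)
        mask = build_detector_mask(frame.shape, [("v", 30, 5)])
        profile = azimuthal_integration(frame, GEOM, mask, n_bins=400)
        total = (profile.intensity * profile.npix).sum()
        assert total == pytest.approx(frame[mask].sum(), rel=1e-9)


class TestSubtraction:
    def grid_profile(self, values):
        tth = np.linspace(5, 15, values.size)
        return RadialProfile(tth, values, np.ones(values.size, int))

    def test_self_subtraction_zero(self):
        p = self.grid_profile(np.linspace(1, 5, 50))
        assert np.all(subtract_empty_beam(p, p).intensity == 0.0)

    def test_zero_empty_identity(self):
        p = self.grid_profile(np.linspace(1, 5, 50))
        z = self.grid_profile(np.zeros(50))
        np.testing.assert_array_equal(subtract_empty_beam(p, z).intensity, p.intensity)

    def test_constructed_pair_recovers_signal(self):
        rng = np.random.default_rng(3)
        signal = np.exp(-((np.linspace(5, 15, 200) - 10) ** 2) / 0.5) * 100
        bg = 40 + 2 * np.linspace(5, 15, 200)
        noisy = rng.poisson(signal + bg).astype(float)
        est = subtract_empty_beam(self.grid_profile(noisy), self.grid_profile(bg))
        assert np.abs(est.intensity - signal).mean() < 3 * np.sqrt(bg.mean())

    def test_grid_mismatch_rejected(self):
        a = self.grid_profile(np.ones(50))
        b = RadialProfile(np.linspace(5.1, 15.1, 50), np.ones(50), np.ones(50, int))
        with pytest.raises(ValueError, match="grids"):
            subtract_empty_beam(a, b)


def synthetic_voigt(center=11.5, sigma=0.06, gamma=0.02, amp=50.0,
                    slope=-2.0, intercept=40.0, n=200):
    tth = np.linspace(10.5, 12.5, n)
    y = amp * voigt_profile(tth - center, sigma, gamma) + slope * tth + intercept
    return tth, y


class TestVoigtFit:
    def test_noise_free_parameter_recovery(self):
        tth, y = synthetic_voigt()
        fit = fit_voigt_linear(RadialProfile(tth, y, np.ones(tth.size, int)))
        assert fit.center_2theta_deg == pytest.approx(11.5, abs=1e-4)
        assert fit.gaussian_sigma_deg == pytest.approx(0.06, rel=1e-3)
        assert fit.lorentzian_gamma_deg == pytest.approx(0.02, rel=1e-2)
        assert fit.linear_slope == pytest.approx(-2.0, rel=1e-3)

    def test_translation_equivariance(self):
        tth, y = synthetic_voigt(center=11.50)
        _, y2 = synthetic_voigt(center=11.51)
        f1 = fit_voigt_linear(RadialProfile(tth, y, np.ones(tth.size, int)))
        f2 = fit_voigt_linear(RadialProfile(tth, y2, np.ones(tth.size, int)))
        assert f2.center_2theta_deg - f1.center_2theta_deg == pytest.approx(0.01, abs=2e-4)

    def test_center_bias_under_poisson_noise(self):
        """Center bias < 5% of a bin width at peak SNR ~20, 60 replicates."""
        tth, clean = synthetic_voigt(amp=400 * 0.06 * np.sqrt(2 * np.pi))
        rng = np.random.default_rng(4)
        centers = []
        for _ in range(60):
            noisy = rng.poisson(np.clip(clean, 0, None)).astype(float)
            fit = fit_voigt_linear(RadialProfile(tth, noisy, np.ones(tth.size, int)))
            centers.append(fit.center_2theta_deg)
        bin_width = np.diff(tth).mean()
        assert abs(np.mean(centers) - 11.5) < 0.05 * bin_width

    def test_empty_bins_in_window_rejected(self):
        tth, y = synthetic_voigt()
        npix = np.ones(tth.size, int)
        npix[100] = 0
        with pytest.raises(ValueError, match="empty integration bins"):
            fit_voigt_linear(RadialProfile(tth, y, npix))


class TestBragg:
    def test_known_lattice_angle(self):
        tth = c_to_two_theta(6.88, GEOM)
        assert tth == pytest.approx(11.492, abs=5e-3)
        assert two_theta_to_c(tth, GEOM) == pytest.approx(6.88, abs=1e-10)

    def test_wavelength_consistency(self):
        assert GEOM.wavelength_a == pytest.approx(12.3984 / 18.0, abs=1e-4)

    def test_halving_wavelength_halves_sine(self):
        g2 = DetectorGeometry(50.0, 100.0, (127.0, 127.0), 36.0)
        s1 = math.sin(math.radians(c_to_two_theta(6.88, GEOM)) / 2)
        s2 = math.sin(math.radians(c_to_two_theta(6.88, g2)) / 2)
        assert s2 == pytest.approx(s1 / 2, rel=1e-12)

    def test_round_trip_identity(self):
        for c in (6.5, 6.88, 7.2):
            assert two_theta_to_c(c_to_two_theta(c, GEOM), GEOM) == pytest.approx(
                c, abs=1e-10
            )

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            two_theta_to_c(0.0, GEOM)
        with pytest.raises(ValueError):
            c_to_two_theta(0.3, GEOM)  # no Bragg solution


def fit_from_center(center, se=1e-4):
    return PeakFitResult(center, se, 0.05, 0.02, 1.0, 0.0, 0.0, 1.0)


class TestStrainSeries:
    def test_constant_center_zero_strain(self):
        fits = [fit_from_center(11.5) for _ in range(4)]
        s = strain_series(fits, [0, 40, 80, 160], GEOM, fit_relaxation=False)
        np.testing.assert_allclose(s.strain_pct, 0.0, atol=1e-12)

    def test_noise_free_schedule_exact_recovery(self):
        t = np.array([0.0, 40.0, 80.0, 160.0, 240.0, 320.0])
        strain_true = 0.2 * (1 - np.exp(-0.01 * t))
        c_true = 6.88 * (1 + strain_true / 100)
        fits = [fit_from_center(c_to_two_theta(c, GEOM)) for c in c_true]
        s = strain_series(fits, t, GEOM)
        np.testing.assert_allclose(s.strain_pct, strain_true, atol=1e-8)
        assert s.relaxation_rate == pytest.approx(0.01, rel=1e-4)
        assert s.relaxation_plateau_pct == pytest.approx(0.2, rel=1e-4)


class TestFrameRoundTrip:
    @pytest.fixture(scope="class")
    def recovered(self):
        scenario = SyntheticScenario(seed=5)
        frames, empty, mask, truth, geometry = gen_diffraction_sequence(scenario)
        empty_profile = azimuthal_integration(empty, geometry, mask)
        fits = [
            fit_voigt_linear(
                subtract_empty_beam(azimuthal_integration(f, geometry, mask),
                                    empty_profile)
            )
            for f in frames
        ]
        return strain_series(fits, truth["exposure_s"], geometry), truth

    def test_strain_recovered_within_hundredth_pct_point(self, recovered):
        series, truth = recovered
        err = series.strain_pct - truth["strain_pct_true"].to_numpy()
        assert np.abs(err).max() < 0.01

    def test_strain_monotone_for_monotone_schedule(self, recovered):
        series, _ = recovered
        assert np.all(np.diff(series.strain_pct) > -0.005)

    def test_relaxation_parameters_recovered(self, recovered):
        series, truth = recovered
        assert series.relaxation_rate == pytest.approx(truth.attrs["rate_per_s"], rel=0.1)
        assert series.relaxation_plateau_pct == pytest.approx(
            truth.attrs["plateau_pct"], rel=0.05
        )

    def test_flux_ordering_of_recovered_rates(self):
        """Higher flux, faster programmed relaxation, larger fitted rate."""
        rates = []
        for flux in (2.0e7, 5.5e7, 1.1e8):
            scenario = SyntheticScenario(seed=6)
            frames, empty, mask, truth, geometry = gen_diffraction_sequence(
                scenario, flux=flux, times_s=(0.0, 60.0, 140.0, 240.0, 320.0)
            )
            empty_profile = azimuthal_integration(empty, geometry, mask)
            fits = [
                fit_voigt_linear(
                    subtract_empty_beam(azimuthal_integration(f, geometry, mask),
                                        empty_profile)
                )
                for f in frames
            ]
            s = strain_series(fits, truth["exposure_s"], geometry, flux=flux)
            rates.append(s.relaxation_rate)
        assert rates[0] < rates[1] < rates[2]
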