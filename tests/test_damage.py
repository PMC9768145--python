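"""Damage-spread model: sources, convolution, thresholds, kinetics fits."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bonerad import (
    DamageModelConfig,
    DamageSpreadModel,
    ExponentialDamageModel,
    PenetrationDistribution,
    beam_source,
    cumulative_deposition,
    damage_extent,
    energy_deposition,
    relative_damage,
    relative_damage_volume,
)
from bonerad.synthetic import gen_damage_curve

NOTAIL = DamageModelConfig(tail_extrapolation=False)


def _integral(x, y):
    return float(y.sum() * (x[1] - x[0]))


class TestBeamSource:
    def test_center_inside_outside_edge(self):
        assert beam_source(20.0, 0.0) == 1.0
        assert beam_source(20.0, 15.0) == 0.0
        assert beam_source(20.0, 10.0) == 0.5  # distributional edge convention
        assert beam_source(20.0, -10.0) == 0.5

    def test_nonpositive_width_rejected(self):
        with pytest.raises(ValueError):
            beam_source(0.0, 0.0)


class TestEnergyDeposition:
    def test_point_mass_kernel_identity(self):
        p = PenetrationDistribution.from_point_mass()
        x, eta = energy_deposition(10.0, p, NOTAIL)
        assert eta.max() == pytest.approx(1.0, rel=1e-9)
        inside = np.abs(x) < 4.9
        assert np.all(eta[inside] > 0.999)
        assert _integral(x, eta) == pytest.approx(10.0, rel=1e-9)

    @given(
        w=st.floats(0.5, 60.0),
        lam=st.floats(0.2, 4.0),
        seedmass=st.integers(0, 2**31 - 1),
    )
    @settings(max_examples=25, deadline=None)
    def test_conservation_for_arbitrary_p(self, w, lam, seedmass):
        """integral(eta) = w within 0.1% for random penetration histograms."""
        rng = np.random.default_rng(seedmass)
        half = rng.random(60) * np.exp(-np.arange(60) / (lam * 10))
        half /= 2 * half.sum()
        edges = np.linspace(0, 6 * lam, 61)
        p = PenetrationDistribution(
            np.concatenate([-edges[::-1], edges[1:]]),
            np.concatenate([half[::-1], half]),
            0, "random", 0.0,
        )
        x, eta = energy_deposition(w, p, NOTAIL)
        assert _integral(x, eta) == pytest.approx(w, rel=1e-3)
        assert np.all(eta >= 0)

    def test_symmetric_about_zero(self):
        p = PenetrationDistribution.from_laplace(1.0)
        x, eta = energy_deposition(8.0, p, NOTAIL)
        np.testing.assert_allclose(eta, eta[::-1], atol=1e-12 * eta.max())

    def test_laplace_tail_closed_form(self):
        """eta(x) = exp(-x/lam) sinh(w/2lam) outside the beam, within 0.5%."""
        lam, w = 1.5, 6.0
        p = PenetrationDistribution.from_laplace(lam, extent_um=40, n_bins=4000)
        x, eta = energy_deposition(w, p, NOTAIL)
        sel = (x > w / 2 + 1.0) & (x < 15.0)
        expected = np.exp(-x[sel] / lam) * np.sinh(w / (2 * lam))
        np.testing.assert_allclose(eta[sel], expected, rtol=5e-3)

    def test_truncating_grid_rejected(self):
        p = PenetrationDistribution.from_laplace(2.0, extent_um=30)
        with pytest.raises(ValueError, match="grid_extent too small"):
            energy_deposition(10.0, p, DamageModelConfig(
                grid_extent=5.0, tail_extrapolation=False))


class TestCumulativeDeposition:
    def test_zero_time(self):
        assert np.all(cumulative_deposition(np.ones(5), 0.0) == 0.0)

    def test_linearity_in_time(self):
        eta = np.array([0.1, 0.5, 1.0])
        np.testing.assert_allclose(
            cumulative_deposition(eta, 640.0), 2 * cumulative_deposition(eta, 320.0)
        )
        np.testing.assert_allclose(cumulative_deposition(eta, 320.0), 320.0 * eta)


class TestDamageExtent:
    def test_sharp_beam_gives_half_width(self):
        p = PenetrationDistribution.from_point_mass()
        x, eta = energy_deposition(10.0, p, NOTAIL)
        h = cumulative_deposition(eta, 1.0)  # H=1 inside the beam
        xw = damage_extent(x, h, NOTAIL)
        # within the point-mass kernel half-width plus one grid step
        assert xw == pytest.approx(5.0, abs=2e-3)

    def test_no_damage_sentinel(self):
        x = np.linspace(-5, 5, 101)
        h = np.full(101, 0.01)
        h[50] = 0.04
        assert damage_extent(x, h) is None
        assert relative_damage(None, 10.0) == 0.0

    def test_laplace_threshold_closed_form(self):
        """x_w = lam ln(dt sinh(w/2lam)/thr) for a Laplace kernel, within 0.5%."""
        lam, w, dt = 1.5, 100.0, 320.0
        p = PenetrationDistribution.from_laplace(lam, extent_um=80, n_bins=8000)
        cfg = DamageModelConfig(tail_extrapolation=False)
        x, eta = energy_deposition(w, p, cfg)
        xw = damage_extent(x, cumulative_deposition(eta, dt), cfg)
        expected = lam * np.log(dt * np.sinh(w / (2 * lam)) / 0.05)
        assert xw == pytest.approx(expected, rel=5e-3)


class TestRatios:
    def test_relative_damage_examples(self):
        assert relative_damage(10.0, 20.0) == 1.0
        assert relative_damage(20.0, 20.0) == 2.0

    def test_volume_product_examples(self):
        assert relative_damage_volume(1.0, 1.0) == 1.0
        assert relative_damage_volume(1.5, 1.0) == 1.5

    def test_ellipse_area_identity(self):
        """Z equals the damaged-ellipse / beam-disc area ratio."""
        zh, zv, w = 1.7, 1.2, 20.0
        a, b = zh * w / 2, zv * w / 2
        area_ratio = (np.pi * a * b) / (np.pi * (w / 2) ** 2)
        assert relative_damage_volume(zh, zv) == pytest.approx(area_ratio, rel=1e-12)


class TestModelMonotonicity:
    @pytest.fixture(scope="class")
    def model(self):
        return DamageSpreadModel(PenetrationDistribution.from_laplace(1.0),
                                 DamageModelConfig(tail_extrapolation=False))

    def test_zeta_nondecreasing_in_time(self, model):
        zetas = [model.evaluate(20.0, dt).zeta_h for dt in (40, 80, 160, 320)]
        assert np.all(np.diff(zetas) >= 0)

    def test_zeta_antitone_in_beam_width(self, model):
        zetas = [model.evaluate(w, 320.0).zeta_h for w in (5.0, 10.0, 20.0, 100.0)]
        assert np.all(np.diff(zetas) <= 0)

    def test_z_ordering_in_time(self, model):
        assert (
            model.evaluate(20.0, 320.0).relative_damage_volume
            >= model.evaluate(20.0, 80.0).relative_damage_volume
        )

    def test_computed_zeta_v_from_point_mass_is_unity(self):
        ph = PenetrationDistribution.from_laplace(1.0)
        pv = PenetrationDistribution.from_point_mass()
        model = DamageSpreadModel(
            ph,
            DamageModelConfig(zeta_v_mode="computed", tail_extrapolation=False),
            penetration_vertical=pv,
        )
        res = model.evaluate(20.0, 320.0)
        assert res.zeta_v == pytest.approx(1.0, abs=0.01)
        assert res.relative_damage_volume == pytest.approx(res.zeta_h * res.zeta_v)

    def test_sweep_covers_grid(self, model):
        df = model.sweep([5.0, 20.0], [80.0, 320.0])
        assert len(df) == 4
        assert set(map(tuple, df[["w_um", "dt_s"]].to_numpy())) == {
            (5.0, 80.0), (5.0, 320.0), (20.0, 80.0), (20.0, 320.0),
        }


class TestExponentialDamageFit:
    def test_noise_free_exact_recovery(self):
        for k, plateau in [(0.07, 150.0), (0.02, 260.0), (0.33, 120.0)]:
            t, d = gen_damage_curve(k, plateau, 0.0, n_points=20, seed=0)
            res = ExponentialDamageModel(t, d).fit()
            assert res.k == pytest.approx(k, rel=1e-6)
            assert res.plateau == pytest.approx(plateau, rel=1e-6)

    def test_constant_series_is_flat(self):
        t = np.linspace(0, 320, 10)
        res = ExponentialDamageModel(t, np.full(10, 100.0)).fit()
        assert np.max(np.abs(res.predict(t) - 100.0)) < 1e-6

    def test_recovery_under_noise_simulation_study(self):
        """Median k error < 15% at 3% noise over 100 seeded replicates."""
        errs = []
        for rep in range(100):
            t, d = gen_damage_curve(0.07, 150.0, 3.0, n_points=20, seed=5000 + rep)
            errs.append(abs(ExponentialDamageModel(t, d).fit().k - 0.07) / 0.07)
        assert np.median(errs) < 0.15

    def test_summary_mentions_parameters(self):
        t, d = gen_damage_curve(0.07, 150.0, 0.0, seed=0)
        text = ExponentialDamageModel(t, d).fit().summary()
        assert "k" in text and "D_inf" in text

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            ExponentialDamageModel([0, 1], [100, 110])
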