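"""RF analysis: tuning curves, circular variance, Gabor fitting and shape tables."""

import numpy as np
import pytest

import v1sparse as v
from v1sparse.rf import (
    GaborFit,
    TuningCurve,
    circular_variance,
    fit_gabor,
    gabor,
    orientation_histograms,
    shape_table,
    tuning_curve,
)


class TestTuningCurve:
    def test_bank_grating_self_match(self, small_bank):
        g = small_bank.gratings[8, 12, 3]
        tc = tuning_curve(g, small_bank)
        assert tc.optimal_sf == small_bank.spatial_frequencies[8]
        assert tc.theta[np.argmax(tc.alpha)] == small_bank.orientations[12]

    def test_isotropic_blob_is_untuned(self, small_bank):
        y, x = np.mgrid[0:16, 0:16] - 7.5
        blob = np.exp(-(x**2 + y**2) / (2 * 3.0**2)).ravel()
        tc = tuning_curve(blob, small_bank)
        assert tc.alpha.std() / tc.alpha.mean() < 0.05
        assert circular_variance(tc).circular_variance > 0.95

    def test_two_orthogonal_gratings_give_two_peaks(self, small_bank):
        g1 = small_bank.gratings[6, 0, 0]
        g2 = small_bank.gratings[6, 18, 0]  # pi/2 away
        tc = tuning_curve(g1 + g2, small_bank)
        top_two = np.argsort(tc.alpha)[-2:]
        seps = np.abs(tc.theta[top_two[0]] - tc.theta[top_two[1]])
        assert seps == pytest.approx(np.pi / 2, abs=np.pi / 36)
        assert tc.alpha[top_two[0]] == pytest.approx(tc.alpha[top_two[1]], rel=0.05)

    def test_alpha_nonnegative(self, small_bank, rng):
        for _ in range(5):
            tc = tuning_curve(rng.standard_normal(256), small_bank)
            assert np.all(tc.alpha >= 0)

    def test_wrong_size_rejected(self, small_bank):
        with pytest.raises(ValueError):
            tuning_curve(np.zeros(100), small_bank)


class TestCircularVariance:
    def _orients(self):
        return np.arange(36) * np.pi / 36

    def test_single_orientation_responder(self):
        alpha = np.zeros(36)
        alpha[7] = 3.0
        stats = circular_variance(TuningCurve(alpha, self._orients(), 2.0))
        assert stats.circular_variance == pytest.approx(0.0, abs=1e-12)
        assert stats.preferred_orientation == pytest.approx(self._orients()[7])

    def test_flat_curve(self):
        stats = circular_variance(TuningCurve(np.ones(36), self._orients(), 2.0))
        assert stats.circular_variance == pytest.approx(1.0, abs=1e-12)

    def test_orthogonal_pair(self):
        alpha = np.zeros(36)
        alpha[3] = 1.0
        alpha[3 + 18] = 1.0  # +pi/2: doubled-angle phasors cancel
        stats = circular_variance(TuningCurve(alpha, self._orients(), 2.0))
        assert stats.circular_variance == pytest.approx(1.0, abs=1e-12)

    def test_scale_invariance_and_range(self, rng):
        for _ in range(20):
            alpha = rng.uniform(0, 1, 36)
            tc = TuningCurve(alpha, self._orients(), 2.0)
            tc10 = TuningCurve(alpha * 10, self._orients(), 2.0)
            a, b = circular_variance(tc), circular_variance(tc10)
            assert 0.0 <= a.circular_variance <= 1.0
            assert a.circular_variance == pytest.approx(b.circular_variance)

    def test_all_zero_curve_rejected(self):
        with pytest.raises(ValueError):
            circular_variance(TuningCurve(np.zeros(36), self._orients(), 2.0))

    def test_preferred_orientation_equivariance(self, small_bank):
        # rotating a grating unit shifts the preferred orientation accordingly
        base = tuning_curve(small_bank.gratings[8, 6, 0], small_bank)
        shifted = tuning_curve(small_bank.gratings[8, 15, 0], small_bank)
        d = circular_variance(shifted).preferred_orientation - circular_variance(
            base
        ).preferred_orientation
        expected = (15 - 6) * np.pi / 36
        assert d % np.pi == pytest.approx(expected, abs=np.pi / 36)


class TestOrientationHistograms:
    def test_identical_units_occupy_one_bin(self):
        stats = [v.OrientationStats(0.25, 0.75 + 0j, 1.0)] * 10
        out = orientation_histograms(stats, bins=10)
        cv = out["circular_variance"]
        assert (cv.mass > 0).sum() == 1
        assert cv.mass.sum() == pytest.approx(1.0, abs=1e-12)
        po = out["preferred_orientation"]
        assert po.proportion.max() == pytest.approx(1.0)

    def test_masses_sum_to_one(self, rng):
        stats = [
            v.OrientationStats(float(c), 0.5 + 0j, float(p))
            for c, p in zip(rng.uniform(0, 1, 57), rng.uniform(0, np.pi, 57))
        ]
        out = orientation_histograms(stats, bins=18)
        assert out["circular_variance"].mass.sum() == pytest.approx(1.0, abs=1e-12)
        assert out["preferred_orientation"].proportion.sum() == pytest.approx(1.0, abs=1e-12)

    def test_uniform_grating_population_is_flat(self, small_bank):
        stats = []
        for j in range(36):
            tc = tuning_curve(small_bank.gratings[8, j, 0], small_bank)
            stats.append(circular_variance(tc))
        out = orientation_histograms(stats, bins=6)
        np.testing.assert_allclose(out["preferred_orientation"].proportion, 1 / 6, atol=0.05)


class TestGaborFit:
    def test_noiseless_recovery(self):
        true = dict(
            amplitude=1.3,
            center=(7.2, 8.1),
            orientation=0.7,
            period=5.5,
            phase=1.1,
            sigma_parallel=3.2,
            sigma_orthogonal=2.1,
        )
        unit = gabor(16, **true)
        fit = fit_gabor(unit, restarts=8, seed=0)
        assert fit.r2 > 0.999
        assert fit.amplitude == pytest.approx(true["amplitude"], rel=0.01)
        assert fit.orientation == pytest.approx(true["orientation"], rel=0.01)
        assert fit.period == pytest.approx(true["period"], rel=0.01)
        assert fit.sigma_parallel == pytest.approx(true["sigma_parallel"], rel=0.01)
        assert fit.sigma_orthogonal == pytest.approx(true["sigma_orthogonal"], rel=0.01)

    def test_noise_unit_fails_r2_filter(self, rng):
        fit = fit_gabor(rng.standard_normal(256), restarts=6, seed=1)
        assert fit.r2 < 0.6

    def test_rotation_symmetry_of_sigmas(self):
        unit = gabor(16, 1.0, (7.5, 7.5), 0.4, 6.0, 0.3, 3.0, 1.8)
        rotated = gabor(16, 1.0, (7.5, 7.5), 0.4 + np.pi, 6.0, 0.3, 3.0, 1.8)
        f1 = fit_gabor(unit, restarts=8, seed=0)
        f2 = fit_gabor(rotated, restarts=8, seed=0)
        assert f1.sigma_parallel == pytest.approx(f2.sigma_parallel, rel=0.01)
        assert f1.sigma_orthogonal == pytest.approx(f2.sigma_orthogonal, rel=0.01)
        assert f1.orientation == pytest.approx(f2.orientation, abs=0.01)


class TestShapeTable:
    def _fit(self, r2, sp=2.0, so=2.0, period=5.0):
        return GaborFit(1.0, (8.0, 8.0), 0.5, period, 0.0, sp, so, r2)

    def test_all_below_threshold_gives_empty_table(self):
        table = shape_table([self._fit(0.1), self._fit(0.59)])
        assert len(table) == 0

    def test_isotropic_gabor_aspect_ratio_one(self):
        table = shape_table([self._fit(0.9, sp=2.5, so=2.5)])
        assert table.aspect_ratio.iloc[0] == pytest.approx(1.0)

    def test_threshold_keeps_exactly_the_clean_fits(self, rng):
        clean = [
            fit_gabor(
                gabor(16, 1.0, (7.5, 7.5), th, 5.0, 0.0, 2.5, 1.5), restarts=6, seed=0
            )
            for th in np.linspace(0.1, 2.8, 10)
        ]
        noise = [fit_gabor(rng.standard_normal(256), restarts=4, seed=k) for k in range(5)]
        table = shape_table(clean + noise, r2_min=0.6)
        assert len(table) == 10

    def test_normalization_by_period(self):
        table = shape_table([self._fit(0.9, sp=3.0, so=1.5, period=6.0)])
        assert table.sigma_par_norm.iloc[0] == pytest.approx(0.5)
        assert table.sigma_orth_norm.iloc[0] == pytest.approx(0.25)
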