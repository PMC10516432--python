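"""Coding step: proximal-gradient correctness against independent oracles."""

import numpy as np
import pytest

import v1sparse as v
from v1sparse.coding import CodingConfig, effective_energy, energy, lipschitz_bound, sparse_code, sparse_code_batch
from v1sparse.operators import PenaltySpec


class TestLipschitzBound:
    def test_orthonormal(self):
        q, _ = np.linalg.qr(np.random.default_rng(0).standard_normal((12, 12)))
        assert lipschitz_bound(q) == pytest.approx(1.0)

    def test_duplicated_column(self):
        col = np.array([1.0, 0.0, 0.0])
        phi = np.stack([col, col], axis=1)
        assert lipschitz_bound(phi) == pytest.approx(2.0)

    def test_matches_svd(self, rng):
        phi = v.random_unit_dictionary(64, 120, seed=2)
        s = np.linalg.svd(phi, compute_uv=False)[0]
        assert lipschitz_bound(phi) == pytest.approx(s**2, abs=1e-8)


class TestSparseCode:
    def test_zero_patch_gives_zero_code(self, tiny_dictionary):
        pen = PenaltySpec("soft_l1", 0.1, 1.0)
        code = sparse_code(np.zeros(8), tiny_dictionary, pen)
        assert code.active_count == 0
        assert code.final_mse == 0.0
        assert np.all(code.r == 0)

    def test_huge_lambda_silences_everything(self, tiny_dictionary, rng):
        patch = rng.standard_normal(8)
        pen = PenaltySpec("soft_l1", 1e6, 1.0)
        code = sparse_code(patch, tiny_dictionary, pen, CodingConfig(max_iters=1))
        assert code.active_count == 0

    def test_matches_lasso_oracle(self, rng):
        # coordinate-descent lasso (scikit-learn) is the independent oracle
        from sklearn.linear_model import Lasso

        m, n = 8, 20
        for trial in range(10):
            phi = v.random_unit_dictionary(m, n, seed=trial)
            patch = rng.standard_normal(m)
            lam = float(rng.uniform(0.02, 0.3))
            pen = PenaltySpec("soft_l1", lam, 1.0)
            oracle = Lasso(alpha=lam / m, fit_intercept=False, max_iter=200_000, tol=1e-14)
            oracle.fit(phi, patch)
            e_oracle = energy(patch, phi, oracle.coef_, pen)
            # escalate the fixed iteration budget for near-degenerate instances
            for iters in (20_000, 500_000):
                mine = sparse_code(patch, phi, pen, CodingConfig(max_iters=iters, record_energy=False))
                e_mine = energy(patch, phi, mine.r, pen)
                if abs(e_mine - e_oracle) <= 1e-6:
                    break
            assert e_mine == pytest.approx(e_oracle, abs=1e-6)

    @pytest.mark.parametrize("kind", ["soft_l1", "half_l12", "hard_l0", "cel0"])
    @pytest.mark.parametrize("sign", [1.0, -1.0])
    def test_one_sparse_noiseless_support_recovery(self, kind, sign):
        phi = v.random_unit_dictionary(32, 16, seed=4)
        mu = 0.2 if kind == "cel0" else None
        for i in [0, 5, 11]:
            patch = sign * phi[:, i]  # unit-amplitude planted atom, no noise
            pen = PenaltySpec(kind, 0.05, mu if mu else 1.0)
            got = sparse_code(patch, phi, pen, CodingConfig(mu=mu, max_iters=300, record_energy=False))
            active = np.nonzero(got.r)[0]
            assert list(active) == [i]
            assert np.sign(got.r[i]) == sign

    def test_determinism(self, tiny_dictionary, rng):
        patch = rng.standard_normal(8)
        pen = PenaltySpec("half_l12", 0.1, 1.0)
        a = sparse_code(patch, tiny_dictionary, pen)
        b = sparse_code(patch, tiny_dictionary, pen)
        np.testing.assert_array_equal(a.r, b.r)

    def test_divergent_step_size_raises(self, tiny_dictionary, rng):
        patch = rng.standard_normal(8)
        pen = PenaltySpec("soft_l1", 0.01, 1.0)
        bad = CodingConfig(mu=50.0 / lipschitz_bound(tiny_dictionary), max_iters=400)
        with pytest.raises(FloatingPointError, match="mu"):
            sparse_code(patch, tiny_dictionary, pen, bad)


class TestEnergy:
    def test_zero_code_energy_is_half_norm(self, tiny_dictionary, rng):
        patch = rng.standard_normal(8)
        for kind in ["soft_l1", "half_l12", "hard_l0", "cel0"]:
            pen = PenaltySpec(kind, 0.3, 0.5)
            assert energy(patch, tiny_dictionary, np.zeros(20), pen) == pytest.approx(
                0.5 * patch @ patch
            )

    def test_exact_code_hard_energy_is_lambda_k(self):
        phi = v.random_unit_dictionary(16, 8, seed=1)
        model = v.PlantedModel(phi, sparsity_k=3, amplitude_scale=1.0, noise_sigma=0.0, seed=2)
        patches, codes = v.sample_planted_patches(model, 5)
        pen = PenaltySpec("hard_l0", 0.7, 1.0)
        for patch, code in zip(patches, codes):
            assert energy(patch, phi, code, pen) == pytest.approx(0.7 * 3)

    @pytest.mark.parametrize("kind", ["soft_l1", "half_l12", "hard_l0", "cel0"])
    def test_effective_energy_monotone_under_coding(self, kind, rng):
        # the proximal iteration descends the energy at the operator's
        # effective weight (for soft and cel0 that IS the nominal energy)
        phi = v.random_unit_dictionary(16, 40, seed=6)
        patch = rng.standard_normal(16)
        mu = 1.0 / lipschitz_bound(phi)
        pen = PenaltySpec(kind, 0.15, mu)
        from v1sparse.operators import threshold

        r = np.zeros(40)
        gram, drive = phi.T @ phi, phi.T @ patch
        prev = effective_energy(patch, phi, r, pen)
        for _ in range(80):
            r = threshold(r - mu * (gram @ r - drive), pen)
            cur = effective_energy(patch, phi, r, pen)
            assert cur <= prev + 1e-10
            prev = cur

    def test_soft_energy_trace_monotone(self, rng):
        phi = v.random_unit_dictionary(16, 40, seed=6)
        patch = rng.standard_normal(16)
        pen = PenaltySpec("soft_l1", 0.1, 1.0)
        code = sparse_code(patch, phi, pen, CodingConfig(max_iters=150))
        assert np.all(np.diff(code.energy_trace) <= 1e-10)


def test_batch_and_single_coding_agree(pink_images):
    batch = v.extract_patches(pink_images, 8, 6, seed=3)
    phi = v.random_unit_dictionary(64, 96, seed=0)
    pen = PenaltySpec("cel0", 0.1, 0.05)
    cfg = CodingConfig(mu=0.05, max_iters=60, record_energy=False)
    codes, mse, active = sparse_code_batch(batch.patches, phi, pen, cfg)
    for b in range(6):
        single = sparse_code(batch.patches[b], phi, pen, cfg)
        np.testing.assert_allclose(single.r, codes[b], atol=1e-12)
        assert single.active_count == active[b]
        assert single.final_mse == pytest.approx(mse[b])
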