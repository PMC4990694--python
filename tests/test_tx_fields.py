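import numpy as np
import pytest

from pnpmrf import tx_fields as tx


def ring_mask(M, frac=0.45):
    yy, xx = np.mgrid[0:M, 0:M]
    c = (M - 1) / 2.0
    return np.hypot(xx - c, yy - c) <= frac * M


class TestModeWeights:
    def test_cp_phase_increment(self):
        w = tx.mode_weights(16, 1).weights
        inc = np.angle(w[1] / w[0])
        assert np.degrees(inc) == pytest.approx(22.5)

    def test_two_element_linear(self):
        w = tx.mode_weights(2, 1).weights
        assert w[1] / w[0] == pytest.approx(-1.0)

    @pytest.mark.parametrize("K", [2, 4, 8, 16])
    def test_modes_orthonormal(self, K):
        G = np.stack([tx.mode_weights(K, n).weights for n in range(1, K + 1)])
        gram = G @ G.conj().T
        assert np.allclose(gram, np.eye(K), atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            tx.mode_weights(8, 0)
        with pytest.raises(ValueError):
            tx.mode_weights(8, 9)


class TestCombine:
    def test_unit_vector_selects_element(self):
        S = tx.synthetic_element_fields(32, K=4)
        b = tx.DriveVector(np.array([0, 0, 1.0, 0], complex))
        assert np.allclose(tx.combine(S, b).map, S.fields[2])

    def test_linearity(self, rng):
        S = tx.synthetic_element_fields(32, K=4)
        b1 = tx.DriveVector(rng.standard_normal(4) + 1j * rng.standard_normal(4))
        b2 = tx.DriveVector(rng.standard_normal(4) + 1j * rng.standard_normal(4))
        both = tx.DriveVector(b1.weights + 2j * b2.weights)
        assert np.allclose(tx.combine(S, both).map,
                           tx.combine(S, b1).map + 2j * tx.combine(S, b2).map,
                           atol=1e-12)

    def test_length_mismatch_rejected(self):
        S = tx.synthetic_element_fields(32, K=4)
        with pytest.raises(ValueError):
            tx.combine(S, tx.DriveVector(np.ones(5, complex)))


class TestApproxCpCalibration:
    def _centre(self, M, frac=0.05):
        yy, xx = np.mgrid[0:M, 0:M]
        c = (M - 1) / 2.0
        area = frac * np.pi * (0.45 * M) ** 2
        r = np.sqrt(area / np.pi)
        return np.hypot(xx - c, yy - c) <= r

    def test_aligns_phases_at_centre(self):
        M = 32
        S = tx.synthetic_element_fields(M, K=8)
        region = self._centre(M)
        b = tx.approx_cp_calibration(S, region)
        means = S.fields[:, region].mean(axis=1) * b.weights
        phases = np.angle(means)
        assert np.ptp(np.unwrap(phases)) < 1e-9

    def test_coherent_sum_of_magnitudes(self):
        M = 32
        rng = np.random.default_rng(3)
        yy, xx = np.mgrid[0:M, 0:M]
        fields = np.stack([np.full((M, M), np.exp(1j * p))
                           for p in rng.uniform(0, 2 * np.pi, 6)])
        S = tx.ElementFieldSet(fields, np.zeros((6, 2)))
        region = self._centre(M)
        b = tx.approx_cp_calibration(S, region)
        net = tx.combine(S, b).map
        assert abs(net[M // 2, M // 2]) * np.sqrt(6) == pytest.approx(6.0, rel=1e-9)

    def test_beats_99pct_of_ideal_cp(self):
        M = 48
        S = tx.synthetic_element_fields(M, K=8)
        region = self._centre(M)
        b = tx.approx_cp_calibration(S, region)
        centre_val = abs(tx.combine(S, b).map[M // 2, M // 2])
        ideal = np.abs(S.fields[:, M // 2, M // 2]).sum() / np.sqrt(8)
        assert centre_val >= 0.99 * ideal

    def test_zero_element_rejected(self):
        M = 16
        S = tx.synthetic_element_fields(M, K=4)
        S.fields[2] = 0.0
        with pytest.raises(ValueError, match="element 2"):
            tx.approx_cp_calibration(S, self._centre(M, 0.2))


class TestMlsShim:
    def test_scalar_closed_form(self):
        M = 16
        rng = np.random.default_rng(0)
        s = (rng.standard_normal((1, M, M)) + 1j * rng.standard_normal((1, M, M)))
        S = tx.ElementFieldSet(s, np.zeros((1, 2)))
        mask = np.ones((M, M), bool)
        m = np.full((M, M), 2.0)
        b, hist = tx.mls_shim(S, m, mask, n_iter=30)
        sa = np.abs(s[0]).ravel()
        want = (sa * 2.0).sum() / (sa * sa).sum()
        assert abs(b.weights[0]) == pytest.approx(want, abs=1e-9)

    def test_planted_solution_recovery(self, rng):
        M = 24
        S = tx.synthetic_element_fields(M, K=6)
        mask = ring_mask(M)
        b_star = tx.DriveVector(rng.standard_normal(6) + 1j * rng.standard_normal(6))
        m = np.abs(tx.combine(S, b_star).map)
        m = np.where(m > 1e-12, m, 1e-12)
        b, hist = tx.mls_shim(S, m, mask, n_iter=200, seed=0, n_restarts=8)
        assert hist[-1] < 1e-10

    def test_objective_monotone_many_seeds(self):
        M = 24
        mask = ring_mask(M)
        for seed in range(10):
            rng = np.random.default_rng(seed)
            fields = (rng.standard_normal((5, M, M))
                      + 1j * rng.standard_normal((5, M, M)))
            S = tx.ElementFieldSet(fields, np.zeros((5, 2)))
            m = np.abs(rng.standard_normal((M, M))) + 0.5
            _, hist = tx.mls_shim(S, m, mask, n_iter=50, seed=seed)
            assert np.all(np.diff(hist) <= 1e-10)

    def test_shimmed_cv_beats_cp(self):
        M = 48
        S = tx.synthetic_element_fields(M, K=8)
        mask = ring_mask(M)
        cp = tx.combine(S, tx.mode_weights(8, 1))
        target = np.full((M, M), np.abs(cp.map)[mask].mean())
        b, _ = tx.mls_shim(S, target, mask, n_iter=60)
        assert tx.field_cv(tx.combine(S, b), mask) <= tx.field_cv(cp, mask)

    def test_empty_mask_rejected(self):
        S = tx.synthetic_element_fields(16, K=2)
        with pytest.raises(ValueError):
            tx.mls_shim(S, np.ones((16, 16)), np.zeros((16, 16), bool))


class TestFieldCv:
    def test_uniform_field_zero(self):
        f = tx.NetField(np.ones((8, 8), complex))
        assert tx.field_cv(f, np.ones((8, 8), bool)) == 0.0

    def test_two_voxel_case(self):
        f = tx.NetField(np.array([[1.0, 3.0]], dtype=complex))
        assert tx.field_cv(f, np.ones((1, 2), bool)) == pytest.approx(0.5)

    def test_matches_two_pass_oracle(self, rng):
        f = tx.NetField(rng.standard_normal((16, 16))
                        + 1j * rng.standard_normal((16, 16)))
        mask = rng.uniform(size=(16, 16)) > 0.3
        v = np.abs(f.map)[mask]
        mean = sum(v) / len(v)
        sd = np.sqrt(sum((x - mean) ** 2 for x in v) / len(v))
        assert tx.field_cv(f, mask) == pytest.approx(sd / mean, rel=1e-12)

    def test_zero_mean_rejected(self):
        f = tx.NetField(np.zeros((4, 4), complex))
        with pytest.raises(ValueError, match="CV"):
            tx.field_cv(f, np.ones((4, 4), bool))


class TestSyntheticFields:
    def test_long_wavelength_cp_uniform_centre(self):
        M = 64
        S = tx.synthetic_element_fields(M, K=8, effective_wavelength=1e9)
        cp = tx.combine(S, tx.mode_weights(8, 1))
        q = M // 4
        centre = np.zeros((M, M), bool)
        centre[M // 2 - q // 2:M // 2 + q // 2,
               M // 2 - q // 2:M // 2 + q // 2] = True
        assert tx.field_cv(cp, centre) < 0.05

    def test_gradient_mode_centre_null(self):
        M = 64
        cp, grad = tx.default_illuminations(M)
        c = M // 2
        assert abs(grad.map[c, c]) < 0.1 * np.abs(grad.map).max()
        assert abs(cp.map[c, c]) > 0.5 * np.abs(cp.map).max()

    def test_complementary_voids(self):
        M = 64
        cp, grad = tx.default_illuminations(M)
        mask = ring_mask(M)
        mags = np.stack([np.abs(cp.map), np.abs(grad.map)])
        coverage = mags.max(axis=0)[mask].min()
        peak = mags[:, mask].max()
        assert coverage > 0.15 * peak

    def test_field_maximal_at_own_element(self):
        M = 64
        S = tx.synthetic_element_fields(M, K=8)
        mag = np.abs(S.fields[0])
        positions = np.round(S.element_positions).astype(int)
        vals = []
        for k, (ex, ey) in enumerate(positions):
            ex = np.clip(ex, 0, M - 1)
            ey = np.clip(ey, 0, M - 1)
            vals.append(mag[int(ey), int(ex)])
        assert np.argmax(vals) == 0

    def test_deterministic_given_seed(self):
        a = tx.synthetic_element_fields(32, K=4, seed=9)
        b = tx.synthetic_element_fields(32, K=4, seed=9)
        assert np.array_equal(a.fields, b.fields)

    def test_too_few_elements_rejected(self):
        with pytest.raises(ValueError):
            tx.synthetic_element_fields(32, K=1)
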