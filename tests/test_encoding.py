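import numpy as np
import pytest

from pnpmrf import encoding as enc
from pnpmrf.dictionary import compression_plan
from pnpmrf.schedule import coil_sequence


def dft_forward_oracle(image, kx, ky):
    """Direct O(S * M^2) discrete Fourier sum, centred convention."""
    M = image.shape[0]
    x = np.arange(M) - M // 2
    out = np.zeros(np.shape(kx), dtype=complex)
    for idx in np.ndindex(np.shape(kx)):
        phase = np.exp(-2j * np.pi * (kx[idx] * x[:, None]
                                      + ky[idx] * x[None, :]) / M)
        out[idx] = (image * phase).sum()
    return out


def antialiased_disk(M, radius_frac=0.35):
    yy, xx = np.mgrid[0:M, 0:M]
    c = (M - 1) / 2.0
    r = np.hypot(xx - c, yy - c)
    return np.clip(radius_frac * M + 0.5 - r, 0.0, 1.0).astype(complex)


class TestAccelerationFactor:
    @pytest.mark.parametrize("M,N,R", [(160, 9, 28), (160, 5, 50),
                                       (160, 3, 84), (336, 12, 44)])
    def test_printed_triples(self, M, N, R):
        assert enc.acceleration_factor(M, N) == R

    def test_zero_spokes_rejected(self):
        with pytest.raises(ValueError):
            enc.acceleration_factor(160, 0)


class TestTrajectory:
    def test_rotation_rule(self):
        t = enc.build_trajectory(160, 9, 10)
        assert t.rotation_per_timepoint == pytest.approx(14 * 6 / 9)
        assert t.rotation_per_timepoint == pytest.approx(9.3333, abs=1e-3)

    def test_single_spoke_base_angle(self):
        t = enc.build_trajectory(64, 1, 2)
        assert t.angles(0)[0] == 0.0

    def test_evenly_spaced_within_timepoint(self):
        t = enc.build_trajectory(64, 5, 2)
        a = t.angles(0)
        assert np.allclose(np.diff(a), np.pi / 5)

    @pytest.mark.parametrize("N", [3, 5, 9, 12])
    def test_rotation_not_spoke_multiple(self, N):
        rot = np.radians(14 * 6 / N)
        assert rot % (np.pi / N) > 1e-9

    def test_k_extent(self):
        t = enc.build_trajectory(64, 4, 3)
        kx, ky = t.k_coords(2)
        assert np.hypot(kx, ky).max() <= 32.0 + 1e-9

    def test_corner_coverage_extent(self):
        t = enc.build_trajectory(64, 4, 3, corner_coverage=True)
        assert np.hypot(*t.k_coords(0)).max() <= 64 / np.sqrt(2) + 1e-9
        assert np.hypot(*t.k_coords(0)).max() > 32.0


class TestNufft:
    def test_forward_matches_dft_oracle(self, rng):
        M = 32
        img = rng.standard_normal((M, M)) + 1j * rng.standard_normal((M, M))
        traj = enc.build_trajectory(M, 5, 3)
        kx, ky = traj.k_coords(1)
        got = enc.nufft_forward(img, kx, ky)
        want = dft_forward_oracle(img, kx, ky)
        assert np.linalg.norm(got - want) / np.linalg.norm(want) < 1e-6

    def test_forward_linearity(self, rng):
        M = 32
        x = rng.standard_normal((M, M)) + 1j * rng.standard_normal((M, M))
        y = rng.standard_normal((M, M)) + 1j * rng.standard_normal((M, M))
        traj = enc.build_trajectory(M, 3, 1)
        kx, ky = traj.k_coords(0)
        lhs = enc.nufft_forward(2.0 * x + 0.5j * y, kx, ky)
        rhs = 2.0 * enc.nufft_forward(x, kx, ky) + 0.5j * enc.nufft_forward(y, kx, ky)
        assert np.allclose(lhs, rhs, rtol=1e-12, atol=1e-9)

    def test_central_impulse_constant_spokes(self):
        M = 32
        img = np.zeros((M, M), dtype=complex)
        img[M // 2, M // 2] = 1.0
        traj = enc.build_trajectory(M, 4, 1)
        kx, ky = traj.k_coords(0)
        s = enc.nufft_forward(img, kx, ky)
        assert np.allclose(np.abs(s), 1.0, rtol=1e-6)

    def test_adjoint_inner_product(self, rng):
        M = 32
        img = rng.standard_normal((M, M)) + 1j * rng.standard_normal((M, M))
        traj = enc.build_trajectory(M, 6, 2)
        kx, ky = traj.k_coords(1)
        y = rng.standard_normal(kx.shape) + 1j * rng.standard_normal(kx.shape)
        lhs = np.vdot(y, enc.nufft_forward(img, kx, ky))
        rhs = np.vdot(enc.nufft_adjoint(y, kx, ky, M), img)
        assert abs(lhs - rhs) / abs(lhs) < 1e-6

    def test_zero_kspace_zero_image(self):
        M = 32
        traj = enc.build_trajectory(M, 4, 1)
        kx, ky = traj.k_coords(0)
        img = enc.nufft_adjoint(np.zeros(kx.shape, complex), kx, ky, M)
        assert np.all(img == 0)


class TestRecon:
    def test_fully_sampled_round_trip(self):
        M = 64
        disk = antialiased_disk(M)
        N = enc.fully_sampled_spokes(M)
        traj = enc.build_trajectory(M, N, 1)
        kx, ky = traj.k_coords(0)
        samp = enc.nufft_forward(disk, kx, ky)[None]
        series = enc.RadialKSpaceSeries(samp[None], traj)
        rec = enc.adjoint_recon(series, 0, "ramp")[0]
        assert np.linalg.norm(rec - disk) / np.linalg.norm(disk) <= 0.05

    def test_unknown_compensation_rejected(self):
        M = 32
        traj = enc.build_trajectory(M, 4, 1)
        series = enc.RadialKSpaceSeries(
            np.zeros((1, 1, 4, traj.samples_per_spoke), complex), traj)
        with pytest.raises(ValueError, match="compensation"):
            enc.adjoint_recon(series, 0, "voronoi")

    def test_lsq_recon_exact_with_corner_coverage(self, rng):
        M = 32
        img = rng.standard_normal((M, M)) + 1j * rng.standard_normal((M, M))
        N = enc.fully_sampled_spokes(M)
        traj = enc.build_trajectory(M, N, 1, corner_coverage=True)
        kx, ky = traj.k_coords(0)
        y = enc.nufft_forward(img, kx, ky)[None]
        rec = enc.lsq_recon(y, kx, ky, traj)
        assert np.linalg.norm(rec[0] - img) / np.linalg.norm(img) < 1e-5

    def test_pooled_equals_sum_of_adjoints(self, rng):
        M = 32
        traj = enc.build_trajectory(M, 3, 4)
        data = (rng.standard_normal((4, 2, 3, traj.samples_per_spoke))
                + 1j * rng.standard_normal((4, 2, 3, traj.samples_per_spoke)))
        series = enc.RadialKSpaceSeries(data, traj)
        pooled = enc.pooled_recon(series, [0, 2, 3])
        summed = sum(enc.adjoint_recon(series, t) for t in (0, 2, 3))
        assert np.allclose(pooled, summed, rtol=1e-10, atol=1e-12)

    def test_psf_incoherence_between_timepoints(self):
        # rotation makes t and t+1 PSFs less alike than a PSF with itself
        M = 64
        traj = enc.build_trajectory(M, 4, 2)
        psfs = []
        for t in (0, 1):
            kx, ky = traj.k_coords(t)
            w = enc.radial_density_weights(traj)
            psf = enc.nufft_adjoint(np.broadcast_to(w, kx.shape).astype(complex),
                                    kx, ky, M)
            psfs.append(psf.ravel())
        a, b = psfs
        cross = abs(np.vdot(a, b)) / (np.linalg.norm(a) * np.linalg.norm(b))
        assert cross < 1.0 - 1e-6


class TestSensitivities:
    def _make_series(self, M, maps, plan, image):
        traj = enc.build_trajectory(M, 6, 480)
        n_rx = len(maps)
        tps = sorted(set(plan.bin_indices[0]))
        data = np.zeros((480, n_rx, 6, traj.samples_per_spoke), complex)
        rx = enc.RxSensitivities(maps, np.ones((M, M), bool))
        for t in tps:
            data[t] = enc.forward_sample(image, traj, rx, t)
        return enc.RadialKSpaceSeries(data, traj)

    def test_uniform_single_channel(self, default_schedule):
        M = 48
        plan = compression_plan(coil_sequence(default_schedule))
        img = antialiased_disk(M, 0.4)
        maps = np.ones((1, M, M), complex)
        series = self._make_series(M, maps, plan, img)
        est = enc.estimate_rx_sensitivities(series, plan)
        sel = est.support & (np.abs(img) > 0.5)
        assert np.allclose(np.abs(est.maps[0][sel]), 1.0, atol=0.05)

    def test_rss_is_unity_inside_support(self, default_schedule, rng):
        M = 48
        plan = compression_plan(coil_sequence(default_schedule))
        img = antialiased_disk(M, 0.4)
        yy, xx = np.mgrid[0:M, 0:M]
        maps = np.stack([
            (0.5 + np.exp(-((xx - 10) ** 2 + (yy - 20) ** 2) / 900)).astype(complex),
            (0.5 + np.exp(-((xx - 40) ** 2 + (yy - 30) ** 2) / 900)).astype(complex),
        ])
        series = self._make_series(M, maps, plan, img)
        est = enc.estimate_rx_sensitivities(series, plan)
        rss = np.sqrt((np.abs(est.maps) ** 2).sum(axis=0))
        assert np.allclose(rss[est.support], 1.0, rtol=1e-9)

    def test_known_smooth_maps_recovered(self, default_schedule):
        M = 48
        plan = compression_plan(coil_sequence(default_schedule))
        img = antialiased_disk(M, 0.4)
        yy, xx = np.mgrid[0:M, 0:M]
        maps = np.stack([
            (0.6 + 0.4 * xx / M).astype(complex),
            (0.6 + 0.4 * yy / M).astype(complex),
        ])
        series = self._make_series(M, maps, plan, img)
        est = enc.estimate_rx_sensitivities(series, plan)
        true_rss = np.sqrt((np.abs(maps) ** 2).sum(axis=0))
        sel = est.support & (np.abs(img) > 0.9)
        for c in range(2):
            want = np.abs(maps[c] / true_rss)[sel]
            got = np.abs(est.maps[c])[sel]
            assert np.abs(got - want).max() < 0.10

    def test_all_zero_data_rejected(self):
        M = 32
        traj = enc.build_trajectory(M, 4, 480)

        class P:
            bin_indices = np.arange(480).reshape(32, 15)

        series = enc.RadialKSpaceSeries(
            np.zeros((480, 1, 4, traj.samples_per_spoke), complex), traj)
        with pytest.raises(ValueError, match="degenerate"):
            enc.estimate_rx_sensitivities(series, P())


class TestCombineRx:
    def test_single_uniform_channel_identity(self, rng):
        M = 16
        img = rng.standard_normal((M, M)) + 1j * rng.standard_normal((M, M))
        sens = enc.RxSensitivities(np.ones((1, M, M), complex),
                                   np.ones((M, M), bool))
        assert np.allclose(enc.combine_rx(img[None], sens), img)

    def test_matched_filter_fixed_point(self, rng):
        M = 16
        common = rng.standard_normal((M, M)) + 1j * rng.standard_normal((M, M))
        maps = (rng.standard_normal((3, M, M)) + 1j * rng.standard_normal((3, M, M)))
        sens = enc.RxSensitivities(maps, np.ones((M, M), bool))
        out = enc.combine_rx(maps * common, sens)
        assert np.allclose(out, common, rtol=1e-10)

    def test_snr_gain_over_single_channel(self):
        M = 16
        rng = np.random.default_rng(7)
        truth = np.ones((M, M), dtype=complex)
        maps = np.stack([np.full((M, M), 0.9 + 0.1j), np.full((M, M), 0.7 - 0.2j)])
        sens = enc.RxSensitivities(maps, np.ones((M, M), bool))
        err_comb, err_single = [], []
        for _ in range(100):
            noise = (rng.standard_normal((2, M, M))
                     + 1j * rng.standard_normal((2, M, M))) * 0.1
            imgs = maps * truth + noise
            comb = enc.combine_rx(imgs, sens)
            err_comb.append(np.abs(comb - truth).std())
            err_single.append(np.abs(imgs[0] / maps[0] - truth).std())
        assert np.mean(err_comb) < np.mean(err_single)


class TestKSpaceIO:
    def test_round_trip(self, tmp_path, rng):
        traj = enc.build_trajectory(32, 3, 4)
        data = (rng.standard_normal((4, 2, 3, traj.samples_per_spoke))
                + 1j * rng.standard_normal((4, 2, 3, traj.samples_per_spoke)))
        series = enc.RadialKSpaceSeries(data, traj, noise_sd=0.3, seed=5)
        p = tmp_path / "k.h5"
        enc.save_kspace(p, series)
        back = enc.load_kspace(p)
        assert np.array_equal(back.data, data)
        assert back.trajectory == traj
        assert back.noise_sd == 0.3 and back.seed == 5
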