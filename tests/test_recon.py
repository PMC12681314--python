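"""Encoding operator, ADMM solver, CG-SENSE baseline, and post-filtering."""

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from smsradial.recon import (
    ReconConfig,
    SmsEncodingOperator,
    admm_reconstruct,
    cg_sense,
    soft_threshold,
    temporal_diff,
    temporal_diff_adjoint,
    temporal_median_filter,
)
from smsradial.simulator import CoilMaps, DynamicPhantom, MultiCoilKSpace, acquire, make_coil_maps, make_phantom
from smsradial.trajectory import caipirinha_schedule, make_trajectory


def _smooth_video(rng, n_slices, n_frames, n):
    """Temporally and spatially smooth complex video, unit-scale."""
    x = rng.standard_normal((n_slices, n_frames, n, n)) + 1j * rng.standard_normal(
        (n_slices, n_frames, n, n)
    )
    x = gaussian_filter(x.real, sigma=(0, 0.5, 1.5, 1.5)) + 1j * gaussian_filter(
        x.imag, sigma=(0, 0.5, 1.5, 1.5)
    )
    return x / np.abs(x).max()


def _tiny_problem(rng, n=8, n_slices=1, n_coils=1, n_frames=3, spokes_per_frame=24, ppe=16):
    """Densely sampled tiny acquisition with uniform coil sensitivities."""
    x = _smooth_video(rng, n_slices, n_frames, n)
    maps = CoilMaps(maps=np.ones((n_slices, n_coils, n, n), dtype=complex))
    traj = make_trajectory(
        "SMS_GA", n_slices, n_frames * spokes_per_frame,
        points_per_spoke=ppe, spokes_per_frame=spokes_per_frame,
    )
    sched = caipirinha_schedule(n_slices, traj.n_spokes)
    phantom = DynamicPhantom(slices=x)
    ks = acquire(phantom, maps, traj, sched, noise_sigma=0.0)
    return x, maps, ks


class TestSmsOperator:
    def test_zero_image_zero_data(self, rng):
        _, maps, ks = _tiny_problem(rng, n_slices=2, n_coils=2)
        op = SmsEncodingOperator(ks.trajectory, ks.schedule, maps)
        assert np.all(op.forward(np.zeros((2, 3, 8, 8), dtype=complex)) == 0)
        assert np.all(op.adjoint(np.zeros((3, 2, 24 * 16), dtype=complex)) == 0)

    def test_single_slice_uniform_map_is_framewise_nufft(self, rng):
        from smsradial.nufft import NufftPlan

        x, maps, ks = _tiny_problem(rng)
        op = SmsEncodingOperator(ks.trajectory, ks.schedule, maps)
        y = op.forward(x)
        for t in range(3):
            plan = NufftPlan(ks.trajectory.frame_coords(t), 8)
            np.testing.assert_allclose(y[t, 0], plan.forward(x[0, t]), atol=1e-10)

    def test_forward_adjoint_dot_product(self, rng):
        maps = make_coil_maps(16, 3, 4, seed=0)
        traj = make_trajectory("SMS_GA", 3, 12, points_per_spoke=24, spokes_per_frame=6)
        sched = caipirinha_schedule(3, 12)
        op = SmsEncodingOperator(traj, sched, maps)
        x = rng.standard_normal((3, 2, 16, 16)) + 1j * rng.standard_normal((3, 2, 16, 16))
        y = rng.standard_normal((2, 4, 6 * 24)) + 1j * rng.standard_normal((2, 4, 6 * 24))
        lhs = np.vdot(y, op.forward(x))
        rhs = np.vdot(op.adjoint(y), x)
        assert abs(lhs - rhs) / abs(lhs) < 1e-6

    def test_zero_frames_rejected(self):
        maps = make_coil_maps(32, 1, 2, seed=0)
        traj = make_trajectory("GA", 1, 10, points_per_spoke=16, spokes_per_frame=25)
        with pytest.raises(ValueError):
            SmsEncodingOperator(traj, caipirinha_schedule(1, 10), maps)


class TestTemporalDiff:
    def test_constant_video_gives_zero(self):
        x = np.ones((2, 5, 4, 4), dtype=complex)
        assert np.all(temporal_diff(x) == 0)

    def test_linear_ramp_gives_constant(self):
        t = np.arange(6, dtype=float)
        x = np.broadcast_to(t[None, :, None, None], (1, 6, 3, 3)).astype(complex)
        d = temporal_diff(x)
        np.testing.assert_allclose(d, 1.0, atol=1e-14)

    def test_single_frame_inert(self):
        d = temporal_diff(np.ones((1, 1, 4, 4), dtype=complex))
        assert d.shape[1] == 0

    def test_adjoint_dot_product(self, rng):
        x = rng.standard_normal((2, 7, 5, 5)) + 1j * rng.standard_normal((2, 7, 5, 5))
        d = rng.standard_normal((2, 6, 5, 5)) + 1j * rng.standard_normal((2, 6, 5, 5))
        lhs = np.vdot(d, temporal_diff(x))
        rhs = np.vdot(temporal_diff_adjoint(d, 7), x)
        assert abs(lhs - rhs) / abs(lhs) < 1e-12


class TestSoftThreshold:
    def test_zero_threshold_is_identity(self, rng):
        z = rng.standard_normal(10) + 1j * rng.standard_normal(10)
        np.testing.assert_array_equal(soft_threshold(z, 0.0), z)

    def test_small_magnitudes_zeroed(self):
        z = np.array([0.1 + 0.1j, -0.05j, 0.0])
        assert np.all(soft_threshold(z, 0.5) == 0)

    def test_closed_form_shrinkage(self):
        out = soft_threshold(np.array([3.0 + 4.0j]), 1.0)
        assert np.abs(out[0]) == pytest.approx(4.0)
        assert np.angle(out[0]) == pytest.approx(np.angle(3.0 + 4.0j))

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            soft_threshold(np.array([1.0 + 0j]), -0.1)


class TestAdmm:
    def test_lambda_zero_matches_cg_sense_on_dense_fixture(self, rng):
        x, maps, ks = _tiny_problem(rng)
        cfg = ReconConfig(max_iterations=60, inner_cg_iterations=20, tolerance=1e-9)
        a = admm_reconstruct(ks, maps, lam=0.0, config=cfg).videos
        b = cg_sense(ks, maps, n_iterations=60).videos
        assert np.linalg.norm(a - b) / np.linalg.norm(b) < 1e-3

    def test_exact_recovery_fully_sampled_noiseless(self, rng):
        # >= pi/2 * N spokes per frame: the data term alone determines x
        n = 32
        x = _smooth_video(rng, 1, 2, n)
        maps = CoilMaps(maps=np.ones((1, 1, n, n), dtype=complex))
        traj = make_trajectory("GA", 1, 128, points_per_spoke=64, spokes_per_frame=64)
        sched = caipirinha_schedule(1, 128)
        ks = acquire(DynamicPhantom(slices=x), maps, traj, sched, noise_sigma=0.0)
        cfg = ReconConfig(max_iterations=30, inner_cg_iterations=15)
        rec = admm_reconstruct(ks, maps, lam=0.0, config=cfg).videos
        assert np.linalg.norm(rec - x) / np.linalg.norm(x) < 1e-2

    def test_objective_non_increasing_after_burn_in(self, rng):
        # accurate inner solves so descent is not masked by subproblem error
        x, maps, ks = _tiny_problem(rng, n_frames=4)
        cfg = ReconConfig(max_iterations=30, inner_cg_iterations=50)
        res = admm_reconstruct(ks, maps, lam=0.04, config=cfg)
        obj = res.objective
        upticks = np.diff(obj[5:]) / obj[5:-1]
        assert upticks.size == 0 or upticks.max() < 1e-6

    def test_regularization_path_monotone(self, rng):
        x, maps, ks = _tiny_problem(rng, spokes_per_frame=6, n_frames=4)
        cfg = ReconConfig(max_iterations=40, inner_cg_iterations=15)
        l1 = []
        for lam in (0.001, 0.01, 0.04, 0.1):
            res = admm_reconstruct(ks, maps, lam=lam, config=cfg)
            l1.append(np.sum(np.abs(temporal_diff(res.videos))))
        assert all(b <= a * (1 + 1e-6) for a, b in zip(l1, l1[1:]))

    def test_negative_lambda_rejected(self, rng):
        _, maps, ks = _tiny_problem(rng)
        with pytest.raises(ValueError):
            admm_reconstruct(ks, maps, lam=-1.0)


class TestCgSense:
    def test_matches_direct_normal_equation_solve(self, rng):
        n = 8
        x = _smooth_video(rng, 1, 1, n)
        maps = CoilMaps(maps=np.ones((1, 1, n, n), dtype=complex))
        traj = make_trajectory("GA", 1, 16, points_per_spoke=16, spokes_per_frame=16)
        sched = caipirinha_schedule(1, 16)
        ks = acquire(DynamicPhantom(slices=x), maps, traj, sched, noise_sigma=0.0)
        op = SmsEncodingOperator(traj, sched, maps)
        # dense system matrix, one basis vector at a time
        cols = []
        for p in range(n * n):
            e = np.zeros((1, 1, n, n), dtype=complex)
            e.flat[p] = 1.0
            cols.append(op.forward(e).ravel())
        a = np.stack(cols, axis=1)
        direct = np.linalg.solve(a.conj().T @ a, a.conj().T @ op.bin_data(ks).ravel())
        cg = cg_sense(ks, maps, n_iterations=100).videos.ravel()
        assert np.linalg.norm(cg - direct) / np.linalg.norm(direct) < 1e-6

    def test_zero_data_zero_solution(self, rng):
        _, maps, ks = _tiny_problem(rng)
        ks = MultiCoilKSpace(
            data=np.zeros_like(ks.data), trajectory=ks.trajectory, schedule=ks.schedule
        )
        assert np.all(cg_sense(ks, maps).videos == 0)

    def test_data_residual_non_increasing(self, rng):
        x, maps, ks = _tiny_problem(rng, n_frames=1, spokes_per_frame=10)
        op = SmsEncodingOperator(ks.trajectory, ks.schedule, maps)
        y = op.bin_data(ks)
        resid = [
            np.linalg.norm(op.forward(cg_sense(ks, maps, n_iterations=k).videos) - y)
            for k in range(1, 7)
        ]
        assert all(b <= a + 1e-9 for a, b in zip(resid, resid[1:]))


class TestMedianFilter:
    def test_constant_video_unchanged(self):
        x = np.full((2, 5, 4, 4), 1.0 + 1.0j)
        np.testing.assert_allclose(temporal_median_filter(x), x, atol=1e-14)

    def test_isolated_spike_removed(self):
        x = np.ones((1, 5, 2, 2), dtype=complex)
        x[0, 2] = 10.0
        out = temporal_median_filter(x, width=3)
        assert np.abs(out[0, 2, 0, 0]) == pytest.approx(1.0)

    def test_width_one_is_identity(self, rng):
        x = rng.standard_normal((1, 4, 3, 3)) + 1j * rng.standard_normal((1, 4, 3, 3))
        np.testing.assert_array_equal(temporal_median_filter(x, width=1), x)

    def test_phase_kept_from_center_frame(self):
        x = np.exp(1j * np.linspace(0, 1, 5))[None, :, None, None] * np.ones((1, 5, 2, 2))
        out = temporal_median_filter(x, width=3)
        np.testing.assert_allclose(np.angle(out[0, 2]), np.angle(x[0, 2]), atol=1e-12)

    def test_even_width_rejected(self):
        with pytest.raises(ValueError):
            temporal_median_filter(np.ones((1, 4, 2, 2)), width=2)
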