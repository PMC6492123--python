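"""Temporal-TV ADMM solver: objective oracle, soft-threshold
correctness, limiting behaviours and determinism."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from radcine import cs_recon, encoding
from radcine.cs_recon import CsConfig, objective, reconstruct, soft_threshold
from radcine.encoding import GriddingOperator
from radcine.phantom import PhantomParams, gated_to_realtime, make_gated_cine
from radcine.protocol import (ProtocolConfig, full_sampling_trajectory,
                              make_trajectory)


@pytest.fixture(scope="module")
def tiny_case():
    """4-frame 8x8 problem with 3 spokes/frame, exact backend."""
    cfg = ProtocolConfig(matrix_size=8, crop_size=8, spokes_per_frame=3,
                         full_sampling_spokes=13, readout_samples=16)
    traj = make_trajectory(cfg, "tga_rot", 4)
    rng = np.random.default_rng(0)
    img = rng.random((4, 8, 8))
    ksp = encoding.forward(img, traj, backend="direct")
    return traj, ksp


class TestObjective:
    def test_zero_image_gives_half_data_energy(self, tiny_case):
        _, ksp = tiny_case
        cfg = CsConfig(lam=0.025, backend="direct")
        x0 = np.zeros((4, 8, 8), dtype=complex)
        assert objective(x0, ksp, cfg) == pytest.approx(
            0.5 * np.sum(np.abs(ksp.samples) ** 2))

    def test_lam_zero_is_pure_data_term(self, tiny_case):
        traj, ksp = tiny_case
        rng = np.random.default_rng(1)
        x = rng.random((4, 8, 8)) + 1j * rng.random((4, 8, 8))
        op = GriddingOperator(traj, 8, backend="direct")
        expected = 0.5 * np.sum(np.abs(op.forward(x) - ksp.samples) ** 2)
        cfg = CsConfig(lam=0.0, backend="direct")
        assert objective(x, ksp, cfg) == pytest.approx(expected, rel=1e-12)

    def test_agrees_with_brute_force_summation(self, tiny_case):
        """Independent elementwise summation of the data and TV terms."""
        traj, ksp = tiny_case
        rng = np.random.default_rng(2)
        x = rng.random((4, 8, 8)) + 1j * rng.random((4, 8, 8))
        cfg = CsConfig(lam=0.025, backend="direct")

        op = GriddingOperator(traj, 8, backend="direct")
        data = 0.0
        pred = op.forward(x)
        for f in range(4):
            for s in range(3):
                for m in range(16):
                    data += 0.5 * abs(pred[f, s, m] - ksp.samples[f, s, m]) ** 2
        tv = 0.0
        for f in range(3):
            for r in range(8):
                for c in range(8):
                    tv += abs(x[f + 1, r, c] - x[f, r, c])
        s_img = np.max(np.abs(encoding.adjoint(ksp, density_comp=True,
                                               backend="direct")))
        big_l = cs_recon._operator_norm(op, 4)
        brute = data + cfg.lam * s_img * big_l ** 2 * tv
        assert objective(x, ksp, cfg) == pytest.approx(brute, rel=1e-10)


class TestSoftThreshold:
    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(v=st.floats(-5, 5), thr=st.floats(0, 3))
    def test_matches_scalar_prox_minimizer(self, v, thr):
        """prox of thr*|.|: brute-force grid minimization of
        thr*|z| + 0.5*(z-v)^2 agrees with the closed form."""
        grid = np.linspace(-6, 6, 240001)
        cost = thr * np.abs(grid) + 0.5 * (grid - v) ** 2
        zstar = grid[np.argmin(cost)]
        assert soft_threshold(np.array([v + 0j]), thr)[0].real == \
            pytest.approx(zstar, abs=1e-4)

    def test_complex_phase_preserved(self):
        v = np.array([3 * np.exp(1j * 0.7), 0.1 * np.exp(-1j * 2.0)])
        out = soft_threshold(v, 1.0)
        assert np.angle(out[0]) == pytest.approx(0.7)
        assert abs(out[0]) == pytest.approx(2.0)
        assert out[1] == 0.0


class TestReconstruct:
    def test_single_frame_raises(self, tiny_case):
        traj, ksp = tiny_case
        one = encoding.KSpaceFrameSeries(ksp.samples[:1], traj.truncated(1), 8)
        with pytest.raises(ValueError, match="2 frames"):
            reconstruct(one, CsConfig(backend="direct"))

    def test_objective_decreases_over_iterations(self, tiny_case):
        _, ksp = tiny_case
        _, diag = reconstruct(ksp, CsConfig(n_iters=50, backend="direct"))
        obj = diag["objective"]
        assert obj[49] <= obj[4]

    def test_deterministic(self, tiny_case):
        _, ksp = tiny_case
        v1, _ = reconstruct(ksp, CsConfig(n_iters=6, backend="direct"))
        v2, _ = reconstruct(ksp, CsConfig(n_iters=6, backend="direct"))
        assert np.array_equal(v1.frames, v2.frames)

    def test_large_lambda_forces_temporal_flatness(self, tiny_case):
        _, ksp = tiny_case
        vol, _ = reconstruct(ksp, CsConfig(lam=10.0, n_iters=40,
                                           backend="direct"))
        assert np.abs(np.diff(vol.frames, axis=0)).max() < 1e-3

    def test_lam_zero_fully_sampled_matches_gridding(self):
        cfg = ProtocolConfig(matrix_size=16, crop_size=16,
                             spokes_per_frame=26, full_sampling_spokes=26,
                             readout_samples=32)
        traj = full_sampling_trajectory(cfg, 2)
        from scipy.ndimage import gaussian_filter

        # compact smooth object (full-FOV content is not radially
        # Nyquist-sampled at the corners and would penalize the more
        # accurate least-squares solution)
        idx = np.arange(16) - 8
        r = np.hypot(*np.meshgrid(idx, idx, indexing="ij"))
        blob = gaussian_filter((r < 5).astype(float), 1.2)
        img = np.stack([blob, blob]) / blob.max()
        ksp = encoding.forward(img, traj, backend="direct")
        vol, _ = reconstruct(ksp, CsConfig(lam=0.0, n_iters=15,
                                           backend="direct"))
        grid = np.abs(encoding.adjoint(ksp, density_comp=True,
                                       backend="direct"))
        nrmse = np.sqrt(np.mean((vol.frames - grid) ** 2)) \
            / (grid.max() - grid.min())
        assert nrmse < 0.05

    def test_static_phantom_temporal_variation_collapses(self):
        """13x undersampled static scene: temporal TV removes nearly
        all frame-to-frame alias variation of the gridded recon."""
        pcfg = ProtocolConfig(matrix_size=48, fov_mm=320, crop_size=32,
                              n_frames_fixed=8, readout_samples=96)
        p = PhantomParams(matrix=60, pixel_mm=320 / 60,
                          contraction_fraction=0.0, n_phases=6)
        rt = gated_to_realtime(make_gated_cine(p), pcfg)
        rt = rt.copy_with(rt.frames[:8])
        traj = make_trajectory(pcfg, "tga_rot", 8)
        ksp = encoding.forward(rt.frames, traj)
        vol, _ = reconstruct(ksp, CsConfig(lam=0.025, n_iters=50))
        aliased = np.abs(encoding.adjoint(ksp, density_comp=True))
        ratio = vol.frames.std(axis=0).mean() / aliased.std(axis=0).mean()
        assert ratio < 0.1
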