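"""Phantom rendering and the gated-to-real-time preparation pipeline."""

import numpy as np
import pytest

from radcine.phantom import (CineVolume, PhantomParams, gated_to_realtime,
                             make_dataset, make_gated_cine, normalize01,
                             prepare_pair)
from radcine.protocol import (ProtocolConfig, full_sampling_trajectory,
                              make_trajectory)


class TestGatedCine:
    def test_shape_and_range(self):
        cine = make_gated_cine(PhantomParams())
        assert cine.shape == (40, 240, 240)
        assert cine.frames.min() >= 0.0
        assert cine.frames.max() <= 1.0

    def test_static_when_no_contraction(self):
        p = PhantomParams(contraction_fraction=0.0, n_phases=5)
        cine = make_gated_cine(p)
        assert np.allclose(cine.frames, cine.frames[0], atol=1e-12)

    def test_motion_is_periodic(self):
        p = PhantomParams(n_phases=8)
        cine = make_gated_cine(p)
        # re-render the first phase of the next cycle: t = 1 === t = 0
        single = make_gated_cine(PhantomParams(n_phases=1))
        rms = np.sqrt(np.mean((cine.frames[0] - single.frames[0]) ** 2))
        assert rms < 1e-6

    def test_deterministic(self):
        a = make_gated_cine(PhantomParams(seed=3, n_phases=4))
        b = make_gated_cine(PhantomParams(seed=3, n_phases=4))
        assert np.array_equal(a.frames, b.frames)

    def test_oversized_geometry_raises(self):
        with pytest.raises(ValueError, match="exceeds"):
            make_gated_cine(PhantomParams(matrix=64, lv_radius_mm=80.0))


class TestGatedToRealtime:
    @pytest.mark.parametrize("rr,expected", [(800.0, 21), (1000.0, 27)])
    def test_frame_count_is_floor_of_rr(self, rr, expected):
        p = PhantomParams(rr_ms=rr, n_phases=10, matrix=60,
                          pixel_mm=320 / 60)
        rt = gated_to_realtime(make_gated_cine(p), ProtocolConfig())
        assert rt.n_frames == expected

    def test_output_matrix(self):
        p = PhantomParams(n_phases=6)
        rt = gated_to_realtime(make_gated_cine(p), ProtocolConfig())
        assert rt.frames.shape[1:] == (192, 192)

    def test_short_rr_raises(self):
        p = PhantomParams(rr_ms=20.0, n_phases=4, matrix=60,
                          pixel_mm=320 / 60)
        with pytest.raises(ValueError):
            gated_to_realtime(make_gated_cine(p), ProtocolConfig())


class TestPreparePair:
    def test_default_output_shape_is_20x128x128(self):
        cfg = ProtocolConfig()
        p = PhantomParams(rr_ms=750.0, n_phases=8)
        rt = gated_to_realtime(make_gated_cine(p), cfg)
        traj = make_trajectory(cfg, "tga_rot", rt.n_frames)
        truth, aliased = prepare_pair(rt, traj, cfg)
        assert truth.shape == (20, 128, 128)
        assert aliased.shape == (20, 128, 128)
        for vol in (truth, aliased):
            assert vol.frames.min() == 0.0
            assert vol.frames.max() == 1.0

    def test_zero_input_maps_to_zero(self, micro_protocol, micro_traj):
        zero = CineVolume(np.zeros((4, 48, 48)), 320 / 48, 36.4, rr_ms=800)
        truth, aliased = prepare_pair(zero, micro_traj, micro_protocol)
        assert np.all(truth.frames == 0)
        assert np.all(aliased.frames == 0)

    def test_interpolation_endpoints_pinned(self, micro_protocol,
                                            micro_truth_rt, micro_traj):
        """First/last output frames are the original first/last source
        frames up to the volume-wide affine normalization."""
        truth, _ = prepare_pair(micro_truth_rt, micro_traj, micro_protocol)
        lo = (48 - 32) // 2
        src = micro_truth_rt.frames[:, lo:lo + 32, lo:lo + 32]
        for out_f, src_f in ((truth.frames[0], src[0]),
                             (truth.frames[-1], src[-1])):
            a, b = np.polyfit(src_f.ravel(), out_f.ravel(), 1)
            assert np.allclose(out_f, a * src_f + b, atol=1e-9)

    def test_crop_out_of_bounds_raises(self, micro_protocol, micro_truth_rt,
                                       micro_traj):
        with pytest.raises(ValueError, match="crop"):
            prepare_pair(micro_truth_rt, micro_traj, micro_protocol,
                         crop_offset=(30, 0))

    def test_fully_sampled_pair_nearly_lossless(self, micro_truth_rt):
        """With a Nyquist trajectory the aliased branch reproduces the
        truth branch: the gridding round trip is faithful."""
        cfg = ProtocolConfig(matrix_size=48, fov_mm=320, crop_size=32,
                             n_frames_fixed=8, readout_samples=96,
                             spokes_per_frame=76, full_sampling_spokes=76)
        traj = full_sampling_trajectory(cfg, micro_truth_rt.n_frames)
        truth, aliased = prepare_pair(micro_truth_rt, traj, cfg)
        nrmse = np.sqrt(np.mean((truth.frames - aliased.frames) ** 2))
        assert nrmse < 0.05


class TestNormalization:
    def test_idempotent(self):
        rng = np.random.default_rng(0)
        x = rng.random((3, 8, 8)) * 7 + 2
        once = normalize01(x)
        assert np.array_equal(normalize01(once), once)
        assert once.min() == 0.0 and once.max() == 1.0

    def test_constant_maps_to_zeros(self):
        assert np.all(normalize01(np.full((2, 4, 4), 3.3)) == 0)


class TestAliasStructure:
    def test_static_no_rot_aliases_identical_across_frames(
            self, micro_protocol):
        """Non-rotating sampling of a static scene gives frame-wise
        identical aliasing."""
        p = PhantomParams(matrix=60, pixel_mm=320 / 60,
                          contraction_fraction=0.0, n_phases=6)
        rt = gated_to_realtime(make_gated_cine(p), micro_protocol)
        rt = rt.copy_with(rt.frames[:6])
        traj = make_trajectory(micro_protocol, "tga_no_rot", 6)
        _, aliased = prepare_pair(rt, traj, micro_protocol)
        rms = np.sqrt(np.mean((aliased.frames - aliased.frames[0]) ** 2))
        assert rms < 1e-6

    def test_rotating_aliases_vary_across_frames(self, micro_protocol,
                                                 micro_truth_rt):
        traj = make_trajectory(micro_protocol, "tga_rot",
                               micro_truth_rt.n_frames)
        _, aliased = prepare_pair(micro_truth_rt, traj, micro_protocol)
        rms = np.sqrt(np.mean((aliased.frames[1:] - aliased.frames[:-1]) ** 2))
        assert rms > 1e-3


class TestMakeDataset:
    def test_counts_and_determinism(self, micro_protocol,
                                    micro_phantom_params):
        pairs, manifest = make_dataset(2, 3, micro_protocol, "tga_rot",
                                       seed=5,
                                       template=micro_phantom_params)
        assert len(pairs) == 6
        assert len(manifest) == 6
        pairs2, manifest2 = make_dataset(2, 3, micro_protocol, "tga_rot",
                                         seed=5,
                                         template=micro_phantom_params)
        assert manifest.equals(manifest2)
        for (t1, a1), (t2, a2) in zip(pairs, pairs2):
            assert np.array_equal(a1.frames, a2.frames)

    def test_heart_rate_range_bounds_frame_counts(self, micro_protocol,
                                                  micro_phantom_params):
        _, manifest = make_dataset(6, 1, micro_protocol, "tga_rot", seed=9,
                                   template=micro_phantom_params)
        # R-R in [600, 1200] ms at 36.4 ms spacing -> 16..32 frames
        assert manifest["n_rt_frames"].between(16, 32).all()
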