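"""Shared fixtures: a reduced acquisition protocol and phantom sized so
that every operator test runs in seconds, plus a tiny trained network
for inference-level tests."""

import numpy as np
import pytest

from radcine.artifact_net import NetConfig, build_network, train
from radcine.phantom import PhantomParams, gated_to_realtime, make_gated_cine
from radcine.protocol import ProtocolConfig, make_trajectory


@pytest.fixture(scope="session")
def micro_protocol() -> ProtocolConfig:
    """48-matrix analogue of the real-time protocol: same 14-spoke /
    182-reference radial geometry (13x), crop 32, 8 fixed frames."""
    return ProtocolConfig(matrix_size=48, fov_mm=320.0, crop_size=32,
                          n_frames_fixed=8, readout_samples=96)


@pytest.fixture(scope="session")
def micro_phantom_params() -> PhantomParams:
    return PhantomParams(matrix=60, pixel_mm=320.0 / 60)


@pytest.fixture(scope="session")
def micro_truth_rt(micro_protocol, micro_phantom_params):
    """One real-time ground-truth cine on the reduced protocol."""
    gated = make_gated_cine(micro_phantom_params)
    return gated_to_realtime(gated, micro_protocol)


@pytest.fixture(scope="session")
def micro_traj(micro_protocol, micro_truth_rt):
    return make_trajectory(micro_protocol, "tga_rot",
                           micro_truth_rt.n_frames)


@pytest.fixture(scope="session")
def tiny_trained_model():
    """A very small network trained briefly on identity-ish pairs;
    enough for inference contracts, not for quality claims."""
    from radcine.phantom import CineVolume

    rng = np.random.default_rng(7)
    cfg = NetConfig(n_scales=2, base_channels=4, epochs=4, batch=2, seed=7)
    pairs = []
    for _ in range(4):
        truth = np.clip(rng.random((4, 16, 16)), 0, 1)
        aliased = np.clip(truth + 0.1 * rng.standard_normal((4, 16, 16)),
                          0, 1)
        pairs.append((CineVolume(truth, 1.0, 36.4),
                      CineVolume(aliased, 1.0, 36.4)))
    return train(build_network(cfg), pairs, cfg), pairs
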