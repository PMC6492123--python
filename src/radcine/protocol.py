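"""Acquisition protocol constants and radial sampling trajectories.

The real-time sequence this package simulates acquires 2D radial bSSFP
frames with 14 spokes per frame on a 192x192 matrix; a fully sampled
k-space would need 182 uniformly spaced spokes, so each frame is 13x
undersampled.  Four spoke-ordering schemes are supported, differing in
(a) whether spokes within a frame are spaced regularly (180/14 deg) or
by the tiny golden angle, and (b) whether the pattern rotates between
frames:

``reg_no_rot``
    regular spacing, identical angles in every frame.
``reg_rot``
    regular spacing, rotated by (180/14)/13 deg per frame so that 13
    consecutive frames pool to a complete 182-spoke set.
``tga_no_rot``
    tiny-golden-angle spacing, identical angles in every frame.
``tga_rot``
    tiny-golden-angle increments accumulating continuously across
    frames (the scheme used for the in vivo protocol).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SCHEMES",
    "ProtocolConfig",
    "RadialTrajectory",
    "tiny_golden_angle",
    "acceleration_factor",
    "make_trajectory",
]

#: Recognised spoke-ordering schemes.
SCHEMES = ("reg_no_rot", "reg_rot", "tga_no_rot", "tga_rot")

_GOLDEN_RATIO = (1.0 + math.sqrt(5.0)) / 2.0


def tiny_golden_angle(n: int = 7) -> float:
    """Return the N-th tiny golden angle in degrees.

    psi_N = 180 / (tau + N - 1) with tau the golden ratio.  The default
    N=7 gives ~23.63 deg, the increment used by the tGA schemes; it
    retains the golden-angle property of near-uniform incremental
    angular coverage while keeping consecutive spokes close, which
    reduces eddy-current perturbations on the scanner.
    """
    if n < 1:
        raise ValueError("tiny golden angle index must be >= 1")
    return 180.0 / (_GOLDEN_RATIO + n - 1)


@dataclass(frozen=True)
class ProtocolConfig:
    """Constants of the simulated real-time radial acquisition.

    Defaults mirror the in vivo protocol: 192 matrix / 320 mm FOV
    (1.67 mm pixels), 14 spokes per 36.4 ms frame against 182 spokes
    for full sampling (13x acceleration), frames cropped to 128x128
    and interpolated to a fixed 20 time points for the network.
    """

    matrix_size: int = 192
    fov_mm: float = 320.0
    spokes_per_frame: int = 14
    full_sampling_spokes: int = 182
    tr_ms: float = 2.8
    frame_spacing_ms: float = 36.4
    crop_size: int = 128
    n_frames_fixed: int = 20
    readout_samples: int = 0  # 0 -> 2 * matrix_size

    def __post_init__(self):
        if self.readout_samples == 0:
            object.__setattr__(self, "readout_samples", 2 * self.matrix_size)
        for name in ("matrix_size", "spokes_per_frame", "full_sampling_spokes",
                     "crop_size", "n_frames_fixed", "readout_samples"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v > 0):
                raise ValueError(f"{name} must be a positive integer, got {v!r}")
        if self.spokes_per_frame > self.full_sampling_spokes:
            raise ValueError("spokes_per_frame must not exceed full_sampling_spokes")
        if self.crop_size > self.matrix_size:
            raise ValueError("crop_size must not exceed matrix_size")
        if not (self.fov_mm > 0 and self.tr_ms > 0 and self.frame_spacing_ms > 0):
            raise ValueError("fov_mm, tr_ms and frame_spacing_ms must be positive")

    @property
    def pixel_mm(self) -> float:
        """In-plane pixel size in mm (FOV / matrix)."""
        return self.fov_mm / self.matrix_size

    @property
    def acceleration(self) -> float:
        return acceleration_factor(self)


def acceleration_factor(config: ProtocolConfig) -> float:
    """Undersampling factor: full-sampling spoke count over spokes per frame."""
    return config.full_sampling_spokes / config.spokes_per_frame


@dataclass
class RadialTrajectory:
    """Per-frame spoke angles and normalized k-space sample coordinates.

    ``angles_deg`` has shape (frames, spokes) with angles in [0, 360);
    ``coords`` has shape (frames, spokes, samples, 2) holding (kx, ky)
    in cycles/pixel within [-0.5, 0.5).  0 deg points along +kx,
    counter-clockwise positive.
    """

    scheme: str
    angles_deg: np.ndarray
    coords: np.ndarray
    spokes_per_frame: int = field(init=False)

    def __post_init__(self):
        self.angles_deg = np.asarray(self.angles_deg, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.angles_deg.ndim != 2:
            raise ValueError("angles_deg must be (frames, spokes)")
        if self.coords.shape[:2] != self.angles_deg.shape or self.coords.shape[-1] != 2:
            raise ValueError("coords must be (frames, spokes, samples, 2)")
        self.spokes_per_frame = self.angles_deg.shape[1]

    @property
    def n_frames(self) -> int:
        return self.angles_deg.shape[0]

    @property
    def n_samples(self) -> int:
        return self.coords.shape[2]

    def frame_coords(self, f: int) -> np.ndarray:
        """Flattened (K, 2) sample coordinates of frame ``f``."""
        return self.coords[f].reshape(-1, 2)

    def truncated(self, n_frames: int) -> "RadialTrajectory":
        """First ``n_frames`` frames as a new trajectory."""
        if n_frames > self.n_frames:
            raise ValueError("cannot truncate to more frames than available")
        return RadialTrajectory(self.scheme, self.angles_deg[:n_frames],
                                self.coords[:n_frames])

    def save_h5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.attrs["scheme"] = self.scheme
            f.create_dataset("angles_deg", data=self.angles_deg)
            f.create_dataset("coords", data=self.coords)

    @classmethod
    def load_h5(cls, path) -> "RadialTrajectory":
        import h5py

        with h5py.File(path, "r") as f:
            return cls(str(f.attrs["scheme"]), f["angles_deg"][()], f["coords"][()])


def _scheme_angles(scheme: str, config: ProtocolConfig, n_frames: int) -> np.ndarray:
    ns = config.spokes_per_frame
    s = np.arange(ns, dtype=float)
    f = np.arange(n_frames, dtype=float)[:, None]
    if scheme == "reg_no_rot":
        ang = np.broadcast_to(s * (180.0 / ns), (n_frames, ns)).copy()
    elif scheme == "reg_rot":
        # per-frame rotation of (180/ns)/acceleration so that
        # round(acceleration) consecutive frames tile the full set
        step = (180.0 / ns) / acceleration_factor(config)
        ang = s * (180.0 / ns) + f * step
    elif scheme == "tga_no_rot":
        ang = np.broadcast_to(s * tiny_golden_angle(), (n_frames, ns)).copy()
    elif scheme == "tga_rot":
        ang = (f * ns + s) * tiny_golden_angle()
    else:
        raise ValueError(f"unknown scheme {scheme!r}; expected one of {SCHEMES}")
    return np.mod(ang, 360.0)


def make_trajectory(config: ProtocolConfig, scheme: str,
                    n_frames: int) -> RadialTrajectory:
    """Generate spoke angles and k-space coordinates for one scheme.

    Each spoke carries ``config.readout_samples`` points uniformly
    spaced along the spoke from -0.5 to just below +0.5 cycles/pixel
    (2x readout oversampling by default).  Deterministic: identical
    arguments give bit-identical arrays.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    scheme = scheme.lower()
    ang = _scheme_angles(scheme, config, n_frames)
    m = config.readout_samples
    kr = -0.5 + np.arange(m, dtype=float) / m  # [-0.5, 0.5)
    rad = np.deg2rad(ang)
    # (frames, spokes, samples, 2)
    coords = np.empty(ang.shape + (m, 2), dtype=float)
    coords[..., 0] = np.cos(rad)[..., None] * kr
    coords[..., 1] = np.sin(rad)[..., None] * kr
    return RadialTrajectory(scheme, ang, coords)


def full_sampling_trajectory(config: ProtocolConfig, n_frames: int) -> RadialTrajectory:
    """Uniform 182-spoke (Nyquist) trajectory, identical in every frame.

    Used for gridding round-trip checks and as the lambda=0 CS limit.
    """
    ns = config.full_sampling_spokes
    full_cfg = ProtocolConfig(
        matrix_size=config.matrix_size, fov_mm=config.fov_mm,
        spokes_per_frame=ns, full_sampling_spokes=ns,
        tr_ms=config.tr_ms, frame_spacing_ms=config.frame_spacing_ms,
        crop_size=config.crop_size, n_frames_fixed=config.n_frames_fixed,
        readout_samples=config.readout_samples)
    traj = make_trajectory(full_cfg, "reg_no_rot", n_frames)
    return traj


def minimal_tiling_frames(traj: RadialTrajectory, config: ProtocolConfig,
                          tol_deg: float = 1e-6, m_max: int | None = None) -> int:
    """Smallest m such that the first m frames' pooled angles (mod 180)
    form the complete uniform full-sampling set.

    Exhaustive search; raises if no m up to ``m_max`` (default
    2*acceleration) tiles the set.
    """
    nf = config.full_sampling_spokes
    target = np.arange(nf) * (180.0 / nf)
    if m_max is None:
        m_max = int(math.ceil(2 * acceleration_factor(config)))
    m_max = min(m_max, traj.n_frames)
    for m in range(1, m_max + 1):
        pooled = np.sort(np.mod(traj.angles_deg[:m].ravel(), 180.0))
        if pooled.size != nf:
            continue
        if np.max(np.abs(pooled - target)) <= tol_deg:
            return m
    raise ValueError(f"no tiling found within {m_max} frames")
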