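"""Synthetic short-axis cardiac cine phantom and the conversion of
gated cines into synthetic real-time training pairs.

The phantom stands in for a library of retrospectively gated
breath-hold bSSFP short-axis cines: piecewise-smooth magnitude images
in [0, 1] with bSSFP-like contrast (bright blood pool, darker
myocardium), a periodically contracting left-ventricular annulus with
papillary muscles that move rigidly with the wall, a right-ventricular
crescent, and a torso background.  All shapes are rasterized
analytically with ~1-pixel anti-aliased edges, so the ground truth is
exact and motion is fully controllable.

The conversion pipeline mirrors how gated cines become training data
for the real-time protocol: spatial resampling to the acquisition
matrix, temporal resampling to the real-time frame spacing
(``floor(RR / 36.4 ms)`` frames), radial undersampling + regridding to
create the artifact-contaminated branch, centre-cropping, linear
interpolation to a fixed 20 frames, and per-volume [0, 1]
normalization.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from scipy.ndimage import zoom as _ndzoom

from . import encoding
from .protocol import ProtocolConfig, RadialTrajectory

__all__ = [
    "CineVolume",
    "PhantomParams",
    "make_gated_cine",
    "gated_to_realtime",
    "prepare_pair",
    "make_dataset",
    "normalize01",
]


@dataclass
class CineVolume:
    """A 2D+time magnitude image series — the unit of data everywhere.

    ``frames`` is (frame, row, col), non-negative.
    """

    frames: np.ndarray
    pixel_mm: float
    frame_ms: float
    rr_ms: Optional[float] = None
    subject_id: str = ""
    slice_id: str = ""

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be (frame, row, col)")
        if np.any(self.frames < 0):
            raise ValueError("magnitude images must be non-negative")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.frames.shape

    def copy_with(self, frames: np.ndarray, **kw) -> "CineVolume":
        d = dict(pixel_mm=self.pixel_mm, frame_ms=self.frame_ms,
                 rr_ms=self.rr_ms, subject_id=self.subject_id,
                 slice_id=self.slice_id)
        d.update(kw)
        return CineVolume(frames, **d)


@dataclass
class PhantomParams:
    """Geometry, contrast and motion of one synthetic subject/slice.

    Lengths in mm, times in ms, intensities in [0, 1].  Defaults are
    adult-sized at the gated-library resolution (240 matrix, 1.3 mm,
    40 phases).
    """

    matrix: int = 240
    pixel_mm: float = 1.3
    rr_ms: float = 900.0
    n_phases: int = 40
    lv_center_mm: Tuple[float, float] = (8.0, 10.0)  # (x, y) offset from centre
    lv_radius_mm: float = 24.0        # end-diastolic endocardial radius
    wall_thickness_mm: float = 9.0
    contraction_fraction: float = 0.35
    n_papillary: int = 2
    papillary_radius_mm: float = 3.4
    rv_crescent: bool = True
    rv_radius_mm: float = 30.0
    blood_level: float = 0.9
    myo_level: float = 0.25
    fat_level: float = 0.55
    background_level: float = 0.12
    breathing_amplitude_mm: float = 0.0
    breathing_period_ms: float = 4000.0
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.contraction_fraction < 1.0):
            raise ValueError("contraction_fraction must be in [0, 1)")
        for name in ("lv_radius_mm", "wall_thickness_mm", "papillary_radius_mm",
                     "rv_radius_mm", "pixel_mm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("blood_level", "myo_level", "fat_level", "background_level"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")


def _soft_disc(r: np.ndarray, radius: float, aa: float) -> np.ndarray:
    """Anti-aliased disc indicator from a radial distance map."""
    return np.clip(0.5 - (r - radius) / aa, 0.0, 1.0)


def _blend(base: np.ndarray, mask: np.ndarray, level: float) -> np.ndarray:
    return base * (1.0 - mask) + level * mask


def make_gated_cine(params: PhantomParams) -> CineVolume:
    """Render a retrospectively-gated synthetic short-axis cine.

    Motion is periodic in the cardiac phase: the endocardial radius
    follows r0*(1 - cf*w(t)) with w a smooth asymmetric systolic
    waveform, the epicardium conserves myocardial cross-section, and
    papillary discs ride on the contracting endocardium.  Frame 0 is
    end-diastole; a full-cycle return reproduces frame 0 exactly.
    """
    n = params.matrix
    px = params.pixel_mm
    half_fov = n * px / 2.0
    cx, cy = params.lv_center_mm
    r_epi0 = params.lv_radius_mm + params.wall_thickness_mm
    reach = max(abs(cx), abs(cy)) + max(r_epi0,
                                        params.rv_radius_mm + 12.0)
    if reach > half_fov:
        raise ValueError(
            f"phantom geometry (reach {reach:.1f} mm) exceeds half-FOV "
            f"{half_fov:.1f} mm")

    idx = (np.arange(n) - n // 2) * px
    yy, xx = np.meshgrid(idx, idx, indexing="ij")
    aa = px  # ~1-pixel anti-aliasing band

    torso_a, torso_b = 0.94 * half_fov, 0.78 * half_fov
    frames = np.empty((params.n_phases, n, n), dtype=float)
    t_grid = np.arange(params.n_phases) / params.n_phases

    myo_area0 = np.pi * (r_epi0 ** 2 - params.lv_radius_mm ** 2)
    pap_angles = np.deg2rad(110.0 + 360.0 * np.arange(params.n_papillary)
                            / max(params.n_papillary, 1) * 0.45 + 35.0)

    for i, t in enumerate(t_grid):
        # asymmetric periodic contraction: fast systole, slower diastole
        w = np.sin(np.pi * t) ** 2 * (1.0 + 0.35 * np.sin(2 * np.pi * t))
        w = np.clip(w, 0.0, 1.0)
        r_endo = params.lv_radius_mm * (1.0 - params.contraction_fraction * w)
        r_epi = np.sqrt(r_endo ** 2 + myo_area0 / np.pi)

        dy = 0.0
        if params.breathing_amplitude_mm > 0:
            dy = params.breathing_amplitude_mm * np.sin(
                2 * np.pi * (t * params.rr_ms) / params.breathing_period_ms)

        x = xx - cx
        y = yy - cy - dy
        r_lv = np.hypot(x, y)

        # torso + fat rim (translate with breathing as a whole)
        er = np.hypot(xx / torso_a, (yy - dy) / torso_b)
        img = np.full((n, n), 0.0)
        torso = np.clip(0.5 - (er - 1.0) * torso_b / aa, 0.0, 1.0)
        img = _blend(img, torso, params.background_level)
        rim = np.clip(0.5 - (np.abs(er - 0.92) - 0.045) * torso_b / aa, 0, 1)
        img = _blend(img, rim, params.fat_level)

        # LV: epicardial disc (myocardium), then blood pool
        img = _blend(img, _soft_disc(r_lv, r_epi, aa), params.myo_level)
        img = _blend(img, _soft_disc(r_lv, r_endo, aa), params.blood_level)

        # papillary muscles riding on the endocardium
        for ang in pap_angles[:params.n_papillary]:
            pr = 0.55 * r_endo
            pxc = cx + pr * np.cos(ang)
            pyc = cy + dy + pr * np.sin(ang)
            rp = np.hypot(xx - pxc, yy - pyc)
            img = _blend(img, _soft_disc(rp, params.papillary_radius_mm, aa),
                         params.myo_level)

        # RV crescent to the left of the LV, contracting mildly
        if params.rv_crescent:
            rv_cx = cx - (r_epi + 0.55 * params.rv_radius_mm)
            r_rv = np.hypot(xx - rv_cx, y)
            rv_shrink = 1.0 - 0.43 * params.contraction_fraction * w
            rv_pool = _soft_disc(r_rv, params.rv_radius_mm * rv_shrink, aa)
            rv_pool *= 1.0 - _soft_disc(r_lv, r_epi + 2.0, aa)
            img = _blend(img, rv_pool, 0.95 * params.blood_level)

        frames[i] = img

    frames = np.clip(frames, 0.0, 1.0)
    return CineVolume(frames, pixel_mm=px,
                      frame_ms=params.rr_ms / params.n_phases,
                      rr_ms=params.rr_ms)


def _temporal_linear(frames: np.ndarray, src_t: np.ndarray,
                     dst_t: np.ndarray) -> np.ndarray:
    """Linear interpolation along axis 0 (clamped at the ends)."""
    dst_t = np.clip(dst_t, src_t[0], src_t[-1])
    j = np.searchsorted(src_t, dst_t, side="right") - 1
    j = np.clip(j, 0, len(src_t) - 2)
    denom = src_t[j + 1] - src_t[j]
    a = (dst_t - src_t[j]) / denom
    return (1 - a)[:, None, None] * frames[j] + a[:, None, None] * frames[j + 1]


def gated_to_realtime(cine: CineVolume, config: ProtocolConfig) -> CineVolume:
    """Resample a gated cine onto the real-time protocol's grid.

    Bilinear spatial resampling to ``config.matrix_size`` and linear
    temporal resampling onto points ``config.frame_spacing_ms`` apart;
    the frame count is floor(RR / frame spacing).  The output is the
    ground truth from which training pairs are made.
    """
    if cine.n_frames < 2:
        raise ValueError("need at least 2 frames to resample in time")
    if cine.rr_ms is None:
        raise ValueError("source R-R interval unknown")
    n_out = int(np.floor(cine.rr_ms / config.frame_spacing_ms))
    if n_out < 1:
        raise ValueError("R-R interval shorter than one real-time frame")

    zf = config.matrix_size / cine.frames.shape[1]
    spat = np.stack([_ndzoom(f, zf, order=1, grid_mode=True, mode="nearest")
                     for f in cine.frames])
    src_t = np.arange(cine.n_frames) * cine.frame_ms
    dst_t = np.arange(n_out) * config.frame_spacing_ms
    out = _temporal_linear(spat, src_t, dst_t)
    return cine.copy_with(np.clip(out, 0.0, None),
                          pixel_mm=cine.pixel_mm / zf,
                          frame_ms=config.frame_spacing_ms)


def normalize01(frames: np.ndarray) -> np.ndarray:
    """Min-max normalize one 3D dataset to [0, 1]; constant maps to zeros."""
    lo = frames.min()
    rng = frames.max() - lo
    if rng == 0:
        return np.zeros_like(frames)
    return (frames - lo) / rng


def _center_crop(frames: np.ndarray, size: int,
                 offset: Tuple[int, int]) -> np.ndarray:
    n = frames.shape[1]
    dx, dy = offset
    r0 = (n - size) // 2 + dy
    c0 = (n - size) // 2 + dx
    if r0 < 0 or c0 < 0 or r0 + size > n or c0 + size > n:
        raise ValueError(
            f"crop window (size {size}, offset {offset}) exceeds image "
            f"bounds for matrix {n}")
    return frames[:, r0:r0 + size, c0:c0 + size]


def prepare_pair(truth_rt: CineVolume, traj: RadialTrajectory,
                 config: ProtocolConfig,
                 crop_offset: Tuple[int, int] = (0, 0),
                 backend: str = "kb") -> Tuple[CineVolume, CineVolume]:
    """Create one (ground-truth, artifact-contaminated) training pair.

    The aliased branch is the magnitude of the regridded undersampled
    k-space of the truth; both branches are centre-cropped (optionally
    shifted), linearly interpolated to ``config.n_frames_fixed`` frames
    with endpoints pinned, and min-max normalized per volume.
    """
    nf = truth_rt.n_frames
    if traj.n_frames < nf:
        raise ValueError("trajectory has fewer frames than the cine")
    traj = traj.truncated(nf)

    ksp = encoding.forward(truth_rt.frames, traj, backend=backend)
    aliased = np.abs(encoding.adjoint(ksp, density_comp=True, backend=backend))

    out = []
    for frames in (truth_rt.frames, aliased):
        x = _center_crop(frames, config.crop_size, crop_offset)
        src_t = np.arange(nf, dtype=float)
        dst_t = np.linspace(0.0, nf - 1.0, config.n_frames_fixed)
        x = _temporal_linear(x, src_t, dst_t)
        out.append(normalize01(x))

    span_ms = (nf - 1) * truth_rt.frame_ms
    frame_ms = span_ms / max(config.n_frames_fixed - 1, 1)
    truth_p = truth_rt.copy_with(out[0], frame_ms=frame_ms)
    alias_p = truth_rt.copy_with(out[1], frame_ms=frame_ms)
    return truth_p, alias_p


def _draw_subject_params(rng: np.random.Generator,
                         template: PhantomParams) -> PhantomParams:
    """Per-subject randomization of heart rate, geometry and contrast.

    Ranges: R-R 600-1200 ms; LV radius/wall/contraction +-15-20%;
    contrast levels jittered a few percent — wide enough to emulate
    inter-patient variation, narrow enough to keep geometry valid.
    """
    def jit(v, frac):
        return float(v * rng.uniform(1 - frac, 1 + frac))

    shift = 0.04 * template.pixel_mm * template.matrix
    return replace(
        template,
        rr_ms=float(rng.uniform(600.0, 1200.0)),
        lv_radius_mm=jit(template.lv_radius_mm, 0.18),
        wall_thickness_mm=jit(template.wall_thickness_mm, 0.2),
        contraction_fraction=float(np.clip(
            template.contraction_fraction * rng.uniform(0.75, 1.2), 0.1, 0.6)),
        lv_center_mm=(float(rng.uniform(-shift, shift)),
                      float(rng.uniform(-shift, shift))),
        n_papillary=int(rng.integers(2, 4)),
        rv_radius_mm=jit(template.rv_radius_mm, 0.15),
        blood_level=float(np.clip(jit(template.blood_level, 0.06), 0, 1)),
        myo_level=float(np.clip(jit(template.myo_level, 0.12), 0, 1)),
    )


def make_realtime_truths(n_subjects: int, slices_per_subject: int,
                         config: ProtocolConfig, seed: int,
                         template: Optional[PhantomParams] = None):
    """Draw per-subject phantoms and convert them to real-time truths.

    Returns a list of dicts with keys ``subject``, ``slice``,
    ``params`` and ``truth_rt`` (the uncropped real-time ground-truth
    cine).  Slices within a subject share the heart but shrink toward
    the apex.  Fully determined by ``seed``.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    if template is None:
        template = PhantomParams()
    out = []
    for s in range(n_subjects):
        rng = np.random.default_rng([seed, s])
        sub = _draw_subject_params(rng, template)
        for sl in range(slices_per_subject):
            shrink = 1.0 - 0.08 * sl
            p = replace(sub,
                        lv_radius_mm=sub.lv_radius_mm * shrink,
                        rv_radius_mm=sub.rv_radius_mm * shrink,
                        seed=seed)
            rt = gated_to_realtime(make_gated_cine(p), config)
            rt.subject_id = f"S{s:03d}"
            rt.slice_id = f"Z{sl:02d}"
            out.append(dict(subject=rt.subject_id, slice=rt.slice_id,
                            params=p, truth_rt=rt))
    return out


def make_dataset(n_subjects: int, slices_per_subject: int,
                 config: ProtocolConfig, scheme: str, seed: int,
                 template: Optional[PhantomParams] = None,
                 backend: str = "kb"):
    """Generate a reproducible library of prepared training pairs.

    Per-subject phantom parameters are drawn from documented ranges
    with a single master seed; slices within a subject share the heart
    but differ slightly in apical-basal geometry.  Returns
    ``(pairs, manifest)`` where pairs is a list of (truth, aliased)
    CineVolume tuples and the manifest a DataFrame with one row per
    pair.
    """
    from .protocol import make_trajectory

    records = make_realtime_truths(n_subjects, slices_per_subject, config,
                                   seed, template)
    max_frames = max(r["truth_rt"].n_frames for r in records)
    traj = make_trajectory(config, scheme, max_frames)
    pairs = []
    rows = []
    for r in records:
        rt = r["truth_rt"]
        truth, aliased = prepare_pair(rt, traj, config, backend=backend)
        truth.subject_id = aliased.subject_id = r["subject"]
        truth.slice_id = aliased.slice_id = r["slice"]
        pairs.append((truth, aliased))
        rows.append(dict(subject=r["subject"], slice=r["slice"],
                         rr_ms=r["params"].rr_ms, n_rt_frames=rt.n_frames,
                         scheme=scheme, seed=seed,
                         checksum=float(np.sum(aliased.frames))))
    return pairs, pd.DataFrame(rows)
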