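"""Image-quality evaluation: RMSE, SSIM, profile edge sharpness and
Bland-Altman agreement.

RMSE and SSIM are computed against ground truth on [0, 1]-normalized
volumes, per frame and then averaged over frames; study-level numbers
average over slices and subjects.  Edge sharpness is the maximum
absolute gradient of a normalized intensity profile across a tissue
border (in 1/mm), with a degree-10 polynomial fit suppressing
noise-driven spurious gradients.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from numpy.polynomial import polynomial as npoly
from scipy.ndimage import map_coordinates
from skimage.metrics import structural_similarity

from .phantom import CineVolume

__all__ = ["rmse", "ssim", "edge_sharpness", "bland_altman", "EvalReport",
           "SSIM_PARAMS", "phantom_septal_segments"]

#: SSIM constants recorded in every report (Wang et al. defaults,
#: Gaussian window sigma 1.5, data range 1).
SSIM_PARAMS = dict(K1=0.01, K2=0.03, sigma=1.5, data_range=1.0)


def _check_pair(a: np.ndarray, b: np.ndarray):
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return a, b


def rmse(a: np.ndarray, b: np.ndarray) -> float:
    """Root-mean-square error over all voxels."""
    a, b = _check_pair(a, b)
    return float(np.sqrt(np.mean((a - b) ** 2)))


def ssim(a: np.ndarray, b: np.ndarray) -> float:
    """Structural similarity, per frame then averaged over frames.

    2D input is treated as a single frame.
    """
    a, b = _check_pair(a, b)
    if a.ndim == 2:
        a = a[None]
        b = b[None]
    vals = [structural_similarity(
        fa, fb, gaussian_weights=True, sigma=SSIM_PARAMS["sigma"],
        use_sample_covariance=False, K1=SSIM_PARAMS["K1"],
        K2=SSIM_PARAMS["K2"], data_range=SSIM_PARAMS["data_range"])
        for fa, fb in zip(a, b)]
    return float(np.mean(vals))


def _profile_sharpness(vals: np.ndarray, length_mm: float) -> Optional[float]:
    """Max |d(normalized intensity)/d(mm)| of one profile via a
    degree-10 polynomial fit on a [-1, 1] coordinate."""
    rng = vals.max() - vals.min()
    if rng == 0:
        return None
    v = (vals - vals.min()) / rng
    t = np.linspace(-1.0, 1.0, len(v))
    coef = npoly.polyfit(t, v, 10)
    dcoef = npoly.polyder(coef)
    tt = np.linspace(-1.0, 1.0, 512)
    dv = npoly.polyval(tt, dcoef)  # d(intensity)/dt
    return float(np.max(np.abs(dv)) * 2.0 / length_mm)  # dt/dmm = 2/L


def edge_sharpness(cine: CineVolume,
                   profile_lines: Sequence[Tuple[Tuple[float, float],
                                                 Tuple[float, float]]],
                   n_samples: int = 64) -> float:
    """Mean edge sharpness (1/mm) over profile segments and frames.

    Each segment is ((r0, c0), (r1, c1)) in pixel coordinates and must
    cross an intensity edge.  Intensities are sampled by bilinear
    interpolation, the profile min-max normalized, fitted with a
    degree-10 polynomial and differentiated analytically.  Constant
    profiles are excluded with a warning; fewer than 11 samples is an
    error (the fit would be underdetermined).
    """
    if n_samples < 11:
        raise ValueError("need >= 11 samples for a degree-10 fit")
    vals = []
    for (r0, c0), (r1, c1) in profile_lines:
        length_mm = np.hypot(r1 - r0, c1 - c0) * cine.pixel_mm
        rr = np.linspace(r0, r1, n_samples)
        cc = np.linspace(c0, c1, n_samples)
        for f in range(cine.n_frames):
            prof = map_coordinates(cine.frames[f], [rr, cc], order=1)
            s = _profile_sharpness(prof, length_mm)
            if s is None:
                warnings.warn("constant profile (no edge) excluded from "
                              "edge sharpness", stacklevel=2)
                continue
            vals.append(s)
    if not vals:
        raise ValueError("no usable profiles")
    return float(np.mean(vals))


def phantom_septal_segments(center_rc: Tuple[float, float],
                            r_inner_px: float, r_outer_px: float,
                            n_segments: int = 6,
                            side_deg: float = 200.0,
                            span_deg: float = 70.0):
    """Six canonical profile segments crossing the septal border.

    For the analytic phantom the septum faces the RV (left of the LV
    centre); segments fan over ``span_deg`` centred on ``side_deg``
    and run radially from inside the blood pool to outside the wall.
    """
    cr, cc = center_rc
    angs = np.deg2rad(side_deg + np.linspace(-span_deg / 2, span_deg / 2,
                                             n_segments))
    segs = []
    for a in angs:
        p0 = (cr + r_inner_px * np.sin(a), cc + r_inner_px * np.cos(a))
        p1 = (cr + r_outer_px * np.sin(a), cc + r_outer_px * np.cos(a))
        segs.append((p0, p1))
    return segs


def bland_altman(ref_values: Sequence[float],
                 test_values: Sequence[float]) -> Tuple[float, float, float]:
    """Bias and +-2 SD limits of agreement of test minus reference."""
    ref = np.asarray(ref_values, dtype=float)
    test = np.asarray(test_values, dtype=float)
    if ref.shape != test.shape or ref.ndim != 1:
        raise ValueError("ref and test must be matching 1D sequences")
    if len(ref) < 2:
        raise ValueError("need at least 2 paired values")
    if not (np.all(np.isfinite(ref)) and np.all(np.isfinite(test))):
        raise ValueError("values must be finite")
    d = test - ref
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    return bias, bias - 2 * sd, bias + 2 * sd


@dataclass
class EvalReport:
    """Per-dataset metric rows plus aggregates and sweep tables.

    ``rows`` holds one record per (subject, slice, arm/condition);
    aggregates are recomputed from the rows, never stored stale.
    """

    rows: pd.DataFrame
    sweeps: Dict[str, pd.DataFrame] = field(default_factory=dict)
    meta: Dict = field(default_factory=dict)

    def __post_init__(self):
        if "rmse" in self.rows and np.any(self.rows["rmse"] < 0):
            raise ValueError("rmse must be non-negative")
        if "ssim" in self.rows and not self.rows["ssim"].between(-1, 1).all():
            raise ValueError("ssim must lie in [-1, 1]")
        self.meta.setdefault("ssim_params", dict(SSIM_PARAMS))

    def per_subject(self, metrics=("rmse", "ssim")) -> pd.DataFrame:
        """Mean of each metric over phases/slices within a subject."""
        cols = [m for m in metrics if m in self.rows]
        return self.rows.groupby("subject")[cols].mean()

    def mean(self, metric: str, where: Optional[Dict] = None) -> float:
        df = self.rows
        if where:
            for k, v in where.items():
                df = df[df[k] == v]
        return float(df[metric].mean())

    def to_json(self, path) -> None:
        import json

        payload = dict(rows=self.rows.to_dict(orient="records"),
                       sweeps={k: v.to_dict(orient="records")
                               for k, v in self.sweeps.items()},
                       meta=self.meta)
        with open(path, "w") as f:
            json.dump(payload, f, indent=1, default=float)
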