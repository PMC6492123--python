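"""Cine I/O: NIfTI for single cines, HDF5 bundles for paired datasets,
and an optional DICOM-series reader for user-supplied gated cines.

NIfTI layout: frames on the 4th axis, pixel spacing in the header zooms
(dx, dy, 1, frame spacing in seconds).
"""

from __future__ import annotations

from pathlib import Path
from typing import List, Optional, Tuple

import h5py
import numpy as np

from .phantom import CineVolume

__all__ = ["save_nifti", "load_nifti", "save_pairs_h5", "load_pairs_h5",
           "load_dicom_series"]


def save_nifti(cine: CineVolume, path) -> None:
    import nibabel as nib

    # (frame, row, col) -> (col, row, 1, frame) so time is the 4th axis
    data = np.transpose(cine.frames, (2, 1, 0))[:, :, None, :]
    img = nib.Nifti1Image(data.astype(np.float32), affine=np.eye(4))
    img.header.set_zooms((cine.pixel_mm, cine.pixel_mm, 1.0,
                          cine.frame_ms / 1000.0))
    img.header.set_xyzt_units(xyz="mm", t="sec")
    nib.save(img, str(path))


def load_nifti(path) -> CineVolume:
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 3:
        data = data[:, :, None, :] if data.shape[-1] > 8 else data[..., None]
    if data.ndim != 4:
        raise ValueError(f"expected a 4D cine NIfTI, got shape {data.shape}")
    frames = np.transpose(data[:, :, 0, :], (2, 1, 0)).astype(float)
    zooms = img.header.get_zooms()
    pixel_mm = float(zooms[0])
    frame_ms = float(zooms[3]) * 1000.0 if len(zooms) > 3 and zooms[3] > 0 \
        else 0.0
    return CineVolume(np.clip(frames, 0, None), pixel_mm=pixel_mm,
                      frame_ms=frame_ms)


def save_pairs_h5(pairs: List[Tuple[CineVolume, CineVolume]], path,
                  manifest=None) -> None:
    """Write prepared (truth, aliased) pairs into one HDF5 bundle."""
    with h5py.File(path, "w") as f:
        for i, (truth, aliased) in enumerate(pairs):
            g = f.create_group(f"pair{i:04d}")
            g.create_dataset("truth", data=truth.frames.astype(np.float32),
                             compression="gzip")
            g.create_dataset("aliased",
                             data=aliased.frames.astype(np.float32),
                             compression="gzip")
            g.attrs.update(dict(pixel_mm=truth.pixel_mm,
                                frame_ms=truth.frame_ms,
                                subject=truth.subject_id,
                                slice=truth.slice_id))
        if manifest is not None:
            f.attrs["manifest_json"] = manifest.to_json(orient="records")


def load_pairs_h5(path) -> List[Tuple[CineVolume, CineVolume]]:
    pairs = []
    with h5py.File(path, "r") as f:
        for key in sorted(k for k in f.keys() if k.startswith("pair")):
            g = f[key]
            kw = dict(pixel_mm=float(g.attrs["pixel_mm"]),
                      frame_ms=float(g.attrs["frame_ms"]),
                      subject_id=str(g.attrs["subject"]),
                      slice_id=str(g.attrs["slice"]))
            pairs.append((CineVolume(g["truth"][()], **kw),
                          CineVolume(g["aliased"][()], **kw)))
    return pairs


def load_dicom_series(directory, rr_ms: Optional[float] = None) -> CineVolume:
    """Read a single-slice magnitude cine from a DICOM series directory.

    Files are ordered by InstanceNumber; pixel spacing comes from the
    header, frame spacing from the R-R interval divided by the frame
    count when ``rr_ms`` is given (else from frame-time tags when
    present).
    """
    import pydicom

    files = sorted(Path(directory).glob("*.dcm")) or \
        sorted(p for p in Path(directory).iterdir() if p.is_file())
    if not files:
        raise FileNotFoundError(f"no DICOM files under {directory}")
    slices = sorted((pydicom.dcmread(str(p)) for p in files),
                    key=lambda d: int(getattr(d, "InstanceNumber", 0)))
    frames = np.stack([s.pixel_array.astype(float) for s in slices])
    px = float(slices[0].PixelSpacing[0]) if "PixelSpacing" in slices[0] \
        else 1.0
    if rr_ms is not None:
        frame_ms = rr_ms / len(slices)
    else:
        frame_ms = float(getattr(slices[0], "FrameTime", 0.0))
    return CineVolume(np.clip(frames, 0, None), pixel_mm=px,
                      frame_ms=frame_ms, rr_ms=rr_ms)
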