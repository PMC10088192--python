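"""Image containers and NIfTI-1 round-trip IO.

Volumes are stored as (x, y, slice[, frame]) arrays with voxel sizes in
mm. Per-frame acquisition metadata travels in plain-text sidecars: a
one-column TR table for the saturation-recovery series, and FSL-style
bval/bvec whitespace tables for the DWI series.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np


class VolumeError(ValueError):
    pass


@dataclass
class ImageVolume:
    """A 3-D or 4-D voxel array plus geometry and frame metadata.

    ``frame_meta`` holds either ``{"tr_ms": (n,) array}`` or
    ``{"bvals": (n,), "bvecs": (n, 3)}`` for 4-D series.
    """

    data: np.ndarray
    voxel_size_mm: tuple[float, float, float]
    frame_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim not in (3, 4):
            raise VolumeError(f"expected 3-D or 4-D array, got {self.data.ndim}-D")
        if self.data.ndim == 4:
            n = self.data.shape[3]
            if "tr_ms" in self.frame_meta and len(self.frame_meta["tr_ms"]) != n:
                raise VolumeError(
                    f"series has {n} frames but TR sidecar has "
                    f"{len(self.frame_meta['tr_ms'])} entries"
                )
            if "bvals" in self.frame_meta and len(self.frame_meta["bvals"]) != n:
                raise VolumeError(
                    f"series has {n} frames but bval sidecar has "
                    f"{len(self.frame_meta['bvals'])} entries"
                )

    @property
    def n_frames(self) -> int:
        return 1 if self.data.ndim == 3 else self.data.shape[3]

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    def affine(self) -> np.ndarray:
        # RAS-oriented diagonal affine; slice axis is the third dimension.
        return np.diag([*self.voxel_size_mm, 1.0])


def write_volume(volume: ImageVolume, path: str | Path) -> list[Path]:
    """Write NIfTI-1 plus any metadata sidecars; returns paths written."""
    path = Path(path)
    img = nib.Nifti1Image(volume.data, volume.affine())
    zooms = list(volume.voxel_size_mm) + ([1.0] if volume.data.ndim == 4 else [])
    img.header.set_zooms(zooms)
    nib.save(img, path)
    written = [path]
    stem = path.name.removesuffix(".gz").removesuffix(".nii")
    base = path.parent / stem
    if "tr_ms" in volume.frame_meta:
        p = base.with_suffix(".trs")
        np.savetxt(p, np.asarray(volume.frame_meta["tr_ms"], float), fmt="%.6g")
        written.append(p)
    if "bvals" in volume.frame_meta:
        pb = base.with_suffix(".bval")
        pv = base.with_suffix(".bvec")
        np.savetxt(pb, np.asarray(volume.frame_meta["bvals"], float)[None, :], fmt="%.6g")
        # FSL convention: 3 rows (x, y, z), one column per frame
        np.savetxt(pv, np.asarray(volume.frame_meta["bvecs"], float).T, fmt="%.10g")
        written.extend([pb, pv])
    return written


def read_volume(path: str | Path) -> ImageVolume:
    """Read NIfTI-1 and any sidecars written by :func:`write_volume`."""
    path = Path(path)
    try:
        img = nib.load(path)
    except Exception as exc:  # pragma: no cover - nibabel error text varies
        raise VolumeError(f"cannot read NIfTI file {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj, dtype=float)
    if data.ndim not in (3, 4):
        raise VolumeError(f"{path}: expected 3-D or 4-D image, got {data.ndim}-D")
    voxel_size = tuple(float(z) for z in img.header.get_zooms()[:3])
    meta: dict = {}
    stem = path.name.removesuffix(".gz").removesuffix(".nii")
    base = path.parent / stem
    trs_path = base.with_suffix(".trs")
    if trs_path.exists():
        meta["tr_ms"] = np.atleast_1d(np.loadtxt(trs_path))
    bval_path = base.with_suffix(".bval")
    if bval_path.exists():
        meta["bvals"] = np.atleast_1d(np.loadtxt(bval_path))
        bvec_path = base.with_suffix(".bvec")
        if bvec_path.exists():
            meta["bvecs"] = np.loadtxt(bvec_path).T
    return ImageVolume(data, voxel_size, meta)
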