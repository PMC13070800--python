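"""3D volumes and binary masks with anisotropic voxel spacing.

The package-wide axis convention is ``data[x, y, z]``: array axes 0 and 1 are
the in-plane (axial) axes carrying spacing ``(dx, dy)``, and axis 2 is the
slice (z) axis.  All RECIST diameter geometry is restricted to x-y planes on
fixed z, so the slice axis must never be permuted.  Coordinates are
voxel-center based and 0-indexed: ``physical = origin + index * spacing``.

NIfTI-1 (``.nii`` / ``.nii.gz``) is the single on-disk format; masks are
stored as unsigned 8-bit.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Optional, Tuple

import nibabel as nib
import numpy as np

__all__ = [
    "FormatError",
    "Volume",
    "Mask",
    "PatientCase",
    "read_volume",
    "read_mask",
    "write_volume",
    "binarize",
]


class FormatError(ValueError):
    """Raised when a file or array violates the volume/mask contract."""


def _check_spacing(spacing: Tuple[float, float, float]) -> Tuple[float, float, float]:
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3:
        raise FormatError(f"spacing must have 3 components, got {len(spacing)}")
    if any(s <= 0 for s in spacing):
        raise FormatError(f"spacing components must be positive, got {spacing}")
    return spacing


@dataclass
class Volume:
    """A 3D scalar image with voxel spacing (mm) and origin (mm).

    ``data[x, y, z]``; z (axis 2) is the axial slice axis.
    """

    data: np.ndarray
    spacing: Tuple[float, float, float] = (0.7, 0.7, 3.0)
    origin: Tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise FormatError(
                f"volume data must have exactly 3 axes, got ndim={self.data.ndim}"
            )
        self.spacing = _check_spacing(self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def voxel_volume_mm3(self) -> float:
        dx, dy, dz = self.spacing
        return dx * dy * dz


@dataclass
class Mask(Volume):
    """A binary 3D mask sharing the :class:`Volume` geometry; values in {0, 1}."""

    def __post_init__(self) -> None:
        super().__post_init__()
        vals = np.unique(self.data)
        if not np.isin(vals, (0, 1)).all():
            raise FormatError(f"mask values must be in {{0,1}}, found {vals[:10]}")
        self.data = self.data.astype(np.uint8)

    def voxel_count(self) -> int:
        return int(self.data.sum())


@dataclass
class PatientCase:
    """One patient's pre/post imaging: {CT_pre, Tumor_pre, CT_post, Tumor_post}.

    ``tumor_post`` is optional at inference time (it is the quantity the
    personalized model predicts).
    """

    case_id: str
    ct_pre: Volume
    tumor_pre: Mask
    ct_post: Volume
    tumor_post: Optional[Mask] = None

    def __post_init__(self) -> None:
        if self.ct_pre.shape != self.tumor_pre.shape:
            raise FormatError(
                f"case {self.case_id}: ct_pre shape {self.ct_pre.shape} != "
                f"tumor_pre shape {self.tumor_pre.shape}"
            )
        if self.tumor_post is not None and self.ct_post.shape != self.tumor_post.shape:
            raise FormatError(
                f"case {self.case_id}: ct_post shape {self.ct_post.shape} != "
                f"tumor_post shape {self.tumor_post.shape}"
            )


def read_volume(path: os.PathLike | str) -> Volume:
    """Read a NIfTI-1 file into a :class:`Volume`.

    Spacing is taken from the header zooms and the origin from the affine
    translation.  Only 3D single-channel images are accepted.
    """
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several distinct types
        raise FormatError(f"cannot read NIfTI file {path!r}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise FormatError(f"{path!r}: expected a 3D image, got ndim={data.ndim}")
    zooms = img.header.get_zooms()[:3]
    if any(z <= 0 for z in zooms):
        raise FormatError(f"{path!r}: non-positive header spacing {tuple(zooms)}")
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return Volume(data=np.asarray(data), spacing=tuple(float(z) for z in zooms), origin=origin)


def read_mask(path: os.PathLike | str) -> Mask:
    """Read a NIfTI-1 file into a :class:`Mask` (values must be {0,1})."""
    v = read_volume(path)
    return Mask(data=v.data, spacing=v.spacing, origin=v.origin)


def write_volume(v: Volume, path: os.PathLike | str) -> None:
    """Write a :class:`Volume` or :class:`Mask` as NIfTI-1.

    Masks are written as unsigned 8-bit, scalar volumes as their own dtype
    (float data as float32 is NOT forced; the array dtype round-trips).
    """
    parent = os.path.dirname(os.path.abspath(str(path)))
    if not os.path.isdir(parent):
        raise FileNotFoundError(f"directory does not exist: {parent!r}")
    dx, dy, dz = v.spacing
    affine = np.diag([dx, dy, dz, 1.0])
    affine[:3, 3] = v.origin
    data = v.data
    if isinstance(v, Mask):
        data = data.astype(np.uint8)
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms((dx, dy, dz))
    try:
        nib.save(img, str(path))
    except Exception as exc:
        raise IOError(f"failed to write {path!r}: {exc}") from exc


def binarize(prob: Volume, threshold: float = 0.5) -> Mask:
    """Threshold a class-probability volume into a binary mask.

    A voxel is foreground where ``prob >= threshold`` (inclusive, so the
    default 0.5 matches two-class argmax with ties going to foreground).
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must be in (0,1), got {threshold}")
    p = np.asarray(prob.data, dtype=float)
    if p.min() < 0.0 or p.max() > 1.0:
        raise ValueError(
            f"probability values must lie in [0,1]; found range "
            f"[{p.min():.4g}, {p.max():.4g}]"
        )
    return Mask(
        data=(p >= threshold).astype(np.uint8),
        spacing=prob.spacing,
        origin=prob.origin,
    )
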