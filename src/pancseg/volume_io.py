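"""Volume containers, NIfTI/npz I/O and intensity/geometry preprocessing.

The package works on 3D grayscale volumes (CT-like) with binary ground-truth
masks.  Array order is ``(width, height, depth)`` with depth the axial
stacking direction; indices are 0-based and intervals half-open throughout
the repository.

Preprocessing follows the standard CT recipe for abdominal soft tissue:
clip Hounsfield units to a diagnostic window, rescale affinely to [0, 255],
and resize slices to the network input size.  Rescaled intensities stay
floating point — no integer quantisation is applied.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Optional, Tuple

import nibabel as nib
import numpy as np
from skimage.transform import resize as _sk_resize

__all__ = [
    "Volume",
    "PreprocessSpec",
    "read_volume",
    "write_volume",
    "window_and_rescale",
    "resize_slice",
]


@dataclass
class Volume:
    """A 3D scalar array with optional voxel spacing.

    Parameters
    ----------
    data:
        Array of shape ``(w, h, depth)``.
    spacing:
        Physical voxel size per axis in mm, or None when unknown.
    is_mask:
        True for binary segmentation masks; mask values must be in {0, 1}.
    """

    data: np.ndarray
    spacing: Optional[Tuple[float, float, float]] = None
    is_mask: bool = False

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume data must be 3D, got ndim={self.data.ndim}")
        if any(s < 1 for s in self.data.shape):
            raise ValueError(f"all dims must be >= 1, got shape {self.data.shape}")
        if self.spacing is not None:
            self.spacing = tuple(float(s) for s in self.spacing)
            if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
                raise ValueError(f"spacing must be 3 positive values, got {self.spacing}")
        if self.is_mask:
            vals = np.unique(self.data)
            if not np.isin(vals, (0, 1)).all():
                raise ValueError("mask volume must contain only {0, 1}")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return tuple(self.data.shape)


@dataclass
class PreprocessSpec:
    """Intensity window and in-plane target size for slice preprocessing."""

    window_lo: float = -100.0
    window_hi: float = 240.0
    out_lo: float = 0.0
    out_hi: float = 255.0
    target_size: Tuple[int, int] = (224, 224)

    def __post_init__(self) -> None:
        if not self.window_lo < self.window_hi:
            raise ValueError("window_lo must be < window_hi")
        if not self.out_lo < self.out_hi:
            raise ValueError("out_lo must be < out_hi")
        if any(t < 8 for t in self.target_size):
            raise ValueError("target sizes must be >= 8")


def _is_mask_path(path: str) -> bool:
    base = os.path.basename(path).lower()
    return "mask" in base or "label" in base or "seg" in base


def read_volume(path: str, is_mask: Optional[bool] = None) -> Volume:
    """Read a volume from NIfTI (.nii/.nii.gz) or .npz.

    Mask detection: explicit ``is_mask``, a ``mask``/``label``/``seg``
    filename token, or an ``is_mask`` flag inside the npz.  Mask voxel
    values are coerced to {0, 1} via strict ``> 0``.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if path.endswith(".npz"):
        with np.load(path) as f:
            data = f["data"]
            spacing = tuple(f["spacing"]) if "spacing" in f else None
            stored_mask = bool(f["is_mask"]) if "is_mask" in f else None
    else:
        img = nib.load(path)
        data = np.asanyarray(img.dataobj)
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        stored_mask = None
    if data.ndim != 3:
        raise ValueError(f"non-3D payload in {path}: ndim={data.ndim}")
    if is_mask is None:
        is_mask = stored_mask if stored_mask is not None else _is_mask_path(path)
    if is_mask:
        data = (data > 0).astype(np.uint8)
    return Volume(data=data, spacing=spacing, is_mask=bool(is_mask))


def write_volume(v: Volume, path: str) -> None:
    """Write a volume to NIfTI or .npz; masks are stored as integers."""
    parent = os.path.dirname(os.path.abspath(path))
    if not os.path.isdir(parent):
        raise FileNotFoundError(f"parent directory does not exist: {parent}")
    data = v.data.astype(np.uint8) if v.is_mask else v.data
    if path.endswith(".npz"):
        payload = {"data": data, "is_mask": np.asarray(v.is_mask)}
        if v.spacing is not None:
            payload["spacing"] = np.asarray(v.spacing, dtype=float)
        np.savez_compressed(path, **payload)
        return
    affine = np.eye(4)
    if v.spacing is not None:
        affine[0, 0], affine[1, 1], affine[2, 2] = v.spacing
    nib.save(nib.Nifti1Image(data, affine), path)


def window_and_rescale(v: Volume, spec: PreprocessSpec = PreprocessSpec()) -> Volume:
    """Clip intensities to [window_lo, window_hi] and map affinely to
    [out_lo, out_hi].

    With the defaults this is the CT windowing step: clip to [-100, 240] HU
    then rescale to [0, 255].  Idempotent once the spec maps onto itself and
    monotone non-decreasing in the input intensity.
    """
    if v.is_mask:
        raise ValueError("window_and_rescale must not be applied to a mask volume")
    x = np.clip(np.asarray(v.data, dtype=np.float64), spec.window_lo, spec.window_hi)
    scale = (spec.out_hi - spec.out_lo) / (spec.window_hi - spec.window_lo)
    out = (x - spec.window_lo) * scale + spec.out_lo
    return Volume(data=out, spacing=v.spacing, is_mask=False)


def resize_slice(s: np.ndarray, target: Tuple[int, int], is_mask: bool = False) -> np.ndarray:
    """Resize one 2D slice to ``target``.

    Images use bilinear interpolation (with anti-aliasing when shrinking);
    masks use nearest-neighbour so the output stays binary.
    """
    s = np.asarray(s)
    if s.ndim != 2:
        raise ValueError("resize_slice expects a 2D array")
    if any(t < 1 for t in target):
        raise ValueError(f"degenerate target size {target}")
    if tuple(s.shape) == tuple(target):
        return s.copy()
    if is_mask:
        out = _sk_resize(s, target, order=0, preserve_range=True, anti_aliasing=False)
        return out.astype(s.dtype)
    shrinking = target[0] < s.shape[0] or target[1] < s.shape[1]
    out = _sk_resize(
        s.astype(np.float64), target, order=1, preserve_range=True,
        anti_aliasing=shrinking,
    )
    return out
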