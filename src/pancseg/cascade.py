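"""Coarse-to-fine orchestration: per-view prediction, three-view majority
vote, framed cropping, fine-stage prediction and stitch-back.

The coarse stage localises the organ on the whole volume; a bounding box
around the fused coarse mask — expanded by a safety frame filled with the
original image — defines a crop on which the fine stage re-segments.  Each
stage predicts independently along the sagittal, coronal and axial planes
and the three binary masks are fused per voxel by majority vote
(mean of the three votes >= 0.5, i.e. at least 2 of 3 views).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Tuple

import numpy as np
from scipy import ndimage

from .network import SegModel, predict_slice
from .slicing import AXES, extract_slices, make_input25d, stack_to_volume
from .volume_io import Volume, resize_slice

logger = logging.getLogger(__name__)

__all__ = [
    "ViewPredictions",
    "BoundingBox",
    "EmptyMaskError",
    "predict_volume",
    "fuse_views",
    "coarse_bbox",
    "crop",
    "stitch",
    "largest_component",
    "run_pipeline",
]


class EmptyMaskError(ValueError):
    """Raised when a coarse mask has no foreground; callers should fall
    back to running the fine stage on the whole volume."""


@dataclass
class ViewPredictions:
    """Per-view foreground probability volumes, all at the source shape."""

    sagittal: Volume
    axial: Volume
    coronal: Volume

    def __post_init__(self) -> None:
        shapes = {self.sagittal.shape, self.axial.shape, self.coronal.shape}
        if len(shapes) != 1:
            raise ValueError(f"view predictions disagree on shape: {shapes}")

    def as_dict(self) -> Dict[str, Volume]:
        return {"sagittal": self.sagittal, "axial": self.axial, "coronal": self.coronal}


@dataclass
class BoundingBox:
    """Axis-aligned half-open crop region ``[lo, hi)`` with safety margin."""

    lo: Tuple[int, int, int]
    hi: Tuple[int, int, int]
    margin: int = 0

    def __post_init__(self) -> None:
        self.lo = tuple(int(v) for v in self.lo)
        self.hi = tuple(int(v) for v in self.hi)
        if any(l >= h for l, h in zip(self.lo, self.hi)):
            raise ValueError(f"degenerate box: lo={self.lo}, hi={self.hi}")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return tuple(h - l for l, h in zip(self.lo, self.hi))

    def slices(self) -> Tuple[slice, slice, slice]:
        return tuple(slice(l, h) for l, h in zip(self.lo, self.hi))


def predict_volume(
    model, v: Volume, axis: str, batch_size: int = 8, scale: float = 255.0
) -> Volume:
    """Per-voxel foreground probabilities for one view.

    Slices the volume along ``axis``, builds the 3-channel 2.5D input for
    every slice, resizes it to the model's input size, runs the network,
    resizes each probability map back to the native in-plane resolution
    (bilinear, before any thresholding) and restacks.

    A duck-typed model may implement ``predict_volume(v, axis)`` itself and
    bypass the slicing path entirely (used by oracle baselines in tests).
    """
    if hasattr(model, "predict_volume"):
        return model.predict_volume(v, axis)
    stack = extract_slices(v, axis)
    in_size = model.config.in_size
    native = stack.slices[0].shape
    inputs = np.empty((len(stack), 3, *in_size), dtype=np.float32)
    for i in range(len(stack)):
        tri = make_input25d(stack, i).channels
        for c in range(3):
            inputs[i, c] = resize_slice(tri[c], in_size, is_mask=False)
    probs = np.empty((len(stack), *in_size), dtype=np.float32)
    for lo in range(0, len(stack), batch_size):
        hi = min(lo + batch_size, len(stack))
        probs[lo:hi] = predict_slice(model, inputs[lo:hi], scale=scale)
    maps = [resize_slice(p, native, is_mask=False) for p in probs]
    out = stack_to_volume(maps, axis, v.shape)
    out.data = np.clip(out.data, 0.0, 1.0)
    return out


def fuse_views(preds: ViewPredictions, vote_threshold: float = 0.5) -> Volume:
    """Majority-vote fusion of three per-view predictions into one mask.

    Each view's probability map is binarised at 0.5 first; a voxel is
    foreground iff the mean of the three votes is >= ``vote_threshold``
    (the 0.5 default makes that "at least 2 of 3 views agree").
    """
    views = preds.as_dict()
    votes = [(np.asarray(views[a].data) >= 0.5).astype(np.float64) for a in AXES]
    mean_vote = sum(votes) / 3.0
    return Volume(data=(mean_vote >= vote_threshold).astype(np.uint8), is_mask=True)


def coarse_bbox(mask: Volume, margin: int = 20) -> BoundingBox:
    """Tight foreground bounding box expanded by ``margin`` per side and
    clipped to the volume bounds.

    The margin is the safety frame: the fine stage sees the original image
    intensities in the frame, guarding against coarse under-segmentation.
    """
    fg = np.argwhere(np.asarray(mask.data) > 0)
    if fg.size == 0:
        raise EmptyMaskError(
            "coarse mask is empty; fall back to running the fine stage on the whole volume"
        )
    lo = np.maximum(fg.min(axis=0) - margin, 0)
    hi = np.minimum(fg.max(axis=0) + 1 + margin, mask.shape)
    return BoundingBox(lo=tuple(lo), hi=tuple(hi), margin=margin)


def crop(v: Volume, box: BoundingBox) -> Volume:
    if any(l < 0 or h > s for l, h, s in zip(box.lo, box.hi, v.shape)):
        raise ValueError(f"box {box.lo}..{box.hi} out of bounds for shape {v.shape}")
    return Volume(data=v.data[box.slices()].copy(), spacing=v.spacing, is_mask=v.is_mask)


def stitch(
    fine_mask: Volume, box: BoundingBox, full_shape: Tuple[int, int, int]
) -> Volume:
    """Place a fine-stage mask back into the full-volume frame (zeros
    outside the box)."""
    if tuple(fine_mask.shape) != box.shape:
        raise ValueError(f"fine mask shape {fine_mask.shape} != box shape {box.shape}")
    full = np.zeros(full_shape, dtype=np.uint8)
    full[box.slices()] = fine_mask.data
    return Volume(data=full, is_mask=True)


def largest_component(mask: Volume) -> Volume:
    """The largest 6-connected foreground component of a binary mask.

    Used to localise the crop box: the organ is a single connected
    structure, so scattered false-positive specks in the coarse mask
    should not inflate the fine-stage crop.
    """
    lab, n = ndimage.label(np.asarray(mask.data))
    if n <= 1:
        return mask
    sizes = ndimage.sum_labels(mask.data, lab, index=np.arange(1, n + 1))
    keep = lab == (1 + int(np.argmax(sizes)))
    return Volume(data=keep.astype(np.uint8), is_mask=True)


def _predict_all_views(models: Mapping[str, object], v: Volume) -> ViewPredictions:
    missing = [a for a in AXES if a not in models]
    if missing:
        raise ValueError(f"missing models for views: {missing}")
    return ViewPredictions(
        sagittal=predict_volume(models["sagittal"], v, "sagittal"),
        coronal=predict_volume(models["coronal"], v, "coronal"),
        axial=predict_volume(models["axial"], v, "axial"),
    )


def run_pipeline(
    v: Volume,
    coarse: Mapping[str, object],
    fine: Mapping[str, object],
    margin: int = 20,
    vote_threshold: float = 0.5,
    return_coarse: bool = False,
    localize: str = "largest-component",
):
    """Full coarse-to-fine segmentation of one volume.

    ``coarse`` and ``fine`` map view names to trained models (M_s, M_c,
    M_a per stage).  Steps: coarse per-view prediction -> majority-vote
    fusion -> framed bounding box -> crop the image -> fine per-view
    prediction on the crop -> fusion -> stitch to the full shape.  If the
    coarse mask is empty the fine stage runs on the whole volume (logged).

    ``localize`` selects the voxels that define the crop box:
    "largest-component" (default) keeps only the largest 6-connected
    component of the fused coarse mask, so isolated false-positive specks
    cannot blow the box up to the whole volume; "foreground" uses every
    foreground voxel.  The fused coarse mask itself (returned when
    ``return_coarse`` is set) is never altered.

    Returns the binary mask Volume (and the fused coarse mask when
    ``return_coarse`` is set).
    """
    if localize not in ("largest-component", "foreground"):
        raise ValueError(f"unknown localize mode {localize!r}")
    coarse_preds = _predict_all_views(coarse, v)
    coarse_mask = fuse_views(coarse_preds, vote_threshold)
    loc = largest_component(coarse_mask) if localize == "largest-component" else coarse_mask
    try:
        box = coarse_bbox(loc, margin=margin)
    except EmptyMaskError:
        logger.warning("empty coarse mask; running fine stage on the whole volume")
        box = BoundingBox(lo=(0, 0, 0), hi=v.shape, margin=margin)
    fine_preds = _predict_all_views(fine, crop(v, box))
    fine_mask = fuse_views(fine_preds, vote_threshold)
    full = stitch(fine_mask, box, v.shape)
    if return_coarse:
        return full, coarse_mask
    return full
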