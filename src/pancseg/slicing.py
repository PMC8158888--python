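"""Slice-stack decomposition, 2.5D input construction and reassembly.

A volume ``(w, h, depth)`` is cut into ordered 2D slices along one of the
three anatomical viewing planes.  Axis semantics used throughout:

- ``sagittal``: fix the width index (array axis 0), slices are ``(h, depth)``
- ``coronal``:  fix the height index (array axis 1), slices are ``(w, depth)``
- ``axial``:    fix the depth index (array axis 2), slices are ``(w, h)``

The 2.5D network input for slice i is the 3-channel image
``(S_{i-1}, S_i, S_{i+1})``; at either end of the stack the boundary slice
is replicated three times instead of zero-padding.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np

from .volume_io import Volume

__all__ = [
    "AXES",
    "SliceStack",
    "Input25D",
    "extract_slices",
    "make_input25d",
    "stack_to_volume",
    "filter_training_slices",
]

AXES = ("sagittal", "coronal", "axial")
_AXIS_INDEX = {"sagittal": 0, "coronal": 1, "axial": 2}


@dataclass
class SliceStack:
    """Ordered 2D slices of one volume along one anatomical axis."""

    slices: List[np.ndarray]
    axis: str
    source_shape: Tuple[int, int, int]

    def __post_init__(self) -> None:
        if self.axis not in AXES:
            raise ValueError(f"invalid axis {self.axis!r}; expected one of {AXES}")
        n = self.source_shape[_AXIS_INDEX[self.axis]]
        if len(self.slices) != n:
            raise ValueError(
                f"stack has {len(self.slices)} slices but source extent is {n}"
            )
        shapes = {s.shape for s in self.slices}
        if len(shapes) > 1:
            raise ValueError(f"slices have inconsistent shapes: {shapes}")

    def __len__(self) -> int:
        return len(self.slices)


@dataclass
class Input25D:
    """3-channel 2.5D input: channels (previous, current, next) slice."""

    channels: np.ndarray  # (3, a, b)

    def __post_init__(self) -> None:
        self.channels = np.asarray(self.channels)
        if self.channels.ndim != 3 or self.channels.shape[0] != 3:
            raise ValueError("Input25D requires exactly 3 equally-shaped channels")


def extract_slices(v: Volume, axis: str) -> SliceStack:
    """Cut a volume into its ordered 2D slices along ``axis``."""
    if axis not in AXES:
        raise ValueError(f"invalid axis {axis!r}; expected one of {AXES}")
    ax = _AXIS_INDEX[axis]
    slices = [np.take(v.data, i, axis=ax) for i in range(v.data.shape[ax])]
    return SliceStack(slices=slices, axis=axis, source_shape=v.shape)


def make_input25d(stack: SliceStack, i: int) -> Input25D:
    """Build the 3-channel input for slice ``i``.

    Interior slices get their two neighbours; the first and last slice are
    replicated three times.
    """
    n = len(stack)
    if not 0 <= i < n:
        raise IndexError(f"slice index {i} out of range [0, {n})")
    if i == 0 or i == n - 1:
        tri = (stack.slices[i],) * 3
    else:
        tri = (stack.slices[i - 1], stack.slices[i], stack.slices[i + 1])
    return Input25D(channels=np.stack(tri, axis=0))


def stack_to_volume(
    maps: Sequence[np.ndarray], axis: str, source_shape: Tuple[int, int, int],
    is_mask: bool = False,
) -> Volume:
    """Reassemble per-slice 2D maps into a volume (inverse of extract_slices).

    The maps must already be at the native in-plane resolution of
    ``source_shape``.
    """
    if axis not in AXES:
        raise ValueError(f"invalid axis {axis!r}; expected one of {AXES}")
    ax = _AXIS_INDEX[axis]
    n = source_shape[ax]
    if len(maps) != n:
        raise ValueError(f"got {len(maps)} maps but source extent along {axis} is {n}")
    expected = tuple(s for k, s in enumerate(source_shape) if k != ax)
    for m in maps:
        if tuple(m.shape) != expected:
            raise ValueError(f"map shape {m.shape} != expected in-plane shape {expected}")
    data = np.stack(maps, axis=ax)
    return Volume(data=data, is_mask=is_mask)


def filter_training_slices(
    image_stack: SliceStack, mask_stack: SliceStack, min_pixels: int = 100
) -> List[int]:
    """Indices of slices whose mask foreground count is strictly greater
    than ``min_pixels``.

    Used to restrict coarse-stage training to slices that actually contain
    a substantial piece of the organ.
    """
    if (
        image_stack.axis != mask_stack.axis
        or len(image_stack) != len(mask_stack)
        or image_stack.source_shape != mask_stack.source_shape
    ):
        raise ValueError("image and mask stacks are misaligned")
    return [
        i for i, m in enumerate(mask_stack.slices) if int(np.count_nonzero(m)) > min_pixels
    ]
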