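"""Phantom volume generation.

The generator emulates the statistical setting the segmentation method is
designed for: a small (< 2% of the volume), irregularly shaped,
low-contrast foreground organ with a blurred boundary, surrounded by
distractor blobs whose intensities overlap the organ's, on a smoothly
varying background with additive Gaussian noise.  It exists so that every
stage of the pipeline — slicing, training, cascading, evaluation — is
exercisable end-to-end without any external dataset.

The organ is a randomly posed ellipsoid whose boundary is perturbed by a
low-frequency sinusoidal displacement field (irregular shape, large
case-to-case variation, few parameters).  Intensities are generated
directly on the post-preprocessing [0, 255] scale; ``hu_scale=True``
shifts/scales them into a CT-like window so the windowing step can be
exercised too.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, asdict, field
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy import ndimage

from .metrics import dsc
from .volume_io import Volume, write_volume, read_volume

__all__ = [
    "PhantomSpec",
    "Case",
    "generate_phantom",
    "generate_dataset",
    "load_dataset",
    "global_threshold_dsc",
]


@dataclass
class PhantomSpec:
    """Parameters of one phantom volume.

    shape: voxel grid (w, h, depth).
    organ_fraction_max: hard cap on the organ's volume fraction (the organ
        the method targets occupies well under 2% of a scan).
    organ_contrast: mean intensity offset of the organ over background.
    boundary_blur_sigma: Gaussian blur applied to the organ/distractor
        contrast (vague boundary), in voxels.
    n_distractors: number of confounding blobs with organ-like intensity.
    noise_sigma: additive Gaussian noise level.
    """

    shape: Tuple[int, int, int] = (64, 64, 48)
    organ_fraction_max: float = 0.02
    organ_contrast: float = 60.0
    boundary_blur_sigma: float = 1.0
    n_distractors: int = 10
    noise_sigma: float = 5.0
    seed: int = 0
    background_level: float = 80.0
    hu_scale: bool = False

    def __post_init__(self) -> None:
        self.shape = tuple(int(s) for s in self.shape)
        if not 0 < self.organ_fraction_max < 0.1:
            raise ValueError("organ_fraction_max must be in (0, 0.1)")
        if any(s < 16 for s in self.shape):
            raise ValueError("all shape dims must be >= 16")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


@dataclass
class Case:
    case_id: str
    image: Volume
    mask: Volume
    seed: int
    image_path: Optional[str] = None
    mask_path: Optional[str] = None


def _smooth_field(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    f = ndimage.gaussian_filter(rng.normal(size=shape), sigma)
    s = f.std()
    return f / s if s > 0 else f


def _deformed_ellipsoid(
    rng: np.random.Generator,
    shape: Tuple[int, int, int],
    center: np.ndarray,
    radii: np.ndarray,
    amp: float = 0.25,
) -> np.ndarray:
    """Binary ellipsoid with radius modulated by low-frequency sinusoids."""
    grids = np.meshgrid(*(np.arange(s, dtype=np.float64) for s in shape), indexing="ij")
    q = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center, radii))
    deform = np.zeros(shape)
    for _ in range(3):
        k = rng.uniform(0.5, 2.0, size=3)
        phase = rng.uniform(0, 2 * np.pi)
        arg = sum(2 * np.pi * kk * g / s for kk, g, s in zip(k, grids, shape))
        deform += rng.uniform(0.3, 1.0) * np.sin(arg + phase)
    deform *= amp / 3.0
    return q <= (1.0 + deform) ** 2


def _largest_component(mask: np.ndarray) -> np.ndarray:
    # 6-connectivity (default structure in 3D)
    lab, n = ndimage.label(mask)
    if n <= 1:
        return mask
    sizes = ndimage.sum_labels(mask, lab, index=np.arange(1, n + 1))
    return lab == (1 + int(np.argmax(sizes)))


def generate_phantom(
    spec: PhantomSpec, return_parts: bool = False
) -> "Tuple[Volume, Volume] | Tuple[Volume, Volume, Dict[str, np.ndarray]]":
    """One (image, mask) phantom pair, deterministic given ``spec.seed``.

    The mask is the pre-blur organ voxel set (a single 6-connected
    component) and its volume fraction never exceeds
    ``spec.organ_fraction_max``.
    """
    rng = np.random.default_rng(spec.seed)
    shape = spec.shape
    nvox = int(np.prod(shape))

    # strong low-frequency inhomogeneity: a single global threshold cannot
    # separate the organ from bright background regions
    bg = spec.background_level + 25.0 * _smooth_field(rng, shape, sigma=8.0)

    # organ: pose + radii from a target volume fraction, then deform
    center = np.array(
        [s / 2 + rng.uniform(-0.1, 0.1) * s for s in shape], dtype=np.float64
    )
    frac = rng.uniform(0.45, 0.85) * spec.organ_fraction_max
    aniso = rng.uniform(0.7, 1.4, size=3)
    aniso /= aniso.prod() ** (1 / 3)
    r_iso = (frac * nvox * 3.0 / (4.0 * np.pi)) ** (1 / 3)
    radii = r_iso * aniso
    if any(r >= 0.45 * s for r, s in zip(radii, shape)):
        raise ValueError("infeasible spec: organ cannot fit inside the volume")
    organ = None
    for _ in range(8):
        organ = _largest_component(_deformed_ellipsoid(rng, shape, center, radii))
        if 0 < organ.sum() <= spec.organ_fraction_max * nvox:
            break
        radii = radii * 0.9  # deformation overshot the cap; shrink and retry
    if organ is None or organ.sum() == 0:
        raise ValueError("infeasible spec: organ generation produced an empty mask")

    # distractors: organ-like intensity, placed off the (dilated) organ
    organ_zone = ndimage.binary_dilation(organ, iterations=3)
    distractor_map = np.zeros(shape)
    distractor_mask = np.zeros(shape, dtype=bool)
    grids = np.meshgrid(*(np.arange(s, dtype=np.float64) for s in shape), indexing="ij")
    placed = 0
    attempts = 0
    while placed < spec.n_distractors and attempts < 100 * spec.n_distractors:
        attempts += 1
        c = np.array([rng.uniform(0.1 * s, 0.9 * s) for s in shape])
        r = rng.uniform(2.0, 5.0, size=3)
        blob = sum(((g - cc) / rr) ** 2 for g, cc, rr in zip(grids, c, r)) <= 1.0
        if not blob.any() or (blob & organ_zone).any():
            continue
        # distractor intensities straddle the organ's: only shape/size and
        # spatial context can tell them apart
        amp = np.clip(rng.normal(1.0, 0.2), 0.5, 1.5) * spec.organ_contrast
        distractor_map[blob] += amp
        distractor_mask |= blob
        placed += 1

    contrast = spec.organ_contrast * organ.astype(np.float64) + distractor_map
    image = bg + ndimage.gaussian_filter(contrast, spec.boundary_blur_sigma)
    if spec.noise_sigma > 0:
        image = image + rng.normal(0.0, spec.noise_sigma, size=shape)
    image = np.clip(image, 0.0, 255.0)
    if spec.hu_scale:
        # map [0, 255] back into the CT window [-100, 240]
        image = image / 255.0 * 340.0 - 100.0

    img_vol = Volume(data=image.astype(np.float32), is_mask=False)
    mask_vol = Volume(data=organ.astype(np.uint8), is_mask=True)
    if return_parts:
        return img_vol, mask_vol, {"distractor_mask": distractor_mask, "background": bg}
    return img_vol, mask_vol


def generate_dataset(
    n: int, spec: PhantomSpec = PhantomSpec(), out_dir: Optional[str] = None
) -> List[Case]:
    """Generate ``n`` phantom cases with seeds seed, seed+1, ...

    With ``out_dir`` set, volumes are written as NIfTI and a
    ``manifest.json`` records every file with its seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    cases: List[Case] = []
    for i in range(n):
        cs = PhantomSpec(**{**asdict(spec), "seed": spec.seed + i})
        image, mask = generate_phantom(cs)
        case = Case(case_id=f"case_{i:03d}", image=image, mask=mask, seed=cs.seed)
        cases.append(case)
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        manifest = {"spec": asdict(spec), "cases": []}
        for case in cases:
            img_name = f"{case.case_id}_image.nii.gz"
            mask_name = f"{case.case_id}_mask.nii.gz"
            write_volume(case.image, os.path.join(out_dir, img_name))
            write_volume(case.mask, os.path.join(out_dir, mask_name))
            case.image_path = img_name
            case.mask_path = mask_name
            manifest["cases"].append(
                {"id": case.case_id, "image": img_name, "mask": mask_name, "seed": case.seed}
            )
        with open(os.path.join(out_dir, "manifest.json"), "w") as f:
            json.dump(manifest, f, indent=2)
    return cases


def load_dataset(data_dir: str) -> List[Case]:
    """Load a generated dataset back from its manifest."""
    with open(os.path.join(data_dir, "manifest.json")) as f:
        manifest = json.load(f)
    cases = []
    for entry in manifest["cases"]:
        cases.append(
            Case(
                case_id=entry["id"],
                image=read_volume(os.path.join(data_dir, entry["image"]), is_mask=False),
                mask=read_volume(os.path.join(data_dir, entry["mask"]), is_mask=True),
                seed=entry.get("seed", -1),
                image_path=entry["image"],
                mask_path=entry["mask"],
            )
        )
    return cases


def global_threshold_dsc(image: Volume, mask: Volume, n_thresholds: int = 64) -> float:
    """Best DSC a global intensity threshold can reach on one phantom.

    The strongest segmenter with no spatial context; its score separates
    "the task is intensity-trivial" from "spatial context is required".
    """
    data = np.asarray(image.data)
    best = 0.0
    for t in np.linspace(data.min(), data.max(), n_thresholds):
        pred = (data >= t).astype(np.uint8)
        best = max(best, dsc(pred, mask.data))
    return best
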