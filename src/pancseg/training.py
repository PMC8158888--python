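"""Per-view model training and the k-fold cross-validation harness.

The reference regime: each model (per view, per stage) trains with Adam,
batch size 1, minimising the soft Dice loss on 2.5D slice inputs; 10% of
the training slices are held out as a validation set.  Coarse-stage
training uses only slices whose mask has more than ``min_pancreas_pixels``
foreground pixels; the fine stage trains on cropped volumes (ground-truth
box plus safety margin by default) and keeps every slice containing any
foreground.

All randomness (initialisation, slice shuffling, fold assignment) flows
from the single configured seed, so runs are bit-reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from . import autograd as ag
from .autograd import Adam, Tensor
from .cascade import coarse_bbox, crop, run_pipeline
from .metrics import ScoreSummary, dsc, dice_loss, summarize
from .network import ModelConfig, SegModel, build_model
from .slicing import AXES, extract_slices, filter_training_slices, make_input25d
from .synthetic import Case
from .volume_io import Volume, resize_slice

logger = logging.getLogger(__name__)

__all__ = [
    "TrainConfig",
    "train_stage",
    "train_cascade",
    "cross_validate",
    "make_folds",
    "build_slice_dataset",
    "split_validation",
]


@dataclass
class TrainConfig:
    """Training regime; defaults follow the reference recipe (30 epochs,
    Adam, lr 1e-5, batch size 1, 10% slice-level validation split, >100
    foreground pixels required of a coarse training slice)."""

    epochs: int = 30
    optimizer: str = "adam"
    learning_rate: float = 1e-5
    batch_size: int = 1
    val_fraction: float = 0.10
    val_split: str = "slice"  # "slice" (reference regime) or "case"
    min_pancreas_pixels: int = 100
    seed: int = 0
    folds: int = 4

    def __post_init__(self) -> None:
        if not 0 < self.val_fraction < 1:
            raise ValueError("val_fraction must be in (0, 1)")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")
        if self.optimizer != "adam":
            raise ValueError(f"unsupported optimizer {self.optimizer!r}")
        if self.val_split not in ("slice", "case"):
            raise ValueError(f"val_split must be 'slice' or 'case', got {self.val_split!r}")


def build_slice_dataset(
    volumes: Sequence[Tuple[Volume, Volume]],
    axis: str,
    in_size: Tuple[int, int],
    min_pixels: int,
    scale: float = 255.0,
) -> Tuple[np.ndarray, np.ndarray]:
    """Qualifying 2.5D inputs and mask targets, resized to ``in_size``.

    Returns X (M, 3, h, w) scaled to [0, 1] and Y (M, 1, h, w) binary.
    """
    xs: List[np.ndarray] = []
    ys: List[np.ndarray] = []
    for image, mask in volumes:
        istack = extract_slices(image, axis)
        mstack = extract_slices(mask, axis)
        for i in filter_training_slices(istack, mstack, min_pixels):
            tri = make_input25d(istack, i).channels
            x = np.stack([resize_slice(ch, in_size, is_mask=False) for ch in tri])
            y = resize_slice(mstack.slices[i], in_size, is_mask=True)
            xs.append(x.astype(np.float32) / scale)
            ys.append(y[None].astype(np.float32))
    if not xs:
        raise ValueError(f"no qualifying training slices on axis {axis!r}")
    return np.stack(xs), np.stack(ys)


def split_validation(
    n_slices: int, val_fraction: float, rng: np.random.Generator
) -> Tuple[np.ndarray, np.ndarray]:
    """Disjoint (validation, training) slice indices; the validation set
    holds round(val_fraction * n) slices."""
    perm = rng.permutation(n_slices)
    n_val = int(round(val_fraction * n_slices))
    return perm[:n_val], perm[n_val:]


def soft_dice_loss(pred: Tensor, target: np.ndarray, eps: float = 1e-6) -> Tensor:
    """Soft Dice loss on an autodiff tensor (training objective)."""
    num = 2.0 * (pred * target).sum() + eps
    den = pred.sum() + float(target.sum()) + eps
    return 1.0 - num / den


def train_stage(
    volumes: Sequence[Tuple[Volume, Volume]],
    axis: str,
    cfg: TrainConfig,
    model_cfg: ModelConfig,
    stage: str = "coarse",
) -> Tuple[SegModel, Dict[str, List[float]]]:
    """Train one per-view model; returns the model and its loss history.

    ``stage="coarse"`` applies the >min_pancreas_pixels slice filter;
    ``stage="fine"`` keeps every slice with any foreground (the caller is
    expected to pass already-cropped volumes for the fine stage).
    """
    if len(volumes) < 2:
        raise ValueError("need at least 2 volumes to train")
    if stage not in ("coarse", "fine"):
        raise ValueError(f"stage must be 'coarse' or 'fine', got {stage!r}")
    min_px = cfg.min_pancreas_pixels if stage == "coarse" else 0
    rng = np.random.default_rng(cfg.seed)
    if cfg.val_split == "case":
        # hold out whole cases: no slice of a validation case is trained on
        order = rng.permutation(len(volumes))
        n_valc = int(round(cfg.val_fraction * len(volumes)))
        train_vols = [volumes[i] for i in order[n_valc:]]
        val_vols = [volumes[i] for i in order[:n_valc]]
        X, Y = build_slice_dataset(train_vols, axis, model_cfg.in_size, min_px)
        train_idx = np.arange(X.shape[0])
        if val_vols:
            Xv, Yv = build_slice_dataset(val_vols, axis, model_cfg.in_size, min_px)
            val_idx = np.arange(X.shape[0], X.shape[0] + Xv.shape[0])
            X, Y = np.concatenate([X, Xv]), np.concatenate([Y, Yv])
        else:
            val_idx = np.arange(0)
        m = X.shape[0]
    else:
        X, Y = build_slice_dataset(volumes, axis, model_cfg.in_size, min_px)
        m = X.shape[0]
        val_idx, train_idx = split_validation(m, cfg.val_fraction, rng)
    if train_idx.size == 0:
        raise ValueError("no training slices left after validation split")

    model = build_model(model_cfg, seed=cfg.seed)
    opt = Adam(model.parameters(), lr=cfg.learning_rate)
    history: Dict[str, List[float]] = {"train_loss": [], "val_loss": []}
    logger.info(
        "train_stage axis=%s stage=%s slices=%d (train=%d val=%d) epochs=%d lr=%g",
        axis, stage, m, train_idx.size, val_idx.size, cfg.epochs, cfg.learning_rate,
    )
    for epoch in range(cfg.epochs):
        order = rng.permutation(train_idx)
        losses = []
        for lo in range(0, order.size, cfg.batch_size):
            idx = order[lo : lo + cfg.batch_size]
            opt.zero_grad()
            pred = model.forward(X[idx])
            loss = soft_dice_loss(pred, Y[idx])
            loss.backward()
            opt.step()
            losses.append(loss.item())
        history["train_loss"].append(float(np.mean(losses)))
        history["val_loss"].append(_eval_loss(model, X, Y, val_idx, cfg.batch_size))
        logger.info(
            "epoch %d/%d train_loss=%.4f val_loss=%.4f",
            epoch + 1, cfg.epochs, history["train_loss"][-1], history["val_loss"][-1],
        )
    return model, history


def _eval_loss(
    model: SegModel, X: np.ndarray, Y: np.ndarray, idx: np.ndarray, batch_size: int
) -> float:
    if idx.size == 0:
        return float("nan")
    losses = []
    with ag.no_grad():
        for lo in range(0, idx.size, batch_size):
            sel = idx[lo : lo + batch_size]
            p = model.forward(X[sel]).data
            losses.append(dice_loss(Y[sel].astype(np.uint8), p))
    return float(np.mean(losses))


def _fine_training_volumes(
    volumes: Sequence[Tuple[Volume, Volume]], margin: int
) -> List[Tuple[Volume, Volume]]:
    """Ground-truth-box crops (plus margin) used to train the fine stage."""
    out = []
    for image, mask in volumes:
        box = coarse_bbox(mask, margin=margin)
        out.append((crop(image, box), crop(mask, box)))
    return out


def train_cascade(
    volumes: Sequence[Tuple[Volume, Volume]],
    cfg: TrainConfig,
    model_cfg: ModelConfig,
    margin: int = 20,
    views: Sequence[str] = AXES,
) -> Tuple[Dict[str, SegModel], Dict[str, SegModel], Dict[str, Dict]]:
    """Train all coarse and fine per-view models for the cascade."""
    coarse: Dict[str, SegModel] = {}
    fine: Dict[str, SegModel] = {}
    histories: Dict[str, Dict] = {}
    fine_vols = _fine_training_volumes(volumes, margin)
    for axis in views:
        coarse[axis], histories[f"coarse_{axis}"] = train_stage(
            volumes, axis, cfg, model_cfg, stage="coarse"
        )
        fine[axis], histories[f"fine_{axis}"] = train_stage(
            fine_vols, axis, cfg, model_cfg, stage="fine"
        )
    return coarse, fine, histories


def make_folds(n_cases: int, folds: int, seed: int) -> List[np.ndarray]:
    """Deterministic fold assignment: a seeded permutation split into
    ``folds`` test sets whose sizes differ by at most one."""
    if folds > n_cases:
        raise ValueError(f"folds={folds} > cases={n_cases}")
    perm = np.random.default_rng(seed).permutation(n_cases)
    return [np.sort(part) for part in np.array_split(perm, folds)]


def cross_validate(
    dataset: Sequence[Case],
    cfg: TrainConfig,
    model_cfg: ModelConfig,
    margin: int = 20,
    vote_threshold: float = 0.5,
) -> Dict:
    """K-fold cross-validation of the full cascade.

    Each case is tested exactly once; fold assignment is deterministic in
    the seed.  Returns per-fold and pooled score summaries plus the raw
    per-case DSCs.
    """
    folds = make_folds(len(dataset), cfg.folds, cfg.seed)
    per_fold: List[ScoreSummary] = []
    case_scores: Dict[str, float] = {}
    for fold_id, test_idx in enumerate(folds):
        test_set = set(int(i) for i in test_idx)
        train_cases = [c for i, c in enumerate(dataset) if i not in test_set]
        volumes = [(c.image, c.mask) for c in train_cases]
        coarse, fine, _ = train_cascade(volumes, cfg, model_cfg, margin=margin)
        scores = []
        for i in sorted(test_set):
            case = dataset[i]
            pred = run_pipeline(
                case.image, coarse, fine, margin=margin, vote_threshold=vote_threshold
            )
            s = dsc(pred.data, case.mask.data)
            case_scores[case.case_id] = s
            scores.append(s)
        per_fold.append(summarize(scores))
        logger.info("fold %d: mean DSC %.4f over %d cases", fold_id, per_fold[-1].mean, len(scores))
    pooled = summarize(list(case_scores.values()))
    return {
        "per_fold": per_fold,
        "pooled": pooled,
        "fold_assignment": [f.tolist() for f in folds],
        "case_scores": case_scores,
    }
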