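"""Dice similarity coefficient, Dice loss, score summaries and the
DSC-distribution histogram.

The headline metric is the volume-level DSC, ``2|A∩B| / (|A|+|B|)``,
computed on the reconstructed 3D masks; slice-level DSCs feed the
distribution histogram only.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, asdict
from typing import List, Sequence, Tuple

import numpy as np

__all__ = [
    "ScoreSummary",
    "DscHistogram",
    "DSC_BIN_EDGES",
    "dsc",
    "dice_loss",
    "summarize",
    "dsc_histogram",
    "write_report",
]

#: Bin edges of the DSC-distribution table: first bin [0, 0.5] closed,
#: later bins half-open-left (lo, hi].
DSC_BIN_EDGES = (0.0, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0)


@dataclass
class ScoreSummary:
    mean: float
    std: float
    max: float
    min: float
    n_cases: int


@dataclass
class DscHistogram:
    bin_edges: Tuple[float, ...]
    fractions: Tuple[float, ...]  # percentages per bin, summing to 100

    def labels(self) -> List[str]:
        e = self.bin_edges
        out = [f"DSC [{e[0]:g}, {e[1]:g}]"]
        out += [f"DSC ({e[k]:g}, {e[k + 1]:g}]" for k in range(1, len(e) - 1)]
        return out


def _check_binary(a: np.ndarray, name: str) -> np.ndarray:
    a = np.asarray(a)
    if not np.isin(a, (0, 1)).all():
        raise ValueError(f"{name} must be binary (values in {{0, 1}})")
    return a


def dsc(a: np.ndarray, b: np.ndarray) -> float:
    """Dice similarity coefficient between two binary masks.

    Symmetric, in [0, 1]; the degenerate both-empty case is defined as 1
    (perfect agreement).
    """
    a = _check_binary(a, "a")
    b = _check_binary(b, "b")
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    na = int(np.count_nonzero(a))
    nb = int(np.count_nonzero(b))
    if na + nb == 0:
        return 1.0
    inter = int(np.count_nonzero(np.logical_and(a, b)))
    return 2.0 * inter / (na + nb)


def dice_loss(y: np.ndarray, y_hat: np.ndarray, eps: float = 1e-6) -> float:
    """Soft Dice loss ``1 - 2 Σ y ŷ / (Σ y + Σ ŷ)`` with additive smoothing.

    ``y`` is a binary target, ``y_hat`` a probability map in [0, 1].  The
    smoothing term ``eps`` on numerator and denominator avoids 0/0 on empty
    targets.  The training loop computes the same expression on autodiff
    tensors; this numpy form is the evaluation-side reference.
    """
    y = _check_binary(y, "y")
    y_hat = np.asarray(y_hat, dtype=np.float64)
    if y.shape != y_hat.shape:
        raise ValueError(f"shape mismatch: {y.shape} vs {y_hat.shape}")
    num = 2.0 * float((y * y_hat).sum()) + eps
    den = float(y.sum()) + float(y_hat.sum()) + eps
    return 1.0 - num / den


def summarize(scores: Sequence[float], ddof: int = 0) -> ScoreSummary:
    """Mean / std / max / min over per-case DSC scores.

    ``ddof=0`` (population std) by default; pass ``ddof=1`` for the sample
    standard deviation.
    """
    if len(scores) == 0:
        raise ValueError("cannot summarize an empty score list")
    arr = np.asarray(scores, dtype=np.float64)
    return ScoreSummary(
        mean=float(arr.mean()),
        std=float(arr.std(ddof=ddof)) if len(arr) > ddof else 0.0,
        max=float(arr.max()),
        min=float(arr.min()),
        n_cases=len(arr),
    )


def dsc_histogram(scores: Sequence[float]) -> DscHistogram:
    """Bin DSC scores into the distribution table structure.

    The first bin is the closed interval [0, 0.5]; subsequent bins are
    half-open-left (0.5, 0.6], (0.6, 0.7], (0.7, 0.8], (0.8, 0.9], (0.9, 1].
    Fractions are percentages and sum to 100.
    """
    arr = np.asarray(scores, dtype=np.float64)
    if arr.size == 0:
        raise ValueError("empty score list")
    if ((arr < 0) | (arr > 1)).any():
        raise ValueError("scores must lie in [0, 1]")
    edges = DSC_BIN_EDGES
    counts = np.zeros(len(edges) - 1, dtype=np.int64)
    for s in arr:
        if s <= edges[1]:
            counts[0] += 1
            continue
        for k in range(1, len(edges) - 1):
            if edges[k] < s <= edges[k + 1]:
                counts[k] += 1
                break
    fractions = tuple(100.0 * c / arr.size for c in counts)
    return DscHistogram(bin_edges=edges, fractions=fractions)


def write_report(
    case_ids: Sequence[str], scores: Sequence[float], csv_path: str, json_path: str
) -> ScoreSummary:
    """Write a per-case CSV and a JSON summary (with histogram) to disk."""
    if len(case_ids) != len(scores):
        raise ValueError("case_ids and scores must align")
    with open(csv_path, "w", newline="") as f:
        w = csv.writer(f)
        w.writerow(["case", "dsc"])
        for cid, s in zip(case_ids, scores):
            w.writerow([cid, f"{s:.6f}"])
    summary = summarize(scores)
    hist = dsc_histogram(scores)
    with open(json_path, "w") as f:
        json.dump(
            {
                "summary": asdict(summary),
                "histogram": {
                    "labels": hist.labels(),
                    "percent": list(hist.fractions),
                },
            },
            f,
            indent=2,
        )
    return summary
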