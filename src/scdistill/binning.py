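"""Discretization of confidence scores in (0, 1) into equal-width class bins.

Predicted structure-confidence scores (pTM, pLDDT) are trained as a
classification problem over ``n_bins`` equal-width bins tiling (0, 1)
(50 by default).  Bins are half-open ``[edge, edge + width)`` with the
final bin closed, which makes discretization total and deterministic;
values exactly at 0 or 1 are nudged into the open interval by one machine
epsilon before binning.
"""

from __future__ import annotations

import dataclasses

import numpy as np

__all__ = ["ScoreBinning", "discretize_score", "bin_center"]


@dataclasses.dataclass(frozen=True)
class ScoreBinning:
    n_bins: int = 50
    lo: float = 0.0
    hi: float = 1.0

    def __post_init__(self) -> None:
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        if not self.hi > self.lo:
            raise ValueError("hi must exceed lo")

    @property
    def width(self) -> float:
        return (self.hi - self.lo) / self.n_bins

    @property
    def centers(self) -> np.ndarray:
        return self.lo + (np.arange(self.n_bins) + 0.5) * self.width


def discretize_score(x, binning: ScoreBinning = ScoreBinning()):
    """Map score(s) in (lo, hi) to class label(s) in ``[0, n_bins)``.

    ``label = floor((x - lo) / width)`` clamped into range; accepts scalars
    or arrays.  Values outside ``[lo, hi]`` raise; exact endpoint values are
    clamped into the open interval first.
    """
    arr = np.asarray(x, dtype=float)
    if np.any(~np.isfinite(arr)) or np.any(arr < binning.lo) or np.any(arr > binning.hi):
        raise ValueError(f"scores must lie in [{binning.lo}, {binning.hi}]")
    eps = np.finfo(float).eps
    arr = np.clip(arr, binning.lo + eps, binning.hi - eps)
    labels = np.floor((arr - binning.lo) / binning.width).astype(int)
    labels = np.clip(labels, 0, binning.n_bins - 1)
    return labels if labels.ndim else int(labels)


def bin_center(label, binning: ScoreBinning = ScoreBinning()):
    """Representative score of a class label: the bin midpoint."""
    arr = np.asarray(label, dtype=int)
    if np.any(arr < 0) or np.any(arr >= binning.n_bins):
        raise ValueError(f"labels must lie in [0, {binning.n_bins})")
    centers = binning.lo + (arr + 0.5) * binning.width
    return centers if centers.ndim else float(centers)
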