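"""Sequence- and structure-level evaluation of designed sequences.

Recovery (0-100) is the percentage of positions at which a designed
sequence matches the ground truth; diversity (0-100) is the complement of
the mean pairwise recovery within a set of designs for the same backbone;
perplexity is the exponentiated mean negative log-likelihood of the true
residues.  Per-class breakdowns partition residues into core / surface /
intermediate by C-alpha neighbor density.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
import warnings
from typing import Dict, List, Optional, Sequence

import numpy as np

from .metrics import neighbor_classes
from .structure import BackboneStructure

__all__ = ["recovery", "diversity", "perplexity", "per_class_report",
           "DesignEvalReport", "percent_gain"]


def recovery(predicted: str, truth: str) -> float:
    """Percentage of exactly matching positions between two equal-length sequences."""
    if len(predicted) != len(truth):
        raise ValueError(f"length mismatch: {len(predicted)} vs {len(truth)}")
    if len(predicted) == 0:
        raise ValueError("sequences must be non-empty")
    matches = sum(a == b for a, b in zip(predicted, truth))
    return 100.0 * matches / len(truth)


def diversity(samples: Sequence[str]) -> float:
    """100 minus the mean pairwise recovery over a set of equal-length designs."""
    if len(samples) < 2:
        raise ValueError("diversity requires at least 2 samples")
    pair_rec = [recovery(a, b) for a, b in itertools.combinations(samples, 2)]
    return 100.0 - float(np.mean(pair_rec))


def perplexity(truth_probs: Sequence[float]) -> float:
    """exp(mean(-ln p)) over per-position probabilities of the true residues.

    Probabilities of exactly zero are clamped to 1e-12 with a warning.
    """
    p = np.asarray(truth_probs, float)
    if p.size == 0:
        raise ValueError("truth_probs must be non-empty")
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("probabilities must lie in [0, 1]")
    if np.any(p == 0):
        warnings.warn("zero probabilities clamped to 1e-12 in perplexity")
        p = np.clip(p, 1e-12, 1.0)
    return float(np.exp(-np.mean(np.log(p))))


@dataclasses.dataclass
class DesignEvalReport:
    """Headline design metrics plus core/surface/intermediate breakdowns."""

    recovery: float
    diversity: float
    perplexity: Optional[float] = None
    sc_mean: Optional[float] = None
    tm_mean: Optional[float] = None
    per_class: Optional[Dict[str, Dict[str, float]]] = None

    def __post_init__(self) -> None:
        for v, name in ((self.recovery, "recovery"), (self.diversity, "diversity")):
            if not (0.0 <= v <= 100.0):
                raise ValueError(f"{name} must lie in [0, 100], got {v}")
        if self.perplexity is not None and self.perplexity < 1.0 - 1e-9:
            raise ValueError("perplexity must be >= 1")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)

    def to_tsv(self) -> str:
        lines = ["metric\tclass\tvalue"]
        for name in ("recovery", "diversity", "perplexity", "sc_mean", "tm_mean"):
            v = getattr(self, name)
            if v is not None:
                lines.append(f"{name}\tall\t{v:.4f}")
        for cls, vals in (self.per_class or {}).items():
            for name, v in vals.items():
                if v is not None:
                    lines.append(f"{name}\t{cls}\t{v:.4f}")
        return "\n".join(lines) + "\n"


def _masked_recovery(a: str, b: str, positions: np.ndarray) -> float:
    matches = sum(a[i] == b[i] for i in positions)
    return 100.0 * matches / len(positions)


def per_class_report(
    samples: Sequence[str],
    truth: str,
    structure: BackboneStructure,
) -> DesignEvalReport:
    """Recovery/diversity per neighbor-density class for one backbone.

    Residues are classified core (>= 24 C-alpha neighbors within 10 A),
    surface (<= 16) or intermediate; recovery and diversity are then
    computed restricted to each class's positions, alongside the global
    ("all") values.  Per-class recoveries, weighted by class sizes, average
    exactly to the global recovery.
    """
    if len(truth) != len(structure):
        raise ValueError("structure length must equal sequence length")
    for s in samples:
        if len(s) != len(truth):
            raise ValueError("all samples must match the truth length")
    labels = np.array(neighbor_classes(structure))
    per_class: Dict[str, Dict[str, float]] = {}
    global_rec = float(np.mean([recovery(s, truth) for s in samples]))
    global_div = diversity(samples) if len(samples) >= 2 else 0.0
    for cls in ("core", "surface", "intermediate", "all"):
        pos = np.flatnonzero(labels == cls) if cls != "all" \
            else np.arange(len(truth))
        if pos.size == 0:
            per_class[cls] = {"n_positions": 0, "recovery": None, "diversity": None}
            continue
        rec = float(np.mean([_masked_recovery(s, truth, pos) for s in samples]))
        if len(samples) >= 2:
            div = 100.0 - float(np.mean([
                _masked_recovery(a, b, pos)
                for a, b in itertools.combinations(samples, 2)
            ]))
        else:
            div = 0.0
        per_class[cls] = {"n_positions": int(pos.size),
                          "recovery": rec, "diversity": div}
    return DesignEvalReport(recovery=global_rec, diversity=global_div,
                            per_class=per_class)


def percent_gain(value: float, baseline: float) -> float:
    """Relative gain over a baseline, in percent: 100 * (value - baseline) / baseline."""
    if baseline == 0:
        raise ValueError("baseline must be non-zero")
    return 100.0 * (value - baseline) / baseline
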