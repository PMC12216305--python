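"""Desk-scale synthetic fixtures: backbones, scored-sequence oracles and a
toy structure-conditioned design task.

Everything an experiment needs can be generated here deterministically
from a seed: C-alpha backbones (ideal helix, extended strand, self-avoiding
random coil), graded structure pairs via Gaussian coordinate perturbation,
a sequence -> score oracle with a planted signal (logistic of windowed
composition) standing in for folding-model confidence labels, and a
structure -> sequence design task with a planted, noise-corrupted
residue-class rule.  The oracle and the task rule are *independent*
constructions, so structure-consistency regularization of a designer pulls
toward sequences the oracle favors, not toward the task's ground truth.
"""

from __future__ import annotations

import dataclasses
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial.distance import cdist

from .data import AA_ALPHABET, ScoredSequence
from .structure import BackboneStructure

__all__ = [
    "make_backbone",
    "perturb_backbone",
    "SyntheticOracle",
    "make_oracle",
    "ToyDesignTask",
    "make_design_task",
    "backbone_features",
    "FEATURE_DIM",
]

_STEP = 3.8          # consecutive C-alpha distance for coil chains, Angstrom
_CLASH = 3.4         # self-avoidance threshold for non-adjacent residues
_HELIX_RISE = 1.5    # rise per residue of an ideal alpha helix
_HELIX_TURN = np.deg2rad(100.0)   # ~3.6 residues per turn
_HELIX_RADIUS = 2.3


def make_backbone(length: int, kind: str = "random_coil",
                  rng: Optional[np.random.Generator] = None) -> BackboneStructure:
    """Generate a toy C-alpha backbone of the given kind.

    ``helix`` uses ideal alpha-helix geometry (1.5 A rise, ~3.6
    residues/turn); ``extended`` spaces residues ~3.5 A along an axis with
    a small alternating zigzag (keeps the chain non-collinear);
    ``random_coil`` is a self-avoiding random walk with 3.8 A steps.
    Consecutive C-alpha distances always fall inside [2.9, 4.1] A.
    """
    if length < 2:
        raise ValueError("length must be >= 2")
    rng = np.random.default_rng() if rng is None else rng
    if kind == "helix":
        i = np.arange(length)
        coords = np.column_stack([
            _HELIX_RADIUS * np.cos(i * _HELIX_TURN),
            _HELIX_RADIUS * np.sin(i * _HELIX_TURN),
            i * _HELIX_RISE,
        ])
    elif kind == "extended":
        i = np.arange(length)
        coords = np.column_stack([
            i * 3.5,
            0.3 * np.where(i % 2 == 0, 1.0, -1.0),
            np.zeros(length),
        ])
    elif kind == "random_coil":
        coords = _self_avoiding_walk(length, rng)
    else:
        raise ValueError(f"unknown backbone kind {kind!r}")
    return BackboneStructure(ca_coords=coords)


def _self_avoiding_walk(length: int, rng: np.random.Generator,
                        max_restarts: int = 20, max_tries: int = 60) -> np.ndarray:
    for _ in range(max_restarts):
        coords = [np.zeros(3)]
        direction = _random_unit(rng)
        coords.append(coords[0] + _STEP * direction)
        failed = False
        for _ in range(length - 2):
            for _try in range(max_tries):
                # bias the new step towards the previous direction so the
                # chain is locally stiff (protein-like persistence)
                step = 0.8 * direction + _random_unit(rng)
                step /= np.linalg.norm(step)
                cand = coords[-1] + _STEP * step
                prior = np.asarray(coords[:-1])
                if prior.size == 0 or np.min(
                        np.linalg.norm(prior - cand, axis=1)) >= _CLASH:
                    coords.append(cand)
                    direction = step
                    break
            else:
                failed = True
                break
        if not failed:
            return np.asarray(coords)
    raise RuntimeError(
        f"could not place a self-avoiding chain of length {length} "
        f"after {max_restarts} restarts"
    )


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def perturb_backbone(structure: BackboneStructure, magnitude: float,
                     rng: np.random.Generator) -> BackboneStructure:
    """Add isotropic Gaussian displacement of the given scale (A) to each C-alpha.

    Magnitude 0 returns an identical-coordinate copy; increasing magnitudes
    produce structure pairs of decreasing TM/LDDT, which is how metric
    monotonicity is exercised.
    """
    if magnitude < 0:
        raise ValueError("magnitude must be non-negative")
    noise = rng.normal(scale=magnitude, size=structure.ca_coords.shape) \
        if magnitude > 0 else np.zeros_like(structure.ca_coords)
    return BackboneStructure(
        ca_coords=structure.ca_coords + noise,
        sequence=structure.sequence,
    )


# ---------------------------------------------------------------------------
# sequence -> score oracle

@dataclasses.dataclass
class SyntheticOracle:
    """Deterministic sequence -> confidence-score oracle with a planted signal.

    Per-residue score = sigmoid(gain * mean(coef[aa] over a +-window) + bias)
    with fixed per-amino-acid coefficients drawn once from the seed; the
    scalar score is the mean of the per-residue track (the same way mean
    per-residue confidence summarizes a track).  Scores are strictly inside
    (0, 1) and local: editing one residue can only move scores within the
    feature window.
    """

    coefficients: np.ndarray
    window: int = 4
    gain: float = 5.0
    bias: float = 0.0
    seed: int = 0

    @property
    def description(self) -> dict:
        return {
            "signal": "sigmoid of windowed amino-acid composition",
            "window_halfwidth": self.window,
            "gain": self.gain,
            "bias": self.bias,
            "seed": self.seed,
            "coefficients": {aa: round(float(c), 6)
                             for aa, c in zip(AA_ALPHABET + "X", self.coefficients)},
        }

    def score_track(self, sequence: str) -> np.ndarray:
        idx = np.array([(AA_ALPHABET + "X").index(c) for c in sequence])
        vals = self.coefficients[idx]
        L = len(vals)
        cs = np.concatenate([[0.0], np.cumsum(vals)])
        hi = np.minimum(np.arange(L) + self.window + 1, L)
        lo = np.maximum(np.arange(L) - self.window, 0)
        local_mean = (cs[hi] - cs[lo]) / (hi - lo)
        track = 1.0 / (1.0 + np.exp(-(self.gain * local_mean + self.bias)))
        return np.clip(track, 1e-6, 1.0 - 1e-6)

    def score(self, sequence: str) -> float:
        return float(self.score_track(sequence).mean())

    __call__ = score


def make_oracle(seed: int = 0, window: int = 4, gain: float = 5.0,
                bias: float = 0.0) -> SyntheticOracle:
    """Draw oracle coefficients from a seed ('X' gets coefficient 0)."""
    rng = np.random.default_rng(seed)
    coefs = rng.normal(0.0, 1.0, size=len(AA_ALPHABET) + 1)
    coefs[-1] = 0.0
    return SyntheticOracle(coefficients=coefs, window=window, gain=gain,
                           bias=bias, seed=seed)


#: Kyte-Doolittle hydropathy values for the 20 standard amino acids.
_KYTE_DOOLITTLE = {
    "A": 1.8, "C": 2.5, "D": -3.5, "E": -3.5, "F": 2.8, "G": -0.4,
    "H": -3.2, "I": 4.5, "K": -3.9, "L": 3.8, "M": 1.9, "N": -3.5,
    "P": -1.6, "Q": -3.5, "R": -4.5, "S": -0.8, "T": -0.7, "V": 4.2,
    "W": -0.9, "Y": -1.3,
}


def hydropathy_oracle(window: int = 4, gain: float = 5.0,
                      bias: float = 0.0) -> SyntheticOracle:
    """The canonical fixed oracle: logistic of windowed hydrophobic fraction.

    Coefficients are the Kyte-Doolittle hydropathy scale normalized to
    [-1, 1], so the per-residue score is a logistic function of the local
    mean hydropathy — a fixed, interpretable planted signal.  Because
    hydropathy preference differs from the design task's planted class
    rule, consistency regularization against this oracle genuinely pulls a
    designer toward sequences *other* than the task's ground truth (were
    the two aligned, the regularizer would be indistinguishable from more
    reconstruction training).
    """
    coefs = np.array([_KYTE_DOOLITTLE[aa] for aa in AA_ALPHABET] + [0.0]) / 4.5
    return SyntheticOracle(coefficients=coefs, window=window, gain=gain,
                           bias=bias, seed=-1)


# ---------------------------------------------------------------------------
# toy structure-conditioned design task

#: Rotation-invariant per-residue backbone features (see backbone_features).
FEATURE_DIM = 8


def backbone_features(structure: BackboneStructure) -> np.ndarray:
    """Rotation/translation-invariant per-residue features, shape (L, 8).

    Neighbor counts at 6/8/10 A (scaled), sequence-separation distances
    |i-2, i+2|, |i-4, i+4| span distances, distances to i-2 and i+2 (0 when
    out of range), and the relative chain position.  Invariance means the
    design task cannot be solved by memorizing absolute coordinates.
    """
    xyz = structure.ca_coords
    L = len(xyz)
    d = cdist(xyz, xyz)
    feats = np.zeros((L, FEATURE_DIM))
    for r_i, radius in enumerate((6.0, 8.0, 10.0)):
        feats[:, r_i] = (np.sum(d <= radius, axis=1) - 1) / 10.0

    def span(i, lo, hi):
        if lo < 0 or hi >= L:
            return 0.0
        return d[lo, hi]

    for i in range(L):
        feats[i, 3] = span(i, i - 2, i + 2) / 10.0
        feats[i, 4] = span(i, i - 4, i + 4) / 10.0
        feats[i, 5] = (d[i, i - 2] if i - 2 >= 0 else 0.0) / 10.0
        feats[i, 6] = (d[i, i + 2] if i + 2 < L else 0.0) / 10.0
        feats[i, 7] = i / max(L - 1, 1)
    return feats


# Planted rule: bucket each residue by (neighbor density, local span
# geometry) into one of 6 classes, each preferring one amino acid.  The
# preferred residues are all polar/charged (hydropathy-negative), like real
# surface and loop positions, so the hydropathy oracle's preference is
# genuinely distinct from the task's ground truth — a prerequisite for the
# consistency-regularization experiment to measure guidance that is not
# confounded with the reconstruction signal.
_RULE_AAS = "NDGESK"  # one preferred residue per planted class


def _residue_classes(structure: BackboneStructure) -> np.ndarray:
    xyz = structure.ca_coords
    L = len(xyz)
    d = cdist(xyz, xyz)
    counts = np.sum(d <= 10.0, axis=1) - 1
    dens = np.digitize(counts, [6, 10])          # 0 sparse / 1 medium / 2 dense
    spans = np.zeros(L)
    for i in range(L):
        lo, hi = max(i - 2, 0), min(i + 2, L - 1)
        spans[i] = d[lo, hi]
    bent = (spans < 9.0).astype(int)             # helix-like vs extended window
    return dens * 2 + bent                       # class id in [0, 6)


@dataclasses.dataclass
class ToyDesignTask:
    """Paired (backbone, sequence) records with a planted recoverable rule.

    ``sequences`` follow the class -> amino-acid rule except at positions
    independently corrupted at rate ``noise`` (replaced by a uniform random
    amino acid).  ``mask_spans`` gives a contiguous masked window per
    record for the infilling variant (reconstructing a hidden span from
    its context, the loop-infilling analogue).
    """

    backbones: List[BackboneStructure]
    sequences: List[str]
    classes: List[np.ndarray]
    features: List[np.ndarray]
    mask_spans: List[Tuple[int, int]]
    noise: float
    seed: int
    rule: str = _RULE_AAS

    def __len__(self) -> int:
        return len(self.backbones)

    def rule_lookup_sequence(self, index: int) -> str:
        """The noise-free rule prediction for one backbone (oracle designer)."""
        return "".join(self.rule[c] for c in self.classes[index])

    @property
    def chance_recovery(self) -> float:
        """Expected recovery (percent) of any fixed prediction at noise 1."""
        return 100.0 / len(AA_ALPHABET)


def make_design_task(
    n: int,
    lengths: Tuple[int, int] = (30, 50),
    noise: float = 0.2,
    rng: Optional[np.random.Generator] = None,
    mask_fraction: float = 0.2,
    kinds: Sequence[str] = ("random_coil", "helix", "extended"),
) -> ToyDesignTask:
    """Generate a toy inverse-folding task with a planted class rule.

    Backbones cycle through ``kinds`` (coil/helix/extended give the rule's
    geometry buckets real variety); each residue's true amino acid is the
    planted rule's choice for its structural class, corrupted independently
    with probability ``noise``.  A contiguous mask span of
    ``mask_fraction`` of the length is recorded per backbone for the
    infilling variant.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not (0.0 <= noise <= 1.0):
        raise ValueError("noise must lie in [0, 1]")
    rng = np.random.default_rng() if rng is None else rng
    seed_echo = int(rng.integers(0, 2 ** 31))  # recorded for the manifest
    backbones, sequences, classes, features, spans = [], [], [], [], []
    for i in range(n):
        L = int(rng.integers(lengths[0], lengths[1] + 1))
        bb = make_backbone(L, kind=kinds[i % len(kinds)], rng=rng)
        cls = _residue_classes(bb)
        seq = [_RULE_AAS[c] for c in cls]
        corrupt = rng.random(L) < noise
        for j in np.flatnonzero(corrupt):
            seq[j] = AA_ALPHABET[rng.integers(0, len(AA_ALPHABET))]
        span_len = max(1, int(round(mask_fraction * L)))
        start = int(rng.integers(0, L - span_len + 1))
        bb = dataclasses.replace(bb, sequence="".join(seq),
                                 residue_ids=bb.residue_ids)
        backbones.append(bb)
        sequences.append("".join(seq))
        classes.append(cls)
        features.append(backbone_features(bb))
        spans.append((start, start + span_len))
    return ToyDesignTask(
        backbones=backbones, sequences=sequences, classes=classes,
        features=features, mask_spans=spans, noise=noise, seed=seed_echo,
    )
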