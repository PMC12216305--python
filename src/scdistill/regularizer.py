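"""Structure-consistency (SC) regularization of sequence-design training.

A frozen, pre-trained distillation model scores candidate sequences with a
structure-confidence value SC in (0, 1); the design objective becomes

    L = L_CE + alpha * L_SC,      L_SC = sum_i (1 - SC(s_hat_i)),

with alpha (default 1) weighting the SC term.  Because the distill model
is differentiable down to its input probabilities, the SC term can pass
gradients into the generator: ``soft`` mode feeds the generator's
per-position probability distributions through probability-weighted token
embeddings; ``hard`` mode embeds discrete sequences (no generator
gradient); ``straight_through`` scores the argmax sequence forward but
propagates the soft gradient backward.
"""

from __future__ import annotations

import dataclasses
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np

from .binning import ScoreBinning
from .data import AA_ALPHABET
from .model import DistillEncoder, TOKEN_ALPHABET, expected_score_grad

__all__ = ["SCLossTerm", "sc_loss", "combined_loss", "score_generated",
           "score_and_input_grad"]


@dataclasses.dataclass(frozen=True)
class SCLossTerm:
    """The components of the regularized objective: total = ce + alpha * sc."""

    ce_loss: float
    sc_loss: float
    alpha: float
    total: float

    def __post_init__(self) -> None:
        if self.ce_loss < 0 or self.sc_loss < 0 or self.alpha < 0:
            raise ValueError("loss components and alpha must be non-negative")
        if self.total != self.ce_loss + self.alpha * self.sc_loss:
            raise ValueError("total must equal ce + alpha * sc exactly")


def sc_loss(sc_scores: Sequence[float]) -> float:
    """``sum_i (1 - SC_i)`` over per-sample structure-consistency scores."""
    scores = np.asarray(sc_scores, float)
    if scores.size == 0:
        raise ValueError("sc_scores must be non-empty")
    if np.any(scores <= 0.0) or np.any(scores >= 1.0):
        raise ValueError("SC scores must lie strictly inside (0, 1)")
    return float(np.sum(1.0 - scores))


def combined_loss(ce: float, sc_scores: Sequence[float], alpha: float = 1.0) -> SCLossTerm:
    """Assemble the regularized objective; ``alpha = 0`` returns total == ce."""
    if ce < 0:
        raise ValueError("ce must be non-negative")
    if alpha < 0:
        raise ValueError("alpha must be non-negative")
    sc = sc_loss(sc_scores)
    return SCLossTerm(ce_loss=float(ce), sc_loss=sc, alpha=float(alpha),
                      total=float(ce) + float(alpha) * sc)


def _soft_input(probs: np.ndarray) -> np.ndarray:
    """Lift (L, 20) amino-acid distributions to the (L, 21) model alphabet."""
    probs = np.asarray(probs, float)
    if probs.ndim != 2 or probs.shape[1] not in (len(AA_ALPHABET), len(TOKEN_ALPHABET)):
        raise ValueError("soft samples must be (L, 20) or (L, 21) probability rows")
    if np.any(probs < -1e-9):
        raise ValueError("probabilities must be non-negative")
    if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("probability rows must sum to 1")
    if probs.shape[1] == len(TOKEN_ALPHABET):
        return probs
    X = np.zeros((probs.shape[0], len(TOKEN_ALPHABET)))
    X[:, :len(AA_ALPHABET)] = probs
    return X


def _score_one(model: DistillEncoder, x, kind: str, binning: ScoreBinning,
               want_grad: bool):
    """SC score of one (soft or hard) sample; optionally its input gradient."""
    seq_logits, per_pos, cache = model.forward(x, want_cache=True)
    if kind == "ptm":
        score, dz = expected_score_grad(seq_logits, binning)
        if not want_grad:
            return score, None
        _, dX = model.backward(cache, dz, None)
    elif kind == "plddt":
        # per-residue expectations averaged to one scalar per sample
        scores, dP = [], np.zeros_like(per_pos)
        for i in range(per_pos.shape[0]):
            s_i, dz_i = expected_score_grad(per_pos[i], binning)
            scores.append(s_i)
            dP[i] = dz_i / per_pos.shape[0]
        score = float(np.mean(scores))
        if not want_grad:
            return score, None
        _, dX = model.backward(cache, None, dP)
    else:
        raise ValueError("kind must be 'ptm' or 'plddt'")
    return score, dX


def score_generated(
    model: DistillEncoder,
    generated: Sequence,
    mode: str = "soft",
    kind: str = "ptm",
    binning: Optional[ScoreBinning] = None,
) -> np.ndarray:
    """Per-sample SC scores for generated sequences or distributions.

    ``generated`` holds either discrete sequences (strings / token index
    arrays; modes ``hard`` and ``straight_through``) or per-position
    probability matrices over the amino-acid alphabet (mode ``soft``).
    ``kind`` selects the scalar head (``ptm``) or the mean of the
    per-residue track (``plddt``).
    """
    if len(generated) == 0:
        raise ValueError("generated batch must be non-empty")
    if mode not in ("soft", "hard", "straight_through"):
        raise ValueError("mode must be 'soft', 'hard' or 'straight_through'")
    binning = binning or ScoreBinning(n_bins=model.n_bins)
    out = []
    for sample in generated:
        if mode == "soft":
            x = _soft_input(sample)
        elif isinstance(sample, str) or np.asarray(sample).ndim == 1:
            x = sample
        else:  # distribution given in a discrete mode: score its argmax sequence
            x = np.argmax(_soft_input(sample), axis=1)
        out.append(_score_one(model, x, kind, binning, False)[0])
    return np.asarray(out)


def score_and_input_grad(
    model: DistillEncoder,
    probs: np.ndarray,
    mode: str = "soft",
    kind: str = "ptm",
    binning: Optional[ScoreBinning] = None,
) -> Tuple[float, np.ndarray]:
    """SC score of one probability sample plus d(score)/d(probabilities).

    ``soft``: score and gradient both use the probability-weighted
    embedding.  ``straight_through``: the score is computed on the argmax
    (hard) sequence while the gradient is the soft-input gradient — the
    straight-through estimator.  The returned gradient is (L, 20), over the
    amino-acid alphabet.
    """
    binning = binning or ScoreBinning(n_bins=model.n_bins)
    X = _soft_input(probs)
    if mode == "soft":
        score, dX = _score_one(model, X, kind, binning, True)
    elif mode == "straight_through":
        score, _ = _score_one(model, np.argmax(X, axis=1), kind, binning, False)
        _, dX = _score_one(model, X, kind, binning, True)
    else:
        raise ValueError("gradient modes are 'soft' and 'straight_through'")
    return score, dX[:, :len(AA_ALPHABET)]
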