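"""Toy structure-conditioned sequence designer with SC-regularized training.

A small per-residue MLP maps rotation-invariant backbone features to a
categorical distribution over the 20 amino acids.  Training minimizes the
reconstruction cross-entropy, optionally augmented with the
structure-consistency loss ``alpha * sum_i (1 - SC(s_hat_i))`` computed by
a *frozen* pre-trained distill model on the designer's output
distributions (soft mode, so the SC gradient reaches the designer).  This
is the desk-scale analogue of regularizing an inverse-folding model.

With ``alpha = 0`` the SC term contributes an exactly-zero gradient, so
the training trajectory is bit-for-bit identical to the unregularized one
under the same seed.
"""

from __future__ import annotations

import dataclasses
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .data import AA_ALPHABET
from .model import DistillEncoder
from .regularizer import SCLossTerm, combined_loss, score_and_input_grad
from .synthetic import FEATURE_DIM, ToyDesignTask
from .train import _Adam

__all__ = ["DesignerConfig", "ResidueDesigner", "train_designer"]

_N_AA = len(AA_ALPHABET)


@dataclasses.dataclass
class DesignerConfig:
    hidden: int = 48
    learning_rate: float = 1e-2
    epochs: int = 15              # reconstruction (CE-only) phase
    sc_epochs: int = 1            # consistency fine-tuning phase (SC active)
    batch_size: int = 16
    seed: int = 0
    alpha: float = 0.0            # SC weight; 1.0 is the standard setting
    sc_mode: str = "soft"         # "soft" | "straight_through"
    sc_kind: str = "ptm"          # which distill head provides SC


def _softmax_rows(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


@dataclasses.dataclass
class ResidueDesigner:
    """Per-residue MLP: backbone features (L, 8) -> amino-acid logits (L, 20)."""

    hidden: int = 48
    params: Optional[dict] = None

    def init_params(self, rng: np.random.Generator) -> None:
        def xavier(n_in, n_out):
            return rng.normal(0.0, np.sqrt(2.0 / (n_in + n_out)), size=(n_in, n_out))

        self.params = {
            "W1": xavier(FEATURE_DIM, self.hidden), "b1": np.zeros(self.hidden),
            "W2": xavier(self.hidden, _N_AA), "b2": np.zeros(_N_AA),
        }

    @property
    def parameter_count(self) -> int:
        return int(sum(p.size for p in self.params.values()))

    def forward(self, features: np.ndarray, want_cache: bool = False):
        P = self.params
        H = np.tanh(features @ P["W1"] + P["b1"])
        logits = H @ P["W2"] + P["b2"]
        if want_cache:
            return logits, {"F": features, "H": H}
        return logits

    def backward(self, cache, d_logits: np.ndarray) -> dict:
        P = self.params
        H, F = cache["H"], cache["F"]
        dH = (d_logits @ P["W2"].T) * (1.0 - H ** 2)
        return {
            "W2": H.T @ d_logits, "b2": d_logits.sum(axis=0),
            "W1": F.T @ dH, "b1": dH.sum(axis=0),
        }

    def probabilities(self, features: np.ndarray) -> np.ndarray:
        return _softmax_rows(self.forward(features))

    def greedy(self, features: np.ndarray) -> str:
        return "".join(AA_ALPHABET[i]
                       for i in np.argmax(self.forward(features), axis=1))

    def sample(self, features: np.ndarray, n_samples: int,
               rng: np.random.Generator, temperature: float = 1.0) -> List[str]:
        logits = self.forward(features) / temperature
        probs = _softmax_rows(logits)
        out = []
        for _ in range(n_samples):
            draws = [rng.choice(_N_AA, p=probs[i]) for i in range(len(probs))]
            out.append("".join(AA_ALPHABET[j] for j in draws))
        return out

    def truth_probabilities(self, features: np.ndarray, truth: str) -> np.ndarray:
        """Per-position probability assigned to the true residues (for perplexity)."""
        probs = self.probabilities(features)
        idx = [AA_ALPHABET.index(c) for c in truth]
        return probs[np.arange(len(truth)), idx]


def _ce_and_grad(logits: np.ndarray, truth: str) -> Tuple[float, np.ndarray]:
    """Mean per-position cross-entropy of the true sequence and d/d logits."""
    probs = _softmax_rows(logits)
    idx = np.array([AA_ALPHABET.index(c) for c in truth])
    L = len(idx)
    pt = np.clip(probs[np.arange(L), idx], 1e-12, 1.0)
    ce = float(-np.mean(np.log(pt)))
    d = probs.copy()
    d[np.arange(L), idx] -= 1.0
    return ce, d / L


def train_designer(
    task: ToyDesignTask,
    config: DesignerConfig,
    distill_model: Optional[DistillEncoder] = None,
    indices: Optional[Sequence[int]] = None,
) -> Tuple[ResidueDesigner, List[SCLossTerm]]:
    """Train a designer on a toy task, optionally SC-regularized.

    Training runs in two phases with the same minibatch schedule: a
    reconstruction phase of ``config.epochs`` CE-only epochs, then a
    consistency fine-tuning phase of ``config.sc_epochs`` epochs during
    which the SC term is active, each phase with a freshly initialized
    optimizer.  Applying the regularizer as a brief fine-tune of the
    converged designer keeps it a perturbative nudge: at this toy scale a
    long jointly-trained SC term can dominate the converged CE equilibrium
    and collapse recovery toward pure high-confidence sequences.

    ``distill_model`` (frozen) provides SC scores of the designer's output
    distributions; it is required when ``config.alpha > 0`` and optional
    otherwise (when given with ``alpha = 0`` the SC term is still computed
    for logging but contributes an exactly-zero gradient, so the trajectory
    is bit-for-bit the unregularized one).  Returns the designer and a
    per-step log of :class:`SCLossTerm` components.
    """
    if config.alpha > 0 and distill_model is None:
        raise ValueError("SC-regularized training (alpha > 0) needs a distill model")
    idx = list(range(len(task))) if indices is None else list(indices)
    if not idx:
        raise ValueError("no training records")
    rng = np.random.default_rng(config.seed)
    designer = ResidueDesigner(hidden=config.hidden)
    designer.init_params(rng)
    log: List[SCLossTerm] = []
    for phase_epochs, sc_active in ((config.epochs, False), (config.sc_epochs, True)):
        if phase_epochs == 0:
            continue
        opt = _Adam(designer.params, lr=config.learning_rate)
        for _epoch in range(phase_epochs):
            order = rng.permutation(len(idx))
            for start in range(0, len(order), config.batch_size):
                batch = [idx[i] for i in order[start:start + config.batch_size]]
                grads = {k: np.zeros_like(v) for k, v in designer.params.items()}
                ce_sum, sc_scores = 0.0, []
                for ti in batch:
                    feats, truth = task.features[ti], task.sequences[ti]
                    logits, cache = designer.forward(feats, want_cache=True)
                    ce, d_logits = _ce_and_grad(logits, truth)
                    ce_sum += ce
                    if sc_active and distill_model is not None:
                        probs = _softmax_rows(logits)
                        sc, d_probs = score_and_input_grad(
                            distill_model, probs, mode=config.sc_mode,
                            kind=config.sc_kind,
                        )
                        sc_scores.append(sc)
                        if config.alpha > 0:
                            # d(1 - SC)/d logits through the softmax Jacobian
                            g = -d_probs
                            inner = np.sum(g * probs, axis=1, keepdims=True)
                            d_logits = d_logits + config.alpha * probs * (g - inner)
                    g = designer.backward(cache, d_logits)
                    for k in grads:
                        grads[k] += g[k] / len(batch)
                opt.step(designer.params, grads)
                if sc_scores:
                    log.append(combined_loss(ce_sum / len(batch),
                                             sc_scores, config.alpha))
                else:
                    log.append(SCLossTerm(
                        ce_loss=ce_sum / len(batch), sc_loss=0.0,
                        alpha=config.alpha, total=ce_sum / len(batch)))
    return designer, log
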