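"""Small sequence -> score-bin encoder with analytic gradients.

The distillation model contract: a sequence model that emits, for a token
sequence, a *sequence-level* logit vector over the score bins (the scalar
pTM-style readout, analogous to a first-token/CLS head) and *per-position*
logit vectors over the same bins (the pLDDT-style track).  The reference
architecture here is a deliberately small CPU-trainable encoder:

    one-hot / probability input  (L, 21)
      -> learned embedding                       (L, d)
      -> concat[embedding, window-mean(+-2), window-mean(+-5)]   (L, 3d)
      -> tanh MLP -> per-position logits         (L, n_bins)
      mean-pooled features -> tanh MLP -> sequence-level logits  (n_bins,)

All forward/backward passes are explicit numpy, which keeps the model
end-to-end differentiable down to its *input probabilities* — the property
the structure-consistency regularizer needs to pass gradients into a
sequence generator.  Any model exposing the same ``forward`` contract can
be substituted.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Dict, Optional, Tuple

import numpy as np

from .binning import ScoreBinning
from .data import AA_ALPHABET

__all__ = [
    "TOKEN_ALPHABET",
    "encode_sequence",
    "one_hot",
    "DistillEncoder",
    "focal_loss",
    "focal_loss_from_logits",
    "expected_score",
    "expected_score_grad",
]

#: Model token alphabet: the 20 amino acids plus unknown 'X'.
TOKEN_ALPHABET = AA_ALPHABET + "X"
_TOKEN_INDEX = {c: i for i, c in enumerate(TOKEN_ALPHABET)}

_PT_EPS = 1e-12  # clamp for log(p_t); documented lower bound on class probability


def encode_sequence(sequence: str) -> np.ndarray:
    """Token indices for a sequence; raises naming the first illegal position."""
    if not sequence:
        raise ValueError("sequence must be non-empty")
    idx = np.empty(len(sequence), dtype=int)
    for i, c in enumerate(sequence):
        j = _TOKEN_INDEX.get(c)
        if j is None:
            raise ValueError(f"illegal character {c!r} at position {i} (1-based {i + 1})")
        idx[i] = j
    return idx


def one_hot(tokens: np.ndarray, n_tokens: int = len(TOKEN_ALPHABET)) -> np.ndarray:
    X = np.zeros((len(tokens), n_tokens))
    X[np.arange(len(tokens)), tokens] = 1.0
    return X


# ---------------------------------------------------------------------------
# losses and readout

def focal_loss(class_probs: np.ndarray, true_label: int, gamma: float = 2.0) -> float:
    """Focal loss ``-(1 - p_t)^gamma * log(p_t)`` on a probability vector.

    ``gamma = 0`` recovers plain cross-entropy; larger gamma down-weights
    well-classified examples, emphasising rare/hard score bins.  ``p_t`` is
    clamped at 1e-12 before the log.
    """
    p = np.asarray(class_probs, float)
    if p.ndim != 1:
        raise ValueError("class_probs must be a vector")
    if not np.isclose(p.sum(), 1.0, atol=1e-6):
        raise ValueError(f"class_probs must sum to 1, got {p.sum():.6f}")
    if not (0 <= true_label < len(p)):
        raise ValueError("true_label out of range")
    if gamma < 0:
        raise ValueError("gamma must be non-negative")
    pt = max(float(p[true_label]), _PT_EPS)
    return float(-((1.0 - pt) ** gamma) * np.log(pt))


def _softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def focal_loss_from_logits(logits: np.ndarray, true_label: int,
                           gamma: float = 2.0) -> Tuple[float, np.ndarray]:
    """Focal loss and its gradient with respect to the logits."""
    p = _softmax(np.asarray(logits, float))
    pt = max(float(p[true_label]), _PT_EPS)
    loss = -((1.0 - pt) ** gamma) * np.log(pt)
    # d loss / d p_t, then chain through softmax: dp_t/dz_j = p_t (delta_tj - p_j)
    if gamma == 0.0:
        dz = p.copy()
        dz[true_label] -= 1.0
    else:
        dl_dpt = gamma * (1.0 - pt) ** (gamma - 1.0) * np.log(pt) \
            - ((1.0 - pt) ** gamma) / pt
        delta = np.zeros_like(p)
        delta[true_label] = 1.0
        dz = dl_dpt * pt * (delta - p)
    return float(loss), dz


def expected_score(logits: np.ndarray, binning: ScoreBinning = ScoreBinning()) -> float:
    """Differentiable scalar readout: softmax-probability-weighted bin centers.

    Smooth in the logits and invariant to adding a constant to all of them;
    bounded strictly inside (lo, hi) because bin centers are interior.
    An argmax-bin-center readout is available for reporting via
    ``binning.centers[np.argmax(logits)]``.
    """
    logits = np.asarray(logits, float)
    if not np.all(np.isfinite(logits)):
        raise ValueError("logits must be finite")
    p = _softmax(logits, axis=-1)
    return p @ binning.centers if logits.ndim > 1 else float(p @ binning.centers)


def expected_score_grad(logits: np.ndarray,
                        binning: ScoreBinning = ScoreBinning()) -> Tuple[float, np.ndarray]:
    """Expected score and its gradient with respect to the logits."""
    logits = np.asarray(logits, float)
    p = _softmax(logits)
    s = float(p @ binning.centers)
    return s, p * (binning.centers - s)


# ---------------------------------------------------------------------------
# encoder

def _window_mean(E: np.ndarray, k: int) -> Tuple[np.ndarray, np.ndarray]:
    L = len(E)
    S = np.vstack([np.zeros((1, E.shape[1])), np.cumsum(E, axis=0)])
    hi = np.minimum(np.arange(L) + k + 1, L)
    lo = np.maximum(np.arange(L) - k, 0)
    counts = (hi - lo).astype(float)
    return (S[hi] - S[lo]) / counts[:, None], counts


def _window_sum(E: np.ndarray, k: int) -> np.ndarray:
    L = len(E)
    S = np.vstack([np.zeros((1, E.shape[1])), np.cumsum(E, axis=0)])
    hi = np.minimum(np.arange(L) + k + 1, L)
    lo = np.maximum(np.arange(L) - k, 0)
    return S[hi] - S[lo]


@dataclasses.dataclass
class DistillEncoder:
    """Reference small distillation encoder (see module docstring).

    ``forward`` maps an input of token indices, a sequence string, or an
    ``(L, 21)`` probability matrix to ``(sequence_logits, per_position_logits)``.
    Evaluation is deterministic; all stochasticity lives in initialization
    and training.
    """

    n_bins: int = 50
    d_embed: int = 24
    hidden: int = 64
    windows: Tuple[int, int] = (2, 5)
    params: Optional[Dict[str, np.ndarray]] = None

    def init_params(self, rng: np.random.Generator) -> None:
        V, d, H, nb = len(TOKEN_ALPHABET), self.d_embed, self.hidden, self.n_bins
        F = 3 * d

        def xavier(n_in, n_out):
            return rng.normal(0.0, np.sqrt(2.0 / (n_in + n_out)), size=(n_in, n_out))

        self.params = {
            "emb": xavier(V, d),
            "W1": xavier(F, H), "b1": np.zeros(H),
            "W2": xavier(H, nb), "b2": np.zeros(nb),
            "W1s": xavier(F, H), "b1s": np.zeros(H),
            "W2s": xavier(H, nb), "b2s": np.zeros(nb),
        }

    @property
    def parameter_count(self) -> int:
        return int(sum(p.size for p in self.params.values()))

    def _as_input(self, x) -> np.ndarray:
        if isinstance(x, str):
            x = encode_sequence(x)
        x = np.asarray(x)
        if x.ndim == 1:  # token indices
            return one_hot(x.astype(int))
        if x.ndim == 2 and x.shape[1] == len(TOKEN_ALPHABET):
            return np.asarray(x, float)
        raise ValueError("input must be a sequence, token indices, or (L, 21) matrix")

    def forward(self, x, want_cache: bool = False):
        """Return ``(sequence_logits, per_position_logits[, cache])``."""
        if self.params is None:
            raise RuntimeError("model parameters not initialized")
        X = self._as_input(x)
        P = self.params
        E = X @ P["emb"]
        k1, k2 = self.windows
        M1, c1 = _window_mean(E, k1)
        M2, c2 = _window_mean(E, k2)
        F = np.hstack([E, M1, M2])
        H1 = np.tanh(F @ P["W1"] + P["b1"])
        per_pos = H1 @ P["W2"] + P["b2"]
        g = F.mean(axis=0)
        Hs = np.tanh(g @ P["W1s"] + P["b1s"])
        seq_logits = Hs @ P["W2s"] + P["b2s"]
        if not want_cache:
            return seq_logits, per_pos
        cache = {"X": X, "F": F, "H1": H1, "g": g, "Hs": Hs, "c1": c1, "c2": c2}
        return seq_logits, per_pos, cache

    def backward(self, cache, d_seq_logits: Optional[np.ndarray],
                 d_per_pos: Optional[np.ndarray]):
        """Gradients of a scalar loss given its logit gradients.

        Returns ``(param_grads, input_grad)`` where ``input_grad`` has the
        shape of the one-hot/probability input — the hook the SC
        regularizer uses to push gradients into a generator.
        """
        P = self.params
        X, F, H1, g, Hs = cache["X"], cache["F"], cache["H1"], cache["g"], cache["Hs"]
        L, d = X.shape[0], self.d_embed
        grads = {k: np.zeros_like(v) for k, v in P.items()}
        dF = np.zeros_like(F)
        if d_per_pos is not None:
            dH1 = (d_per_pos @ P["W2"].T) * (1.0 - H1 ** 2)
            grads["W2"] += H1.T @ d_per_pos
            grads["b2"] += d_per_pos.sum(axis=0)
            grads["W1"] += F.T @ dH1
            grads["b1"] += dH1.sum(axis=0)
            dF += dH1 @ P["W1"].T
        if d_seq_logits is not None:
            dHs = (d_seq_logits @ P["W2s"].T) * (1.0 - Hs ** 2)
            grads["W2s"] += np.outer(Hs, d_seq_logits)
            grads["b2s"] += d_seq_logits
            grads["W1s"] += np.outer(g, dHs)
            grads["b1s"] += dHs
            dF += (P["W1s"] @ dHs)[None, :] / L
        k1, k2 = self.windows
        dE = dF[:, :d].copy()
        dE += _window_sum(dF[:, d:2 * d] / cache["c1"][:, None], k1)
        dE += _window_sum(dF[:, 2 * d:] / cache["c2"][:, None], k2)
        grads["emb"] += X.T @ dE
        dX = dE @ P["emb"].T
        return grads, dX

    # -- persistence ---------------------------------------------------------

    def save(self, path) -> None:
        """Save weights plus architecture config as a single .npz checkpoint."""
        meta = {
            "n_bins": self.n_bins, "d_embed": self.d_embed,
            "hidden": self.hidden, "windows": list(self.windows),
        }
        np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                 **self.params)

    @classmethod
    def load(cls, path) -> "DistillEncoder":
        data = np.load(path)
        meta = json.loads(bytes(data["__meta__"]).decode())
        model = cls(n_bins=meta["n_bins"], d_embed=meta["d_embed"],
                    hidden=meta["hidden"], windows=tuple(meta["windows"]))
        model.params = {k: data[k] for k in data.files if k != "__meta__"}
        return model
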