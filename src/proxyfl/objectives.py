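"""Deep mutual learning objectives.

Two models trained on the same data pull each other together: each minimises
a convex combination of its own cross-entropy and a KL divergence from its
predictive distribution to its peer's.  The peer's predictions are always
treated as constants (no gradient flows into the peer), which is what makes
alternating updates between the two models well defined.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Batch, Classifier, forward_logits, per_example_grads, softmax

__all__ = [
    "MutualWeights",
    "ce_loss",
    "kl_loss",
    "private_objective",
    "proxy_objective",
    "mixed_per_example_grads",
    "CrossEntropyLoss",
    "MixedLoss",
    "PROB_FLOOR",
]

# Floor inside logarithms; numerical safety only, never alters losses measurably.
PROB_FLOOR = 1e-12


@dataclass(frozen=True)
class MutualWeights:
    """Mixing weights of the two mutual-learning objectives.

    ``alpha`` weights the KL term in the private model's objective, ``beta``
    the KL term in the proxy's.  Both live in the open interval (0, 1);
    the boundary values are admitted only with ``diagnostic=True`` (used by
    reduction tests where one term must vanish exactly).
    """

    alpha: float
    beta: float
    diagnostic: bool = False

    def __post_init__(self):
        lo, hi = (0.0, 1.0)
        for name, v in (("alpha", self.alpha), ("beta", self.beta)):
            if self.diagnostic:
                ok = lo <= v <= hi
            else:
                ok = lo < v < hi
            if not ok:
                raise ValueError(
                    f"{name}={v} outside the {'closed' if self.diagnostic else 'open'} interval (0, 1)"
                )


def ce_loss(probs: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Per-example cross entropy -log p[i, y_i] on probability rows."""
    probs = np.asarray(probs, dtype=np.float64)
    y = np.asarray(y, dtype=np.int64)
    if np.any(y < 0) or np.any(y >= probs.shape[1]):
        raise ValueError("labels out of range for the given probability rows")
    p_true = np.clip(probs[np.arange(len(y)), y], PROB_FLOOR, None)
    return -np.log(p_true)


def kl_loss(p_rows: np.ndarray, q_rows: np.ndarray) -> np.ndarray:
    """Per-example KL(p || q) between probability rows."""
    p = np.asarray(p_rows, dtype=np.float64)
    q = np.asarray(q_rows, dtype=np.float64)
    if p.shape != q.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {q.shape}")
    logp = np.log(np.clip(p, PROB_FLOOR, None))
    logq = np.log(np.clip(q, PROB_FLOOR, None))
    return np.sum(p * (logp - logq), axis=1)


def _probs(model: Classifier, x: np.ndarray) -> np.ndarray:
    return softmax(forward_logits(model, x))


def private_objective(
    private: Classifier, proxy: Classifier, batch: Batch, w: MutualWeights
) -> float:
    """(1 - alpha) * mean CE(private) + alpha * mean KL(private || proxy).

    The proxy's outputs enter as constants.
    """
    if not 0.0 <= w.alpha <= 1.0:
        raise ValueError(f"alpha={w.alpha} outside [0, 1]")
    p = _probs(private, batch.x)
    q = _probs(proxy, batch.x)
    return float(
        (1 - w.alpha) * ce_loss(p, batch.y).mean() + w.alpha * kl_loss(p, q).mean()
    )


def proxy_objective(
    proxy: Classifier, private: Classifier, batch: Batch, w: MutualWeights
) -> float:
    """(1 - beta) * mean CE(proxy) + beta * mean KL(proxy || private)."""
    if not 0.0 <= w.beta <= 1.0:
        raise ValueError(f"beta={w.beta} outside [0, 1]")
    p = _probs(proxy, batch.x)
    q = _probs(private, batch.x)
    return float(
        (1 - w.beta) * ce_loss(p, batch.y).mean() + w.beta * kl_loss(p, q).mean()
    )


class CrossEntropyLoss:
    """Per-example CE on logits, with its gradient w.r.t. the logits."""

    @staticmethod
    def values(logits: np.ndarray, y: np.ndarray) -> np.ndarray:
        return ce_loss(softmax(logits), y)

    @staticmethod
    def dlogits(logits: np.ndarray, y: np.ndarray) -> np.ndarray:
        p = softmax(logits)
        onehot = np.zeros_like(p)
        onehot[np.arange(len(y)), y] = 1.0
        return p - onehot


class MixedLoss:
    """(1 - weight) * CE + weight * KL(model || peer) with fixed peer rows.

    The KL gradient w.r.t. the model's logits has the closed form
    p_j * (a_j - sum_c p_c a_c) with a = log p - log q.
    """

    def __init__(self, peer_probs: np.ndarray, weight: float):
        if not 0.0 <= weight <= 1.0:
            raise ValueError(f"mixing weight {weight} outside [0, 1]")
        self.peer_probs = np.asarray(peer_probs, dtype=np.float64)
        self.weight = float(weight)

    def values(self, logits: np.ndarray, y: np.ndarray) -> np.ndarray:
        p = softmax(logits)
        return (1 - self.weight) * ce_loss(p, y) + self.weight * kl_loss(p, self.peer_probs)

    def dlogits(self, logits: np.ndarray, y: np.ndarray) -> np.ndarray:
        p = softmax(logits)
        out = (1 - self.weight) * CrossEntropyLoss.dlogits(logits, y)
        if self.weight:
            a = np.log(np.clip(p, PROB_FLOOR, None)) - np.log(
                np.clip(self.peer_probs, PROB_FLOOR, None)
            )
            kl_grad = p * (a - np.sum(p * a, axis=1, keepdims=True))
            out = out + self.weight * kl_grad
        return out


def mixed_per_example_grads(
    model: Classifier,
    peer: Classifier | None,
    batch: Batch,
    weight: float,
) -> np.ndarray:
    """Per-example gradients of the mixed CE + KL(model || peer) loss.

    Gradients are taken w.r.t. ``model``'s parameters only; the peer is a
    constant.  ``peer=None`` requires ``weight == 0`` and reduces to plain CE.
    """
    if peer is None:
        if weight != 0.0:
            raise ValueError("a peer model is required when the KL weight is nonzero")
        return per_example_grads(model, CrossEntropyLoss(), batch)
    peer_probs = _probs(peer, batch.x)
    return per_example_grads(model, MixedLoss(peer_probs, weight), batch)
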