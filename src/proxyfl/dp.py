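"""Differentially private gradient steps.

The privacy-critical primitive: per-example gradients are clipped to an L2
ball of radius C, summed, Gaussian noise of scale sigma*C is added, and the
result is divided by the realized batch size.  Each noised mean emits exactly
one StepReceipt, the unit the privacy accountant composes over.  Only proxy
(shared) models ever pass through this module; private models are updated
with ordinary, non-private gradients elsewhere.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .nn import Batch, Classifier, OptState, apply_update
from .objectives import mixed_per_example_grads

__all__ = [
    "DPConfig",
    "StepReceipt",
    "clip_rows",
    "privatize_mean",
    "dp_step",
    "poisson_sample",
    "write_ledger",
    "read_ledger",
]


@dataclass(frozen=True)
class DPConfig:
    """Clipping threshold and Gaussian noise multiplier for DP-SGD.

    ``sigma = 0`` is admitted for oracle tests only (no privacy)."""

    clip_C: float
    sigma: float
    enabled: bool = True

    def __post_init__(self):
        if self.clip_C <= 0:
            raise ValueError(f"clip_C must be positive, got {self.clip_C}")
        if self.sigma < 0:
            raise ValueError(f"sigma must be nonnegative, got {self.sigma}")


@dataclass(frozen=True)
class StepReceipt:
    """Record of one privatized gradient release: (sampling rate, noise, steps)."""

    q: float
    sigma: float
    steps: int = 1


def clip_rows(grads: np.ndarray, C: float) -> np.ndarray:
    """Scale each row i by 1 / max(1, ||row_i||_2 / C).

    Rows with norm <= C pass through unchanged; clipped rows keep their
    direction with norm exactly C.
    """
    if C <= 0:
        raise ValueError(f"clipping threshold must be positive, got {C}")
    grads = np.asarray(grads, dtype=np.float64)
    finite = np.isfinite(grads).all(axis=1)
    if not finite.all():
        bad = int(np.flatnonzero(~finite)[0])
        raise FloatingPointError(f"non-finite gradient row at example index {bad}")
    norms = np.linalg.norm(grads, axis=1, keepdims=True)
    scale = np.minimum(1.0, C / np.maximum(norms, 1e-300))
    # exact no-op for rows already inside the ball (bit-identical rows)
    scale[norms <= C] = 1.0
    return grads * scale


def privatize_mean(
    clipped: np.ndarray, C: float, sigma: float, rng: np.random.Generator
) -> np.ndarray:
    """(1/B) * (sum of clipped rows + N(0, sigma^2 C^2 I)).

    Deterministic given the generator state; sigma = 0 returns the exact
    clipped mean.
    """
    if sigma < 0:
        raise ValueError(f"sigma must be nonnegative, got {sigma}")
    clipped = np.asarray(clipped, dtype=np.float64)
    B, P = clipped.shape
    total = clipped.sum(axis=0)
    if sigma > 0:
        total = total + rng.normal(0.0, sigma * C, P)
    return total / B


def dp_step(
    model: Classifier,
    peer: Classifier | None,
    batch: Batch,
    weight: float,
    dp: DPConfig,
    opt_state: OptState | None,
    rng: np.random.Generator,
    *,
    sampling_rate: float,
    rule: str = "adam",
    lr: float = 0.001,
    weight_decay: float = 0.0,
) -> tuple[Classifier, OptState | None, StepReceipt]:
    """One DP optimizer step on the mixed CE/KL objective.

    Composes mixed per-example gradients -> clip -> noised mean -> optimizer
    update, and returns the receipt the accountant must be fed.  Refuses to
    run with DP disabled: privacy can only be spent through receipts.
    """
    if not dp.enabled:
        raise RuntimeError("dp_step called with DP disabled; use a plain update instead")
    grads = mixed_per_example_grads(model, peer, batch, weight)
    clipped = clip_rows(grads, dp.clip_C)
    noisy_mean = privatize_mean(clipped, dp.clip_C, dp.sigma, rng)
    new_params, opt_state = apply_update(
        model.params, noisy_mean, opt_state, rule=rule, lr=lr, weight_decay=weight_decay
    )
    receipt = StepReceipt(q=float(sampling_rate), sigma=dp.sigma, steps=1)
    return Classifier(model.arch, new_params, dict(model.layout)), opt_state, receipt


def poisson_sample(
    dataset, q: float, rng: np.random.Generator
) -> Batch | None:
    """Poisson-subsampled mini-batch: each example included independently
    with probability q (original order preserved).  Returns None on an empty
    draw — the caller skips the step (no update, no receipt).  q = 1 returns
    the full dataset.
    """
    if not 0.0 < q <= 1.0:
        raise ValueError(f"sampling rate must be in (0, 1], got {q}")
    n = len(dataset.y)
    if q == 1.0:
        return Batch(dataset.x, dataset.y)
    mask = rng.random(n) < q
    if not mask.any():
        return None
    return Batch(dataset.x[mask], dataset.y[mask])


def write_ledger(path: str | Path, receipts: list[StepReceipt]) -> None:
    """Append receipts to a JSON-lines ledger file."""
    path = Path(path)
    with path.open("a") as fh:
        for i, r in enumerate(receipts):
            fh.write(json.dumps({"q": r.q, "sigma": r.sigma, "steps": r.steps}) + "\n")


def read_ledger(path: str | Path) -> list[StepReceipt]:
    """Read a JSON-lines ledger back into receipts (replayable into a report)."""
    out = []
    for line in Path(path).read_text().splitlines():
        if line.strip():
            d = json.loads(line)
            out.append(StepReceipt(q=d["q"], sigma=d["sigma"], steps=d.get("steps", 1)))
    return out
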