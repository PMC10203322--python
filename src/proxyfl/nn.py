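"""Minimal differentiable classifiers with per-example gradients.

Models are stored as a flat float64 parameter vector plus a layout map, so
that clipping, noising, gossip averaging and norms are architecture-agnostic
vector operations.  Two families are provided: a fully connected network
(``mlp``) and a small strided-convolution network (``cnn``).  Backpropagation
is written out explicitly and always produces *per-example* parameter
gradients — the quantity differential privacy needs — from which batch
gradients are the row mean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "ArchSpec",
    "Batch",
    "Classifier",
    "OptState",
    "init_classifier",
    "forward_logits",
    "forward_probs",
    "per_example_grads",
    "apply_update",
    "softmax",
]


@dataclass(frozen=True)
class ArchSpec:
    """Architecture description.

    family
        ``"mlp"``: ``hidden`` is a sequence of dense widths.
        ``"cnn"``: ``hidden`` is a sequence of ``(channels, kernel, stride)``
        conv descriptors applied to a ``(C, H, W)`` input, followed by a
        dense head.
    input_shape
        Shape of one example, e.g. ``(16,)`` or ``(1, 8, 8)``.
    n_classes
        Number of output classes (>= 2).
    """

    family: str
    input_shape: tuple[int, ...]
    hidden: tuple
    n_classes: int

    def __post_init__(self):
        if self.family not in ("mlp", "cnn"):
            raise ValueError(f"family must be 'mlp' or 'cnn', got {self.family!r}")
        if self.n_classes < 2:
            raise ValueError(f"n_classes must be >= 2, got {self.n_classes}")
        object.__setattr__(self, "input_shape", tuple(int(s) for s in self.input_shape))
        object.__setattr__(self, "hidden", tuple(
            tuple(int(v) for v in h) if isinstance(h, (tuple, list)) else int(h)
            for h in self.hidden
        ))
        if any(s <= 0 for s in self.input_shape):
            raise ValueError(f"input_shape entries must be positive, got {self.input_shape}")
        if self.family == "mlp":
            if any(not isinstance(h, int) or h <= 0 for h in self.hidden):
                raise ValueError(f"hidden widths must be positive integers, got {self.hidden}")
        else:
            if len(self.input_shape) != 3:
                raise ValueError("cnn input_shape must be (channels, height, width)")
            for h in self.hidden:
                if not (isinstance(h, tuple) and len(h) == 3):
                    raise ValueError(f"cnn hidden entries must be (channels, kernel, stride), got {h!r}")
                if any(v <= 0 for v in h):
                    raise ValueError(f"conv descriptor entries must be positive, got {h}")

    def layer_shapes(self) -> list[tuple[str, tuple[int, ...]]]:
        """Ordered (name, shape) pairs of all parameter arrays."""
        shapes: list[tuple[str, tuple[int, ...]]] = []
        if self.family == "mlp":
            dims = [int(np.prod(self.input_shape))] + list(self.hidden) + [self.n_classes]
            for i in range(len(dims) - 1):
                shapes.append((f"dense{i}.W", (dims[i], dims[i + 1])))
                shapes.append((f"dense{i}.b", (dims[i + 1],)))
        else:
            c, h, w = self.input_shape
            for i, (cout, k, s) in enumerate(self.hidden):
                if k > h or k > w:
                    raise ValueError(f"kernel {k} exceeds feature map size {(h, w)} at conv{i}")
                shapes.append((f"conv{i}.W", (cout, c, k, k)))
                shapes.append((f"conv{i}.b", (cout,)))
                h = (h - k) // s + 1
                w = (w - k) // s + 1
                c = cout
            shapes.append(("head.W", (c * h * w, self.n_classes)))
            shapes.append(("head.b", (self.n_classes,)))
        return shapes

    @property
    def n_params(self) -> int:
        return sum(int(np.prod(s)) for _, s in self.layer_shapes())

    def compatible_with(self, other: "ArchSpec") -> bool:
        """Two specs may exchange parameters iff structurally identical."""
        return self == other


@dataclass
class Batch:
    """A mini-batch of examples with integer class labels."""

    x: np.ndarray
    y: np.ndarray

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=np.int64)
        if self.x.shape[0] != self.y.shape[0]:
            raise ValueError(f"x and y batch dims differ: {self.x.shape[0]} vs {self.y.shape[0]}")
        if self.x.shape[0] < 1:
            raise ValueError("batch must contain at least one example")

    def __len__(self) -> int:
        return self.x.shape[0]


@dataclass
class Classifier:
    """A model: an ArchSpec plus a flat parameter vector with a layout map."""

    arch: ArchSpec
    params: np.ndarray
    layout: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self):
        self.params = np.asarray(self.params, dtype=np.float64)
        if not self.layout:
            self.layout = _build_layout(self.arch)
        if self.params.shape != (self.arch.n_params,):
            raise ValueError(
                f"parameter vector length {self.params.shape} does not match "
                f"arch parameter count {self.arch.n_params}"
            )

    def view(self, name: str) -> np.ndarray:
        """A reshaped view of one layer's parameters (shares memory)."""
        lo, hi = self.layout[name]
        shape = dict(self.arch.layer_shapes())[name]
        return self.params[lo:hi].reshape(shape)

    def copy(self) -> "Classifier":
        return Classifier(self.arch, self.params.copy(), dict(self.layout))

    @property
    def n_params(self) -> int:
        return self.params.size


def _build_layout(arch: ArchSpec) -> dict[str, tuple[int, int]]:
    layout = {}
    off = 0
    for name, shape in arch.layer_shapes():
        n = int(np.prod(shape))
        layout[name] = (off, off + n)
        off += n
    return layout


def init_classifier(arch: ArchSpec, seed: int, zero_init: bool = False) -> Classifier:
    """Deterministically initialise a classifier from (arch, seed).

    He-style scaling (std = sqrt(2 / fan_in)) on weights, zero biases.
    ``zero_init`` forces all-zero parameters (uniform output probabilities),
    useful for diagnostics.
    """
    params = np.zeros(arch.n_params, dtype=np.float64)
    model = Classifier(arch, params)
    if not zero_init:
        rng = np.random.default_rng(seed)
        for name, shape in arch.layer_shapes():
            if name.endswith(".W"):
                fan_in = int(np.prod(shape[:-1])) if len(shape) == 2 else int(np.prod(shape[1:]))
                std = math.sqrt(2.0 / fan_in)
                lo, hi = model.layout[name]
                model.params[lo:hi] = rng.normal(0.0, std, hi - lo)
    return model


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _check_input(arch: ArchSpec, x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64)
    if x.shape[1:] != arch.input_shape:
        raise ValueError(f"input shape {x.shape[1:]} does not match arch input_shape {arch.input_shape}")
    return x


def _forward(model: Classifier, x: np.ndarray):
    """Forward pass returning logits and the activation caches for backprop."""
    x = _check_input(model.arch, x)
    arch = model.arch
    caches = []
    if arch.family == "mlp":
        a = x.reshape(x.shape[0], -1)
        n_dense = len(arch.hidden) + 1
        for i in range(n_dense):
            W = model.view(f"dense{i}.W")
            b = model.view(f"dense{i}.b")
            z = a @ W + b
            caches.append(("dense", i, a, z))
            a = np.maximum(z, 0.0) if i < n_dense - 1 else z
        return a, caches
    # cnn: strided valid convolutions with ReLU, then a dense head
    a = x
    for i, (cout, k, s) in enumerate(arch.hidden):
        W = model.view(f"conv{i}.W")
        b = model.view(f"conv{i}.b")
        patches = sliding_window_view(a, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        z = np.einsum("bchwkl,fckl->bfhw", patches, W) + b[None, :, None, None]
        caches.append(("conv", i, a, patches, z))
        a = np.maximum(z, 0.0)
    flat = a.reshape(a.shape[0], -1)
    W = model.view("head.W")
    b = model.view("head.b")
    logits = flat @ W + b
    caches.append(("head", None, flat, a.shape))
    return logits, caches


def forward_logits(model: Classifier, x: np.ndarray) -> np.ndarray:
    logits, _ = _forward(model, x)
    return logits


def forward_probs(model: Classifier, x: np.ndarray) -> np.ndarray:
    """Class probabilities; each row is a point on the simplex."""
    return softmax(forward_logits(model, x))


def _backward(model: Classifier, caches, dlogits: np.ndarray) -> np.ndarray:
    """Per-example parameter gradients [B, P] from per-example dL/dlogits."""
    arch = model.arch
    B = dlogits.shape[0]
    grads = np.zeros((B, model.n_params), dtype=np.float64)

    def put(name, g):
        lo, hi = model.layout[name]
        grads[:, lo:hi] = g.reshape(B, -1)

    if arch.family == "mlp":
        delta = dlogits
        for kind, i, a, z in reversed(caches):
            put(f"dense{i}.W", np.einsum("bi,bo->bio", a, delta))
            put(f"dense{i}.b", delta)
            if i > 0:
                W = model.view(f"dense{i}.W")
                delta = (delta @ W.T) * (caches[i - 1][3] > 0)
        return grads

    kind, _, flat, conv_out_shape = caches[-1]
    put("head.W", np.einsum("bi,bo->bio", flat, dlogits))
    put("head.b", dlogits)
    W = model.view("head.W")
    delta = (dlogits @ W.T).reshape(conv_out_shape)
    for kind, i, a_in, patches, z in reversed(caches[:-1]):
        delta = delta * (z > 0)
        cout, k, s = model.arch.hidden[i]
        put(f"conv{i}.W", np.einsum("bchwkl,bfhw->bfckl", patches, delta))
        put(f"conv{i}.b", delta.sum(axis=(2, 3)))
        if i > 0:
            Wc = model.view(f"conv{i}.W")
            Ho, Wo = delta.shape[2], delta.shape[3]
            dx = np.zeros_like(a_in)
            for p in range(k):
                for q in range(k):
                    dx[:, :, p : p + s * Ho : s, q : q + s * Wo : s] += np.einsum(
                        "fc,bfhw->bchw", Wc[:, :, p, q], delta
                    )
            delta = dx
    return grads


def per_example_grads(model: Classifier, loss, batch: Batch) -> np.ndarray:
    """Per-example gradients of a scalar loss w.r.t. the flat parameters.

    ``loss`` exposes ``values(logits, y) -> [B]`` and
    ``dlogits(logits, y) -> [B, n_classes]``.  Row i of the result is the
    gradient of example i's loss; the row mean equals the gradient of the
    mean loss.
    """
    logits, caches = _forward(model, batch.x)
    vals = loss.values(logits, batch.y)
    if not np.all(np.isfinite(vals)):
        bad = int(np.flatnonzero(~np.isfinite(vals))[0])
        raise FloatingPointError(f"non-finite loss at example index {bad}")
    return _backward(model, caches, loss.dlogits(logits, batch.y))


@dataclass
class OptState:
    """Optimizer state: Adam first/second moments and step counter."""

    m: np.ndarray
    v: np.ndarray
    t: int = 0

    @classmethod
    def fresh(cls, n_params: int) -> "OptState":
        return cls(np.zeros(n_params), np.zeros(n_params), 0)


def apply_update(
    params: np.ndarray,
    grad: np.ndarray,
    opt_state: OptState | None,
    rule: str = "sgd",
    lr: float = 0.001,
    weight_decay: float = 0.0,
    betas: tuple[float, float] = (0.9, 0.999),
    eps: float = 1e-8,
) -> tuple[np.ndarray, OptState | None]:
    """One optimizer step on a flat parameter vector.

    ``sgd``: params - lr * grad.  ``adam``: the standard bias-corrected
    first/second-moment update.  Weight decay, when nonzero, is added to the
    gradient (L2 style) before the moment updates.
    """
    params = np.asarray(params, dtype=np.float64)
    grad = np.asarray(grad, dtype=np.float64)
    if grad.shape != params.shape:
        raise ValueError(f"gradient length {grad.shape} does not match params {params.shape}")
    if weight_decay:
        grad = grad + weight_decay * params
    if rule == "sgd":
        return params - lr * grad, opt_state
    if rule != "adam":
        raise ValueError(f"unknown update rule {rule!r}")
    if opt_state is None:
        opt_state = OptState.fresh(params.size)
    b1, b2 = betas
    t = opt_state.t + 1
    m = b1 * opt_state.m + (1 - b1) * grad
    v = b2 * opt_state.v + (1 - b2) * grad * grad
    m_hat = m / (1 - b1 ** t)
    v_hat = v / (1 - b2 ** t)
    new = params - lr * m_hat / (np.sqrt(v_hat) + eps)
    return new, OptState(m, v, t)
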