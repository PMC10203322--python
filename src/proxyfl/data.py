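"""Synthetic classification data, non-IID partitioners, and metrics.

The generator produces Gaussian class blobs whose mean separation is the
difficulty dial, standing in for small image benchmarks so every protocol is
testable without downloads.  Two partitioners reproduce the label-skew
structures used in multi-institutional experiments: a major-class scheme
(fraction ``p_major`` of each client's data from one assigned class) and
Dirichlet allocation of each class across clients.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .nn import Classifier, forward_probs

__all__ = [
    "LabelledDataset",
    "PartitionPlan",
    "make_synthetic",
    "partition_skewed",
    "partition_dirichlet",
    "evaluate",
    "save_dataset",
    "load_dataset",
    "save_plan",
    "load_plan",
    "load_idx",
]


@dataclass
class LabelledDataset:
    """Feature tensors x[N, ...] with integer labels y[N] in [0, class_count)."""

    x: np.ndarray
    y: np.ndarray
    class_count: int

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=np.int64)
        if self.x.shape[0] != self.y.shape[0]:
            raise ValueError("x and y lengths differ")
        if self.y.size and (self.y.min() < 0 or self.y.max() >= self.class_count):
            raise ValueError("labels out of range")
        if self.x.shape[0] < self.class_count:
            raise ValueError("need at least one example per class")

    def __len__(self) -> int:
        return self.x.shape[0]

    def subset(self, indices: np.ndarray) -> "LabelledDataset":
        idx = np.asarray(indices, dtype=np.int64)
        return LabelledDataset(self.x[idx], self.y[idx], self.class_count)


@dataclass
class PartitionPlan:
    """Disjoint per-client index sets into a pooled dataset."""

    assignments: list[np.ndarray]
    major_class: list[int] | None = None

    def __post_init__(self):
        self.assignments = [np.asarray(a, dtype=np.int64) for a in self.assignments]
        seen: set[int] = set()
        for a in self.assignments:
            s = set(a.tolist())
            if seen & s:
                raise ValueError("partition index sets overlap")
            seen |= s


def make_synthetic(
    n_classes: int,
    shape,
    n_per_class: int,
    class_separation: float = 3.0,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> LabelledDataset:
    """Balanced Gaussian-blob classification data, deterministic per seed.

    Class means are drawn isotropically and scaled so the expected pairwise
    mean distance equals ``class_separation``; examples add isotropic noise
    of standard deviation ``noise_sd``.  ``shape`` may be an int (flat
    features) or a tuple (image-shaped features).
    """
    if n_classes < 2:
        raise ValueError(f"n_classes must be >= 2, got {n_classes}")
    shape = (int(shape),) if np.isscalar(shape) else tuple(int(s) for s in shape)
    if any(s <= 0 for s in shape):
        raise ValueError(f"degenerate feature shape {shape}")
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    dim = int(np.prod(shape))
    rng = np.random.default_rng(seed)
    # mean-to-mean distance for N(0, s^2 I_d) pairs concentrates at s*sqrt(2d)
    s = class_separation / np.sqrt(2.0 * dim)
    means = rng.normal(0.0, s, (n_classes, dim))
    x = np.repeat(means, n_per_class, axis=0) + rng.normal(
        0.0, noise_sd, (n_classes * n_per_class, dim)
    )
    y = np.repeat(np.arange(n_classes), n_per_class)
    perm = rng.permutation(len(y))
    return LabelledDataset(x[perm].reshape(-1, *shape), y[perm], n_classes)


def partition_skewed(
    dataset: LabelledDataset,
    K: int,
    p_major: float,
    per_client_n: int,
    seed: int = 0,
) -> PartitionPlan:
    """Label-skewed partition: each client gets an assigned major class.

    floor(p_major * n) examples come from the client's major class, the
    remainder uniformly from all other classes; all draws are without
    replacement from the pool so client sets are disjoint.
    ``p_major = 1/class_count`` recovers the IID setting.
    """
    nc = dataset.class_count
    if not 1.0 / nc <= p_major <= 1.0:
        raise ValueError(f"p_major must be in [1/{nc}, 1], got {p_major}")
    rng = np.random.default_rng(seed)
    majors = [int(rng.integers(nc)) for _ in range(K)]
    n_major = int(np.floor(p_major * per_client_n))
    n_minor = per_client_n - n_major

    by_class = {c: list(rng.permutation(np.flatnonzero(dataset.y == c))) for c in range(nc)}
    assignments = []
    for k, major in enumerate(majors):
        if len(by_class[major]) < n_major:
            raise ValueError(
                f"insufficient examples of major class {major} for client {k}: "
                f"need {n_major}, have {len(by_class[major])}"
            )
        take = [by_class[major].pop() for _ in range(n_major)]
        # remaining data drawn uniformly (IID) over all other classes
        minor_pool = np.concatenate(
            [np.asarray(by_class[c], dtype=np.int64) for c in range(nc) if c != major]
        )
        if len(minor_pool) < n_minor:
            raise ValueError(f"insufficient minor-class examples for client {k}")
        chosen = rng.choice(minor_pool, size=n_minor, replace=False)
        chosen_set = set(chosen.tolist())
        for c in range(nc):
            if c != major:
                by_class[c] = [i for i in by_class[c] if i not in chosen_set]
        assignments.append(np.concatenate([np.asarray(take, dtype=np.int64), chosen]))
    return PartitionPlan(assignments=assignments, major_class=majors)


def partition_dirichlet(
    dataset: LabelledDataset,
    K: int,
    concentration: float,
    seed: int = 0,
) -> PartitionPlan:
    """Dirichlet partition: each class is split across the K clients with
    proportions drawn from Dirichlet(concentration * 1_K); per-class totals
    are conserved exactly.
    """
    if concentration <= 0:
        raise ValueError(f"concentration must be positive, got {concentration}")
    rng = np.random.default_rng(seed)
    buckets: list[list[np.ndarray]] = [[] for _ in range(K)]
    for c in range(dataset.class_count):
        idx = rng.permutation(np.flatnonzero(dataset.y == c))
        props = rng.dirichlet(np.full(K, concentration))
        # largest-remainder split conserves the class total exactly
        cuts = np.floor(np.cumsum(props) * len(idx) + 0.5).astype(int)
        cuts[-1] = len(idx)
        start = 0
        for k, stop in enumerate(cuts):
            stop = max(stop, start)
            buckets[k].append(idx[start:stop])
            start = stop
    assignments = [
        np.concatenate(b) if b else np.empty(0, dtype=np.int64) for b in buckets
    ]
    return PartitionPlan(assignments=assignments)


def evaluate(model: Classifier, test_set: LabelledDataset) -> tuple[float, float]:
    """(accuracy, macro-averaged accuracy) of argmax predictions.

    Macro accuracy is the unweighted mean of per-class recalls over the
    classes present in the test set.
    """
    if len(test_set) == 0:
        raise ValueError("empty test set")
    preds = []
    for lo in range(0, len(test_set), 512):
        probs = forward_probs(model, test_set.x[lo : lo + 512])
        preds.append(np.argmax(probs, axis=1))
    pred = np.concatenate(preds)
    acc = float(np.mean(pred == test_set.y))
    recalls = []
    for c in range(test_set.class_count):
        mask = test_set.y == c
        if mask.any():
            recalls.append(float(np.mean(pred[mask] == c)))
    return acc, float(np.mean(recalls))


def save_dataset(path: str | Path, dataset: LabelledDataset) -> None:
    np.savez(path, x=dataset.x, y=dataset.y, class_count=dataset.class_count)


def load_dataset(path: str | Path) -> LabelledDataset:
    with np.load(path) as z:
        return LabelledDataset(z["x"], z["y"], int(z["class_count"]))


def save_plan(path: str | Path, plan: PartitionPlan) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "assignments": [a.tolist() for a in plan.assignments],
                "major_class": plan.major_class,
            }
        )
    )


def load_plan(path: str | Path) -> PartitionPlan:
    d = json.loads(Path(path).read_text())
    return PartitionPlan(
        assignments=[np.asarray(a, dtype=np.int64) for a in d["assignments"]],
        major_class=d.get("major_class"),
    )


def load_idx(path: str | Path) -> np.ndarray:
    """Thin adapter for IDX-format array files (the MNIST container format).

    Not used by the test suite; provided so real benchmark files can be fed
    to the partitioners.
    """
    raw = Path(path).read_bytes()
    if raw[0] != 0 or raw[1] != 0:
        raise ValueError("not an IDX file")
    dtype = {0x08: np.uint8, 0x09: np.int8, 0x0B: np.int16, 0x0C: np.int32,
             0x0D: np.float32, 0x0E: np.float64}[raw[2]]
    ndim = raw[3]
    dims = [int.from_bytes(raw[4 + 4 * i : 8 + 4 * i], "big") for i in range(ndim)]
    data = np.frombuffer(raw, dtype=np.dtype(dtype).newbyteorder(">"), offset=4 + 4 * ndim)
    return data.reshape(dims).astype(np.float64 if dtype != np.uint8 else np.uint8)
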