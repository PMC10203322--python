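import numpy as np
import pytest

from proxyfl.nn import ArchSpec, Batch, Classifier, init_classifier


@pytest.fixture
def tiny_arch():
    """MLP small enough for finite-difference checks (<= 50 parameters)."""
    return ArchSpec("mlp", (3,), (4,), 3)  # 3*4+4 + 4*3+3 = 31 params


@pytest.fixture
def tiny_model(tiny_arch):
    return init_classifier(tiny_arch, seed=7)


@pytest.fixture
def tiny_batch():
    rng = np.random.default_rng(11)
    return Batch(rng.normal(size=(4, 3)), np.array([0, 1, 2, 1]))


def finite_diff_grads(model: Classifier, batch: Batch, per_example_loss, step=1e-5):
    """Central finite differences of per-example losses w.r.t. flat params.

    ``per_example_loss(model, batch) -> [B]``; returns a [B, P] matrix.
    """
    B = len(batch)
    P = model.n_params
    out = np.zeros((B, P))
    for j in range(P):
        plus = model.params.copy()
        plus[j] += step
        minus = model.params.copy()
        minus[j] -= step
        lp = per_example_loss(Classifier(model.arch, plus), batch)
        lm = per_example_loss(Classifier(model.arch, minus), batch)
        out[:, j] = (lp - lm) / (2 * step)
    return out
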