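"""Rényi differential privacy accounting for the subsampled Gaussian mechanism.

Each DP-SGD step on a Poisson-subsampled batch (rate q, noise multiplier
sigma) incurs a Rényi divergence bound at every order alpha.  These bounds
compose additively over steps and convert to an (epsilon, delta)-DP
statement by minimising over orders.  Integer orders use the exact
binomial-expansion bound; fractional orders are evaluated directly through
the erfc decomposition of the two-Gaussian mixture integral (the standard
accountant computation, not an interpolation).

Two RDP -> (epsilon, delta) conversions are provided.  The default is the
improved conversion

    eps = rdp + log((alpha-1)/alpha) - (log delta + log alpha)/(alpha - 1),

which is what contemporary DP training libraries report; the classical
``basic`` conversion eps = rdp + log(1/delta)/(alpha-1) is available via
``conversion="basic"`` and is uniformly looser (~15-20% at these scales).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import special

__all__ = [
    "DEFAULT_ORDERS",
    "AccountantState",
    "PrivacyReport",
    "gaussian_rdp",
    "subsampled_gaussian_rdp",
    "compose",
    "to_epsilon",
    "epsilon_for_training",
    "check_budget",
    "state_from_receipts",
]

# Fractional orders 1.1 .. 10.9 step 0.1, then integers to 63, then sparse tail.
DEFAULT_ORDERS: tuple[float, ...] = tuple(
    [round(1 + x / 10.0, 2) for x in range(1, 100)] + list(range(11, 64)) + [128, 256, 512]
)


@dataclass(frozen=True)
class AccountantState:
    """Accumulated RDP of repeated subsampled-Gaussian releases.

    ``rdp[j]`` bounds the Rényi divergence at ``orders[j]`` after ``steps``
    compositions at sampling rate ``q`` and noise multiplier ``sigma``.
    """

    q: float
    sigma: float
    orders: tuple[float, ...] = DEFAULT_ORDERS
    rdp: tuple[float, ...] = ()
    steps: int = 0

    def __post_init__(self):
        if not 0.0 <= self.q <= 1.0:
            raise ValueError(f"sampling rate must be in [0, 1], got {self.q}")
        if any(a <= 1 for a in self.orders):
            raise ValueError("all Rényi orders must exceed 1")
        if not self.rdp:
            object.__setattr__(self, "rdp", tuple(0.0 for _ in self.orders))
        if len(self.rdp) != len(self.orders):
            raise ValueError("rdp and orders length mismatch")


@dataclass(frozen=True)
class PrivacyReport:
    epsilon: float
    delta: float
    optimal_order: float
    budget_exhausted: bool = False


def gaussian_rdp(sigma: float, order: float) -> float:
    """RDP of the unsampled Gaussian mechanism at unit sensitivity: alpha/(2 sigma^2)."""
    if order <= 1:
        raise ValueError(f"Rényi order must exceed 1, got {order}")
    if sigma <= 0:
        return math.inf
    return order / (2.0 * sigma ** 2)


def _log_add(a: float, b: float) -> float:
    if a == -math.inf:
        return b
    if b == -math.inf:
        return a
    return max(a, b) + math.log1p(math.exp(-abs(a - b)))


def _log_comb(n: float, k: float) -> float:
    return float(special.gammaln(n + 1) - special.gammaln(k + 1) - special.gammaln(n - k + 1))


def _log_erfc(x: float) -> float:
    # log(erfc(x)) via the normal log-CDF, stable for large |x|
    return math.log(2.0) + float(special.log_ndtr(-x * math.sqrt(2.0)))


def _log_a_int(q: float, sigma: float, alpha: int) -> float:
    """log E[(P/Q)^alpha] by the exact binomial expansion at integer alpha."""
    la = -math.inf
    for i in range(alpha + 1):
        term = (
            _log_comb(alpha, i)
            + i * math.log(q)
            + (alpha - i) * math.log1p(-q)
            + (i * i - i) / (2.0 * sigma ** 2)
        )
        la = _log_add(la, term)
    return la


def _log_a_frac(q: float, sigma: float, alpha: float) -> float:
    """log E[(P/Q)^alpha] at fractional alpha via the erfc split of the integral."""
    la0, la1 = -math.inf, -math.inf
    z0 = sigma ** 2 * math.log(1.0 / q - 1.0) + 0.5
    i = 0
    while True:
        coef = _log_comb(alpha, i)
        log_t0 = coef + i * math.log(q) + (alpha - i) * math.log1p(-q)
        log_t1 = coef + (alpha - i) * math.log(q) + i * math.log1p(-q)
        log_e0 = math.log(0.5) + _log_erfc((i - z0) / (math.sqrt(2.0) * sigma))
        log_e1 = math.log(0.5) + _log_erfc((z0 - (alpha - i)) / (math.sqrt(2.0) * sigma))
        log_s0 = log_t0 + (i * i - i) / (2.0 * sigma ** 2) + log_e0
        log_s1 = log_t1 + ((alpha - i) ** 2 - (alpha - i)) / (2.0 * sigma ** 2) + log_e1
        la0 = _log_add(la0, log_s0)
        la1 = _log_add(la1, log_s1)
        i += 1
        if max(log_s0, log_s1) < -40 and i > alpha:
            break
        if i > 5000:  # safety; never reached for sane (q, sigma, alpha)
            break
    return _log_add(la0, la1)


def subsampled_gaussian_rdp(q: float, sigma: float, order: float) -> float:
    """Per-step RDP of the Poisson-subsampled Gaussian mechanism.

    Monotone nondecreasing in q; equals the unsampled closed form at q = 1;
    returns +inf (never raises) in divergent regimes such as sigma = 0.
    """
    if not 0.0 <= q <= 1.0:
        raise ValueError(f"sampling rate must be in [0, 1], got {q}")
    if order <= 1:
        raise ValueError(f"Rényi order must exceed 1, got {order}")
    if q == 0.0:
        return 0.0
    if sigma <= 0:
        return math.inf
    if q == 1.0:
        return gaussian_rdp(sigma, order)
    if float(order).is_integer():
        log_a = _log_a_int(q, sigma, int(order))
    else:
        log_a = _log_a_frac(q, sigma, order)
    return log_a / (order - 1.0)


_PER_STEP_CACHE: dict[tuple, tuple[float, ...]] = {}


def _per_step_rdp(q: float, sigma: float, orders: tuple[float, ...]) -> tuple[float, ...]:
    key = (q, sigma, orders)
    if key not in _PER_STEP_CACHE:
        _PER_STEP_CACHE[key] = tuple(
            subsampled_gaussian_rdp(q, sigma, a) for a in orders
        )
        if len(_PER_STEP_CACHE) > 256:
            _PER_STEP_CACHE.pop(next(iter(_PER_STEP_CACHE)))
    return _PER_STEP_CACHE[key]


def compose(state: AccountantState, n_steps: int) -> AccountantState:
    """Advance the ledger by n_steps identical subsampled-Gaussian releases."""
    if n_steps < 0:
        raise ValueError(f"n_steps must be nonnegative, got {n_steps}")
    if n_steps == 0:
        return state
    per_step = _per_step_rdp(state.q, state.sigma, state.orders)
    new_rdp = tuple(r + n_steps * p for r, p in zip(state.rdp, per_step))
    return replace(state, rdp=new_rdp, steps=state.steps + n_steps)


def _convert(rdp: float, order: float, delta: float, conversion: str) -> float:
    if not math.isfinite(rdp):
        return math.inf
    if conversion == "basic":
        return rdp + math.log(1.0 / delta) / (order - 1.0)
    if conversion == "improved":
        eps = (
            rdp
            + math.log((order - 1.0) / order)
            - (math.log(delta) + math.log(order)) / (order - 1.0)
        )
        return max(eps, 0.0)
    raise ValueError(f"unknown conversion {conversion!r}")


def to_epsilon(
    state: AccountantState, delta: float, conversion: str = "improved"
) -> PrivacyReport:
    """Convert accumulated RDP to an (epsilon, delta) statement.

    epsilon is the minimum over orders of the per-order conversion; the
    minimising order is reported.  If every order diverges the report
    carries epsilon = +inf and the exhausted flag.
    """
    if not 0.0 < delta < 1.0:
        raise ValueError(f"delta must be in (0, 1), got {delta}")
    eps = [
        _convert(r, a, delta, conversion) for r, a in zip(state.rdp, state.orders)
    ]
    j = int(np.argmin(eps))
    best = eps[j]
    return PrivacyReport(
        epsilon=float(best),
        delta=delta,
        optimal_order=float(state.orders[j]),
        budget_exhausted=not math.isfinite(best),
    )


def epsilon_for_training(
    N: int,
    B: int,
    epochs: int,
    sigma: float,
    delta: float,
    orders: tuple[float, ...] = DEFAULT_ORDERS,
    conversion: str = "improved",
) -> float:
    """epsilon spent by DP training: rate q = B/N, epochs * ceil(N/B) steps.

    Mirrors per-epoch accounting where each epoch takes a number of Poisson-
    subsampled gradient steps equivalent to one pass over the N examples at
    expected batch size B.
    """
    if B > N:
        raise ValueError(f"batch size {B} exceeds dataset size {N}")
    if epochs < 1:
        raise ValueError(f"epochs must be >= 1, got {epochs}")
    q = B / N
    steps = epochs * math.ceil(N / B)
    state = compose(AccountantState(q=q, sigma=sigma, orders=orders), steps)
    return to_epsilon(state, delta, conversion=conversion).epsilon


def check_budget(state: AccountantState, delta: float, budget_epsilon: float) -> bool:
    """True iff the accumulated epsilon has reached the prespecified budget."""
    if budget_epsilon <= 0:
        raise ValueError(f"budget_epsilon must be positive, got {budget_epsilon}")
    return to_epsilon(state, delta).epsilon >= budget_epsilon


def state_from_receipts(
    receipts, orders: tuple[float, ...] = DEFAULT_ORDERS
) -> AccountantState:
    """Replay a ledger of StepReceipts into an AccountantState.

    Receipts may mix sampling rates; the accumulated RDP is the sum of the
    per-receipt bounds (q and sigma of the state reflect the last receipt).
    """
    receipts = list(receipts)
    if not receipts:
        return AccountantState(q=0.0, sigma=0.0, orders=orders)
    rdp = [0.0] * len(orders)
    steps = 0
    for r in receipts:
        per = _per_step_rdp(r.q, r.sigma, orders)
        rdp = [acc + r.steps * p for acc, p in zip(rdp, per)]
        steps += r.steps
    last = receipts[-1]
    return AccountantState(
        q=last.q, sigma=last.sigma, orders=orders, rdp=tuple(rdp), steps=steps
    )
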