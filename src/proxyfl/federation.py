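"""Decentralized training protocols over a directed, time-varying topology.

A round has three phases: local training (the only phase that touches data),
communication along a column-stochastic adjacency matrix, and aggregation.
The flagship protocol trains a private/proxy model pair per client by mutual
learning — only the DP-trained proxy is ever transmitted — and gossips
proxies by PushSum: parameters mix as Theta' = P Theta together with a
weight vector w' = P w whose entries de-bias the stationary distribution, so
theta_k / w_k tracks the network average even on asymmetric graphs.

Six comparison protocols share the same round skeleton: central parameter
averaging (fedavg), its decentralized PushSum analogue (avgpush), cyclic
model passing (cwt), centrally averaged mutual learning (fml), isolated
local training (regular), and pooled-data training (joint).  Single-model
protocols train their one shared-architecture model with DP-SGD; the
two-model protocols apply DP only to the proxy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
import pandas as pd

from .accountant import AccountantState, check_budget, compose, to_epsilon
from .data import LabelledDataset, evaluate
from .dp import DPConfig, StepReceipt, dp_step, poisson_sample
from .nn import ArchSpec, Batch, Classifier, OptState, apply_update, init_classifier
from .objectives import MutualWeights, mixed_per_example_grads

__all__ = [
    "ClientState",
    "CommRound",
    "ProtocolConfig",
    "METHODS",
    "exponential_graph",
    "pushsum_mix",
    "debias",
    "proxyfl_round",
    "baseline_round",
    "run_protocol",
]

METHODS = ("proxyfl", "fml", "fedavg", "avgpush", "cwt", "regular", "joint")
TWO_MODEL_METHODS = ("proxyfl", "fml")


@dataclass
class ClientState:
    """One collaborator: model(s), PushSum weight, data, and privacy ledger.

    Two-model protocols use both slots; single-model protocols keep their
    one DP-trained, shareable model in ``proxy`` and leave ``private`` None.
    """

    id: int
    proxy: Classifier
    dataset: LabelledDataset
    accountant: AccountantState
    private: Classifier | None = None
    pushsum_weight: float = 1.0
    proxy_opt: OptState | None = None
    private_opt: OptState | None = None
    receipts: list[StepReceipt] = field(default_factory=list)
    dropped: bool = False

    def __post_init__(self):
        if self.pushsum_weight <= 0:
            raise ValueError(f"pushsum weight must be positive, got {self.pushsum_weight}")


@dataclass(frozen=True)
class CommRound:
    """Column-stochastic adjacency matrix for one gossip round.

    ``P[k, k']`` nonzero means client k receives from client k'."""

    P: np.ndarray
    t: int

    def __post_init__(self):
        P = np.asarray(self.P, dtype=np.float64)
        object.__setattr__(self, "P", P)
        if P.ndim != 2 or P.shape[0] != P.shape[1]:
            raise ValueError(f"adjacency matrix must be square, got {P.shape}")
        if (P < 0).any():
            raise ValueError("adjacency matrix entries must be nonnegative")
        colsums = P.sum(axis=0)
        if np.max(np.abs(colsums - 1.0)) > 1e-9:
            raise ValueError("adjacency matrix must be column-stochastic")


@dataclass(frozen=True)
class ProtocolConfig:
    """Everything needed to replay a run bit-for-bit (given platform numerics)."""

    method: str
    rounds: int
    proxy_arch: ArchSpec
    private_arch: ArchSpec | tuple[ArchSpec, ...] | None = None
    mutual: MutualWeights = MutualWeights(0.5, 0.5)
    dp: DPConfig = DPConfig(clip_C=1.0, sigma=1.0)
    lr: float = 0.001
    rule: str = "adam"
    weight_decay: float = 0.0
    batch_size: int = 32
    seed: int = 0
    delta: float = 1e-5
    budget_epsilon: float | None = None
    local_steps: int | None = None  # override of the epoch-equivalent step count

    def __post_init__(self):
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}, got {self.method!r}")
        if self.rounds < 0:
            raise ValueError(f"rounds must be nonnegative, got {self.rounds}")


def exponential_graph(t: int, K: int) -> CommRound:
    """Time-varying permutation topology with hop offsets 2^0, 2^1, ...

    At round t each client k sends to (k + 2^(t mod m)) mod K, with
    m = floor(log2(K-1)) + 1 offsets in the cycle, so one marked client's
    information reaches all K clients in ceil(log2 K) rounds.
    """
    if K < 2:
        raise ValueError(f"exponential graph needs at least 2 clients, got {K}")
    m = int(math.floor(math.log2(K - 1))) + 1 if K > 2 else 1
    offset = 2 ** (t % m)
    P = np.zeros((K, K))
    for k in range(K):
        P[(k + offset) % K, k] = 1.0
    return CommRound(P=P, t=t)


def pushsum_mix(
    Theta: np.ndarray, w: np.ndarray, round: CommRound
) -> tuple[np.ndarray, np.ndarray]:
    """One gossip round: Theta' = P Theta, w' = P w.

    Column-stochasticity makes both column sums invariants (mass
    conservation): sum_k theta'_k = sum_k theta_k and sum_k w'_k = sum_k w_k.
    """
    Theta = np.asarray(Theta, dtype=np.float64)
    w = np.asarray(w, dtype=np.float64)
    if Theta.shape[0] != round.P.shape[0] or w.shape[0] != round.P.shape[0]:
        raise ValueError("row count of Theta/w must match the adjacency matrix")
    return round.P @ Theta, round.P @ w


def debias(proxy_row: np.ndarray, weight: float) -> np.ndarray:
    """De-biased PushSum estimate theta_k / w_k of the network average."""
    if weight <= 0:
        raise ValueError(f"pushsum weight must be positive, got {weight}")
    return np.asarray(proxy_row, dtype=np.float64) / weight


# ---------------------------------------------------------------------------
# local training epochs


def _epoch_steps(client: ClientState, config: ProtocolConfig) -> tuple[int, float]:
    """(number of steps, Poisson rate) for one epoch-equivalent of training."""
    n = len(client.dataset)
    q = min(config.batch_size / n, 1.0)
    steps = config.local_steps if config.local_steps is not None else math.ceil(n / config.batch_size)
    return steps, q


def _plain_step(
    model: Classifier,
    peer: Classifier | None,
    batch: Batch,
    weight: float,
    opt: OptState | None,
    config: ProtocolConfig,
) -> tuple[Classifier, OptState | None]:
    """Ordinary (non-private) step on the mean mixed gradient."""
    grad = mixed_per_example_grads(model, peer, batch, weight).mean(axis=0)
    params, opt = apply_update(
        model.params, grad, opt, rule=config.rule, lr=config.lr,
        weight_decay=config.weight_decay,
    )
    return Classifier(model.arch, params, dict(model.layout)), opt


def _train_epoch_single(
    client: ClientState, config: ProtocolConfig, rng: np.random.Generator
) -> None:
    """One epoch of DP-SGD on the client's single model (CE loss only)."""
    steps, q = _epoch_steps(client, config)
    for _ in range(steps):
        batch = poisson_sample(client.dataset, q, rng)
        if batch is None:
            continue  # empty Poisson draw: no update, no receipt
        client.proxy, client.proxy_opt, receipt = dp_step(
            client.proxy, None, batch, 0.0, config.dp, client.proxy_opt, rng,
            sampling_rate=q, rule=config.rule, lr=config.lr,
            weight_decay=config.weight_decay,
        )
        client.receipts.append(receipt)
        client.accountant = compose(client.accountant, 1)


def _train_epoch_mutual(
    client: ClientState, config: ProtocolConfig, rng: np.random.Generator
) -> None:
    """One epoch of alternating mutual-learning steps.

    Each step draws one Poisson batch; the private model takes an ordinary
    step on its mixed objective (KL weight alpha), then the proxy takes a DP
    step on its own mixed objective (KL weight beta) on the same batch.
    """
    steps, q = _epoch_steps(client, config)
    for _ in range(steps):
        batch = poisson_sample(client.dataset, q, rng)
        if batch is None:
            continue
        client.private, client.private_opt = _plain_step(
            client.private, client.proxy, batch, config.mutual.alpha,
            client.private_opt, config,
        )
        client.proxy, client.proxy_opt, receipt = dp_step(
            client.proxy, client.private, batch, config.mutual.beta, config.dp,
            client.proxy_opt, rng, sampling_rate=q, rule=config.rule,
            lr=config.lr, weight_decay=config.weight_decay,
        )
        client.receipts.append(receipt)
        client.accountant = compose(client.accountant, 1)


def _check_budgets(clients: list[ClientState], config: ProtocolConfig) -> None:
    if config.budget_epsilon is None:
        return
    for c in clients:
        if not c.dropped and check_budget(c.accountant, config.delta, config.budget_epsilon):
            c.dropped = True


# ---------------------------------------------------------------------------
# communication


def _gossip_replace(
    clients: list[ClientState],
    comm: CommRound,
    transcript: list | None,
) -> None:
    """Mix proxies and weights through P, then aggregate-and-replace.

    Each client's proxy becomes the de-biased received aggregate theta'/w'
    and its PushSum weight resets to 1 (for the permutation protocol this is
    exactly replacement by the received proxy, whose weight is already 1).
    Only proxy parameters and PushSum weights ever cross client boundaries.
    """
    active = [c for c in clients if not c.dropped]
    Theta = np.stack([c.proxy.params for c in active])
    w = np.array([c.pushsum_weight for c in active])
    if transcript is not None:
        rows, cols = np.nonzero(comm.P)
        for r, s in zip(rows, cols):
            transcript.append(
                {
                    "round": comm.t,
                    "from": active[s].id,
                    "to": active[r].id,
                    "payload": ["proxy_params", "pushsum_weight"],
                }
            )
    Theta2, w2 = pushsum_mix(Theta, w, comm)
    for i, c in enumerate(active):
        c.proxy = Classifier(c.proxy.arch, debias(Theta2[i], w2[i]), dict(c.proxy.layout))
        c.pushsum_weight = 1.0


# ---------------------------------------------------------------------------
# rounds


def proxyfl_round(
    clients: list[ClientState],
    t: int,
    config: ProtocolConfig,
    rngs: list[np.random.Generator],
    transcript: list | None = None,
) -> list[ClientState]:
    """One full round: mutual train, gossip proxies, aggregate-and-replace.

    Budget-exhausted clients are marked dropped and the permutation is built
    over the remaining clients.  With a single (or single remaining) client
    the communication phase is skipped and the round reduces to local mutual
    learning.
    """
    for c, rng in zip(clients, rngs):
        if not c.dropped:
            _train_epoch_mutual(c, config, rng)
    _check_budgets(clients, config)
    n_active = sum(not c.dropped for c in clients)
    if n_active >= 2:
        _gossip_replace(clients, exponential_graph(t, n_active), transcript)
    return clients


def baseline_round(
    clients: list[ClientState],
    t: int,
    config: ProtocolConfig,
    rngs: list[np.random.Generator],
    transcript: list | None = None,
) -> list[ClientState]:
    """One round of a comparison protocol (see module docstring)."""
    method = config.method
    train = _train_epoch_mutual if method == "fml" else _train_epoch_single
    for c, rng in zip(clients, rngs):
        if not c.dropped:
            train(c, config, rng)
    _check_budgets(clients, config)
    active = [c for c in clients if not c.dropped]
    if method in ("regular", "joint") or len(active) < 2:
        return clients
    if method in ("fedavg", "fml"):
        # central averaging of the shared-architecture models
        for c in active[1:]:
            if not c.proxy.arch.compatible_with(active[0].proxy.arch):
                raise ValueError("parameter averaging requires identical architectures")
        mean = np.mean([c.proxy.params for c in active], axis=0)
        if transcript is not None:
            for c in active:
                transcript.append(
                    {"round": t, "from": c.id, "to": "server", "payload": ["proxy_params"]}
                )
        for c in active:
            c.proxy = Classifier(c.proxy.arch, mean.copy(), dict(c.proxy.layout))
    elif method == "avgpush":
        _gossip_replace(active, exponential_graph(t, len(active)), transcript)
    elif method == "cwt":
        # cyclic model passing: client k receives the model of client k-1
        K = len(active)
        P = np.zeros((K, K))
        for k in range(K):
            P[(k + 1) % K, k] = 1.0
        _gossip_replace(active, CommRound(P=P, t=t), transcript)
    return clients


# ---------------------------------------------------------------------------
# full protocol driver


def _init_clients(
    config: ProtocolConfig, datasets: list[LabelledDataset]
) -> list[ClientState]:
    """Shared-architecture models start from a common seed across clients so
    that parameter averaging is meaningful; private models use per-client
    seeds."""
    ss = np.random.SeedSequence(config.seed)
    shared_seed = int(ss.generate_state(1)[0] % (2 ** 31))
    private_seeds = [int(s % (2 ** 31)) for s in ss.generate_state(len(datasets) + 1)[1:]]
    clients = []
    for k, ds in enumerate(datasets):
        q = min(config.batch_size / len(ds), 1.0)
        acct = AccountantState(q=q, sigma=config.dp.sigma)
        proxy = init_classifier(config.proxy_arch, shared_seed)
        private = None
        if config.method in TWO_MODEL_METHODS:
            arch = config.private_arch if config.private_arch is not None else config.proxy_arch
            if isinstance(arch, (list, tuple)):
                arch = arch[k % len(arch)]
            private = init_classifier(arch, private_seeds[k])
        clients.append(
            ClientState(id=k, proxy=proxy, private=private, dataset=ds, accountant=acct)
        )
    return clients


def _evaluate_clients(
    clients: list[ClientState],
    test_set: LabelledDataset,
    config: ProtocolConfig,
    t: int,
    rows: list,
) -> None:
    for c in clients:
        eps = to_epsilon(c.accountant, config.delta).epsilon if c.accountant.steps else 0.0
        models = (
            {"private": c.private, "proxy": c.proxy}
            if config.method in TWO_MODEL_METHODS
            else {"model": c.proxy}
        )
        for name, model in models.items():
            acc, macro = evaluate(model, test_set)
            rows.append(
                {
                    "round": t,
                    "client": c.id,
                    "model": name,
                    "accuracy": acc,
                    "macro_accuracy": macro,
                    "epsilon": eps,
                    "dropped": c.dropped,
                }
            )


def run_protocol(
    config: ProtocolConfig,
    datasets: list[LabelledDataset],
    test_set: LabelledDataset,
    transcript: list | None = None,
) -> tuple[pd.DataFrame, list[ClientState]]:
    """Run a protocol end to end; fully reproducible from (config, seed).

    ``joint`` pools all client datasets into a single client.  Returns the
    per-round per-client metrics table (round -1 rows are the initial
    models) and the final client states, whose accountants and receipts
    carry the privacy ledgers.
    """
    if config.method == "joint":
        pooled = LabelledDataset(
            np.concatenate([d.x for d in datasets]),
            np.concatenate([d.y for d in datasets]),
            datasets[0].class_count,
        )
        datasets = [pooled]
    clients = _init_clients(config, datasets)
    ss = np.random.SeedSequence((config.seed, 0xD1CE))
    rngs = [np.random.default_rng(s) for s in ss.spawn(len(clients))]
    round_fn = proxyfl_round if config.method == "proxyfl" else baseline_round

    rows: list[dict] = []
    _evaluate_clients(clients, test_set, config, -1, rows)
    for t in range(config.rounds):
        try:
            clients = round_fn(clients, t, config, rngs, transcript)
        except Exception as err:
            raise RuntimeError(f"round {t} ({config.method}) failed: {err}") from err
        _evaluate_clients(clients, test_set, config, t, rows)
    return pd.DataFrame(rows), clients
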