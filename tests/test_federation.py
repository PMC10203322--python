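"""Topology, PushSum gossip, round structure, and the comparison protocols."""

import numpy as np
import pandas as pd
import pytest

from proxyfl.data import LabelledDataset, make_synthetic
from proxyfl.dp import DPConfig
from proxyfl.federation import (
    ClientState,
    CommRound,
    ProtocolConfig,
    baseline_round,
    debias,
    exponential_graph,
    proxyfl_round,
    pushsum_mix,
    run_protocol,
)
from proxyfl.nn import ArchSpec, init_classifier
from proxyfl.objectives import MutualWeights, mixed_per_example_grads
from proxyfl.nn import apply_update


ARCH = ArchSpec("mlp", (6,), (8,), 4)


def small_task(seed=0, K=4, n_per_client=40):
    pool = make_synthetic(4, 6, K * n_per_client // 2 + 60, class_separation=4.0, seed=seed)
    test = pool.subset(np.arange(80))
    train = pool.subset(np.arange(80, len(pool)))
    sizes = np.full(K, n_per_client)
    cuts = np.concatenate([[0], np.cumsum(sizes)])
    datasets = [train.subset(np.arange(cuts[i], cuts[i + 1])) for i in range(K)]
    return datasets, test


def config(method="proxyfl", rounds=2, **kw):
    defaults = dict(
        method=method,
        rounds=rounds,
        proxy_arch=ARCH,
        private_arch=ARCH,
        mutual=MutualWeights(0.5, 0.5),
        dp=DPConfig(clip_C=1.0, sigma=1.0),
        batch_size=8,
        seed=0,
    )
    defaults.update(kw)
    return ProtocolConfig(**defaults)


class TestExponentialGraph:
    def test_first_round_receives_from_previous_neighbor(self):
        comm = exponential_graph(0, 8)
        for k in range(8):
            assert comm.P[k, (k - 1) % 8] == 1.0
        assert comm.P.sum() == 8

    def test_permutation_every_round(self):
        for K in (2, 5, 8, 12):
            for t in range(10):
                P = exponential_graph(t, K).P
                assert np.array_equal(P.sum(axis=0), np.ones(K))
                assert np.array_equal(P.sum(axis=1), np.ones(K))

    def test_full_dissemination_in_log2_rounds_for_k8(self):
        """Information from any single client reaches all 8 in exactly 3 rounds."""
        for start in range(8):
            have = np.zeros(8)
            have[start] = 1.0
            for t in range(3):
                have = np.minimum(exponential_graph(t, 8).P @ have + have, 1.0)
            assert have.sum() == 8
        # and strictly fewer rounds do not suffice
        have = np.zeros(8)
        have[0] = 1.0
        for t in range(2):
            have = np.minimum(exponential_graph(t, 8).P @ have + have, 1.0)
        assert have.sum() < 8

    def test_non_power_of_two_still_disseminates(self):
        K = 5
        have = np.zeros(K)
        have[2] = 1.0
        rounds = 0
        while have.sum() < K and rounds < 30:
            have = np.minimum(exponential_graph(rounds, K).P @ have + have, 1.0)
            rounds += 1
        assert have.sum() == K

    def test_too_few_clients_rejected(self):
        with pytest.raises(ValueError, match="clients"):
            exponential_graph(0, 1)


class TestPushSum:
    def test_identity_matrix_is_noop(self):
        Theta = np.random.default_rng(0).normal(size=(4, 6))
        w = np.ones(4)
        T2, w2 = pushsum_mix(Theta, w, CommRound(np.eye(4), 0))
        assert np.array_equal(T2, Theta) and np.array_equal(w2, w)

    def test_permutation_preserves_multiset_and_mass(self):
        rng = np.random.default_rng(1)
        Theta = rng.normal(size=(5, 7))
        w = rng.uniform(0.5, 2.0, 5)
        comm = exponential_graph(3, 5)
        T2, w2 = pushsum_mix(Theta, w, comm)
        assert np.allclose(sorted(T2.sum(axis=1)), sorted(Theta.sum(axis=1)))
        assert np.allclose(T2.sum(axis=0), Theta.sum(axis=0))
        assert np.isclose(w2.sum(), w.sum())

    def test_uniform_matrix_averages_in_one_shot(self):
        Theta = np.random.default_rng(2).normal(size=(4, 3))
        P = np.full((4, 4), 0.25)
        T2, w2 = pushsum_mix(Theta, np.ones(4), CommRound(P, 0))
        assert np.allclose(T2, Theta.mean(axis=0, keepdims=True))
        assert np.allclose(w2, 1.0)

    def test_non_column_stochastic_rejected(self):
        P = np.eye(3)
        P[0, 0] = 0.5
        with pytest.raises(ValueError, match="column-stochastic"):
            CommRound(P, 0)

    def test_mass_conserved_over_many_rounds(self):
        rng = np.random.default_rng(3)
        Theta = rng.normal(size=(5, 8))
        w = np.ones(5)
        s_theta, s_w = Theta.sum(axis=0), w.sum()
        P = _irreducible_matrix()
        for t in range(50):
            Theta, w = pushsum_mix(Theta, w, CommRound(P, t))
            assert np.allclose(Theta.sum(axis=0), s_theta, atol=1e-10)
            assert np.isclose(w.sum(), s_w, atol=1e-12)


def _irreducible_matrix():
    """A fixed 5-client column-stochastic, irreducible, aperiodic matrix."""
    P = np.array(
        [
            [0.5, 0.0, 0.0, 0.0, 0.5],
            [0.5, 0.4, 0.0, 0.0, 0.0],
            [0.0, 0.6, 0.3, 0.0, 0.0],
            [0.0, 0.0, 0.7, 0.2, 0.0],
            [0.0, 0.0, 0.0, 0.8, 0.5],
        ]
    )
    assert np.allclose(P.sum(axis=0), 1.0)
    return P


class TestDebias:
    def test_unit_weight_is_identity(self):
        row = np.arange(4.0)
        assert np.array_equal(debias(row, 1.0), row)

    def test_homogeneity(self):
        row = np.random.default_rng(0).normal(size=6)
        assert np.allclose(debias(3.0 * row, 3.0 * 2.0), debias(row, 2.0))

    def test_nonpositive_weight_rejected(self):
        with pytest.raises(ValueError, match="weight"):
            debias(np.ones(3), 0.0)

    def test_communicate_only_mixing_converges_to_initial_mean(self):
        """With a fixed irreducible aperiodic column-stochastic matrix, the
        de-biased values theta_k/w_k all converge to the initial average —
        the power-iteration limit pi 1^T de-biased by w = K pi."""
        rng = np.random.default_rng(4)
        Theta = rng.normal(size=(5, 10))
        target = Theta.mean(axis=0)
        w = np.ones(5)
        P = _irreducible_matrix()
        for t in range(400):
            Theta, w = pushsum_mix(Theta, w, CommRound(P, t))
        debiased = np.stack([debias(Theta[k], w[k]) for k in range(5)])
        assert np.abs(debiased - target).max() < 1e-6


class TestRounds:
    def test_single_client_round_reduces_to_local_mutual_learning(self):
        datasets, test = small_task(K=1)
        cfg = config(rounds=1)
        metrics, clients = run_protocol(cfg, datasets, test)
        assert len(clients) == 1 and clients[0].accountant.steps > 0

    def test_degenerate_dp_and_identity_comm_equal_plain_mutual_learning(self):
        """sigma=0, huge clip, no gossip: the round is plain alternating
        mutual learning, reproducible by an explicit step loop."""
        datasets, test = small_task(K=1)
        cfg = config(rounds=1, dp=DPConfig(clip_C=1e9, sigma=0.0), rule="sgd", lr=0.05,
                     batch_size=len(datasets[0]))  # q=1: deterministic batches
        _, clients = run_protocol(cfg, datasets, test)

        # manual replay: same initial models, same full-dataset batch each step
        from proxyfl.nn import Batch
        from proxyfl.federation import _init_clients

        manual = _init_clients(cfg, datasets)[0]
        batch = Batch(datasets[0].x, datasets[0].y)
        private, proxy = manual.private, manual.proxy
        for _ in range(1):  # ceil(N/B) = 1 step at q = 1
            g = mixed_per_example_grads(private, proxy, batch, 0.5).mean(axis=0)
            p, _ = apply_update(private.params, g, None, "sgd", lr=0.05)
            private = type(private)(private.arch, p, dict(private.layout))
            g = mixed_per_example_grads(proxy, private, batch, 0.5).mean(axis=0)
            p, _ = apply_update(proxy.params, g, None, "sgd", lr=0.05)
            proxy = type(proxy)(proxy.arch, p, dict(proxy.layout))
        assert np.allclose(clients[0].private.params, private.params, atol=1e-12)
        assert np.allclose(clients[0].proxy.params, proxy.params, atol=1e-12)

    def test_round_replay_is_bit_identical(self):
        datasets, test = small_task(K=8, n_per_client=24)

        def run():
            metrics, clients = run_protocol(config(rounds=2), datasets, test)
            return np.concatenate([c.proxy.params for c in clients])

        assert np.array_equal(run(), run())

    def test_receipt_count_matches_accountant_steps(self):
        datasets, test = small_task(K=3)
        _, clients = run_protocol(config(rounds=2), datasets, test)
        for c in clients:
            assert len(c.receipts) == c.accountant.steps > 0

    def test_messages_contain_only_proxy_payloads(self):
        """Private-model parameters never cross client boundaries."""
        datasets, test = small_task(K=4)
        transcript = []
        run_protocol(config(rounds=2), datasets, test, transcript=transcript)
        assert transcript
        for msg in transcript:
            assert set(msg["payload"]) <= {"proxy_params", "pushsum_weight"}


class TestBaselines:
    def test_fedavg_with_zero_local_steps_is_fixed_point(self):
        """Identical initial models and no training: averaging changes nothing."""
        datasets, test = small_task(K=4)
        cfg = config(method="fedavg", rounds=1, local_steps=0)
        _, clients = run_protocol(cfg, datasets, test)
        ref = clients[0].proxy.params
        for c in clients[1:]:
            assert np.allclose(c.proxy.params, ref, atol=1e-15)

    def test_cwt_cycle_returns_models_to_owner(self):
        """Three passes of cyclic model passing over three clients with no
        training restore every (distinct) model to its owner."""
        from proxyfl.federation import _init_clients

        datasets, test = small_task(K=3)
        cfg = config(method="cwt", rounds=3, local_steps=0)
        clients = _init_clients(cfg, datasets)
        for k, c in enumerate(clients):  # make the three models distinguishable
            c.proxy = init_classifier(ARCH, seed=100 + k)
        originals = [c.proxy.params.copy() for c in clients]
        rngs = [np.random.default_rng(s) for s in range(3)]
        for t in range(3):
            baseline_round(clients, t, cfg, rngs)
        mid = [c.proxy.params.copy() for c in clients]
        for c, orig in zip(clients, originals):
            assert np.array_equal(c.proxy.params, orig)
        # and after a single round they were someone else's
        clients2 = _init_clients(cfg, datasets)
        for k, c in enumerate(clients2):
            c.proxy = init_classifier(ARCH, seed=100 + k)
        baseline_round(clients2, 0, cfg, rngs)
        assert np.array_equal(clients2[1].proxy.params, originals[0])

    def test_avgpush_uniform_matrix_equals_central_mean(self):
        """One PushSum round with the all-1/K matrix reproduces the central
        average exactly — the algebraic bridge between avgpush and fedavg."""
        rng = np.random.default_rng(0)
        models = [init_classifier(ARCH, s) for s in range(4)]
        Theta = np.stack([m.params for m in models])
        P = np.full((4, 4), 0.25)
        T2, w2 = pushsum_mix(Theta, np.ones(4), CommRound(P, 0))
        central = Theta.mean(axis=0)
        for k in range(4):
            assert np.allclose(debias(T2[k], w2[k]), central, atol=1e-10)

    @pytest.mark.parametrize("method", ["fedavg", "avgpush", "cwt", "fml", "regular", "joint"])
    def test_each_baseline_runs_and_logs_metrics(self, method):
        datasets, test = small_task(K=3, n_per_client=24)
        cfg = config(method=method, rounds=1)
        metrics, clients = run_protocol(cfg, datasets, test)
        assert (metrics["round"] == 0).any()
        assert metrics["accuracy"].between(0, 1).all()
        expected_models = {"private", "proxy"} if method == "fml" else {"model"}
        assert set(metrics["model"]) == expected_models

    def test_rounds_zero_reports_initial_models_only(self):
        datasets, test = small_task(K=2)
        metrics, _ = run_protocol(config(rounds=0), datasets, test)
        assert set(metrics["round"]) == {-1}

    def test_architecture_mismatch_rejected_for_averaging(self):
        datasets, test = small_task(K=2)
        other = ArchSpec("mlp", (6,), (12,), 4)
        cfg = config(method="fedavg", rounds=1)
        # force one client onto a different architecture
        from proxyfl.federation import _init_clients

        clients = _init_clients(cfg, datasets)
        clients[1].proxy = init_classifier(other, 0)
        rngs = [np.random.default_rng(s) for s in range(2)]
        with pytest.raises(ValueError, match="identical architectures"):
            baseline_round(clients, 0, cfg, rngs)


class TestBudgetDropout:
    def test_client_drops_when_budget_reached(self):
        datasets, test = small_task(K=3)
        cfg = config(rounds=3, budget_epsilon=1e-4)  # exhausted after round 1
        metrics, clients = run_protocol(cfg, datasets, test)
        assert all(c.dropped for c in clients)
        steps_after_round1 = [c.accountant.steps for c in clients]
        # no further privacy spent once dropped
        cfg2 = config(rounds=1, budget_epsilon=1e-4)
        _, clients2 = run_protocol(cfg2, datasets, test)
        assert steps_after_round1 == [c.accountant.steps for c in clients2]
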