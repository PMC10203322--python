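# Methods

## Problem setting and model

K clients each hold a private labelled dataset drawn from their own local
distribution; the goal is for every client to end up with a model that
generalises to the pooled distribution, without sharing data, without a
central server, and with a quantitative (ε, δ)-DP guarantee on everything a
client releases. Each client keeps a private classifier f_φ (any
architecture; never transmitted; trained noise-free) and a proxy classifier
h_θ (a common architecture across clients; the only object transmitted;
trained with DP-SGD).

Training couples the pair by deep mutual learning. With α, β ∈ (0, 1):

* private objective: (1−α)·mean CE[f(x)‖y] + α·mean KL[f(x)‖h(x)]
* proxy objective: (1−β)·mean CE[h(x)‖y] + β·mean KL[h(x)‖f(x)]

The peer's predictions are constants in each objective (no gradient flows
into the peer). This is the standard mutual-learning convention and is what
makes the alternating update scheme — one private step, then one proxy step,
on the same batch — well defined. Per step, one Poisson-subsampled batch is
drawn (each example included independently with probability q = B/N, B the
nominal batch size); the same batch serves both the CE and KL terms and both
models' steps. An empty Poisson draw is skipped entirely: no update, no
privacy charge.

The KL gradient with respect to the model's logits has the closed form
p_j·(a_j − Σ_c p_c a_c) with a = log p − log q_peer, which the backprop uses
directly. Probabilities are floored at 1e-12 inside logarithms; this is
numerical safety only and never measurably alters a loss.

## Differentially private proxy updates

The proxy's per-example gradients g_i are clipped to the L2 ball of radius
C (g_i scaled by 1/max(1, ‖g_i‖₂/C) — the standard DP-SGD clipping, under
which replacing one example moves the clipped sum by at most C), summed,
noised with N(0, σ²C²I), and divided by the *realized* batch size.
Accounting, by contrast, is done at the sampling-rate level (q), which is
how the subsampled-Gaussian analysis is stated; the realized-B division
affects only the optimizer's effective step size. DP-Adam means feeding the
privatized mean gradient into an ordinary Adam update — post-processing
cannot weaken the guarantee, so the moments need no extra noise.

Every noised release emits exactly one step receipt (q, σ, 1 step); privacy
can only be spent through receipts, and the DP step refuses to run when DP
is disabled, so private models cannot pass through the mechanism by
accident. Receipts can be persisted as JSON-lines ledgers and replayed into
an accountant state.

## Privacy accounting

Each release is a Poisson-subsampled Gaussian mechanism. Its Rényi
divergence bound at order α is computed exactly:

* integer α: the binomial-expansion sum over i of
  C(α,i) q^i (1−q)^(α−i) exp((i²−i)/2σ²), evaluated in log space;
* fractional α: the two-term erfc decomposition of the defining integral
  (the same computation contemporary accountants use — a direct evaluation,
  not an interpolation);
* q = 1 reduces to the unsampled closed form α/(2σ²); q = 0 is free;
  divergent regimes (σ = 0) return +∞ rather than raising.

The test suite cross-checks this path against an independent oracle:
adaptive quadrature (scipy.integrate.quad) of the mixture integral
E_{x∼N(0,σ²)}[((1−q) + q·e^{(2x−1)/2σ²})^α] on a log-space integrand.
Integer orders agree to better than 1e-6 relative; fractional orders are a
tight upper bound within 1%.

Bounds compose additively over steps. Training for E epochs at batch size B
on N examples is accounted as E·⌈N/B⌉ steps at rate q = B/N ("a number of
gradient steps equivalent to one epoch" under Poisson sampling with expected
batch size B).

Conversion to (ε, δ) minimises over a grid of orders — fractional 1.1–10.9
in steps of 0.1, integers 11–63, then {128, 256, 512}; dense enough that the
minimum is stable well below 1%. The default conversion is the improved
variant ε = rdp + log((α−1)/α) − (log δ + log α)/(α−1). We verified
numerically that the classical conversion ε = rdp + log(1/δ)/(α−1)
(available as `conversion="basic"`) is uniformly ~15–20% looser at these
scales and does not reproduce the reference per-client guarantees, while the
improved conversion lands within 1.5% of all five; the improved variant is
therefore the default and is what DP training libraries report in practice.

Budget tracking is per client: each client's accountant converts to ε after
every training epoch, and a client whose prespecified budget is reached
drops out of the protocol; the communication permutation is then rebuilt
over the remaining clients.

## Communication

A communication round is a column-stochastic matrix P (column sums 1 ⇒ the
mass each node sends is conserved; asymmetry and time variation allowed).
Gossip is PushSum: Θ ← PΘ and w ← Pw with w initialised to all ones. Under
standard mixing conditions repeated multiplication converges to π1ᵀ, so raw
parameters converge to π_k·Σθ — biased by the stationary distribution — while
w converges to K·π; the ratio θ_k/w_k recovers the exact network average.
Both column-sum invariants are asserted to machine precision in tests.

The default topology is the exponential permutation protocol: at round t
client k sends to (k + 2^(t mod m)) mod K with m = ⌊log₂(K−1)⌋ + 1. Every
round is a permutation (one send, one receive per client), and any single
client's information reaches all K clients in ⌈log₂ K⌉ rounds.

Aggregate-and-replace: after each gossip round the proxy becomes the
de-biased received aggregate θ'/w' and the client's PushSum weight resets
to 1. For permutation matrices w ≡ 1 throughout and this is exactly
replacement by the received proxy; for general column-stochastic matrices it
implements weighted aggregation of the in-neighbours' proxies. General
matrices are supported and tested (the communicate-only convergence test
drives a fixed irreducible, aperiodic 5-client matrix to the initial mean).

Transport is an in-process exchange against the same adjacency-matrix
contract a message-passing deployment would use; an optional transcript
records every message's payload kind, and a test asserts that only proxy
parameters and PushSum weights ever cross client boundaries.

## Protocols

All protocols share the round skeleton *train locally → communicate →
aggregate*; per round each client takes ⌈N_k/B⌉ steps (its own
epoch-equivalent; clients with unequal data take unequal step counts).

* **proxyfl** — mutual learning per client (private plain, proxy DP), then
  exponential-graph PushSum on proxies, aggregate-and-replace.
* **fml** — same local training; proxies are averaged centrally (uniform
  mean; weighting by dataset size is a variant we do not implement since
  uniform is the common convention).
* **fedavg** — single DP-trained model per client, central uniform averaging.
* **avgpush** — like fedavg but decentralized: one PushSum round on the
  exponential graph instead of a server.
* **cwt** — single DP-trained model passed cyclically to the next client.
* **regular** — isolated local DP training; no communication.
* **joint** — all data pooled into one client; single DP-trained model.

Initialisation: all shared-architecture models (proxies, and every
single-model protocol's model) start from one common seed across clients —
parameter averaging across independently initialised networks is
meaningless — while private models use per-client seeds. Seeds for data,
initialisation, Poisson sampling and noise all derive from the run seed via
SeedSequence spawning; replaying a run reproduces parameters bit-exactly.

## Classifier substrate

Models are flat float64 parameter vectors plus a layout map, so clipping,
noising, norms and gossip are architecture-agnostic vector operations. Two
families: an MLP (dense/ReLU; default hidden width 32–128 depending on the
experiment) and a small CNN of strided valid convolutions with ReLU and a
dense head (downsampling via stride rather than pooling layers — fewer
moving parts in per-example backprop). Normalisation layers are deliberately
absent: batch-coupled statistics would break per-example sensitivity, which
the DP analysis requires. Per-example gradients are exact — dense layers via
einsum outer products, convolutions via sliding-window patches — and are
validated against central finite differences (step 1e-5, agreement 1e-3
relative; observed ~1e-10 absolute on small models). Initialisation is
He-scaled normal weights with zero biases, deterministic per (arch, seed).

## Synthetic data

The generator emulates the statistical shell of small image benchmarks:
isotropic Gaussian class blobs in d dimensions (optionally image-shaped),
balanced classes, with class means scaled so their expected pairwise
distance equals `class_separation` (separation 0 ⇒ chance-level task;
separation ≫ noise ⇒ linearly separable). Two partitioners create the
non-IID structure studied here: the major-class scheme (a randomly assigned
class supplies ⌊p_major·n⌋ of each client's n examples — floor rounding so
counts are deterministic — the remainder drawn IID from the other classes,
all without replacement so clients are disjoint; p_major = 1/n_classes is
the IID setting) and Dirichlet allocation (each class split across clients
with Dirichlet(c·1_K) proportions, largest-remainder rounding so class
totals are conserved exactly). The held-out test set is an IID draw from the
pooled distribution, shared by all clients.

What the generator does *not* emulate: pixel correlations, staining/site
heterogeneity, class-conditional covariance structure, label noise, or any
feature hierarchy that would favour convolutional inductive biases.
Passing protocol-ordering tests on blobs therefore shows the *mechanics*
(mutual learning, DP, gossip) produce the expected qualitative ordering
under label skew — not that any method attains a particular accuracy on real
images.

## Scaled-down study conditions

The protocol-ordering experiment uses: 10 classes in 16 dimensions,
separation 4.0, noise 1.0; 8 clients × 300 examples at p_major = 0.8; an
IID test set of 1500; MLPs with one hidden layer of 32; 20 rounds of
epoch-equivalent training at batch size 32; DP with C = 1.0, σ = 1.0;
α = β = 0.5; Adam at lr 0.001; 5 seeds. These sizes were chosen once as a
desk-scale analogue of the benchmark setting (the full-scale experiments
use real image datasets and GPU training and are out of scope); under them
the final mean accuracies order as joint ≥ proxyfl-private ≥ regular with a
wide margin on every seed.

## Numerical choices and edge cases

* Probability floor 1e-12 inside all logarithms.
* Clipping uses 1/max(1, ‖g‖/C) with an exact no-op branch (rows already
  inside the ball are returned bit-identically).
* Accountant order grid as above; per-step RDP vectors memoized per
  (q, σ, orders).
* Ties in argmax evaluation resolve to the lowest class index (numpy
  convention).
* Degenerate inputs are rejected with messages naming the offending field
  (non-positive widths, non-column-stochastic matrices, out-of-range rates,
  non-finite gradients with the example index).
* `sigma = 0` and huge C are admitted so tests can compare the DP path
  against its noiseless oracle; the accountant reports +∞ for σ = 0.

## Known limitations

* No real network transport, stragglers, asynchrony, or adversarial
  (Byzantine) behaviour; communication is simulated in-process.
* No group-DP adjustment for patients contributing multiple examples;
  ε is reported as if every example belonged to a distinct individual.
* The CNN family is minimal (no padding, pooling choices, or normalisation);
  it exists to exercise architecture heterogeneity, not to be competitive.
* Accuracy numbers on the synthetic task are not comparable to published
  image-benchmark accuracies; only orderings and mechanism-level quantities
  (ε, dissemination counts, conservation laws) are meaningful.
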