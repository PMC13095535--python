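"""The three parameterised models and the stochastic masking step.

* **Actor** — a simple self-attention network over the feature positions
  that emits a per-instance, per-feature selection probability. Bernoulli
  sampling of those probabilities yields a binary mask; the Hadamard
  product with the feature vector zeroes out the unselected features.
* **Critic** — the prediction network: an input linear layer, three
  self-attention blocks (attention, SiLU, linear, dropout) at hidden width
  64, and a sigmoid output giving the sepsis risk from the *masked*
  features only.
* **Baseline** — a temporal convolutional network (causal dilated
  convolutions in residual blocks, pooled three times) that embeds the raw
  monitoring series, concatenated with the static+statistical block and
  passed through a fully connected head. It sees everything the Critic
  does *plus* the raw time series, which makes its loss the natural
  benchmark for the reinforcement reward.

Both the selector and the predictor can be swapped for plain feed-forward
networks (hidden width 100) for ablation studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .autodiff import Parameter, Tensor, concat

NetworkKind = Literal["attention", "feedforward"]


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int,
            shape: tuple[int, ...] | None = None) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape or (fan_in, fan_out))


class Linear:
    def __init__(self, rng: np.random.Generator, n_in: int, n_out: int):
        self.W = Parameter(_glorot(rng, n_in, n_out))
        self.b = Parameter(np.zeros(n_out))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b

    def parameters(self) -> list[Parameter]:
        return [self.W, self.b]


class SimpleSelfAttention:
    """Single-head self-attention over the positions of a feature vector.

    Query/key/value are width-to-width linear maps of the input. The
    scaled query-key product is softmax-normalised across the ``width``
    positions and gates the value vector element-wise; a residual
    connection preserves the input:

        a = softmax(q * k / sqrt(w)),   out = a * v + x.

    The gating (rather than a full position-by-position mixing matrix)
    keeps the attention logits rank-stable, which matters when the input
    is stochastically masked: a mixing-matrix variant built from the same
    scalar tokens trains erratically there, while this form is robust.
    """

    def __init__(self, rng: np.random.Generator, width: int):
        self.q = Linear(rng, width, width)
        self.k = Linear(rng, width, width)
        self.v = Linear(rng, width, width)
        self.width = width

    def __call__(self, x: Tensor) -> Tensor:
        w = x.shape[1]
        q, k, v = self.q(x), self.k(x), self.v(x)
        attn = (q * k * (1.0 / np.sqrt(w))).softmax(axis=-1)
        return attn * v + x

    def parameters(self) -> list[Parameter]:
        return self.q.parameters() + self.k.parameters() + self.v.parameters()


class ActorNet:
    """Feature-selection network: attention (or MLP) -> linear -> sigmoid."""

    def __init__(self, rng: np.random.Generator, d: int,
                 kind: NetworkKind = "attention", hidden: int = 100):
        self.kind = kind
        self.d = d
        if kind == "attention":
            self.attn = SimpleSelfAttention(rng, d)
            self.out = Linear(rng, d, d)
            self._mods = [self.attn, self.out]
        elif kind == "feedforward":
            self.fc1 = Linear(rng, d, hidden)
            self.out = Linear(rng, hidden, d)
            self._mods = [self.fc1, self.out]
        else:
            raise ValueError(f"unknown selector kind {kind!r}")

    def logits(self, x: Tensor) -> Tensor:
        """Pre-sigmoid selection scores (used for a numerically safe L_fs)."""
        if x.shape[1] != self.d:
            raise ValueError(f"expected {self.d} features, got {x.shape[1]}")
        h = self.attn(x) if self.kind == "attention" else self.fc1(x).relu()
        return self.out(h)

    def __call__(self, x: Tensor) -> Tensor:
        return self.logits(x).sigmoid()

    def parameters(self) -> list[Parameter]:
        return [p for m in self._mods for p in m.parameters()]


class CriticNet:
    """Prediction network over the masked feature vector."""

    def __init__(self, rng: np.random.Generator, d: int,
                 kind: NetworkKind = "attention", hidden: int = 64,
                 n_blocks: int = 3, dropout: float = 0.5,
                 mlp_hidden: int = 100):
        self.kind = kind
        self.d = d
        self.dropout = dropout
        if kind == "attention":
            self.inp = Linear(rng, d, hidden)
            self.blocks = [(SimpleSelfAttention(rng, hidden),
                            Linear(rng, hidden, hidden))
                           for _ in range(n_blocks)]
            self.out = Linear(rng, hidden, 1)
            self._mods = [self.inp, self.out] + \
                [m for pair in self.blocks for m in pair]
        elif kind == "feedforward":
            self.fc1 = Linear(rng, d, mlp_hidden)
            self.out = Linear(rng, mlp_hidden, 1)
            self._mods = [self.fc1, self.out]
        else:
            raise ValueError(f"unknown predictor kind {kind!r}")

    def logits(self, x: Tensor, *, train_mode: bool = False,
               rng: np.random.Generator | None = None) -> Tensor:
        """Pre-sigmoid risk score (the numerically safe training target)."""
        if x.shape[1] != self.d:
            raise ValueError(f"expected {self.d} features, got {x.shape[1]}")
        if self.kind == "feedforward":
            h = self.fc1(x).relu()
        else:
            h = self.inp(x)
            for attn, lin in self.blocks:
                h = lin(attn(h).silu())
                if train_mode and self.dropout > 0:
                    if rng is None:
                        raise ValueError("train_mode dropout needs an rng")
                    keep = (rng.random(h.shape) >= self.dropout) / \
                        (1.0 - self.dropout)
                    h = h * Tensor(keep)
        z = self.out(h)
        return z.reshape(z.shape[0])

    def __call__(self, x: Tensor, *, train_mode: bool = False,
                 rng: np.random.Generator | None = None) -> Tensor:
        return self.logits(x, train_mode=train_mode, rng=rng).sigmoid()

    def parameters(self) -> list[Parameter]:
        return [p for m in self._mods for p in m.parameters()]


class ResidualBlock:
    """Two causal dilated convolutions with ReLU and a residual connection."""

    def __init__(self, rng: np.random.Generator, c_in: int, c_out: int,
                 kernel: int, dilation: int):
        def conv_w(ci, co, k):
            # He init: the conv stacks are ReLU-activated
            return Parameter(rng.normal(0.0, np.sqrt(2.0 / (ci * k)),
                                        size=(co, ci, k)))
        self.w1 = conv_w(c_in, c_out, kernel)
        self.b1 = Parameter(np.zeros(c_out))
        self.w2 = conv_w(c_out, c_out, kernel)
        self.b2 = Parameter(np.zeros(c_out))
        self.dilation = dilation
        self.proj: tuple[Parameter, Parameter] | None = None
        if c_in != c_out:
            self.proj = (conv_w(c_in, c_out, 1), Parameter(np.zeros(c_out)))

    def __call__(self, x: Tensor) -> Tensor:
        h = x.causal_conv1d(self.w1, self.b1, self.dilation).relu()
        h = h.causal_conv1d(self.w2, self.b2, self.dilation).relu()
        skip = x if self.proj is None else \
            x.causal_conv1d(self.proj[0], self.proj[1], 1)
        return h + skip

    def parameters(self) -> list[Parameter]:
        ps = [self.w1, self.b1, self.w2, self.b2]
        if self.proj is not None:
            ps += list(self.proj)
        return ps


class TCN:
    """Causal dilated temporal convolutional encoder.

    Ten convolution layers arranged as five residual blocks (two layers
    each) with dilations 1, 2, 4, 8, 16; the sequence is average-pooled
    (window 2) after the first three blocks — "convolved and pooled three
    times" — and globally average-pooled at the end, giving a fixed-width
    embedding whatever the series length.
    """

    def __init__(self, rng: np.random.Generator, n_signals: int,
                 channels: int = 32, kernel: int = 3,
                 dilations: tuple[int, ...] = (1, 2, 4, 8, 16),
                 n_pool: int = 3):
        self.blocks = []
        c_in = n_signals
        for d in dilations:
            self.blocks.append(ResidualBlock(rng, c_in, channels, kernel, d))
            c_in = channels
        self.n_pool = n_pool
        self.channels = channels

    def __call__(self, x: Tensor) -> Tensor:
        if x.ndim != 3:
            raise ValueError("expected (batch, signals, time)")
        if x.shape[2] < 1:
            raise ValueError("empty time axis")
        h = x
        for i, block in enumerate(self.blocks):
            h = block(h)
            if i < self.n_pool and h.shape[2] > 1:
                h = h.avg_pool_time(2)
        return h.mean(axis=2)      # (batch, channels)

    def parameters(self) -> list[Parameter]:
        return [p for b in self.blocks for p in b.parameters()]


class BaselineNet:
    """Fully connected head over [static+statistical block | TCN embedding]."""

    def __init__(self, rng: np.random.Generator, d: int, emb: int,
                 hidden: int = 64):
        self.fc1 = Linear(rng, d + emb, hidden)
        self.out = Linear(rng, hidden, 1)

    def logits(self, x_d: Tensor, embedding: Tensor) -> Tensor:
        if x_d.shape[0] != embedding.shape[0]:
            raise ValueError("feature block and embedding misaligned")
        h = self.fc1(concat([x_d, embedding], axis=1)).relu()
        z = self.out(h)
        return z.reshape(z.shape[0])

    def __call__(self, x_d: Tensor, embedding: Tensor) -> Tensor:
        return self.logits(x_d, embedding).sigmoid()

    def parameters(self) -> list[Parameter]:
        return self.fc1.parameters() + self.out.parameters()


@dataclass
class ModelBundle:
    """The Actor, Critic, TCN and baseline head, built from one seed."""

    actor: ActorNet
    critic: CriticNet
    tcn: TCN
    baseline: BaselineNet
    d: int
    config: dict = field(default_factory=dict)

    @classmethod
    def create(cls, d: int = 30, n_signals: int = 5, *, seed: int = 0,
               selector_kind: NetworkKind = "attention",
               predictor_kind: NetworkKind = "attention",
               hidden: int = 64, tcn_channels: int = 32,
               dropout: float = 0.5) -> "ModelBundle":
        rng = np.random.default_rng(seed)
        actor = ActorNet(rng, d, kind=selector_kind)
        critic = CriticNet(rng, d, kind=predictor_kind, hidden=hidden,
                           dropout=dropout)
        tcn = TCN(rng, n_signals, channels=tcn_channels)
        baseline = BaselineNet(rng, d, tcn_channels)
        cfg = dict(d=d, n_signals=n_signals, seed=seed,
                   selector_kind=selector_kind, predictor_kind=predictor_kind,
                   hidden=hidden, tcn_channels=tcn_channels, dropout=dropout)
        return cls(actor, critic, tcn, baseline, d, cfg)

    def parameters(self) -> list[Parameter]:
        return (self.actor.parameters() + self.critic.parameters()
                + self.tcn.parameters() + self.baseline.parameters())

    def actor_parameters(self) -> list[Parameter]:
        return self.actor.parameters()


def sample_mask(S_d: np.ndarray, mode: str = "bernoulli",
                rng: np.random.Generator | None = None) -> np.ndarray:
    """Draw the selection mask from per-feature probabilities.

    ``bernoulli`` (training) samples each entry independently; ``threshold``
    (evaluation) deterministically selects features with probability >= 0.5.
    """
    S = np.asarray(S_d, dtype=float)
    if mode == "bernoulli":
        if rng is None:
            raise ValueError("bernoulli sampling requires an rng")
        return (rng.random(S.shape) < S).astype(float)
    if mode == "threshold":
        return (S >= 0.5).astype(float)
    raise ValueError(f"unknown sampling mode {mode!r}")


def apply_mask(X_d: Tensor | np.ndarray, M: np.ndarray) -> Tensor:
    """Hadamard product X_d * M; unselected features become exactly zero."""
    x = X_d if isinstance(X_d, Tensor) else Tensor(X_d)
    if x.shape != M.shape:
        raise ValueError(f"shape mismatch {x.shape} vs {M.shape}")
    return x * Tensor(M)
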