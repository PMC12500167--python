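"""Mixture-of-experts attention flow blocks.

The MOE-FB model extends the MAF baseline with three ingredients:

* **Contextual feature masking** — a shallow MLP produces a per-sample soft
  mask ``m in (0, 0.5)^d``; each feature is pulled toward the sample mean,
  ``x' = x (1-m) + x_bar m``.  The step is not invertible and carries no
  Jacobian term: it acts as a learnable preprocessor on the density path and
  is skipped when sampling.
* **ActNorm** — a per-feature affine ``y = s x + b`` with exact
  log-determinant ``sum_j log|s_j|``; can be disabled (identity).  When
  enabled, scale and bias are data-dependently initialized from the first
  training batch so that batch is standardized, then trained.
* **MoE attention coupling** — features are split by an alternating binary
  mask into a pass-through set ``x_a`` and a transformed set ``x_b``.  Each
  of E experts runs multi-head self-attention over the ``x_a`` features
  (one token per feature, scalars linearly embedded); a softmax gate mixes
  the experts; scale/shift heads map the aggregate to
  ``z_b = x_b exp(s) + t`` with ``s = tanh(.)`` so the log-determinant
  ``sum_{j in b} s_j`` is bounded by the size of the b-set.

One block is ``[ActNorm, MoECoupling, ActNorm, MAF]``; the full model is the
context mask followed by ``n_blocks`` such blocks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, relu, sigmoid, softmax
from .maf import Flow, MAFLayer

__all__ = [
    "ContextMask",
    "ActNormLayer",
    "MoECouplingLayer",
    "MoEConfig",
    "coupling_split",
    "build_moefb",
]


class ContextMask:
    """Learnable soft interpolation of each feature toward the sample mean.

    ``c = sigmoid(W_m relu(W_c x + b_c) + b_m)``, ``m = 0.5 c``, so every
    masked value stays a convex combination of ``x_j`` and the sample mean.
    """

    def __init__(self, dim: int, hidden: int, rng: np.random.Generator):
        self.dim = dim
        self.hidden = hidden
        self.W_c = Tensor(rng.normal(0.0, 1.0 / np.sqrt(dim), (dim, hidden)),
                          requires_grad=True)
        self.b_c = Tensor(np.zeros(hidden), requires_grad=True)
        self.W_m = Tensor(rng.normal(0.0, 1.0 / np.sqrt(hidden), (hidden, dim)),
                          requires_grad=True)
        self.b_m = Tensor(np.zeros(dim), requires_grad=True)

    def parameters(self):
        return [self.W_c, self.b_c, self.W_m, self.b_m]

    def mask_t(self, x: Tensor) -> Tensor:
        c = sigmoid(relu(x @ self.W_c + self.b_c) @ self.W_m + self.b_m)
        return c * 0.5

    def apply_t(self, x: Tensor) -> Tensor:
        m = self.mask_t(x)
        xbar = x.mean(axis=1, keepdims=True)
        return x * (1.0 - m) + xbar * m

    def apply(self, x: np.ndarray) -> np.ndarray:
        return self.apply_t(Tensor(np.atleast_2d(np.asarray(x, dtype=np.float64)))).data


class ActNormLayer:
    """Per-feature affine normalization with exact log-determinant.

    Disabled -> identity with logdet 0.  Enabled layers start at the
    identity (s=1, b=0, ``initialized=False``) until
    :meth:`initialize_from` standardizes a data batch.
    """

    def __init__(self, dim: int, enabled: bool = True):
        self.dim = dim
        self.enabled = enabled
        self.initialized = False
        self.s = Tensor(np.ones(dim), requires_grad=enabled)
        self.b = Tensor(np.zeros(dim), requires_grad=enabled)

    def parameters(self):
        return [self.s, self.b] if self.enabled else []

    def initialize_from(self, batch: np.ndarray) -> None:
        """Data-dependent init: the given batch maps to zero mean / unit
        variance per feature."""
        if not self.enabled:
            return
        batch = np.atleast_2d(batch)
        mean = batch.mean(axis=0)
        std = batch.std(axis=0)
        std = np.where(std < 1e-8, 1.0, std)
        self.s.data = 1.0 / std
        self.b.data = -mean / std
        self.initialized = True

    def _check(self):
        if self.enabled and np.any(self.s.data == 0.0):
            raise ValueError("ActNorm scale contains an exact zero")

    def forward_t(self, x: Tensor):
        if not self.enabled:
            return x, Tensor(np.zeros(x.shape[0]))
        self._check()
        y = x * self.s + self.b
        # log|s| written as 0.5 log(s^2) to stay differentiable for s<0
        logdet = ((self.s * self.s).log() * 0.5).sum()
        return y, logdet

    def forward(self, x: np.ndarray):
        x = np.atleast_2d(np.asarray(x, dtype=np.float64))
        if not self.enabled:
            return x, np.zeros(x.shape[0])
        self._check()
        y = x * self.s.data + self.b.data
        logdet = float(np.sum(np.log(np.abs(self.s.data))))
        return y, np.full(x.shape[0], logdet)

    def inverse(self, y: np.ndarray) -> np.ndarray:
        y = np.atleast_2d(np.asarray(y, dtype=np.float64))
        if not self.enabled:
            return y
        self._check()
        return (y - self.b.data) / self.s.data


def coupling_split(x: np.ndarray, M: np.ndarray):
    """Split ``x`` into the pass-through set ``x_a = x * M`` and the
    transformed set ``x_b = x * (1 - M)``; both keep full length d."""
    x = np.asarray(x, dtype=np.float64)
    M = np.asarray(M, dtype=np.float64)
    if x.shape[-1] != M.shape[-1]:
        raise ValueError(f"mask length {M.shape[-1]} != feature count {x.shape[-1]}")
    return x * M, x * (1.0 - M)


class MoECouplingLayer:
    """Affine coupling whose scale/shift are produced by a gated mixture of
    multi-head attention experts over the pass-through features."""

    def __init__(self, dim: int, n_experts: int = 4, n_heads: int = 10,
                 embed_dim: int = 20, gate_hidden: int = 64,
                 rng: np.random.Generator | None = None, mask_parity: int = 0):
        if dim < 2:
            raise ValueError("coupling needs dim >= 2 so both partitions are non-empty")
        if embed_dim % n_heads != 0:
            raise ValueError("embed_dim must be divisible by n_heads")
        rng = np.random.default_rng(0) if rng is None else rng
        self.dim = dim
        self.n_experts = n_experts
        self.n_heads = n_heads
        self.embed_dim = embed_dim
        self.head_dim = embed_dim // n_heads

        # alternating binary partition mask; parity selects which set leads
        self.M = ((np.arange(dim) + mask_parity) % 2 == 0).astype(np.float64)
        self.a_idx = np.flatnonzero(self.M == 1.0)
        self.b_idx = np.flatnonzero(self.M == 0.0)
        k = len(self.a_idx)
        # constant selector: full-length x_a -> a-set token values (d, k)
        self._select_a = np.zeros((dim, k))
        self._select_a[self.a_idx, np.arange(k)] = 1.0

        def w(shape, scale):
            return Tensor(rng.normal(0.0, scale, shape), requires_grad=True)

        e = embed_dim
        self.W_embed = w((1, e), 1.0)
        self.b_embed = Tensor(np.zeros(e), requires_grad=True)
        self.experts = []
        for _ in range(n_experts):
            self.experts.append({
                "Wq": w((e, e), 1.0 / np.sqrt(e)),
                "Wk": w((e, e), 1.0 / np.sqrt(e)),
                "Wv": w((e, e), 1.0 / np.sqrt(e)),
                "Wo": w((e, e), 1.0 / np.sqrt(e)),
                "Wp": w((e, 1), 1.0 / np.sqrt(e)),
                "bp": Tensor(np.zeros(1), requires_grad=True),
            })
        self.U_g = w((dim, gate_hidden), 1.0 / np.sqrt(dim))
        self.W_g = Tensor(np.zeros((gate_hidden, n_experts)), requires_grad=True)
        self.b_g = Tensor(np.zeros(n_experts), requires_grad=True)
        # zero-initialized heads -> the coupling starts as the identity
        self.W_s = Tensor(np.zeros((k, dim)), requires_grad=True)
        self.b_s = Tensor(np.zeros(dim), requires_grad=True)
        self.W_t = Tensor(np.zeros((k, dim)), requires_grad=True)
        self.b_t = Tensor(np.zeros(dim), requires_grad=True)

    def parameters(self):
        params = [self.W_embed, self.b_embed, self.U_g, self.W_g, self.b_g,
                  self.W_s, self.b_s, self.W_t, self.b_t]
        for ex in self.experts:
            params.extend(ex.values())
        return params

    # ----------------------------------------------------------- internals
    def _mha_t(self, tokens: Tensor, ex) -> Tensor:
        """Multi-head self-attention over (n, k, e) tokens for one expert."""
        n, k, e = tokens.shape
        h, dh = self.n_heads, self.head_dim

        def heads(t):
            return t.reshape(n, k, h, dh).transpose((0, 2, 1, 3))

        q, kk, v = heads(tokens @ ex["Wq"]), heads(tokens @ ex["Wk"]), heads(tokens @ ex["Wv"])
        scores = (q @ kk.transpose((0, 1, 3, 2))) * (1.0 / np.sqrt(dh))
        att = softmax(scores, axis=-1) @ v                      # (n, h, k, dh)
        merged = att.transpose((0, 2, 1, 3)).reshape(n, k, e) @ ex["Wo"]
        return (merged @ ex["Wp"] + ex["bp"]).reshape(n, k)

    def moe_attention_t(self, x_a: Tensor) -> Tensor:
        """Gated expert aggregate ``h = sum_e g_e h^(e)`` at a-set positions.

        ``x_a`` is full length d with zeros off-partition (as produced by
        :func:`coupling_split`)."""
        n = x_a.shape[0]
        tokens = (x_a @ self._select_a).reshape(n, len(self.a_idx), 1) \
            @ self.W_embed + self.b_embed
        g = softmax(relu(x_a @ self.U_g) @ self.W_g + self.b_g, axis=-1)   # (n, E)
        agg = None
        for e_i, ex in enumerate(self.experts):
            onehot = np.zeros((self.n_experts, 1))
            onehot[e_i, 0] = 1.0
            weight = g @ onehot                                  # (n, 1)
            term = self._mha_t(tokens, ex) * weight
            agg = term if agg is None else agg + term
        return agg

    def gate_weights(self, x_a: np.ndarray) -> np.ndarray:
        """Softmax gate over experts for a (n, d) zero-padded a-set input."""
        g = softmax(relu(Tensor(np.atleast_2d(x_a)) @ self.U_g) @ self.W_g + self.b_g,
                    axis=-1)
        return g.data

    def _scale_shift_t(self, x_a: Tensor):
        h = self.moe_attention_t(x_a)
        one_minus_M = 1.0 - self.M
        s = (h @ self.W_s + self.b_s).tanh() * one_minus_M
        t = (h @ self.W_t + self.b_t) * one_minus_M
        return s, t

    def scale_shift(self, x_a: np.ndarray):
        s, t = self._scale_shift_t(Tensor(np.atleast_2d(np.asarray(x_a, dtype=np.float64))))
        return s.data, t.data

    # ------------------------------------------------------------- flow API
    def forward_t(self, x: Tensor):
        x_a = x * self.M
        x_b = x * (1.0 - self.M)
        s, t = self._scale_shift_t(x_a)
        z = x_a + x_b * s.exp() + t
        return z, s.sum(axis=1)

    def forward(self, x: np.ndarray):
        x = np.atleast_2d(np.asarray(x, dtype=np.float64))
        x_a, x_b = coupling_split(x, self.M)
        s, t = self.scale_shift(x_a)
        z = x_a + x_b * np.exp(s) + t
        return z, s.sum(axis=1)

    def inverse(self, z: np.ndarray) -> np.ndarray:
        z = np.atleast_2d(np.asarray(z, dtype=np.float64))
        z_a, z_b = coupling_split(z, self.M)
        s, t = self.scale_shift(z_a)
        return z_a + (z_b - t) * np.exp(-s)


@dataclass
class MoEConfig:
    """Architecture knobs for the MOE-FB model."""

    n_blocks: int = 1
    n_experts: int = 4
    n_heads: int = 10
    embed_dim: int = 20
    gate_hidden: int = 64
    mask_hidden: int = 64
    hidden_features: int = 1024
    actnorm: bool = True
    context_mask: bool = True
    seed: int = 0


def build_moefb(d: int, config: MoEConfig | None = None) -> Flow:
    """Assemble the MOE-FB flow: context mask front end plus ``n_blocks`` of
    ``[ActNorm, MoECoupling, ActNorm, MAF]`` over a standard-normal base."""
    if d < 2:
        raise ValueError("MOE-FB requires d >= 2 (coupling needs both partitions)")
    config = config or MoEConfig()
    rng = np.random.default_rng(config.seed)
    mask = ContextMask(d, config.mask_hidden, rng) if config.context_mask else None
    layers = []
    for block in range(config.n_blocks):
        layers.append(ActNormLayer(d, enabled=config.actnorm))
        layers.append(MoECouplingLayer(
            d, n_experts=config.n_experts, n_heads=config.n_heads,
            embed_dim=config.embed_dim, gate_hidden=config.gate_hidden,
            rng=rng, mask_parity=block % 2))
        layers.append(ActNormLayer(d, enabled=config.actnorm))
        layers.append(MAFLayer(d, config.hidden_features, rng))
    return Flow(d, layers, context_mask=mask)
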