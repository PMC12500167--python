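"""Masked affine autoregressive flow (MAF) and the generic flow container.

The flow maps data ``x`` through a chain of invertible layers to a latent
``z`` that is modelled as standard multivariate normal.  Each MAF layer
transforms coordinates as

    z_i = (x_i - mu_i(x_<i)) / sigma_i(x_<i),

where ``mu`` and ``sigma`` come from a single masked MLP conditioner
(MADE-style) whose weight masks guarantee that output ``i`` depends only on
inputs with smaller index.  The Jacobian is triangular, so the
log-determinant is ``-sum_i log sigma_i``.  Positivity of ``sigma`` is
enforced with an exponential link: the conditioner emits ``alpha_i`` and
``sigma_i = exp(alpha_i)``, so the log-determinant is simply ``-sum alpha``.

Density evaluation uses one parallel conditioner pass; inversion (sampling)
runs ``d`` sequential passes, filling one coordinate at a time.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, as_tensor, relu

__all__ = [
    "build_autoregressive_masks",
    "base_log_density",
    "MAFLayer",
    "Permutation",
    "Flow",
    "flow_log_density",
    "nll_loss",
]

_LOG_2PI = float(np.log(2.0 * np.pi))


def build_autoregressive_masks(d: int, hidden_features: int):
    """Binary masks enforcing the autoregressive structure of the conditioner.

    Parameters
    ----------
    d : int
        Number of features.
    hidden_features : int
        Width of the single hidden layer.

    Returns
    -------
    (mask_in, mask_out)
        ``mask_in`` has shape ``(d, hidden)`` for an ``x @ W1`` layout;
        ``mask_out`` has shape ``(hidden, d)`` and applies to each of the two
        conditioner heads (mu and alpha).  Output ``i`` can only be reached
        from inputs ``j < i``: hidden units carry degrees in ``1..d-1``, an
        input connects to hidden units of degree >= its own, and output ``i``
        connects to hidden units of degree < ``i``.
    """
    if d < 1 or hidden_features < 1:
        raise ValueError("d and hidden_features must be positive")
    in_deg = np.arange(1, d + 1)
    hid_deg = (np.arange(hidden_features) % max(d - 1, 1)) + 1
    out_deg = np.arange(1, d + 1)
    mask_in = (hid_deg[None, :] >= in_deg[:, None]).astype(np.float64)
    mask_out = (out_deg[None, :] > hid_deg[:, None]).astype(np.float64)
    return mask_in, mask_out


def base_log_density(z: np.ndarray) -> np.ndarray:
    """Standard-normal log-density, ``-0.5 (||z||^2 + d log 2 pi)`` per row."""
    z = np.atleast_2d(np.asarray(z, dtype=np.float64))
    d = z.shape[1]
    return -0.5 * ((z ** 2).sum(axis=1) + d * _LOG_2PI)


def _base_log_density_t(z: Tensor) -> Tensor:
    d = z.shape[1]
    return (z * z).sum(axis=1) * (-0.5) - 0.5 * d * _LOG_2PI


class MAFLayer:
    """One masked affine autoregressive transform with a one-hidden-layer
    ReLU conditioner.

    The conditioner heads are zero-initialized so a fresh layer is exactly
    the identity transform (mu = 0, sigma = 1).
    """

    def __init__(self, dim: int, hidden_features: int, rng: np.random.Generator):
        if dim < 1:
            raise ValueError("dim must be >= 1")
        self.dim = dim
        self.hidden_features = hidden_features
        self.mask_in, self.mask_out = build_autoregressive_masks(dim, hidden_features)
        self.W1 = Tensor(rng.normal(0.0, 1.0 / np.sqrt(dim), (dim, hidden_features)),
                         requires_grad=True)
        self.b1 = Tensor(np.zeros(hidden_features), requires_grad=True)
        # two heads share the hidden layer: columns [0:d] -> mu, [d:2d] -> alpha
        self.W2 = Tensor(np.zeros((hidden_features, 2 * dim)), requires_grad=True)
        self.b2 = Tensor(np.zeros(2 * dim), requires_grad=True)
        self._mask2 = np.concatenate([self.mask_out, self.mask_out], axis=1)

    def parameters(self):
        return [self.W1, self.b1, self.W2, self.b2]

    # conditioner, autodiff path ------------------------------------------
    def _conditioner_t(self, x: Tensor):
        h = relu(x @ (self.W1 * self.mask_in) + self.b1)
        out = h @ (self.W2 * self._mask2) + self.b2
        return out[:, : self.dim], out[:, self.dim:]

    # conditioner, plain-numpy mirror used by the sequential inverse ------
    def conditioner(self, x: np.ndarray):
        h = np.maximum(x @ (self.W1.data * self.mask_in) + self.b1.data, 0.0)
        out = h @ (self.W2.data * self._mask2) + self.b2.data
        return out[:, : self.dim], out[:, self.dim:]

    def forward_t(self, x: Tensor):
        mu, alpha = self._conditioner_t(x)
        z = (x - mu) * (-alpha).exp()
        logdet = -alpha.sum(axis=1)
        return z, logdet

    def forward(self, x: np.ndarray):
        x = np.atleast_2d(np.asarray(x, dtype=np.float64))
        if not np.all(np.isfinite(x)):
            raise ValueError("non-finite input to MAF forward")
        mu, alpha = self.conditioner(x)
        z = (x - mu) * np.exp(-alpha)
        return z, -alpha.sum(axis=1)

    def inverse(self, z: np.ndarray) -> np.ndarray:
        z = np.atleast_2d(np.asarray(z, dtype=np.float64))
        x = np.zeros_like(z)
        for i in range(self.dim):
            mu, alpha = self.conditioner(x)
            x[:, i] = z[:, i] * np.exp(alpha[:, i]) + mu[:, i]
        return x


class Permutation:
    """Fixed feature permutation; logdet 0.  Used between stacked MAF layers
    so later layers see a different autoregressive ordering."""

    def __init__(self, perm: np.ndarray):
        self.perm = np.asarray(perm, dtype=np.intp)
        self.inv = np.argsort(self.perm)
        self.dim = len(self.perm)

    def parameters(self):
        return []

    def forward_t(self, x: Tensor):
        return x[:, self.perm], Tensor(np.zeros(x.shape[0]))

    def forward(self, x: np.ndarray):
        x = np.atleast_2d(x)
        return x[:, self.perm], np.zeros(x.shape[0])

    def inverse(self, z: np.ndarray) -> np.ndarray:
        return np.atleast_2d(z)[:, self.inv]


class Flow:
    """An ordered chain of invertible layers over a standard-normal base,
    with an optional (non-invertible) context-mask front end.

    The context mask, when present, is applied on the density/training path
    only and contributes nothing to the Jacobian; sampling inverts the
    invertible layers only.
    """

    def __init__(self, dim: int, layers, context_mask=None):
        self.dim = dim
        self.layers = list(layers)
        self.context_mask = context_mask
        self.history: list[float] = []

    def parameters(self):
        params = []
        if self.context_mask is not None:
            params.extend(self.context_mask.parameters())
        for layer in self.layers:
            params.extend(layer.parameters())
        return params

    # density path --------------------------------------------------------
    def _forward_t(self, x: Tensor):
        if self.context_mask is not None:
            x = self.context_mask.apply_t(x)
        total = Tensor(np.zeros(x.shape[0]))
        for layer in self.layers:
            x, ld = layer.forward_t(x)
            total = total + ld
        return x, total

    def log_prob(self, x: np.ndarray) -> np.ndarray:
        """Per-row log-density under the flow (change of variables)."""
        x = np.atleast_2d(np.asarray(x, dtype=np.float64))
        z, logdet = self._forward_t(Tensor(x))
        return base_log_density(z.data) + logdet.data

    def nll_t(self, x: np.ndarray) -> Tensor:
        """Mean negative log-likelihood of a batch, as a graph node."""
        x = np.atleast_2d(np.asarray(x, dtype=np.float64))
        if x.shape[0] == 0:
            raise ValueError("empty batch")
        z, logdet = self._forward_t(Tensor(x))
        return -(_base_log_density_t(z) + logdet).mean()

    # sampling path -------------------------------------------------------
    def sample(self, n: int, seed: int) -> np.ndarray:
        """Draw ``n`` rows by passing base-normal draws through the layer
        inverses in reverse order.  The context mask is never applied here."""
        if n < 1:
            raise ValueError("n must be >= 1")
        rng = np.random.default_rng(seed)
        z = rng.standard_normal((n, self.dim))
        for layer in reversed(self.layers):
            z = layer.inverse(z)
        return z


def flow_log_density(x: np.ndarray, model: Flow) -> np.ndarray:
    """Log-density of ``x`` under ``model`` (base density plus layer
    log-determinants)."""
    return model.log_prob(x)


def nll_loss(batch: np.ndarray, model: Flow) -> float:
    """Mean negative log-likelihood of ``batch`` under ``model``."""
    batch = np.atleast_2d(np.asarray(batch, dtype=np.float64))
    if batch.shape[0] == 0:
        raise ValueError("empty batch")
    return float(-np.mean(model.log_prob(batch)))
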