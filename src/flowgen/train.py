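"""Maximum-likelihood training of flow models.

The objective is the mean negative log-likelihood of the training matrix
under the flow.  Defaults follow the selected setting for the MAF baseline:
a single layer, 1024 hidden features, learning rate 1e-6, 100 iterations
(read as full passes over the data).  The optimizer is Adam by default with
plain SGD selectable; minibatches of 256 rows, full batch when the data is
smaller.  All randomness (parameter init, shuffling, jitter) flows from the
config seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .maf import Flow, MAFLayer, Permutation
from .moe import ActNormLayer, MoEConfig, build_moefb

__all__ = ["TrainConfig", "FlowDivergenceError", "build_maf", "train_flow"]


@dataclass
class TrainConfig:
    """Hyperparameters of a flow fit."""

    n_layers: int = 1
    hidden_features: int = 1024
    learning_rate: float = 1e-6
    n_iterations: int = 100
    batch_size: int = 256
    seed: int = 0
    optimizer: str = "adam"


class FlowDivergenceError(RuntimeError):
    """Raised when the training loss becomes non-finite; carries the loss
    history accumulated up to the failure."""

    def __init__(self, message: str, history: list[float]):
        super().__init__(message)
        self.history = history


class _Adam:
    def __init__(self, params, lr: float, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * p.grad
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * p.grad ** 2
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class _SGD:
    def __init__(self, params, lr: float):
        self.params = params
        self.lr = lr

    def step(self):
        for p in self.params:
            if p.grad is not None:
                p.data -= self.lr * p.grad


def build_maf(d: int, config: TrainConfig) -> Flow:
    """A stack of ``n_layers`` MAF layers; random feature permutations are
    inserted between layers of a multi-layer stack so each layer sees a
    different autoregressive ordering."""
    rng = np.random.default_rng(config.seed)
    layers = []
    for i in range(config.n_layers):
        if i > 0:
            layers.append(Permutation(rng.permutation(d)))
        layers.append(MAFLayer(d, config.hidden_features, rng))
    return Flow(d, layers)


def _make_optimizer(name: str, params, lr: float):
    if name == "adam":
        return _Adam(params, lr)
    if name == "sgd":
        return _SGD(params, lr)
    raise ValueError(f"unknown optimizer {name!r}")


def train_flow(data: np.ndarray, config: TrainConfig | None = None,
               model: Flow | None = None, model_kind: str = "maf",
               moe_config: MoEConfig | None = None) -> Flow:
    """Fit a flow to ``data`` by NLL minimization.

    Parameters
    ----------
    data : (n, d) array
        Training matrix, n >= 2.
    config : TrainConfig
        Optimization hyperparameters; the seed controls initialization,
        jitter and shuffling, making the fit bit-reproducible.
    model : Flow, optional
        Pre-built model to train; otherwise one is built per ``model_kind``
        ("maf" or "moe").
    moe_config : MoEConfig, optional
        Architecture of the MOE-FB model when ``model_kind="moe"``.

    Returns
    -------
    Flow
        The fitted model, with per-epoch mean NLL in ``model.history``.
    """
    config = config or TrainConfig()
    data = np.atleast_2d(np.asarray(data, dtype=np.float64))
    if data.shape[0] < 2:
        raise ValueError("training requires at least 2 rows")
    n, d = data.shape
    rng = np.random.default_rng(config.seed)

    std = data.std(axis=0)
    if np.any(std == 0.0):
        flat = np.flatnonzero(std == 0.0)
        warnings.warn(
            f"{len(flat)} zero-variance feature(s) (e.g. column {flat[0]}); "
            "adding 1e-6 Gaussian jitter before fitting")
        data = data.copy()
        data[:, flat] += rng.normal(0.0, 1e-6, (n, len(flat)))

    if model is None:
        if model_kind == "maf":
            model = build_maf(d, config)
        elif model_kind == "moe":
            mcfg = moe_config or MoEConfig()
            model = build_moefb(d, replace(mcfg, seed=config.seed))
        else:
            raise ValueError(f"unknown model kind {model_kind!r}")

    _init_actnorms(model, data[: min(n, max(config.batch_size, 2))])

    params = model.parameters()
    opt = _make_optimizer(config.optimizer, params, config.learning_rate)
    batch = min(config.batch_size, n)
    model.history = []
    for _ in range(config.n_iterations):
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, batch):
            rows = data[order[start:start + batch]]
            loss = model.nll_t(rows)
            if not np.isfinite(loss.data):
                raise FlowDivergenceError(
                    "training loss became non-finite", model.history)
            loss.backward()
            opt.step()
            epoch_losses.append(float(loss.data))
        model.history.append(float(np.mean(epoch_losses)))
    return model


def _init_actnorms(model: Flow, batch: np.ndarray) -> None:
    """Sequential data-dependent init of enabled ActNorm layers from the
    activations the first training batch produces at each depth."""
    from .autodiff import Tensor

    x = batch
    if model.context_mask is not None:
        x = model.context_mask.apply(x)
    for layer in model.layers:
        if isinstance(layer, ActNormLayer) and layer.enabled and not layer.initialized:
            layer.initialize_from(x)
        if hasattr(layer, "forward"):
            x, _ = layer.forward(x)
        else:  # pragma: no cover - all layers implement forward
            x = layer.forward_t(Tensor(x))[0].data
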