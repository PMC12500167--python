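"""Single-file model checkpoints.

A checkpoint is an ``.npz`` archive carrying a versioned JSON header (layer
layout, config echo, training history) plus one array entry per parameter.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .maf import Flow, MAFLayer, Permutation
from .moe import ActNormLayer, ContextMask, MoECouplingLayer

__all__ = ["save_checkpoint", "load_checkpoint"]

SCHEMA_VERSION = 1


def _layer_state(i: int, layer):
    prefix = f"L{i}."
    if isinstance(layer, MAFLayer):
        meta = {"type": "maf", "dim": layer.dim, "hidden": layer.hidden_features}
        arrays = {prefix + n: getattr(layer, n).data for n in ("W1", "b1", "W2", "b2")}
    elif isinstance(layer, Permutation):
        meta = {"type": "perm"}
        arrays = {prefix + "perm": layer.perm}
    elif isinstance(layer, ActNormLayer):
        meta = {"type": "actnorm", "dim": layer.dim, "enabled": layer.enabled,
                "initialized": layer.initialized}
        arrays = {prefix + "s": layer.s.data, prefix + "b": layer.b.data}
    elif isinstance(layer, MoECouplingLayer):
        meta = {"type": "moe_coupling", "dim": layer.dim,
                "n_experts": layer.n_experts, "n_heads": layer.n_heads,
                "embed_dim": layer.embed_dim,
                "gate_hidden": layer.U_g.data.shape[1],
                "mask_parity": int(1 - layer.M[0])}
        arrays = {prefix + n: getattr(layer, n).data
                  for n in ("W_embed", "b_embed", "U_g", "W_g", "b_g",
                            "W_s", "b_s", "W_t", "b_t")}
        for j, ex in enumerate(layer.experts):
            for n, t in ex.items():
                arrays[f"{prefix}E{j}.{n}"] = t.data
    else:
        raise TypeError(f"cannot checkpoint layer {type(layer).__name__}")
    return meta, arrays


def save_checkpoint(model: Flow, path, config: dict | None = None) -> None:
    """Write ``model`` (and an echo of its training config) to ``path``."""
    metas, arrays = [], {}
    for i, layer in enumerate(model.layers):
        meta, arr = _layer_state(i, layer)
        metas.append(meta)
        arrays.update(arr)
    cm = model.context_mask
    header = {
        "schema": SCHEMA_VERSION,
        "dim": model.dim,
        "config": config or {},
        "history": model.history,
        "layers": metas,
        "context_mask": None if cm is None else {"dim": cm.dim, "hidden": cm.hidden},
    }
    if cm is not None:
        arrays.update({f"CM.{n}": getattr(cm, n).data
                       for n in ("W_c", "b_c", "W_m", "b_m")})
    arrays["__header__"] = np.frombuffer(
        json.dumps(header).encode("utf-8"), dtype=np.uint8)
    np.savez(Path(path), **arrays)


def load_checkpoint(path) -> tuple[Flow, dict]:
    """Rebuild a flow from a checkpoint; returns (model, config echo)."""
    with np.load(Path(path)) as archive:
        header = json.loads(bytes(archive["__header__"].tobytes()).decode("utf-8"))
        if header["schema"] != SCHEMA_VERSION:
            raise ValueError(f"unsupported checkpoint schema {header['schema']}")
        arrays = {k: archive[k] for k in archive.files}

    rng = np.random.default_rng(0)
    layers = []
    for i, meta in enumerate(header["layers"]):
        prefix = f"L{i}."
        if meta["type"] == "maf":
            layer = MAFLayer(meta["dim"], meta["hidden"], rng)
            for n in ("W1", "b1", "W2", "b2"):
                getattr(layer, n).data = arrays[prefix + n]
        elif meta["type"] == "perm":
            layer = Permutation(arrays[prefix + "perm"])
        elif meta["type"] == "actnorm":
            layer = ActNormLayer(meta["dim"], enabled=meta["enabled"])
            layer.initialized = meta["initialized"]
            layer.s.data = arrays[prefix + "s"]
            layer.b.data = arrays[prefix + "b"]
        elif meta["type"] == "moe_coupling":
            layer = MoECouplingLayer(
                meta["dim"], n_experts=meta["n_experts"], n_heads=meta["n_heads"],
                embed_dim=meta["embed_dim"], gate_hidden=meta["gate_hidden"],
                rng=rng, mask_parity=meta["mask_parity"])
            for n in ("W_embed", "b_embed", "U_g", "W_g", "b_g",
                      "W_s", "b_s", "W_t", "b_t"):
                getattr(layer, n).data = arrays[prefix + n]
            for j, ex in enumerate(layer.experts):
                for n in ex:
                    ex[n].data = arrays[f"{prefix}E{j}.{n}"]
        else:
            raise ValueError(f"unknown layer type {meta['type']!r}")
        layers.append(layer)

    context_mask = None
    if header["context_mask"] is not None:
        cm_meta = header["context_mask"]
        context_mask = ContextMask(cm_meta["dim"], cm_meta["hidden"], rng)
        for n in ("W_c", "b_c", "W_m", "b_m"):
            getattr(context_mask, n).data = arrays[f"CM.{n}"]

    model = Flow(header["dim"], layers, context_mask=context_mask)
    model.history = list(header["history"])
    return model, header["config"]
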