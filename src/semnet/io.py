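"""Model and configuration persistence.

Trained stacks are stored in NumPy's ``.npz`` container: for each layer
``i`` the arrays ``W{i}`` (row-major float64, shape ``n_hidden x
n_visible``), ``vb{i}``, ``hb{i}``, and optionally ``pi{i}`` for IBP layers,
plus a JSON metadata string recording visible types, sparsity kinds and
configs, and the forward activation.  Configurations are flat key-value
YAML files mirroring :class:`semnet.dbn.TrainConfig` field names.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import yaml

from .dbn import DBNLayer, DBNModel, TrainConfig
from .rbm import RBMParams

__all__ = ["save_model", "load_model", "load_config", "save_config",
           "save_features", "load_features"]


def save_model(model: DBNModel, path: str | Path) -> None:
    arrays: dict[str, np.ndarray] = {}
    meta = {"forward_activation": model.forward_activation, "layers": []}
    for i, layer in enumerate(model.layers):
        arrays[f"W{i}"] = layer.params.weights.astype(np.float64)
        arrays[f"vb{i}"] = layer.params.visible_bias.astype(np.float64)
        arrays[f"hb{i}"] = layer.params.hidden_bias.astype(np.float64)
        if layer.pi is not None:
            arrays[f"pi{i}"] = layer.pi.astype(np.float64)
        meta["layers"].append(
            {
                "visible_type": layer.params.visible_type,
                "sparsity": layer.sparsity,
                "sparsity_config": layer.sparsity_config,
                "trained": bool(layer.trained),
            }
        )
    arrays["meta"] = np.array(json.dumps(meta))
    np.savez(path, **arrays)


def load_model(path: str | Path) -> DBNModel:
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["meta"]))
        layers = []
        for i, lm in enumerate(meta["layers"]):
            params = RBMParams(
                data[f"W{i}"], data[f"vb{i}"], data[f"hb{i}"], lm["visible_type"]
            )
            layer = DBNLayer(
                params,
                lm["sparsity"],
                lm["sparsity_config"],
                trained=lm["trained"],
                pi=data[f"pi{i}"] if f"pi{i}" in data else None,
            )
            layers.append(layer)
    return DBNModel(layers, forward_activation=meta["forward_activation"])


def load_config(path: str | Path) -> TrainConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config file {path} must hold flat key-value pairs")
    return TrainConfig.from_dict(raw)


def save_config(config: TrainConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


def save_features(features: np.ndarray, path: str | Path) -> None:
    """Delimited feature matrix with header columns f0..f{K-1}."""
    features = np.atleast_2d(np.asarray(features, dtype=float))
    header = ",".join(f"f{j}" for j in range(features.shape[1]))
    np.savetxt(path, features, delimiter=",", header=header, comments="")


def load_features(path: str | Path) -> np.ndarray:
    return np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
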