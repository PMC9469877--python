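"""Greedy layer-wise training of the heterogeneous-sparse DBN.

The network stacks RBMs: the first hidden layer is a Gaussian-visible RBM
trained with contrastive divergence under random dropout; the second is a
binary-visible RBM gated by a Beta-Bernoulli (IBP) prior.  Each layer is
trained to completion and frozen, its deterministic mean-field activations
becoming the training data of the next layer.  Feature extraction is the
deterministic forward pass, with the final layer's pre-activation passed
through a configurable nonlinearity (ReLU by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.special import expit

from . import ibp, rbm

__all__ = ["TrainConfig", "DBNLayer", "DBNModel", "init_model", "train_layerwise",
           "infer_hidden", "extract_features"]


@dataclass
class TrainConfig:
    """Hyperparameters of the full stack.

    Defaults mirror the reference network: hidden widths 2048 and 1024,
    dropout rate 0.3 on layer 1, IBP parameters alpha = 1 and beta = 5 on
    layer 2, weights initialized from N(0, 0.005^2), multiplicative weight
    decay 0.998 and momentum 0.95, and a ReLU readout on the final layer.
    Learning rate, epochs, batch size, and CD steps are not pinned by the
    reference recipe; the defaults here are conventional CD-1 settings.
    """

    layer_sizes: tuple[int, ...] = (2048, 1024)
    dropout_rate: float = 0.3
    alpha: float = 1.0
    beta: float = 5.0
    learning_rate: float = 0.01
    epochs: int = 100
    batch_size: int = 100
    momentum: float = 0.95
    weight_decay: float = 0.998
    cd_k: int = 1
    init_sd: float = 0.005
    seed: int = 0
    forward_activation: str = "relu"
    #: Reproduce the literal four-state conditional without the hidden bias
    #: in its exponent (the bias is included by default, matching the
    #: hidden conditional of the plain RBM).
    literal_hz_conditional: bool = False

    def __post_init__(self) -> None:
        self.layer_sizes = tuple(int(s) for s in self.layer_sizes)
        if not self.layer_sizes or any(s <= 0 for s in self.layer_sizes):
            raise ValueError("layer_sizes must be positive integers")
        if not 0.0 <= self.dropout_rate <= 1.0:
            raise ValueError("dropout_rate must lie in [0, 1]")
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("alpha and beta must be positive")
        if not 0.0 <= self.momentum < 1.0:
            raise ValueError("momentum must lie in [0, 1)")
        if not 0.0 < self.weight_decay <= 1.0:
            raise ValueError("weight_decay must lie in (0, 1]")
        if self.forward_activation not in ("relu", "logistic"):
            raise ValueError("forward_activation must be 'relu' or 'logistic'")
        if self.epochs < 0 or self.batch_size < 1 or self.cd_k < 1:
            raise ValueError("invalid epochs / batch_size / cd_k")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["layer_sizes"] = list(self.layer_sizes)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TrainConfig":
        return cls(**d)


@dataclass
class DBNLayer:
    """One trained (or to-be-trained) RBM layer plus its sparsity mechanism."""

    params: rbm.RBMParams
    sparsity: str  # "dropout" | "ibp" | "none"
    sparsity_config: dict = field(default_factory=dict)
    trained: bool = False
    #: Final Beta-Bernoulli gate probabilities (IBP layers, after training).
    pi: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.sparsity not in ("dropout", "ibp", "none"):
            raise ValueError(f"unknown sparsity kind {self.sparsity!r}")


@dataclass
class DBNModel:
    """Ordered stack of RBM layers with chained dimensions."""

    layers: list[DBNLayer]
    forward_activation: str = "relu"

    def __post_init__(self) -> None:
        for lower, upper in zip(self.layers, self.layers[1:]):
            if upper.params.n_visible != lower.params.n_hidden:
                raise ValueError(
                    "layer dimensions do not chain: "
                    f"{lower.params.n_hidden} hidden -> {upper.params.n_visible} visible"
                )
        for i, layer in enumerate(self.layers):
            if layer.trained and not all(l.trained for l in self.layers[:i]):
                raise ValueError("a layer may be trained only if all earlier layers are")

    @property
    def n_features(self) -> int:
        return self.layers[-1].params.n_hidden

    @property
    def trained(self) -> bool:
        return all(layer.trained for layer in self.layers)


def init_model(config: TrainConfig, n_input: int) -> DBNModel:
    """Initialize the stack: N(0, init_sd^2) weights, zero biases.

    The first layer has Gaussian visible units (standardized real-valued
    input) and dropout sparsity; the last layer has binary visible units and
    IBP sparsity.  Any intermediate layers are plain binary RBMs.
    """
    if n_input <= 0:
        raise ValueError("n_input must be positive")
    rng = np.random.default_rng(config.seed)
    layers: list[DBNLayer] = []
    n_below = n_input
    last = len(config.layer_sizes) - 1
    for i, width in enumerate(config.layer_sizes):
        params = rbm.RBMParams(
            weights=rng.normal(0.0, config.init_sd, size=(width, n_below)),
            visible_bias=np.zeros(n_below),
            hidden_bias=np.zeros(width),
            visible_type="gaussian" if i == 0 else "binary",
        )
        if i == 0 and last > 0:
            kind, cfg = "dropout", {"rate": config.dropout_rate}
        elif i == last:
            kind, cfg = "ibp", {"alpha": config.alpha, "beta": config.beta}
        else:
            kind, cfg = "none", {}
        layers.append(DBNLayer(params, kind, cfg))
        n_below = width
    return DBNModel(layers, forward_activation=config.forward_activation)


def _minibatches(n: int, batch_size: int, rng: np.random.Generator):
    perm = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield perm[start : start + batch_size]


def _train_dropout_layer(
    layer: DBNLayer, data: np.ndarray, config: TrainConfig, rng: np.random.Generator
) -> None:
    params = layer.params
    state = rbm.UpdateState.for_params(
        params, config.momentum, config.weight_decay, config.learning_rate
    )
    rate = layer.sparsity_config.get("rate", config.dropout_rate)
    for _ in range(config.epochs):
        for idx in _minibatches(data.shape[0], config.batch_size, rng):
            mask = ibp.sample_dropout_mask(params.n_hidden, rate, rng)
            grad = rbm.cd_gradient(params, data[idx], config.cd_k, rng, mask.mask)
            params = rbm.apply_update(params, grad, state)
    layer.params = params


def _train_ibp_layer(
    layer: DBNLayer, data: np.ndarray, config: TrainConfig, rng: np.random.Generator
) -> None:
    params = layer.params
    state = rbm.UpdateState.for_params(
        params, config.momentum, config.weight_decay, config.learning_rate
    )
    alpha = layer.sparsity_config.get("alpha", config.alpha)
    beta = layer.sparsity_config.get("beta", config.beta)
    ibp_state = ibp.sample_ibp_prior(params.n_hidden, alpha, beta, rng)
    include_bias = not config.literal_hz_conditional
    n = data.shape[0]
    for _ in range(config.epochs):
        for idx in _minibatches(n, config.batch_size, rng):
            grad, ibp_state = ibp.ibp_cd_step(
                params,
                data[idx],
                ibp_state,
                config.cd_k,
                rng,
                n_total=n,
                include_hidden_bias=include_bias,
            )
            params = rbm.apply_update(params, grad, state)
    layer.params = params
    layer.pi = ibp_state.pi.copy()


def _train_plain_layer(
    layer: DBNLayer, data: np.ndarray, config: TrainConfig, rng: np.random.Generator
) -> None:
    params = layer.params
    state = rbm.UpdateState.for_params(
        params, config.momentum, config.weight_decay, config.learning_rate
    )
    for _ in range(config.epochs):
        for idx in _minibatches(data.shape[0], config.batch_size, rng):
            grad = rbm.cd_gradient(params, data[idx], config.cd_k, rng)
            params = rbm.apply_update(params, grad, state)
    layer.params = params


def train_layerwise(
    model: DBNModel,
    data: np.ndarray,
    config: TrainConfig,
    rng: np.random.Generator | None = None,
) -> DBNModel:
    """Greedy layer-wise pretraining of the whole stack.

    Each layer is trained on the frozen mean-field output of the layers
    below it (``data`` itself for layer 0, standardized per channel by the
    caller).  Returns the same model object with all layers trained.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    data = np.asarray(data, dtype=float)
    layer_input = data
    for i, layer in enumerate(model.layers):
        if any(not l.trained for l in model.layers[:i]):
            raise RuntimeError("earlier layers must be trained first")
        if layer.sparsity == "dropout":
            _train_dropout_layer(layer, layer_input, config, rng)
        elif layer.sparsity == "ibp":
            _train_ibp_layer(layer, layer_input, config, rng)
        else:
            _train_plain_layer(layer, layer_input, config, rng)
        layer.trained = True
        if i < len(model.layers) - 1:
            layer_input = infer_hidden(model, i, layer_input)
    return model


def infer_hidden(model: DBNModel, layer_index: int, data: np.ndarray) -> np.ndarray:
    """Deterministic mean-field activation of one layer on its own input rows.

    Logistic of the pre-activation; dropout layers are scaled by the keep
    probability (1 - rate) so the deterministic pass matches the expected
    activation under training-time dropout.
    """
    if not 0 <= layer_index < len(model.layers):
        raise IndexError(f"layer index {layer_index} out of range")
    layer = model.layers[layer_index]
    act = expit(rbm.hidden_preactivation(layer.params, np.asarray(data, dtype=float)))
    if layer.sparsity == "dropout":
        act = act * (1.0 - layer.sparsity_config.get("rate", 0.0))
    return act


def extract_features(model: DBNModel, windows: np.ndarray) -> np.ndarray:
    """Deterministic features: forward pass through all layers.

    All layers but the last use the mean-field logistic (with dropout
    scaling); the last layer applies ``model.forward_activation`` (ReLU by
    default) to its pre-activation.
    """
    if not model.trained:
        raise RuntimeError("model must be fully trained before feature extraction")
    x = np.atleast_2d(np.asarray(windows, dtype=float))
    if x.shape[1] != model.layers[0].params.n_visible:
        raise ValueError(
            f"input width {x.shape[1]} != layer-1 visible width "
            f"{model.layers[0].params.n_visible}"
        )
    for i, layer in enumerate(model.layers[:-1]):
        x = infer_hidden(model, i, x)
    pre = rbm.hidden_preactivation(model.layers[-1].params, x)
    if model.forward_activation == "relu":
        return np.maximum(pre, 0.0)
    return expit(pre)
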