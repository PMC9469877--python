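"""Restricted Boltzmann machine primitives.

An RBM is a bipartite undirected energy model over a visible layer ``v``
(binary or real-valued) and a binary hidden layer ``h``.  The energy of a
joint configuration is

    E(v, h) = -h^T W v - b_vis^T v - b_hid^T h            (binary visibles)

and, for Gaussian (unit-variance) visibles, the linear visible term is
replaced by a quadratic one:

    E(v, h) = ||v - b_vis||^2 / 2 - h^T W v - b_hid^T h.

This module provides the energy, the factorized conditionals, blocked Gibbs
transitions, contrastive-divergence (CD-k) gradient estimates with optional
dropout masking of hidden units, a momentum/weight-decay parameter update,
and exact-likelihood oracles (full state enumeration) that are tractable
only for tiny models but serve as ground truth in tests.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, logsumexp

__all__ = [
    "RBMParams",
    "GibbsChain",
    "UpdateState",
    "RBMGradient",
    "CapacityError",
    "energy",
    "hidden_conditional",
    "visible_conditional",
    "sample_visible",
    "gibbs_step",
    "cd_gradient",
    "apply_update",
    "exact_log_likelihood",
    "exact_gradient",
    "enumerate_binary_states",
]

#: Largest |pre-activation| fed to exp(); beyond this the conditionals are
#: saturated to machine precision anyway.
_MAX_PREACT = 300.0


class CapacityError(ValueError):
    """Raised when an exact-enumeration oracle is asked for a model too large
    to enumerate (n_visible + n_hidden > 20)."""


@dataclass
class RBMParams:
    """Parameters of one RBM.

    Attributes
    ----------
    weights:
        Array of shape ``(n_hidden, n_visible)``; ``weights[k, i]`` couples
        hidden unit ``k`` to visible unit ``i``.
    visible_bias:
        Length ``n_visible``.
    hidden_bias:
        Length ``n_hidden``.
    visible_type:
        ``"binary"`` for Bernoulli visibles, ``"gaussian"`` for unit-variance
        Gaussian visibles (real-valued sensor data standardized per channel).
    """

    weights: np.ndarray
    visible_bias: np.ndarray
    hidden_bias: np.ndarray
    visible_type: str = "binary"

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.visible_bias = np.asarray(self.visible_bias, dtype=float)
        self.hidden_bias = np.asarray(self.hidden_bias, dtype=float)
        if self.weights.ndim != 2:
            raise ValueError("weights must be a 2-D array (n_hidden, n_visible)")
        if self.weights.shape != (self.hidden_bias.size, self.visible_bias.size):
            raise ValueError(
                f"weights shape {self.weights.shape} inconsistent with bias "
                f"lengths ({self.hidden_bias.size}, {self.visible_bias.size})"
            )
        if self.visible_type not in ("binary", "gaussian"):
            raise ValueError(f"unknown visible_type {self.visible_type!r}")
        for arr in (self.weights, self.visible_bias, self.hidden_bias):
            if not np.all(np.isfinite(arr)):
                raise ValueError("RBM parameters must be finite")

    @property
    def n_hidden(self) -> int:
        return self.hidden_bias.size

    @property
    def n_visible(self) -> int:
        return self.visible_bias.size

    def copy(self) -> "RBMParams":
        return RBMParams(
            self.weights.copy(),
            self.visible_bias.copy(),
            self.hidden_bias.copy(),
            self.visible_type,
        )


@dataclass
class GibbsChain:
    """State of one blocked-Gibbs sampling chain."""

    visible_state: np.ndarray
    hidden_state: np.ndarray
    step_count: int = 0

    def __post_init__(self) -> None:
        self.visible_state = np.asarray(self.visible_state, dtype=float)
        self.hidden_state = np.asarray(self.hidden_state, dtype=float)
        if not np.all(np.isin(self.hidden_state, (0.0, 1.0))):
            raise ValueError("hidden_state entries must be 0 or 1")
        if self.step_count < 0:
            raise ValueError("step_count must be nonnegative")


@dataclass
class UpdateState:
    """Momentum velocity plus the optimizer hyperparameters.

    ``weight_decay`` is multiplicative and applies to the weight matrix only
    (biases are never decayed); ``momentum`` accumulates the gradient into a
    velocity term.  Defaults follow the network's training recipe
    (weight decay 0.998, momentum 0.95).
    """

    velocity_weights: np.ndarray
    velocity_visible_bias: np.ndarray
    velocity_hidden_bias: np.ndarray
    momentum: float = 0.95
    weight_decay: float = 0.998
    learning_rate: float = 0.01

    def __post_init__(self) -> None:
        if not 0.0 <= self.momentum < 1.0:
            raise ValueError("momentum must lie in [0, 1)")
        if not 0.0 < self.weight_decay <= 1.0:
            raise ValueError("weight_decay must lie in (0, 1]")
        if self.learning_rate < 0.0:
            raise ValueError("learning_rate must be nonnegative")

    @classmethod
    def for_params(
        cls,
        params: RBMParams,
        momentum: float = 0.95,
        weight_decay: float = 0.998,
        learning_rate: float = 0.01,
    ) -> "UpdateState":
        return cls(
            np.zeros_like(params.weights),
            np.zeros_like(params.visible_bias),
            np.zeros_like(params.hidden_bias),
            momentum=momentum,
            weight_decay=weight_decay,
            learning_rate=learning_rate,
        )


@dataclass
class RBMGradient:
    """Gradient (ascent direction on the log-likelihood) with RBMParams shapes."""

    weights: np.ndarray
    visible_bias: np.ndarray
    hidden_bias: np.ndarray


def _check_vectors(params: RBMParams, v: np.ndarray, h: np.ndarray | None = None) -> None:
    if np.shape(v)[-1] != params.n_visible:
        raise ValueError(
            f"visible vector length {np.shape(v)[-1]} != n_visible {params.n_visible}"
        )
    if h is not None and np.shape(h)[-1] != params.n_hidden:
        raise ValueError(
            f"hidden vector length {np.shape(h)[-1]} != n_hidden {params.n_hidden}"
        )


def energy(params: RBMParams, v: np.ndarray, h: np.ndarray) -> float:
    """Energy of the joint configuration ``(v, h)``.

    Binary mode: ``-h^T W v - b_vis^T v - b_hid^T h``.  Gaussian mode replaces
    the linear visible term with ``+||v - b_vis||^2 / 2``.
    """
    v = np.asarray(v, dtype=float)
    h = np.asarray(h, dtype=float)
    _check_vectors(params, v, h)
    coupling = -float(h @ params.weights @ v)
    hidden_term = -float(params.hidden_bias @ h)
    if params.visible_type == "binary":
        visible_term = -float(params.visible_bias @ v)
    else:
        visible_term = 0.5 * float(np.sum((v - params.visible_bias) ** 2))
    return coupling + visible_term + hidden_term


def hidden_preactivation(params: RBMParams, v: np.ndarray) -> np.ndarray:
    """``W v + b_hid`` for one visible vector or a batch (rows)."""
    v = np.asarray(v, dtype=float)
    _check_vectors(params, v)
    return v @ params.weights.T + params.hidden_bias


def hidden_conditional(params: RBMParams, v: np.ndarray) -> np.ndarray:
    """``p(h_k = 1 | v)`` — elementwise logistic of the hidden pre-activation.

    Accepts a single visible vector or a batch (one row per instance).
    """
    return expit(hidden_preactivation(params, v))


def visible_conditional(params: RBMParams, h: np.ndarray) -> np.ndarray:
    """Mean of ``p(v | h)`` per visible unit.

    Binary mode: Bernoulli means ``logistic(W^T h + b_vis)``.  Gaussian mode:
    Normal means ``W^T h + b_vis`` with unit variance.
    """
    h = np.asarray(h, dtype=float)
    _check_vectors(params, np.empty(params.n_visible), h)
    pre = h @ params.weights + params.visible_bias
    if params.visible_type == "binary":
        return expit(pre)
    return pre


def sample_visible(params: RBMParams, h: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Draw ``v ~ p(v | h)`` (Bernoulli or unit-variance Normal per unit)."""
    mean = visible_conditional(params, h)
    if params.visible_type == "binary":
        return (rng.random(mean.shape) < mean).astype(float)
    return mean + rng.standard_normal(mean.shape)


def gibbs_step(params: RBMParams, chain: GibbsChain, rng: np.random.Generator) -> GibbsChain:
    """One blocked-Gibbs transition: sample ``h | v`` then ``v | h``."""
    ph = hidden_conditional(params, chain.visible_state)
    h = (rng.random(ph.shape) < ph).astype(float)
    v = sample_visible(params, h, rng)
    return GibbsChain(v, h, chain.step_count + 1)


def cd_gradient(
    params: RBMParams,
    batch: np.ndarray,
    k: int = 1,
    rng: np.random.Generator | None = None,
    dropout_mask: np.ndarray | None = None,
) -> RBMGradient:
    """CD-k estimate of the log-likelihood gradient on a minibatch.

    The data term uses the analytic hidden probabilities; the model term is
    obtained after ``k`` alternations of (sampled hidden, mean-field visible)
    reconstruction, with the hidden probabilities of the final step used for
    the statistics.  When ``dropout_mask`` is given (1 = keep), masked hidden
    units are removed from the model: their activation is zero everywhere and
    their gradient rows vanish.
    """
    if rng is None:
        raise ValueError("a seeded numpy Generator is required")
    if k < 1:
        raise ValueError("k must be >= 1")
    batch = np.atleast_2d(np.asarray(batch, dtype=float))
    if batch.shape[0] == 0:
        raise ValueError("empty batch")
    _check_vectors(params, batch)
    n = batch.shape[0]
    mask = np.ones(params.n_hidden) if dropout_mask is None else np.asarray(dropout_mask, float)

    p_data = hidden_conditional(params, batch) * mask
    h = (rng.random((n, params.n_hidden)) < p_data).astype(float)
    v_model = batch
    p_model = p_data
    for step in range(k):
        v_model = visible_conditional(params, h)
        p_model = hidden_conditional(params, v_model) * mask
        if step < k - 1:
            h = (rng.random((n, params.n_hidden)) < p_model).astype(float)
    return RBMGradient(
        (p_data.T @ batch - p_model.T @ v_model) / n,
        np.mean(batch - v_model, axis=0),
        np.mean(p_data - p_model, axis=0),
    )


def apply_update(params: RBMParams, grad: RBMGradient, state: UpdateState) -> RBMParams:
    """Momentum + weight-decay ascent step; mutates ``state``'s velocity.

    velocity <- momentum * velocity + learning_rate * grad
    weights  <- weight_decay * weights + velocity      (decay on weights only)
    biases   <- biases + velocity
    """
    m, lr = state.momentum, state.learning_rate
    state.velocity_weights = m * state.velocity_weights + lr * grad.weights
    state.velocity_visible_bias = m * state.velocity_visible_bias + lr * grad.visible_bias
    state.velocity_hidden_bias = m * state.velocity_hidden_bias + lr * grad.hidden_bias
    return RBMParams(
        state.weight_decay * params.weights + state.velocity_weights,
        params.visible_bias + state.velocity_visible_bias,
        params.hidden_bias + state.velocity_hidden_bias,
        params.visible_type,
    )


def enumerate_binary_states(n: int) -> np.ndarray:
    """All 2**n binary vectors of length n, one per row (lexicographic)."""
    if n == 0:
        return np.zeros((1, 0))
    return np.array(list(itertools.product((0.0, 1.0), repeat=n)))


def _check_capacity(params: RBMParams) -> None:
    if params.visible_type != "binary":
        raise ValueError("exact enumeration requires binary visible units")
    if params.n_visible + params.n_hidden > 20:
        raise CapacityError(
            f"model too large to enumerate: n_v + n_h = "
            f"{params.n_visible + params.n_hidden} > 20"
        )


def _log_unnorm(params: RBMParams, V: np.ndarray) -> np.ndarray:
    """log sum_h exp(-E(v, h)) for each row v of V, by enumerating h."""
    H = enumerate_binary_states(params.n_hidden)
    neg_E = H @ params.weights @ V.T + (V @ params.visible_bias)[None, :] \
        + (H @ params.hidden_bias)[:, None]
    return logsumexp(neg_E, axis=0)


def exact_log_partition(params: RBMParams) -> float:
    _check_capacity(params)
    V = enumerate_binary_states(params.n_visible)
    return float(logsumexp(_log_unnorm(params, V)))


def exact_log_likelihood(params: RBMParams, v: np.ndarray) -> float:
    """log P(v) by full enumeration of hidden and visible states.

    Only valid for tiny binary models (n_visible + n_hidden <= 20); raises
    :class:`CapacityError` otherwise.  This is the test oracle against which
    the CD approximation is validated.
    """
    _check_capacity(params)
    v = np.asarray(v, dtype=float)
    _check_vectors(params, v)
    return float(_log_unnorm(params, v[None, :])[0]) - exact_log_partition(params)


def exact_gradient(params: RBMParams, batch: np.ndarray) -> RBMGradient:
    """Exact log-likelihood gradient of a tiny binary RBM by enumeration.

    data term: E_{p(h|v)}[...] averaged over the batch;
    model term: expectation under the full joint, computed from the exact
    marginal P(v) and the factorized p(h|v).
    """
    _check_capacity(params)
    batch = np.atleast_2d(np.asarray(batch, dtype=float))
    _check_vectors(params, batch)
    n = batch.shape[0]
    p_data = hidden_conditional(params, batch)

    V = enumerate_binary_states(params.n_visible)
    log_pv = _log_unnorm(params, V)
    pv = np.exp(log_pv - logsumexp(log_pv))
    p_hidden_given_v = hidden_conditional(params, V)

    gw_data = p_data.T @ batch / n
    gw_model = (p_hidden_given_v * pv[:, None]).T @ V
    return RBMGradient(
        gw_data - gw_model,
        batch.mean(axis=0) - pv @ V,
        p_data.mean(axis=0) - pv @ p_hidden_given_v,
    )
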