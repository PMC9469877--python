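"""Sparsity mechanisms for RBM hidden layers.

Two mechanisms are provided:

* **Random dropout** — at each training iteration an i.i.d. Bernoulli
  indicator vector removes each hidden unit with probability ``rate``.

* **Beta-Bernoulli / Indian-buffet-process (IBP) gating** — each hidden unit
  ``k`` carries a stick weight ``pi_k ~ Beta(alpha/K, beta*(K-1)/K)`` and each
  training instance carries a binary selection vector ``z`` with
  ``z_k ~ Bernoulli(pi_k)``.  Only selected units participate in the energy:

      E(v, h, z) = -(z*h)^T W v - b_hid^T (z*h) - b_vis^T v

  For large ``K`` most ``pi_k`` concentrate near zero, so the prior enforces
  strong sparsity while letting the posterior revive units that the data
  supports.  Inference is blocked Gibbs: ``(h_k, z_k)`` pairs are drawn
  jointly from a four-state conditional, and ``pi`` is drawn from its
  conjugate Beta posterior given the selection counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .rbm import (
    RBMGradient,
    RBMParams,
    hidden_preactivation,
    visible_conditional,
)

__all__ = [
    "DropoutMask",
    "IBPState",
    "sample_dropout_mask",
    "sample_ibp_prior",
    "ibp_energy",
    "joint_hz_conditional",
    "sample_hz",
    "sample_pi_posterior",
    "ibp_cd_step",
    "beta_shape_parameters",
]

#: Lower clamp for degenerate Beta shape parameters (e.g. K = 1 makes the
#: second shape exactly 0, which is outside the Beta family).
_SHAPE_EPS = 1e-6
#: pi is kept strictly inside (0, 1).
_PI_EPS = 1e-12
#: exp() saturation guard for the four-state conditional.
_MAX_PREACT = 300.0


@dataclass
class DropoutMask:
    """Binary keep-mask over K hidden units (1 = keep, 0 = dropped)."""

    mask: np.ndarray
    rate: float

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=float)
        if not np.all(np.isin(self.mask, (0.0, 1.0))):
            raise ValueError("mask entries must be 0 or 1")
        if not 0.0 <= self.rate <= 1.0:
            raise ValueError("rate must lie in [0, 1]")


@dataclass
class IBPState:
    """State of the Beta-Bernoulli gate over K hidden units.

    ``pi`` holds the per-unit Bernoulli parameters (strictly inside (0, 1));
    ``z`` holds one binary selection vector per instance (rows), or None
    before any instance has been visited.
    """

    pi: np.ndarray
    alpha: float
    beta: float
    z: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.pi = np.clip(np.asarray(self.pi, dtype=float), _PI_EPS, 1.0 - _PI_EPS)
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("alpha and beta must be positive")
        if self.z is not None:
            self.z = np.atleast_2d(np.asarray(self.z, dtype=float))
            if not np.all(np.isin(self.z, (0.0, 1.0))):
                raise ValueError("z entries must be 0 or 1")
            if self.z.shape[1] != self.pi.size:
                raise ValueError("z width must equal len(pi)")

    @property
    def n_units(self) -> int:
        return self.pi.size


def sample_dropout_mask(K: int, rate: float, rng: np.random.Generator) -> DropoutMask:
    """Draw a dropout keep-mask: each unit dropped independently w.p. ``rate``."""
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must lie in [0, 1]")
    if K <= 0:
        raise ValueError("K must be positive")
    return DropoutMask((rng.random(K) >= rate).astype(float), rate)


def beta_shape_parameters(alpha: float, beta: float, K: int) -> tuple[float, float]:
    """Prior Beta shapes (alpha/K, beta*(K-1)/K), clamped away from zero."""
    return max(alpha / K, _SHAPE_EPS), max(beta * (K - 1) / K, _SHAPE_EPS)


def sample_ibp_prior(
    K: int,
    alpha: float,
    beta: float,
    rng: np.random.Generator,
    n_instances: int = 1,
) -> IBPState:
    """Draw ``pi`` from the Beta-Bernoulli prior and ``z ~ Bernoulli(pi)``."""
    if alpha <= 0 or beta <= 0:
        raise ValueError("alpha and beta must be positive")
    a, b = beta_shape_parameters(alpha, beta, K)
    pi = rng.beta(a, b, size=K)
    z = (rng.random((n_instances, K)) < pi).astype(float)
    return IBPState(pi=pi, alpha=alpha, beta=beta, z=z)


def ibp_energy(params: RBMParams, v: np.ndarray, h: np.ndarray, z: np.ndarray) -> float:
    """Energy of the gated configuration: only units with z_k = 1 couple.

    With z all ones this reduces exactly to the plain binary RBM energy.
    """
    v = np.asarray(v, dtype=float)
    h = np.asarray(h, dtype=float)
    z = np.asarray(z, dtype=float)
    if v.size != params.n_visible or h.size != params.n_hidden or z.size != params.n_hidden:
        raise ValueError("dimension mismatch with RBM parameters")
    zh = z * h
    return (
        -float(zh @ params.weights @ v)
        - float(params.hidden_bias @ zh)
        - float(params.visible_bias @ v)
    )


def joint_hz_conditional(
    params: RBMParams,
    v: np.ndarray,
    pi_k: float,
    k: int,
    include_hidden_bias: bool = True,
) -> np.ndarray:
    """Normalized 2x2 table ``p(h_k = a, z_k = b | v, pi_k)``, indexed [a, b].

    Unnormalized weights: (1,1): pi * exp(s_k); (0,1): pi; (0,0): 1 - pi;
    (1,0): 1 - pi, where ``s_k = W[k] . v + b_hid[k]``.  A dropped unit
    (z = 0) contributes nothing to the energy, so both h values are equally
    likely given z = 0.  Set ``include_hidden_bias=False`` to use the bare
    pre-activation ``W[k] . v`` instead.
    """
    if not 0.0 < pi_k < 1.0:
        raise ValueError("pi_k must lie strictly inside (0, 1)")
    s = float(np.asarray(params.weights[k], dtype=float) @ np.asarray(v, dtype=float))
    if include_hidden_bias:
        s += float(params.hidden_bias[k])
    s = float(np.clip(s, -_MAX_PREACT, _MAX_PREACT))
    table = np.array(
        [
            [1.0 - pi_k, pi_k],               # h = 0: z = 0, z = 1
            [1.0 - pi_k, pi_k * np.exp(s)],   # h = 1: z = 0, z = 1
        ]
    )
    return table / table.sum()


def _hz_state_probs(
    params: RBMParams,
    v: np.ndarray,
    pi: np.ndarray,
    include_hidden_bias: bool = True,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized four-state probabilities (p11, p01, p00) per instance/unit.

    p10 is the complement.  ``v`` may be one vector or a batch of rows.
    """
    s = hidden_preactivation(params, v)
    if not include_hidden_bias:
        s = s - params.hidden_bias
    s = np.clip(s, -_MAX_PREACT, _MAX_PREACT)
    es = np.exp(s)
    total = pi * (1.0 + es) + 2.0 * (1.0 - pi)
    return pi * es / total, pi / total, (1.0 - pi) / total


def effective_activation_probability(
    params: RBMParams,
    v: np.ndarray,
    pi: np.ndarray,
    include_hidden_bias: bool = True,
) -> np.ndarray:
    """``p(h_k = 1, z_k = 1 | v, pi)`` — the mean of the gated unit z_k * h_k."""
    p11, _, _ = _hz_state_probs(params, v, pi, include_hidden_bias)
    return p11


def sample_hz(
    params: RBMParams,
    v: np.ndarray,
    pi: np.ndarray,
    rng: np.random.Generator,
    include_hidden_bias: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw ``(h, z)`` jointly from the per-unit four-state conditional.

    ``v`` may be a single vector or a batch of rows; the return shapes match.
    One uniform variate is consumed per (instance, unit), with the states
    ordered (1,1), (0,1), (0,0), (1,0) along the cumulative scale.
    """
    v = np.asarray(v, dtype=float)
    single = v.ndim == 1
    p11, p01, p00 = _hz_state_probs(params, np.atleast_2d(v), pi, include_hidden_bias)
    u = rng.random(p11.shape)
    c1 = p11
    c2 = p11 + p01
    c3 = c2 + p00
    h = ((u < c1) | (u >= c3)).astype(float)
    z = (u < c2).astype(float)
    if single:
        return h[0], z[0]
    return h, z


def sample_pi_posterior(
    alpha: float,
    beta: float,
    K: int,
    z_sums: np.ndarray,
    M: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Conjugate Beta draw of ``pi`` given selection counts over M instances:

        pi_k ~ Beta(alpha/K + sum_j z_k^j,  beta*(K-1)/K + sum_j (1 - z_k^j))
    """
    z_sums = np.asarray(z_sums, dtype=float)
    if np.any(z_sums < -1e-9) or np.any(z_sums > M + 1e-9):
        raise ValueError("z_sums must lie in [0, M]")
    z_sums = np.clip(z_sums, 0.0, float(M))
    a0, b0 = beta_shape_parameters(alpha, beta, K)
    pi = rng.beta(a0 + z_sums, b0 + (M - z_sums))
    return np.clip(pi, _PI_EPS, 1.0 - _PI_EPS)


def ibp_cd_step(
    params: RBMParams,
    batch: np.ndarray,
    state: IBPState,
    k_steps: int = 1,
    rng: np.random.Generator | None = None,
    n_total: int | None = None,
    resample_pi: bool = True,
    include_hidden_bias: bool = True,
) -> tuple[RBMGradient, IBPState]:
    """One CD step of the IBP-gated RBM on a minibatch.

    The data phase draws ``(h, z)`` per instance; the reconstruction chain and
    all gradient statistics use the gated activation ``z * h`` (its analytic
    mean ``p(h=1, z=1 | v, pi)`` for the statistics, samples for the chain).
    After the gradient, ``pi`` is redrawn from the conjugate posterior using
    the batch selection counts scaled by ``n_total / batch_size`` — a
    stochastic approximation of the full-data conditional, which sums counts
    over all ``n_total`` training instances.
    """
    if rng is None:
        raise ValueError("a seeded numpy Generator is required")
    batch = np.atleast_2d(np.asarray(batch, dtype=float))
    if batch.shape[0] == 0:
        raise ValueError("empty batch")
    n = batch.shape[0]
    M = n if n_total is None else int(n_total)
    pi = state.pi

    p_data = effective_activation_probability(params, batch, pi, include_hidden_bias)
    h0, z0 = sample_hz(params, batch, pi, rng, include_hidden_bias)
    eff = z0 * h0
    v_model = batch
    p_model = p_data
    for step in range(k_steps):
        v_model = visible_conditional(params, eff)
        p_model = effective_activation_probability(params, v_model, pi, include_hidden_bias)
        if step < k_steps - 1:
            h, z = sample_hz(params, v_model, pi, rng, include_hidden_bias)
            eff = z * h
    grad = RBMGradient(
        (p_data.T @ batch - p_model.T @ v_model) / n,
        np.mean(batch - v_model, axis=0),
        np.mean(p_data - p_model, axis=0),
    )
    if resample_pi:
        counts = z0.sum(axis=0) * (M / n)
        new_pi = sample_pi_posterior(state.alpha, state.beta, pi.size, counts, M, rng)
    else:
        new_pi = pi
    return grad, IBPState(pi=new_pi, alpha=state.alpha, beta=state.beta, z=z0)
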