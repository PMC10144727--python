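"""Q-value network implementations in plain numpy.

Two policy representations are supported:

* ``feedforward`` — the 40-50-50-6 multilayer perceptron with ReLU between
  layers; this is the architecture the value function approximator uses for
  the standard agent.
* ``recurrent`` — the same stack with a 27-unit LSTM inserted after the
  input, followed by a drop-out layer (keep rate 0.8 while training), so the
  policy can carry information across the windows of an episode.

The optimizer is Adam (first-moment decay 0.9, second 0.999) with an L2
penalty applied to the weight matrices only.  Everything is deterministic
given the seeds handed in, which is what makes full training runs
bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .features import FEATURE_DIM

N_ACTIONS = 6


@dataclass
class NetworkArch:
    variant: str = "feedforward"  # or "recurrent"
    n_inputs: int = FEATURE_DIM
    hidden: tuple[int, int] = (50, 50)
    n_actions: int = N_ACTIONS
    lstm_units: int = 27
    dropout: float = 0.2

    def __post_init__(self) -> None:
        if self.variant not in ("feedforward", "recurrent"):
            raise ValueError(f"unknown network variant {self.variant!r}")


def _uniform(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int):
    scale = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-scale, scale, size=shape)


def init_params(arch: NetworkArch, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Seed-deterministic small-uniform initialisation."""
    h1, h2 = arch.hidden
    p: dict[str, np.ndarray] = {}
    if arch.variant == "recurrent":
        H = arch.lstm_units
        p["Wx"] = _uniform(rng, (arch.n_inputs, 4 * H), arch.n_inputs)
        p["Wh"] = _uniform(rng, (H, 4 * H), H)
        b = np.zeros(4 * H)
        b[H : 2 * H] = 1.0  # forget-gate bias opens the memory path at init
        p["b"] = b
        dense_in = H
    else:
        dense_in = arch.n_inputs
    p["W1"] = _uniform(rng, (dense_in, h1), dense_in)
    p["b1"] = np.zeros(h1)
    p["W2"] = _uniform(rng, (h1, h2), h1)
    p["b2"] = np.zeros(h2)
    p["W3"] = _uniform(rng, (h2, arch.n_actions), h2)
    p["b3"] = np.zeros(arch.n_actions)
    return p


def clone_params(params: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    return {k: v.copy() for k, v in params.items()}


# ---------------------------------------------------------------- MLP


def mlp_forward(params, X: np.ndarray):
    """Q-values for a batch of observations.  X: (B, n_inputs)."""
    z1 = X @ params["W1"] + params["b1"]
    a1 = np.maximum(z1, 0.0)
    z2 = a1 @ params["W2"] + params["b2"]
    a2 = np.maximum(z2, 0.0)
    q = a2 @ params["W3"] + params["b3"]
    return q, (X, z1, a1, z2, a2)


def mlp_backward(params, cache, dQ: np.ndarray) -> dict[str, np.ndarray]:
    X, z1, a1, z2, a2 = cache
    grads = {
        "W3": a2.T @ dQ,
        "b3": dQ.sum(axis=0),
    }
    dz2 = (dQ @ params["W3"].T) * (z2 > 0.0)
    grads["W2"] = a1.T @ dz2
    grads["b2"] = dz2.sum(axis=0)
    dz1 = (dz2 @ params["W2"].T) * (z1 > 0.0)
    grads["W1"] = X.T @ dz1
    grads["b1"] = dz1.sum(axis=0)
    return grads


# ---------------------------------------------------------------- LSTM


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def lstm_cell(params, x: np.ndarray, h: np.ndarray, c: np.ndarray):
    """One recurrent step; returns (i, f, g, o, c_new, h_new)."""
    H = h.shape[0]
    z = x @ params["Wx"] + h @ params["Wh"] + params["b"]
    i = _sigmoid(z[:H])
    f = _sigmoid(z[H : 2 * H])
    g = np.tanh(z[2 * H : 3 * H])
    o = _sigmoid(z[3 * H :])
    c_new = f * c + i * g
    h_new = o * np.tanh(c_new)
    return i, f, g, o, c_new, h_new


def recurrent_forward(params, X: np.ndarray, drop_mask: np.ndarray | None = None):
    """Unroll over a whole episode.  X: (N, n_inputs) -> Q: (N, n_actions).

    ``drop_mask`` is an inverted-dropout mask over the LSTM output shared
    across time steps (None = evaluation mode, no dropout).
    """
    H = params["Wh"].shape[0]
    N = X.shape[0]
    h = np.zeros(H)
    c = np.zeros(H)
    caches = []
    hd_all = np.empty((N, H))
    for t in range(N):
        h_prev, c_prev = h, c
        i, f, g, o, c, h = lstm_cell(params, X[t], h_prev, c_prev)
        hd = h * drop_mask if drop_mask is not None else h
        hd_all[t] = hd
        caches.append((X[t], h_prev, c_prev, i, f, g, o, c, h))
    z1 = hd_all @ params["W1"] + params["b1"]
    a1 = np.maximum(z1, 0.0)
    z2 = a1 @ params["W2"] + params["b2"]
    a2 = np.maximum(z2, 0.0)
    q = a2 @ params["W3"] + params["b3"]
    return q, (caches, hd_all, z1, a1, z2, a2, drop_mask)


def recurrent_backward(params, cache, dQ: np.ndarray) -> dict[str, np.ndarray]:
    """Backpropagation through time over one episode."""
    caches, hd_all, z1, a1, z2, a2, drop_mask = cache
    grads = {k: np.zeros_like(v) for k, v in params.items()}
    grads["W3"] = a2.T @ dQ
    grads["b3"] = dQ.sum(axis=0)
    dz2 = (dQ @ params["W3"].T) * (z2 > 0.0)
    grads["W2"] = a1.T @ dz2
    grads["b2"] = dz2.sum(axis=0)
    dz1 = (dz2 @ params["W2"].T) * (z1 > 0.0)
    grads["W1"] = hd_all.T @ dz1
    grads["b1"] = dz1.sum(axis=0)
    dhd_all = dz1 @ params["W1"].T

    H = params["Wh"].shape[0]
    dh_next = np.zeros(H)
    dc_next = np.zeros(H)
    for t in range(len(caches) - 1, -1, -1):
        x, h_prev, c_prev, i, f, g, o, c, h = caches[t]
        dh = dhd_all[t] * (drop_mask if drop_mask is not None else 1.0) + dh_next
        tanh_c = np.tanh(c)
        do = dh * tanh_c
        dc = dh * o * (1.0 - tanh_c**2) + dc_next
        di = dc * g
        df = dc * c_prev
        dg = dc * i
        dc_next = dc * f
        dz = np.concatenate(
            [
                di * i * (1.0 - i),
                df * f * (1.0 - f),
                dg * (1.0 - g**2),
                do * o * (1.0 - o),
            ]
        )
        grads["Wx"] += np.outer(x, dz)
        grads["Wh"] += np.outer(h_prev, dz)
        grads["b"] += dz
        dh_next = params["Wh"] @ dz
    return grads


def q_values(params, arch: NetworkArch, X: np.ndarray) -> np.ndarray:
    """Evaluation-mode Q-values for a batch (hidden state starts at zero for
    the recurrent variant; use :func:`lstm_cell` directly to carry state)."""
    X = np.atleast_2d(X)
    if arch.variant == "recurrent":
        q, _ = recurrent_forward(params, X, drop_mask=None)
    else:
        q, _ = mlp_forward(params, X)
    return q


# ---------------------------------------------------------------- Adam


@dataclass
class Adam:
    """Adaptive-moment optimizer with decoupled-from-nothing classic L2
    (the penalty enters the gradient, as the original formulation does)."""

    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    t: int = 0
    m: dict[str, np.ndarray] = field(default_factory=dict)
    v: dict[str, np.ndarray] = field(default_factory=dict)

    def step(self, params, grads, alpha: float, l2: float = 0.0) -> None:
        self.t += 1
        for k in sorted(params):
            g = grads[k]
            if l2 and k.startswith("W"):
                g = g + l2 * params[k]
            if k not in self.m:
                self.m[k] = np.zeros_like(params[k])
                self.v[k] = np.zeros_like(params[k])
            self.m[k] = self.beta1 * self.m[k] + (1.0 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1.0 - self.beta2) * g * g
            m_hat = self.m[k] / (1.0 - self.beta1**self.t)
            v_hat = self.v[k] / (1.0 - self.beta2**self.t)
            params[k] -= alpha * m_hat / (np.sqrt(v_hat) + self.eps)
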