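"""DQN / Double-DQN agent: action selection, replay, targets, updates.

The online network Q(.;theta) drives the epsilon-greedy policy; a target
network Q(.;theta-) supplies the bootstrap values.  Per transition the
regression target is

* terminal:        Y = R
* dqn:             Y = R + gamma * max_a Q(O', a; theta-)
* double_dqn:      Y = R + gamma * Q(O', argmax_a Q(O', a; theta); theta-)

i.e. Double-DQN selects the bootstrap action with the online network but
evaluates it with the target network, which removes the upward bias the
shared max introduces.  Learning is one Adam step on the mean squared error
between Q(O, A; theta) and Y over a uniformly sampled replay minibatch; the
target network is soft-updated (theta- <- tau_s*theta + (1-tau_s)*theta-)
every ``target_update_freq`` learn steps.
"""

from __future__ import annotations

import json
from collections import deque
from dataclasses import asdict, dataclass, field

import numpy as np

from .network import (
    Adam,
    NetworkArch,
    clone_params,
    init_params,
    lstm_cell,
    mlp_backward,
    mlp_forward,
    q_values,
    recurrent_backward,
    recurrent_forward,
)


@dataclass
class AgentConfig:
    """Training hyperparameters (defaults are the tuned operating point)."""

    alpha: float = 3e-4
    gamma: float = 0.99
    epsilon_init: float = 1.0
    epsilon_decay: float = 5e-3  # multiplicative, per learn step
    epsilon_min: float = 0.01
    smooth_factor: float = 5e-3  # tau_s of the soft target update
    target_update_freq: int = 1  # tau: soft update every tau learn steps
    buffer_capacity: int = 1_000_000
    minibatch: int = 64
    l2: float = 1e-4
    grad_decay: float = 0.9  # Adam first-moment decay
    epochs: int = 15  # passes over the user's training set
    mode: str = "dqn"  # or "double_dqn"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError("gamma must lie in [0, 1]")
        if self.alpha < 0.0:
            raise ValueError("alpha must be nonnegative")
        if self.target_update_freq < 1:
            raise ValueError("target_update_freq must be >= 1")
        if self.mode not in ("dqn", "double_dqn"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass
class Transition:
    """One replay entry E_t = (O_t, A_t, R_{t+1}, O_{t+1}, done)."""

    obs: np.ndarray
    action: int
    reward: float
    next_obs: np.ndarray | None
    done: bool

    def __post_init__(self) -> None:
        if self.done != (self.next_obs is None):
            raise ValueError("done must hold exactly when next_obs is None")


class ReplayBuffer:
    """FIFO transition store with uniform sampling without replacement."""

    def __init__(self, capacity: int):
        self.capacity = capacity
        self._items: deque = deque(maxlen=capacity)

    def __len__(self) -> int:
        return len(self._items)

    def push(self, item) -> None:
        self._items.append(item)

    def sample(self, k: int, rng: np.random.Generator) -> list:
        if not self._items:
            raise ValueError("cannot sample from an empty replay buffer")
        k = min(k, len(self._items))
        idx = rng.choice(len(self._items), size=k, replace=False)
        return [self._items[i] for i in idx]


def replay_push_sample(
    buffer: ReplayBuffer,
    new: list[Transition],
    k: int,
    rng: np.random.Generator,
) -> list[Transition]:
    """Push transitions (FIFO eviction at capacity) then draw a minibatch."""
    for tr in new:
        buffer.push(tr)
    return buffer.sample(k, rng)


@dataclass
class QNetworkParams:
    """Online + target parameters, optimizer state and observation scaling."""

    theta: dict[str, np.ndarray]
    theta_target: dict[str, np.ndarray]
    arch: NetworkArch
    opt: Adam = field(default_factory=Adam)
    obs_scale: np.ndarray | None = None  # per-dim divisor applied upstream
    learn_steps: int = 0
    epsilon: float = 1.0


def init_agent(
    arch: NetworkArch, config: AgentConfig, rng: np.random.Generator
) -> QNetworkParams:
    theta = init_params(arch, rng)
    return QNetworkParams(
        theta=theta,
        theta_target=clone_params(theta),
        arch=arch,
        opt=Adam(beta1=config.grad_decay),
        epsilon=config.epsilon_init,
    )


def scale_obs(params: QNetworkParams, obs: np.ndarray) -> np.ndarray:
    if params.obs_scale is None:
        return obs
    return obs / params.obs_scale


def greedy_action(params: QNetworkParams, obs: np.ndarray) -> int:
    """argmax_a Q(obs, a; theta); value ties go to the lowest action index."""
    q = q_values(params.theta, params.arch, obs)[0]
    return int(np.argmax(q))


def select_action(
    params: QNetworkParams,
    obs: np.ndarray,
    epsilon: float,
    rng: np.random.Generator,
) -> int:
    """Epsilon-greedy over the six gesture actions."""
    if epsilon > 0.0 and rng.random() < epsilon:
        return int(rng.integers(params.arch.n_actions))
    return greedy_action(params, obs)


def select_action_recurrent(
    params: QNetworkParams,
    obs: np.ndarray,
    h: np.ndarray,
    c: np.ndarray,
    epsilon: float,
    rng: np.random.Generator,
):
    """Epsilon-greedy step for the recurrent variant; carries hidden state.

    The hidden state advances with the observation regardless of whether the
    action came from exploration, so the memory trace matches what the
    network would see at evaluation time.
    """
    _, _, _, _, c_new, h_new = lstm_cell(params.theta, obs, h, c)
    hd = np.vstack([h_new])
    z1 = hd @ params.theta["W1"] + params.theta["b1"]
    a1 = np.maximum(z1, 0.0)
    z2 = a1 @ params.theta["W2"] + params.theta["b2"]
    a2 = np.maximum(z2, 0.0)
    q = (a2 @ params.theta["W3"] + params.theta["b3"])[0]
    if epsilon > 0.0 and rng.random() < epsilon:
        action = int(rng.integers(params.arch.n_actions))
    else:
        action = int(np.argmax(q))
    return action, h_new, c_new


def _stack_batch(batch: list[Transition], n_inputs: int):
    B = len(batch)
    obs = np.vstack([tr.obs for tr in batch])
    actions = np.array([tr.action for tr in batch], dtype=int)
    rewards = np.array([tr.reward for tr in batch], dtype=float)
    done = np.array([tr.done for tr in batch], dtype=bool)
    next_obs = np.zeros((B, n_inputs))
    for i, tr in enumerate(batch):
        if tr.next_obs is not None:
            next_obs[i] = tr.next_obs
    return obs, actions, rewards, next_obs, done


def compute_targets(
    batch: list[Transition],
    params: QNetworkParams,
    gamma: float,
    mode: str,
) -> np.ndarray:
    """Regression targets Y per transition (constants w.r.t. theta)."""
    if not batch:
        raise ValueError("empty batch")
    _, _, rewards, next_obs, done = _stack_batch(batch, params.arch.n_inputs)
    q_target = q_values(params.theta_target, params.arch, next_obs)
    if mode == "double_dqn":
        q_online = q_values(params.theta, params.arch, next_obs)
        sel = np.argmax(q_online, axis=1)
        boot = q_target[np.arange(len(batch)), sel]
    elif mode == "dqn":
        boot = q_target.max(axis=1)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return rewards + gamma * boot * (~done)


def learn_step(
    params: QNetworkParams,
    batch: list[Transition],
    config: AgentConfig,
) -> float:
    """One Adam step on the minibatch squared error; theta- untouched."""
    if not batch:
        raise ValueError("empty batch")
    targets = compute_targets(batch, params, config.gamma, config.mode)
    obs, actions, _, _, _ = _stack_batch(batch, params.arch.n_inputs)
    q, cache = mlp_forward(params.theta, obs)
    B = len(batch)
    taken = q[np.arange(B), actions]
    diff = taken - targets
    loss = float(np.mean(diff**2))
    dQ = np.zeros_like(q)
    dQ[np.arange(B), actions] = 2.0 * diff / B
    grads = mlp_backward(params.theta, cache, dQ)
    params.opt.beta1 = config.grad_decay
    params.opt.step(params.theta, grads, config.alpha, config.l2)
    return loss


def learn_step_sequence(
    params: QNetworkParams,
    episode: list[Transition],
    config: AgentConfig,
    rng: np.random.Generator,
) -> float:
    """BPTT update of the recurrent variant over one stored episode.

    Targets use the target network unrolled over the same episode, so the
    bootstrap hidden state is well-defined; the dropout mask is shared
    across time steps (variational dropout).
    """
    if not episode:
        raise ValueError("empty episode")
    N = len(episode)
    X = np.vstack([tr.obs for tr in episode])
    actions = np.array([tr.action for tr in episode], dtype=int)
    rewards = np.array([tr.reward for tr in episode], dtype=float)
    done = np.array([tr.done for tr in episode], dtype=bool)

    q_tar, _ = recurrent_forward(params.theta_target, X, drop_mask=None)
    if config.mode == "double_dqn":
        q_on, _ = recurrent_forward(params.theta, X, drop_mask=None)
        sel = np.argmax(q_on, axis=1)
        boot = q_tar[np.arange(N), sel]
    else:
        boot = q_tar.max(axis=1)
    targets = rewards.copy()
    targets[:-1] += config.gamma * boot[1:] * (~done[:-1])

    H = params.arch.lstm_units
    keep = 1.0 - params.arch.dropout
    drop_mask = (rng.random(H) < keep).astype(float) / keep
    q, cache = recurrent_forward(params.theta, X, drop_mask=drop_mask)
    taken = q[np.arange(N), actions]
    diff = taken - targets
    loss = float(np.mean(diff**2))
    dQ = np.zeros_like(q)
    dQ[np.arange(N), actions] = 2.0 * diff / N
    grads = recurrent_backward(params.theta, cache, dQ)
    params.opt.beta1 = config.grad_decay
    params.opt.step(params.theta, grads, config.alpha, config.l2)
    return loss


def update_target(
    params: QNetworkParams, config: AgentConfig, learn_step_count: int
) -> None:
    """Soft update theta- every ``target_update_freq`` learn steps."""
    if learn_step_count % config.target_update_freq != 0:
        return
    ts = config.smooth_factor
    for k in params.theta:
        params.theta_target[k] = (
            ts * params.theta[k] + (1.0 - ts) * params.theta_target[k]
        )


def decay_epsilon(epsilon: float, config: AgentConfig) -> float:
    return max(config.epsilon_min, epsilon * (1.0 - config.epsilon_decay))


# ------------------------------------------------------------ checkpointing


def save_checkpoint(
    params: QNetworkParams,
    config: AgentConfig,
    path,
    extra: dict | None = None,
    extra_arrays: dict[str, np.ndarray] | None = None,
) -> None:
    """Serialize agent state (networks, optimizer moments, epsilon, counters,
    config) so training can resume bit-compatibly."""
    arrays: dict[str, np.ndarray] = {}
    for prefix, d in (
        ("theta.", params.theta),
        ("target.", params.theta_target),
        ("adam_m.", params.opt.m),
        ("adam_v.", params.opt.v),
    ):
        for k, v in d.items():
            arrays[prefix + k] = v
    if params.obs_scale is not None:
        arrays["obs_scale"] = params.obs_scale
    for k, v in (extra_arrays or {}).items():
        arrays["extra." + k] = v
    meta = {
        "arch": asdict(params.arch),
        "config": asdict(config),
        "opt_t": params.opt.t,
        "learn_steps": params.learn_steps,
        "epsilon": params.epsilon,
        "extra": extra or {},
    }
    np.savez(path, meta=np.array(json.dumps(meta)), **arrays)


def load_checkpoint(path):
    """Inverse of :func:`save_checkpoint`.

    Returns (params, config, extra, extra_arrays).
    """
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["meta"]))
        arch_d = dict(meta["arch"])
        arch_d["hidden"] = tuple(arch_d["hidden"])
        arch = NetworkArch(**arch_d)
        config = AgentConfig(**meta["config"])
        theta, target, m, v = {}, {}, {}, {}
        extra_arrays: dict[str, np.ndarray] = {}
        obs_scale = None
        for key in data.files:
            if key == "meta":
                continue
            if key == "obs_scale":
                obs_scale = data[key]
            elif key.startswith("theta."):
                theta[key[6:]] = data[key]
            elif key.startswith("target."):
                target[key[7:]] = data[key]
            elif key.startswith("adam_m."):
                m[key[7:]] = data[key]
            elif key.startswith("adam_v."):
                v[key[7:]] = data[key]
            elif key.startswith("extra."):
                extra_arrays[key[6:]] = data[key]
        opt = Adam(beta1=config.grad_decay, t=meta["opt_t"], m=m, v=v)
        params = QNetworkParams(
            theta=theta,
            theta_target=target,
            arch=arch,
            opt=opt,
            obs_scale=obs_scale,
            learn_steps=meta["learn_steps"],
            epsilon=meta["epsilon"],
        )
    return params, config, meta["extra"], extra_arrays
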