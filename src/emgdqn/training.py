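"""Per-user training loop and hyperparameter sweeps.

One model is trained per user: the dataset is orientation-corrected, every
training sample becomes an episode, and for ``epochs`` passes (seeded
shuffle per pass) the agent acts epsilon-greedily through each episode,
storing transitions in replay and taking one learning step per environment
step once the buffer holds a full minibatch.  Per episode the loop logs the
cumulative reward, its trailing 5-episode mean and the initial-observation
value estimate max_a Q(O_1; theta) — the three standard training curves.

Raw window features span several orders of magnitude (energy vs mean
absolute value), so the trainer computes a per-dimension max-abs scale over
the training windows and divides every observation by it.  Zeros stay zeros
(inactive windows keep their all-zero observation); the scale is stored in
the checkpoint and applied identically at evaluation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .agent import (
    AgentConfig,
    QNetworkParams,
    ReplayBuffer,
    Transition,
    decay_epsilon,
    init_agent,
    learn_step,
    learn_step_sequence,
    load_checkpoint,
    save_checkpoint,
    select_action,
    select_action_recurrent,
    update_target,
)
from .datasets import UserDataset
from .env import RewardSpec, make_episode, reset_episode, step
from .network import NetworkArch, q_values
from .posteval import EvaluationResult, evaluate_user
from .preprocess import WindowSpec, correct_orientation
from .synthetic import ConfigurationError

#: BPTT updates taken after each acted episode (recurrent variant only).
RECURRENT_UPDATES_PER_EPISODE = 4


@dataclass
class TrainResult:
    params: QNetworkParams
    log: pd.DataFrame
    dataset: UserDataset  # orientation-corrected copy (evaluate on .testing)
    config: AgentConfig
    window: WindowSpec
    rewards: RewardSpec
    _rng_state: dict = field(default_factory=dict, repr=False)
    _buffer: object = None

    def evaluate(self) -> EvaluationResult:
        return evaluate_user(
            self.params, self.dataset.testing, self.window, self.rewards
        )


def compute_obs_scale(observation_matrices) -> np.ndarray:
    """Per-dimension max-abs divisor over all training windows (0 -> 1)."""
    stacked = np.vstack(observation_matrices)
    scale = np.abs(stacked).max(axis=0)
    scale[scale == 0.0] = 1.0
    return scale


def _buffer_to_arrays(buffer: ReplayBuffer, recurrent: bool):
    items = list(buffer._items)
    if recurrent:
        transitions = [tr for ep in items for tr in ep]
        lengths = np.array([len(ep) for ep in items], dtype=int)
    else:
        transitions = items
        lengths = np.array([], dtype=int)
    n = len(transitions)
    if n == 0:
        return {"buf_lengths": lengths}
    dim = transitions[0].obs.shape[0]
    obs = np.vstack([tr.obs for tr in transitions])
    next_obs = np.zeros((n, dim))
    for i, tr in enumerate(transitions):
        if tr.next_obs is not None:
            next_obs[i] = tr.next_obs
    return {
        "buf_obs": obs,
        "buf_actions": np.array([tr.action for tr in transitions], dtype=int),
        "buf_rewards": np.array([tr.reward for tr in transitions], dtype=float),
        "buf_next_obs": next_obs,
        "buf_done": np.array([tr.done for tr in transitions], dtype=bool),
        "buf_lengths": lengths,
    }


def _buffer_from_arrays(arrays, capacity: int, recurrent: bool) -> ReplayBuffer:
    buffer = ReplayBuffer(capacity)
    if "buf_obs" not in arrays:
        return buffer
    transitions = [
        Transition(
            obs=arrays["buf_obs"][i],
            action=int(arrays["buf_actions"][i]),
            reward=float(arrays["buf_rewards"][i]),
            next_obs=None if arrays["buf_done"][i] else arrays["buf_next_obs"][i],
            done=bool(arrays["buf_done"][i]),
        )
        for i in range(arrays["buf_obs"].shape[0])
    ]
    if recurrent:
        pos = 0
        for length in arrays["buf_lengths"]:
            buffer.push(tuple(transitions[pos : pos + int(length)]))
            pos += int(length)
    else:
        for tr in transitions:
            buffer.push(tr)
    return buffer


def train_user_model(
    user: UserDataset,
    config: AgentConfig | None = None,
    window: WindowSpec | None = None,
    rewards: RewardSpec | None = None,
    arch: NetworkArch | None = None,
    resume=None,
    progress=None,
) -> TrainResult:
    """Train one user-specific agent; fully deterministic given the seed.

    ``resume`` accepts the tuple returned by :func:`load_trained` and
    continues from the stored epoch boundary (pass a ``config`` with a
    larger ``epochs`` to extend the run); continuation is bit-compatible
    with an uninterrupted run.  ``progress`` is an optional callback taking
    the per-episode log record.
    """
    window = window or WindowSpec()
    rewards = rewards or RewardSpec()
    if not user.training:
        raise ConfigurationError(f"user {user.user_id}: no training samples")
    corrected = correct_orientation(user)
    episodes = [make_episode(s, window, rewards) for s in corrected.training]

    if resume is None:
        config = config or AgentConfig()
        arch = arch or NetworkArch()
        rng = np.random.default_rng(config.seed)
        params = init_agent(arch, config, rng)
        params.obs_scale = compute_obs_scale(
            [ep.observations for ep in episodes]
        )
        buffer = ReplayBuffer(config.buffer_capacity)
        epochs_done = 0
        epsilon = config.epsilon_init
        log_rows: list[dict] = []
    else:
        params, loaded_config, extra, extra_arrays = resume
        config = config or loaded_config
        arch = params.arch
        rng = np.random.default_rng(0)
        rng.bit_generator.state = json.loads(extra["rng_state"])
        buffer = _buffer_from_arrays(
            extra_arrays, config.buffer_capacity, arch.variant == "recurrent"
        )
        epochs_done = int(extra["epochs_done"])
        epsilon = params.epsilon
        log_rows = json.loads(extra.get("log", "[]"))

    recurrent = arch.variant == "recurrent"
    for ep in episodes:
        ep.observations = ep.observations / params.obs_scale

    rewards_history = [row["reward"] for row in log_rows]
    for _epoch in range(epochs_done, config.epochs):
        order = rng.permutation(len(episodes))
        for idx in order:
            ep = reset_episode(episodes[idx])
            q0 = float(q_values(params.theta, arch, ep.observations[0]).max())
            cumulative = 0.0
            h = c = np.zeros(arch.lstm_units) if recurrent else None
            obs = ep.current_observation
            episode_transitions: list[Transition] = []
            while True:
                if recurrent:
                    action, h, c = select_action_recurrent(
                        params, obs, h, c, epsilon, rng
                    )
                else:
                    action = select_action(params, obs, epsilon, rng)
                next_obs, reward, done = step(ep, action)
                cumulative += reward
                tr = Transition(
                    obs=obs,
                    action=action,
                    reward=reward,
                    next_obs=None if done else next_obs,
                    done=done,
                )
                if recurrent:
                    episode_transitions.append(tr)
                else:
                    buffer.push(tr)
                    if len(buffer) >= config.minibatch:
                        batch = buffer.sample(config.minibatch, rng)
                        learn_step(params, batch, config)
                        params.learn_steps += 1
                        update_target(params, config, params.learn_steps)
                        epsilon = decay_epsilon(epsilon, config)
                if done:
                    break
                obs = next_obs
            if recurrent:
                buffer.push(tuple(episode_transitions))
                for _ in range(RECURRENT_UPDATES_PER_EPISODE):
                    sampled = buffer.sample(1, rng)[0]
                    learn_step_sequence(params, list(sampled), config, rng)
                    params.learn_steps += 1
                    update_target(params, config, params.learn_steps)
                    epsilon = decay_epsilon(epsilon, config)
            rewards_history.append(cumulative)
            row = {
                "episode": len(rewards_history) - 1,
                "reward": cumulative,
                "reward_trailing5": float(np.mean(rewards_history[-5:])),
                "q0": q0,
                "epsilon": epsilon,
            }
            log_rows.append(row)
            if progress is not None:
                progress(row)
    params.epsilon = epsilon

    return TrainResult(
        params=params,
        log=pd.DataFrame(
            log_rows,
            columns=["episode", "reward", "reward_trailing5", "q0", "epsilon"],
        ),
        dataset=corrected,
        config=config,
        window=window,
        rewards=rewards,
        _rng_state=rng.bit_generator.state,
        _buffer=buffer,
    )


def save_trained(result: TrainResult, path) -> None:
    """Checkpoint a finished (or partially finished) training run."""
    extra = {
        "epochs_done": result.config.epochs,
        "rng_state": json.dumps(result._rng_state),
        "log": json.dumps(result.log.to_dict(orient="records")),
        "user_id": result.dataset.user_id,
        "window": {
            "length": result.window.length,
            "stride": result.window.stride,
            "energy_threshold": result.window.energy_threshold,
        },
    }
    extra_arrays = _buffer_to_arrays(
        result._buffer, result.params.arch.variant == "recurrent"
    )
    save_checkpoint(result.params, result.config, path, extra, extra_arrays)


def load_trained(path):
    """Load a checkpoint; the returned tuple feeds ``resume=`` directly."""
    return load_checkpoint(path)


def sweep(
    users: list[UserDataset],
    grid: list[AgentConfig],
    window: WindowSpec | None = None,
    rewards: RewardSpec | None = None,
    arch: NetworkArch | None = None,
) -> pd.DataFrame:
    """Train/evaluate every (user, config) pair; mean +- SD per config."""
    if not users or not grid:
        raise ConfigurationError("sweep needs at least one user and one config")
    rows = []
    for cfg_idx, cfg in enumerate(grid):
        cls, rec = [], []
        for user in users:
            result = train_user_model(user, cfg, window, rewards, arch)
            ev = result.evaluate()
            cls.append(ev.classification_accuracy)
            rec.append(ev.recognition_accuracy)
        rows.append(
            {
                "config": cfg_idx,
                "mode": cfg.mode,
                "alpha": cfg.alpha,
                "target_update_freq": cfg.target_update_freq,
                "n_users": len(users),
                "classification_mean": float(np.mean(cls)),
                "classification_sd": float(np.std(cls, ddof=0)),
                "recognition_mean": float(np.mean(rec)),
                "recognition_sd": float(np.std(rec, ddof=0)),
            }
        )
    return pd.DataFrame(rows)
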