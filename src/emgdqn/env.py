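"""The sequential-labelling environment: one EMG sample = one episode.

The agent never sees the raw signal, only the 40-dim feature vector of the
current window (a partially observable decision process: distinct windows
can produce identical observations).  Its action at each step is a gesture
label.  Rewards:

* every step: +1 if the action matches the window's true label, else -1;
* at the last window the full predicted label sequence is post-processed
  (expansion to points + majority vote) and compared with the ground truth:
  +10 if the overlap factor exceeds 75% (strict) *and* the dominant
  predicted label is the sample's gesture, else -10.  The terminal reward is
  the last classification reward plus this recognition bonus/penalty.

A window's true label is the sample's gesture when the window span overlaps
the activity mask by more than half the window length, relax otherwise.  The
truth vector used for the overlap factor is the ground truth rendered
through the same window-to-point expansion as the prediction, so an oracle
policy that emits every window's true label scores rho = 1 exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._labels import expand_windows, overlap_factor, postprocess_prediction
from .datasets import GESTURES, RELAX, EmgSample
from .features import compute_features
from .preprocess import WindowSpec, segment_sample

__all__ = [
    "RewardSpec",
    "EpisodeState",
    "make_episode",
    "reset_episode",
    "step",
    "overlap_factor",
]


@dataclass
class RewardSpec:
    r_correct: float = 1.0
    r_wrong: float = -1.0
    r_recog: float = 10.0
    r_norecog: float = -10.0
    overlap_threshold: float = 0.75  # strict >

    def __post_init__(self) -> None:
        if not 0.0 < self.overlap_threshold < 1.0:
            raise ValueError("overlap_threshold must lie in (0, 1)")


class EpisodeStateError(RuntimeError):
    """Stepping a finished episode."""


@dataclass
class EpisodeState:
    """Mutable per-episode state; observations and truths are fixed."""

    observations: np.ndarray  # (N, 40)
    window_truth: np.ndarray  # (N,) label indices
    actives: np.ndarray  # (N,) bool
    starts: np.ndarray  # (N,) window start indices
    spec: WindowSpec
    sample: EmgSample
    rewards: RewardSpec
    truth_points: np.ndarray  # (T,) ground truth at window resolution
    t: int = 1  # 1-based current step
    actions_taken: list[int] = field(default_factory=list)
    done: bool = False

    @property
    def N(self) -> int:
        return self.observations.shape[0]

    @property
    def gesture_index(self) -> int:
        return GESTURES.index(self.sample.gesture)

    @property
    def current_observation(self) -> np.ndarray:
        return self.observations[self.t - 1]


def make_episode(
    sample: EmgSample,
    spec: WindowSpec | None = None,
    rewards: RewardSpec | None = None,
) -> EpisodeState:
    """Segment + featurise a sample into a fresh episode."""
    spec = spec or WindowSpec()
    rewards = rewards or RewardSpec()
    windows = segment_sample(sample, spec)
    obs = np.vstack([compute_features(w).values for w in windows])
    starts = np.array([w.start for w in windows], dtype=int)
    actives = np.array([w.active for w in windows], dtype=bool)
    mask = np.asarray(sample.ground_truth, dtype=bool)
    gesture = GESTURES.index(sample.gesture)
    overlaps = np.array(
        [int(mask[s : s + spec.length].sum()) for s in starts]
    )
    truth = np.where(overlaps > spec.length / 2, gesture, RELAX)
    truth_points = expand_windows(
        truth, spec, sample.n_points, actives, starts
    )
    return EpisodeState(
        observations=obs,
        window_truth=truth,
        actives=actives,
        starts=starts,
        spec=spec,
        sample=sample,
        rewards=rewards,
        truth_points=truth_points,
    )


def reset_episode(state: EpisodeState) -> EpisodeState:
    """Fresh episode over the same (already computed) observations."""
    return EpisodeState(
        observations=state.observations,
        window_truth=state.window_truth,
        actives=state.actives,
        starts=state.starts,
        spec=state.spec,
        sample=state.sample,
        rewards=state.rewards,
        truth_points=state.truth_points,
    )


def step(state: EpisodeState, action: int):
    """Advance one window.  Returns (next_observation | None, reward, done)."""
    if state.done or state.t > state.N:
        raise EpisodeStateError("episode is already finished")
    rw = state.rewards
    correct = action == state.window_truth[state.t - 1]
    r_c = rw.r_correct if correct else rw.r_wrong
    state.actions_taken.append(int(action))
    if state.t < state.N:
        state.t += 1
        return state.current_observation, r_c, False
    # Terminal: post-process the whole predicted sequence and score overlap.
    cleaned, dominant = postprocess_prediction(
        state.actions_taken, state.spec, state.sample.n_points,
        state.actives, state.starts,
    )
    rho = overlap_factor(cleaned, state.truth_points)
    recognized = rho > rw.overlap_threshold and dominant == state.gesture_index
    reward = r_c + (rw.r_recog if recognized else rw.r_norecog)
    state.done = True
    state.t += 1
    return None, reward, True
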