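"""Majority-vote post-processing and classification/recognition scoring.

Classification accuracy asks "was the dominant predicted label the true
gesture"; recognition accuracy additionally asks "did the predicted gesture
span overlap the true activity region by more than 75%" (Dice form), i.e.
the gesture was not only identified but temporally localised.  Recognition
therefore implies classification, never the reverse.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._labels import (
    dominant_label,
    expand_windows,
    majority_vote,
    overlap_factor,
    postprocess_prediction,
)
from .datasets import GESTURES, EmgSample
from .network import q_values
from .preprocess import WindowSpec

__all__ = [
    "expand_windows",
    "majority_vote",
    "dominant_label",
    "PredictionResult",
    "EvaluationResult",
    "predict_sample",
    "evaluate_user",
    "results_table",
]


@dataclass
class PredictionResult:
    """Post-processed outcome for a single test sample."""

    window_labels: np.ndarray
    point_labels: np.ndarray
    dominant: int
    rho: float
    classified_ok: bool
    recognized_ok: bool


@dataclass
class EvaluationResult:
    classification_accuracy: float
    recognition_accuracy: float
    confusion: np.ndarray  # (6, 6) true x predicted-dominant counts
    predictions: list[PredictionResult] = field(default_factory=list)


def predict_sample(model, sample: EmgSample, spec=None, rewards=None) -> PredictionResult:
    """Greedy (epsilon = 0) prediction for one sample, post-processed."""
    from .agent import scale_obs
    from .env import RewardSpec, make_episode

    spec = spec or WindowSpec()
    rewards = rewards or RewardSpec()
    episode = make_episode(sample, spec, rewards)
    obs = scale_obs(model, episode.observations)
    # Greedy actions do not influence the recurrent hidden state, so one
    # full-sequence forward pass reproduces the step-by-step greedy policy.
    q = q_values(model.theta, model.arch, obs)
    labels = np.argmax(q, axis=1)
    cleaned, dominant = postprocess_prediction(
        labels, spec, sample.n_points, episode.actives, episode.starts
    )
    rho = overlap_factor(cleaned, episode.truth_points)
    classified = dominant == episode.gesture_index
    recognized = classified and rho > rewards.overlap_threshold
    return PredictionResult(
        window_labels=labels,
        point_labels=cleaned,
        dominant=dominant,
        rho=rho,
        classified_ok=bool(classified),
        recognized_ok=bool(recognized),
    )


def evaluate_user(model, test_samples, spec=None, rewards=None) -> EvaluationResult:
    """Greedy evaluation over a user's test split.

    ``test_samples`` must have gone through the same orientation correction
    as the training data the model saw.
    """
    if not test_samples:
        raise ValueError("empty test set")
    n_classes = len(GESTURES)
    confusion = np.zeros((n_classes, n_classes), dtype=int)
    predictions = []
    for sample in test_samples:
        pred = predict_sample(model, sample, spec, rewards)
        predictions.append(pred)
        confusion[GESTURES.index(sample.gesture), pred.dominant] += 1
    n = len(predictions)
    return EvaluationResult(
        classification_accuracy=sum(p.classified_ok for p in predictions) / n,
        recognition_accuracy=sum(p.recognized_ok for p in predictions) / n,
        confusion=confusion,
        predictions=predictions,
    )


def results_table(rows: list[tuple[str, EvaluationResult]]):
    """Per-user summary as a DataFrame (user_id, classification, recognition)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "user_id": uid,
                "classification": res.classification_accuracy,
                "recognition": res.recognition_accuracy,
            }
            for uid, res in rows
        ]
    )
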