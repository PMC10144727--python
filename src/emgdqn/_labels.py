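"""Shared label-vector primitives used by both the environment reward and the
evaluation pipeline, so training-time recognition and test-time recognition
are scored by exactly the same code."""

from __future__ import annotations

import numpy as np

from .datasets import RELAX, ValidationError


def expand_windows(
    window_labels,
    spec,
    T: int,
    actives,
    starts=None,
) -> np.ndarray:
    """Per-point labels from per-window labels.

    Each point receives the label of the last (latest-starting) *active*
    window covering it; points covered by no active window are relax.
    """
    window_labels = np.asarray(window_labels, dtype=int)
    actives = np.asarray(actives, dtype=bool)
    if starts is None:
        starts = np.arange(len(window_labels)) * spec.stride
    starts = np.asarray(starts, dtype=int)
    if not (len(window_labels) == len(actives) == len(starts)):
        raise ValidationError(
            "window_labels, actives and starts must have equal lengths"
        )
    if len(starts) and starts[-1] + spec.length > T:
        raise ValidationError("windows extend past the sample length")
    points = np.full(T, RELAX, dtype=int)
    for lab, act, s in zip(window_labels, actives, starts):
        if act:
            points[s : s + spec.length] = lab
    return points


def dominant_label(labels: np.ndarray) -> int:
    """Mode of the non-relax labels; ties broken by earliest first occurrence;
    relax if no non-relax label exists."""
    labels = np.asarray(labels, dtype=int)
    nonrelax = labels[labels != RELAX]
    if nonrelax.size == 0:
        return RELAX
    values, counts = np.unique(nonrelax, return_counts=True)
    best = counts.max()
    tied = set(values[counts == best])
    for lab in labels:  # earliest first occurrence among tied modes
        if lab in tied:
            return int(lab)
    raise AssertionError("unreachable")


def majority_vote(point_labels, activity_mask) -> np.ndarray:
    """Replace every label inside the activity region by the modal non-relax
    label and force relax outside it.  All-relax input stays all relax."""
    point_labels = np.asarray(point_labels, dtype=int)
    activity_mask = np.asarray(activity_mask, dtype=bool)
    if point_labels.shape != activity_mask.shape:
        raise ValidationError("point_labels and activity_mask length mismatch")
    region = point_labels[activity_mask]
    mode = dominant_label(region) if region.size else RELAX
    out = np.full_like(point_labels, RELAX)
    if mode != RELAX:
        out[activity_mask] = mode
    return out


def overlap_factor(pred_labels, truth_labels) -> float:
    """Sørensen–Dice overlap between the dominant predicted gesture span and
    the non-relax truth span: rho = 2|A n B| / (|A| + |B|).

    rho = 1 when both spans are empty, 0 when exactly one is.
    """
    pred = np.asarray(pred_labels, dtype=int)
    truth = np.asarray(truth_labels, dtype=int)
    if pred.shape != truth.shape:
        raise ValidationError("label vectors must have equal lengths")
    dom = dominant_label(pred)
    A = (pred == dom) if dom != RELAX else np.zeros_like(pred, dtype=bool)
    B = truth != RELAX
    na, nb = int(A.sum()), int(B.sum())
    if na + nb == 0:
        return 1.0
    return 2.0 * int((A & B).sum()) / (na + nb)


def postprocess_prediction(window_labels, spec, T, actives, starts=None):
    """Expand window labels to points and majority-vote them.

    The vote's activity region is the non-relax support of the expanded
    prediction, so voting homogenises the label but never widens the span.
    Returns (cleaned point labels, dominant label).
    """
    points = expand_windows(window_labels, spec, T, actives, starts)
    cleaned = majority_vote(points, points != RELAX)
    return cleaned, dominant_label(cleaned)
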