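"""Time-domain window features: the 40-dimensional observation vector.

Each 8-channel window maps to five features per channel, channel-major::

    [AE, E, RMS, STD, MAV] x 8 channels  ->  40 values

MAV  mean absolute value          (1/L) sum |x|
RMS  root mean square             sqrt((1/L) sum x^2)
E    energy                       sum x^2
STD  sample standard deviation    unbiased, denominator L-1
AE   absolute envelope            mean of the rectified signal smoothed by a
                                  centred 25-point moving average (~125 ms at
                                  200 Hz, edges truncated)

A window that failed the energy gate contributes the all-zero vector, which
is exactly what the Q-network receives for "no muscle activity here".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datasets import N_CHANNELS, ValidationError
from .preprocess import WindowObservationRaw, WindowSpec, segment_sample

FEATURE_NAMES = ("AE", "E", "RMS", "STD", "MAV")
FEATURES_PER_CHANNEL = len(FEATURE_NAMES)
FEATURE_DIM = FEATURES_PER_CHANNEL * N_CHANNELS  # 40, the network input size
AE_SMOOTH_WIDTH = 25


@dataclass
class FeatureVector:
    values: np.ndarray  # (40,)
    active: bool


def _absolute_envelope(x: np.ndarray) -> float:
    rect = np.abs(x)
    kernel = np.ones(AE_SMOOTH_WIDTH)
    counts = np.convolve(np.ones(x.shape[0]), kernel, mode="same")
    smoothed = np.convolve(rect, kernel, mode="same") / counts
    return float(smoothed.mean())


def compute_features(window: WindowObservationRaw) -> FeatureVector:
    """Map one raw window to its 40-dim observation (zeros if inactive)."""
    data = np.asarray(window.data, dtype=np.float64)
    if data.ndim != 2 or data.shape[0] != N_CHANNELS or data.shape[1] < 2:
        raise ValidationError(
            f"window data must be {N_CHANNELS} x L with L >= 2, "
            f"got shape {data.shape}"
        )
    if not window.active:
        return FeatureVector(values=np.zeros(FEATURE_DIM), active=False)
    L = data.shape[1]
    values = np.empty(FEATURE_DIM)
    for ch in range(N_CHANNELS):
        x = data[ch]
        sq = float(x @ x)
        base = ch * FEATURES_PER_CHANNEL
        values[base + 0] = _absolute_envelope(x)
        values[base + 1] = sq
        values[base + 2] = np.sqrt(sq / L)
        values[base + 3] = float(np.std(x, ddof=1))
        values[base + 4] = float(np.mean(np.abs(x)))
    return FeatureVector(values=values, active=True)


def feature_stream(sample, spec: WindowSpec) -> list[FeatureVector]:
    """Segment a sample and featurise every window, in temporal order."""
    return [compute_features(w) for w in segment_sample(sample, spec)]


def feature_matrix(sample, spec: WindowSpec) -> np.ndarray:
    """(N_windows, 40) observation matrix for one sample."""
    return np.vstack([fv.values for fv in feature_stream(sample, spec)])
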