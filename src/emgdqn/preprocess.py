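"""Sliding-window segmentation, energy gating and orientation correction.

Windows of 300 points with a 40-point stride tile each recording; a window
is kept ("active") only if its energy reaches 18% of the maximum window
energy within the same sample, a self-normalising gate that is insensitive
to per-user gain.  Armband orientation is corrected by finding the
maximum-energy channel over the user's waveOut synchronization samples and
circularly rotating every sample so that channel sits at index 0.

Conventions: 0-based indices, half-open window spans [start, start+length);
the energy gate is inclusive (ties at the threshold pass); argmax ties go to
the lowest channel index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datasets import N_CHANNELS, EmgSample, UserDataset
from .synthetic import ConfigurationError, rotate_channels


class SegmentationError(ValueError):
    """Sample too short for the requested window."""


@dataclass
class WindowSpec:
    length: int = 300
    stride: int = 40
    energy_threshold: float = 0.18

    def __post_init__(self) -> None:
        if self.length < 1 or self.stride < 1:
            raise ConfigurationError("window length and stride must be >= 1")
        if not 0.0 <= self.energy_threshold <= 1.0:
            raise ConfigurationError("energy_threshold must lie in [0, 1]")


@dataclass
class WindowObservationRaw:
    data: np.ndarray  # (8, length)
    start: int
    active: bool


def window_starts(T: int, spec: WindowSpec) -> np.ndarray:
    """All window start indices; count = floor((T - length)/stride) + 1."""
    if T < spec.length:
        raise SegmentationError(
            f"sample length {T} shorter than window length {spec.length}"
        )
    return np.arange(0, T - spec.length + 1, spec.stride)


def segment_sample(sample: EmgSample, spec: WindowSpec) -> list[WindowObservationRaw]:
    """Cut a sample into energy-gated sliding windows in temporal order."""
    sig = np.asarray(sample.signal, dtype=np.float64)
    starts = window_starts(sig.shape[1], spec)
    slices = [sig[:, s : s + spec.length] for s in starts]
    energies = np.array([float((w * w).sum()) for w in slices])
    e_max = energies.max()
    if e_max <= 0.0:
        active = np.zeros(len(starts), dtype=bool)
    else:
        active = energies / e_max >= spec.energy_threshold
    return [
        WindowObservationRaw(data=w, start=int(s), active=bool(a))
        for w, s, a in zip(slices, starts, active)
    ]


def sync_channel_energies(samples: list[EmgSample]) -> np.ndarray:
    """Per-channel energy (sum of squared amplitudes) over all samples."""
    energies = np.zeros(N_CHANNELS)
    for s in samples:
        sig = np.asarray(s.signal, dtype=np.float64)
        energies += (sig * sig).sum(axis=1)
    return energies


def correct_orientation(dataset: UserDataset) -> UserDataset:
    """Rotate every sample so the sync max-energy channel maps to index 0."""
    if not dataset.sync_samples:
        raise ConfigurationError(
            f"user {dataset.user_id}: no synchronization samples for "
            "orientation correction"
        )
    energies = sync_channel_energies(dataset.sync_samples)
    k = int(np.argmax(energies))  # ties -> lowest index
    return UserDataset(
        user_id=dataset.user_id,
        training=[rotate_channels(s, k) for s in dataset.training],
        testing=[rotate_channels(s, k) for s in dataset.testing],
        sync_samples=[rotate_channels(s, k) for s in dataset.sync_samples],
    )
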