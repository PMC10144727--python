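"""Per-user EMG dataset containers and the plain-text on-disk layout.

A recording session for one user is a :class:`UserDataset`: training and
testing gesture samples plus a handful of "waveOut" synchronization samples
used only for armband orientation correction.  Each :class:`EmgSample` is an
8-channel signal sampled at 200 Hz with a per-point binary muscle-activity
mask (the ground truth used for recognition scoring).

On disk a user is a directory::

    user_<id>/
        meta.json            user id, sampling rate, class list
        train/<sample>.txt   one plain-text file per sample
        test/<sample>.txt
        sync/<sample>.txt    waveOut synchronization samples

Sample files store the signal as float32 rendered with 9 significant digits,
which round-trips float32 exactly and makes writes byte-deterministic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

#: Canonical gesture labels; the index in this tuple is the action index.
GESTURES = ("fist", "waveIn", "open", "waveOut", "pinch", "relax")
#: Action index of the no-gesture class.
RELAX = GESTURES.index("relax")
N_CHANNELS = 8
DEFAULT_FS = 200.0

_FMT = "%.9g"  # exact float32 round-trip


class ValidationError(ValueError):
    """A sample or dataset violates a structural invariant."""


@dataclass
class EmgSample:
    """One gesture recording: 8 x T signal plus per-point activity mask."""

    signal: np.ndarray  # (8, T) float32
    gesture: str
    ground_truth: np.ndarray  # (T,) uint8, all zero for relax
    fs: float = DEFAULT_FS
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=np.float32)
        self.ground_truth = np.asarray(self.ground_truth, dtype=np.uint8)

    @property
    def n_points(self) -> int:
        return self.signal.shape[1]

    def validate(self) -> None:
        sid = self.sample_id or "<unnamed>"
        if self.signal.ndim != 2 or self.signal.shape[0] != N_CHANNELS:
            raise ValidationError(
                f"sample {sid}: signal must be {N_CHANNELS} x T, "
                f"got shape {self.signal.shape}"
            )
        if self.signal.shape[1] < 1:
            raise ValidationError(f"sample {sid}: empty signal")
        if self.gesture not in GESTURES:
            raise ValidationError(f"sample {sid}: unknown gesture {self.gesture!r}")
        if self.ground_truth.shape != (self.signal.shape[1],):
            raise ValidationError(
                f"sample {sid}: ground_truth length {self.ground_truth.shape} "
                f"does not match T={self.signal.shape[1]}"
            )
        if self.gesture == "relax" and self.ground_truth.any():
            raise ValidationError(f"sample {sid}: relax sample with nonzero mask")


@dataclass
class UserDataset:
    """All recordings of one user, split into train/test plus sync samples."""

    user_id: str
    training: list[EmgSample] = field(default_factory=list)
    testing: list[EmgSample] = field(default_factory=list)
    sync_samples: list[EmgSample] = field(default_factory=list)

    def validate(self) -> None:
        for s in self.training + self.testing + self.sync_samples:
            s.validate()
        for s in self.sync_samples:
            if s.gesture != "waveOut":
                raise ValidationError(
                    f"sync sample {s.sample_id}: gesture must be waveOut, "
                    f"got {s.gesture!r}"
                )


def _write_sample(sample: EmgSample, path: Path) -> None:
    sig = np.asarray(sample.signal, dtype=np.float32)
    lines = [
        f"sample_id\t{sample.sample_id}",
        f"gesture\t{sample.gesture}",
        f"fs\t{_FMT % sample.fs}",
        f"shape\t{sig.shape[0]}\t{sig.shape[1]}",
        "mask\t" + "".join("1" if v else "0" for v in sample.ground_truth),
    ]
    for ch in sig:
        lines.append(" ".join(_FMT % v for v in ch))
    path.write_text("\n".join(lines) + "\n")


def _read_sample(path: Path) -> EmgSample:
    lines = path.read_text().splitlines()
    try:
        header = dict(
            (ln.split("\t", 1)[0], ln.split("\t", 1)[1]) for ln in lines[:3]
        )
        shape_parts = lines[3].split("\t")
        n_ch, n_pts = int(shape_parts[1]), int(shape_parts[2])
        mask_str = lines[4].split("\t", 1)[1]
    except (IndexError, KeyError) as exc:  # malformed file
        raise ValidationError(f"{path}: malformed sample file") from exc
    rows = [
        np.array(ln.split(), dtype=np.float32) for ln in lines[5 : 5 + n_ch]
    ]
    if len(rows) != n_ch or any(r.shape != (n_pts,) for r in rows):
        raise ValidationError(f"{path}: data block does not match declared shape")
    mask = np.frombuffer(mask_str.encode(), dtype=np.uint8) - ord("0")
    return EmgSample(
        signal=np.vstack(rows) if rows else np.empty((0, n_pts), np.float32),
        gesture=header["gesture"],
        ground_truth=mask,
        fs=float(header["fs"]),
        sample_id=header["sample_id"],
    )


def save_user_dataset(dataset: UserDataset, path: str | Path) -> None:
    """Write a validated dataset to ``path`` in the documented layout.

    Writing the same dataset twice produces byte-identical files.
    """
    dataset.validate()
    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)
    order: dict[str, list[str]] = {}
    for sub, samples in (
        ("train", dataset.training),
        ("test", dataset.testing),
        ("sync", dataset.sync_samples),
    ):
        d = root / sub
        d.mkdir(exist_ok=True)
        names = []
        for i, s in enumerate(samples):
            name = s.sample_id or f"{sub}_{i:04d}"
            _write_sample(s, d / f"{name}.txt")
            names.append(name)
        order[sub] = names
    meta = {
        "user_id": dataset.user_id,
        "fs": dataset.training[0].fs if dataset.training else DEFAULT_FS,
        "classes": list(GESTURES),
        "samples": order,  # preserves the stored sample order on reload
        "format": "emgdqn-user-v1",
    }
    (root / "meta.json").write_text(
        json.dumps(meta, sort_keys=True, indent=2) + "\n"
    )


def load_user_dataset(path: str | Path) -> UserDataset:
    """Load a dataset written by :func:`save_user_dataset` and validate it."""
    root = Path(path)
    meta_path = root / "meta.json"
    if not meta_path.exists():
        raise FileNotFoundError(f"no meta.json under {root}")
    meta = json.loads(meta_path.read_text())
    order = meta.get("samples", {})
    parts: dict[str, list[EmgSample]] = {}
    for sub in ("train", "test", "sync"):
        d = root / sub
        if sub in order:
            files = [d / f"{name}.txt" for name in order[sub]]
        else:
            files = sorted(d.glob("*.txt")) if d.is_dir() else []
        parts[sub] = [_read_sample(f) for f in files]
    ds = UserDataset(
        user_id=str(meta.get("user_id", root.name)),
        training=parts["train"],
        testing=parts["test"],
        sync_samples=parts["sync"],
    )
    ds.validate()
    return ds
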