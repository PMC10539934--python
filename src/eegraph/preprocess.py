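"""Continuous-EEG preprocessing: band-pass filtering, epoching, artifact screening.

The fixed order of operations is filter (continuous) -> epoch -> screen ->
select; :func:`preprocess_recording` enforces it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .montage import validate_channels

__all__ = [
    "Recording",
    "EpochSet",
    "bandpass_filter",
    "epoch",
    "screen_artifacts",
    "select_epochs",
    "preprocess_recording",
]


@dataclass
class Recording:
    """A continuous multichannel recording in microvolts.

    ``data`` is a (n_channels, n_samples) array; ``channels`` are montage
    labels in row order.
    """

    channels: tuple[str, ...]
    fs: float
    data: np.ndarray
    subject_id: str = ""
    group: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.channels = tuple(self.channels)
        if self.data.ndim != 2 or self.data.shape[0] != len(self.channels):
            raise ValueError(
                f"data must be (n_channels, n_samples); got {self.data.shape} "
                f"for {len(self.channels)} channels"
            )
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        validate_channels(self.channels)

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


@dataclass
class EpochSet:
    """Fixed-length epochs, shape (n_epochs, n_channels, n_samples_per_epoch)."""

    epochs: np.ndarray
    channels: tuple[str, ...]
    fs: float
    epoch_length: float
    subject_id: str = ""
    group: str = ""
    kept_indices: tuple[int, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=float)
        self.channels = tuple(self.channels)
        if self.epochs.ndim != 3:
            raise ValueError("epochs must be a 3-d array")
        if self.epochs.shape[0] < 1:
            raise ValueError("need at least one epoch")
        expected = round(self.fs * self.epoch_length)
        if self.epochs.shape[2] != expected:
            raise ValueError(
                f"epoch length mismatch: {self.epochs.shape[2]} samples, "
                f"expected {expected}"
            )

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    def concatenated(self) -> np.ndarray:
        """Channel-wise concatenation of all epochs, shape (n_channels, total)."""
        return np.concatenate(list(self.epochs), axis=1)

    def save(self, path) -> None:
        """Write epochs as a ``.npy`` array with a JSON provenance sidecar."""
        import json
        from pathlib import Path

        path = Path(path)
        np.save(path, self.epochs)
        meta = {
            "channels": list(self.channels),
            "fs": self.fs,
            "epoch_length": self.epoch_length,
            "subject_id": self.subject_id,
            "group": self.group,
            "kept_indices": [int(i) for i in self.kept_indices],
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, path) -> "EpochSet":
        import json
        from pathlib import Path

        path = Path(path)
        if path.suffix != ".npy":
            path = path.with_suffix(".npy")
        meta = json.loads(path.with_suffix(".json").read_text())
        return cls(
            np.load(path), tuple(meta["channels"]), meta["fs"],
            meta["epoch_length"], subject_id=meta["subject_id"],
            group=meta["group"], kept_indices=tuple(meta["kept_indices"]),
        )


def bandpass_filter(rec: Recording, f_lo: float, f_hi: float, order: int = 4) -> Recording:
    """Zero-phase Butterworth band-pass of a continuous recording.

    Applies a forward-backward (``sosfiltfilt``) 4th-order Butterworth filter
    per channel, preserving length and avoiding phase distortion that would
    corrupt downstream phase-based connectivity.
    """
    nyq = rec.fs / 2.0
    if not (0 <= f_lo < f_hi < nyq):
        raise ValueError(f"invalid band edges ({f_lo}, {f_hi}) for fs={rec.fs}")
    if f_lo == 0:
        sos = signal.butter(order, f_hi, btype="lowpass", fs=rec.fs, output="sos")
    else:
        sos = signal.butter(order, [f_lo, f_hi], btype="bandpass", fs=rec.fs, output="sos")
    filtered = signal.sosfiltfilt(sos, rec.data, axis=1)
    return Recording(rec.channels, rec.fs, filtered, rec.subject_id, rec.group)


def epoch(rec: Recording, epoch_length: float = 2.0) -> EpochSet:
    """Cut a recording into consecutive non-overlapping fixed-length epochs.

    A trailing partial epoch is discarded.
    """
    n_per = round(rec.fs * epoch_length)
    n_ep = rec.n_samples // n_per
    if n_ep < 1:
        raise ValueError(
            f"recording of {rec.duration:.2f} s shorter than one "
            f"{epoch_length} s epoch"
        )
    trimmed = rec.data[:, : n_ep * n_per]
    eps = trimmed.reshape(rec.data.shape[0], n_ep, n_per).transpose(1, 0, 2)
    return EpochSet(
        eps, rec.channels, rec.fs, epoch_length,
        subject_id=rec.subject_id, group=rec.group,
        kept_indices=tuple(range(n_ep)),
    )


def screen_artifacts(
    es: EpochSet, amp_limit: float = 150.0, flat_limit: float = 0.5
) -> np.ndarray:
    """Boolean mask of artifact-free epochs (True = keep).

    An epoch is rejected if any channel's peak-to-peak amplitude exceeds
    ``amp_limit`` (gross artifact) or falls below ``flat_limit`` (flatline).
    Automated stand-in for visual epoch rejection.
    """
    if amp_limit <= 0 or flat_limit <= 0:
        raise ValueError("limits must be positive")
    ptp = es.epochs.max(axis=2) - es.epochs.min(axis=2)  # (n_epochs, n_channels)
    bad = (ptp > amp_limit).any(axis=1) | (ptp < flat_limit).any(axis=1)
    return ~bad


def select_epochs(es: EpochSet, mask: np.ndarray, n_keep: int = 50) -> EpochSet:
    """Keep the first ``n_keep`` good epochs in temporal order."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != (es.n_epochs,):
        raise ValueError("mask length must equal number of epochs")
    good = np.flatnonzero(mask)
    if good.size < n_keep:
        raise ValueError(
            f"insufficient artifact-free epochs: need {n_keep}, "
            f"have {good.size} (short by {n_keep - good.size})"
        )
    sel = good[:n_keep]
    provenance = (np.asarray(es.kept_indices) if es.kept_indices
                  else np.arange(es.n_epochs))
    return EpochSet(
        es.epochs[sel], es.channels, es.fs, es.epoch_length,
        subject_id=es.subject_id, group=es.group,
        kept_indices=tuple(provenance[sel]),
    )


def preprocess_recording(
    rec: Recording,
    f_lo: float = 0.1,
    f_hi: float = 50.0,
    epoch_length: float = 2.0,
    n_keep: int = 50,
    amp_limit: float = 150.0,
    flat_limit: float = 0.5,
) -> EpochSet:
    """Full preprocessing chain: filter -> epoch -> screen -> select."""
    filt = bandpass_filter(rec, f_lo, f_hi)
    es = epoch(filt, epoch_length)
    mask = screen_artifacts(es, amp_limit=amp_limit, flat_limit=flat_limit)
    return select_epochs(es, mask, n_keep=n_keep)
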