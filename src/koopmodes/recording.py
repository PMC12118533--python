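"""Core in-memory containers for multichannel EEG data.

A :class:`MultichannelRecording` is the unit every stage of the pipeline
consumes and produces: a real-valued ``(n_channels, n_samples)`` array with
its sampling rate, channel labels and an optional brain-state tag.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

#: The 19 scalp electrodes of the standard 10-20 montage, in clinical order.
CHANNELS_1020 = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T3", "C3", "Cz", "C4", "T4",
    "T5", "P3", "Pz", "P4", "T6",
    "O1", "O2",
)


def default_labels(n_ch: int) -> list[str]:
    """Channel labels for ``n_ch`` channels: 10-20 names when they fit."""
    if n_ch <= len(CHANNELS_1020):
        return list(CHANNELS_1020[:n_ch])
    return list(CHANNELS_1020) + [f"EEG{i}" for i in range(len(CHANNELS_1020), n_ch)]


@dataclass
class MultichannelRecording:
    """A multichannel time series with sampling metadata.

    Parameters
    ----------
    data
        Real matrix of shape ``(n_channels, n_samples)`` (µV or arbitrary
        units).
    fs
        Sampling rate in Hz, strictly positive.
    channel_labels
        Unique names, one per channel; defaults to 10-20 names.
    state_label
        Optional brain-state tag (e.g. ``"Status"`` or ``"Resolved"``).
    """

    data: np.ndarray
    fs: float
    channel_labels: list[str] = field(default_factory=list)
    state_label: str | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (n_channels, n_samples)")
        if not np.isfinite(self.data).all():
            raise ValueError("recording contains NaN or infinite samples")
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if not self.channel_labels:
            self.channel_labels = default_labels(self.n_channels)
        if len(self.channel_labels) != self.n_channels:
            raise ValueError(
                f"{len(self.channel_labels)} labels for {self.n_channels} channels"
            )
        dupes = _duplicates(self.channel_labels)
        if dupes:
            raise ValueError(f"duplicate channel labels: {sorted(dupes)}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Length in seconds."""
        return self.n_samples / self.fs

    def with_data(self, data: np.ndarray, fs: float | None = None) -> "MultichannelRecording":
        """Copy of this recording with new samples (and optionally new fs)."""
        return replace(self, data=np.asarray(data, float), fs=self.fs if fs is None else fs)


@dataclass
class EpochSet:
    """Equal-length windows cut from one recording.

    ``epochs`` is a list of ``(n_channels, epoch_samples)`` views in temporal
    order; metadata of the parent recording is carried along so downstream
    spectral estimators know the sampling rate and channel names.
    """

    epochs: list[np.ndarray]
    epoch_length: float
    fs: float
    channel_labels: list[str]
    state_label: str | None = None

    def __post_init__(self) -> None:
        shapes = {e.shape for e in self.epochs}
        if len(shapes) > 1:
            raise ValueError(f"epochs have inconsistent shapes: {shapes}")

    def __len__(self) -> int:
        return len(self.epochs)

    def __iter__(self):
        return iter(self.epochs)

    def as_array(self) -> np.ndarray:
        """Stack into ``(n_epochs, n_channels, epoch_samples)``."""
        return np.stack(self.epochs) if self.epochs else np.empty((0, 0, 0))


def _duplicates(labels: Sequence[str]) -> set[str]:
    seen: set[str] = set()
    dupes: set[str] = set()
    for lab in labels:
        if lab in seen:
            dupes.add(lab)
        seen.add(lab)
    return dupes
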