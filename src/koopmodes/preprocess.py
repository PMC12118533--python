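"""Preprocessing: high-pass filtering, resampling, epoching, sliding windows.

Clinical status-epilepticus EEG needs little cleaning; the pipeline only
high-pass filters at 0.5 Hz (removing drifts and DC) and resamples from the
acquisition rate (typically 200 Hz) down to 100 Hz, which keeps every band up
to low gamma while halving the modeling cost.  The filter is a zero-phase
forward-backward 4th-order Butterworth so mode phases are not distorted;
resampling is polyphase with anti-aliasing.
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np
from scipy import signal

from .recording import EpochSet, MultichannelRecording

__all__ = ["preprocess", "epoch", "sliding_windows"]

DEFAULT_HP_CUTOFF = 0.5  # Hz
DEFAULT_TARGET_FS = 100.0  # Hz
DEFAULT_EPOCH_LENGTH = 20.0  # s


def preprocess(
    rec: MultichannelRecording,
    hp_cutoff: float = DEFAULT_HP_CUTOFF,
    target_fs: float = DEFAULT_TARGET_FS,
) -> MultichannelRecording:
    """High-pass filter then downsample a recording.

    Parameters
    ----------
    rec
        Input recording.
    hp_cutoff
        High-pass corner frequency in Hz (zero-phase Butterworth, order 4).
        ``0`` disables filtering.
    target_fs
        Output sampling rate; must not exceed ``rec.fs`` (no upsampling).
    """
    if target_fs > rec.fs:
        raise ValueError(
            f"upsampling not supported: target_fs={target_fs} > fs={rec.fs}"
        )
    if hp_cutoff >= target_fs / 2:
        raise ValueError(
            f"hp_cutoff={hp_cutoff} must be below the output Nyquist {target_fs / 2}"
        )
    data = rec.data
    if hp_cutoff > 0:
        sos = signal.butter(4, hp_cutoff, btype="highpass", fs=rec.fs, output="sos")
        data = signal.sosfiltfilt(sos, data, axis=1)
    if target_fs != rec.fs:
        ratio = Fraction(target_fs / rec.fs).limit_denominator(1000)
        data = signal.resample_poly(data, ratio.numerator, ratio.denominator, axis=1)
    return rec.with_data(data, fs=target_fs)


def epoch(
    rec: MultichannelRecording,
    epoch_length: float = DEFAULT_EPOCH_LENGTH,
    overlap: float = 0.0,
) -> EpochSet:
    """Cut a recording into equal-length epochs.

    The maximal set of epochs at stride ``epoch_length - overlap`` is
    returned; a trailing segment shorter than ``epoch_length`` is discarded.
    A recording shorter than one epoch yields an empty :class:`EpochSet`.
    """
    if epoch_length <= 0:
        raise ValueError(f"epoch_length must be positive, got {epoch_length}")
    if overlap < 0:
        raise ValueError(f"overlap must be non-negative, got {overlap}")
    if overlap >= epoch_length:
        raise ValueError("overlap must be smaller than epoch_length")
    n_epoch = int(round(epoch_length * rec.fs))
    stride = int(round((epoch_length - overlap) * rec.fs))
    epochs = [
        rec.data[:, start : start + n_epoch]
        for start in range(0, rec.n_samples - n_epoch + 1, stride)
    ]
    return EpochSet(
        epochs=epochs,
        epoch_length=epoch_length,
        fs=rec.fs,
        channel_labels=rec.channel_labels,
        state_label=rec.state_label,
    )


def sliding_windows(
    data: np.ndarray, n: int, stride: int
) -> list[tuple[int, np.ndarray]]:
    """Sliding analysis windows over ``(n_ch, n_samples)`` data.

    Returns ``(start_sample, window_view)`` pairs; windows of length ``n``
    advance by ``stride`` samples and a trailing partial window is dropped.
    """
    if n <= 0 or stride <= 0:
        raise ValueError("window length and stride must be positive")
    return [
        (start, data[:, start : start + n])
        for start in range(0, data.shape[1] - n + 1, stride)
    ]
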