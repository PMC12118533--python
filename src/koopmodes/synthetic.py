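"""Synthetic two-state EEG with planted coherent oscillations.

Real status-epilepticus recordings cannot be redistributed, so every stage of
the pipeline is exercised on surrogate data instead.  A surrogate recording is
a sum of planted coherent oscillations — each one a fixed frequency with a
per-channel amplitude and phase profile, exactly the structure a DMD mode
describes — on top of channel-independent pink (1/f power) and white noise.

Two presets emulate the two clinical brain states: a "Status"-like state
dominated by a strong low-delta coherent mode, and a "Resolved"-like state in
which delta power is reduced and an alpha-band coherent mode appears.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .recording import MultichannelRecording, default_labels

__all__ = [
    "OscillatorSpec",
    "StateSpec",
    "generate_state_recording",
    "make_two_state_dataset",
    "status_like_spec",
    "resolved_like_spec",
    "pink_noise",
]


@dataclass(frozen=True)
class OscillatorSpec:
    """One planted coherent oscillation.

    ``channel_amplitudes[j] * decay**t * cos(2*pi*frequency*t/fs +
    channel_phases[j])`` is added to channel ``j``.  ``decay`` = 1 is a pure
    steady state; values below 1 give an exponentially damped transient.
    """

    frequency: float
    channel_amplitudes: tuple[float, ...]
    channel_phases: tuple[float, ...]
    decay: float = 1.0

    def __post_init__(self) -> None:
        amps = np.asarray(self.channel_amplitudes, float)
        phases = np.asarray(self.channel_phases, float)
        if self.frequency <= 0:
            raise ValueError(f"frequency must be positive, got {self.frequency}")
        if amps.shape != phases.shape:
            raise ValueError("amplitude and phase vectors must have equal length")
        if (amps < 0).any():
            raise ValueError("channel amplitudes must be non-negative")
        if (phases <= -np.pi).any() or (phases > np.pi).any():
            raise ValueError("channel phases must lie in (-pi, pi]")
        if not 0 < self.decay <= 1:
            raise ValueError(f"decay must be in (0, 1], got {self.decay}")

    @property
    def n_ch(self) -> int:
        return len(self.channel_amplitudes)


@dataclass(frozen=True)
class StateSpec:
    """Full description of one synthetic brain state."""

    oscillators: tuple[OscillatorSpec, ...]
    pink_noise_scale: float = 0.0
    white_noise_scale: float = 0.0
    duration: float = 60.0
    fs: float = 200.0
    n_ch: int = 19
    seed: int = 0
    state_label: str | None = None

    def __post_init__(self) -> None:
        n = self.duration * self.fs
        if abs(n - round(n)) > 1e-9:
            raise ValueError("duration * fs must be a whole number of samples")
        if self.n_ch < 2:
            raise ValueError("need at least 2 channels")
        if self.pink_noise_scale < 0 or self.white_noise_scale < 0:
            raise ValueError("noise scales must be non-negative")
        for osc in self.oscillators:
            if osc.n_ch != self.n_ch:
                raise ValueError(
                    f"oscillator has {osc.n_ch} channels, state has {self.n_ch}"
                )
            if osc.frequency >= self.fs / 2:
                raise ValueError(
                    f"oscillator frequency {osc.frequency} Hz is at or above "
                    f"the Nyquist frequency {self.fs / 2} Hz"
                )

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.fs))


def pink_noise(rng: np.random.Generator, n_samples: int) -> np.ndarray:
    """One channel of unit-variance pink noise (power spectral density ∝ 1/f).

    White Gaussian noise is shaped in the frequency domain by a 1/sqrt(f)
    amplitude profile (the DC bin is zeroed) and renormalised to unit sample
    variance, so ``scale * pink_noise(...)`` has variance ``scale**2`` exactly.
    """
    white = rng.standard_normal(n_samples)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n_samples)
    shaping = np.zeros_like(freqs)
    shaping[1:] = 1.0 / np.sqrt(freqs[1:])
    x = np.fft.irfft(spec * shaping, n=n_samples)
    std = x.std()
    return x / std if std > 0 else x


def generate_state_recording(spec: StateSpec) -> MultichannelRecording:
    """Render a :class:`StateSpec` into a deterministic multichannel recording.

    The signal is the closed-form sum of the planted oscillators plus
    independent pink and white noise per channel; the same seed yields a
    bit-identical recording.
    """
    n = spec.n_samples
    t = np.arange(n)
    data = np.zeros((spec.n_ch, n))
    for osc in spec.oscillators:
        amps = np.asarray(osc.channel_amplitudes)[:, None]
        phases = np.asarray(osc.channel_phases)[:, None]
        envelope = osc.decay ** t if osc.decay < 1.0 else 1.0
        phase = 2 * np.pi * osc.frequency * t / spec.fs
        data += amps * envelope * np.cos(phase[None, :] + phases)

    rng = np.random.default_rng(spec.seed)
    if spec.pink_noise_scale > 0:
        for ch in range(spec.n_ch):
            data[ch] += spec.pink_noise_scale * pink_noise(rng, n)
    if spec.white_noise_scale > 0:
        white = rng.standard_normal((spec.n_ch, n))
        white /= white.std(axis=1, keepdims=True)
        data += spec.white_noise_scale * white

    return MultichannelRecording(
        data=data,
        fs=spec.fs,
        channel_labels=default_labels(spec.n_ch),
        state_label=spec.state_label,
    )


def _anterior_posterior_gradient(n_ch: int, front: float, back: float) -> tuple[float, ...]:
    """Amplitude profile decreasing (or increasing) from channel 0 to n_ch-1.

    With 10-20 ordering this is roughly an anterior→posterior gradient, giving
    each planted mode a non-trivial scalp topography.
    """
    return tuple(np.linspace(front, back, n_ch))


def _phase_gradient(n_ch: int, span: float) -> tuple[float, ...]:
    """Linear phase gradient over channels, total span ``span`` radians."""
    return tuple(np.linspace(0.0, span, n_ch))


def status_like_spec(
    *,
    n_ch: int = 19,
    fs: float = 200.0,
    duration: float = 60.0,
    seed: int = 11,
    delta_freq: float = 2.5,
    noise: float = 1.0,
) -> StateSpec:
    """Preset emulating ongoing status epilepticus.

    A single strong coherent delta-band oscillation (default 2.5 Hz) with a
    frontal-dominant amplitude gradient and a mild phase gradient, over a
    pink + white noise background.  ``noise`` scales both noise components
    together (1.0 = the default moderate background).
    """
    return StateSpec(
        oscillators=(
            OscillatorSpec(
                frequency=delta_freq,
                channel_amplitudes=_anterior_posterior_gradient(n_ch, 1.6, 0.9),
                channel_phases=_phase_gradient(n_ch, np.pi / 3),
            ),
        ),
        pink_noise_scale=0.30 * noise,
        white_noise_scale=0.10 * noise,
        duration=duration,
        fs=fs,
        n_ch=n_ch,
        seed=seed,
        state_label="Status",
    )


def resolved_like_spec(
    *,
    n_ch: int = 19,
    fs: float = 200.0,
    duration: float = 60.0,
    seed: int = 23,
    alpha_freq: float = 10.5,
    delta_freq: float = 2.5,
    noise: float = 1.0,
) -> StateSpec:
    """Preset emulating the resolved state after status epilepticus.

    Delta-band coherence is strongly reduced and a posterior-dominant
    alpha-band coherent mode (default 10.5 Hz) appears.
    """
    return StateSpec(
        oscillators=(
            OscillatorSpec(
                frequency=alpha_freq,
                channel_amplitudes=_anterior_posterior_gradient(n_ch, 0.7, 1.3),
                channel_phases=_phase_gradient(n_ch, np.pi / 4),
            ),
            OscillatorSpec(
                frequency=delta_freq,
                channel_amplitudes=_anterior_posterior_gradient(n_ch, 0.30, 0.18),
                channel_phases=_phase_gradient(n_ch, np.pi / 6),
            ),
        ),
        pink_noise_scale=0.30 * noise,
        white_noise_scale=0.10 * noise,
        duration=duration,
        fs=fs,
        n_ch=n_ch,
        seed=seed,
        state_label="Resolved",
    )


def make_two_state_dataset(
    status_spec: StateSpec | None = None,
    resolved_spec: StateSpec | None = None,
) -> tuple[MultichannelRecording, MultichannelRecording]:
    """Generate a labeled (Status-like, Resolved-like) pair of recordings.

    With no arguments the default presets are used.  The two specs must agree
    in channel count and sampling rate so downstream comparisons are
    element-wise meaningful.
    """
    if status_spec is None:
        status_spec = status_like_spec()
    if resolved_spec is None:
        resolved_spec = resolved_like_spec()
    if status_spec.n_ch != resolved_spec.n_ch:
        raise ValueError(
            f"channel counts differ: {status_spec.n_ch} vs {resolved_spec.n_ch}"
        )
    if status_spec.fs != resolved_spec.fs:
        raise ValueError(f"sampling rates differ: {status_spec.fs} vs {resolved_spec.fs}")
    status = generate_state_recording(
        replace(status_spec, state_label=status_spec.state_label or "Status")
    )
    resolved = generate_state_recording(
        replace(resolved_spec, state_label=resolved_spec.state_label or "Resolved")
    )
    return status, resolved
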