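"""Shared fixtures: small planted-signal recordings and linear-system oracles."""

from __future__ import annotations

import numpy as np
import pytest

from koopmodes import OscillatorSpec, StateSpec, generate_state_recording
from koopmodes.dmd import DMDWindowResult


def rotation_block(theta: float) -> np.ndarray:
    return np.array(
        [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
    )


@pytest.fixture(scope="session")
def rotation_system():
    """Known 4x4 linear system: two rotation blocks at 5 Hz and 12 Hz, fs=100.

    Returns (A, trajectory) with a 200-sample trajectory; DMD must recover
    spec(A) exactly on this noise-free data.
    """
    fs = 100.0
    A = np.zeros((4, 4))
    A[:2, :2] = rotation_block(2 * np.pi * 5 / fs)
    A[2:, 2:] = rotation_block(2 * np.pi * 12 / fs)
    x = np.array([1.0, 0.0, 0.5, 0.2])
    traj = [x]
    for _ in range(199):
        x = A @ x
        traj.append(x)
    return A, np.array(traj).T, fs


def make_oscillator(
    freq: float, amps, phases, decay: float = 1.0
) -> OscillatorSpec:
    return OscillatorSpec(
        frequency=freq,
        channel_amplitudes=tuple(amps),
        channel_phases=tuple(phases),
        decay=decay,
    )


def clean_state(
    freqs_amps_phases, n_ch: int, duration: float = 10.0, fs: float = 100.0, seed: int = 0
) -> StateSpec:
    """Noise-free multi-oscillator state spec."""
    oscs = tuple(make_oscillator(f, a, p) for f, a, p in freqs_amps_phases)
    return StateSpec(
        oscillators=oscs, duration=duration, fs=fs, n_ch=n_ch, seed=seed
    )


@pytest.fixture()
def clean_two_mode_recording():
    """Noise-free 4-channel recording with coherent 3 Hz and 10 Hz modes."""
    spec = clean_state(
        [
            (3.0, [1.0, 0.8, 0.6, 0.4], [0.0, 0.5, 1.0, 1.5]),
            (10.0, [0.4, 0.6, 0.8, 1.0], [0.0, -0.4, -0.8, -1.2]),
        ],
        n_ch=4,
        duration=30.0,
    )
    return generate_state_recording(spec)


def fake_window_result(
    freqs, vectors, amps, fs: float = 100.0, window_start: int = 0
) -> DMDWindowResult:
    """Hand-built window result with unit-circle eigenvalues at given freqs.

    ``vectors`` are channel-space mode columns (will be unit-normalized);
    only positive-frequency representatives are included, which is all the
    tracking layer looks at.
    """
    freqs = np.asarray(freqs, float)
    lam = np.exp(2j * np.pi * freqs / fs)
    V = np.stack([np.asarray(v, complex) / np.linalg.norm(v) for v in vectors], axis=1)
    return DMDWindowResult(
        eigenvalues=lam,
        modes=V,
        amplitudes=np.asarray(amps, complex),
        rank=len(freqs),
        residual=0.0,
        window_start=window_start,
        fs=fs,
    )
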