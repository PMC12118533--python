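"""Delay-embedded (Hankel) dynamic mode decomposition of one time window.

DMD finds the best-fit linear operator A advancing the windowed multichannel
signal one sample forward, x_{t+1} = A x_t, via an SVD-based regression on
the pair of shifted data matrices X, X'.  Its eigendecomposition
A = Φ Λ Φ⁺ yields spatially coherent oscillatory modes: each eigenvalue λ
encodes a frequency f = arg(λ)·fs/(2π) and growth rate |λ|, and the matching
eigenvector encodes a per-channel complex amplitude profile.

EEG is sampled densely in time but sparsely in space, so the plain data
matrix supports at most n_ch modes.  Vertically stacking h time-shifted
copies of the window (delay embedding) raises the available rank to
n_ch·h, enough modes to tile the spectrum of interest.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = [
    "AugmentedDataPair",
    "DMDWindowResult",
    "build_augmented_matrices",
    "fit_dmd",
    "mode_frequency",
    "project_mode_to_channels",
    "windowed_dmd",
]

DEFAULT_WINDOW_SAMPLES = 200  # minimal window covering the bands of interest
DEFAULT_STACKING = 10
DEFAULT_ENERGY = 0.999  # cumulative squared-singular-value fraction retained


@dataclass
class AugmentedDataPair:
    """Shifted data-matrix pair (X, X') built from one window.

    Row block k (0-based) of either matrix holds the window advanced by k
    samples; X' equals X advanced by one further sample.  Shapes are
    ``(n_ch*h, n-h)`` for a window of n samples.
    """

    X: np.ndarray
    X_prime: np.ndarray
    h: int
    n_ch: int
    window_start: int
    fs: float


@dataclass
class DMDWindowResult:
    """Eigen-decomposition of the window's best-fit linear operator.

    ``eigenvalues[k]`` is the per-step multiplier λ_k; ``modes[:, k]`` the
    channel-space eigenvector (unit norm, reference-channel phase 0);
    ``amplitudes[k]`` the complex coefficient b_k such that the window is
    approximately ``Re Σ_k modes[:, k] * b_k * λ_k**t``.
    """

    eigenvalues: np.ndarray  # (r,)
    modes: np.ndarray  # (n_ch, r)
    amplitudes: np.ndarray  # (r,)
    rank: int
    residual: float  # relative one-step error ||X' - A X||_F / ||X'||_F
    window_start: int
    fs: float
    embedded_modes: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_ch(self) -> int:
        return self.modes.shape[0]

    @property
    def frequencies(self) -> np.ndarray:
        """Per-mode frequency in Hz, in (-fs/2, fs/2]."""
        return np.array([mode_frequency(lam, self.fs) for lam in self.eigenvalues])

    def positive_frequency_indices(self, tol: float = 1e-12) -> np.ndarray:
        """Indices of the f >= 0 conjugate representatives."""
        return np.flatnonzero(self.eigenvalues.imag >= -tol)


def build_augmented_matrices(
    window_data: np.ndarray, h: int, window_start: int = 0, fs: float = 1.0
) -> AugmentedDataPair:
    """Stack ``h`` time-shifted copies of a window into the (X, X') pair.

    ``h = 1`` is the unaugmented case: X and X' are the window minus its
    last / first sample.
    """
    window_data = np.asarray(window_data)
    if window_data.ndim != 2:
        raise ValueError("window must be 2-D (n_ch, n_samples)")
    n_ch, n = window_data.shape
    if h < 1:
        raise ValueError(f"stacking degree must be >= 1, got {h}")
    if h >= n:
        raise ValueError(f"stacking degree h={h} must be below window length n={n}")
    # embedded column t = [x_t; x_{t+1}; ...; x_{t+h-1}], t = 0..n-h
    embedded = np.vstack([window_data[:, k : n - h + 1 + k] for k in range(h)])
    return AugmentedDataPair(
        X=embedded[:, :-1],
        X_prime=embedded[:, 1:],
        h=h,
        n_ch=n_ch,
        window_start=window_start,
        fs=fs,
    )


def _resolve_rank(s: np.ndarray, rank_rule: float | int | Callable) -> int:
    """Number of singular values retained under the rule.

    A float in (0, 1] keeps the smallest leading set whose cumulative squared
    energy reaches that fraction; an int keeps a fixed count; a callable maps
    the singular-value vector to a count.  Always capped at the numerical
    rank.
    """
    num_rank = int(np.sum(s > s[0] * max(s.shape) * np.finfo(float).eps)) if s.size else 0
    if callable(rank_rule):
        r = int(rank_rule(s))
    elif isinstance(rank_rule, (int, np.integer)):
        r = int(rank_rule)
    else:
        frac = float(rank_rule)
        if not 0 < frac <= 1:
            raise ValueError(f"energy fraction must be in (0, 1], got {frac}")
        energy = np.cumsum(s**2) / np.sum(s**2)
        r = int(np.searchsorted(energy, frac - 1e-15) + 1)
    r = min(r, num_rank)
    if r < 1:
        raise ValueError("rank rule retained 0 components")
    return r


def fit_dmd(
    pair: AugmentedDataPair,
    rank_rule: float | int | Callable = DEFAULT_ENERGY,
    keep_embedded: bool = False,
) -> DMDWindowResult:
    """SVD-based DMD of one augmented window.

    Computes the reduced operator Ã = Uᴴ X' V Σ⁻¹ on the retained
    SVD subspace of X, eigendecomposes it, and maps each eigenvector back to
    channel space (first delay block, unit-normalized, reference-channel
    phase zeroed).  Amplitudes are least-squares coefficients of the window's
    first embedded state on the embedded modes, rescaled to refer to the
    stored channel-space modes.
    """
    X, Xp = pair.X, pair.X_prime
    if X.shape[1] < 2:
        raise ValueError("need at least 2 columns in X")
    norm_Xp = np.linalg.norm(Xp)
    if np.linalg.norm(X) == 0 or norm_Xp == 0:
        raise ValueError("degenerate window: all-zero data")

    U, s, Vh = np.linalg.svd(X, full_matrices=False)
    r = _resolve_rank(s, rank_rule)
    U, s, Vh = U[:, :r], s[:r], Vh[:r]
    Atilde = U.conj().T @ Xp @ Vh.conj().T / s

    lam, W = np.linalg.eig(Atilde)
    phi_emb = U @ W  # projected DMD modes in embedded space

    # amplitudes from the window's first embedded state
    b_emb, *_ = np.linalg.lstsq(phi_emb, X[:, 0].astype(complex), rcond=None)

    n_ch = pair.n_ch
    blocks = phi_emb[:n_ch].astype(complex)  # (n_ch, r) first delay block per mode
    modes = np.zeros_like(blocks)
    amps = np.zeros(r, dtype=complex)
    for k in range(r):
        block = blocks[:, k]
        s_k = np.linalg.norm(block)
        if s_k == 0:
            continue
        ref = int(np.argmax(np.abs(block)))
        gauge = np.exp(-1j * np.angle(block[ref]))
        modes[:, k] = block / s_k * gauge
        # block * b_emb == modes * (s_k * conj(gauge) * b_emb)
        amps[k] = s_k * np.conj(gauge) * b_emb[k]

    residual = float(np.linalg.norm(Xp - U @ (Atilde @ (U.conj().T @ X))) / norm_Xp)
    return DMDWindowResult(
        eigenvalues=lam,
        modes=modes,
        amplitudes=amps,
        rank=r,
        residual=residual,
        window_start=pair.window_start,
        fs=pair.fs,
        embedded_modes=phi_emb if keep_embedded else None,
    )


def mode_frequency(lam: complex, fs: float) -> float:
    """Frequency in Hz of a DMD eigenvalue: f = arg(λ) · fs / 2π."""
    if lam == 0:
        raise ValueError("frequency of a zero eigenvalue is undefined")
    return float(np.angle(lam) * fs / (2 * np.pi))


def project_mode_to_channels(
    augmented_eigenvector: np.ndarray, n_ch: int, lam: complex | None = None
) -> np.ndarray:
    """Channel-space profile of an embedded-space eigenvector.

    Takes the first delay block (length ``n_ch``), normalizes it to unit norm
    and rotates the whole vector so the reference channel — the channel of
    maximum amplitude — has phase zero.  The result is gauge invariant:
    multiplying the input by any unit complex scalar leaves it unchanged.
    """
    vec = np.asarray(augmented_eigenvector, dtype=complex).ravel()
    if vec.size % n_ch != 0:
        raise ValueError(
            f"eigenvector length {vec.size} is not a multiple of n_ch={n_ch}"
        )
    block = vec[:n_ch]
    norm = np.linalg.norm(block)
    if norm == 0:
        raise ValueError("eigenvector has a zero first delay block")
    block = block / norm
    ref = int(np.argmax(np.abs(block)))
    return block * np.exp(-1j * np.angle(block[ref]))


def windowed_dmd(
    data: np.ndarray,
    fs: float,
    n: int = DEFAULT_WINDOW_SAMPLES,
    stride: int | None = None,
    h: int = DEFAULT_STACKING,
    rank_rule: float | int | Callable = DEFAULT_ENERGY,
    n_jobs: int = 1,
) -> list[DMDWindowResult]:
    """DMD of every sliding window of ``data`` (default 50% overlap).

    Windows are independent, so ``n_jobs > 1`` processes them in parallel
    (joblib); results are returned in window order regardless of worker
    scheduling, keeping the output deterministic.
    """
    from .preprocess import sliding_windows

    if stride is None:
        stride = n // 2
    windows = sliding_windows(np.asarray(data), n, stride)

    def one(start: int, window: np.ndarray) -> DMDWindowResult:
        return fit_dmd(build_augmented_matrices(window, h, window_start=start, fs=fs), rank_rule)

    if n_jobs == 1:
        return [one(start, w) for start, w in windows]
    from joblib import Parallel, delayed

    return Parallel(n_jobs=n_jobs)(delayed(one)(start, w) for start, w in windows)
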