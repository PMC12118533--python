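"""Effective coherent oscillations: collapsing a track population to modes.

Each persistent oscillation of the network is summarized by (i) its
effective frequency — a peak of the relative-incidence distribution — and
(ii) an effective spatial profile: one amplitude and one relative phase per
channel.  The profile is the maximum of a Gaussian kernel density estimate
over the per-channel complex mode coefficients a·e^{iφ} pooled from every
track entry near the peak, so a noisy cloud of window-wise eigenvectors
collapses to its most typical value rather than a mean that could be washed
out by phase outliers.

The KDE runs per channel on the complex plane (Re, Im), which handles the
circularity of phase without wrap-around artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal
from scipy.stats import gaussian_kde

from .tracking import IncidenceDistribution, ModeTrack, TrackEntry

__all__ = [
    "EffectiveMode",
    "find_frequency_peaks",
    "effective_spatial_profile",
    "extract_effective_modes",
    "kde_peak_2d",
]

DEFAULT_PROMINENCE = 0.05  # fraction of the maximum histogram weight
KDE_GRID = 128
KDE_PAD_BANDWIDTHS = 3.0


@dataclass
class EffectiveMode:
    """One persistent coherent oscillation of the network."""

    frequency: float  # Hz, incidence-distribution peak
    amplitudes: np.ndarray  # per-channel a_j >= 0
    phases: np.ndarray  # per-channel phase in (-pi, pi], reference = 0
    support: int  # number of contributing track entries

    @property
    def complex_profile(self) -> np.ndarray:
        return self.amplitudes * np.exp(1j * self.phases)


def find_frequency_peaks(
    dist: IncidenceDistribution, prominence_rule: float = DEFAULT_PROMINENCE
) -> list[float]:
    """Frequencies of local maxima of the incidence distribution.

    ``prominence_rule`` is the required peak prominence as a fraction of the
    largest bin weight.  Peaks are returned sorted by descending mass; a
    boundary bin qualifies when it rises above its single neighbor by the
    prominence.  A flat distribution has no peaks.
    """
    w = dist.relative_incidence
    if w.size == 0 or w.max() <= 0:
        return []
    prominence = max(prominence_rule * w.max(), 1e-15)
    idx, _ = signal.find_peaks(w, prominence=prominence)
    idx = list(idx)
    # boundary bins: qualify if they rise above their single neighbor
    if w.size >= 2 and w[0] >= w[1] + prominence:
        idx.insert(0, 0)
    if w.size >= 2 and w[-1] >= w[-2] + prominence:
        idx.append(w.size - 1)
    idx = np.array(idx, dtype=int)
    if idx.size == 0:
        return []
    order = np.argsort(-w[idx])
    return [float(dist.bin_centers[i]) for i in idx[order]]


def kde_peak_2d(samples: np.ndarray, bw_method: str | float = "scott"):
    """Peak of a 2-D Gaussian KDE evaluated on a padded regular grid.

    Returns ``(peak_xy, density, x_grid, y_grid)`` where ``density`` is the
    KDE evaluated on a ``KDE_GRID x KDE_GRID`` grid covering the sample
    bounding box padded by ``KDE_PAD_BANDWIDTHS`` bandwidths per axis.
    Degenerate clouds (all points equal, or collinear) are handled by
    falling back to the dominant point / a 1-D KDE along the spread axis.
    """
    samples = np.asarray(samples, float)  # (2, n)
    spread = samples.std(axis=1)
    scale = max(np.abs(samples).max(), 1.0)
    if samples.shape[1] < 2 or spread.max() <= 1e-12 * scale:
        return samples.mean(axis=1), None, None, None
    if spread.min() <= 1e-9 * max(spread.max(), 1e-30):
        # collinear cloud: 1-D KDE along the spread axis
        axis = int(np.argmax(spread))
        x = samples[axis]
        kde = gaussian_kde(x, bw_method=bw_method)
        bw = np.sqrt(kde.covariance[0, 0])
        grid = np.linspace(
            x.min() - KDE_PAD_BANDWIDTHS * bw, x.max() + KDE_PAD_BANDWIDTHS * bw, KDE_GRID
        )
        peak = np.array([0.0, 0.0])
        peak[axis] = grid[int(np.argmax(kde(grid)))]
        peak[1 - axis] = samples[1 - axis].mean()
        return peak, None, None, None

    kde = gaussian_kde(samples, bw_method=bw_method)
    bw = np.sqrt(np.diag(kde.covariance))
    x = np.linspace(
        samples[0].min() - KDE_PAD_BANDWIDTHS * bw[0],
        samples[0].max() + KDE_PAD_BANDWIDTHS * bw[0],
        KDE_GRID,
    )
    y = np.linspace(
        samples[1].min() - KDE_PAD_BANDWIDTHS * bw[1],
        samples[1].max() + KDE_PAD_BANDWIDTHS * bw[1],
        KDE_GRID,
    )
    xx, yy = np.meshgrid(x, y, indexing="ij")
    density = kde(np.vstack([xx.ravel(), yy.ravel()])).reshape(xx.shape)
    i, j = np.unravel_index(np.argmax(density), density.shape)
    return np.array([x[i], y[j]]), density, x, y


def effective_spatial_profile(
    entries: list[TrackEntry],
    frequency: float,
    bw_method: str | float = "scott",
    min_entries: int = 3,
) -> EffectiveMode:
    """Effective per-channel amplitude and phase of one oscillation.

    All entry eigenvectors are first brought to a common gauge (the channel
    with the largest pooled mean amplitude is rotated to phase zero in each
    vector); then, channel by channel, the KDE maximum over the complex
    coefficients defines the effective amplitude and phase.  The output is
    re-gauged so the reference channel's phase is exactly zero.
    """
    if len(entries) < min_entries:
        raise ValueError(
            f"insufficient support: {len(entries)} entries near {frequency} Hz, "
            f"need {min_entries}"
        )
    vecs = np.stack([e.eigenvector for e in entries], axis=1)  # (n_ch, n_entries)
    mean_amp = np.abs(vecs).mean(axis=1)
    ref = int(np.argmax(mean_amp))
    vecs = vecs * np.exp(-1j * np.angle(vecs[ref]))[None, :]

    n_ch = vecs.shape[0]
    amplitudes = np.zeros(n_ch)
    phases = np.zeros(n_ch)
    for ch in range(n_ch):
        pts = np.vstack([vecs[ch].real, vecs[ch].imag])
        peak, *_ = kde_peak_2d(pts, bw_method=bw_method)
        z = complex(peak[0], peak[1])
        amplitudes[ch] = abs(z)
        phases[ch] = np.angle(z)

    phases = np.angle(np.exp(1j * (phases - phases[ref])))
    phases[ref] = 0.0
    return EffectiveMode(
        frequency=frequency,
        amplitudes=amplitudes,
        phases=phases,
        support=len(entries),
    )


def extract_effective_modes(
    tracks: list[ModeTrack],
    dist: IncidenceDistribution,
    prominence_rule: float = DEFAULT_PROMINENCE,
    bw_method: str | float = "scott",
    min_entries: int = 3,
    max_modes: int | None = None,
) -> list[EffectiveMode]:
    """Full summary: incidence peaks plus their KDE spatial profiles.

    Entries contribute to a peak at f* if their frequency lies within ± one
    histogram bin of f*.  Peaks with insufficient support are skipped.
    """
    peaks = find_frequency_peaks(dist, prominence_rule)
    if max_modes is not None:
        peaks = peaks[:max_modes]
    modes = []
    all_entries = [e for t in tracks for e in t.entries]
    for f_star in peaks:
        near = [e for e in all_entries if abs(e.frequency - f_star) <= dist.bin_width]
        if len(near) < min_entries:
            continue
        modes.append(
            effective_spatial_profile(near, f_star, bw_method=bw_method, min_entries=min_entries)
        )
    return modes
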