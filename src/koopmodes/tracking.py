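"""Adiabatic tracking of DMD modes across sliding windows.

A mode found in one window is only physiologically meaningful if it
persists: the same oscillation should reappear in the next window with
nearly the same frequency and nearly the same spatial profile.  Matching is
gated by the frequency step |Δf| = |f_{t+1} − f_t| and the Hermitian overlap
o = ⟨φ_{t+1}|φ_t⟩ of the channel-space eigenvectors; modes that drift slowly
enough through both are chained into tracks, and short tracks — accidental
noise contributions that dominate a single window — are discarded.

The retained track population is summarized by the relative-incidence
distribution over frequency, whose peaks mark the network's persistent
coherent oscillations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .dmd import DMDWindowResult

__all__ = [
    "TrackEntry",
    "ModeTrack",
    "IncidenceDistribution",
    "mode_match",
    "build_tracks",
    "incidence_distribution",
]

DEFAULT_DF_MAX = 1.0  # Hz per window step
DEFAULT_O_MIN = 0.9  # |<phi_{t+1}|phi_t>| gate
DEFAULT_MIN_TRACK_WINDOWS = 3
_BIG_COST = 1e9


@dataclass
class TrackEntry:
    window: int  # index into the window-result sequence
    mode: int  # mode index within that window's result
    frequency: float  # Hz
    eigenvector: np.ndarray  # channel-space, unit norm
    amplitude: float  # |b|


@dataclass
class ModeTrack:
    """A chain of matched modes across consecutive windows."""

    entries: list[TrackEntry] = field(default_factory=list)
    overlaps: list[float] = field(default_factory=list)  # |o| between entries
    freq_steps: list[float] = field(default_factory=list)  # Δf between entries

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def frequencies(self) -> np.ndarray:
        return np.array([e.frequency for e in self.entries])

    @property
    def mean_frequency(self) -> float:
        return float(self.frequencies.mean())


@dataclass
class IncidenceDistribution:
    """Normalized histogram of track-entry frequencies."""

    bin_centers: np.ndarray  # Hz
    relative_incidence: np.ndarray  # weights summing to 1
    bin_width: float
    entries: pd.DataFrame  # per-entry (window, frequency, weight, track) trace

    def band_mass(self, f_lo: float, f_hi: float) -> float:
        """Total relative incidence in [f_lo, f_hi)."""
        sel = (self.bin_centers >= f_lo) & (self.bin_centers < f_hi)
        return float(self.relative_incidence[sel].sum())


def _rep_indices(result: DMDWindowResult) -> np.ndarray:
    """Positive-frequency conjugate representatives of a window result."""
    return result.positive_frequency_indices()


def mode_match(
    result_a: DMDWindowResult,
    result_b: DMDWindowResult,
    df_max: float = DEFAULT_DF_MAX,
    o_min: float = DEFAULT_O_MIN,
) -> list[tuple[int, int]]:
    """One-to-one matching of modes between two consecutive windows.

    A pair qualifies only if |f_b − f_a| <= df_max and the eigenvector
    overlap |⟨φ_b|φ_a⟩| >= o_min.  Among qualifying pairs, an optimal
    assignment minimizes the total cost
    ``|Δf|/df_max + (1 − |o|)/(1 − o_min)``, with ties broken toward the
    smaller |Δf|.  Only positive-frequency conjugate representatives are
    considered; returned indices refer to the original mode arrays.
    """
    if not 0 <= o_min <= 1:
        raise ValueError(f"o_min must be in [0, 1], got {o_min}")
    if df_max < 0:
        raise ValueError(f"df_max must be non-negative, got {df_max}")
    if result_a.fs != result_b.fs or result_a.n_ch != result_b.n_ch:
        raise ValueError("window results differ in fs or channel count")

    ia, ib = _rep_indices(result_a), _rep_indices(result_b)
    if ia.size == 0 or ib.size == 0:
        return []
    fa = result_a.frequencies[ia]
    fb = result_b.frequencies[ib]
    overlap = np.abs(result_b.modes[:, ib].conj().T @ result_a.modes[:, ia]).T  # (a, b)
    dfreq = np.abs(fb[None, :] - fa[:, None])
    qualify = (dfreq <= df_max) & (overlap >= o_min)

    gate = max(1.0 - o_min, 1e-12)
    cost = np.where(
        qualify,
        dfreq / max(df_max, 1e-12) + (1.0 - overlap) / gate + 1e-9 * dfreq,
        _BIG_COST,
    )
    rows, cols = linear_sum_assignment(cost)
    return [
        (int(ia[r]), int(ib[c]))
        for r, c in zip(rows, cols)
        if qualify[r, c]
    ]


def build_tracks(
    window_results: list[DMDWindowResult],
    df_max: float = DEFAULT_DF_MAX,
    o_min: float = DEFAULT_O_MIN,
    min_track_windows: int = DEFAULT_MIN_TRACK_WINDOWS,
) -> list[ModeTrack]:
    """Chain matched modes through the whole window sequence.

    Every positive-frequency mode opens a (possibly singleton) track when it
    first appears; a track ends the first time its mode finds no match in
    the next window.  Tracks spanning fewer than ``min_track_windows``
    windows are discarded as transients.
    """
    if not window_results:
        return []

    def entry(w: int, k: int) -> TrackEntry:
        res = window_results[w]
        return TrackEntry(
            window=w,
            mode=k,
            frequency=float(res.frequencies[k]),
            eigenvector=res.modes[:, k],
            amplitude=float(np.abs(res.amplitudes[k])),
        )

    finished: list[ModeTrack] = []
    active: dict[int, ModeTrack] = {
        int(k): ModeTrack(entries=[entry(0, int(k))])
        for k in _rep_indices(window_results[0])
    }
    for w in range(len(window_results) - 1):
        pairs = mode_match(window_results[w], window_results[w + 1], df_max, o_min)
        matched_a = {a: b for a, b in pairs}
        nxt: dict[int, ModeTrack] = {}
        for k, track in active.items():
            if k in matched_a:
                b = matched_a[k]
                e = entry(w + 1, b)
                prev = track.entries[-1]
                track.overlaps.append(
                    float(np.abs(np.vdot(e.eigenvector, prev.eigenvector)))
                )
                track.freq_steps.append(e.frequency - prev.frequency)
                track.entries.append(e)
                nxt[b] = track
            else:
                finished.append(track)
        matched_b = set(matched_a.values())
        for k in _rep_indices(window_results[w + 1]):
            if int(k) not in matched_b:
                nxt[int(k)] = ModeTrack(entries=[entry(w + 1, int(k))])
        active = nxt
    finished.extend(active.values())
    return [t for t in finished if len(t) >= min_track_windows]


def incidence_distribution(
    tracks: list[ModeTrack],
    bin_width: float = 0.5,
    weighting: str = "amplitude",
    f_max: float | None = None,
) -> IncidenceDistribution:
    """Relative-incidence histogram of all track entries over frequency.

    ``weighting="amplitude"`` weights each entry by its |b| (stronger modes
    count more, as in time-frequency displays where opacity encodes
    strength); ``"count"`` weights all entries equally.  The histogram is
    normalized to total mass 1.
    """
    if bin_width <= 0:
        raise ValueError(f"bin_width must be positive, got {bin_width}")
    if weighting not in ("amplitude", "count"):
        raise ValueError(f"unknown weighting {weighting!r}")
    if not tracks:
        raise ValueError("no tracks to histogram")

    rows = [
        (tid, e.window, e.frequency, e.amplitude if weighting == "amplitude" else 1.0)
        for tid, track in enumerate(tracks)
        for e in track.entries
    ]
    frame = pd.DataFrame(rows, columns=["track", "window", "frequency", "weight"])
    if f_max is None:
        f_max = float(frame.frequency.max()) + bin_width
    n_bins = max(1, int(np.ceil(f_max / bin_width)))
    edges = np.arange(n_bins + 1) * bin_width
    hist, _ = np.histogram(frame.frequency, bins=edges, weights=frame.weight)
    total = hist.sum()
    if total > 0:
        hist = hist / total
    return IncidenceDistribution(
        bin_centers=(edges[:-1] + edges[1:]) / 2,
        relative_incidence=hist,
        bin_width=bin_width,
        entries=frame,
    )
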