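"""Measured-vs-modeled validation: spectra, connectivity, SSIM, classification.

Modeled data are judged on exactly the quantities a clinician reads off an
EEG: channel-wise Welch power spectra and phase-lag-based connectivity.
Agreement between condition pairs (measured/modeled x Status/Resolved) is
scored with a structural similarity index (SSIM), its significance assessed
by label-permutation tests with Bonferroni correction over the 6 pairwise
comparisons, and the preservation of state differences is checked by binary
logistic-regression classification with cross-validation and bootstrap
confidence intervals.

The connectivity estimators are the weighted phase lag index (wPLI) — the
ratio |E[Im S]| / E[|Im S|] of the imaginary cross-spectrum, insensitive to
zero-lag volume conduction — and its debiased squared variant (dwPLI),
whose expectation is zero for independent signals.  dwPLI pools all epochs
during debiasing; per-epoch distributions for classification therefore use
wPLI without debiasing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .recording import EpochSet

__all__ = [
    "BANDS",
    "N_PAIRWISE_COMPARISONS",
    "PSDMatrix",
    "ConnectivityMatrix",
    "SSIMReport",
    "ClassificationReport",
    "compute_psd_matrix",
    "compute_connectivity",
    "wpli_per_epoch",
    "ssim",
    "ssim_report",
    "permutation_pvalue",
    "dwpli_suffstats",
    "dwpli_from_suffstats",
    "dwpli_ssim_report",
    "classify_states",
    "psd_features",
    "connectivity_features",
]

#: Canonical EEG band edges in Hz (upper edge capped at 45 Hz for fs = 100).
BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, 45.0),
}

#: Pairwise comparisons among the four condition matrices (4 choose 2).
N_PAIRWISE_COMPARISONS = 6

WELCH_SEGMENT_SECONDS = 2.0
WELCH_OVERLAP = 0.5


@dataclass
class PSDMatrix:
    """Per-epoch channel x frequency Welch power densities."""

    values: np.ndarray  # (n_epochs, n_ch, n_freq), µV²/Hz
    freqs: np.ndarray  # Hz
    condition: str = ""
    welch_params: dict = field(default_factory=dict)


@dataclass
class ConnectivityMatrix:
    """Channel x channel phase-lag connectivity in one frequency band."""

    values: np.ndarray  # (n_ch, n_ch) symmetric, zero diagonal
    band: str
    estimator: str  # "wpli" or "dwpli"
    per_epoch: np.ndarray | None = None  # (n_epochs, n_ch, n_ch) for wPLI


@dataclass
class SSIMReport:
    """Condition-pair SSIM matrix with permutation significance."""

    labels: list[str]
    matrix: np.ndarray  # (n_cond, n_cond), diagonal 1
    p_values: np.ndarray
    mask: np.ndarray  # True where p <= alpha / n_comparisons
    alpha: float
    n_comparisons: int
    n_perm: int
    seed: int


@dataclass
class ClassificationReport:
    """Cross-validated metrics per train-test combination."""

    results: dict[str, dict]  # combo -> {accuracy, roc_auc, *_ci}
    folds: int
    n_boot: int
    seed: int


def compute_psd_matrix(
    epochs: EpochSet,
    segment_seconds: float = WELCH_SEGMENT_SECONDS,
    overlap: float = WELCH_OVERLAP,
    condition: str = "",
) -> PSDMatrix:
    """Welch PSD per channel per epoch (Hann taper, 50% overlap default)."""
    if len(epochs) == 0:
        raise ValueError("empty epoch set")
    nperseg = int(round(segment_seconds * epochs.fs))
    if epochs.epochs[0].shape[1] < nperseg:
        raise ValueError(
            f"epoch of {epochs.epochs[0].shape[1]} samples is shorter than one "
            f"{nperseg}-sample Welch segment"
        )
    noverlap = int(round(nperseg * overlap))
    data = epochs.as_array()
    freqs, psd = signal.welch(
        data, fs=epochs.fs, nperseg=nperseg, noverlap=noverlap, window="hann", axis=2
    )
    keep = freqs >= min(0.5, freqs[-1])
    return PSDMatrix(
        values=psd[:, :, keep],
        freqs=freqs[keep],
        condition=condition or (epochs.state_label or ""),
        welch_params={"nperseg": nperseg, "noverlap": noverlap, "window": "hann"},
    )


def _segment_spectra(
    epochs: EpochSet, segment_seconds: float, overlap: float
) -> tuple[np.ndarray, np.ndarray]:
    """Tapered segment FFTs: returns (freqs, Z) with Z (n_epochs, n_segs, n_ch, n_freq)."""
    nperseg = int(round(segment_seconds * epochs.fs))
    step = nperseg - int(round(nperseg * overlap))
    data = epochs.as_array()
    n_samples = data.shape[2]
    if n_samples < nperseg:
        raise ValueError("epoch shorter than one segment")
    taper = signal.get_window("hann", nperseg)
    starts = range(0, n_samples - nperseg + 1, step)
    segs = np.stack([data[:, :, s : s + nperseg] * taper for s in starts], axis=1)
    Z = np.fft.rfft(segs, axis=3)
    freqs = np.fft.rfftfreq(nperseg, d=1.0 / epochs.fs)
    return freqs, Z


def _imag_cross_spectra(Z: np.ndarray) -> np.ndarray:
    """Im S_ij for all channel pairs: (n_obs, n_ch, n_ch, n_freq)."""
    n_ep, n_seg, n_ch, n_freq = Z.shape
    Zf = Z.reshape(n_ep * n_seg, n_ch, n_freq)
    S = np.einsum("oif,ojf->oijf", Zf, np.conj(Zf))
    return S.imag


def _wpli_from_imag(im_s: np.ndarray) -> np.ndarray:
    """wPLI over the observation axis 0: |E[Im S]| / E[|Im S|] (0/0 -> 0)."""
    num = np.abs(im_s.mean(axis=0))
    den = np.abs(im_s).mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        w = np.where(den > 0, num / np.maximum(den, 1e-300), 0.0)
    return w


def _dwpli_from_imag(im_s: np.ndarray) -> np.ndarray:
    """Debiased squared wPLI over axis 0; expectation 0 under independence."""
    s = im_s.sum(axis=0)
    s_sq = (im_s**2).sum(axis=0)
    s_abs = np.abs(im_s).sum(axis=0)
    num = s**2 - s_sq
    den = s_abs**2 - s_sq
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(den > 0, num / np.maximum(den, 1e-300), 0.0)
    return d


def _band_average(estimator: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Cross-power-weighted mean of a per-bin estimator over band bins.

    A flat mean would dilute a narrow coherent line with noise-only bins
    where a phase-lag estimator is ~0; weighting each bin by the pair's mean
    imaginary cross-power magnitude makes the band value reflect the bins
    that actually carry coherent interaction.  With zero total weight the
    flat mean is returned.
    """
    total = weights.sum(axis=-1)
    safe = np.where(total > 0, total, 1.0)
    weighted = (estimator * weights).sum(axis=-1) / safe
    return np.where(total > 0, weighted, estimator.mean(axis=-1))


def _band_mask(freqs: np.ndarray, band: str | tuple[float, float]) -> np.ndarray:
    lo, hi = BANDS[band] if isinstance(band, str) else band
    mask = (freqs >= lo) & (freqs < hi)
    if not mask.any():
        raise ValueError(f"band {band} contains no frequency bins")
    return mask


def compute_connectivity(
    epochs: EpochSet,
    band: str | tuple[float, float] = "delta",
    estimator: str = "dwpli",
    segment_seconds: float = WELCH_SEGMENT_SECONDS,
    overlap: float = WELCH_OVERLAP,
) -> ConnectivityMatrix:
    """Band-averaged phase-lag connectivity matrix.

    ``estimator="wpli"`` also exposes per-epoch matrices (segments averaged
    within each epoch) in ``per_epoch``; ``"dwpli"`` pools segments of all
    epochs during debiasing, yielding a single matrix, and requires at least
    two epochs.
    """
    if epochs.epochs and epochs.epochs[0].shape[0] < 2:
        raise ValueError("connectivity requires at least 2 channels")
    freqs, Z = _segment_spectra(epochs, segment_seconds, overlap)
    mask = _band_mask(freqs, band)
    band_name = band if isinstance(band, str) else f"{band[0]}-{band[1]}Hz"

    if estimator == "wpli":
        per_epoch = []
        for e in range(Z.shape[0]):
            im_s = _imag_cross_spectra(Z[e : e + 1])  # (n_seg, ch, ch, f)
            w = _band_average(
                _wpli_from_imag(im_s)[:, :, mask], np.abs(im_s).mean(axis=0)[:, :, mask]
            )
            np.fill_diagonal(w, 0.0)
            per_epoch.append(w)
        per_epoch = np.stack(per_epoch)
        values = per_epoch.mean(axis=0)
        return ConnectivityMatrix(values, band_name, "wpli", per_epoch=per_epoch)
    if estimator == "dwpli":
        if Z.shape[0] < 2:
            raise ValueError("dwPLI pools across epochs: need at least 2")
        im_s = _imag_cross_spectra(Z)
        d = _band_average(
            _dwpli_from_imag(im_s)[:, :, mask], np.abs(im_s).mean(axis=0)[:, :, mask]
        )
        np.fill_diagonal(d, 0.0)
        return ConnectivityMatrix(d, band_name, "dwpli")
    raise ValueError(f"unknown estimator {estimator!r}")


def wpli_per_epoch(
    epochs: EpochSet, band: str | tuple[float, float] = "delta", **kwargs
) -> np.ndarray:
    """Per-epoch wPLI matrices (n_epochs, n_ch, n_ch) for classification."""
    return compute_connectivity(epochs, band, estimator="wpli", **kwargs).per_epoch


def ssim(
    mat_a: np.ndarray,
    mat_b: np.ndarray,
    k1: float = 0.01,
    k2: float = 0.03,
    data_range: float | None = None,
) -> float:
    """Global structural similarity index between two equal-shape matrices.

    SSIM = (2 μa μb + C1)(2 cov + C2) / ((μa² + μb² + C1)(σa² + σb² + C2))
    with C1 = (k1 L)², C2 = (k2 L)² and L the shared data range (joint
    max − min by default).  Equals 1 iff the matrices are identical, and is
    symmetric in its arguments.  Computed globally — these are physical
    matrices, not natural images, so no sliding window is used.
    """
    a = np.asarray(mat_a, float)
    b = np.asarray(mat_b, float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if data_range is None:
        lo = min(a.min(), b.min())
        hi = max(a.max(), b.max())
        data_range = hi - lo if hi > lo else 1.0
    c1 = (k1 * data_range) ** 2
    c2 = (k2 * data_range) ** 2
    mu_a, mu_b = a.mean(), b.mean()
    var_a, var_b = a.var(), b.var()
    cov = ((a - mu_a) * (b - mu_b)).mean()
    return float(
        (2 * mu_a * mu_b + c1)
        * (2 * cov + c2)
        / ((mu_a**2 + mu_b**2 + c1) * (var_a + var_b + c2))
    )


def _time_averaged_ssim(stack_a: np.ndarray, stack_b: np.ndarray) -> float:
    """Mean SSIM over index-aligned epoch pairs of two (n_epochs, ...) stacks."""
    n = min(len(stack_a), len(stack_b))
    return float(np.mean([ssim(stack_a[i], stack_b[i]) for i in range(n)]))


def permutation_pvalue(
    stat_fn,
    group_a: np.ndarray,
    group_b: np.ndarray,
    n_perm: int,
    rng: np.random.Generator,
) -> tuple[float, float]:
    """Label-permutation p-value for a two-group statistic.

    Epochs of both groups are pooled and reassigned at random ``n_perm``
    times, keeping group sizes; the p-value is the proportion of permuted
    statistics that equal or exceed the observed one.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    observed = stat_fn(group_a, group_b)
    pooled = np.concatenate([group_a, group_b], axis=0)
    n_a = len(group_a)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(len(pooled))
        stat = stat_fn(pooled[perm[:n_a]], pooled[perm[n_a:]])
        if stat >= observed - 1e-15:
            count += 1
    return observed, count / n_perm


def ssim_report(
    condition_matrices: dict[str, np.ndarray],
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> SSIMReport:
    """Time-averaged SSIM over all condition pairs with permutation tests.

    ``condition_matrices`` maps a condition label (e.g. ``"measured/Status"``)
    to a stack of per-epoch matrices.  For each of the 6 pairs the epoch
    condition labels are shuffled ``n_perm`` times to build the SSIM null;
    elements with p <= alpha / 6 are marked significant in ``mask``.
    """
    labels = list(condition_matrices)
    stacks = [np.asarray(condition_matrices[lab], float) for lab in labels]
    if any(len(s) < 2 for s in stacks):
        raise ValueError("each condition needs at least 2 epochs")
    n = len(labels)
    rng = np.random.default_rng(seed)
    matrix = np.eye(n)
    p_values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            obs, p = permutation_pvalue(
                _time_averaged_ssim, stacks[i], stacks[j], n_perm, rng
            )
            matrix[i, j] = matrix[j, i] = obs
            p_values[i, j] = p_values[j, i] = p
    threshold = alpha / N_PAIRWISE_COMPARISONS
    mask = p_values <= threshold
    np.fill_diagonal(mask, True)
    return SSIMReport(
        labels=labels,
        matrix=matrix,
        p_values=p_values,
        mask=mask,
        alpha=alpha,
        n_comparisons=N_PAIRWISE_COMPARISONS,
        n_perm=n_perm,
        seed=seed,
    )


def dwpli_suffstats(
    epochs: EpochSet,
    band: str | tuple[float, float] = "delta",
    segment_seconds: float = WELCH_SEGMENT_SECONDS,
    overlap: float = WELCH_OVERLAP,
) -> np.ndarray:
    """Per-epoch sufficient statistics for pooled dwPLI.

    Debiased wPLI combines observations across epochs, so permutation tests
    that reassign epochs between conditions need each epoch's contribution
    separately.  Returns ``(n_epochs, 3, n_ch, n_ch, n_bins)`` holding, per
    epoch and band bin, the segment sums of Im S, (Im S)² and |Im S|; any
    subset of epochs can then be pooled with :func:`dwpli_from_suffstats`.
    """
    freqs, Z = _segment_spectra(epochs, segment_seconds, overlap)
    mask = _band_mask(freqs, band)
    out = []
    for e in range(Z.shape[0]):
        im_s = _imag_cross_spectra(Z[e : e + 1])[:, :, :, mask]
        out.append(
            np.stack([im_s.sum(axis=0), (im_s**2).sum(axis=0), np.abs(im_s).sum(axis=0)])
        )
    return np.stack(out)


def dwpli_from_suffstats(suffstats: np.ndarray) -> np.ndarray:
    """Pooled band dwPLI matrix from stacked epoch sufficient stats."""
    s, s_sq, s_abs = suffstats.sum(axis=0)
    num = s**2 - s_sq
    den = s_abs**2 - s_sq
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(den > 0, num / np.maximum(den, 1e-300), 0.0)
    d = _band_average(d, s_abs)
    np.fill_diagonal(d, 0.0)
    return d


def _pooled_dwpli_ssim(group_a: np.ndarray, group_b: np.ndarray) -> float:
    return ssim(dwpli_from_suffstats(group_a), dwpli_from_suffstats(group_b))


def dwpli_ssim_report(
    condition_epochs: dict[str, EpochSet],
    band: str | tuple[float, float],
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> SSIMReport:
    """Condition-pair SSIM of pooled dwPLI matrices in one band.

    Unlike the PSD report there is one dwPLI matrix per condition (debiasing
    pools epochs), so each pair contributes a single SSIM value; the
    permutation null reassigns whole epochs between the two conditions and
    re-pools.
    """
    labels = list(condition_epochs)
    stacks = [dwpli_suffstats(condition_epochs[lab], band) for lab in labels]
    if any(len(s) < 2 for s in stacks):
        raise ValueError("each condition needs at least 2 epochs")
    n = len(labels)
    rng = np.random.default_rng(seed)
    matrix = np.eye(n)
    p_values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            obs, p = permutation_pvalue(
                _pooled_dwpli_ssim, stacks[i], stacks[j], n_perm, rng
            )
            matrix[i, j] = matrix[j, i] = obs
            p_values[i, j] = p_values[j, i] = p
    threshold = alpha / N_PAIRWISE_COMPARISONS
    mask = p_values <= threshold
    np.fill_diagonal(mask, True)
    return SSIMReport(
        labels=labels,
        matrix=matrix,
        p_values=p_values,
        mask=mask,
        alpha=alpha,
        n_comparisons=N_PAIRWISE_COMPARISONS,
        n_perm=n_perm,
        seed=seed,
    )


def psd_features(psd: PSDMatrix, log: bool = False) -> np.ndarray:
    """Flatten per-epoch PSD matrices into classifier feature vectors.

    Linear power is the default: a mode-based model reproduces the power-
    carrying structure of the spectrum but not the noise floor, which on a
    log scale would dominate the feature distance between measured and
    modeled data.
    """
    v = psd.values.reshape(psd.values.shape[0], -1)
    return np.log10(np.maximum(v, 1e-12)) if log else v


def connectivity_features(per_epoch: np.ndarray) -> np.ndarray:
    """Upper-triangle entries of per-epoch connectivity matrices."""
    n_ch = per_epoch.shape[1]
    iu = np.triu_indices(n_ch, k=1)
    return per_epoch[:, iu[0], iu[1]]


def _fold_predictions(
    X_train_src: np.ndarray,
    X_test_src: np.ndarray,
    y: np.ndarray,
    folds: int,
    seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Cross-validated probabilities: train on one source, test on the other.

    Both sources describe the same epochs (index-aligned), so one fold split
    serves all four train-test combinations.
    """
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    probs = np.zeros(len(y))
    for train_idx, test_idx in skf.split(X_train_src, y):
        # No per-feature standardization: modeled epochs are near-deterministic
        # within a state, and rescaling by their vanishing variances amplifies
        # numerical noise into dominant features.
        clf = LogisticRegression(C=1.0, max_iter=2000)
        clf.fit(X_train_src[train_idx], y[train_idx])
        probs[test_idx] = clf.predict_proba(X_test_src[test_idx])[:, 1]
    return probs, (probs >= 0.5).astype(int)


def _bootstrap_ci(
    y: np.ndarray, probs: np.ndarray, n_boot: int, rng: np.random.Generator
) -> tuple[tuple[float, float], tuple[float, float]]:
    accs, aucs = [], []
    preds = (probs >= 0.5).astype(int)
    for _ in range(n_boot):
        idx = rng.integers(0, len(y), len(y))
        accs.append(np.mean(preds[idx] == y[idx]))
        if len(np.unique(y[idx])) == 2:
            aucs.append(roc_auc_score(y[idx], probs[idx]))
    acc_ci = tuple(np.percentile(accs, [2.5, 97.5]))
    auc_ci = tuple(np.percentile(aucs, [2.5, 97.5])) if aucs else (np.nan, np.nan)
    return acc_ci, auc_ci


def classify_states(
    features_measured: np.ndarray,
    features_modeled: np.ndarray,
    labels: np.ndarray,
    folds: int = 10,
    n_boot: int = 10000,
    seed: int = 0,
) -> ClassificationReport:
    """Binary logistic regression over all measured/modeled combinations.

    ``features_measured`` and ``features_modeled`` are index-aligned
    (n_epochs, n_features) matrices describing the same epochs; ``labels``
    are the binary state labels.  For each of the four train-test
    combinations, stratified ``folds``-fold cross-validation yields pooled
    out-of-fold predictions, from which accuracy, ROC-AUC and percentile
    bootstrap confidence intervals (``n_boot`` resamples) are computed.
    """
    y = np.asarray(labels)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError(f"need exactly 2 classes, got {classes.size}")
    y = (y == classes[1]).astype(int)
    counts = np.bincount(y)
    if counts.min() < folds:
        raise ValueError(
            f"need at least {folds} epochs per class for {folds}-fold CV, "
            f"got {counts.tolist()}"
        )
    sources = {"measured": np.asarray(features_measured), "modeled": np.asarray(features_modeled)}
    if sources["measured"].shape[0] != sources["modeled"].shape[0]:
        raise ValueError("measured and modeled feature sets must be index-aligned")

    rng = np.random.default_rng(seed)
    results: dict[str, dict] = {}
    for train_src in ("measured", "modeled"):
        for test_src in ("measured", "modeled"):
            probs, preds = _fold_predictions(
                sources[train_src], sources[test_src], y, folds, seed
            )
            acc = float(np.mean(preds == y))
            auc = float(roc_auc_score(y, probs))
            acc_ci, auc_ci = _bootstrap_ci(y, probs, n_boot, rng)
            results[f"train_{train_src}_test_{test_src}"] = {
                "accuracy": acc,
                "roc_auc": auc,
                "accuracy_ci": acc_ci,
                "roc_auc_ci": auc_ci,
            }
    return ClassificationReport(results=results, folds=folds, n_boot=n_boot, seed=seed)
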