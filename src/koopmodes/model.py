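"""Generative linear oscillator-network model of one brain state.

The DMD eigenpairs of a window define an effective dynamical connectivity
operator A = Φ Λ Φ⁺ whose trajectory from an initial state x0 is the
closed-form superposition x_t = Re Σ_k φ_k b_k λ_k^t: a network of coupled
damped oscillators.  The mode set (Φ, Λ) is fixed by the decomposition; the
only remaining freedom of the autonomous linear model is its boundary
condition — the mode-coefficient vector b — which is fitted with BFGS so
the generated signal reproduces the measured window's Welch log-power
spectrum.  Because the modeled states are near-steady (|λ| ≈ 1), the model
extrapolates beyond the window it was fitted on.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy import optimize, signal

from .dmd import DMDWindowResult
from .recording import MultichannelRecording, default_labels

__all__ = [
    "DynamicalModel",
    "assemble_model",
    "simulate",
    "optimize_initial_state",
    "generate_state_dataset",
    "save_model",
    "load_model",
]

logger = logging.getLogger(__name__)

_OVERFLOW_LOG = 230.0  # natural-log budget before |lambda|**t overflows
PSD_FLOOR = 1e-12
FIT_BAND = (0.5, 45.0)  # Hz range of the spectral objective


@dataclass
class DynamicalModel:
    """Factored linear model x_{t+1} = Φ Λ Φ⁺ x_t with initial state x0.

    ``Phi`` holds channel-space modes as columns, ``Lambda`` the per-step
    eigenvalue multipliers, ``x0`` the complex mode coefficients.  With
    ``clamp=True`` (default) eigenvalue magnitudes are projected to <= 1
    during generation so long extrapolations cannot diverge.
    """

    Phi: np.ndarray  # (n_ch, K) complex
    Lambda: np.ndarray  # (K,) complex
    x0: np.ndarray  # (K,) complex
    fs: float
    h: int = 1
    clamp: bool = True
    channel_labels: list[str] | None = None
    state_label: str | None = None

    def __post_init__(self) -> None:
        if self.Phi.shape[1] != self.Lambda.size or self.Lambda.size != self.x0.size:
            raise ValueError("Phi, Lambda and x0 dimensions disagree")

    @property
    def n_ch(self) -> int:
        return self.Phi.shape[0]

    @property
    def n_modes(self) -> int:
        return self.Lambda.size

    def generation_eigenvalues(self) -> np.ndarray:
        lam = self.Lambda
        if self.clamp:
            mag = np.abs(lam)
            lam = np.where(mag > 1.0, lam / mag, lam)
        return lam

    def one_step_operator(self) -> np.ndarray:
        """Explicit A = Φ Λ Φ⁺ on the retained mode subspace."""
        return self.Phi @ np.diag(self.Lambda) @ np.linalg.pinv(self.Phi)


def fit_amplitudes(Phi: np.ndarray, Lambda: np.ndarray, data: np.ndarray) -> np.ndarray:
    """Least-squares mode coefficients reproducing a window trajectory.

    Solves min_b || data - Σ_k Phi[:, k] b_k Lambda_k^t ||² over the whole
    window.  Full-mode-set DMD amplitudes rely on cancellation between
    non-orthogonal modes; a kept *subset* must have its coefficients refit
    this way, otherwise the uncancelled remainders appear as large spurious
    transients.
    """
    n_ch, n_t = data.shape
    t = np.arange(n_t)
    powers = Lambda[None, :] ** t[:, None]  # (n_t, K)
    design = (Phi[:, None, :] * powers[None, :, :]).reshape(n_ch * n_t, -1)
    b, *_ = np.linalg.lstsq(design, data.reshape(-1).astype(complex), rcond=None)
    return b


def _conjugate_partner(eigenvalues: np.ndarray, k: int) -> int:
    """Index of the eigenvalue closest to conj(λ_k)."""
    target = np.conj(eigenvalues[k])
    return int(np.argmin(np.abs(eigenvalues - target)))


def assemble_model(
    window_result: DMDWindowResult,
    keep_modes: str | int | list[int] = "all",
    clamp: bool = True,
    lambda_min: float = 0.0,
    project_unit_circle: bool = False,
    window_data: np.ndarray | None = None,
    channel_labels: list[str] | None = None,
    state_label: str | None = None,
) -> DynamicalModel:
    """Build a generative model from a window's DMD result.

    ``keep_modes`` selects which modes enter the model: ``"all"``, a number
    (the strongest-amplitude positive-frequency modes), or explicit indices.
    With a count rule, ``lambda_min`` first drops modes with |λ| below the
    threshold: for a near-steady state only near-unit-circle modes persist
    beyond the fitted window, and strongly decaying modes would otherwise be
    fitted with huge coefficients that turn into start-of-signal transients.
    ``project_unit_circle=True`` additionally replaces each kept λ by
    λ/|λ| — the steady-state idealization: window-fitted magnitudes carry
    noise-induced decay that compounds over long extrapolations, whereas a
    steady state's persistent oscillations sit on the unit circle.
    The kept set is closed under complex conjugation so generated data is
    real; a missing partner is auto-completed and logged.
    """
    lam_all = window_result.eigenvalues
    if isinstance(keep_modes, str):
        if keep_modes != "all":
            raise ValueError(f"unknown keep_modes rule {keep_modes!r}")
        keep = list(range(lam_all.size))
    elif isinstance(keep_modes, (int, np.integer)):
        reps = window_result.positive_frequency_indices()
        if lambda_min > 0:
            stable = reps[np.abs(lam_all[reps]) >= lambda_min]
            if stable.size == 0:  # degenerate window: fall back to most stable
                stable = reps[[int(np.argmax(np.abs(lam_all[reps])))]]
            reps = stable
        order = np.argsort(-np.abs(window_result.amplitudes[reps]))
        keep = [int(i) for i in reps[order][: int(keep_modes)]]
    else:
        keep = [int(i) for i in keep_modes]
    if not keep:
        raise ValueError("empty mode set: nothing to model")

    closed = list(dict.fromkeys(keep))
    for k in list(closed):
        partner = _conjugate_partner(lam_all, k)
        if partner not in closed:
            if abs(lam_all[partner] - np.conj(lam_all[k])) > 1e-6 * (1 + abs(lam_all[k])):
                logger.warning(
                    "mode %d has no conjugate partner; realness is approximate", k
                )
            else:
                logger.debug("auto-completing conjugate partner %d of mode %d", partner, k)
                closed.append(partner)
    closed = sorted(closed)
    Phi = window_result.modes[:, closed].copy()
    Lambda = lam_all[closed].copy()
    if project_unit_circle:
        mags = np.abs(Lambda)
        Lambda = np.where(mags > 0, Lambda / np.where(mags > 0, mags, 1.0), Lambda)
    if window_data is not None:
        x0 = fit_amplitudes(Phi, Lambda, np.asarray(window_data, float))
    else:
        x0 = window_result.amplitudes[closed].copy()
    return DynamicalModel(
        Phi=Phi,
        Lambda=Lambda,
        x0=x0,
        fs=window_result.fs,
        clamp=clamp,
        channel_labels=channel_labels,
        state_label=state_label,
    )


def _simulate_array(model: DynamicalModel, n_steps: int, t0: int = 0) -> np.ndarray:
    lam = model.generation_eigenvalues()
    max_mag = np.abs(lam).max() if lam.size else 0.0
    if max_mag > 1.0 and (t0 + n_steps) * np.log(max_mag) > _OVERFLOW_LOG:
        raise ValueError(
            f"|lambda|={max_mag:.4f} grows past the overflow horizon over "
            f"{t0 + n_steps} steps; enable eigenvalue clamping (clamp=True)"
        )
    t = t0 + np.arange(n_steps)
    powers = lam[:, None] ** t[None, :]  # (K, n_steps)
    traj = model.Phi @ (powers * model.x0[:, None])
    re, im = traj.real, traj.imag
    scale = np.abs(re).max()
    if scale > 0 and np.abs(im).max() > 1e-8 * scale:
        logger.warning(
            "imaginary residue %.2e relative to signal scale; mode set may not "
            "be conjugate-closed",
            np.abs(im).max() / scale,
        )
    return re


def simulate(model: DynamicalModel, n_steps: int, t0: int = 0) -> MultichannelRecording:
    """Generate ``n_steps`` samples from the model starting at step ``t0``.

    x_t = Re Σ_k φ_k b_k λ_k^t; ``t0 > 0`` advances all mode phases, so two
    consecutive calls tile one continuous trajectory.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    data = _simulate_array(model, n_steps, t0)
    labels = model.channel_labels or default_labels(model.n_ch)
    return MultichannelRecording(
        data=data, fs=model.fs, channel_labels=labels, state_label=model.state_label
    )


def _welch_log_psd(
    data: np.ndarray, fs: float, nperseg: int
) -> tuple[np.ndarray, np.ndarray]:
    freqs, psd = signal.welch(data, fs=fs, nperseg=min(nperseg, data.shape[1]), axis=1)
    band = (freqs >= FIT_BAND[0]) & (freqs <= FIT_BAND[1])
    return freqs[band], np.log10(np.maximum(psd[:, band], PSD_FLOOR))


def optimize_initial_state(
    model: DynamicalModel,
    target: MultichannelRecording | np.ndarray,
    maxiter: int = 100,
    gtol: float = 1e-8,
    horizon_steps: int | None = None,
) -> tuple[DynamicalModel, dict]:
    """BFGS fit of the model's boundary condition to a target window.

    The free parameters are the real and imaginary parts of the coefficients
    of the positive-frequency representatives (conjugate partners are tied).
    The objective is the channel-wise squared difference of Welch PSD
    between simulated and target data over the fitting band, normalized by
    the target's total squared power.  The linear-power scale concentrates
    the fit on the spectral regions that carry the state's power: a model
    restricted to a few persistent modes has essentially no broadband floor,
    and a log-scale objective would let the unreachable floor bins dominate
    the loss and push the optimizer into spectral artifacts.
    ``horizon_steps`` sets the simulated length entering the loss (default:
    the target's length); when the model is meant to extrapolate past the
    fitted segment, evaluating the loss over the full generation horizon
    prevents solutions in which near-degenerate modes cancel inside the
    segment and beat to large amplitude outside it.
    Returns the refitted model and a fit report; the final loss never
    exceeds the initial one.
    """
    if isinstance(target, MultichannelRecording):
        if target.fs != model.fs:
            raise ValueError(f"target fs {target.fs} differs from model fs {model.fs}")
        target_data = target.data
    else:
        target_data = np.asarray(target, float)
    n_steps = horizon_steps or target_data.shape[1]
    nperseg = int(round(2.0 * model.fs))
    _, log_target = _welch_log_psd(target_data, model.fs, nperseg)
    lin_target = 10.0**log_target
    norm = float((lin_target**2).sum())
    if norm == 0:
        raise ValueError("target window has zero power in the fitting band")

    lam = model.Lambda
    reps = [k for k in range(lam.size) if lam[k].imag >= -1e-12]
    partners = {k: _conjugate_partner(lam, k) for k in reps}

    def unpack(params: np.ndarray) -> np.ndarray:
        x0 = np.zeros(lam.size, dtype=complex)
        for i, k in enumerate(reps):
            c = params[2 * i] + 1j * params[2 * i + 1]
            p = partners[k]
            if p == k:  # real eigenvalue: real coefficient
                x0[k] = params[2 * i]
            else:
                x0[k] = c
                x0[p] = np.conj(c)
        return x0

    def loss(params: np.ndarray) -> float:
        trial = replace(model, x0=unpack(params))
        sim = _simulate_array(trial, n_steps)
        _, log_sim = _welch_log_psd(sim, model.fs, nperseg)
        lin_sim = 10.0**log_sim
        return float(((lin_sim - lin_target) ** 2).sum() / norm)

    p0 = np.empty(2 * len(reps))
    for i, k in enumerate(reps):
        p0[2 * i] = model.x0[k].real
        p0[2 * i + 1] = model.x0[k].imag
    initial_loss = loss(p0)
    res = optimize.minimize(
        loss, p0, method="BFGS", options={"maxiter": maxiter, "gtol": gtol}
    )
    best_params, best_loss = (res.x, float(res.fun))
    if best_loss > initial_loss:  # optimizer contract: never return worse
        best_params, best_loss = p0, initial_loss
    fitted = replace(model, x0=unpack(best_params))
    report = {
        "initial_loss": initial_loss,
        "final_loss": best_loss,
        "n_iter": int(res.nit),
        "converged": bool(res.success),
    }
    return fitted, report


def generate_state_dataset(
    models: list[DynamicalModel],
    layout: list[tuple[int, int]],
    crossfade: float = 0.25,
) -> MultichannelRecording:
    """Concatenate modeled segments into one recording.

    ``layout`` is a list of ``(model_index, n_samples)`` segments.  A model
    reused in consecutive segments continues its mode phases (the global
    step counter per model advances), so joins within one model are exact.
    At joins between different models the first ``crossfade`` seconds of the
    new segment are linearly blended with the old model's extrapolation.
    """
    if not models:
        raise ValueError("need at least one fitted model")
    fs = models[0].fs
    t0 = [0] * len(models)
    segments: list[tuple[int, np.ndarray]] = []
    for idx, n_samp in layout:
        segments.append((idx, _simulate_array(models[idx], n_samp, t0=t0[idx])))
        t0[idx] += n_samp

    out = [segments[0][1]]
    fade_n = int(round(crossfade * fs))
    for (prev_idx, _), (idx, seg) in zip(segments, segments[1:]):
        if idx != prev_idx and fade_n > 0:
            m = min(fade_n, seg.shape[1])
            tail = _simulate_array(models[prev_idx], m, t0=t0[prev_idx])
            ramp = np.linspace(0.0, 1.0, m)[None, :]
            seg = seg.copy()
            seg[:, :m] = (1 - ramp) * tail + ramp * seg[:, :m]
        out.append(seg)
    data = np.concatenate(out, axis=1)
    labels = models[0].channel_labels or default_labels(models[0].n_ch)
    return MultichannelRecording(
        data=data, fs=fs, channel_labels=labels, state_label=models[0].state_label
    )


def save_model(model: DynamicalModel, path: str | Path) -> Path:
    """Serialize a model as an ``.npz`` bundle with JSON metadata."""
    path = Path(path)
    meta = {
        "fs": model.fs,
        "h": model.h,
        "clamp": model.clamp,
        "channel_labels": model.channel_labels,
        "state_label": model.state_label,
    }
    np.savez_compressed(
        path, Phi=model.Phi, Lambda=model.Lambda, x0=model.x0, meta=np.array(json.dumps(meta))
    )
    return path


def load_model(path: str | Path) -> DynamicalModel:
    with np.load(path, allow_pickle=False) as bundle:
        meta = json.loads(str(bundle["meta"]))
        return DynamicalModel(
            Phi=bundle["Phi"],
            Lambda=bundle["Lambda"],
            x0=bundle["x0"],
            fs=float(meta["fs"]),
            h=int(meta["h"]),
            clamp=bool(meta["clamp"]),
            channel_labels=meta.get("channel_labels"),
            state_label=meta.get("state_label"),
        )
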