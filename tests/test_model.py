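"""Generative oscillator-network model: assembly, simulation, boundary fit."""

import numpy as np
import pytest
from scipy import signal

from koopmodes import (
    DynamicalModel,
    assemble_model,
    build_augmented_matrices,
    fit_dmd,
    generate_state_dataset,
    load_model,
    optimize_initial_state,
    save_model,
    simulate,
)
from koopmodes.model import _simulate_array, fit_amplitudes


def conj_pair_model(freq, fs=100.0, mag=1.0, profile=None, b=1.0 + 0.5j, clamp=True):
    """Two-mode model: one oscillation and its conjugate partner."""
    v = np.asarray(profile if profile is not None else [1.0, 0.6], complex)
    lam = mag * np.exp(2j * np.pi * freq / fs)
    Phi = np.stack([v, np.conj(v)], axis=1)
    return DynamicalModel(
        Phi=Phi,
        Lambda=np.array([lam, np.conj(lam)]),
        x0=np.array([b, np.conj(b)]),
        fs=fs,
        clamp=clamp,
    )


class TestAssembleModel:
    def test_full_mode_set_reproduces_fitted_operator(self, rotation_system):
        A, traj, fs = rotation_system
        res = fit_dmd(build_augmented_matrices(traj, h=1, fs=fs))
        model = assemble_model(res, keep_modes="all")
        np.testing.assert_allclose(model.one_step_operator().real, A, atol=1e-8)
        assert np.abs(model.one_step_operator().imag).max() < 1e-8

    def test_constant_signal_zero_frequency_mode(self):
        data = np.full((2, 60), 3.0)
        res = fit_dmd(build_augmented_matrices(data, h=1, fs=100.0), rank_rule=1)
        model = assemble_model(res, keep_modes="all", window_data=data)
        out = simulate(model, 30)
        np.testing.assert_allclose(out.data, 3.0, atol=1e-6)

    def test_empty_keep_set_rejected(self, rotation_system):
        _, traj, fs = rotation_system
        res = fit_dmd(build_augmented_matrices(traj, h=1, fs=fs))
        with pytest.raises(ValueError, match="empty"):
            assemble_model(res, keep_modes=[])

    def test_conjugate_partner_auto_completed(self, rotation_system):
        _, traj, fs = rotation_system
        res = fit_dmd(build_augmented_matrices(traj, h=1, fs=fs))
        k = int(np.argmax(res.eigenvalues.imag))  # one member of a pair
        model = assemble_model(res, keep_modes=[k])
        assert model.n_modes == 2
        lam = model.Lambda
        assert abs(lam[0] - np.conj(lam[1])) < 1e-10


class TestSimulate:
    def test_identity_mode_constant_trajectory(self):
        model = DynamicalModel(
            Phi=np.array([[1.0], [1.0]], complex),
            Lambda=np.array([1.0 + 0j]),
            x0=np.array([2.0 + 0j]),
            fs=100.0,
        )
        out = simulate(model, 50)
        np.testing.assert_allclose(out.data, 2.0)

    def test_unit_circle_pair_peaks_at_mode_frequency(self):
        model = conj_pair_model(3.2)
        out = simulate(model, 4000)
        freqs, psd = signal.welch(out.data, fs=100.0, nperseg=1000, axis=1)
        assert freqs[np.argmax(psd[0])] == pytest.approx(3.2, abs=0.11)

    def test_decaying_mode_envelope_closed_form(self):
        # 5 Hz at fs 100: the period is exactly 20 steps, so samples one
        # period apart differ only by the magnitude factor 0.99**20
        model = conj_pair_model(5.0, mag=0.99, clamp=False)
        x = _simulate_array(model, 400)
        ratio = x[0, 20:] / x[0, :-20]
        np.testing.assert_allclose(ratio, 0.99**20, atol=1e-6)

    def test_generated_signal_is_real_with_tiny_residue(self):
        rng = np.random.default_rng(0)
        v = rng.standard_normal(4) + 1j * rng.standard_normal(4)
        model = conj_pair_model(7.3, profile=v[:2], b=0.3 - 1.1j)
        lam = model.generation_eigenvalues()
        t = np.arange(500)
        traj = model.Phi @ ((lam[:, None] ** t[None, :]) * model.x0[:, None])
        assert np.abs(traj.imag).max() < 1e-10 * np.abs(traj.real).max()

    def test_clamp_caps_growing_modes(self):
        model = conj_pair_model(5.0, mag=1.05, clamp=True)
        x = _simulate_array(model, 2000)
        assert np.abs(x).max() < 10  # bounded: |lambda| projected to 1

    def test_unclamped_growth_beyond_horizon_rejected(self):
        model = conj_pair_model(5.0, mag=1.2, clamp=False)
        with pytest.raises(ValueError, match="clamp"):
            simulate(model, 5000)

    def test_bad_step_count_rejected(self):
        with pytest.raises(ValueError):
            simulate(conj_pair_model(5.0), 0)


class TestFitAmplitudes:
    def test_recovers_coefficients_of_model_generated_window(self):
        model = conj_pair_model(4.0, b=0.8 + 0.2j)
        data = _simulate_array(model, 300)
        b = fit_amplitudes(model.Phi, model.Lambda, data)
        np.testing.assert_allclose(b, model.x0, atol=1e-8)


class TestOptimizeInitialState:
    def test_self_consistency_reaches_near_zero_loss(self):
        truth = conj_pair_model(3.0, b=1.2 - 0.4j)
        target = _simulate_array(truth, 1000)
        start = conj_pair_model(3.0, b=0.3 + 0.3j)
        fitted, report = optimize_initial_state(start, target, maxiter=300)
        assert report["final_loss"] < 1e-6
        assert report["final_loss"] <= report["initial_loss"]

    def test_optimization_strictly_improves_bad_start(self):
        truth = conj_pair_model(3.0, b=1.0 + 0j)
        target = _simulate_array(truth, 1000)
        start = conj_pair_model(3.0, b=0.05 + 0.9j)
        _, report = optimize_initial_state(start, target, maxiter=100)
        assert report["final_loss"] < report["initial_loss"]

    def test_unreachable_peak_leaves_residual_bounded_by_grid_oracle(self):
        # target oscillates at 15 Hz; the model only has a 5 Hz pair
        t = np.arange(1000)
        target = np.vstack([np.sin(2 * np.pi * 15 * t / 100.0)] * 2)
        model = conj_pair_model(5.0, b=0.5 + 0j)
        fitted, report = optimize_initial_state(model, target, maxiter=100)
        # brute-force oracle: coarse grid over the representative coefficient
        from dataclasses import replace
        from koopmodes.model import _welch_log_psd

        _, lt = _welch_log_psd(target, 100.0, 200)
        Pt = 10.0**lt
        norm = (Pt**2).sum()
        losses = []
        for r in np.linspace(0, 2, 9):
            for th in np.linspace(0, 2 * np.pi, 8, endpoint=False):
                b = r * np.exp(1j * th)
                trial = replace(model, x0=np.array([b, np.conj(b)]))
                _, ls = _welch_log_psd(_simulate_array(trial, 1000), 100.0, 200)
                losses.append(((10.0**ls - Pt) ** 2).sum() / norm)
        grid_best = min(losses)
        assert report["final_loss"] <= grid_best + 1e-9
        assert report["final_loss"] > 0.1  # the 15 Hz peak stays unexplained

    def test_fs_mismatch_rejected(self):
        from koopmodes import MultichannelRecording

        model = conj_pair_model(3.0)
        target = MultichannelRecording(np.zeros((2, 500)) + 1.0, 50.0)
        with pytest.raises(ValueError, match="fs"):
            optimize_initial_state(model, target)


class TestGenerateStateDataset:
    def test_single_segment_equals_simulate(self):
        model = conj_pair_model(4.0)
        out = generate_state_dataset([model], [(0, 500)])
        np.testing.assert_array_equal(out.data, simulate(model, 500).data)

    def test_same_model_segments_are_phase_continuous(self):
        model = conj_pair_model(4.1)
        joined = generate_state_dataset([model], [(0, 400), (0, 400)])
        whole = simulate(model, 800)
        np.testing.assert_allclose(joined.data, whole.data, atol=1e-10)

    def test_crossfade_between_different_models(self):
        a = conj_pair_model(3.0)
        b = conj_pair_model(9.0)
        out = generate_state_dataset([a, b], [(0, 400), (1, 400)], crossfade=0.25)
        assert out.data.shape == (2, 800)
        # the step across the join is no larger than the outgoing model's own
        # natural per-sample step (the fade starts from its extrapolation)
        natural = np.abs(np.diff(simulate(a, 802).data)).max()
        join_step = np.abs(out.data[:, 400] - out.data[:, 399]).max()
        assert join_step <= natural + 1e-9

    def test_empty_model_list_rejected(self):
        with pytest.raises(ValueError):
            generate_state_dataset([], [])


def test_model_serialization_round_trip(tmp_path):
    model = conj_pair_model(6.0, b=0.7 - 0.1j)
    model.channel_labels = ["C3", "C4"]
    model.state_label = "Status"
    path = save_model(model, tmp_path / "m.npz")
    back = load_model(path)
    np.testing.assert_array_equal(back.Phi, model.Phi)
    np.testing.assert_array_equal(back.Lambda, model.Lambda)
    np.testing.assert_array_equal(back.x0, model.x0)
    assert back.fs == model.fs and back.clamp == model.clamp
    assert back.channel_labels == ["C3", "C4"] and back.state_label == "Status"
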