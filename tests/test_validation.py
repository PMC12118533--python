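"""Spectral/connectivity estimators, SSIM, permutation tests, classification."""

import numpy as np
import pytest
from scipy import stats

from koopmodes import (
    EpochSet,
    classify_states,
    compute_connectivity,
    compute_psd_matrix,
    psd_features,
    ssim,
    ssim_report,
    wpli_per_epoch,
)
from koopmodes.validation import (
    dwpli_from_suffstats,
    dwpli_suffstats,
    permutation_pvalue,
    _time_averaged_ssim,
)


def epochs_from_array(data_list, fs=100.0):
    n_ch = data_list[0].shape[0]
    return EpochSet(
        epochs=[np.asarray(d, float) for d in data_list],
        epoch_length=data_list[0].shape[1] / fs,
        fs=fs,
        channel_labels=[f"ch{i}" for i in range(n_ch)],
    )


def sine_epochs(freq, n_epochs=4, n_ch=2, seconds=10, fs=100.0, noise=0.0, seed=0, lag=0.0):
    rng = np.random.default_rng(seed)
    t = np.arange(int(seconds * fs))
    out = []
    for _ in range(n_epochs):
        phase0 = rng.uniform(0, 2 * np.pi)
        ep = np.stack(
            [
                np.sin(2 * np.pi * freq * t / fs + phase0 + ch * lag)
                + noise * rng.standard_normal(t.size)
                for ch in range(n_ch)
            ]
        )
        out.append(ep)
    return epochs_from_array(out, fs)


class TestPSD:
    def test_zero_signal_zero_psd(self):
        eps = epochs_from_array([np.zeros((2, 1000))])
        psd = compute_psd_matrix(eps)
        assert np.all(psd.values == 0)

    def test_unit_sine_integrated_power_is_half(self):
        eps = sine_epochs(10.0, n_epochs=2, seconds=20)
        psd = compute_psd_matrix(eps)
        total = np.trapezoid(psd.values[0, 0], psd.freqs)
        assert total == pytest.approx(0.5, rel=0.02)

    def test_status_preset_delta_dominates_alpha_everywhere(self):
        from koopmodes import epoch, generate_state_recording, preprocess, status_like_spec

        rec = preprocess(generate_state_recording(status_like_spec(duration=40.0)))
        psd = compute_psd_matrix(epoch(rec, 20.0))
        f = psd.freqs
        delta = psd.values[:, :, (f >= 0.5) & (f < 4)].sum(axis=2)
        alpha = psd.values[:, :, (f >= 8) & (f < 13)].sum(axis=2)
        assert np.all(delta > alpha)

    def test_epoch_shorter_than_segment_rejected(self):
        eps = epochs_from_array([np.ones((2, 100))])
        with pytest.raises(ValueError, match="shorter"):
            compute_psd_matrix(eps)


class TestConnectivity:
    def test_identical_channels_zero_wpli(self):
        x = np.random.default_rng(0).standard_normal(1000)
        eps = epochs_from_array([np.stack([x, x])] * 2)
        conn = compute_connectivity(eps, band="alpha", estimator="wpli")
        assert conn.values[0, 1] == 0.0

    def test_quarter_cycle_lagged_common_signal_high_dwpli(self):
        eps = sine_epochs(10.0, n_epochs=8, noise=0.05, lag=np.pi / 2, seed=1)
        conn = compute_connectivity(eps, band="alpha", estimator="dwpli")
        assert conn.values[0, 1] > 0.9

    def test_independent_noise_dwpli_near_zero_on_average(self):
        vals = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            eps = epochs_from_array([rng.standard_normal((2, 400)) for _ in range(6)])
            vals.append(compute_connectivity(eps, band="delta").values[0, 1])
        assert abs(np.mean(vals)) < 0.05

    def test_debiasing_consistency_more_epochs_less_bias(self):
        def mean_abs(n_epochs):
            vals = []
            for seed in range(20):
                rng = np.random.default_rng(1000 + seed)
                eps = epochs_from_array(
                    [rng.standard_normal((2, 400)) for _ in range(n_epochs)]
                )
                vals.append(abs(compute_connectivity(eps, band="alpha").values[0, 1]))
            return np.mean(vals)

        assert mean_abs(16) < mean_abs(3)

    def test_wpli_invariant_to_channel_rescaling(self):
        eps = sine_epochs(10.0, n_epochs=4, noise=0.3, lag=0.7, seed=2)
        base = wpli_per_epoch(eps, band="alpha")
        scaled_eps = epochs_from_array(
            [np.diag([7.0, 0.2]) @ e for e in eps], fs=eps.fs
        )
        scaled = wpli_per_epoch(scaled_eps, band="alpha")
        np.testing.assert_allclose(base, scaled, atol=1e-12)

    def test_dwpli_suffstats_match_direct_estimator(self):
        eps = sine_epochs(10.0, n_epochs=5, noise=0.5, lag=0.9, seed=3)
        direct = compute_connectivity(eps, band="alpha", estimator="dwpli").values
        pooled = dwpli_from_suffstats(dwpli_suffstats(eps, band="alpha"))
        np.testing.assert_allclose(pooled, direct, atol=1e-12)

    def test_single_channel_rejected(self):
        eps = epochs_from_array([np.ones((1, 400))] * 2)
        with pytest.raises(ValueError, match="2 channels"):
            compute_connectivity(eps, band="delta")


class TestSSIM:
    def test_identical_matrices_score_one(self):
        a = np.random.default_rng(0).standard_normal((8, 8))
        assert ssim(a, a) == pytest.approx(1.0)

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        a, b = rng.standard_normal((8, 8)), rng.standard_normal((8, 8))
        assert ssim(a, b) == pytest.approx(ssim(b, a))

    def test_constant_matrices_match_closed_form(self):
        c = 3.0
        a = np.full((5, 5), c)
        L = c  # joint range of {c, 2c}
        c1 = (0.01 * L) ** 2
        expected = (2 * c * 2 * c + c1) / (c**2 + (2 * c) ** 2 + c1)
        assert ssim(a, 2 * a) == pytest.approx(expected)

    def test_agrees_with_skimage_global_window(self):
        from skimage.metrics import structural_similarity

        rng = np.random.default_rng(2)
        a, b = rng.standard_normal((19, 19)), rng.standard_normal((19, 19))
        rng_range = max(a.max(), b.max()) - min(a.min(), b.min())
        ref = structural_similarity(
            a,
            b,
            win_size=19,
            gaussian_weights=False,
            use_sample_covariance=False,
            data_range=rng_range,
        )
        assert ssim(a, b) == pytest.approx(ref, abs=1e-10)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ssim(np.zeros((2, 2)), np.zeros((3, 3)))


class TestPermutation:
    def test_shuffle_invariant_statistic_saturates_at_one(self):
        # every epoch identical in both groups: any relabeling leaves the
        # statistic unchanged, so all permuted values tie the observed one
        m = np.random.default_rng(0).standard_normal((6, 6))
        stack = np.stack([m] * 4)
        rng = np.random.default_rng(1)
        _, p = permutation_pvalue(_time_averaged_ssim, stack, stack.copy(), 100, rng)
        assert p == 1.0

    def test_pvalues_uniform_under_true_null(self):
        """Both groups drawn from one distribution: p-values ~ Uniform(0,1)."""
        rng = np.random.default_rng(42)
        ps = []
        for _ in range(50):
            a = rng.standard_normal((5, 8, 8))
            b = rng.standard_normal((5, 8, 8))
            _, p = permutation_pvalue(_time_averaged_ssim, a, b, 200, rng)
            ps.append(p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_nperm_validation(self):
        with pytest.raises(ValueError):
            permutation_pvalue(
                _time_averaged_ssim,
                np.zeros((2, 2, 2)),
                np.zeros((2, 2, 2)),
                0,
                np.random.default_rng(0),
            )


class TestSSIMReport:
    def test_block_diagonal_structure_for_two_distinct_states(self):
        rng = np.random.default_rng(3)
        base1 = rng.standard_normal((8, 8)) * 3
        base2 = rng.standard_normal((8, 8)) * 3
        conds = {
            "measured/S": np.stack([base1 + 0.1 * rng.standard_normal((8, 8)) for _ in range(5)]),
            "modeled/S": np.stack([base1 + 0.1 * rng.standard_normal((8, 8)) for _ in range(5)]),
            "measured/R": np.stack([base2 + 0.1 * rng.standard_normal((8, 8)) for _ in range(5)]),
            "modeled/R": np.stack([base2 + 0.1 * rng.standard_normal((8, 8)) for _ in range(5)]),
        }
        report = ssim_report(conds, n_perm=50, seed=0)
        m = report.matrix
        within = [m[0, 1], m[2, 3]]
        between = [m[0, 2], m[0, 3], m[1, 2], m[1, 3]]
        assert min(within) > max(between)
        np.testing.assert_allclose(np.diag(m), 1.0)
        np.testing.assert_allclose(m, m.T)
        assert report.n_comparisons == 6

    def test_too_few_epochs_rejected(self):
        conds = {"a": np.zeros((1, 4, 4)), "b": np.zeros((3, 4, 4))}
        with pytest.raises(ValueError, match="at least 2"):
            ssim_report(conds, n_perm=10)


class TestClassification:
    @staticmethod
    def two_state_features(seed=0, n_per_state=12):
        eps_a = sine_epochs(3.0, n_epochs=n_per_state, noise=0.2, seed=seed)
        eps_b = sine_epochs(12.0, n_epochs=n_per_state, noise=0.2, seed=seed + 1)
        feats = np.vstack(
            [psd_features(compute_psd_matrix(eps_a)), psd_features(compute_psd_matrix(eps_b))]
        )
        labels = np.array(["A"] * n_per_state + ["B"] * n_per_state)
        return feats, labels

    def test_disjoint_spectral_peaks_classify_perfectly(self):
        feats, labels = self.two_state_features(seed=0)
        feats2, _ = self.two_state_features(seed=10)  # stand-in "modeled" set
        report = classify_states(feats, feats2, labels, folds=4, n_boot=200, seed=0)
        for combo, metrics in report.results.items():
            assert metrics["accuracy"] == 1.0, combo
            assert metrics["roc_auc"] == 1.0, combo

    def test_permuted_labels_give_chance_accuracy(self):
        rng = np.random.default_rng(0)
        feats = rng.standard_normal((24, 30))
        labels = np.array(["A", "B"] * 12)
        report = classify_states(feats, feats, labels, folds=4, n_boot=100, seed=0)
        acc = report.results["train_measured_test_measured"]["accuracy"]
        assert 0.2 <= acc <= 0.8  # binomial 95% band around 0.5 for n=24

    def test_bootstrap_ci_contains_point_estimate(self):
        feats, labels = self.two_state_features(seed=3, n_per_state=8)
        noisy = feats + np.random.default_rng(4).standard_normal(feats.shape) * 0.5
        for seed in range(5):
            report = classify_states(noisy, noisy, labels, folds=4, n_boot=500, seed=seed)
            for metrics in report.results.values():
                lo, hi = metrics["accuracy_ci"]
                assert lo - 1e-12 <= metrics["accuracy"] <= hi + 1e-12
                lo, hi = metrics["roc_auc_ci"]
                assert lo - 1e-12 <= metrics["roc_auc"] <= hi + 1e-12

    def test_single_class_and_small_classes_rejected(self):
        feats = np.zeros((8, 3))
        with pytest.raises(ValueError, match="2 classes"):
            classify_states(feats, feats, np.array(["A"] * 8))
        labels = np.array(["A"] * 4 + ["B"] * 4)
        with pytest.raises(ValueError, match="per class"):
            classify_states(feats, feats, labels, folds=5)
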