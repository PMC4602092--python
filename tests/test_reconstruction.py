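import numpy as np
import pytest

import spikecoch as sc
from spikecoch.errors import SolverError, ValidationError
from spikecoch.reconstruction import lagged_design


def stacked_pinv_solution(Rs, Ss, lag):
    """Oracle: explicit pseudo-inverse least squares on the stacked, centered
    lagged design matrix (independent of the normal-equation path)."""
    X = np.vstack([lagged_design(R, lag) for R in Rs])
    S = np.vstack(Ss)
    Xc = X - X.mean(axis=0)
    Sc = S - S.mean(axis=0)
    W = np.linalg.pinv(Xc) @ Sc
    m = Rs[0].shape[1]
    return W.reshape(2 * lag + 1, m, S.shape[1]).transpose(2, 0, 1)


def triple_loop_apply(g, R, x_mean, s_mean):
    """Oracle: naive evaluation of the lagged sum, one term at a time."""
    F, n_lags, m = g.shape
    L = (n_lags - 1) // 2
    T = R.shape[0]
    Xc = lagged_design(R, L) - x_mean
    S = np.zeros((T, F))
    for t in range(T):
        for f in range(F):
            acc = 0.0
            for j in range(n_lags):
                for c in range(m):
                    acc += g[f, j, c] * Xc[t, j * m + c]
            S[t, f] = acc + s_mean[f]
    return S


class TestFit:
    def test_noiseless_fixture_recovered_exactly(self):
        R, S, g = sc.linear_pair_fixture(T=300, m=4, L=3, noise_snr_db=np.inf, seed=1, n_freq=8)
        decoder = sc.fit_decoder([R], [S], lag=3, ridge_lambda=0.0)
        rel = np.linalg.norm(decoder.weights - g) / np.linalg.norm(g)
        assert rel < 1e-8

    @pytest.mark.parametrize("T,m,L", [(50, 2, 1), (200, 4, 3), (120, 3, 0)])
    def test_matches_stacked_pinv_oracle(self, T, m, L):
        rng = np.random.default_rng(T + m + L)
        Rs = [rng.poisson(2.0, size=(T, m)).astype(float) for _ in range(2)]
        Ss = [rng.standard_normal((T, 5)) for _ in range(2)]
        decoder = sc.fit_decoder(Rs, Ss, lag=L, ridge_lambda=0.0)
        expected = stacked_pinv_solution(Rs, Ss, L)
        rel = np.linalg.norm(decoder.weights - expected) / np.linalg.norm(expected)
        assert rel < 1e-8

    def test_scalar_ridge_closed_form(self):
        rng = np.random.default_rng(0)
        R = rng.poisson(3.0, size=(500, 1)).astype(float)
        S = (2.0 * R + rng.standard_normal((500, 1))).astype(float)
        decoder = sc.fit_decoder([R], [S], lag=0, ridge_lambda=0.0)
        Rc, Sc = R[:, 0] - R.mean(), S[:, 0] - S.mean()
        expected = np.sum(Rc * Sc) / np.sum(Rc**2)
        assert decoder.weights[0, 0, 0] == pytest.approx(expected, rel=1e-10)

    def test_ridge_shrinks_weights_monotonically(self):
        rng = np.random.default_rng(5)
        R = rng.poisson(2.0, size=(400, 4)).astype(float)
        S = rng.standard_normal((400, 6))  # independent of R
        norms = [
            np.linalg.norm(sc.fit_decoder([R], [S], lag=2, ridge_lambda=lam).weights)
            for lam in (1e-3, 1.0, 1e3)
        ]
        assert norms[0] > norms[1] > norms[2]

    def test_singular_system_raises_solver_error(self):
        rng = np.random.default_rng(2)
        base = rng.poisson(2.0, size=(100, 1)).astype(float)
        R = np.hstack([base, base])  # perfectly collinear channels
        S = rng.standard_normal((100, 3))
        with pytest.raises(SolverError, match="ridge"):
            sc.fit_decoder([R], [S], lag=1, ridge_lambda=0.0)

    def test_mismatched_frame_counts_rejected(self):
        with pytest.raises(ValidationError):
            sc.fit_decoder([np.zeros((10, 2))], [np.zeros((11, 4))], lag=1)

    def test_training_set_optimality_against_perturbed_filters(self):
        R, S, _ = sc.linear_pair_fixture(T=400, m=3, L=2, noise_snr_db=10.0, seed=3, n_freq=4)
        decoder = sc.fit_decoder([R], [S], lag=2, ridge_lambda=0.0)
        fitted_mse = np.mean((sc.apply_decoder(decoder, R).values - S.values) ** 2)
        rng = np.random.default_rng(99)
        for _ in range(100):
            perturbed = sc.DecoderFilter(
                weights=decoder.weights + 0.01 * rng.standard_normal(decoder.weights.shape),
                lag=decoder.lag,
                ridge_lambda=0.0,
                ridge_effective=0.0,
                bin_width=decoder.bin_width,
                x_mean=decoder.x_mean,
                s_mean=decoder.s_mean,
            )
            mse = np.mean((sc.apply_decoder(perturbed, R).values - S.values) ** 2)
            assert fitted_mse <= mse

    def test_parameter_recovery_at_20db_snr(self):
        R, S, g = sc.linear_pair_fixture(T=5000, m=8, L=3, noise_snr_db=20.0, seed=2)
        decoder = sc.fit_decoder([R], [S], lag=3, ridge_lambda=0.0)
        cos = np.sum(decoder.weights * g) / (
            np.linalg.norm(decoder.weights) * np.linalg.norm(g)
        )
        assert cos > 0.95


class TestApply:
    def test_zero_spikes_give_mean_spectrogram(self):
        R, S, _ = sc.linear_pair_fixture(T=100, m=3, L=2, seed=4, n_freq=6)
        decoder = sc.fit_decoder([R], [S], lag=2, ridge_lambda=1e-3)
        # all-zero spikes: prediction reduces to the (constant) fitted offset
        out = sc.apply_decoder(decoder, np.zeros_like(R.values)).values
        assert np.allclose(out, out[0], atol=1e-10)

    def test_matches_triple_loop_oracle(self):
        rng = np.random.default_rng(7)
        g = rng.standard_normal((4, 5, 3))  # F=4, L=2, m=3
        x_mean = rng.standard_normal(15)
        s_mean = rng.standard_normal(4)
        decoder = sc.DecoderFilter(g, 2, 0.0, 0.0, 0.01, x_mean, s_mean)
        R = rng.random((5, 3))
        expected = triple_loop_apply(g, R, x_mean, s_mean)
        out = sc.apply_decoder(decoder, R).values
        assert np.allclose(out, expected, atol=1e-12)

    def test_linearity_in_spike_input(self):
        rng = np.random.default_rng(8)
        g = rng.standard_normal((3, 3, 2))
        decoder = sc.DecoderFilter(g, 1, 0.0, 0.0, 0.01, np.zeros(6), np.zeros(3))
        R1, R2 = rng.random((20, 2)), rng.random((20, 2))
        lhs = sc.apply_decoder(decoder, 2.0 * R1 + 3.0 * R2).values
        rhs = 2.0 * sc.apply_decoder(decoder, R1).values + 3.0 * sc.apply_decoder(decoder, R2).values
        assert np.allclose(lhs, rhs, atol=1e-10)

    def test_channel_mismatch_rejected(self):
        decoder = sc.DecoderFilter(np.zeros((2, 3, 4)), 1, 0.0, 0.0, 0.01,
                                   np.zeros(12), np.zeros(2))
        with pytest.raises(ValidationError):
            sc.apply_decoder(decoder, np.zeros((10, 5)))


class TestErrorProfile:
    def test_perfect_reconstruction_has_zero_error(self):
        S = np.random.default_rng(0).random((20, 8))
        profile = sc.error_profile(S, S)
        assert np.all(profile.e_f == 0.0)

    def test_constant_reconstruction_uniform_psd(self):
        S_hat = np.full((10, 128), 3.0)
        profile = sc.error_profile(np.ones((10, 128)), S_hat)
        assert np.allclose(profile.mean_psd, 3.0)
        assert np.allclose(profile.normalized_psd, 1.0 / 128)
        assert profile.normalized_psd.sum() == pytest.approx(1.0)

    def test_toy_case_matches_hand_computation(self):
        S = np.array([[1.0, 0.0], [0.0, 1.0]])
        S_hat = np.array([[0.0, 0.0], [0.0, 1.0]])
        profile = sc.error_profile(S, S_hat)
        assert np.allclose(profile.e_f, [1.0, 0.0])
        assert np.allclose(profile.power_normalized_error, [1.0, 0.0])

    def test_zero_power_channel_flagged_nan(self):
        S = np.zeros((5, 2))
        S[:, 1] = 1.0
        profile = sc.error_profile(S, np.ones((5, 2)))
        assert np.isnan(profile.power_normalized_error[0])
        assert np.isfinite(profile.power_normalized_error[1])


class TestSplit:
    def test_even_split_of_ten(self):
        train, test = sc.train_test_split(list(range(10)), fraction=0.5, seed=0)
        assert len(train) == 5 and len(test) == 5
        assert sorted(train + test) == list(range(10))

    def test_same_seed_same_split(self):
        a = sc.train_test_split(list(range(9)), seed=4)
        b = sc.train_test_split(list(range(9)), seed=4)
        assert a == b

    def test_disjoint_and_exhaustive_over_many_seeds(self):
        items = list(range(10))
        for seed in range(1000):
            train, test = sc.train_test_split(items, fraction=0.5, seed=seed)
            assert set(train) & set(test) == set()
            assert sorted(train + test) == items

    def test_too_few_utterances_rejected(self):
        with pytest.raises(ValidationError):
            sc.train_test_split([1], fraction=0.5, seed=0)


class TestPersistence:
    def test_save_load_round_trip(self, tmp_path):
        R, S, _ = sc.linear_pair_fixture(T=80, m=2, L=1, seed=6, n_freq=4)
        decoder = sc.fit_decoder([R], [S], lag=1, ridge_lambda=1e-3)
        path = tmp_path / "dec.h5"
        sc.save_decoder(path, decoder)
        restored = sc.load_decoder(path)
        assert np.array_equal(restored.weights, decoder.weights)
        assert restored.lag == decoder.lag
        assert np.array_equal(restored.x_mean, decoder.x_mean)
        out_a = sc.apply_decoder(decoder, R).values
        out_b = sc.apply_decoder(restored, R).values
        assert np.array_equal(out_a, out_b)


class TestNoiseSuppression:
    def test_decoder_trained_on_clean_targets_suppresses_silent_frame_noise(self):
        """A decoder fitted from noise-corrupted spikes to clean targets emits
        less energy in silent frames than the noisy observation carries."""
        rng = np.random.default_rng(12)
        T, m, F = 600, 8, 16
        active = np.zeros(T, dtype=bool)
        active[100:300] = True  # the "digit"; the rest is silence
        S_clean = np.zeros((T, F))
        S_clean[active] = rng.random((active.sum(), F)) * 2.0
        R = rng.poisson(0.5, size=(T, m)).astype(float)  # noise floor (-10 dB regime)
        R[active] += rng.poisson(3.0, size=(active.sum(), m))
        S_noisy = S_clean + 0.8 * rng.random((T, F))  # what a noisy spectrogram shows
        decoder = sc.fit_decoder([R], [S_clean], lag=2, ridge_lambda=1e-2)
        S_hat = np.clip(sc.apply_decoder(decoder, R).values, 0.0, None)
        assert S_hat[~active].mean() < S_noisy[~active].mean()
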