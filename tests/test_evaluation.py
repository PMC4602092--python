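import numpy as np
import pytest
from scipy.fft import rfft

import spikecoch as sc
from spikecoch.errors import ValidationError
from spikecoch.evaluation import FeatureConfig, mel_filterbank, mfcc_features

from reference_stoi import reference_stoi


class TestMixAtSnr:
    def test_zero_db_equalizes_power(self, vowel_token, babble):
        _, sig, noise = sc.mix_at_snr(vowel_token, babble, 0.0, seed=1, return_components=True)
        assert np.mean(noise**2) == pytest.approx(np.mean(sig**2), rel=1e-10)

    @pytest.mark.parametrize("snr_db", [10.0, 0.0, -10.0])
    def test_realized_snr_is_exact(self, vowel_token, babble, snr_db):
        _, sig, noise = sc.mix_at_snr(vowel_token, babble, snr_db, seed=2, return_components=True)
        realized = 10.0 * np.log10(np.mean(sig**2) / np.mean(noise**2))
        assert realized == pytest.approx(snr_db, abs=1e-2)

    def test_zero_noise_rejected(self, vowel_token):
        silent = sc.AudioSignal(np.zeros(len(vowel_token) + 100), vowel_token.sample_rate)
        with pytest.raises(ValidationError):
            sc.mix_at_snr(vowel_token, silent, 0.0)

    def test_short_noise_rejected(self, vowel_token):
        short = sc.AudioSignal(np.ones(10), vowel_token.sample_rate)
        with pytest.raises(ValidationError):
            sc.mix_at_snr(vowel_token, short, 0.0)

    def test_seeded_offset_reproducible(self, vowel_token, babble):
        a = sc.mix_at_snr(vowel_token, babble, 0.0, seed=3)
        b = sc.mix_at_snr(vowel_token, babble, 0.0, seed=3)
        assert np.array_equal(a.samples, b.samples)


class TestStoi:
    def test_identity_scores_near_one(self, vowel_token):
        assert sc.stoi(vowel_token, vowel_token) >= 0.99

    def test_unrelated_noise_scores_low(self, vowel_token, babble):
        unrelated = sc.AudioSignal(babble.samples[: len(vowel_token)], 16000.0)
        assert sc.stoi(vowel_token, unrelated) < 0.3

    def test_monotone_in_snr(self, babble):
        tokens = sc.make_class_set(5, 2, seed=31)
        for tok in tokens:
            scores = [
                sc.stoi(tok.audio, sc.mix_at_snr(tok.audio, babble, snr, seed=5))
                for snr in (10.0, 0.0, -10.0)
            ]
            assert scores[0] >= scores[1] >= scores[2]

    def test_agrees_with_independent_reference(self, babble):
        tokens = sc.make_class_set(5, 2, seed=23)
        rng = np.random.default_rng(0)
        for i, tok in enumerate(tokens):
            snr = float(rng.choice([12.0, 6.0, 0.0, -6.0]))
            degraded = sc.mix_at_snr(tok.audio, babble, snr, seed=i)
            mine = sc.stoi(tok.audio, degraded)
            ref = reference_stoi(tok.audio.samples, degraded.samples, 16000)
            assert mine == pytest.approx(ref, abs=0.02)

    def test_too_short_input_rejected(self):
        x = sc.AudioSignal(np.random.default_rng(0).standard_normal(1000), 16000.0)
        with pytest.raises(ValidationError, match="ms"):
            sc.stoi(x, x)

    def test_length_mismatch_rejected(self, vowel_token):
        shorter = sc.AudioSignal(vowel_token.samples[:-10], 16000.0)
        with pytest.raises(ValidationError):
            sc.stoi(vowel_token, shorter)


class TestMfcc:
    def test_single_tone_matches_direct_cepstrum_oracle(self, tone):
        """The first 13 coefficients must equal an explicit DCT-of-log-mel
        computation done from scratch on the same framing convention."""
        audio = tone(1000.0, duration=0.2)
        config = FeatureConfig()
        feats = mfcc_features(audio, config)

        x = audio.samples.copy()
        x = np.append(x[0], x[1:] - 0.97 * x[:-1])
        frame, hop = 400, 160
        n_frames = (len(x) - frame) // hop + 1
        fb = mel_filterbank(26, 512, 16000.0)
        expected = np.zeros((n_frames, 13))
        for i in range(n_frames):
            seg = x[i * hop : i * hop + frame] * np.hamming(frame)
            power = np.abs(rfft(seg, 512)) ** 2
            loge = np.log(np.maximum(power @ fb.T, 1e-12))
            for k in range(13):  # explicit orthonormal DCT-II
                scale = np.sqrt(1.0 / 26) if k == 0 else np.sqrt(2.0 / 26)
                expected[i, k] = scale * np.sum(
                    loge * np.cos(np.pi * k * (2 * np.arange(26) + 1) / (2 * 26))
                )
        assert np.allclose(feats[:, :13], expected, atol=1e-6)

    def test_feature_dimension_is_39(self, vowel_token):
        feats = mfcc_features(vowel_token)
        assert feats.shape[1] == 39
        assert np.all(np.isfinite(feats))


class TestClassifier:
    def test_resubstitution_on_separable_classes_is_perfect(self):
        tokens = sc.make_class_set(2, 4, seed=41)
        model = sc.train_classifier(tokens, seed=0)
        assert sc.classification_accuracy(model, tokens) == 1.0

    def test_heldout_accuracy_on_formant_separated_classes(self):
        """Two classes differing in formant layout, 20 train / 20 held-out
        exemplars each: the template classifier should stay above 90%."""
        tokens = sc.make_class_set(2, 40, seed=51)
        by_label = {}
        for tok in tokens:
            by_label.setdefault(tok.label, []).append(tok)
        train = [t for toks in by_label.values() for t in toks[:20]]
        test = [t for toks in by_label.values() for t in toks[20:]]
        model = sc.train_classifier(train, seed=0)
        assert sc.classification_accuracy(model, test) >= 0.90

    def test_single_class_rejected(self):
        tokens = sc.make_class_set(2, 2, seed=1)
        only_one = [t for t in tokens if t.label == tokens[0].label]
        with pytest.raises(ValidationError):
            sc.train_classifier(only_one, seed=0)

    def test_deterministic_given_data(self, small_class_set):
        a = sc.train_classifier(small_class_set, seed=0)
        b = sc.train_classifier(small_class_set, seed=0)
        assert np.array_equal(a.means, b.means)
        assert np.array_equal(a.variances, b.variances)


@pytest.fixture(scope="module")
def domains():
    tokens = sc.make_class_set(3, 4, seed=61)
    signals = [t.audio for t in tokens]
    labels = [t.label for t in tokens]
    rng = np.random.default_rng(0)
    # a mildly degraded domain: additive noise changes the statistics
    distorted = [
        sc.AudioSignal(s.samples + 0.05 * rng.standard_normal(len(s)), s.sample_rate)
        for s in signals
    ]
    return {"original": signals, "distorted": distorted}, labels


class TestProtocol:

    def test_matched_conditions_dominate_mismatched(self, domains):
        doms, labels = domains
        grid = [("original", "original"), ("original", "distorted"),
                ("distorted", "distorted"), ("distorted", "original")]
        table = sc.matched_mismatch_protocol(doms, labels, grid, seed=3)
        acc = {(r.train_domain, r.test_domain): r.accuracy for r in table.itertuples()}
        assert acc[("original", "original")] >= acc[("distorted", "original")]
        assert acc[("distorted", "distorted")] >= acc[("original", "distorted")]

    def test_empty_condition_grid_gives_empty_table(self, domains):
        doms, labels = domains
        table = sc.matched_mismatch_protocol(doms, labels, [], seed=0)
        assert len(table) == 0

    def test_bookkeeping_conservation(self, domains):
        doms, labels = domains
        table = sc.matched_mismatch_protocol(
            doms, labels, [("original", "original")], seed=1
        )
        row = table.iloc[0]
        assert 0.0 <= row.accuracy <= 100.0
        assert row.n_train + row.n_test == len(labels)
        assert row.n_correct <= row.n_test
        assert row.accuracy == pytest.approx(100.0 * row.n_correct / row.n_test)

    def test_unaligned_domains_rejected(self, domains):
        doms, labels = domains
        bad = dict(doms)
        bad["truncated"] = doms["original"][:-1]
        with pytest.raises(ValidationError, match="truncated"):
            sc.matched_mismatch_protocol(bad, labels, [("truncated", "truncated")])
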