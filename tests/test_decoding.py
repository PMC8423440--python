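"""Features, ridge decoding, temporal generalisation, LDA, and cluster tests."""

import numpy as np
import pytest
from scipy.stats import norm

from confacc.decoding import (
    EpochTensor,
    cluster_permutation_test,
    hilbert_features,
    last_samples_contrast,
    lda_response_classifier,
    precision_by_outcome,
    ridge_decode,
    strength_evidence_regression,
    temporal_generalization,
    wavelet_power,
)


class TestHilbertFeatures:
    def test_in_band_sinusoid_constant_amplitude(self):
        fs, f0 = 64.0, 4.0
        t = np.arange(0, 30, 1 / fs)  # long signal: filter transients decay
        data = np.sin(2 * np.pi * f0 * t)[None, None, :]
        feats = hilbert_features(data, fs, band=(1, 8))
        amp = np.sqrt(feats[0, 0] ** 2 + feats[0, 1] ** 2)
        middle = amp[len(t) // 3 : -len(t) // 3]
        assert np.all(np.abs(middle - 1.0) < 0.01)

    def test_out_of_band_attenuated_20db(self):
        fs = 256.0
        t = np.arange(0, 30, 1 / fs)
        data = np.sin(2 * np.pi * 40.0 * t)[None, None, :]
        feats = hilbert_features(data, fs, band=(1, 8))
        amp = np.sqrt(feats[0, 0] ** 2 + feats[0, 1] ** 2)
        assert amp[len(t) // 3 : -len(t) // 3].max() < 10 ** (-20 / 20)

    def test_zero_input_zero_output(self):
        feats = hilbert_features(np.zeros((2, 3, 64)), 64.0, band=(1, 8))
        assert np.allclose(feats, 0.0)

    def test_band_above_quarter_fs_rejected(self):
        with pytest.raises(ValueError, match="sampling rate"):
            hilbert_features(np.zeros((1, 1, 64)), 20.0, band=(1, 8))


class TestWaveletPower:
    def test_peak_at_tone_frequency(self):
        fs = 128.0
        t = np.arange(0, 2, 1 / fs)
        data = np.sin(2 * np.pi * 10.0 * t)[None, :]
        freqs = np.array([4.0, 7.0, 10.0, 14.0, 20.0])
        power = wavelet_power(data, fs, freqs)
        centre = power[0, :, len(t) // 2]
        assert freqs[np.argmax(centre)] == 10.0

    def test_amplitude_doubling_quadruples_power(self):
        fs = 128.0
        t = np.arange(0, 2, 1 / fs)
        base = np.sin(2 * np.pi * 10.0 * t)[None, :]
        p1 = wavelet_power(base, fs, np.array([10.0]))[0, 0, len(t) // 2]
        p2 = wavelet_power(2 * base, fs, np.array([10.0]))[0, 0, len(t) // 2]
        assert p2 / p1 == pytest.approx(4.0, rel=1e-6)

    def test_white_noise_flat_log_power(self):
        rng = np.random.default_rng(0)
        data = rng.standard_normal((40, 512))
        freqs = np.array([4.0, 8.0, 16.0, 32.0])
        power = wavelet_power(data, 128.0, freqs)
        mean_log = np.log(power[..., 128:-128].mean(axis=(0, 2)))
        slope = np.polyfit(np.log(freqs), mean_log, 1)[0]
        assert abs(slope) < 0.3

    def test_too_short_epoch_rejected(self):
        with pytest.raises(ValueError, match="short"):
            wavelet_power(np.zeros((1, 32)), 64.0, np.array([1.0]))


class TestRidgeDecode:
    def test_noiseless_linear_encoding_high_precision(self):
        rng = np.random.default_rng(1)
        n = 200
        y = rng.standard_normal(n)
        w = rng.standard_normal(8)
        X = (y[:, None] * w[None, :] + 0.05 * rng.standard_normal((n, 8)))[..., None]
        curve = ridge_decode(X, y, n_folds=10)
        assert curve.z[0] > 2.0

    def test_fisher_transform_value(self):
        from confacc.decoding import fisher_z

        assert fisher_z(0.5) == pytest.approx(0.5493, abs=1e-4)

    def test_null_z_within_fisher_bound(self):
        from confacc.decoding import cv_predictions, null_precision_distribution

        rng = np.random.default_rng(2)
        n = 100
        preds = cv_predictions(
            rng.standard_normal((n, 6, 1)), rng.standard_normal(n), n_folds=10
        )[..., 0]
        zs = null_precision_distribution(preds, n_null=300, seed=3)
        frac = np.mean(np.abs(zs) < 2 / np.sqrt(n - 3))
        assert frac >= 0.93

    def test_constant_target_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            ridge_decode(np.random.default_rng(0).standard_normal((20, 3, 1)),
                         np.ones(20))

    def test_orientation_decoding_on_doubled_angle_pair(self):
        rng = np.random.default_rng(4)
        n = 300
        theta = rng.uniform(-np.pi / 2, np.pi / 2, n)
        target = np.stack([np.sin(2 * theta), np.cos(2 * theta)], axis=1)
        w = rng.standard_normal((2, 10))
        X = (target @ w + 0.05 * rng.standard_normal((n, 10)))[..., None]
        curve = ridge_decode(X, target, orientation=True)
        assert curve.z[0] > 2.0


@pytest.fixture(scope="module")
def sustained_data():
    rng = np.random.default_rng(5)
    n, p, T = 150, 6, 8
    y = rng.standard_normal(n)
    w = rng.standard_normal(p)
    X = y[:, None, None] * w[None, :, None] * np.ones(T) \
        + 0.3 * rng.standard_normal((n, p, T))
    return X, y


class TestTemporalGeneralization:

    def test_diagonal_equals_ridge_decode(self, sustained_data):
        X, y = sustained_data
        tg = temporal_generalization(X, y, n_folds=5, seed=3)
        direct = ridge_decode(X, y, n_folds=5, seed=3)
        np.testing.assert_allclose(np.diag(tg.z), direct.z, atol=1e-10)

    def test_sustained_code_generalises_off_diagonal(self, sustained_data):
        X, y = sustained_data
        tg = temporal_generalization(X, y, n_folds=5, seed=3)
        off = tg.z[np.triu_indices_from(tg.z, k=2)]
        assert off.min() > 1.0  # square block: training transfers everywhere

    def test_transient_chain_stays_on_diagonal(self):
        rng = np.random.default_rng(6)
        n, p, T = 150, 8, 6
        y = rng.standard_normal(n)
        X = 0.3 * rng.standard_normal((n, p, T))
        for t in range(T):  # rotating code: a different channel per time point
            X[:, t % p, t] += y
        tg = temporal_generalization(X, y, n_folds=5, seed=3)
        diag = np.diag(tg.z).mean()
        far_off = np.mean([tg.z[i, j] for i in range(T) for j in range(T)
                           if abs(i - j) >= 2])
        assert diag > 1.0 and far_off < 0.5 * diag


class TestLDAClassifier:
    def test_null_auc_near_half(self):
        rng = np.random.default_rng(7)
        X = rng.standard_normal((500, 6, 1))
        y = np.repeat([1, 2], 250)
        out = lda_response_classifier(X, y, n_folds=10)
        assert abs(out["auc"][0, 0] - 0.5) < 0.06

    @pytest.mark.parametrize("d", [1.0, 2.0])
    def test_auc_matches_gaussian_closed_form(self, d):
        rng = np.random.default_rng(8)
        n = 5000
        y = np.where(np.arange(n) % 2 == 0, 1, 2)
        X = rng.standard_normal((n, 4))
        X[:, 0] += np.where(y == 2, d, 0.0)
        out = lda_response_classifier(X[:, :, None], y, n_folds=10)
        assert abs(out["auc"][0, 0] - norm.cdf(d / np.sqrt(2))) < 0.02

    def test_equidistant_trial_strength_half(self):
        rng = np.random.default_rng(9)
        n = 400
        y = np.repeat([1, 2], n // 2)
        X = rng.standard_normal((n, 3)) + np.where(y == 2, 1.5, -1.5)[:, None]
        out = lda_response_classifier(X[:, :, None], y, n_folds=5)
        s = out["strength"]
        assert 0 <= s.min() and s.max() <= 1
        # a trial whose score sits exactly between the class means scores 0.5
        scores = out["scores"][:, 0, 0]
        m1 = scores[y == 1].mean()
        m2 = scores[y == 2].mean()
        mid = np.argmin(np.abs(scores - 0.5 * (m1 + m2)))
        assert s[mid] == pytest.approx(0.5, abs=0.05)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="two classes"):
            lda_response_classifier(np.zeros((10, 2, 1)), np.ones(10))


class TestStrengthRegression:
    def test_terminal_strength_decays_with_horizon(self):
        rng = np.random.default_rng(10)
        n = 600
        E = np.cumsum(rng.standard_normal((n, 4)), axis=1)[:, ::-1]
        strength = 0.5 + 0.1 * E[:, 0] + 0.02 * rng.standard_normal(n)
        cond = np.repeat(["less"], n)
        subj = np.tile(np.arange(3), n // 3)
        res = strength_evidence_regression(strength, E, cond, subj)
        means = res["betas"].groupby("horizon")["beta"].mean()
        assert means.iloc[0] > means.iloc[-1]

    def test_shuffled_strength_flat(self):
        rng = np.random.default_rng(11)
        n = 600
        E = rng.standard_normal((n, 3))
        strength = rng.random(n)
        res = strength_evidence_regression(
            strength, E, np.repeat(["less"], n), np.tile(np.arange(3), n // 3)
        )
        assert res["betas"]["beta"].abs().max() < 0.05

    def test_rank_deficiency_rejected(self):
        with pytest.raises(ValueError, match="rank"):
            strength_evidence_regression(
                np.random.default_rng(0).random(30),
                np.zeros((30, 2)),
                np.repeat(["less"], 30),
                np.zeros(30, dtype=int),
            )


def _forward_cells(rng, n_subj, n_per_cell, noise_by_cell):
    """Epochs with a linear target code whose noise varies by outcome cell."""
    rows_X, rows_y, rows = [], [], []
    w = rng.standard_normal(6)
    for subj in range(n_subj):
        for p_flag in (True, False):
            for c_flag in (True, False):
                y = rng.standard_normal(n_per_cell)
                noise = noise_by_cell[(p_flag, c_flag)]
                X = y[:, None] * w[None, :] + noise * rng.standard_normal(
                    (n_per_cell, 6)
                )
                rows_X.append(X)
                rows_y.append(y)
                rows.extend(
                    {"subject_id": subj, "perceptual_optimal": p_flag,
                     "confidence_optimal": c_flag}
                    for _ in range(n_per_cell)
                )
    import pandas as pd

    X = np.concatenate(rows_X)[..., None] * np.ones(3)
    return X, np.concatenate(rows_y), pd.DataFrame(rows)


class TestPrecisionByOutcome:
    def test_injected_perceptual_effect_detected(self):
        rng = np.random.default_rng(12)
        X, y, flags = _forward_cells(
            rng, 6, 40,
            {(True, True): 0.4, (True, False): 0.4,
             (False, True): 2.5, (False, False): 2.5},
        )
        res = precision_by_outcome(X, y, flags, n_folds=5, n_perm=300, seed=1)
        perc = res["clusters"]["perceptual"]
        assert any(c.p_value < 0.05 and c.mass > 0 for c in perc)

    def test_label_swap_flips_effect_sign(self):
        rng = np.random.default_rng(13)
        X, y, flags = _forward_cells(
            rng, 5, 40,
            {(True, True): 0.4, (True, False): 0.4,
             (False, True): 2.0, (False, False): 2.0},
        )
        res = precision_by_outcome(X, y, flags, n_folds=5, n_perm=100, seed=1)
        swapped = flags.copy()
        swapped["perceptual_optimal"] = ~swapped["perceptual_optimal"]
        res2 = precision_by_outcome(X, y, swapped, n_folds=5, n_perm=100, seed=1)
        np.testing.assert_allclose(
            res["effects"]["perceptual"], -res2["effects"]["perceptual"], atol=1e-10
        )

    def test_empty_cell_rejected(self):
        rng = np.random.default_rng(14)
        X, y, flags = _forward_cells(rng, 3, 30, dict.fromkeys(
            [(True, True), (True, False), (False, True), (False, False)], 1.0))
        flags.loc[flags["perceptual_optimal"] & flags["confidence_optimal"],
                  "confidence_optimal"] = False
        with pytest.raises(ValueError, match="degenerate"):
            precision_by_outcome(X, y, flags, n_folds=5, n_perm=50)


class TestClusterPermutation:
    def test_consistent_effect_found_and_null_quiet(self):
        rng = np.random.default_rng(15)
        effects = 0.2 * rng.standard_normal((12, 30))
        effects[:, 10:16] += 1.0
        clusters = cluster_permutation_test(effects, n_perm=500, seed=0)
        sig = [c for c in clusters if c.p_value < 0.05]
        assert sig and sig[0].start >= 8 and sig[0].stop <= 18
        null = cluster_permutation_test(
            0.2 * rng.standard_normal((12, 30)), n_perm=500, seed=0
        )
        assert all(c.p_value > 0.05 for c in null)


class TestLastSamplesContrast:
    def test_k_equals_one_uses_final_sample_only(self, epoch_cohort):
        ep = epoch_cohort["stim_epochs"]
        res = last_samples_contrast(
            ep.data[:, :, ::8], ep.labels["accumulated"].to_numpy(), ep.labels,
            k=1, n_folds=4, n_perm=50,
        )
        # only final-sample epochs enter: counts match the trial count
        lab = ep.labels
        for cond in ("more", "less"):
            n_trials = lab[(lab["condition"] == cond)
                           & (lab["sample_index"] == lab["n_shown"])].shape[0]
            assert n_trials > 0
        assert res["difference"].shape[0] == lab["subject_id"].nunique()


class TestEpochIO:
    def test_hdf5_roundtrip(self, epoch_cohort, tmp_path):
        ep = epoch_cohort["stim_epochs"]
        path = tmp_path / "epochs.h5"
        ep.save(path)
        back = EpochTensor.load(path)
        np.testing.assert_allclose(back.data, ep.data)
        np.testing.assert_allclose(back.times, ep.times)
        assert back.lock == "stimulus"
        assert list(back.labels.columns) == list(ep.labels.columns)
        np.testing.assert_allclose(
            back.labels["accumulated"], ep.labels["accumulated"]
        )
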