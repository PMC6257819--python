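"""Decoding pipeline: folds, averaging, z-scoring, maps, evidence."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from seqdecode.decode import (
    DecodeConfig,
    InsufficientDataError,
    decode_conditional,
    decode_map,
    fold_average,
    make_folds,
    summarize_period,
    window_average,
    zscore_across,
)
from helpers import toy_tf


class TestFolds:
    def test_counts_equated_within_and_across_folds(self):
        rng = np.random.default_rng(0)
        labels = np.repeat(["a", "b", "c"], [40, 37, 35])
        fold = make_folds(labels, 4, rng)
        # 35 // 4 = 8 per class per fold
        for r in range(4):
            for c in "abc":
                assert np.sum((fold == r) & (labels == c)) == 8
        assert np.sum(fold == -1) == (40 - 32) + (37 - 32) + (35 - 32)

    def test_balanced_input_drops_nothing(self):
        rng = np.random.default_rng(0)
        labels = np.repeat(["a", "b", "c"], 36)
        fold = make_folds(labels, 4, rng)
        assert not np.any(fold == -1)

    def test_insufficient_class_raises(self):
        rng = np.random.default_rng(0)
        labels = np.array(["a"] * 10 + ["b"] * 3)
        with pytest.raises(InsufficientDataError, match="b"):
            make_folds(labels, 4, rng)


class TestFoldMatrix:
    def test_zscore_toy_cell(self):
        # 3 electrodes with values 1,2,3 -> population z-scores
        z = zscore_across(np.array([[1.0, 2.0, 3.0]]), axis=1)
        assert z[0] == pytest.approx([-1.224744871, 0.0, 1.224744871])

    def test_constant_across_electrodes_maps_to_zero(self):
        rng = np.random.default_rng(1)
        n = 24
        power = np.ones((n, 5, 2, 3))
        labels = np.tile(["a", "b", "c"], n // 3)
        fold = make_folds(labels, 4, rng)
        F = fold_average(power, fold, labels, np.unique(labels), 4)
        assert np.all(F == 0)

    def test_window_one_is_identity(self):
        x = np.random.default_rng(2).standard_normal((2, 3, 4, 50))
        assert window_average(x, 1) is x

    def test_window_average_is_centered_mean(self):
        x = np.zeros((1, 1, 1, 11))
        x[..., 5] = 1.0
        w = window_average(x, 5)
        assert w[0, 0, 0, 5] == pytest.approx(0.2)
        assert w[0, 0, 0, 2] == 0.0


class TestDecodeMap:
    def test_permuted_labels_at_chance(self, noise_tf, small_schedule):
        rng = np.random.default_rng(3)
        labels = small_schedule["within_chunk_position"].to_numpy()
        cfg = DecodeConfig(n_iterations=2, window_step=25, seed=7,
                           compute_evidence=False)
        accs = []
        for k in range(3):
            res = decode_map(noise_tf, rng.permutation(labels), cfg)
            accs.append(res.accuracy.mean())
        assert np.mean(accs) == pytest.approx(1 / 3, abs=0.02)

    def test_injected_pattern_recovered_in_band_window(
        self, element_tf, small_schedule, quick_config
    ):
        res = decode_map(element_tf, small_schedule["element"].to_numpy(),
                         quick_config)
        inside = summarize_period(res.accuracy, res.freqs, res.times,
                                  (8, 12), (-500, -100))
        far_freq = summarize_period(res.accuracy, res.freqs, res.times,
                                    (25, 35), (-500, -100))
        after = summarize_period(res.accuracy, res.freqs, res.times,
                                 (8, 12), (300, 400))
        assert inside > 0.9
        assert abs(far_freq - 1 / 3) < 0.1
        assert abs(after - 1 / 3) < 0.1

    def test_other_code_not_decodable(self, element_tf, small_schedule, quick_config):
        # only the element pattern is present: positions stay at chance
        res = decode_map(element_tf,
                         small_schedule["within_chunk_position"].to_numpy(),
                         quick_config)
        assert res.accuracy.mean() == pytest.approx(1 / 3, abs=0.03)

    def test_confusion_columns_sum_to_one(self, element_tf, small_schedule,
                                          quick_config):
        res = decode_map(element_tf, small_schedule["element"].to_numpy(),
                         quick_config)
        assert np.allclose(res.confusion.sum(axis=2), 1.0)

    def test_evidence_finite_and_higher_for_decodable_signal(
        self, element_tf, small_schedule
    ):
        cfg = DecodeConfig(n_iterations=2, window_step=25, seed=5)
        res = decode_map(element_tf, small_schedule["element"].to_numpy(), cfg)
        ev = res.evidence[~np.isnan(res.evidence)]
        assert np.isfinite(ev).all()
        prep = summarize_period(np.nanmean(res.evidence, axis=0), res.freqs,
                                res.times, (8, 12), (-500, -100))
        off = summarize_period(np.nanmean(res.evidence, axis=0), res.freqs,
                               res.times, (25, 35), (-500, -100))
        assert prep > off

    def test_accuracy_monotone_in_snr(self, small_schedule, small_bank):
        from seqdecode.spectral import tf_power
        from seqdecode.synth_eeg import ALPHA, CodePatternSpec, NoiseSpec, simulate_dataset

        sched = small_schedule.head(162)
        cfg = DecodeConfig(n_iterations=2, window_step=25, seed=6,
                           compute_evidence=False)
        accs = []
        for amp in (0.0, 3.0, 12.0):
            patterns = [CodePatternSpec(code="element", band=ALPHA,
                                        window=(-600, 0), amplitude=amp)]
            eeg = simulate_dataset(sched, patterns, NoiseSpec(noise_sd=10.0),
                                   seed=33, analysis_window=(-700.0, 400.0))
            tf = tf_power(eeg, small_bank)
            res = decode_map(tf, sched["element"].to_numpy(), cfg)
            accs.append(summarize_period(res.accuracy, res.freqs, res.times,
                                         (8, 12), (-500, -100)))
        assert accs[0] <= accs[1] + 0.05 <= accs[2] + 0.05
        assert accs[2] > 0.9

    def test_two_class_gaussian_matches_bayes_rate(self):
        # closed-form oracle: for two isotropic Gaussian classes with mean
        # separation d (in noise-SD units), the Bayes accuracy is Phi(d/2)
        rng = np.random.default_rng(8)
        e, n_per = 8, 320
        mu = rng.standard_normal(e)
        mu -= mu.mean()
        mu /= np.linalg.norm(mu)
        d = 1.4
        bayes = stats.norm.cdf(d / 2)
        X = np.concatenate([
            rng.standard_normal((n_per, e)) + d / 2 * mu,
            rng.standard_normal((n_per, e)) - d / 2 * mu,
        ])
        labels = np.array(["hi"] * n_per + ["lo"] * n_per)
        tf = toy_tf(X)
        cfg = DecodeConfig(n_folds=8, n_iterations=8, window_samples=1, seed=9)
        res = decode_map(tf, labels, cfg)
        trial_acc = np.nanmean(res.trial_accuracy)
        assert trial_acc == pytest.approx(bayes, abs=0.05)


class TestSummarize:
    def test_constant_map(self):
        acc = np.full((4, 5), 0.4)
        freqs = np.array([4, 6, 9, 12])
        times = np.array([-600, -300, 0, 150, 300])
        assert summarize_period(acc, freqs, times, (4, 7), (-600, 0)) == pytest.approx(0.4)

    def test_block_constant_map(self):
        freqs = np.array([4.0, 6.0, 10.0])
        times = np.array([-400.0, 100.0])
        acc = np.full((3, 2), 1 / 3)
        acc[:2, 0] = 0.5  # theta x prep block
        assert summarize_period(acc, freqs, times, (4, 7), (-600, 0)) == pytest.approx(0.5)
        assert summarize_period(acc, freqs, times, (8, 12), (0, 300)) == pytest.approx(1 / 3)

    def test_checker_map_equals_hand_mean(self):
        freqs = np.array([4.0, 6.0])
        times = np.array([-100.0, 0.0])
        acc = np.array([[0.2, 0.4], [0.6, 0.8]])
        assert summarize_period(acc, freqs, times, (4, 7), (-600, 0)) == pytest.approx(0.5)

    def test_empty_selection_errors(self):
        with pytest.raises(ValueError):
            summarize_period(np.ones((2, 2)), np.array([4, 5]),
                             np.array([0, 1]), (20, 30), (0, 1))


class TestConditional:
    def _stratified_features(self, rng, n=216):
        # element pattern present only when chunk_position == 1
        e = 12
        topo = {c: v for c, v in zip("ABC", rng.standard_normal((3, e)))}
        element = np.tile(list("ABC"), n // 3)
        stratum = np.tile([1, 1, 2, 2, 3, 3], n // 6)
        X = rng.standard_normal((n, e))
        for i in range(n):
            if stratum[i] == 1:
                X[i] += 5.0 * topo[element[i]]
        return X, element, stratum

    def test_pattern_only_in_stratum_one(self):
        rng = np.random.default_rng(10)
        X, element, stratum = self._stratified_features(rng)
        tf = toy_tf(X)
        cfg = DecodeConfig(n_iterations=6, window_samples=1, seed=11)
        maps = decode_conditional(tf, element, stratum, cfg, mode="train_all")
        assert maps[1].accuracy.mean() > 0.6
        assert maps[2].accuracy.mean() == pytest.approx(1 / 3, abs=0.12)
        assert maps[3].accuracy.mean() == pytest.approx(1 / 3, abs=0.12)

    def test_single_stratum_equals_decode_map(self, noise_tf, small_schedule):
        labels = small_schedule["element"].to_numpy()
        cfg = DecodeConfig(n_iterations=1, window_step=50, seed=12,
                           compute_evidence=False)
        ref = decode_map(noise_tf, labels, cfg)
        got = decode_conditional(noise_tf, labels, np.ones(len(labels)), cfg,
                                 mode="within")
        assert np.allclose(got[1.0].accuracy, ref.accuracy)

    def test_empty_stratum_warns(self):
        rng = np.random.default_rng(13)
        X = rng.standard_normal((60, 6))
        labels = np.tile(list("ABC"), 20)
        cond = np.ones(60)
        cfg = DecodeConfig(n_iterations=1, window_samples=1, seed=1,
                           compute_evidence=False)
        res = decode_conditional(toy_tf(X), labels, cond, cfg, mode="within")
        assert set(res) == {1.0}
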