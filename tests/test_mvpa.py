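"""EEG decoding stage: hygiene, ERPs, CPCA, classifier, AUC, CV."""

import numpy as np
import pytest

from cueshift.mvpa import (
    CPCA,
    LinearBayesClassifier,
    auc_mann_whitney,
    crossval_decode,
    difference_erp,
    linear_bayes_classify,
    reject_noisy_epochs,
)
from cueshift.simulate import EegEpochs, simulate_eeg


def _epochs_from(data, labels=None, cond=None, sfreq=128.0):
    n = data.shape[0]
    labels = labels if labels is not None else np.array(["face", "car"] * (n // 2))
    cond = cond if cond is not None else np.full(n, "x")
    return EegEpochs(data, labels, cond, sfreq)


class TestRejectNoisyEpochs:
    def test_identical_epochs_keep_all(self):
        data = np.tile(np.sin(np.linspace(0, 5, 89)), (20, 4, 1))
        mask = reject_noisy_epochs(_epochs_from(data))
        assert not mask.any()

    def test_scaled_outlier_flagged(self):
        rng = np.random.default_rng(0)
        data = rng.standard_normal((100, 4, 89))
        data[17, 2] = data[17, 2] * 100 + 50
        mask = reject_noisy_epochs(_epochs_from(data))
        assert mask[17, 2]
        assert mask.sum() <= 3  # essentially only the planted outlier

    def test_rule_stable_on_retained_set(self):
        rng = np.random.default_rng(1)
        data = rng.standard_normal((200, 4, 89))
        ep = _epochs_from(data)
        mask = reject_noisy_epochs(ep)
        kept = ~mask.any(axis=1)
        second = reject_noisy_epochs(ep.select(kept))
        assert second.mean() <= mask.mean() + 0.01

    def test_too_few_epochs_warns_and_keeps(self):
        data = np.random.default_rng(2).standard_normal((5, 4, 89))
        with pytest.warns(UserWarning):
            mask = reject_noisy_epochs(
                EegEpochs(data, np.array(["face"] * 5), np.full(5, "x"), 128.0)
            )
        assert not mask.any()


class TestDifferenceErp:
    def test_identical_class_means_give_zero(self):
        rng = np.random.default_rng(0)
        trial = rng.standard_normal((1, 4, 89))
        data = np.tile(trial, (20, 1, 1))
        wave = difference_erp(_epochs_from(data))
        np.testing.assert_allclose(wave, 0.0, atol=1e-12)

    def test_peak_latency_tracks_injected_signal(self):
        # average an electrode set with a consistent topography sign, as in
        # ERP practice; a whole-scalp average cancels opposite polarities
        ep = simulate_eeg(40, {"x": 2.0}, n_channels=8, sfreq=256, seed=3)
        wave = difference_erp(ep, channels=[0, 1])
        peak_ms = ep.times[np.argmax(np.abs(wave))]
        assert 200.0 <= peak_ms <= 300.0

    def test_linearity(self):
        ep = simulate_eeg(10, {"x": 1.0}, n_channels=4, sfreq=128, seed=4)
        scaled = EegEpochs(3.0 * ep.data, ep.labels, ep.condition, ep.sfreq,
                           ep.window_ms, ep.baseline_ms)
        np.testing.assert_allclose(difference_erp(scaled), 3.0 * difference_erp(ep),
                                   rtol=1e-10)

    def test_missing_class_rejected(self):
        data = np.zeros((6, 2, 10))
        with pytest.raises(ValueError):
            difference_erp(EegEpochs(data, np.array(["face"] * 6), np.full(6, "x"), 128.0))


class TestCPCA:
    def _geometry(self, seed, snr=1.0, d=50, n=40):
        rng = np.random.default_rng(seed)
        noise_dir = np.zeros(d); noise_dir[0] = 1.0
        sig_dir = np.zeros(d); sig_dir[1] = 1.0
        X = rng.standard_normal((n, d)) * 0.3 + rng.standard_normal((n, 1)) * 5 * noise_dir
        y = np.array(["a"] * (n // 2) + ["b"] * (n // 2))
        X[y == "b"] += snr * sig_dir
        return X, y, sig_dir

    def test_retains_discriminative_direction(self):
        """The class-separating axis survives despite dominant shared noise."""
        hits = 0
        for seed in range(10):
            X, y, sig_dir = self._geometry(seed)
            cpca = CPCA(0.99).fit(X, y)
            hits += np.linalg.norm(cpca.components_ @ sig_dir) > 0.9
        assert hits >= 9

    def test_no_leakage_from_test_data(self):
        X, y, _ = self._geometry(0)
        a = CPCA(0.99).fit(X, y)
        b = CPCA(0.99).fit(X, y)
        np.testing.assert_array_equal(a.components_, b.components_)
        test = np.random.default_rng(1).standard_normal((5, X.shape[1]))
        np.testing.assert_array_equal(a.transform(test), b.transform(test))

    def test_dimensionality_bounded_by_trials(self):
        X, y, _ = self._geometry(2, n=24)
        cpca = CPCA(0.99).fit(X, y)
        assert cpca.components_.shape[0] <= 24
        assert cpca.transform(X).shape == (24, cpca.components_.shape[0])

    def test_variance_argument_validated(self):
        X, y, _ = self._geometry(3)
        for bad in (0.0, 1.2, -0.5):
            with pytest.raises(ValueError):
                CPCA(bad).fit(X, y)

    def test_components_orthonormal(self):
        X, y, _ = self._geometry(4)
        cpca = CPCA(0.99).fit(X, y)
        gram = cpca.components_ @ cpca.components_.T
        np.testing.assert_allclose(gram, np.eye(len(gram)), atol=1e-8)


class TestLinearBayes:
    def _symmetric_data(self, rng, n=200, d=4):
        mu = np.zeros(d); mu[0] = 2.0
        X = np.vstack([rng.standard_normal((n, d)) - mu,
                       rng.standard_normal((n, d)) + mu])
        y = np.array(["a"] * n + ["b"] * n)
        return X, y, mu

    def test_midpoint_posterior_half(self):
        X, y, _ = self._symmetric_data(np.random.default_rng(0))
        post = linear_bayes_classify(X, y, np.zeros((1, X.shape[1])))
        assert post[0] == pytest.approx(0.5, abs=0.05)

    def test_far_point_saturates(self):
        X, y, mu = self._symmetric_data(np.random.default_rng(1))
        post = linear_bayes_classify(X, y, (20 * mu)[None, :])
        assert post[0] > 1.0 - 1e-6

    def test_log_odds_affine_in_features(self):
        rng = np.random.default_rng(2)
        X, y, _ = self._symmetric_data(rng)
        clf = LinearBayesClassifier().fit(X, y)
        grid = rng.standard_normal((40, X.shape[1]))
        p = np.clip(clf.predict_proba(grid)[:, -1], 1e-12, 1 - 1e-12)
        logodds = np.log(p / (1 - p))
        # affine model reproduces the log-odds exactly
        design = np.hstack([grid, np.ones((len(grid), 1))])
        coef, *_ = np.linalg.lstsq(design, logodds, rcond=None)
        np.testing.assert_allclose(design @ coef, logodds, atol=1e-8)

    def test_single_class_rejected(self):
        X = np.random.default_rng(3).standard_normal((10, 3))
        with pytest.raises(ValueError):
            LinearBayesClassifier().fit(X, np.array(["a"] * 10))


class TestAuc:
    def test_perfect_separation(self):
        scores = np.r_[np.zeros(10), np.ones(10)]
        labels = np.array(["a"] * 10 + ["b"] * 10)
        assert auc_mann_whitney(scores, labels, positive="b") == 1.0

    def test_matches_pair_counting_oracle_exactly(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            n1, n2 = rng.integers(2, 12, 2)
            scores = np.round(rng.normal(size=n1 + n2), 1)  # force ties
            labels = np.array(["a"] * n1 + ["b"] * n2)
            s_pos, s_neg = scores[n1:], scores[:n1]
            oracle = np.mean(
                (s_pos[:, None] > s_neg[None, :]) + 0.5 * (s_pos[:, None] == s_neg[None, :])
            )
            assert auc_mann_whitney(scores, labels, positive="b") == pytest.approx(
                oracle, abs=1e-12
            )

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(6)
        scores = rng.random(100)
        labels = np.array(["a", "b"] * 50)
        a1 = auc_mann_whitney(scores, labels)
        a2 = auc_mann_whitney(np.exp(5 * scores) - 2, labels)
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_single_class_undefined(self):
        assert np.isnan(auc_mann_whitney(np.ones(5), np.array(["a"] * 5)))


class TestCrossvalDecode:
    def test_windowed_scope_recovers_signal_latency(self):
        """Signal centred at 250 ms peaks in the 200-300 ms windows."""
        # moderate SNR: strong windows stay below AUC 1.0, so the peak
        # window is identifiable rather than a tie among saturated ones
        hits = 0
        for seed in range(10):
            ep = simulate_eeg(30, {"x": 0.6}, n_channels=8, sfreq=128, seed=seed)
            res = crossval_decode(ep, folds=10, seed=seed, scope="window")
            best = res.window_starts_ms[np.argmax(res.window_aucs)]
            hits += 200.0 <= best < 300.0
        assert hits >= 9

    def test_fold_assignment_partitions_trials(self):
        ep = simulate_eeg(20, {"x": 0.5}, n_channels=4, sfreq=64, seed=1)
        res = crossval_decode(ep, folds=10, seed=1)
        counts = np.bincount(res.fold_assignment, minlength=10)
        assert counts.sum() == ep.n_trials and counts.min() >= 2

    def test_deterministic_given_seed(self):
        ep = simulate_eeg(15, {"x": 0.5}, n_channels=4, sfreq=64, seed=2)
        r1 = crossval_decode(ep, folds=5, seed=3)
        r2 = crossval_decode(ep, folds=5, seed=3)
        assert r1.auc == r2.auc
        np.testing.assert_array_equal(r1.posteriors, r2.posteriors)

    def test_electrode_scope_shapes(self):
        ep = simulate_eeg(15, {"x": 1.0}, n_channels=4, sfreq=64, seed=4)
        res = crossval_decode(ep, folds=5, seed=4, scope="electrode")
        n_win = len(res.window_starts_ms)
        assert res.electrode_window_aucs.shape == (4, n_win)
        assert res.window_pvalues_fdr.shape == (n_win,)

    def test_too_few_trials_rejected(self):
        ep = simulate_eeg(5, {"x": 0.5}, n_channels=4, sfreq=64, seed=5)
        with pytest.raises(ValueError):
            crossval_decode(ep, folds=10, seed=5)
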