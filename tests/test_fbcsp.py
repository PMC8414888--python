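"""Filter-bank CSP decoding: closed forms, features, QDA, cross-validation."""

import numpy as np
import pytest

from restbci.cohort import SubjectProfile, default_layout, generate_mi_session
from restbci.fbcsp import (CvScheme, FilterBank, ShrinkageQda,
                           apply_filter_bank, cross_validate,
                           csp_eigendecomposition, csp_features, csp_fit)
from restbci.preprocessing import EpochSet, extract_mi_epochs


def toy_epochs(data, layout=None, fs=160.0, labels=None):
    layout = layout or default_layout()
    return EpochSet(epochs=data, fs=fs, layout=layout,
                    condition="MI" if labels is not None else "REO",
                    labels=labels)


@pytest.fixture(scope="module")
def small_layout():
    from restbci.cohort import ChannelLayout
    return ChannelLayout(names=("C3", "Cz", "C4"), frontal_set=(),
                         central_set=("C3", "Cz", "C4"))


class TestFilterBank:
    def test_nine_bands(self):
        bank = FilterBank()
        assert len(bank.bands) == 9
        assert bank.bands[0] == (4.0, 8.0) and bank.bands[-1] == (36.0, 40.0)

    def test_output_leading_axis_is_bands(self, small_layout, rng):
        epochs = toy_epochs(rng.standard_normal((4, 3, 640)), small_layout)
        banded = apply_filter_bank(epochs)
        assert banded.shape == (9, 4, 3, 640)

    def test_sinusoid_lands_in_its_band(self, small_layout):
        t = np.arange(640) / 160.0
        x = np.tile(np.sin(2 * np.pi * 10.0 * t), (1, 3, 1))
        banded = apply_filter_bank(toy_epochs(x, small_layout))
        energies = (banded ** 2).sum(axis=(1, 2, 3))
        assert energies[1] / energies.sum() > 0.8  # 8-12 Hz copy

    def test_zero_epochs_stay_zero(self, small_layout):
        banded = apply_filter_bank(toy_epochs(np.zeros((2, 3, 640)),
                                              small_layout))
        assert not banded.any()

    def test_band_above_nyquist_rejected(self, small_layout, rng):
        epochs = toy_epochs(rng.standard_normal((2, 3, 640)), small_layout,
                            fs=70.0)
        with pytest.raises(ValueError):
            apply_filter_bank(epochs)


class TestCspClosedForms:
    def test_equal_covariances_give_half_eigenvalues(self, rng):
        A = rng.standard_normal((4, 4))
        S = A @ A.T + 4 * np.eye(4)
        _, d = csp_eigendecomposition(S, S)
        np.testing.assert_allclose(d, 0.5, atol=1e-10)

    def test_diagonal_covariances_closed_form(self):
        a = np.array([4.0, 1.0, 0.25])
        b = np.array([1.0, 1.0, 1.0])
        W, d = csp_eigendecomposition(np.diag(a), np.diag(b))
        np.testing.assert_allclose(d, np.sort(a / (a + b))[::-1], atol=1e-12)
        # filters are coordinate axes (up to sign/scale)
        for col in W.T:
            assert np.sum(np.abs(col) > 1e-9) == 1

    def test_eigenvalue_duality_under_class_swap(self, rng):
        A = rng.standard_normal((5, 5)); S1 = A @ A.T + np.eye(5)
        B = rng.standard_normal((5, 5)); S2 = B @ B.T + np.eye(5)
        _, d12 = csp_eigendecomposition(S1, S2)
        _, d21 = csp_eigendecomposition(S2, S1)
        np.testing.assert_allclose(d12, (1 - d21)[::-1], atol=1e-10)

    def test_planted_source_beats_every_single_channel(self, rng):
        """The leading CSP filter's between-class variance ratio exceeds
        that of each raw channel (brute-force per-channel oracle)."""
        n_tr, n_ch, n_s = 30, 6, 200
        mix = rng.standard_normal((n_ch, 2))
        trials = np.empty((2 * n_tr, n_ch, n_s))
        labels = np.repeat(["a", "b"], n_tr)
        for i in range(2 * n_tr):
            src = rng.standard_normal((2, n_s))
            src[0] *= 3.0 if labels[i] == "a" else 1.0
            trials[i] = mix @ src + 0.5 * rng.standard_normal((n_ch, n_s))
        banded = trials[None]  # single pseudo-band
        model = csp_fit(banded, labels, n_pairs=1)
        W = model.filters[0]
        def ratio(series_per_trial):
            va = np.array([s.var() for s in series_per_trial[labels == "a"]])
            vb = np.array([s.var() for s in series_per_trial[labels == "b"]])
            return va.mean() / vb.mean()
        csp_ratio = ratio(np.einsum("c,tcs->ts", W[:, 0], trials))
        channel_ratios = [ratio(trials[:, c]) for c in range(n_ch)]
        assert csp_ratio > max(channel_ratios)

    def test_single_class_rejected(self, rng):
        banded = rng.standard_normal((1, 4, 3, 50))
        with pytest.raises(ValueError):
            csp_fit(banded, np.array(["a"] * 4))


class TestCspFeatures:
    def test_vector_length_is_bands_times_2m(self, rng):
        banded = rng.standard_normal((9, 6, 4, 100))
        labels = np.array(["a", "b"] * 3)
        model = csp_fit(banded, labels, n_pairs=2)
        feats = csp_features(banded, model)
        assert feats.shape == (6, 36)

    def test_entries_are_log_fractions(self, rng):
        banded = rng.standard_normal((2, 5, 4, 80))
        model = csp_fit(banded, np.array(["a", "a", "b", "b", "a"]), n_pairs=1)
        assert (csp_features(banded, model) <= 0).all()

    def test_identity_filters_reproduce_hand_computation(self):
        x = np.array([[[1.0, 2.0, 3.0], [0.5, -0.5, 1.5]]])  # 1 trial, 2 ch
        banded = x[None]
        model_w = np.eye(2)
        from restbci.fbcsp import CspModel
        model = CspModel(filters=[model_w], eigenvalues=[np.array([1.0, 0.0])],
                         n_pairs=1)
        feats = csp_features(banded, model)[0]
        v = (x[0] ** 2).sum(axis=1)  # per-channel variances
        np.testing.assert_allclose(feats, np.log(v / v.sum()), atol=1e-12)


class TestQda:
    def test_separated_clouds_perfect_training_accuracy(self, rng):
        X = np.vstack([rng.normal(0, 1, (30, 3)), rng.normal(8, 1, (30, 3))])
        y = np.repeat(["a", "b"], 30)
        clf = ShrinkageQda().fit(X, y)
        assert (clf.predict(X) == y).all()

    def test_identical_distributions_near_chance(self, rng):
        X_train = rng.standard_normal((200, 4))
        y_train = np.repeat(["a", "b"], 100)
        clf = ShrinkageQda().fit(X_train, y_train)
        X_test = rng.standard_normal((400, 4))
        y_test = rng.choice(["a", "b"], 400)
        acc = (clf.predict(X_test) == y_test).mean()
        assert abs(acc - 0.5) < 1.96 * np.sqrt(0.25 / 400) + 0.02

    def test_equal_covariances_reduce_to_lda(self, rng):
        """When both empirical class covariances are identical, the QDA
        boundary equals the linear-discriminant boundary (sklearn LDA
        as the independent oracle)."""
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
        Xa = rng.standard_normal((40, 3))
        Xb = Xa + np.array([1.5, -0.5, 0.25])  # same scatter, shifted mean
        X = np.vstack([Xa, Xb])
        y = np.repeat(["a", "b"], 40)
        qda = ShrinkageQda(shrinkage=0.0).fit(X, y)
        lda = LinearDiscriminantAnalysis().fit(X, y)
        grid = rng.standard_normal((500, 3)) * 2 + np.array([0.75, -0.25, 0.125])
        agreement = (qda.predict(grid) == lda.predict(grid)).mean()
        assert agreement > 0.99

    def test_degenerate_single_class_rejected(self, rng):
        with pytest.raises(ValueError):
            ShrinkageQda().fit(rng.standard_normal((5, 2)), np.array(["a"] * 5))


class TestCrossValidation:
    def make_session_epochs(self, erd, seed, n_trials=15, noise=0.5):
        profile = SubjectProfile(0, erd_strength=erd, noise_scale=noise)
        ses = generate_mi_session(profile, n_trials, seed=seed)
        return extract_mi_epochs(ses)

    def test_25_fold_accuracies(self):
        epochs = self.make_session_epochs(0.7, seed=11)
        res = cross_validate(epochs, scheme=CvScheme(seed=1))
        assert res.fold_accuracies.shape == (5, 5)
        assert 0.0 <= res.mean_accuracy <= 1.0

    def test_deterministic_given_seed(self):
        epochs = self.make_session_epochs(0.5, seed=4)
        a = cross_validate(epochs, scheme=CvScheme(seed=3))
        b = cross_validate(epochs, scheme=CvScheme(seed=3))
        np.testing.assert_array_equal(a.fold_accuracies, b.fold_accuracies)

    def test_label_shuffle_is_at_chance(self, rng):
        epochs = self.make_session_epochs(0.8, seed=6, n_trials=21)
        epochs.labels = rng.permutation(epochs.labels)
        res = cross_validate(epochs, scheme=CvScheme(seed=2))
        # binomial band on the 42 distinct trials
        half_width = 1.96 * np.sqrt(0.25 / 42)
        assert abs(res.mean_accuracy - 0.5) < half_width

    def test_leaky_variant_inflates_shuffled_accuracy(self, rng):
        """Fitting CSP on all trials before splitting leaks test
        information; on label-shuffled data it shifts accuracy above the
        leakage-free estimate."""
        epochs = self.make_session_epochs(0.8, seed=9, n_trials=21)
        epochs.labels = np.asarray(rng.permutation(epochs.labels))
        clean = cross_validate(epochs, scheme=CvScheme(seed=5))
        leaky = cross_validate(epochs, scheme=CvScheme(seed=5), leaky=True)
        assert leaky.mean_accuracy > clean.mean_accuracy

    def test_global_rescaling_invariance(self):
        # trace normalisation and log-fraction features cancel any
        # scalar gain exactly
        epochs = self.make_session_epochs(0.6, seed=13)
        base = cross_validate(epochs, scheme=CvScheme(seed=7))
        epochs.epochs = epochs.epochs * 37.5
        scaled = cross_validate(epochs, scheme=CvScheme(seed=7))
        np.testing.assert_allclose(base.fold_accuracies,
                                   scaled.fold_accuracies, atol=1e-9)

    def test_channel_rescaling_changes_little(self):
        # per-channel gains alter per-trial trace normalisation, so
        # exact invariance is impossible; the summary should barely move
        epochs = self.make_session_epochs(0.6, seed=13)
        base = cross_validate(epochs, scheme=CvScheme(seed=7))
        scale = np.linspace(0.5, 4.0, epochs.epochs.shape[1])
        epochs.epochs = epochs.epochs * scale[None, :, None]
        scaled = cross_validate(epochs, scheme=CvScheme(seed=7))
        assert abs(base.mean_accuracy - scaled.mean_accuracy) < 0.08

    def test_too_few_trials_rejected(self):
        epochs = self.make_session_epochs(0.5, seed=1, n_trials=3)
        with pytest.raises(ValueError):
            cross_validate(epochs, scheme=CvScheme(n_folds=5))
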