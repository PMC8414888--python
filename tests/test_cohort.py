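"""Synthetic cohort generator: layout, determinism, planted effects."""

import numpy as np
import pytest

from restbci.cohort import (ChannelLayout, EffectSpec, SubjectProfile,
                            default_layout, draw_profiles, generate_cohort,
                            generate_mi_session, generate_resting_recording)
from restbci.preprocessing import extract_mi_epochs
from restbci.spectral import compute_psd


def band_power(x, fs, low, high):
    """Periodogram band power, inclusive edges (oracle helper)."""
    freqs = np.fft.rfftfreq(len(x), 1 / fs)
    p = np.abs(np.fft.rfft(x)) ** 2
    return p[(freqs >= low) & (freqs <= high)].sum()


class TestLayout:
    def test_default_has_56_unique_channels(self, layout):
        assert layout.n_channels == 56
        assert len(set(layout.names)) == 56

    def test_excluded_channels_absent(self, layout):
        for ch in ("AF7", "AF8", "FT7", "FT8", "T9", "T10", "Iz", "Oz"):
            assert ch not in layout.names

    def test_duplicate_labels_rejected(self):
        with pytest.raises(ValueError):
            ChannelLayout(names=("C3", "C3"), frontal_set=(), central_set=())

    def test_subset_outside_layout_rejected(self):
        with pytest.raises(ValueError):
            ChannelLayout(names=("C3", "C4"), frontal_set=("F3",),
                          central_set=())


class TestRestingRecording:
    def test_no_sources_no_noise_is_all_zero(self, layout):
        profile = SubjectProfile(0, theta_level=0, alpha_level=0,
                                 beta_level=0, noise_scale=0)
        rec = generate_resting_recording(profile, "REO", 2.0, 160.0, layout, 0)
        assert not rec.data.any()

    def test_sample_count_and_shape(self, layout):
        profile = SubjectProfile(0)
        rec = generate_resting_recording(profile, "REO", 60.0, 160.0, layout, 1)
        assert rec.data.shape == (56, 9600)
        assert rec.condition == "REO"

    def test_fully_regular_theta_is_pure_periodic(self, layout):
        """With regularity 1 and no noise, frontal channels carry a pure
        periodic oscillation whose power lies >99% inside 4-8 Hz."""
        profile = SubjectProfile(0, theta_level=2.0, alpha_level=0,
                                 beta_level=0, regularity=1.0, noise_scale=0)
        rec = generate_resting_recording(profile, "REO", 4.0, 160.0, layout, 3)
        frontal = layout.indices(layout.frontal_set)
        x = rec.data[frontal[len(frontal) // 2]]
        assert x.std() > 0
        total = band_power(x, 160.0, 0.0, 80.0)
        inband = band_power(x, 160.0, 4.0, 8.0)
        assert inband / total > 0.99
        # periodicity: one fundamental period of 0.25 s repeats exactly
        period = 40
        assert np.allclose(x[:-period], x[period:], atol=1e-8 * x.std())

    def test_determinism(self, layout):
        profile = SubjectProfile(0)
        a = generate_resting_recording(profile, "REO", 3.0, 160.0, layout, 7)
        b = generate_resting_recording(profile, "REO", 3.0, 160.0, layout, 7)
        np.testing.assert_array_equal(a.data, b.data)

    def test_rec_has_more_occipito_parietal_alpha(self, layout):
        """Eyes-closed alpha dominance: REC recordings hold more 8-13 Hz
        power over occipito-parietal channels than paired REO."""
        profile = SubjectProfile(0)
        idx = layout.indices(layout.occipito_parietal_set)
        reo = generate_resting_recording(profile, "REO", 10.0, 160.0, layout, 5)
        rec = generate_resting_recording(profile, "REC", 10.0, 160.0, layout, 6)
        alpha_reo = sum(band_power(reo.data[i], 160.0, 8, 13) for i in idx)
        alpha_rec = sum(band_power(rec.data[i], 160.0, 8, 13) for i in idx)
        assert alpha_rec > 2.0 * alpha_reo

    def test_unknown_condition_rejected(self, layout):
        with pytest.raises(ValueError):
            generate_resting_recording(SubjectProfile(0), "MI", 2.0, 160.0,
                                       layout, 0)


class TestMiSession:
    def test_trial_count_and_annotations(self, layout):
        ses = generate_mi_session(SubjectProfile(0), 5, 160.0, layout, 1)
        assert len(ses.annotations) == 10
        labels = [lab for _, lab in ses.annotations]
        assert sorted(set(labels)) == ["L", "R"]
        assert ses.n_samples == 10 * 6 * 160

    def test_full_suppression_zeroes_contralateral_mu(self, layout):
        """erd_strength 1 with no noise removes all task-window power on
        the suppressed hemisphere."""
        profile = SubjectProfile(0, theta_level=0, erd_strength=1.0,
                                 noise_scale=0)
        ses = generate_mi_session(profile, 4, 160.0, layout, 2)
        epochs = extract_mi_epochs(ses)
        left = layout.indices(tuple(
            ch for ch in layout.central_set if ch[-1] in "135"))
        right = layout.indices(tuple(
            ch for ch in layout.central_set if ch[-1] in "246"))
        for ep, lab in zip(epochs.epochs, epochs.labels):
            suppressed = right if lab == "L" else left
            active = left if lab == "L" else right
            # suppressed channels are flat (zero oscillatory power; only
            # the constant fixation-baseline offset remains)
            assert ep[suppressed].std(axis=1).max() < 1e-12
            assert ep[active].std(axis=1).min() > 0

    def test_null_effect_leaves_classes_indistinguishable(self, layout):
        """With erd_strength 0, class-conditional mu power differs only
        by sampling noise (ratio near 1)."""
        profile = SubjectProfile(0, erd_strength=0.0, noise_scale=0.2)
        ses = generate_mi_session(profile, 20, 160.0, layout, 3)
        epochs = extract_mi_epochs(ses)
        central = layout.indices(layout.central_set)
        power = (epochs.epochs[:, central, :] ** 2).sum(axis=(1, 2))
        mask = epochs.labels == "L"
        ratio = power[mask].mean() / power[~mask].mean()
        assert 0.8 < ratio < 1.25

    def test_strong_effect_supports_band_power_threshold_classifier(self, layout):
        """A threshold on the best single channel's task-window variance
        separates classes when the planted effect is strong."""
        profile = SubjectProfile(0, erd_strength=0.8, noise_scale=0.3)
        ses = generate_mi_session(profile, 20, 160.0, layout, 4)
        epochs = extract_mi_epochs(ses)
        y = (epochs.labels == "L")
        best = 0.0
        for ch in layout.indices(layout.central_set):
            v = np.log((epochs.epochs[:, ch, :] ** 2).sum(axis=1))
            thr = np.median(v)
            acc = max(((v > thr) == y).mean(), ((v <= thr) == y).mean())
            best = max(best, acc)
        assert best > 0.8

    def test_fixation_carries_no_class_information(self, layout):
        """A variance-threshold decoder trained on fixation windows
        performs at chance within the binomial band."""
        profile = SubjectProfile(0, erd_strength=0.9, noise_scale=0.3)
        ses = generate_mi_session(profile, 30, 160.0, layout, 8)
        n_fix = 320
        accs = []
        y = np.array([lab == "L" for _, lab in ses.annotations])
        for ch in layout.indices(layout.central_set):
            v = np.array([
                np.log((ses.data[ch, onset - n_fix:onset] ** 2).sum())
                for onset, _ in ses.annotations])
            thr = np.median(v)
            accs.append(max(((v > thr) == y).mean(), ((v <= thr) == y).mean()))
        # the best of 21 channels on 60 chance trials: allow selection bias
        assert max(accs) < 0.5 + 2.5 * np.sqrt(0.25 / 60)

    def test_low_sampling_rate_rejected(self, layout):
        with pytest.raises(ValueError):
            generate_mi_session(SubjectProfile(0), 2, 50.0, layout, 0)


class TestCohort:
    def test_cardinality(self, layout):
        spec = EffectSpec(rho=0.5, n_subjects=3, seed=1)
        profiles, resting, mi = generate_cohort(spec, 160.0, layout,
                                                duration_s=2.0,
                                                n_trials_per_class=1)
        assert len(profiles) == 3
        assert len(resting) == 3 and len(mi) == 3
        for sid in resting:
            assert set(resting[sid]) == {"REO", "REC"}

    def test_profiles_deterministic(self):
        a, _ = draw_profiles(EffectSpec(rho=0.4, n_subjects=10, seed=9))
        b, _ = draw_profiles(EffectSpec(rho=0.4, n_subjects=10, seed=9))
        assert a == b

    @pytest.mark.parametrize("rho,tol", [(0.0, 0.15), (0.9, 0.10)])
    def test_planted_correlation_recovered(self, rho, tol):
        """Empirical corr(theta_level, erd_strength) approaches the
        planted copula correlation for a large cohort."""
        profiles, _ = draw_profiles(EffectSpec(rho=rho, n_subjects=200, seed=21))
        theta = np.array([p.theta_level for p in profiles])
        erd = np.array([p.erd_strength for p in profiles])
        assert abs(np.corrcoef(theta, erd)[0, 1] - rho) < tol

    def test_top_theta_tercile_has_higher_erd(self):
        profiles, _ = draw_profiles(EffectSpec(rho=0.6, n_subjects=60, seed=3))
        theta = np.array([p.theta_level for p in profiles])
        erd = np.array([p.erd_strength for p in profiles])
        order = np.argsort(theta)
        third = len(order) // 3
        assert erd[order[-third:]].mean() > erd[order[:third]].mean()

    def test_rec_theta_decoupled_from_reo(self):
        """The eyes-closed recording draws independent theta parameters,
        so the planted link is specific to eyes-open."""
        reo, rec = draw_profiles(EffectSpec(rho=0.8, n_subjects=150, seed=5))
        erd = np.array([p.erd_strength for p in reo])
        theta_rec = np.array([p.theta_level for p in rec])
        assert abs(np.corrcoef(theta_rec, erd)[0, 1]) < 0.15

    def test_recording_roundtrip_via_array_and_sidecar(self, layout, tmp_path):
        profile = SubjectProfile(0)
        ses = generate_mi_session(profile, 2, 160.0, layout, 11)
        from restbci.cohort import load_recording, save_recording
        save_recording(ses, tmp_path / "s0_mi")
        back = load_recording(tmp_path / "s0_mi")
        assert back.condition == "MI"
        assert back.layout.names == layout.names
        assert back.annotations == ses.annotations
        np.testing.assert_allclose(back.data, ses.data, atol=1e-6)  # float32

    def test_invalid_rho_rejected(self):
        with pytest.raises(ValueError):
            EffectSpec(rho=1.0, n_subjects=10, seed=0)

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            EffectSpec(rho=0.0, n_subjects=2, seed=0)
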