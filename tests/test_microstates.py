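"""Tests of GFP, peak detection, AAHC clustering, labeling, backfitting and
GEV, including exact agreement with an independent greedy-rule oracle."""

import numpy as np
import pytest

import eegstates as es
from eegstates.exceptions import (InvalidArgumentError,
                                  UndefinedCorrelationError)
from eegstates.microstates import _fill_between_peaks

from oracles import aahc_oracle


def _orthogonal_maps(n_ch: int, k: int, seed: int = 0) -> np.ndarray:
    """k orthogonal, average-referenced, unit-GFP maps."""
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n_ch, n_ch))
    X -= X.mean(axis=0, keepdims=True)
    Q, _ = np.linalg.qr(X)
    maps = Q[:, 1:k + 1].T  # skip the component aligned with the mean
    maps = maps - maps.mean(axis=1, keepdims=True)
    return maps / maps.std(axis=1, keepdims=True)


class TestGfp:
    def test_values(self):
        assert es.gfp(np.array([1.0, -1.0])) == pytest.approx(1.0)
        assert es.gfp(np.array([3.0, 3.0, 3.0])) == 0.0

    def test_homogeneity(self):
        rng = np.random.default_rng(1)
        frames = rng.standard_normal((12, 40))
        assert np.allclose(es.gfp(2.5 * frames), 2.5 * es.gfp(frames))
        assert np.allclose(es.gfp(-frames), es.gfp(frames))


class TestPeaks:
    def test_rectified_sinusoid_spacing(self):
        fs = 1000.0
        t = np.arange(int(fs)) / fs
        g = np.abs(np.sin(2 * np.pi * 10.0 * t))
        peaks = es.find_gfp_peaks(g, fs)
        spacing = np.diff(peaks) / fs * 1000.0
        assert np.all(np.abs(spacing - 50.0) <= 1.0)

    def test_monotone_ramp_has_no_peaks(self):
        assert es.find_gfp_peaks(np.linspace(0, 1, 100), 100.0).size == 0

    def test_plateau_keeps_earlier_sample(self):
        g = np.array([0.0, 1.0, 1.0, 0.0, 2.0, 0.0])
        peaks = es.find_gfp_peaks(g, 1000.0, min_distance_ms=1.0)
        assert 1 in peaks  # earlier index of the two equal maxima
        assert 2 not in peaks

    def test_min_distance_enforced(self):
        fs = 1000.0
        g = np.zeros(200)
        g[50] = 1.0
        g[53] = 0.9
        peaks = es.find_gfp_peaks(g, fs, min_distance_ms=10.0)
        assert list(peaks) == [50]

    def test_endpoints_never_peaks(self):
        g = np.array([5.0, 1.0, 0.5, 1.0, 5.0])
        peaks = es.find_gfp_peaks(g, 100.0)
        assert 0 not in peaks and 4 not in peaks


class TestSpatialCorrelation:
    def test_identity_polarity_orthogonal(self):
        maps = _orthogonal_maps(16, 2)
        assert es.spatial_correlation(maps[0], maps[0]) == pytest.approx(1.0)
        assert es.spatial_correlation(maps[0], -maps[0]) == pytest.approx(1.0)
        assert es.spatial_correlation(maps[0], -maps[0],
                                      polarity_invariant=False) == \
            pytest.approx(-1.0)
        assert abs(es.spatial_correlation(maps[0], maps[1])) < 1e-10

    def test_constant_map_rejected(self):
        with pytest.raises(UndefinedCorrelationError):
            es.spatial_correlation(np.ones(8), np.arange(8.0))


class TestAahc:
    def test_separable_case_exact(self):
        truth = _orthogonal_maps(16, 4)
        rng = np.random.default_rng(3)
        signs = rng.choice([-1.0, 1.0], size=40)
        scale = rng.uniform(0.5, 2.0, size=40)
        which = np.repeat(np.arange(4), 10)
        rng.shuffle(which)
        maps = signs[:, None] * scale[:, None] * truth[which]
        ts, assign = es.aahc(maps, 4, return_assignment=True)
        # partition equals ground truth (up to cluster renaming)
        for k in range(4):
            assert len(set(assign[which == k])) == 1
        assert len(set(assign)) == 4
        # centroids match templates with |r| = 1
        for c in range(4):
            k = which[np.flatnonzero(assign == c)[0]]
            assert es.spatial_correlation(ts.maps[c], truth[k]) == \
                pytest.approx(1.0, abs=1e-9)

    def test_degenerate_k_equals_n(self):
        maps = _orthogonal_maps(12, 5)
        ts = es.aahc(maps, 5)
        assert ts.K == 5
        assert ts.gev == pytest.approx(1.0, abs=1e-12)

    def test_k_too_large(self):
        maps = _orthogonal_maps(12, 3)
        with pytest.raises(InvalidArgumentError):
            es.aahc(maps, 4)

    @pytest.mark.parametrize("trial", range(8))
    def test_matches_independent_oracle(self, trial):
        """On small random peak-map sets the clustering replays the greedy
        atomize/reassign rule exactly, step for step."""
        rng = np.random.default_rng(100 + trial)
        n = int(rng.integers(5, 11))
        K = int(rng.integers(2, min(4, n - 1) + 1))
        maps = rng.standard_normal((n, 16)) * rng.uniform(0.5, 3.0, (n, 1))
        maps -= maps.mean(axis=1, keepdims=True)
        ts, assign = es.aahc(maps, K, return_assignment=True)
        assign_o, centroids_o, gev_o = aahc_oracle(maps, K)
        assert np.array_equal(assign, assign_o)
        assert ts.gev == pytest.approx(gev_o, abs=1e-12)
        for c in range(K):
            r = es.spatial_correlation(ts.maps[c], centroids_o[c])
            assert r == pytest.approx(1.0, abs=1e-9)

    def test_gev_monotone_in_k(self):
        rng = np.random.default_rng(5)
        maps = rng.standard_normal((30, 16))
        maps -= maps.mean(axis=1, keepdims=True)
        gevs = [es.aahc(maps, K).gev for K in (2, 4, 8, 16, 30)]
        assert np.all(np.diff(gevs) >= -1e-12)

    def test_sign_and_scale_invariance(self):
        rng = np.random.default_rng(6)
        maps = rng.standard_normal((20, 16))
        maps -= maps.mean(axis=1, keepdims=True)
        ts1, a1 = es.aahc(maps, 3, return_assignment=True)
        ts2, a2 = es.aahc(-2.0 * maps, 3, return_assignment=True)
        assert np.array_equal(a1, a2)
        assert ts1.gev == pytest.approx(ts2.gev, abs=1e-12)
        for c in range(3):
            assert es.spatial_correlation(ts1.maps[c], ts2.maps[c]) == \
                pytest.approx(1.0, abs=1e-9)


class TestTwoLevel:
    def test_single_subject_degenerate(self):
        rng = np.random.default_rng(7)
        maps = rng.standard_normal((40, 16))
        maps -= maps.mean(axis=1, keepdims=True)
        ind = es.aahc(maps, 4)
        grp = es.two_level_cluster([maps], 4)
        assert grp.level == "group"
        matched = {int(np.argmax([es.spatial_correlation(g, i)
                                  for i in ind.maps])) for g in grp.maps}
        assert matched == set(range(4))
        for g in grp.maps:
            best = max(es.spatial_correlation(g, i) for i in ind.maps)
            assert best == pytest.approx(1.0, abs=1e-6)


class TestLabelTemplates:
    def test_identity_and_permutation(self, montage16):
        canon = es.canonical_maps(montage16)
        same = es.label_templates(canon, canon)
        assert same.class_labels == canon.class_labels
        assert np.allclose(same.maps, canon.maps)
        perm = [2, 0, 3, 1]
        shuffled = es.TemplateSet(canon.maps[perm] * -1.0,
                                  ("T1", "T2", "T3", "T4"), "group")
        out = es.label_templates(shuffled, canon)
        assert out.class_labels == canon.class_labels
        for k in range(4):
            assert es.spatial_correlation(out.maps[k], canon.maps[k]) == \
                pytest.approx(1.0, abs=1e-9)
            # sign flipped back to positive correlation
            assert np.dot(out.maps[k], canon.maps[k]) > 0

    def test_deterministic_on_random_maps(self, montage16):
        canon = es.canonical_maps(montage16)
        rng = np.random.default_rng(9)
        maps = rng.standard_normal((4, 16))
        maps -= maps.mean(axis=1, keepdims=True)
        maps /= maps.std(axis=1, keepdims=True)
        ts = es.TemplateSet(maps, ("T1", "T2", "T3", "T4"))
        a = es.label_templates(ts, canon)
        b = es.label_templates(ts, canon)
        assert a.class_labels == b.class_labels
        assert np.array_equal(a.maps, b.maps)


class TestBackfit:
    def test_midpoint_rule(self):
        # 11 samples between peaks: first 6 go to the earlier peak
        out = _fill_between_peaks(20, np.array([3, 15]), np.array([0, 1]))
        assert np.all(out[:10] == 0)
        assert np.all(out[10:] == 1)

    def test_noise_free_peak_labels_exact(self, montage16):
        ts = es.generate_templates(4, montage16, seed=1)
        spec = es.SimSpec(n_channels=16, record_length=20.0, snr_db=np.inf)
        seq = es.generate_state_sequence(spec, "HC", seed=2)
        rec = es.synthesize_eeg(ts, seq, spec, seed=3, montage=montage16)
        lab = es.backfit(rec, ts)
        peaks = es.find_gfp_peaks(es.gfp(rec.data), spec.fs)
        assert np.all(lab.labels[peaks] == seq.labels[peaks])

    def test_epoch_without_peaks_unassigned(self, montage16):
        data = np.zeros((16, 200))
        t = np.arange(100) / 100.0
        data[:, 100:] = np.outer(es.canonical_maps(montage16).maps[0],
                                 np.abs(np.sin(2 * np.pi * 10 * t)))
        canon = es.canonical_maps(montage16)
        lab = es.backfit(data, canon, fs=100.0,
                         epoch_edges=np.array([0, 100, 200]))
        assert np.all(lab.labels[:100] == es.UNASSIGNED)
        assert np.all(lab.labels[100:] == 0)

    def test_noisy_recovery(self, noisy_subject, templates32):
        """At 10 dB SNR the backfit recovers >= 85% of all samples and
        >= 90% of GFP-peak samples."""
        spec, seq, rec = noisy_subject
        lab = es.backfit(rec, templates32)
        peaks = es.find_gfp_peaks(es.gfp(rec.data), spec.fs)
        assert np.mean(lab.labels[peaks] == seq.labels[peaks]) >= 0.90
        assert np.mean(lab.labels == seq.labels) >= 0.85

    def test_polarity_invariance(self, montage16):
        ts = es.generate_templates(4, montage16, seed=1)
        spec = es.SimSpec(n_channels=16, record_length=10.0)
        seq = es.generate_state_sequence(spec, "HC", seed=2)
        rec = es.synthesize_eeg(ts, seq, spec, seed=3, montage=montage16)
        a = es.backfit(rec, ts)
        b = es.backfit(rec.with_data(-rec.data), ts)
        assert np.array_equal(a.labels, b.labels)


class TestGev:
    def test_noise_free_ground_truth_is_one(self, montage16):
        ts = es.generate_templates(4, montage16, seed=1)
        spec = es.SimSpec(n_channels=16, record_length=20.0, snr_db=np.inf)
        seq = es.generate_state_sequence(spec, "HC", seed=2)
        rec = es.synthesize_eeg(ts, seq, spec, seed=3, montage=montage16)
        assert es.gev(rec, seq, ts) == pytest.approx(1.0, abs=1e-6)

    def test_single_template(self, montage16):
        canon = es.canonical_maps(montage16)
        one = es.TemplateSet(canon.maps[:1], ("A",))
        t = np.arange(500) / 250.0
        data = np.outer(one.maps[0], np.abs(np.sin(2 * np.pi * 10 * t)))
        seq = es.LabelSequence(np.zeros(500, dtype=int), 250.0, ("A",))
        assert es.gev(data, seq, one) == pytest.approx(1.0, abs=1e-6)

    def test_shuffled_labels_lower(self, noisy_subject, templates32):
        spec, seq, rec = noisy_subject
        true_gev = es.gev(rec, seq, templates32)
        rng = np.random.default_rng(0)
        shuffled = es.LabelSequence(rng.permutation(seq.labels), spec.fs,
                                    seq.class_labels)
        assert es.gev(rec, shuffled, templates32) < true_gev

    def test_sign_and_scale_invariance(self, noisy_subject, templates32):
        spec, seq, rec = noisy_subject
        a = es.gev(rec, seq, templates32)
        b = es.gev(rec.with_data(-3.0 * rec.data), seq, templates32)
        assert a == pytest.approx(b, abs=1e-12)
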