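import numpy as np
import pytest

from slowosc.bands import make_band_scheme
from slowosc.exceptions import ParameterError, ValidationError
from slowosc.ica import (
    GroupICA,
    GroupICAConfig,
    _abs_corr,
    infomax_unmix,
    match_templates,
    robustness_filter,
    stability_resample,
    temporal_concat_pca,
)
from slowosc.preprocess import preprocess_scan

TR = 2.6


def _whiten(X):
    Xc = X - X.mean(axis=1, keepdims=True)
    C = np.cov(Xc)
    w, V = np.linalg.eigh(C)
    return (V / np.sqrt(w)) @ V.T @ Xc


class TestTemporalConcatPCA:
    def test_duplicate_subjects_add_no_variance_directions(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(300, 60))  # voxels x time
        cfg = GroupICAConfig(n_components=4, subject_pca_dim=8)
        red1, *_ = temporal_concat_pca([X], cfg)
        red3, *_ = temporal_concat_pca([X, X, X], cfg)
        # same spatial subspace up to sign
        r = _abs_corr(red1, red3)
        assert np.allclose(np.sort(r.max(axis=1)), 1.0, atol=1e-6)

    def test_full_dimension_reconstruction_is_exact(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(80, 40))  # voxels x time, full temporal rank
        cfg = GroupICAConfig(n_components=5, subject_pca_dim=40)
        _, bases, *_ = temporal_concat_pca([X], cfg)
        U = bases[0]
        Xt = X.T - X.T.mean(axis=0, keepdims=True)  # time x voxels, demeaned
        assert np.allclose(U @ (U.T @ Xt), Xt, atol=1e-8)

    def test_planted_orthogonal_sources_span_top_group_pcs(self):
        rng = np.random.default_rng(2)
        n_vox, T = 400, 100
        S = np.linalg.qr(rng.normal(size=(n_vox, 3)))[0].T  # 3 orthonormal spatial sources
        scans = []
        for _ in range(4):
            tc = rng.normal(size=(T, 3)) * 10.0
            scans.append((tc @ S).T + 0.01 * rng.normal(size=(n_vox, T)))
        cfg = GroupICAConfig(n_components=3, subject_pca_dim=10)
        red, *_ = temporal_concat_pca(scans, cfg)
        # principal angles between recovered subspace and source subspace
        Q1 = np.linalg.qr(red.T)[0]
        Q2 = np.linalg.qr(S.T)[0]
        angles = np.degrees(np.arccos(np.clip(np.linalg.svd(Q1.T @ Q2)[1], -1, 1)))
        assert angles.max() < 5.0

    def test_rank_deficient_subject_named(self):
        X = np.zeros((50, 30))
        X[:, :] = np.outer(np.arange(50), np.ones(30))  # rank 1
        cfg = GroupICAConfig(n_components=2, subject_pca_dim=5)
        with pytest.raises(ValidationError, match="rank"):
            temporal_concat_pca([X], cfg)


class TestInfomax:
    def test_recovers_laplacian_sources_through_known_mixing(self):
        rng = np.random.default_rng(3)
        S = rng.laplace(size=(2, 4000))
        X = np.array([[1.0, 0.6], [0.4, 1.0]]) @ S
        W, maps = infomax_unmix(_whiten(X), GroupICAConfig(n_components=2, seed=0))
        r = _abs_corr(maps, S)
        assert np.sort(r.max(axis=1)).min() > 0.99

    def test_already_unmixed_input_gives_signed_permutation(self):
        rng = np.random.default_rng(4)
        S = rng.laplace(size=(3, 4000))
        W, maps = infomax_unmix(_whiten(S), GroupICAConfig(n_components=3, seed=1))
        r = _abs_corr(maps, S)
        # each output matches exactly one input source
        assert np.all(r.max(axis=1) > 0.98)
        assert np.all((r > 0.9).sum(axis=1) == 1)

    def test_gaussian_sources_terminate(self):
        rng = np.random.default_rng(5)
        S = rng.normal(size=(2, 2000))
        W, maps = infomax_unmix(_whiten(S), GroupICAConfig(n_components=2, seed=0, max_iter=50))
        assert np.all(np.isfinite(maps))

    def test_maps_unit_variance_positive_skew(self):
        rng = np.random.default_rng(6)
        S = rng.laplace(size=(2, 3000)) ** 2  # skewed sources
        W, maps = infomax_unmix(_whiten(S), GroupICAConfig(n_components=2, seed=0))
        assert np.allclose(maps.std(axis=1), 1.0, atol=1e-9)
        skew = ((maps - maps.mean(axis=1, keepdims=True)) ** 3).mean(axis=1)
        assert np.all(skew >= 0)


class TestBackReconstruction:
    def test_identical_subjects_share_group_timecourse(self):
        rng = np.random.default_rng(7)
        S = rng.laplace(size=(2, 500))
        tc = rng.normal(size=(80, 2)) * 5.0
        X = (tc @ S).T + 0.01 * rng.normal(size=(500, 80))
        scans = [X, X.copy(), X.copy()]
        cfg = GroupICAConfig(n_components=2, subject_pca_dim=6, seed=0)
        fit = GroupICA(scans, cfg).fit()
        for k in range(2):
            r01 = np.corrcoef(fit.subject_timecourses[0, :, k], fit.subject_timecourses[1, :, k])[0, 1]
            r02 = np.corrcoef(fit.subject_timecourses[0, :, k], fit.subject_timecourses[2, :, k])[0, 1]
            assert abs(r01) > 0.999 and abs(r02) > 0.999

    def test_planted_cohort_timecourse_recovery(self, small_cohort, small_ica_config):
        scans, truth = small_cohort
        kept = [preprocess_scan(s) for s in scans]
        fit = GroupICA(kept, small_ica_config).fit()
        assign = fit.match_templates(truth.maps)
        assert len(assign.labels) == 5
        for ci, lab in assign.labels.items():
            assert assign.correlations[ci] >= 0.8
            rs = []
            for si, s in enumerate(kept):
                true_tc = truth.timecourses[s.subject_id][lab][10:]
                rs.append(abs(np.corrcoef(fit.subject_timecourses[si, :, ci], true_tc)[0, 1]))
            assert np.mean(rs) > 0.9

    def test_zero_signal_subject_has_small_amplitude(self):
        rng = np.random.default_rng(8)
        S = rng.laplace(size=(2, 600))
        scans = []
        for _ in range(3):
            tc = rng.normal(size=(90, 2)) * 8.0
            scans.append((tc @ S).T + 0.05 * rng.normal(size=(600, 90)))
        scans.append(0.05 * rng.normal(size=(600, 90)))  # pure-noise subject
        cfg = GroupICAConfig(n_components=2, subject_pca_dim=6, seed=0)
        fit = GroupICA(scans, cfg).fit()
        signal_amp = np.abs(fit.subject_timecourses[:3]).mean()
        null_amp = np.abs(fit.subject_timecourses[3]).mean()
        assert null_amp < 0.1 * signal_amp


class TestModelInvariances:
    def test_scale_and_sign_invariance_of_decisions(self, small_cohort, small_ica_config):
        scans, truth = small_cohort
        kept = [preprocess_scan(s) for s in scans]
        scheme = make_band_scheme(0.5 / TR)
        fit1 = GroupICA(kept, small_ica_config).fit()
        a1 = fit1.match_templates(truth.maps)
        r1, _ = fit1.robustness(scheme, TR)
        scaled = [
            type(s)(subject_id=s.subject_id, group=s.group, data=-3.0 * s.data,
                    tr_seconds=s.tr_seconds, motion=s.motion)
            for s in kept
        ]
        fit2 = GroupICA(scaled, small_ica_config).fit()
        a2 = fit2.match_templates(truth.maps)
        r2, _ = fit2.robustness(scheme, TR)
        assert sorted(a1.labels.values()) == sorted(a2.labels.values())
        by_label_1 = {lab: r1[ci] for ci, lab in a1.labels.items()}
        by_label_2 = {lab: r2[ci] for ci, lab in a2.labels.items()}
        assert by_label_1 == by_label_2

    def test_variance_explained_monotone_in_components(self, small_cohort):
        scans, _ = small_cohort
        kept = [preprocess_scan(s) for s in scans[:6]]
        ve = []
        for k in (2, 4, 6):
            cfg = GroupICAConfig(n_components=k, subject_pca_dim=9, seed=0, max_iter=5)
            ve.append(GroupICA(kept, cfg).fit().variance_explained)
        assert ve[0] <= ve[1] <= ve[2] <= 1.0
        assert ve[0] > 0.0

    def test_subject_permutation_leaves_group_maps_unchanged(self, small_cohort, small_ica_config):
        scans, _ = small_cohort
        kept = [preprocess_scan(s) for s in scans]
        fit1 = GroupICA(kept, small_ica_config).fit()
        fit2 = GroupICA(kept[::-1], small_ica_config).fit()
        r = _abs_corr(fit1.group_maps, fit2.group_maps)
        assert np.all(np.sort(r.max(axis=1)) > 0.999)


class TestStability:
    def test_planted_sources_more_stable_than_noise(self, small_cohort, small_ica_config):
        scans, truth = small_cohort
        kept = [preprocess_scan(s) for s in scans]
        fit = GroupICA(kept, small_ica_config).fit(stability=True)
        assign = fit.match_templates(truth.maps)
        planted = fit.stability_index[sorted(assign.labels)]
        assert np.all(planted > 0.9)
        rng = np.random.default_rng(5)
        noise_scans = [rng.normal(size=(kept[0].n_voxels, 230)) for _ in range(12)]
        noise_stab = stability_resample(noise_scans, small_ica_config)
        assert noise_stab.max() < planted.min()

    def test_single_run_rejected(self, small_cohort):
        scans, _ = small_cohort
        cfg = GroupICAConfig(n_components=4, subject_pca_dim=6, n_stability_runs=1)
        with pytest.raises(ParameterError):
            stability_resample([s.data for s in scans[:4]], cfg)


class TestTemplateMatching:
    def test_orthogonal_templates_unassigned(self):
        rng = np.random.default_rng(9)
        maps = rng.normal(size=(3, 500))
        # templates orthogonal to every map
        Q, _ = np.linalg.qr(np.vstack([maps, rng.normal(size=(3, 500))]).T)
        templates = {"a": Q[:, 3], "b": Q[:, 4]}
        assign, _ = match_templates(maps, templates, threshold=0.3)
        assert assign.labels == {}
        assert set(assign.unassigned_templates) == {"a", "b"}

    def test_duplicate_templates_take_distinct_components(self):
        rng = np.random.default_rng(10)
        base = rng.normal(size=500)
        maps = np.vstack([base, 0.9 * base + 0.4 * rng.normal(size=500), rng.normal(size=500)])
        templates = {"t1": base, "t2": base.copy()}
        assign, _ = match_templates(maps, templates, threshold=0.3)
        assert len(assign.labels) == 2
        assert len(set(assign.labels.keys())) == 2  # two different components

    def test_assigned_maps_flipped_to_positive_correlation(self):
        rng = np.random.default_rng(11)
        tmpl = rng.normal(size=400)
        maps = np.vstack([-tmpl])
        assign, flipped = match_templates(maps, {"t": tmpl})
        assert np.corrcoef(flipped[0], tmpl)[0, 1] > 0.99


class TestRobustnessFilter:
    def test_narrowband_component_robust_white_noise_not(self, scheme):
        rng = np.random.default_rng(12)
        T = 220
        t = np.arange(T) * TR
        narrow = np.sin(2 * np.pi * (11 / (T * TR)) * t)
        tcs = np.zeros((5, T, 2))
        for s in range(5):
            tcs[s, :, 0] = narrow + 1e-6 * rng.normal(size=T)
            tcs[s, :, 1] = rng.normal(size=T)
        robust, ratios = robustness_filter(tcs, TR, scheme)
        assert robust[0] and not robust[1]
        assert ratios[0] > 50 and ratios[1] < 5

    def test_zero_hf_power_is_trivially_robust(self, scheme):
        T = 220
        t = np.arange(T) * TR
        tcs = np.sin(2 * np.pi * (11 / (T * TR)) * t)[None, :, None]
        robust, ratios = robustness_filter(np.repeat(tcs, 2, axis=0), TR, scheme)
        assert robust[0]

    def test_threshold_is_strict(self, scheme):
        rng = np.random.default_rng(13)
        tcs = rng.normal(size=(4, 220, 1))
        _, ratios = robustness_filter(tcs, TR, scheme)
        robust_at_own_mean, _ = robustness_filter(tcs, TR, scheme, threshold=float(ratios[0]))
        assert not robust_at_own_mean[0]  # ratio == threshold -> not robust
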