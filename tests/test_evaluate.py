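"""Evaluation battery: maps, ROC/AUC, localisation, eigenvariates, spectra."""
import numpy as np
import pytest
from scipy import sparse

from megpeb.evaluate import (GroundTruthLabels, SourceMap, amplitude_spectrum, build_report,
                             extract_voi_timecourse, localization_errors,
                             normalize_source_map, rmse, roc_auc, truth_labels,
                             virtual_sensor_timecourse)
from megpeb.exceptions import DataError
from megpeb.geometry import CorticalMesh


def _line_mesh(n, spacing=5.0):
    verts = np.zeros((n, 3))
    verts[:, 0] = np.arange(n) * spacing
    a = sparse.diags([np.ones(n - 1), np.ones(n - 1)], [-1, 1]).tocsr()
    return CorticalMesh(verts, np.zeros((0, 3), dtype=int),
                        np.tile([0.0, 0.0, 1.0], (n, 1)), a)


class TestNormalizeSourceMap:
    def test_single_active_vertex(self):
        post = np.zeros((5, 10))
        post[2, 4] = -3.0
        m = normalize_source_map(post)
        assert m.values.tolist() == [0, 0, 1.0, 0, 0]

    def test_scale_invariance(self, rng):
        post = rng.normal(size=(8, 20))
        assert np.allclose(normalize_source_map(post).values,
                           normalize_source_map(17.3 * post).values)

    def test_argmax_matches_window_power(self, rng):
        post = rng.normal(size=(30, 40))
        window = slice(10, 30)
        m = normalize_source_map(post, window)
        brute = np.argmax(np.abs(post[:, window]).max(axis=1))
        assert np.argmax(m.values) == brute

    def test_null_map_flagged(self):
        m = normalize_source_map(np.zeros((4, 6)))
        assert m.is_null and not m.values.any()


class TestRocAuc:
    def test_perfect_map(self):
        labels = GroundTruthLabels(np.array([1, 1, 0, 0, 0], dtype=bool), 10.0)
        m = SourceMap(np.array([1.0, 0.9, 0.05, 0.0, 0.1]))
        assert roc_auc(m, labels).auc == pytest.approx(1.0)

    def test_matches_rank_statistic_oracle(self, rng):
        """Dense-threshold limit: AUC equals the Mann-Whitney statistic
        (scikit-learn's roc_auc_score) within 1/n_thresholds."""
        sklearn_metrics = pytest.importorskip("sklearn.metrics")
        for _ in range(5):
            scores = rng.random(400)
            scores /= scores.max()
            y = rng.random(400) < 0.1
            if y.all() or not y.any():
                continue
            ours = roc_auc(SourceMap(scores), GroundTruthLabels(y, 10.0), 101).auc
            ref = sklearn_metrics.roc_auc_score(y, scores)
            assert abs(ours - ref) <= 0.01

    def test_random_scores_near_half(self, rng):
        scores = rng.random(5000)
        scores /= scores.max()
        y = rng.random(5000) < 0.3
        auc = roc_auc(SourceMap(scores), GroundTruthLabels(y, 10.0)).auc
        assert abs(auc - 0.5) < 0.03

    def test_antisymmetry_under_score_inversion(self, rng):
        scores = rng.random(200)
        scores[scores.argmin()] = 0.0
        scores /= scores.max()
        y = rng.random(200) < 0.2
        y[:2] = [True, False]
        flipped = 1.0 - scores
        a1 = roc_auc(SourceMap(scores), GroundTruthLabels(y, 10.0), 1001).auc
        a2 = roc_auc(SourceMap(flipped / flipped.max()), GroundTruthLabels(y, 10.0), 1001).auc
        assert a1 + a2 == pytest.approx(1.0, abs=0.01)

    def test_endpoint_conventions(self, rng):
        scores = rng.random(50)
        scores /= scores.max()
        y = rng.random(50) < 0.4
        y[:2] = [True, False]
        roc = roc_auc(SourceMap(scores), GroundTruthLabels(y, 10.0))
        assert roc.sensitivity[0] == 1.0  # beta = 0 declares everything active
        assert np.all(np.diff(roc.sensitivity) <= 1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(DataError):
            roc_auc(SourceMap(np.array([1.0, 0.5])),
                    GroundTruthLabels(np.array([True, True]), 10.0))


class TestLocalizationErrors:
    def test_exact_hit_gives_zero_errors(self):
        mesh = _line_mesh(9)
        values = np.zeros(9)
        values[3] = 1.0
        rep = localization_errors(SourceMap(values), [mesh.vertices[3]], mesh)
        assert rep.peak_error_mm[0] == 0.0 and rep.cmass_error_mm[0] == 0.0

    def test_symmetric_cluster_centroid_beats_peak(self):
        # peak at vertex 4, symmetric suprathreshold cluster 3-4-5; truth
        # midway between vertices 4 and 5: centroid (weighted toward 4..5
        # midpoint) must beat the peak-vertex distance
        mesh = _line_mesh(9)
        values = np.array([0, 0, 0, 0.8, 1.0, 0.8, 0, 0, 0.0])
        truth = mesh.vertices[4] + np.array([2.5, 0, 0])
        rep = localization_errors(SourceMap(values), [truth], mesh)
        assert rep.cmass_error_mm[0] == pytest.approx(2.5)  # symmetric -> centroid at peak
        weights = values[3:6]
        centroid = weights @ mesh.vertices[3:6] / weights.sum()
        assert rep.cmass_error_mm[0] == pytest.approx(np.linalg.norm(centroid - truth))

    def test_centroid_matches_direct_sum(self, rng):
        mesh = _line_mesh(15)
        values = np.clip(rng.random(15), 0.05, None)
        values[7] = 1.0
        rep = localization_errors(SourceMap(values / values.max()), [mesh.vertices[7]],
                                  mesh, cluster_threshold=0.3)
        members = values >= 0.3 * values.max()
        # connected run containing vertex 7
        lo = hi = 7
        while lo > 0 and members[lo - 1]:
            lo -= 1
        while hi < 14 and members[hi + 1]:
            hi += 1
        w = values[lo:hi + 1]
        centroid = w @ mesh.vertices[lo:hi + 1] / w.sum()
        assert rep.cmass_error_mm[0] == pytest.approx(
            np.linalg.norm(centroid - mesh.vertices[7]))

    def test_two_source_partition(self):
        mesh = _line_mesh(20)
        values = np.zeros(20)
        values[2] = 1.0
        values[15] = 0.4  # weaker second source still scored in its region
        rep = localization_errors(SourceMap(values),
                                  [mesh.vertices[2], mesh.vertices[16]], mesh)
        assert rep.peak_error_mm[0] == 0.0
        assert rep.peak_error_mm[1] == pytest.approx(5.0)

    def test_null_map_rejected(self):
        mesh = _line_mesh(5)
        with pytest.raises(DataError):
            localization_errors(SourceMap(np.zeros(5), is_null=True),
                                [mesh.vertices[0]], mesh)


class TestEigenvariate:
    def test_rank_one_stack(self):
        mesh = _line_mesh(4, spacing=2.0)
        c = np.sin(np.linspace(0, 7, 50))
        stack = np.outer([1.0, 2.0, 0.5, 1.5], c)
        est = extract_voi_timecourse(stack, mesh.vertices[1], mesh, radius_mm=10.0)
        corr = np.corrcoef(est.samples, c)[0, 1]
        assert corr == pytest.approx(1.0, abs=1e-12)

    def test_matches_eigendecomposition_oracle(self, rng):
        mesh = _line_mesh(6, spacing=2.0)
        stack = rng.normal(size=(6, 40))
        est = extract_voi_timecourse(stack, mesh.vertices[2], mesh, radius_mm=100.0)
        # independent route: dominant eigenvector of the temporal Gram matrix
        gram = stack.T @ stack
        vals, vecs = np.linalg.eigh(gram)
        expected = np.sqrt(vals[-1]) * vecs[:, -1]
        if np.dot(expected, stack.mean(axis=0)) < 0:
            expected = -expected
        assert np.allclose(est.samples, expected, atol=1e-8 * np.abs(expected).max())

    def test_robust_to_orthogonal_noise(self, rng):
        mesh = _line_mesh(8, spacing=2.0)
        c = np.sin(np.linspace(0, 9, 120))
        noise = rng.normal(size=(4, 120)) * 0.7
        noise -= np.outer(noise @ c, c) / (c @ c)  # orthogonalise to c
        stack = np.vstack([np.outer(np.ones(4), c), noise])
        est = extract_voi_timecourse(stack, mesh.vertices[3], mesh, radius_mm=100.0)
        corr_eig = abs(np.corrcoef(est.samples, c)[0, 1])
        corr_mean = abs(np.corrcoef(stack.mean(axis=0), c)[0, 1])
        assert corr_eig > corr_mean

    def test_empty_voi_rejected(self):
        mesh = _line_mesh(3)
        with pytest.raises(DataError):
            extract_voi_timecourse(np.ones((3, 5)), [500.0, 0, 0], mesh, radius_mm=1.0)


class TestRmse:
    def test_closed_forms_and_brute_force(self, rng):
        assert rmse(np.ones(5), np.ones(5)) == 0.0
        assert rmse(np.full(8, 0.3), np.zeros(8)) == pytest.approx(0.3)
        a, b = rng.normal(size=(2, 100))
        assert rmse(a, b) == pytest.approx(np.sqrt(np.mean((a - b) ** 2)))

    def test_normalization_semantics(self):
        a = np.array([0.0, 2.0, -4.0])
        b = np.array([0.0, 0.5, -1.0])
        assert rmse(a, b, normalize=True) == pytest.approx(0.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(DataError):
            rmse(np.ones(3), np.ones(4))


class TestAmplitudeSpectrum:
    def test_unit_tone_peaks_at_one(self):
        fs = 600.0
        t = np.arange(180) / fs  # 3 whole periods of 10 Hz
        freqs, amp = amplitude_spectrum(np.sin(2 * np.pi * 10 * t), fs)
        k = np.argmax(amp)
        assert freqs[k] == pytest.approx(10.0)
        assert amp[k] == pytest.approx(1.0, abs=1e-12)

    def test_zero_signal(self):
        _, amp = amplitude_spectrum(np.zeros(64), 100.0)
        assert not amp.any()

    @pytest.mark.parametrize("n", [64, 65])
    def test_parseval_consistency(self, rng, n):
        x = rng.normal(size=n)
        _, amp = amplitude_spectrum(x, 1.0)
        power = amp[0] ** 2 + 0.5 * np.sum(amp[1:] ** 2)
        if n % 2 == 0:
            power += 0.5 * amp[-1] ** 2  # Nyquist bin is not doubled
        assert power == pytest.approx(np.mean(x**2), rel=1e-10)


class TestVirtualSensor:
    def test_unit_gain_and_linearity_and_recovery(self, small_geometry, small_leadfield):
        mesh, _, _ = small_geometry
        from megpeb.geometry import nearest_vertex

        target = (-54.0, -13.0, 5.0)
        v = nearest_vertex(target, mesh)
        c = np.sin(np.linspace(0, 20, 100))
        data = np.einsum("m,t->mt", small_leadfield.matrix[:, v], c)[None]
        out = virtual_sensor_timecourse(data, small_leadfield, target, mesh)
        assert np.corrcoef(out[0], c)[0, 1] > 0.99
        out2 = virtual_sensor_timecourse(2.0 * data, small_leadfield, target, mesh)
        assert np.allclose(out2, 2.0 * out, rtol=1e-8)


class TestBuildReport:
    def test_full_grid_and_cell_equality(self):
        metrics = {}
        for v in ("none", "all", "valid", "invalid"):
            for nz in ("no_noise", "10dB", "-10dB"):
                metrics[(v, nz)] = {"auc": hash((v, nz)) % 100 / 100,
                                    "peak_x1": 1.0, "cmass_x1": 2.0,
                                    "peak_x2": 3.0, "cmass_x2": 4.0,
                                    "rmse_time_avg_x1": 0.1, "rmse_time_trial_x1": 0.2,
                                    "rmse_time_avg_x2": 0.3, "rmse_time_trial_x2": 0.4,
                                    "rmse_freq_avg_x1": 0.5, "rmse_freq_trial_x1": 0.6,
                                    "rmse_freq_avg_x2": 0.7, "rmse_freq_trial_x2": 0.8}
        tables = build_report(metrics)
        t1 = tables["localization"]
        assert t1.shape == (15, 4)  # 3 noise x (2 sources x 2 metrics + AUC)
        auc_cells = t1.xs("AUC", level="metric")
        for v, title in (("none", "No priors"), ("valid", "Valid Only")):
            assert auc_cells.loc[("no_noise", ""), title] == metrics[(v, "no_noise")]["auc"]
        assert tables["rmse_time"].shape == (12, 4)

    def test_missing_cells_become_na(self):
        metrics = {("none", "no_noise"): {"auc": 0.8}}
        t1 = build_report(metrics)["localization"]
        assert t1.isna().sum().sum() > 0
        assert t1.xs("AUC", level="metric").iloc[0, 0] == 0.8


class TestTruthLabels:
    def test_radius_controls_positives(self, small_geometry):
        mesh, _, _ = small_geometry
        labels = truth_labels(mesh, [(-38.0, 43.0, 5.0)], radius_mm=10.0)
        d = np.linalg.norm(mesh.vertices - np.array([-38.0, 43.0, 5.0]), axis=1)
        assert np.array_equal(labels.labels, d <= 10.0)


class TestRmseProperties:
    def test_matches_brute_force_over_random_vectors(self):
        from hypothesis import given, settings, strategies as st

        @settings(deadline=None, max_examples=50, derandomize=True)
        @given(st.lists(st.floats(-1e3, 1e3), min_size=2, max_size=40),
               st.integers(0, 2**31 - 1))
        def check(a, seed):
            a = np.asarray(a)
            b = np.random.default_rng(seed).normal(size=len(a))
            assert rmse(a, b) == pytest.approx(np.sqrt(np.mean((a - b) ** 2)))

        check()
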