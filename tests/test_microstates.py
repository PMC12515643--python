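"""Microstate machinery: GFP, clustering, backfitting, parameters, GEV."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import motorstates as ms
from motorstates.io import EpochSet
from motorstates.microstates import UNLABELED, GfpSeries, TopographyModel


def epochs_from(data, fs=500.0):
    """Wrap one channels × samples array as a single-epoch EpochSet."""
    data = np.asarray(data, dtype=float)
    return EpochSet(data[None], fs=fs, epoch_length_s=data.shape[1] / fs,
                    channel_labels=[f"c{i}" for i in range(data.shape[0])])


class TestGfp:
    @pytest.mark.parametrize("column, expected", [
        ([1.0, -1.0], 1.0),
        ([5.0, 5.0, 5.0], 0.0),
        ([3.0, 1.0, -1.0, -3.0], np.sqrt(5)),
    ])
    def test_hand_values(self, column, expected):
        gfp = ms.compute_gfp(np.array(column)[:, None])
        assert gfp.values[0] == pytest.approx(expected)

    def test_single_channel_raises(self):
        with pytest.raises(ValueError):
            ms.compute_gfp(np.ones((1, 10)))

    def test_nonnegative(self):
        x = np.random.default_rng(0).standard_normal((8, 200))
        assert (ms.compute_gfp(x).values >= 0).all()


class TestGfpPeaks:
    def test_monotone_series_has_no_peaks(self):
        assert ms.find_gfp_peaks(GfpSeries(np.arange(10.0), 1.0)).size == 0

    def test_single_peak(self):
        np.testing.assert_array_equal(
            ms.find_gfp_peaks(GfpSeries(np.array([0.0, 1.0, 0.0]), 1.0)), [1])

    def test_plateau_midpoint(self):
        peaks = ms.find_gfp_peaks(GfpSeries(np.array([0, 1, 1, 1, 0.0]), 1.0))
        np.testing.assert_array_equal(peaks, [2])

    def test_matches_brute_force_scan(self):
        values = np.random.default_rng(1).random(200)
        peaks = ms.find_gfp_peaks(GfpSeries(values, 1.0))
        brute = [i for i in range(1, 199)
                 if values[i] > values[i - 1] and values[i] > values[i + 1]]
        np.testing.assert_array_equal(peaks, brute)

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            ms.find_gfp_peaks(GfpSeries(np.array([0.0, 1.0]), 1.0))


class TestModifiedKmeans:
    def test_recovers_orthogonal_planted_templates(self):
        rng = np.random.default_rng(2)
        t1 = np.array([1, -1, 1, -1, 0, 0, 0, 0.0])
        t2 = np.array([0, 0, 0, 0, 1, -1, 1, -1.0])
        templates = TopographyModel(np.vstack([t1, t2]))
        signs = rng.choice([-1, 1], size=200)
        which = rng.integers(2, size=200)
        maps = templates.maps[which] * signs[:, None] * rng.uniform(0.5, 2, (200, 1))
        model = ms.modified_kmeans(maps, 2, n_restarts=5, seed=3)
        corr = np.abs(ms.spatial_correlation(model.maps, templates.maps))
        assert corr.max(axis=0).min() >= 0.999

    def test_polarity_invariance_k1(self):
        m = TopographyModel(np.array([[1.0, 0, -1, 0]])).maps[0]
        maps = np.vstack([m] * 10 + [-m] * 10)
        model = ms.modified_kmeans(maps, 1, n_restarts=3, seed=0)
        assert abs(float(model.maps[0] @ m)) == pytest.approx(1.0)

    def test_determinism(self):
        maps = np.random.default_rng(4).standard_normal((50, 8))
        a = ms.modified_kmeans(maps, 3, n_restarts=5, seed=9)
        b = ms.modified_kmeans(maps, 3, n_restarts=5, seed=9)
        np.testing.assert_array_equal(a.maps, b.maps)

    def test_fewer_maps_than_k_raises(self):
        with pytest.raises(ValueError):
            ms.modified_kmeans(np.ones((3, 8)), 5)

    def test_output_maps_normalised(self):
        maps = np.random.default_rng(5).standard_normal((60, 8))
        model = ms.modified_kmeans(maps, 4, n_restarts=3, seed=1)
        assert np.allclose(model.maps.mean(axis=1), 0, atol=1e-10)
        assert np.allclose(np.linalg.norm(model.maps, axis=1), 1, atol=1e-10)


class TestAggregateGroupModel:
    def test_single_subject_fixed_point(self, templates16):
        group = ms.aggregate_group_model([templates16], 5, n_restarts=10, seed=0)
        corr = np.abs(ms.spatial_correlation(group.maps, templates16.maps))
        assert corr.max(axis=0).min() >= 0.999

    def test_identical_subjects(self, templates16):
        group = ms.aggregate_group_model([templates16] * 4, 5, n_restarts=10, seed=0)
        corr = np.abs(ms.spatial_correlation(group.maps, templates16.maps))
        assert corr.max(axis=0).min() >= 0.999

    def test_disjoint_families_all_recovered(self):
        fam1 = ms.make_templates(16, 2, seed=1)
        fam2 = ms.make_templates(16, 2, seed=20)
        group = ms.aggregate_group_model([fam1, fam1, fam2, fam2], 4,
                                         n_restarts=20, seed=2)
        pooled = np.vstack([fam1.maps, fam2.maps])
        corr = np.abs(ms.spatial_correlation(group.maps, pooled))
        assert corr.max(axis=0).min() >= 0.99

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            ms.aggregate_group_model([], 2)


class TestBackfit:
    def test_templates_label_themselves(self, templates16):
        eps = epochs_from(templates16.maps.T)
        lab = ms.backfit(eps, templates16)
        np.testing.assert_array_equal(lab.labels[0], np.arange(5))
        np.testing.assert_allclose(lab.fit_corr[0], 1.0, atol=1e-12)

    def test_sign_flip_keeps_label(self, templates16):
        eps = epochs_from(-templates16.maps.T)
        lab = ms.backfit(eps, templates16)
        np.testing.assert_array_equal(lab.labels[0], np.arange(5))

    def test_matches_exhaustive_argmax_oracle(self, templates16):
        data = np.random.default_rng(6).standard_normal((16, 1000))
        lab = ms.backfit(epochs_from(data), templates16)
        for t in range(1000):
            v = data[:, t] - data[:, t].mean()
            v = v / np.linalg.norm(v)
            corrs = np.abs(templates16.maps @ v)
            assert lab.labels[0, t] == np.argmax(corrs)
            assert lab.fit_corr[0, t] == pytest.approx(corrs.max())

    def test_channel_mismatch_raises(self, templates16):
        with pytest.raises(ValueError):
            ms.backfit(epochs_from(np.zeros((8, 10))), templates16)

    def test_zero_variance_sample_unlabeled(self, templates16):
        data = np.random.default_rng(7).standard_normal((16, 10))
        data[:, 3] = 2.5
        lab = ms.backfit(epochs_from(data), templates16)
        assert lab.labels[0, 3] == UNLABELED
        assert lab.fit_corr[0, 3] == 0.0


class TestLabelClasses:
    def test_identity_assignment(self, templates16):
        refs = ms.builtin_reference_maps()
        out = ms.label_classes(refs, refs)
        assert out.class_labels == list("ABCDE")
        np.testing.assert_allclose(
            np.abs(np.sum(out.maps * refs.maps, axis=1)), 1.0, atol=1e-9)

    def test_shuffled_references_recovered(self):
        refs = ms.builtin_reference_maps()
        perm = [3, 0, 4, 1, 2]
        shuffled = TopographyModel(refs.maps[perm],
                                   class_labels=[refs.class_labels[i] for i in perm],
                                   channel_labels=refs.channel_labels)
        out = ms.label_classes(shuffled, refs)
        assert out.class_labels == list("ABCDE")

    def test_sign_flips_do_not_change_assignment(self):
        refs = ms.builtin_reference_maps()
        flipped = TopographyModel(refs.maps * np.array([[-1], [1], [-1], [1], [-1]]),
                                  channel_labels=refs.channel_labels)
        out = ms.label_classes(flipped, refs)
        assert out.class_labels == list("ABCDE")

    def test_montage_mismatch_raises(self, templates16):
        small = TopographyModel(np.random.default_rng(0).standard_normal((2, 8)))
        with pytest.raises(ValueError):
            ms.label_classes(small, templates16)


def rle_oracle(rows, fs, class_labels):
    """Independent run-length-encoding computation of the three parameters."""
    K = len(class_labels)
    runs = {k: [] for k in range(K)}
    n_total = 0
    for row in rows:
        n_total += len(row)
        start = 0
        for i in range(1, len(row) + 1):
            if i == len(row) or row[i] != row[start]:
                if row[start] != UNLABELED:
                    runs[row[start]].append(i - start)
                start = i
    total_s = n_total / fs
    out = {}
    for k in range(K):
        r = runs[k]
        out[class_labels[k]] = (
            np.mean(r) * 1000 / fs if r else np.nan,       # duration ms
            sum(r) / n_total * 100,                         # coverage %
            len(r) / total_s,                               # occurrence 1/s
        )
    return out


class TestMicrostateParameters:
    def test_hand_counted_example(self):
        lab = ms.LabelSequence([[0] * 5 + [1] * 5], np.ones((1, 10)), fs=500,
                               class_labels=["A", "B"])
        par = ms.microstate_parameters(lab)
        assert par.mean_duration_ms[0] == pytest.approx(10.0)
        assert par.coverage_pct[0] == pytest.approx(50.0)
        assert par.occurrence_per_s[0] == pytest.approx(50.0)

    def test_single_class_whole_epoch(self):
        lab = ms.LabelSequence([[0] * 1000], np.ones((1, 1000)), fs=500,
                               class_labels=["A"])
        par = ms.microstate_parameters(lab)
        assert par.coverage_pct[0] == pytest.approx(100.0)
        assert par.occurrence_per_s[0] == pytest.approx(0.5)
        assert par.mean_duration_ms[0] == pytest.approx(2000.0)

    def test_matches_rle_oracle(self):
        rng = np.random.default_rng(8)
        rows = rng.integers(0, 3, size=(4, 250))
        lab = ms.LabelSequence(rows, np.ones_like(rows, dtype=float), fs=250,
                               class_labels=["A", "B", "C"])
        par = ms.microstate_parameters(lab)
        oracle = rle_oracle(rows, 250, ["A", "B", "C"])
        for i, c in enumerate(["A", "B", "C"]):
            assert par.mean_duration_ms[i] == pytest.approx(oracle[c][0])
            assert par.coverage_pct[i] == pytest.approx(oracle[c][1])
            assert par.occurrence_per_s[i] == pytest.approx(oracle[c][2])

    def test_absent_class_reported_missing(self):
        lab = ms.LabelSequence([[0] * 10], np.ones((1, 10)), fs=100,
                               class_labels=["A", "B"])
        par = ms.microstate_parameters(lab)
        assert np.isnan(par.mean_duration_ms[1])
        assert par.coverage_pct[1] == 0.0 and par.occurrence_per_s[1] == 0.0

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.integers(0, 3), min_size=4, max_size=200),
           st.sampled_from([100.0, 250.0, 500.0]))
    def test_coverage_identity_property(self, row, fs):
        lab = ms.LabelSequence([row], np.ones((1, len(row))), fs=fs,
                               class_labels=list("ABCD"))
        par = ms.microstate_parameters(lab)
        assert par.coverage_pct.sum() == pytest.approx(100.0, abs=1e-9)
        for k in range(4):
            if not np.isnan(par.mean_duration_ms[k]):
                assert par.coverage_pct[k] == pytest.approx(
                    par.occurrence_per_s[k] * par.mean_duration_ms[k] / 10, abs=1e-9)

    def test_boundary_run_exclusion_flag(self):
        lab = ms.LabelSequence([[0, 0, 1, 1, 1, 0]], np.ones((1, 6)), fs=100,
                               class_labels=["A", "B"])
        par = ms.microstate_parameters(lab, include_boundary_runs=False)
        assert np.isnan(par.mean_duration_ms[0])          # only boundary runs of A
        assert par.mean_duration_ms[1] == pytest.approx(30.0)
        assert par.occurrence_per_s[0] == pytest.approx(2 / 0.06)  # still counted


class TestSmoothing:
    def test_short_runs_absorbed(self):
        row = [0] * 20 + [1] * 2 + [0] * 20
        lab = ms.LabelSequence([row], np.ones((1, 42)), fs=1000,
                               class_labels=["A", "B"])
        out = ms.smooth_labels(lab, min_duration_ms=5)
        assert (out.labels[0] == 0).all()

    def test_noop_below_resolution(self):
        row = [0, 1, 0, 1]
        lab = ms.LabelSequence([row], np.ones((1, 4)), fs=1000, class_labels=["A", "B"])
        out = ms.smooth_labels(lab, min_duration_ms=0)
        np.testing.assert_array_equal(out.labels, lab.labels)


class TestGlobalExplainedVariance:
    def test_perfect_fit_is_one(self, templates16):
        eps = epochs_from(templates16.maps.T * np.array([1, 2, 3, 4, 5.0]))
        lab = ms.backfit(eps, templates16)
        assert ms.global_explained_variance(eps, templates16, lab) == pytest.approx(1.0)

    def test_backfit_beats_random_labels(self, templates16):
        data = np.random.default_rng(9).standard_normal((16, 400))
        eps = epochs_from(data)
        lab = ms.backfit(eps, templates16)
        gev = ms.global_explained_variance(eps, templates16, lab)
        rnd = ms.LabelSequence(np.random.default_rng(10).integers(0, 5, (1, 400)),
                               lab.fit_corr, fs=eps.fs,
                               class_labels=templates16.class_labels)
        gev_rnd = ms.global_explained_variance(eps, templates16, rnd)
        assert gev_rnd <= gev + 1e-12

    def test_orthogonal_model_gives_zero(self):
        model = TopographyModel(np.array([[1, -1, 0, 0.0]]))
        data = np.array([[0, 0], [0, 0], [1, 2], [-1, -2.0]])
        eps = epochs_from(data)
        lab = ms.LabelSequence([[0, 0]], np.zeros((1, 2)), fs=eps.fs,
                               class_labels=["A"])
        assert ms.global_explained_variance(eps, model, lab) == pytest.approx(0.0, abs=1e-12)


class TestPolarityInvarianceSuite:
    """Flipping the sign of any epoch or template changes no label, no parameter."""

    def test_epoch_sign_flip(self, templates16, noisefree_sim):
        _, _, epochs = noisefree_sim
        flipped = EpochSet(-epochs.epochs, fs=epochs.fs,
                           epoch_length_s=epochs.epoch_length_s,
                           channel_labels=epochs.channel_labels)
        a = ms.backfit(epochs, templates16)
        b = ms.backfit(flipped, templates16)
        np.testing.assert_array_equal(a.labels, b.labels)
        pa = ms.microstate_parameters(a).to_frame()
        pb = ms.microstate_parameters(b).to_frame()
        assert pa.equals(pb)

    def test_template_sign_flip(self, templates16, noisefree_sim):
        _, _, epochs = noisefree_sim
        flipped = TopographyModel(templates16.maps * np.array([[-1], [1], [-1], [1], [-1]]),
                                  channel_labels=templates16.channel_labels)
        a = ms.backfit(epochs, templates16)
        b = ms.backfit(epochs, flipped)
        np.testing.assert_array_equal(a.labels, b.labels)
        np.testing.assert_allclose(a.fit_corr, b.fit_corr, atol=1e-12)
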