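"""Pre-processing stage tests: noise estimation, peak detection, common-axis
construction, recalibration, rasterisation, segmentation, spatial filtering
and the two normalisations."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from msitma import MassAxis, MsitmaWarning, SimulationConfig, ValidationError, \
    build_common_axis, detect_peaks, estimate_noise, estimate_ppm_offset, \
    median_fold_change_normalize, rasterize, recalibrate_run, reference_intensity_scale, \
    render_profile, segment_kmeans, simulate_dataset, spatial_filter_features
from msitma.io import PeakList

from conftest import make_matrix, make_peaklist


class TestEstimateNoise:
    def test_constant_spectrum_is_noiseless(self):
        assert estimate_noise(np.full(100, 3.7)) == 0.0
        assert estimate_noise(np.zeros(50)) == 0.0

    def test_gaussian_noise_scale_recovered(self):
        x = np.random.default_rng(0).normal(0.0, 1.0, 100_000)
        assert abs(estimate_noise(x) - 1.0) < 0.02

    def test_robust_to_single_huge_spike(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0.0, 1.0, 10_000)
        base = estimate_noise(x)
        x_spiked = x.copy()
        x_spiked[123] = 1e9
        assert abs(estimate_noise(x_spiked) - base) / base < 0.05


class TestDetectPeaks:
    def test_flat_zero_spectrum_gives_no_peaks(self):
        axis = np.linspace(100, 200, 500)
        assert len(detect_peaks(axis, np.zeros(500), 3.0)) == 0

    def test_strong_gaussian_found_at_centre(self):
        axis = np.linspace(499.0, 501.0, 201)  # 10 mTh bins
        rng = np.random.default_rng(0)
        noise = rng.normal(0, 1.0, axis.size)
        profile = render_profile(make_peaklist([500.0], [10.0]), axis, width_mz=0.02) + noise
        peaks = detect_peaks(axis, profile, snr_min=3.0)
        assert len(peaks) == 1
        assert abs(peaks.mz[0] - 500.0) <= 0.01  # within one bin

    def test_subthreshold_amplitude_not_detected(self):
        axis = np.linspace(499.0, 501.0, 201)
        rng = np.random.default_rng(0)
        noise = rng.normal(0, 1.0, axis.size)
        profile = render_profile(make_peaklist([500.0], [2.0]), axis, width_mz=0.02) + noise
        assert len(detect_peaks(axis, profile, snr_min=3.0)) == 0


class TestBuildCommonAxis:
    def test_identical_runs_give_that_axis(self):
        pl = make_peaklist([100.0, 200.0, 300.0])
        axis = build_common_axis([pl, pl], ppm_tol=10)
        assert np.allclose(axis.mz, [100.0, 200.0, 300.0])

    def test_peaks_within_tolerance_merge(self):
        # 0.004 / 500 = 8 ppm < 10 ppm
        axis = build_common_axis([make_peaklist([500.000]), make_peaklist([500.004])], 10)
        assert len(axis) == 1

    def test_peaks_outside_tolerance_split(self):
        # 0.010 / 500 = 20 ppm > 10 ppm
        axis = build_common_axis([make_peaklist([500.000]), make_peaklist([500.010])], 10)
        assert len(axis) == 2

    def test_permutation_invariant_in_run_order(self, rng):
        lists = [make_peaklist(np.sort(rng.uniform(100, 1000, 30)),
                               rng.uniform(1, 10, 30)) for _ in range(4)]
        a1 = build_common_axis(lists, 10)
        a2 = build_common_axis(lists[::-1], 10)
        assert np.allclose(a1.mz, a2.mz)


class TestRecalibration:
    def test_on_axis_run_has_zero_offset(self, rng):
        mz = np.sort(rng.uniform(100, 1000, 40))
        assert estimate_ppm_offset(make_peaklist(mz), MassAxis(mz), 10) == 0.0

    def test_uniform_shift_recovered_exactly(self, rng):
        mz = np.sort(rng.uniform(100, 1000, 40))
        shifted = make_peaklist(mz * (1 + 5e-6))
        assert abs(estimate_ppm_offset(shifted, MassAxis(mz), 10) - 5.0) < 0.1
        recal = recalibrate_run(shifted, MassAxis(mz), 10)
        assert np.max(np.abs(recal.mz / mz - 1)) * 1e6 < 0.1

    def test_median_estimator_tolerates_per_peak_noise(self, rng):
        mz = np.sort(rng.uniform(100, 1000, 60))
        noisy = mz * (1 + (5.0 + rng.normal(0, 1.0, 60)) * 1e-6)
        off = estimate_ppm_offset(make_peaklist(np.sort(noisy)), MassAxis(mz), 10)
        assert abs(off - 5.0) < 1.0

    def test_too_few_matches_warns_and_applies_zero(self):
        pl = make_peaklist([100.0, 500.0])
        with pytest.warns(MsitmaWarning):
            out = recalibrate_run(pl, MassAxis(np.array([700.0, 800.0])), 10)
        assert np.array_equal(out.mz, pl.mz)


class TestRasterize:
    def test_on_axis_run_copies_intensities(self, rng):
        mz = np.sort(rng.uniform(100, 1000, 5))
        mat = make_matrix(rng.uniform(0, 10, (4, 5)), mz=mz)
        out = rasterize([mat], MassAxis(mz), 10)[0]
        assert np.allclose(out.intensities, mat.intensities)

    def test_peak_far_from_axis_dropped(self):
        mat = make_matrix([[7.0]], mz=[500.0 * (1 + 15e-6)])  # 15 ppm off
        out = rasterize([mat], MassAxis(np.array([500.0])), 10)[0]
        assert out.intensities[0, 0] == 0.0

    def test_collision_intensities_summed(self):
        # two run features both within tolerance of one axis entry
        mat = make_matrix([[2.0, 3.0]], mz=[500.000, 500.004])
        out = rasterize([mat], MassAxis(np.array([500.002])), 10)[0]
        assert out.intensities[0, 0] == 5.0


class TestSegmentation:
    def test_partition_matches_generator_tissue_mask(self):
        cfg = SimulationConfig(seed=3, n_slides=1, cores_per_slide=10, n_features=100,
                               core_radius_px=2)
        runs, _, truth = simulate_dataset(cfg)
        seg = segment_kmeans(runs[0], k=2, seed=0)
        mask = truth.tissue_masks["run0"]
        agreement = max(np.mean((seg.labels == 0) == mask),
                        np.mean((seg.labels == 1) == mask))
        assert agreement == 1.0

    def test_single_cluster_contains_everything(self):
        mat = make_matrix(np.random.default_rng(0).uniform(0, 1, (10, 4)))
        seg = segment_kmeans(mat, k=1, seed=0)
        assert set(seg.labels) == {0}

    def test_deterministic_under_seed(self, rng):
        mat = make_matrix(rng.uniform(0, 1, (50, 6)))
        s1 = segment_kmeans(mat, k=3, seed=11)
        s2 = segment_kmeans(mat, k=3, seed=11)
        assert np.array_equal(s1.labels, s2.labels)

    def test_fewer_pixels_than_clusters_errors(self):
        with pytest.raises(ValidationError):
            segment_kmeans(make_matrix(np.ones((2, 3))), k=5, seed=0)


class TestSpatialFilter:
    def test_tissue_localised_feature_retained(self, rng):
        intens = np.zeros((100, 1))
        mask = np.zeros(100, bool)
        mask[:50] = True
        present = rng.random(50) < 0.8
        intens[:50, 0] = np.where(present, 5.0, 0.0)
        retained, _ = spatial_filter_features(make_matrix(intens), mask)
        assert 0 in retained

    def test_single_pixel_feature_dropped(self):
        intens = np.zeros((10_000, 1))
        intens[0, 0] = 100.0
        mask = np.ones(10_000, bool)
        retained, _ = spatial_filter_features(make_matrix(intens), mask)
        assert retained.size == 0

    def test_spatially_uniform_feature_dropped(self):
        intens = np.full((100, 1), 2.0)  # identical on and off tissue: ratio 1
        mask = np.zeros(100, bool)
        mask[:40] = True
        retained, scores = spatial_filter_features(make_matrix(intens), mask)
        assert retained.size == 0
        assert scores["on_off_ratio"][0] == pytest.approx(1.0)


class TestReferenceScaling:
    def test_identical_runs_scale_by_one(self):
        mat = make_matrix(np.ones((4, 3)))
        scaled, s = reference_intensity_scale([mat, mat], [np.ones(4, bool)] * 2)
        assert np.allclose(s, 1.0)

    def test_doubled_run_gets_two_thirds(self, rng):
        a = make_matrix(rng.uniform(1, 5, (6, 3)), run_id="a", slide_id="sa")
        b = make_matrix(a.intensities * 2, run_id="b", slide_id="sb")
        scaled, s = reference_intensity_scale([a, b], [np.ones(6, bool)] * 2)
        assert np.allclose(s, [4 / 3, 2 / 3])
        med_a = np.median(scaled[0].tic())
        med_b = np.median(scaled[1].tic())
        assert med_a == pytest.approx(med_b, rel=1e-12)

    def test_batch_factors_equalised_to_machine_precision(self, rng):
        base = rng.uniform(1, 5, (8, 4))
        mats, masks = [], []
        for i, f in enumerate([0.5, 1.0, 2.0]):
            mats.append(make_matrix(base * f, run_id=f"r{i}", slide_id=f"s{i}"))
            masks.append(np.ones(8, bool))
        scaled, _ = reference_intensity_scale(mats, masks)
        meds = [np.median(m.tic()) for m in scaled]
        assert np.std(meds) / np.mean(meds) < 1e-12

    def test_empty_reference_mask_names_slide(self):
        mat = make_matrix(np.ones((4, 3)), slide_id="slideX")
        with pytest.raises(ValidationError, match="slideX"):
            reference_intensity_scale([mat], [np.zeros(4, bool)])


class TestMedianFoldChange:
    def test_pure_dilution_removed(self, rng):
        ref = rng.uniform(1, 10, 20)
        spectra = np.vstack([ref, 3.0 * ref])
        normed, factors = median_fold_change_normalize(spectra, reference=ref)
        assert factors[1] == pytest.approx(3.0)
        assert np.allclose(normed[1], ref)

    def test_reference_itself_unchanged(self, rng):
        ref = rng.uniform(1, 10, 20)
        normed, factors = median_fold_change_normalize(ref[None, :], reference=ref)
        assert factors[0] == pytest.approx(1.0)
        assert np.allclose(normed[0], ref)

    def test_defining_property_median_fold_change_is_one(self, rng):
        spectra = rng.lognormal(0, 1, (30, 50))
        normed, _ = median_fold_change_normalize(spectra)
        ref = np.median(spectra, axis=0)
        for row in normed:
            shared = (row > 0) & (ref > 0)
            assert abs(np.median(row[shared] / ref[shared]) - 1.0) < 1e-12

    def test_idempotent(self, rng):
        spectra = rng.lognormal(0, 1, (20, 40))
        normed, _ = median_fold_change_normalize(spectra)
        _, factors2 = median_fold_change_normalize(normed, reference=np.median(spectra, axis=0))
        assert np.allclose(factors2, 1.0)

    def test_disjoint_support_warns_and_keeps_factor_one(self):
        spectra = np.array([[0.0, 0.0, 1.0]])
        ref = np.array([1.0, 1.0, 0.0])
        with pytest.warns(MsitmaWarning):
            normed, factors = median_fold_change_normalize(spectra, reference=ref)
        assert factors[0] == 1.0


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=2 ** 31 - 1))
def test_recalibrate_then_rasterize_recovers_assignments(seed):
    """At <=3 ppm jitter and 10 ppm tolerance, every synthetic feature should
    land back on its own common-axis entry after recalibration."""
    rng = np.random.default_rng(seed)
    true = np.sort(rng.uniform(100, 1000, 40))
    # enforce 100 ppm spacing so axis entries are unambiguous
    keep = np.concatenate([[True], np.diff(true) / true[:-1] > 1e-4])
    true = true[keep]
    offset = rng.normal(0, 3.0)
    shifted = make_peaklist(true * (1 + offset * 1e-6))
    recal = recalibrate_run(shifted, MassAxis(true), 10)
    mat = make_matrix(np.ones((1, true.size)), mz=recal.mz)
    out = rasterize([mat], MassAxis(true), 10)[0]
    assert (out.intensities[0] > 0).mean() >= 0.99
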