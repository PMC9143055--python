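"""Core-level analysis tests: pixel assignment, core averaging, affine mask
registration and FF/FFPE mass-axis matching."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage

from msitma import MassAxis, MsitmaWarning, SimulationConfig, ValidationError, \
    assign_pixels_to_cores, average_core_spectra, match_peak_axes, register_affine, \
    simulate_dataset
from msitma.cores import concat_core_tables

from conftest import make_matrix


def annotation(rows):
    return pd.DataFrame(rows, columns=["core_id", "slide_id", "patient_id", "label",
                                       "x_center", "y_center"])


class TestAssignPixels:
    def setup_method(self):
        self.mat = make_matrix(np.ones((81, 2)), run_id="r", slide_id="s")
        self.ann = annotation([("c1", "s", "p1", "tumour", 2, 2),
                               ("c2", "s", "p2", "normal", 6, 6)])

    def test_pixel_at_core_centre_assigned_to_it(self):
        out = assign_pixels_to_cores(self.mat, self.ann, radius=2)
        centre_idx = np.flatnonzero((self.mat.coords == [2, 2]).all(axis=1))[0]
        assert out[centre_idx] == "c1"

    def test_pixel_beyond_radius_is_background(self):
        out = assign_pixels_to_cores(self.mat, self.ann, radius=1)
        far = np.flatnonzero((self.mat.coords == [8, 0]).all(axis=1))[0]
        assert out[far] == ""

    def test_tissue_mask_vetoes_assignment(self):
        mask = np.zeros(81, bool)
        out = assign_pixels_to_cores(self.mat, self.ann, radius=2, tissue_mask=mask)
        assert (out == "").all()

    def test_overlapping_discs_resolved_by_nearest_with_warning(self):
        ann = annotation([("c1", "s", "p1", "tumour", 3, 3),
                          ("c2", "s", "p2", "normal", 5, 3)])
        with pytest.warns(MsitmaWarning):
            out = assign_pixels_to_cores(self.mat, ann, radius=2)
        i = np.flatnonzero((self.mat.coords == [3, 3]).all(axis=1))[0]
        j = np.flatnonzero((self.mat.coords == [5, 3]).all(axis=1))[0]
        assert out[i] == "c1" and out[j] == "c2"

    def test_matches_generator_ground_truth(self):
        cfg = SimulationConfig(seed=5, n_slides=1, cores_per_slide=8, n_features=20,
                               core_radius_px=2)
        runs, ann, truth = simulate_dataset(cfg)
        out = assign_pixels_to_cores(runs[0], ann, radius=2)
        assert np.array_equal(out, truth.pixel_core_ids["run0"])

    def test_centres_outside_grid_rejected(self):
        ann = annotation([("c1", "s", "p1", "tumour", 99, 99)])
        with pytest.raises(ValidationError):
            assign_pixels_to_cores(self.mat, ann, radius=2)


class TestAverageCoreSpectra:
    def test_identical_pixels_average_to_that_spectrum(self):
        mat = make_matrix(np.tile([1.0, 2.0, 3.0], (9, 1)), slide_id="s")
        ann = annotation([("c1", "s", "p1", "tumour", 1, 1)])
        assigned = assign_pixels_to_cores(mat, ann, radius=1)
        table = average_core_spectra(mat, assigned, ann)
        assert np.allclose(table.spectra[0], [1.0, 2.0, 3.0])
        assert table.meta.loc[0, "n_pixels"] == 5  # centre + 4 neighbours

    def test_two_pixel_arithmetic_mean(self):
        mat = make_matrix(np.array([[0.0, 2.0], [2.0, 0.0]]), slide_id="s",
                          coords=np.array([[0, 0], [0, 1]]))
        ann = annotation([("c1", "s", "p1", "tumour", 0, 0)])
        table = average_core_spectra(mat, np.array(["c1", "c1"], object), ann)
        assert np.allclose(table.spectra[0], [1.0, 1.0])

    def test_noise_free_core_means_equal_class_templates(self):
        cfg = SimulationConfig(seed=2, n_slides=1, cores_per_slide=6, n_features=15,
                               noise_sd=0.0, slide_batch_sd=0.0, core_radius_px=2)
        runs, ann, truth = simulate_dataset(cfg)
        assigned = truth.pixel_core_ids["run0"]
        table = average_core_spectra(runs[0], assigned, ann)
        tumour = table.spectra[(table.meta["label"] == "tumour").to_numpy()]
        # all tumour cores identical in the noise-free limit
        assert np.allclose(tumour, tumour[0])

    def test_empty_core_excluded_with_warning(self):
        mat = make_matrix(np.ones((4, 2)), slide_id="s")
        ann = annotation([("c1", "s", "p1", "tumour", 0, 0),
                          ("c2", "s", "p2", "normal", 1, 1)])
        assigned = np.array(["c1", "c1", "", ""], object)
        with pytest.warns(MsitmaWarning):
            table = average_core_spectra(mat, assigned, ann)
        assert table.meta["core_id"].tolist() == ["c1"]

    def test_pixel_weighted_mean_of_cores_conserves_total(self, rng):
        mat = make_matrix(rng.uniform(0, 5, (25, 4)), slide_id="s")
        ann = annotation([("c1", "s", "p1", "tumour", 1, 1),
                          ("c2", "s", "p2", "normal", 3, 3)])
        assigned = assign_pixels_to_cores(mat, ann, radius=1)
        table = average_core_spectra(mat, assigned, ann)
        n = table.meta["n_pixels"].to_numpy()
        weighted = (table.spectra * n[:, None]).sum(axis=0) / n.sum()
        assert np.allclose(weighted, mat.intensities[assigned != ""].mean(axis=0))

    def test_reference_kidney_label_mapped_to_reference(self):
        mat = make_matrix(np.ones((4, 2)), slide_id="s")
        ann = annotation([("ref", "s", "pr", "reference-kidney", 0, 0)])
        table = average_core_spectra(mat, np.array(["ref", "", "", ""], object), ann)
        assert table.meta.loc[0, "label"] == "reference"


def blob_image():
    img = np.zeros((64, 64))
    img[20:35, 18:40] = 1.0
    img[25:45, 30:38] = 1.0  # asymmetric, so rotations are observable
    return img


class TestRegisterAffine:
    def test_identity_for_identical_masks(self):
        img = blob_image()
        p = register_affine(img, img)
        assert p.final_loss == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(p.linear, np.eye(2)) and np.allclose(p.translation, 0)

    def test_translation_recovered_within_half_pixel(self):
        img = blob_image()
        moving = np.roll(np.roll(img, 5, axis=0), -3, axis=1)
        p = register_affine(img, moving)
        # moving content sits at +(5, -3): moving->fixed translation is (-5, +3)
        assert np.allclose(p.translation, [-5.0, 3.0], atol=0.5)

    def test_rotation_and_scale_recovered_to_dice_095(self):
        img = blob_image()
        ang, sc, c = np.deg2rad(10), 1.1, 31.5
        R = sc * np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
        inv = np.linalg.inv(R)
        moving = ndimage.affine_transform(img, inv, offset=c - inv @ np.array([c, c]), order=1)
        moving = (moving > 0.5).astype(float)
        p = register_affine(img, moving, n_iters=500)
        linv = np.linalg.inv(p.linear)
        warped = ndimage.affine_transform(moving, linv, offset=-linv @ p.translation, order=0)
        dice = 2 * np.sum((warped > 0.5) & (img > 0.5)) / (np.sum(warped > 0.5) + np.sum(img > 0.5))
        assert dice >= 0.95

    def test_swap_invariance_inverts_translation(self):
        img = blob_image()
        moving = np.roll(np.roll(img, 4, axis=0), 2, axis=1)
        fwd = register_affine(img, moving)
        bwd = register_affine(moving, img)
        assert np.allclose(fwd.translation, -bwd.translation, atol=0.5)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValidationError):
            register_affine(np.zeros((8, 8)), blob_image())


def brute_force_matching(a, b, ppm_tol):
    """Exhaustive search over one-to-one matchings: maximise the number of
    pairs, then minimise the total ppm distance."""
    candidates = []
    for i, j in itertools.product(range(a.size), range(b.size)):
        ppm = abs(a[i] - b[j]) / (0.5 * (a[i] + b[j])) * 1e6
        if ppm <= ppm_tol:
            candidates.append((i, j, ppm))
    best = (0, 0.0, [])

    def rec(k, used_a, used_b, pairs, total):
        nonlocal best
        count = len(pairs)
        if (count, -total) > (best[0], -best[1]):
            best = (count, total, list(pairs))
        if k == len(candidates):
            return
        i, j, ppm = candidates[k]
        if i not in used_a and j not in used_b:
            rec(k + 1, used_a | {i}, used_b | {j}, pairs + [(i, j)], total + ppm)
        rec(k + 1, used_a, used_b, pairs, total)

    rec(0, frozenset(), frozenset(), [], 0.0)
    return sorted(best[2])


class TestMatchPeakAxes:
    def test_identical_axes_fully_shared(self, rng):
        mz = np.sort(rng.uniform(100, 1000, 20))
        pairs, frac = match_peak_axes(MassAxis(mz), MassAxis(mz), 10)
        assert frac == 1.0 and pairs == [(i, i) for i in range(20)]

    def test_distant_axes_share_nothing(self):
        a = MassAxis(np.array([100.0, 200.0]))
        b = MassAxis(np.array([150.0, 250.0]))
        pairs, frac = match_peak_axes(a, b, 10)
        assert pairs == [] and frac == 0.0

    def test_greedy_equals_exhaustive_on_small_axes(self, rng):
        def well_spaced(mz, min_ppm=40.0):
            mz = np.sort(mz)
            return mz[np.concatenate([[True], np.diff(mz) / mz[:-1] * 1e6 > min_ppm])]

        for _ in range(30):
            # spacing > 2x tolerance within each axis keeps the optimal
            # matching unique, which is where greedy provably agrees
            a = well_spaced(rng.uniform(100, 1000, int(rng.integers(3, 13))))
            shared = a[rng.random(a.size) < 0.7]
            b = shared * (1 + rng.normal(0, 4, shared.size) * 1e-6)
            b = well_spaced(np.concatenate([b, rng.uniform(100, 1000, 3)]))
            pairs, _ = match_peak_axes(MassAxis(a), MassAxis(b), 10)
            assert pairs == brute_force_matching(a, b, 10)

    def test_symmetric_in_arguments(self, rng):
        a = np.sort(rng.uniform(100, 1000, 10))
        b = np.sort(np.concatenate([a[:6] * (1 + 3e-6), rng.uniform(100, 1000, 4)]))
        p_ab, f_ab = match_peak_axes(MassAxis(a), MassAxis(b), 10)
        p_ba, f_ba = match_peak_axes(MassAxis(b), MassAxis(a), 10)
        assert sorted((j, i) for i, j in p_ab) == sorted(p_ba)
        assert f_ab == f_ba


def test_concat_requires_shared_axis(rng):
    cfg = SimulationConfig(seed=2, n_slides=1, cores_per_slide=4, n_features=10,
                           core_radius_px=2)
    runs, ann, truth = simulate_dataset(cfg)
    table = average_core_spectra(runs[0], truth.pixel_core_ids["run0"], ann)
    other = make_matrix(np.ones((1, 3)), slide_id="s")
    ann2 = annotation([("cX", "s", "p", "tumour", 0, 0)])
    t2 = average_core_spectra(other, np.array(["cX"], object), ann2)
    with pytest.raises(ValidationError):
        concat_core_tables([table, t2])
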