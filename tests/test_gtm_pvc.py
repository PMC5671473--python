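import numpy as np
import pytest

from taupvc.gtm_pvc import (
    GtmModel,
    build_transfer_matrix,
    calc_pre_pvc,
    pvc_image,
    residuals_and_pvcnstd,
    roi_means,
    solve_gtm,
)
from taupvc.phantom import gtm_block_phantom
from taupvc.reference_region import SuvrVolume
from taupvc.volume_io import LabeledVolume, PsfModel, ScalarVolume, default_grid

from _oracles import lstsq_oracle


def _suvr_from(scalar: ScalarVolume) -> SuvrVolume:
    return SuvrVolume(scalar.data, scalar.grid, 1.0)


class TestTransferMatrix:
    def test_identity_limit_for_subvoxel_psf(self):
        grid = default_grid((16, 16, 16), 2.0)
        labels = np.zeros(grid.shape, dtype=np.int32)
        labels[2:6, 2:6, 2:6] = 1
        labels[9:13, 9:13, 9:13] = 2
        model = build_transfer_matrix(LabeledVolume(labels, grid), [1, 2],
                                      PsfModel.isotropic(0.5))
        assert np.allclose(model.omega, np.eye(2))

    def test_symmetric_half_space_rois(self):
        grid = default_grid((32, 32, 32), 2.0)
        labels = np.ones(grid.shape, dtype=np.int32)
        labels[16:] = 2
        model = build_transfer_matrix(LabeledVolume(labels, grid), [1, 2],
                                      PsfModel.isotropic(6.0))
        assert model.omega[0, 0] == pytest.approx(model.omega[1, 1], rel=1e-12)
        assert model.omega[0, 1] == pytest.approx(model.omega[1, 0], rel=1e-12)
        # full grid: rows sum to 1 minus boundary leakage only (a 32^3
        # grid loses ~9% of each half-space's mass through its faces)
        sums = model.omega.sum(axis=1)
        assert sums[0] == pytest.approx(sums[1], rel=1e-12)
        assert np.all(sums <= 1 + 1e-9) and np.all(sums > 0.85)

    def test_single_whole_grid_roi(self):
        grid = default_grid((32, 32, 32), 2.0)
        labels = np.ones(grid.shape, dtype=np.int32)
        model = build_transfer_matrix(LabeledVolume(labels, grid), [1],
                                      PsfModel.isotropic(6.0))
        assert 0.9 < model.omega[0, 0] <= 1.0

    def test_rows_sum_to_one_for_interior_rois(self):
        labels_vol, pet, truth, psf = gtm_block_phantom(n_rois=4)
        model = build_transfer_matrix(labels_vol, sorted(truth), psf)
        assert np.all(model.omega >= 0)
        assert np.all(model.omega <= 1 + 1e-9)
        # interior slabs are >3 sigma from the zero boundary in z only at
        # the inner edges; rows still sum below 1
        assert np.all(model.omega.sum(axis=1) <= 1 + 1e-9)

    def test_absent_labels_dropped_with_warning(self, caplog):
        grid = default_grid((8, 8, 8), 2.0)
        labels = np.zeros(grid.shape, dtype=np.int32)
        labels[2:5, 2:5, 2:5] = 1
        model = build_transfer_matrix(LabeledVolume(labels, grid), [1, 85],
                                      PsfModel.isotropic(6.0))
        assert model.roi_labels == [1]

    def test_no_labels_present_raises(self):
        grid = default_grid((8, 8, 8), 2.0)
        empty = LabeledVolume(np.zeros(grid.shape, dtype=np.int32), grid)
        with pytest.raises(ValueError):
            build_transfer_matrix(empty, [3], PsfModel.isotropic(6.0))


class TestSolve:
    def test_identity_omega_returns_observed(self):
        model = GtmModel([1, 2], np.eye(2), observed_means=np.array([1.5, 0.5]))
        out = solve_gtm(model)
        assert np.allclose(out.corrected_means, [1.5, 0.5])
        assert not out.used_pseudoinverse

    def test_hand_inverted_2x2(self):
        omega = np.array([[0.8, 0.2], [0.2, 0.8]])
        model = GtmModel([1, 2], omega, observed_means=np.array([1.0, 2.0]))
        out = solve_gtm(model)
        assert np.allclose(out.corrected_means, [2 / 3, 7 / 3], atol=1e-12)

    @pytest.mark.parametrize("n", [3, 6, 10])
    def test_matches_least_squares_oracle(self, n):
        rng = np.random.default_rng(n)
        omega = np.eye(n) * 0.7 + rng.random((n, n)) * 0.3 / n
        t = rng.random(n) * 3
        out = solve_gtm(GtmModel(list(range(1, n + 1)), omega,
                                 observed_means=t))
        assert np.abs(out.corrected_means - lstsq_oracle(omega, t)).max() < 1e-10

    def test_singular_omega_falls_back_to_pseudoinverse(self):
        omega = np.array([[0.5, 0.5], [0.5, 0.5]])
        model = GtmModel([1, 2], omega, observed_means=np.array([1.0, 1.0]))
        out = solve_gtm(model)
        assert out.used_pseudoinverse
        assert np.allclose(omega @ out.corrected_means, [1.0, 1.0])

    def test_block_phantom_recovery_is_exact(self):
        labels_vol, pet, truth, psf = gtm_block_phantom()
        order = sorted(truth)
        model = build_transfer_matrix(labels_vol, order, psf)
        t = roi_means(pet.data, labels_vol, order)
        out = solve_gtm(model, observed_means=t)
        expect = np.array([truth[k] for k in order])
        assert np.abs(out.corrected_means - expect).max() < 1e-6 * expect.max()

    def test_spill_out_recovery_exceeds_observed(self):
        # a small hot ROI against a cold neighbour: PVC must recover a
        # mean above the observed one
        labels_vol, pet, truth, psf = gtm_block_phantom(
            n_rois=2, means=[3.0, 0.2])
        order = [1, 2]
        model = build_transfer_matrix(labels_vol, order, psf)
        t = roi_means(pet.data, labels_vol, order)
        out = solve_gtm(model, observed_means=t)
        assert out.corrected_means[0] > t[0]


class TestImagesAndQc:
    def test_pvc_image_paints_corrected_means(self):
        grid = default_grid((8, 8, 8), 2.0)
        labels = np.zeros(grid.shape, dtype=np.int32)
        labels[2:5, 2:5, 2:5] = 7
        model = GtmModel([7], np.eye(1), corrected_means=np.array([2.5]))
        img = pvc_image(LabeledVolume(labels, grid), model)
        assert (img.data[labels == 7] == 2.5).all()
        assert (img.data[labels == 0] == 0.0).all()

    def test_pvc_image_has_n_distinct_nonzero_values(self):
        labels_vol, pet, truth, psf = gtm_block_phantom()
        order = sorted(truth)
        model = build_transfer_matrix(labels_vol, order, psf)
        model = solve_gtm(model, roi_means(pet.data, labels_vol, order))
        img = pvc_image(labels_vol, model)
        nonzero = np.unique(img.data[img.data != 0])
        assert len(nonzero) == len(order)

    def test_forward_round_trip_reproduces_observed(self):
        labels_vol, pet, truth, psf = gtm_block_phantom()
        order = sorted(truth)
        model = build_transfer_matrix(labels_vol, order, psf)
        model = solve_gtm(model, roi_means(pet.data, labels_vol, order))
        pre = calc_pre_pvc(pvc_image(labels_vol, model), psf)
        assert np.abs(pre.data - pet.data).max() < 1e-6

    def test_calc_pre_pvc_linearity(self):
        grid = default_grid((16, 16, 16), 2.0)
        rng = np.random.default_rng(9)
        a = ScalarVolume(rng.random(grid.shape), grid)
        b = ScalarVolume(rng.random(grid.shape), grid)
        psf = PsfModel.isotropic(6.0)
        lhs = calc_pre_pvc(ScalarVolume(a.data + b.data, grid), psf)
        rhs = calc_pre_pvc(a, psf).data + calc_pre_pvc(b, psf).data
        assert np.abs(lhs.data - rhs).max() < 1e-12

    def test_pvcnstd_zero_for_perfect_model(self):
        labels_vol, pet, truth, psf = gtm_block_phantom()
        order = sorted(truth)
        model = build_transfer_matrix(labels_vol, order, psf)
        model = solve_gtm(model, roi_means(pet.data, labels_vol, order))
        pre = calc_pre_pvc(pvc_image(labels_vol, model), psf)
        qc = residuals_and_pvcnstd(_suvr_from(pet), pre, labels_vol,
                                   qc_labels=order)
        assert qc.table["pvcnstd"].max() < 1e-9
        assert qc.global_pvcnstd < 1e-9

    def test_constant_residual_gives_zero_pvcnstd(self):
        grid = default_grid((8, 8, 8), 2.0)
        labels = np.zeros(grid.shape, dtype=np.int32)
        labels[2:6, 2:6, 2:6] = 1
        suvr = SuvrVolume(np.ones(grid.shape), grid, 1.0)
        pre = ScalarVolume(np.ones(grid.shape) + 0.25, grid)
        qc = residuals_and_pvcnstd(suvr, pre, LabeledVolume(labels, grid),
                                   qc_labels=[1])
        row = qc.table.iloc[0]
        assert row["residual_mean"] == pytest.approx(0.25)
        assert row["pvcnstd"] == pytest.approx(0.0, abs=1e-15)

    def test_unmodeled_hotspot_raises_pvcnstd_and_modeling_it_lowers(self):
        labels_vol, pet, truth, psf = gtm_block_phantom(n_rois=3)
        grid = labels_vol.grid
        hotspot = np.zeros(grid.shape, dtype=bool)
        hotspot[26:32, 26:32, 4:8] = True      # outside the modeled slabs
        assert not labels_vol.data[hotspot].any()
        activity = np.zeros(grid.shape)
        for lab, val in truth.items():
            activity[labels_vol.data == lab] = val
        activity[hotspot] = 3.0
        from taupvc.volume_io import smooth_array
        pet2 = ScalarVolume(smooth_array(activity, grid.voxel_size_mm,
                                         psf.fwhm_mm), grid)

        def qc_for(label_data, order):
            lv = LabeledVolume(label_data, grid)
            m = build_transfer_matrix(lv, order, psf)
            m = solve_gtm(m, roi_means(pet2.data, lv, order))
            pre = calc_pre_pvc(pvc_image(lv, m), psf)
            return residuals_and_pvcnstd(_suvr_from(pet2), pre, lv,
                                         qc_labels=sorted(truth))

        base = qc_for(labels_vol.data, sorted(truth))
        with_hot = labels_vol.data.copy()
        with_hot[hotspot] = 9
        modeled = qc_for(with_hot, sorted(truth) + [9])
        assert base.global_pvcnstd > 1e-4
        assert modeled.global_pvcnstd < base.global_pvcnstd
        assert modeled.global_pvcnstd < 1e-6

    def test_nonpositive_mean_suvr_excluded_from_global(self):
        grid = default_grid((8, 8, 8), 2.0)
        labels = np.zeros(grid.shape, dtype=np.int32)
        labels[1:3, 1:3, 1:3] = 1
        labels[5:7, 5:7, 5:7] = 2
        data = np.zeros(grid.shape)
        data[labels == 2] = 1.0        # ROI 1 has zero mean SUVR
        suvr = SuvrVolume(data, grid, 1.0)
        pre = ScalarVolume(data, grid)
        qc = residuals_and_pvcnstd(suvr, pre, LabeledVolume(labels, grid),
                                   qc_labels=[1, 2])
        assert np.isnan(qc.table.set_index("label").loc[1, "pvcnstd"])
        assert qc.global_pvcnstd == pytest.approx(0.0)

    def test_std_ddof_configurable(self):
        grid = default_grid((6, 6, 6), 2.0)
        labels = np.zeros(grid.shape, dtype=np.int32)
        labels[0, 0, :4] = 1
        rng = np.random.default_rng(3)
        res = rng.random(grid.shape)
        suvr = SuvrVolume(np.ones(grid.shape), grid, 1.0)
        pre = ScalarVolume(np.ones(grid.shape) + res, grid)
        pop = residuals_and_pvcnstd(suvr, pre, LabeledVolume(labels, grid),
                                    qc_labels=[1], ddof=0)
        samp = residuals_and_pvcnstd(suvr, pre, LabeledVolume(labels, grid),
                                     qc_labels=[1], ddof=1)
        r = res[labels == 1]
        assert pop.table["residual_std"][0] == pytest.approx(r.std(ddof=0))
        assert samp.table["residual_std"][0] == pytest.approx(r.std(ddof=1))
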