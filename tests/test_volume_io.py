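import nibabel as nib
import numpy as np
import pytest

from taupvc.volume_io import (
    GridMismatchError,
    LabeledVolume,
    ProbabilityVolume,
    PsfModel,
    ScalarVolume,
    VolumeGrid,
    VolumeValidationError,
    assert_same_grid,
    component_masks,
    default_grid,
    gaussian_smooth,
    read_volume,
    smooth_array,
    write_volume,
)

from _oracles import dense_gaussian_smooth, flood_fill_components


class TestReadWrite:
    def test_label_roundtrip_is_bit_exact(self, tmp_path):
        grid = default_grid((8, 8, 8), 2.0)
        rng = np.random.default_rng(0)
        vol = LabeledVolume(rng.integers(0, 90, size=(8, 8, 8)), grid)
        write_volume(vol, tmp_path / "lab.nii.gz")
        back = read_volume(tmp_path / "lab.nii.gz", expect="label")
        assert np.array_equal(back.data, vol.data)
        assert back.data.dtype.kind == "i"

    def test_float_stored_integer_labels_are_rounded(self, tmp_path):
        data = np.zeros((4, 4, 4), dtype=np.float32)
        data[1, 1, 1] = 17.0
        nib.Nifti1Image(data, np.eye(4)).to_filename(str(tmp_path / "f.nii"))
        vol = read_volume(tmp_path / "f.nii", expect="label")
        assert set(np.unique(vol.data)) == {0, 17}

    def test_scalar_roundtrip_within_float32(self, tmp_path):
        grid = default_grid((6, 6, 6), 2.0)
        rng = np.random.default_rng(1)
        vol = ScalarVolume(rng.normal(size=(6, 6, 6)), grid)
        write_volume(vol, tmp_path / "s.nii.gz")
        back = read_volume(tmp_path / "s.nii.gz", expect="scalar")
        assert np.abs(back.data - vol.data).max() < 1e-6

    def test_probability_out_of_range_rejected(self, tmp_path):
        data = np.full((4, 4, 4), 1.5, dtype=np.float32)
        nib.Nifti1Image(data, np.eye(4)).to_filename(str(tmp_path / "p.nii"))
        with pytest.raises(VolumeValidationError, match="probability"):
            read_volume(tmp_path / "p.nii", expect="probability")

    def test_non_integer_data_rejected_as_labels(self, tmp_path):
        rng = np.random.default_rng(2)
        data = rng.random((4, 4, 4)).astype(np.float32) * 0.8 + 0.1
        nib.Nifti1Image(data, np.eye(4)).to_filename(str(tmp_path / "x.nii"))
        with pytest.raises(VolumeValidationError, match="non-integer"):
            read_volume(tmp_path / "x.nii", expect="label")

    def test_4d_input_rejected(self, tmp_path):
        data = np.zeros((4, 4, 4, 3), dtype=np.float32)
        nib.Nifti1Image(data, np.eye(4)).to_filename(str(tmp_path / "d4.nii"))
        with pytest.raises(VolumeValidationError, match="3-D"):
            read_volume(tmp_path / "d4.nii", expect="scalar")

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_volume(tmp_path / "absent.nii", expect="scalar")


class TestGridContract:
    def test_matching_grids_pass(self):
        g = default_grid((8, 8, 8), 2.0)
        a = ScalarVolume(np.zeros((8, 8, 8)), g)
        b = ScalarVolume(np.ones((8, 8, 8)), g)
        assert_same_grid([a, b])

    def test_shape_mismatch_reports_volume(self):
        a = ScalarVolume(np.zeros((8, 8, 8)), default_grid((8, 8, 8)))
        b = ScalarVolume(np.zeros((8, 8, 7)), default_grid((8, 8, 7)))
        with pytest.raises(GridMismatchError, match="pet"):
            assert_same_grid([a, b], names=["aparc", "pet"])

    def test_half_mm_translation_exceeds_tolerance(self):
        g1 = default_grid((8, 8, 8), 2.0)
        aff = np.array(g1.affine)
        aff[0, 3] += 0.5
        g2 = VolumeGrid((8, 8, 8), aff)
        with pytest.raises(GridMismatchError, match="affine"):
            assert_same_grid([g1, g2])

    def test_invalid_grids_rejected(self):
        with pytest.raises(VolumeValidationError):
            VolumeGrid((8, 8), np.eye(4))
        singular = np.eye(4)
        singular[0, 0] = 0.0
        with pytest.raises(VolumeValidationError):
            VolumeGrid((8, 8, 8), singular)


class TestGaussianSmooth:
    def test_subvoxel_fwhm_degenerates_to_identity(self):
        rng = np.random.default_rng(3)
        data = rng.random((10, 10, 10))
        out = smooth_array(data, 2.0, 0.4)  # 0.2 voxel
        assert np.array_equal(out, data)

    def test_constant_volume_stays_one_in_interior(self):
        grid = default_grid((40, 40, 40), 1.0)
        out = smooth_array(np.ones(grid.shape), grid.voxel_size_mm, 8.0)
        # > 3 sigma (~10 voxels) from every edge
        assert np.abs(out[15:25, 15:25, 15:25] - 1.0).max() < 1e-6

    def test_mass_conserved_up_to_boundary_loss(self):
        rng = np.random.default_rng(4)
        data = rng.random((16, 16, 16))
        out = smooth_array(data, 2.0, 8.0)
        assert out.sum() <= data.sum() * (1 + 1e-9)
        assert np.all(np.isfinite(out))

    def test_linearity(self):
        rng = np.random.default_rng(5)
        X = rng.random((16, 16, 16))
        Y = rng.random((16, 16, 16))
        a, b = 2.5, -1.25
        lhs = smooth_array(a * X + b * Y, 2.0, 6.0)
        rhs = a * smooth_array(X, 2.0, 6.0) + b * smooth_array(Y, 2.0, 6.0)
        assert np.abs(lhs - rhs).max() <= 1e-10 * np.abs(rhs).max()

    @pytest.mark.parametrize("shape,fwhm", [((21, 21, 21), 8.0),
                                            ((15, 17, 21), 5.0)])
    def test_agrees_with_dense_convolution_oracle(self, shape, fwhm):
        rng = np.random.default_rng(6)
        data = rng.random(shape)
        ours = smooth_array(data, 1.0, fwhm)
        oracle = dense_gaussian_smooth(data, 1.0, fwhm)
        assert np.abs(ours - oracle).max() <= 1e-8 * np.abs(oracle).max()

    def test_point_source_matches_oracle(self):
        data = np.zeros((21, 21, 21))
        data[10, 10, 10] = 1.0
        ours = smooth_array(data, 1.0, 8.0)
        oracle = dense_gaussian_smooth(data, 1.0, 8.0)
        assert np.abs(ours - oracle).max() <= 1e-12

    def test_volume_wrapper_and_psf_validation(self):
        grid = default_grid((8, 8, 8), 2.0)
        vol = ScalarVolume(np.ones(grid.shape), grid)
        out = gaussian_smooth(vol, PsfModel.isotropic(6.0))
        assert isinstance(out, ScalarVolume)
        with pytest.raises(VolumeValidationError):
            PsfModel.isotropic(-1.0)
        with pytest.raises(ValueError):
            smooth_array(np.ones((4, 4, 4)), 2.0, 0.0)


class TestComponents:
    @pytest.mark.parametrize("connectivity", [6, 26])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_flood_fill_oracle(self, connectivity, seed):
        rng = np.random.default_rng(seed)
        mask = rng.random((18, 18, 18)) < 0.25
        ours = component_masks(mask, connectivity)
        oracle = flood_fill_components(mask, connectivity)
        ours_sets = {frozenset(map(tuple, np.argwhere(c))) for c in ours}
        assert ours_sets == {frozenset(c) for c in oracle}

    def test_deterministic_ordering(self):
        mask = np.zeros((12, 12, 12), dtype=bool)
        mask[1:3, 1:3, 1:3] = True       # 8 voxels
        mask[8:10, 8:10, 8:11] = True    # 12 voxels
        mask[5, 5, 5] = True             # 1 voxel
        comps = component_masks(mask, 26)
        assert [int(c.sum()) for c in comps] == [12, 8, 1]
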