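"""Grid geometry, mask IO and manifest parsing."""

import datetime as dt
import json

import numpy as np
import pytest

from lesionvario import (
    GridSpec,
    LesionMask,
    ManifestError,
    MaskFormatError,
    NonBinaryMaskError,
    read_manifest,
    read_mask,
    write_mask,
)

import nibabel as nib


class TestGridSpec:
    def test_reference_grid_voxel_volume(self):
        grid = GridSpec((121, 145, 121), (1.5, 1.5, 1.5))
        assert grid.voxel_volume_mm3 == pytest.approx(3.375)
        assert grid.n_voxels == 121 * 145 * 121

    @pytest.mark.parametrize(
        "shape,spacing",
        [((0, 5, 5), (1.5, 1.5, 1.5)), ((5, 5, 5), (0.0, 1.5, 1.5)), ((5, 5, 5), (-1, 1, 1))],
    )
    def test_invalid_geometry_rejected(self, shape, spacing):
        with pytest.raises(MaskFormatError):
            GridSpec(shape, spacing)

    def test_anisotropic_spacing_warns(self):
        with pytest.warns(UserWarning, match="anisotropic"):
            GridSpec((5, 5, 5), (1.0, 1.5, 1.5))


class TestLesionMask:
    def test_lesion_fraction_exact(self, small_grid):
        values = np.zeros(small_grid.shape, dtype=np.uint8)
        values[0, 0, 0] = values[3, 4, 5] = 1
        mask = LesionMask(values, small_grid)
        assert mask.lesion_fraction == 2 / small_grid.n_voxels
        assert mask.volume_mm3 == pytest.approx(2 * 3.375)

    def test_nonbinary_values_rejected(self, small_grid):
        values = np.zeros(small_grid.shape)
        values[1, 1, 1] = 2.0
        with pytest.raises(NonBinaryMaskError, match="1 voxel"):
            LesionMask(values, small_grid)


class TestNiftiIO:
    def test_round_trip_preserves_values_and_spacing(self, tmp_path, small_grid):
        rng = np.random.default_rng(7)
        values = (rng.random(small_grid.shape) < 0.1).astype(np.uint8)
        mask = LesionMask(values, small_grid, id="rt")
        path = write_mask(mask, tmp_path / "rt.nii.gz")
        back = read_mask(path)
        np.testing.assert_array_equal(back.values, values)
        assert back.grid.spacing == small_grid.spacing

    def test_all_zero_volume_reads_as_empty_mask(self, tmp_path):
        img = nib.Nifti1Image(np.zeros((121, 145, 121), dtype=np.uint8), np.diag([1.5] * 3 + [1]))
        nib.save(img, tmp_path / "empty.nii.gz")
        mask = read_mask(tmp_path / "empty.nii.gz")
        assert mask.lesion_fraction == 0.0
        assert mask.grid.shape == (121, 145, 121)

    def test_strict_binary_rejects_half_values(self, tmp_path):
        data = np.zeros((6, 6, 6), dtype=np.float32)
        data[2, 2, 2] = 0.5
        img = nib.Nifti1Image(data, np.diag([1.5] * 3 + [1]))
        nib.save(img, tmp_path / "gray.nii.gz")
        with pytest.raises(NonBinaryMaskError, match="1 voxel"):
            read_mask(tmp_path / "gray.nii.gz", strict_binary=True)
        # and lenient mode still rejects 0.5 (not within tolerance of 0/1)
        with pytest.raises(NonBinaryMaskError):
            read_mask(tmp_path / "gray.nii.gz", strict_binary=False)

    def test_lenient_mode_rounds_near_binary(self, tmp_path):
        data = np.zeros((6, 6, 6), dtype=np.float32)
        data[1, 2, 3] = 1.0000001
        img = nib.Nifti1Image(data, np.diag([1.5] * 3 + [1]))
        nib.save(img, tmp_path / "near.nii.gz")
        mask = read_mask(tmp_path / "near.nii.gz", strict_binary=False)
        assert mask.values[1, 2, 3] == 1

    def test_axis_order_permutation(self, tmp_path):
        data = np.zeros((4, 5, 6), dtype=np.uint8)
        data[1, 2, 3] = 1
        img = nib.Nifti1Image(data, np.diag([1.5] * 3 + [1]))
        nib.save(img, tmp_path / "perm.nii.gz")
        mask = read_mask(tmp_path / "perm.nii.gz", axis_order="YXZ")
        assert mask.grid.shape == (5, 4, 6)
        assert mask.values[2, 1, 3] == 1


class TestManifest:
    def test_csv_rows_in_file_order(self, tmp_path):
        path = tmp_path / "m.csv"
        path.write_text("id,path\nc,c.nii\na,a.nii\nb,b.nii\n")
        entries = read_manifest(path)
        assert [e.id for e in entries] == ["c", "a", "b"]

    def test_longitudinal_series_of_five_dated_exams(self, tmp_path):
        dates = ["2009-02-17", "2009-08-10", "2010-02-24", "2011-02-08", "2011-11-23"]
        rows = "".join(f"f1_{i+1},f1_{i+1}.nii,{d}\n" for i, d in enumerate(dates))
        path = tmp_path / "f1.csv"
        path.write_text("id,path,date\n" + rows)
        entries = read_manifest(path)
        assert len(entries) == 5
        assert entries[0].exam_date == dt.date(2009, 2, 17)
        assert entries[-1].exam_date == dt.date(2011, 11, 23)

    def test_json_manifest(self, tmp_path):
        path = tmp_path / "m.json"
        path.write_text(json.dumps([{"id": "x", "path": "x.nii", "date": "2010-01-02"}]))
        entries = read_manifest(path)
        assert entries[0].exam_date == dt.date(2010, 1, 2)

    def test_empty_manifest(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("id,path\n")
        assert read_manifest(path) == []

    def test_duplicate_id_same_date_rejected(self, tmp_path):
        path = tmp_path / "dup.csv"
        path.write_text("id,path,date\nf1,a.nii,2010-01-01\nf1,b.nii,2010-01-01\n")
        with pytest.raises(ManifestError, match="duplicate"):
            read_manifest(path)

    def test_same_id_different_dates_allowed(self, tmp_path):
        path = tmp_path / "ok.csv"
        path.write_text("id,path,date\nf1,a.nii,2010-01-01\nf1,b.nii,2010-06-01\n")
        assert len(read_manifest(path)) == 2
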