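"""Volume I/O, normalization, resampling and volume computation."""

import numpy as np
import pytest

from ovaseg.errors import DegenerateInputError, ShapeError
from ovaseg.volume_io import (
    LabelMap,
    Volume3D,
    normalize_volume,
    read_nifti,
    resample_slice_stack,
    restack_to_volume,
    volume_cc,
    write_nifti,
)


class TestNiftiRoundTrip:
    def test_volume_round_trip_preserves_values_shape_spacing(self, tmp_path, rng):
        v = Volume3D(rng.random((10, 12, 6)), spacing=(0.7, 0.7, 3.0))
        path = write_nifti(v, tmp_path / "v.nii.gz")
        back = read_nifti(path)
        np.testing.assert_allclose(back.voxels, v.voxels, rtol=1e-6)
        assert back.shape == v.shape
        np.testing.assert_allclose(back.spacing, v.spacing, rtol=1e-6)

    def test_mask_values_binarized_on_read(self, tmp_path):
        raw = np.zeros((4, 4, 2))
        raw[1, 1, 0] = 255  # label files are sometimes stored as {0, 255}
        lm = LabelMap(raw, spacing=(1, 1, 1))
        path = write_nifti(lm, tmp_path / "m.nii")
        back = read_nifti(path, as_mask=True)
        assert set(np.unique(back.mask)) <= {0, 1}
        assert back.mask.sum() == 1

    def test_missing_file_raises(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_nifti(tmp_path / "absent.nii.gz")

    def test_non_3d_image_rejected(self, tmp_path):
        import nibabel as nib

        img = nib.Nifti1Image(np.zeros((4, 4, 2, 3), dtype=np.float32), np.eye(4))
        nib.save(img, str(tmp_path / "4d.nii.gz"))
        with pytest.raises(ShapeError):
            read_nifti(tmp_path / "4d.nii.gz")


class TestNormalize:
    def test_output_spans_unit_interval(self, rng):
        v = Volume3D(rng.normal(50, 20, size=(20, 20, 10)), spacing=(1, 1, 1))
        out = normalize_volume(v)
        assert out.voxels.min() == 0.0
        assert out.voxels.max() == 1.0

    def test_value_at_high_percentile_maps_to_one(self, rng):
        v = Volume3D(rng.random((10, 10, 10)) * 100, spacing=(1, 1, 1))
        q99 = np.percentile(v.voxels, 99, method="higher")
        out = normalize_volume(v)
        # voxels clipped at the 99th percentile all map to exactly 1
        assert np.all(out.voxels[v.voxels >= q99] == 1.0)

    def test_linear_ramp_low_percentile_maps_to_zero(self):
        # independent oracle: sort the ramp and pick the order statistics
        raw = np.arange(1000, dtype=float)
        v = Volume3D(raw.reshape(10, 10, 10), spacing=(1, 1, 1))
        srt = np.sort(raw)
        q_low = srt[int(np.floor(0.01 * (len(raw) - 1)))]
        q_high = srt[int(np.ceil(0.99 * (len(raw) - 1)))]
        out = normalize_volume(v)
        below = v.voxels <= q_low
        assert below.any()
        np.testing.assert_allclose(out.voxels[below], 0.0, atol=1e-12)
        expected = (raw[500] - q_low) / (q_high - q_low)
        assert out.voxels.ravel()[500] == pytest.approx(expected)

    def test_idempotent(self, rng):
        v = Volume3D(rng.random((12, 12, 8)), spacing=(1, 1, 1))
        once = normalize_volume(v)
        twice = normalize_volume(once)
        np.testing.assert_allclose(twice.voxels, once.voxels, atol=1e-10)

    def test_constant_volume_rejected(self):
        v = Volume3D(np.full((5, 5, 5), 3.0), spacing=(1, 1, 1))
        with pytest.raises(DegenerateInputError):
            normalize_volume(v)


class TestResample:
    def test_identity_when_grid_matches(self, rng):
        v = Volume3D(rng.random((16, 16, 4)), spacing=(2.0, 2.0, 5.0))
        stack = resample_slice_stack(v, out_size=16, out_spacing=2.0)
        assert len(stack) == 4
        np.testing.assert_allclose(
            stack.slices, np.moveaxis(v.voxels, 2, 0), atol=1e-12
        )

    def test_mask_resampling_stays_binary(self, rng):
        m = LabelMap((rng.random((20, 20, 3)) > 0.6), spacing=(1.0, 1.0, 5.0))
        stack = resample_slice_stack(m, out_size=32, out_spacing=0.8)
        assert set(np.unique(stack.slices)) <= {0.0, 1.0}
        assert len(stack) == 3

    def test_line_survives_downsampling_at_mapped_position(self):
        # single-voxel-wide vertical line at x-index 8; 2x downsampling by
        # doubling the spacing; nearest neighbour maps output index 4 -> input 8
        vox = np.zeros((16, 16, 1))
        vox[8, :, 0] = 1.0
        m = LabelMap(vox, spacing=(1.0, 1.0, 1.0))
        stack = resample_slice_stack(m, out_size=8, out_spacing=2.0)
        out = stack.slices[0]
        assert np.all(out[4, :] == 1.0)
        assert out.sum() == 8

    def test_restack_inverts_resampling_on_matching_grid(self, rng):
        v = Volume3D(rng.random((16, 16, 5)), spacing=(2.0, 2.0, 5.0))
        m = LabelMap((rng.random((16, 16, 5)) > 0.7), spacing=v.spacing)
        stack = resample_slice_stack(m, out_size=16, out_spacing=2.0)
        back = restack_to_volume(stack, v, is_mask=True)
        np.testing.assert_array_equal(back, m.mask)


class TestVolumeCC:
    @pytest.mark.parametrize(
        "n_voxels,spacing,expected",
        [
            (0, (1, 1, 1), 0.0),
            (1000, (1, 1, 1), 1.0),
            (8, (5, 5, 5), 1.0),  # 8 * 125 mm^3 = 1 cc
        ],
    )
    def test_known_volumes(self, n_voxels, spacing, expected):
        vox = np.zeros((10, 10, 10))
        vox.ravel()[:n_voxels] = 1
        lm = LabelMap(vox, spacing=spacing)
        assert volume_cc(lm) == pytest.approx(expected)

    def test_additive_over_disjoint_masks(self, rng):
        a = rng.random((10, 10, 10)) > 0.7
        b = (rng.random((10, 10, 10)) > 0.7) & ~a
        sp = (1.3, 0.9, 2.1)
        total = volume_cc(LabelMap(a | b, spacing=sp))
        parts = volume_cc(LabelMap(a, spacing=sp)) + volume_cc(LabelMap(b, spacing=sp))
        assert total == pytest.approx(parts)
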