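"""Dose grid container invariants and volume file round-trips."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import imptrobust as ir
from imptrobust._errors import (
    EmptyROIError,
    LatticeMismatchError,
    NonFiniteDoseError,
    NonPositiveSpacingError,
    NotAVolumeError,
    UnsupportedFormatError,
)


def random_grid(seed, shape=(8, 8, 8), spacing=(2.5, 2.5, 2.5), origin=(1.0, -2.0, 3.0)):
    rng = np.random.default_rng(seed)
    return ir.DoseGrid(rng.uniform(0.0, 70.0, shape), spacing, origin)


class TestDoseGrid:
    def test_voxel_volume_from_spacing(self):
        g = ir.DoseGrid(np.ones((4, 4, 4)), (2.5, 2.5, 2.5))
        assert g.voxel_volume_cc == pytest.approx(0.015625, abs=0)

    @pytest.mark.parametrize(
        "values,spacing,err",
        [
            (np.ones((4, 4)), (1, 1, 1), NotAVolumeError),
            (np.full((2, 2, 2), np.nan), (1, 1, 1), NonFiniteDoseError),
            (np.ones((2, 2, 2)), (1, -1, 1), NonPositiveSpacingError),
            (np.ones((2, 2, 2)), (1, 0, 1), NonPositiveSpacingError),
        ],
    )
    def test_invalid_grids_rejected(self, values, spacing, err):
        with pytest.raises(err):
            ir.DoseGrid(values, spacing)

    def test_mask_grid_shape_agreement_enforced(self):
        g = random_grid(0, shape=(6, 6, 6))
        roi = ir.ROIMask(np.ones((5, 6, 6), bool), "r", "oar", rx=60.0)
        with pytest.raises(LatticeMismatchError):
            ir.compute_dvh(g, roi)

    def test_empty_roi_rejected(self):
        with pytest.raises(EmptyROIError):
            ir.ROIMask(np.zeros((4, 4, 4), bool), "empty", "oar", rx=60.0)


class TestVolumeIO:
    @pytest.mark.parametrize("suffix", [".nrrd", ".nii.gz"])
    def test_roundtrip_values_and_metadata(self, tmp_path, suffix):
        g = random_grid(3)
        path = ir.write_volume(g, tmp_path / f"vol{suffix}")
        g2 = ir.read_volume(path)
        assert np.array_equal(g.values, g2.values)
        assert max(abs(a - b) for a, b in zip(g.spacing, g2.spacing)) <= 1e-9
        assert max(abs(a - b) for a, b in zip(g.origin, g2.origin)) <= 1e-9

    def test_zero_grid_roundtrip(self, tmp_path):
        g = ir.DoseGrid(np.zeros((4, 4, 4)), (1.0, 1.0, 1.0))
        g2 = ir.read_volume(ir.write_volume(g, tmp_path / "z.nrrd"))
        assert g2.values.max() == 0.0

    def test_nan_grid_rejected_before_writing(self, tmp_path):
        with pytest.raises(NonFiniteDoseError):
            ir.DoseGrid(np.full((2, 2, 2), np.nan), (1, 1, 1))
        assert not any(tmp_path.iterdir())

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            ir.read_volume(tmp_path / "nope.nrrd")

    def test_unknown_suffix(self, tmp_path):
        (tmp_path / "x.foo").write_text("")
        with pytest.raises(UnsupportedFormatError):
            ir.read_volume(tmp_path / "x.foo")

    def test_two_dimensional_payload_rejected(self, tmp_path):
        import nibabel as nib

        nib.save(nib.Nifti1Image(np.ones((4, 4)), np.eye(4)), tmp_path / "flat.nii")
        with pytest.raises(NotAVolumeError):
            ir.read_volume(tmp_path / "flat.nii")

    def test_mask_roundtrip_nonzero_inside(self, tmp_path):
        g = random_grid(4, shape=(6, 6, 6))
        mask = ir.ROIMask(g.values > 35.0, "half", "oar", rx=60.0)
        from imptrobust.grids_io import write_mask

        p = write_mask(mask, g, tmp_path / "m.nrrd")
        m2 = ir.read_mask(p, "half", "oar", rx=60.0)
        assert np.array_equal(mask.mask, m2.mask)

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(
        seed=st.integers(0, 10_000),
        spacing=st.sampled_from([(1.0, 1.0, 1.0), (1.25, 2.0, 2.5), (3.0, 3.0, 3.0)]),
    )
    def test_roundtrip_property(self, tmp_path_factory, seed, spacing):
        tmp = tmp_path_factory.mktemp("rt")
        g = random_grid(seed, shape=(5, 4, 3), spacing=spacing)
        g2 = ir.read_volume(ir.write_volume(g, tmp / "v.nrrd"))
        assert np.array_equal(g.values, g2.values)
        assert g.same_lattice(g2)


class TestDicomRTDose:
    def _make_rtdose(self, path, arr, scaling=0.01):
        import pydicom
        from pydicom.dataset import Dataset, FileMetaDataset
        from pydicom.uid import ExplicitVRLittleEndian, generate_uid

        ds = Dataset()
        ds.Modality = "RTDOSE"
        ds.SOPClassUID = "1.2.840.10008.5.1.4.1.1.481.2"
        ds.SOPInstanceUID = generate_uid()
        ds.NumberOfFrames, ds.Rows, ds.Columns = arr.shape
        ds.BitsAllocated = ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.DoseGridScaling = scaling
        ds.PixelSpacing = [2.0, 3.0]
        ds.GridFrameOffsetVector = [2.5 * k for k in range(arr.shape[0])]
        ds.ImagePositionPatient = [1.0, 2.0, 3.0]
        ds.PixelData = arr.tobytes()
        meta = FileMetaDataset()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        meta.MediaStorageSOPClassUID = ds.SOPClassUID
        meta.MediaStorageSOPInstanceUID = ds.SOPInstanceUID
        ds.file_meta = meta
        ds.save_as(path, enforce_file_format=True)

    def test_rtdose_scaled_to_gy(self, tmp_path):
        rng = np.random.default_rng(5)
        arr = rng.integers(0, 4000, (4, 6, 5)).astype(np.uint16)
        self._make_rtdose(tmp_path / "d.dcm", arr)
        g = ir.read_volume(tmp_path / "d.dcm")
        # axis order: cols -> L/R, rows -> A/P, frames -> S/I
        assert g.shape == (5, 6, 4)
        assert g.spacing == (3.0, 2.0, 2.5)
        assert np.allclose(g.values, np.transpose(arr, (2, 1, 0)) * 0.01)

    def test_non_rtdose_rejected(self, tmp_path):
        rng = np.random.default_rng(5)
        arr = rng.integers(0, 10, (2, 2, 2)).astype(np.uint16)
        import pydicom

        self._make_rtdose(tmp_path / "d.dcm", arr)
        ds = pydicom.dcmread(tmp_path / "d.dcm")
        ds.Modality = "CT"
        ds.save_as(tmp_path / "ct.dcm", enforce_file_format=True)
        with pytest.raises(UnsupportedFormatError):
            ir.read_volume(tmp_path / "ct.dcm", format="dicom_rtdose")


class TestAxialSlice:
    def test_uniform_grid_gives_uniform_slice(self):
        g = ir.DoseGrid(np.full((4, 5, 6), 2.0), (1, 1, 1))
        assert np.all(ir.extract_axial_slice(g, 2) == 2.0)

    def test_slice_matches_voxel_loop(self):
        g = random_grid(9, shape=(5, 6, 7))
        k = 4
        expected = np.array(
            [[g.values[i, j, k] for j in range(6)] for i in range(5)]
        )
        assert np.array_equal(ir.extract_axial_slice(g, k), expected)

    def test_index_at_extent_is_out_of_range(self):
        g = random_grid(9, shape=(5, 6, 7))
        with pytest.raises(IndexError):
            ir.extract_axial_slice(g, 7)
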