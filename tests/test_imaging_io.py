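"""SUV calibration, resampling, reformation and slice-fit geometry."""

from datetime import datetime, timedelta

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from petseg.imaging_io import (CalibrationError, F18_HALF_LIFE_S, Modality,
                               SuvCalibration, VoxelGrid, compute_suv,
                               fit_slice, load_study, reformat,
                               resample_isotropic, restack, save_volume,
                               unfit_slice, load_volume)

T0 = datetime(2024, 1, 1, 10, 0, 0)


def _cal(dose_bq=3.5e8, weight_g=70_000.0, uptake_s=0.0):
    return SuvCalibration(
        injected_dose_bq=dose_bq, patient_weight_g=weight_g,
        injection_time=T0, acquisition_time=T0 + timedelta(seconds=uptake_s))


def _activity(value, shape=(4, 4, 4)):
    return VoxelGrid(np.full(shape, float(value)), (2, 2, 2),
                     Modality.PET_ACTIVITY)


class TestSuv:
    def test_closed_form_unit_suv(self):
        """5000 Bq/mL, 70 kg, 350 MBq, zero uptake time -> SUV exactly 1."""
        suv = compute_suv(_activity(5000.0), _cal())
        assert suv.modality is Modality.PET_SUV
        assert np.allclose(suv.data, 1.0)

    def test_one_half_life_doubles_suv(self):
        """After one half-life the decay-corrected dose halves -> SUV 2."""
        suv = compute_suv(_activity(5000.0), _cal(uptake_s=F18_HALF_LIFE_S))
        assert np.allclose(suv.data, 2.0)

    def test_zero_activity_gives_zero_suv(self):
        assert np.all(compute_suv(_activity(0.0), _cal()).data == 0.0)

    def test_linearity_in_activity(self):
        """compute_suv(a*x) == a*compute_suv(x) for a >= 0."""
        base = compute_suv(_activity(1234.5), _cal(uptake_s=600.0)).data
        for a in (0.0, 0.5, 3.0):
            scaled = compute_suv(_activity(1234.5 * a), _cal(uptake_s=600.0)).data
            assert np.allclose(scaled, a * base)

    def test_incomplete_or_invalid_calibration_rejected(self):
        with pytest.raises(CalibrationError):
            compute_suv(_activity(1.0), SuvCalibration())
        with pytest.raises(CalibrationError):
            compute_suv(_activity(1.0), _cal(dose_bq=-1.0))
        with pytest.raises(CalibrationError):
            compute_suv(_activity(1.0), _cal(uptake_s=-60.0))


class TestResample:
    def test_constant_volume_preserved_exactly(self):
        g = VoxelGrid(np.full((10, 12, 14), 7.5), (4, 4, 4), Modality.CT_HU)
        out = resample_isotropic(g, 2.0)
        assert out.spacing == (2.0, 2.0, 2.0)
        assert np.allclose(out.data, 7.5)
        # physical extent preserved within one voxel per axis
        for n_in, s_in, n_out in zip(g.shape, g.spacing, out.shape):
            assert abs(n_in * s_in - n_out * 2.0) <= 2.0

    def test_mask_resampling_stays_binary(self):
        rng = np.random.default_rng(0)
        m = (rng.random((9, 9, 9)) > 0.5).astype(np.uint8)
        out = resample_isotropic(VoxelGrid(m, (3, 3, 3), Modality.MASK), 2.0)
        assert set(np.unique(out.data)) <= {0, 1}

    def test_ramp_mean_preserved_within_one_percent(self):
        """A linear ramp's mean intensity survives linear resampling."""
        z = np.arange(40, dtype=float)
        ramp = np.broadcast_to(z[:, None, None], (40, 20, 20)).copy()
        g = VoxelGrid(ramp, (4, 4, 4), Modality.PET_SUV)
        out = resample_isotropic(g, 2.0)
        assert abs(out.data.mean() - ramp.mean()) / ramp.mean() < 0.01

    def test_idempotent_at_target_spacing(self):
        rng = np.random.default_rng(1)
        g = VoxelGrid(rng.random((8, 8, 8)), (2, 2, 2), Modality.PET_SUV)
        out = resample_isotropic(g, 2.0)
        assert np.abs(out.data - g.data).max() < 1e-6


class TestReformat:
    def test_slice_counts_and_shapes(self):
        vol = np.zeros((200, 224, 256))
        assert len(reformat(vol, "axial")) == 200
        assert reformat(vol, "axial")[0].shape == (224, 256)
        cor = reformat(vol, "coronal")
        assert len(cor) == 224 and cor[0].shape == (200, 256)
        sag = reformat(vol, "sagittal")
        assert len(sag) == 256 and sag[0].shape == (200, 224)

    @pytest.mark.parametrize("plane", ["axial", "coronal", "sagittal"])
    def test_restack_is_inverse(self, plane):
        rng = np.random.default_rng(2)
        vol = rng.random((12, 10, 14))
        assert np.array_equal(restack(reformat(vol, plane), plane), vol)


class TestFitSlice:
    @given(st.tuples(st.integers(5, 700), st.integers(5, 700)))
    @settings(max_examples=40, deadline=None)
    def test_fit_then_unfit_recovers_original_support(self, shape):
        """Center-crop + pad to 448x512 inverts exactly on the kept window."""
        rng = np.random.default_rng(3)
        img = rng.random(shape)
        fitted, geom = fit_slice(img, (448, 512))
        assert fitted.shape == (448, 512)
        back = unfit_slice(fitted, geom)
        assert back.shape == shape
        (c0, c1), (k0, k1) = geom.crop_start, geom.kept_shape
        kept = (slice(c0, c0 + k0), slice(c1, c1 + k1))
        assert np.array_equal(back[kept], img[kept])
        # outside the kept window the inverse embeds zeros
        mask = np.ones(shape, bool)
        mask[kept] = False
        assert np.all(back[mask] == 0)

    def test_small_slice_gets_symmetric_zero_border(self):
        img = np.ones((224, 256))
        fitted, geom = fit_slice(img)
        assert fitted.sum() == img.size  # all ones kept
        assert geom.pad_start == ((448 - 224) // 2, (512 - 256) // 2)

    def test_all_zero_input_stays_zero(self):
        fitted, _ = fit_slice(np.zeros((100, 600)))
        assert not fitted.any()


class TestIO:
    def test_nifti_roundtrip_preserves_grid(self, tmp_path):
        rng = np.random.default_rng(4)
        g = VoxelGrid(rng.random((10, 12, 14)), (2, 2, 2), Modality.PET_SUV)
        save_volume(g, tmp_path / "x.nii.gz")
        back = load_volume(tmp_path / "x.nii.gz", Modality.PET_SUV)
        assert back.shape == g.shape
        assert back.spacing == g.spacing
        assert np.abs(back.data - g.data).max() < 1e-5

    def test_nifti_identity_load_shape_and_spacing(self, tmp_path):
        g = VoxelGrid(np.zeros((22, 24, 26)), (4, 4, 4), Modality.CT_HU)
        save_volume(g, tmp_path / "ct.nii.gz")
        study = load_study(tmp_path / "ct.nii.gz", tmp_path / "ct.nii.gz")
        assert study.ct.shape == (22, 24, 26)
        assert study.ct.spacing == (4.0, 4.0, 4.0)
        assert not study.calibration.is_complete  # NIfTI carries no dose info

    def test_dicom_series_rescale_and_calibration(self, tmp_path):
        import pydicom
        from pydicom.dataset import Dataset, FileMetaDataset
        from pydicom.uid import ExplicitVRLittleEndian, generate_uid

        series = generate_uid()
        for i in range(3):
            ds = Dataset()
            ds.file_meta = FileMetaDataset()
            ds.file_meta.TransferSyntaxUID = ExplicitVRLittleEndian
            ds.file_meta.MediaStorageSOPClassUID = generate_uid()
            ds.file_meta.MediaStorageSOPInstanceUID = generate_uid()
            ds.PatientID = "P001"
            ds.PatientWeight = 70.0
            ds.SeriesInstanceUID = series
            ds.Rows = ds.Columns = 4
            ds.BitsAllocated = 16
            ds.BitsStored = 16
            ds.HighBit = 15
            ds.PixelRepresentation = 0
            ds.SamplesPerPixel = 1
            ds.PhotometricInterpretation = "MONOCHROME2"
            ds.RescaleSlope = 2.0
            ds.RescaleIntercept = 0.0
            ds.PixelSpacing = [2.0, 2.0]
            ds.SliceThickness = 2.0
            ds.ImagePositionPatient = [0.0, 0.0, -2.0 * i]
            ds.AcquisitionDate = "20240101"
            ds.AcquisitionTime = "110000"
            rpi = Dataset()
            rpi.RadionuclideTotalDose = 3.5e8
            rpi.RadionuclideHalfLife = 6586.2
            rpi.RadiopharmaceuticalStartTime = "100000"
            ds.RadiopharmaceuticalInformationSequence = [rpi]
            ds.PixelData = np.full((4, 4), 100, np.uint16).tobytes()
            ds.SOPInstanceUID = ds.file_meta.MediaStorageSOPInstanceUID
            pydicom.dcmwrite(tmp_path / f"s{i}.dcm", ds,
                             enforce_file_format=True)
        study = load_study(tmp_path, tmp_path)
        # stored value 100 with slope 2 -> activity 200
        assert np.allclose(study.pet.data, 200.0)
        cal = study.calibration
        assert cal.is_complete
        assert cal.patient_weight_g == 70_000.0
        assert cal.uptake_time_s == 3600.0


class TestVoxelGridInvariants:
    def test_rejects_nan_and_nonpositive_spacing(self):
        with pytest.raises(ValueError):
            VoxelGrid(np.full((2, 2, 2), np.nan), (2, 2, 2), Modality.CT_HU)
        with pytest.raises(ValueError):
            VoxelGrid(np.zeros((2, 2, 2)), (0, 2, 2), Modality.CT_HU)

    def test_mask_and_prob_domains_enforced(self):
        with pytest.raises(ValueError):
            VoxelGrid(np.full((2, 2, 2), 2.0), (2, 2, 2), Modality.MASK)
        with pytest.raises(ValueError):
            VoxelGrid(np.full((2, 2, 2), 1.5), (2, 2, 2), Modality.PROB)
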