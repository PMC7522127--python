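"""Cascade stages: 2D prediction, components, patches, refinement, fusion."""

import numpy as np
import pytest

from petseg.anatomy import Region, RegionMap
from petseg.cascade import (CascadeConfig, extract_patches, fuse_masks,
                            label_components, predict_2d, refine_3d,
                            run_pipeline)
from petseg.imaging_io import Modality, PetCtStudy, VoxelGrid
from petseg.losses_metrics import dice_score

from conftest import ConstantModel, TruthEcho2D, TruthEcho3D


def _regions_for(shape, z_top, z_bottom):
    labels = np.full(shape, int(Region.ABDOMEN_PELVIS), np.int8)
    labels[:z_top] = int(Region.HEAD_NECK)
    labels[z_top:z_bottom] = int(Region.CHEST)
    return RegionMap(labels, z_top, z_bottom)


def _study_from(pet, ct=None):
    pet = np.asarray(pet, float)
    ct = np.zeros_like(pet) if ct is None else ct
    return PetCtStudy(pet=VoxelGrid(pet, (2, 2, 2), Modality.PET_SUV),
                      ct=VoxelGrid(ct, (2, 2, 2), Modality.CT_HU))


class TestPredict2D:
    def test_constant_model_gives_constant_volume(self):
        study = _study_from(np.zeros((12, 16, 16)))
        out = predict_2d(study, ConstantModel(0.5), CascadeConfig())
        assert out.modality is Modality.PROB
        assert out.shape == (12, 16, 16)
        assert np.allclose(out.data, 0.5)

    def test_orientations_are_averaged(self):
        """A model answering 1.0 on axial and 0.0 on sagittal averages to 0.5."""
        study = _study_from(np.zeros((8, 8, 8)))

        class PlaneSplit:
            def __init__(self):
                self.calls = 0

            def predict(self, batch):
                n = batch.shape[0]
                self.calls += n
                # first 8 calls are axial slices (plane order is config order)
                val = 1.0 if self.calls <= 8 else 0.0
                return np.full((n, 1) + batch.shape[2:], val)

        cfg = CascadeConfig(orientations=("axial", "sagittal"), batch_slices=8)
        out = predict_2d(study, PlaneSplit(), cfg)
        assert np.allclose(out.data, 0.5)

    def test_truth_echo_round_trips_exactly(self, default_phantom):
        study, truth = default_phantom
        cfg = CascadeConfig(orientations=("axial", "sagittal"), batch_slices=8)
        echo = TruthEcho2D(truth.tumor_mask, cfg.orientations)
        out = predict_2d(study, echo, cfg)
        assert np.array_equal(out.data >= 0.5, truth.tumor_mask > 0)


class TestComponents:
    def test_blobs_assigned_to_centroid_region(self):
        prob = np.zeros((30, 16, 16))
        prob[5:8, 4:7, 4:7] = 0.9     # head-neck blob
        prob[20:23, 8:11, 8:11] = 0.8  # abdomen blob
        grid = VoxelGrid(prob, (2, 2, 2), Modality.PROB)
        comps = label_components(grid, _regions_for(prob.shape, 10, 18))
        assert len(comps) == 2
        regions = {c.region for c in comps.components}
        assert regions == {Region.HEAD_NECK, Region.ABDOMEN_PELVIS}

    def test_empty_probability_yields_empty_set(self):
        grid = VoxelGrid(np.zeros((10, 8, 8)), (2, 2, 2), Modality.PROB)
        comps = label_components(grid, _regions_for((10, 8, 8), 3, 6))
        assert len(comps) == 0

    def test_subthreshold_blob_ignored(self):
        prob = np.full((10, 8, 8), 0.49)
        grid = VoxelGrid(prob, (2, 2, 2), Modality.PROB)
        assert len(label_components(grid, _regions_for((10, 8, 8), 3, 6))) == 0

    def test_threshold_is_inclusive(self):
        prob = np.zeros((10, 8, 8))
        prob[4, 4, 4] = 0.5
        grid = VoxelGrid(prob, (2, 2, 2), Modality.PROB)
        assert len(label_components(grid, _regions_for((10, 8, 8), 3, 6))) == 1


class TestPatches:
    def _components(self, prob_arr, z_top, z_bottom):
        grid = VoxelGrid(prob_arr, (2, 2, 2), Modality.PROB)
        return label_components(grid, _regions_for(prob_arr.shape, z_top,
                                                   z_bottom))

    def test_small_component_gets_single_centred_cube(self):
        prob = np.zeros((40, 40, 40))
        prob[4:8, 10:14, 10:14] = 1.0
        comps = self._components(prob, 20, 30)
        ps = extract_patches(comps, _study_from(prob),
                             CascadeConfig(patch_edges={r: 32 for r in Region}))
        assert len(ps) == 1
        patch = ps.patches[0]
        assert patch.edge == 32
        assert patch.pet.shape == (32, 32, 32)

    def test_oversized_component_tiled_with_overlap(self):
        prob = np.zeros((30, 100, 30))
        prob[10:13, 5:95, 10:13] = 1.0  # 90 voxels long in y
        comps = self._components(prob, 5, 25)
        cfg = CascadeConfig(patch_edges={r: 32 for r in Region})
        ps = extract_patches(comps, _study_from(prob), cfg)
        assert len(ps) >= 2
        starts = sorted(p.start[1] for p in ps.patches)
        # 50% overlap tiling: consecutive starts differ by edge/2
        assert all(b - a == 16 for a, b in zip(starts, starts[1:-1]))
        covered_lo = min(s for s in starts)
        covered_hi = max(s for s in starts) + 32
        assert covered_lo <= 5 and covered_hi >= 95

    def test_corner_component_zero_padded_with_exact_inverse(self):
        prob = np.zeros((40, 40, 40))
        prob[0:3, 0:3, 0:3] = 1.0
        comps = self._components(prob, 20, 30)
        pet = np.arange(40 ** 3, dtype=float).reshape(40, 40, 40)
        ps = extract_patches(comps, _study_from(pet * 0 + prob),
                             CascadeConfig(patch_edges={r: 32 for r in Region}))
        patch = ps.patches[0]
        assert any(s < 0 for s in patch.start)  # clipped at the corner
        # gather/scatter inverse: refine with an echo model reproduces values
        echo = TruthEcho3D(prob)
        vol = refine_3d(ps, {r: echo for r in Region})
        inside = prob > 0
        assert np.array_equal(vol.data[inside] > 0.5, prob[inside] > 0.5)


class TestRefine3D:
    def test_overlapping_patch_predictions_averaged(self):
        from petseg.cascade import Patch, PatchSet

        shape = (20, 20, 20)
        p1 = Patch(1, Region.CHEST, (0, 0, 0), 16,
                   np.zeros((16,) * 3, np.float32), np.zeros((16,) * 3, np.float32))
        p2 = Patch(1, Region.CHEST, (0, 0, 8), 16,
                   np.zeros((16,) * 3, np.float32), np.zeros((16,) * 3, np.float32))

        class Fixed:
            def __init__(self, v):
                self.v = v

            def predict_patch(self, patch):
                return np.full((patch.edge,) * 3, self.v)

        class Alternating:
            def __init__(self):
                self.vals = iter([0.4, 0.8])

            def predict_patch(self, patch):
                return np.full((patch.edge,) * 3, next(self.vals))

        ps = PatchSet([p1, p2], shape)
        vol = refine_3d(ps, {Region.CHEST: Alternating()})
        assert np.allclose(vol.data[0, 0, 9], 0.6)   # overlap: (0.4+0.8)/2
        assert np.allclose(vol.data[0, 0, 2], 0.4)   # only patch 1
        assert np.allclose(vol.data[19, 19, 19], 0.0)  # outside all patches

    def test_empty_patchset_gives_zero_volume(self):
        from petseg.cascade import PatchSet

        vol = refine_3d(PatchSet([], (8, 8, 8)), {})
        assert not vol.data.any()

    def test_missing_region_model_raises(self):
        from petseg.cascade import Patch, PatchSet

        p = Patch(1, Region.CHEST, (0, 0, 0), 8,
                  np.zeros((8,) * 3, np.float32), np.zeros((8,) * 3, np.float32))
        with pytest.raises(KeyError):
            refine_3d(PatchSet([p], (8, 8, 8)), {Region.HEAD_NECK: None})


class TestFusion:
    def test_fusing_identical_masks_is_identity(self):
        rng = np.random.default_rng(0)
        m = (rng.random((8, 8, 8)) > 0.5).astype(float)
        assert np.array_equal(fuse_masks(m, m), m.astype(np.uint8))

    def test_half_average_tie_is_positive(self):
        one = np.ones((4, 4, 4))
        zero = np.zeros((4, 4, 4))
        assert fuse_masks(one, zero).all()

    def test_sub_half_average_is_negative(self):
        a = np.full((4, 4, 4), 0.4)
        assert not fuse_masks(a, a).any()

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            fuse_masks(np.zeros((2, 2, 2)), np.zeros((3, 3, 3)))


class TestPipeline:
    def test_truth_echo_stubs_reproduce_ground_truth_exactly(self,
                                                             default_phantom):
        """With oracle stubs the end-to-end mask equals phantom truth."""
        study, truth = default_phantom
        cfg = CascadeConfig(orientations=("axial", "sagittal"), batch_slices=8)
        model2d = TruthEcho2D(truth.tumor_mask, cfg.orientations)
        models3d = {r: TruthEcho3D(truth.tumor_mask) for r in Region}
        result = run_pipeline(study, model2d, models3d, cfg)
        assert dice_score(result.mask.data > 0, truth.tumor_mask > 0) == 1.0
        assert result.metrics.n_lesions == len(truth.tumors)
        assert result.metrics.tmtv_ml == pytest.approx(truth.tmtv_ml)

    def test_zero_stub_yields_empty_mask_and_zero_tmtv(self, default_phantom):
        study, _ = default_phantom
        result = run_pipeline(study, ConstantModel(0.0),
                              {r: ConstantModel(0.0) for r in Region},
                              CascadeConfig(orientations=("axial",),
                                            batch_slices=8))
        assert not result.mask.data.any()
        assert result.metrics.tmtv_ml == 0.0
        assert result.metrics.suv_max is None

    def test_landmark_failure_falls_back_to_single_region(self):
        """A volume with no detectable anatomy still processes as CHEST."""
        pet = np.zeros((24, 16, 16))
        pet[10:12, 6:8, 6:8] = 4.0
        study = _study_from(pet, ct=np.full((24, 16, 16), 40.0))
        cfg = CascadeConfig(orientations=("axial",), batch_slices=8,
                            patch_edges={r: 16 for r in Region})

        class EchoHot:
            def predict(self, batch):
                return (batch[:, :1] >= 2.5).astype(float)

        result = run_pipeline(study, EchoHot(),
                              {r: TruthEcho3D((pet >= 2.5).astype(np.uint8))
                               for r in Region}, cfg)
        assert result.regions is not None
        assert np.all(result.regions.labels == int(Region.CHEST))
        assert result.mask.data.any()

    def test_inference_is_deterministic(self, default_phantom):
        study, truth = default_phantom
        cfg = CascadeConfig(orientations=("axial",), batch_slices=8)
        masks = []
        for _ in range(2):
            m2 = TruthEcho2D(truth.tumor_mask, cfg.orientations)
            m3 = {r: TruthEcho3D(truth.tumor_mask) for r in Region}
            masks.append(run_pipeline(study, m2, m3, cfg).mask.data)
        assert np.array_equal(masks[0], masks[1])

    def test_final_mask_confined_to_evaluated_support(self, default_phantom):
        """No probability is invented outside patches + 2D-positive voxels."""
        study, truth = default_phantom
        cfg = CascadeConfig(orientations=("axial",), batch_slices=8)
        m2 = TruthEcho2D(truth.tumor_mask, cfg.orientations)
        m3 = {r: ConstantModel(1.0) for r in Region}
        result = run_pipeline(study, m2, m3, cfg)
        support_2d = truth.tumor_mask > 0
        outside = result.mask.data.astype(bool) & ~support_2d
        # positives outside the 2D support must lie in some evaluated patch
        assert outside.sum() == 0 or result.prob_3d.data[outside].min() > 0
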