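"""Voxel phantom loading, synthesis, label surgery, and voxelization."""

import numpy as np
import pytest
import trimesh

from phantomforge import phantom as ph
from phantomforge.errors import (
    EmptyRegionError,
    FeasibilityError,
    ShapeMismatchError,
    ValidationError,
    WatertightError,
)


class TestLoadVoxelPhantom:
    def test_empty_volume_is_valid(self):
        p = ph.load_voxel_phantom(
            np.zeros((2, 2, 2), dtype=np.uint8), (1, 1, 1),
            {1: ("body", "body")},
        )
        assert p.voxel_count(1) == 0

    def test_unknown_label_named_in_error(self):
        labels = np.zeros((3, 3, 3), dtype=np.uint8)
        labels[1, 1, 1] = 5
        with pytest.raises(ValidationError, match="5"):
            ph.load_voxel_phantom(labels, (1, 1, 1), {1: ("body", "body")})

    @pytest.mark.parametrize("spacing", [(0, 1, 1), (1, -2, 1)])
    def test_nonpositive_spacing_rejected(self, spacing):
        with pytest.raises(ValidationError):
            ph.load_voxel_phantom(np.zeros((2, 2, 2), dtype=np.uint8),
                                  spacing, {1: ("x", "other")})

    def test_non_3d_rejected(self):
        with pytest.raises(ShapeMismatchError):
            ph.load_voxel_phantom(np.zeros((4, 4), dtype=np.uint8),
                                  (1, 1, 1), {1: ("x", "other")})

    def test_write_read_round_trip(self, tmp_path, phantom2mm):
        ph.write_phantom(phantom2mm, tmp_path / "p")
        back = ph.read_phantom(tmp_path / "p")
        assert np.array_equal(back.labels, phantom2mm.labels)
        assert back.spacing == phantom2mm.spacing
        assert back.organ_table == phantom2mm.organ_table

    def test_raw_size_mismatch_reports_bytes(self, tmp_path):
        (tmp_path / "bad.raw").write_bytes(b"\x00" * 7)
        with pytest.raises(ShapeMismatchError, match="8"):
            ph.load_raw_labels(tmp_path / "bad.raw", (2, 2, 2))


class TestSyntheticPhantom:
    def test_volumes_within_5pct_of_design(self, phantom2mm):
        got = phantom2mm.volumes_mL()
        for role, target in ph.DESIGN_VOLUMES_ML.items():
            assert got[role] == pytest.approx(target, rel=0.05), role

    def test_deterministic_for_fixed_seed(self, phantom2mm):
        again = ph.generate_synthetic_phantom(ph.default_synthetic_spec())
        assert np.array_equal(phantom2mm.labels, again.labels)

    def test_different_seed_differs(self, phantom2mm):
        other = ph.generate_synthetic_phantom(
            ph.default_synthetic_spec(seed=1))
        assert not np.array_equal(phantom2mm.labels, other.labels)

    def test_tumour_larger_than_liver_infeasible(self):
        vols = dict(ph.DESIGN_VOLUMES_ML, tumour=2000.0)
        with pytest.raises(FeasibilityError):
            ph.SyntheticSpec(volumes_mL=vols)

    def test_tumour_nested_in_liver(self, phantom2mm):
        tum = phantom2mm.mask(phantom2mm.label_for_role("tumour"))
        liver = phantom2mm.mask(phantom2mm.label_for_role("liver"))
        # every face-neighbour of a tumour voxel is tumour or liver
        from scipy import ndimage
        ring = ndimage.binary_dilation(tum) & ~tum
        assert np.all(liver[ring])

    def test_kidneys_nested_and_disjoint(self, phantom2mm):
        for side in ("L", "R"):
            cortex = phantom2mm.mask(phantom2mm.label_for_role(f"cortex-{side}"))
            med = phantom2mm.mask(phantom2mm.label_for_role(f"medulla-{side}"))
            assert not np.any(cortex & med)
            from scipy import ndimage
            ring = ndimage.binary_dilation(med) & ~med
            assert np.all(cortex[ring]), f"medulla-{side} not enclosed by cortex"

    def test_organs_inside_body_and_disjoint(self, phantom2mm):
        organs = [lab for lab, o in phantom2mm.organ_table.items()
                  if o.role not in ("body", "other")]
        counts = sum(phantom2mm.voxel_count(lab) for lab in organs)
        union = np.isin(phantom2mm.labels, organs)
        assert counts == int(union.sum())  # labels are exclusive by construction
        assert phantom2mm.voxel_count(phantom2mm.label_for_role("body")) > 0

    def test_volume_error_decreases_with_finer_grid(self, phantom2mm):
        fine = ph.generate_synthetic_phantom(
            ph.default_synthetic_spec(spacing_mm=1.0))
        def total_err(p):
            got = p.volumes_mL()
            return sum(abs(got[r] - t) / t
                       for r, t in ph.DESIGN_VOLUMES_ML.items())
        assert total_err(fine) < total_err(phantom2mm)

    def test_two_organ_variant(self):
        p = ph.generate_synthetic_phantom(ph.two_organ_synthetic_spec())
        roles = {o.role for o in p.organ_table.values()}
        assert roles == {"body", "spleen", "cortex-R", "medulla-R"}


class TestMergeLabels:
    def test_pelvis_merged_into_medulla(self):
        labels = np.zeros((10, 10, 10), dtype=np.uint8)
        labels[1:9, 1:9, 1:9] = 1          # cortex
        labels[3:7, 3:7, 3:7] = 2          # medulla
        labels[4:6, 4:6, 4:6] = 3          # renal pelvis
        table = {1: ("cortex", "cortex-L"), 2: ("medulla", "medulla-L"),
                 3: ("renal pelvis", "other")}
        p = ph.load_voxel_phantom(labels, (1, 1, 1), table)
        cortex_before = p.voxel_count(1)
        merged = ph.merge_labels(p, {3: 2})
        assert merged.voxel_count(3) == 0
        assert 3 not in merged.organ_table
        assert merged.voxel_count(1) == cortex_before
        assert merged.voxel_count(2) == p.voxel_count(2) + p.voxel_count(3)
        assert (np.count_nonzero(merged.labels)
                == np.count_nonzero(p.labels))

    def test_identity_mapping_is_noop(self, tiny_phantom):
        out = ph.merge_labels(tiny_phantom, {1: 1})
        assert np.array_equal(out.labels, tiny_phantom.labels)

    def test_unknown_id_named(self, tiny_phantom):
        with pytest.raises(ValidationError, match="99"):
            ph.merge_labels(tiny_phantom, {99: 1})


class TestCleanLabelRegion:
    def test_detached_voxel_reassigned(self, tiny_phantom):
        cleaned, log = ph.clean_label_region(tiny_phantom, 1, 2)
        assert log["detached_moved"] == 1
        assert cleaned.labels[9, 9, 9] == 2

    def test_cavity_of_other_label_absorbed(self, tiny_phantom):
        cleaned, log = ph.clean_label_region(tiny_phantom, 1, 2)
        assert log["cavity_absorbed"] == 1
        assert cleaned.labels[4, 4, 4] == 1
        # organ B proper (outside A) untouched
        assert cleaned.voxel_count(2) == tiny_phantom.voxel_count(2)

    def test_conserves_total_nonzero_count(self, tiny_phantom):
        cleaned, _ = ph.clean_label_region(tiny_phantom, 1, 2)
        assert (np.count_nonzero(cleaned.labels)
                == np.count_nonzero(tiny_phantom.labels))

    def test_already_clean_is_identity(self, tiny_phantom):
        once, _ = ph.clean_label_region(tiny_phantom, 1, 2)
        twice, log = ph.clean_label_region(once, 1, 2)
        assert log == {"detached_moved": 0, "cavity_absorbed": 0}
        assert np.array_equal(once.labels, twice.labels)

    def test_large_cavity_preserved(self):
        # a nested region bigger than the threshold must not be eaten
        labels = np.zeros((14, 14, 14), dtype=np.uint8)
        labels[1:13, 1:13, 1:13] = 1
        labels[4:10, 4:10, 4:10] = 2    # 216 voxels >= default threshold
        p = ph.load_voxel_phantom(labels, (1, 1, 1),
                                  {1: ("a", "other"), 2: ("b", "other")})
        cleaned, log = ph.clean_label_region(p, 1, 2)
        assert log["cavity_absorbed"] == 0
        assert cleaned.voxel_count(2) == 216

    def test_empty_region_errors(self, tiny_phantom):
        tiny_phantom.organ_table[3] = ph.Organ("ghost", "other")
        with pytest.raises(EmptyRegionError):
            ph.clean_label_region(tiny_phantom, 3, 1)


class TestVoxelizeMesh:
    def test_axis_aligned_cube_exact(self):
        cube = trimesh.creation.box(extents=[10, 10, 10])
        cube.apply_translation([6, 6, 6])
        mask = ph.voxelize_mesh(cube, (1, 1, 1), (12, 12, 12))
        assert int(mask.sum()) == 1000
        assert mask[1:11, 1:11, 1:11].all()

    def test_mesh_outside_grid_gives_empty_mask(self):
        ball = trimesh.creation.icosphere(2, 5.0)
        ball.apply_translation([100, 100, 100])
        mask = ph.voxelize_mesh(ball, (1, 1, 1), (10, 10, 10))
        assert not mask.any()

    def test_open_mesh_rejected(self):
        tri = trimesh.Trimesh(vertices=[[0, 0, 0], [1, 0, 0], [0, 1, 0]],
                              faces=[[0, 1, 2]], process=False)
        with pytest.raises(WatertightError):
            ph.voxelize_mesh(tri, (1, 1, 1), (4, 4, 4))

    def test_sphere_volume_within_2pct(self):
        r = 12.0
        ball = trimesh.creation.icosphere(4, r)
        ball.apply_translation([20, 20, 20])
        mask = ph.voxelize_mesh(ball, (1, 1, 1), (40, 40, 40))
        vol = mask.sum() / 1000.0  # mL on a 1 mm grid
        assert vol == pytest.approx(ball.volume / 1000.0, rel=0.02)
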