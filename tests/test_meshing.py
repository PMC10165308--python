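"""Surface extraction, smoothing, volumes, shells, assembly and STL I/O."""

import numpy as np
import pytest
import trimesh

from phantomforge import meshing as me, phantom as ph
from phantomforge.errors import (
    AssemblyError,
    EmptyRegionError,
    InvertedWindingError,
    ParameterError,
    ResolutionError,
    StlParseError,
    WatertightError,
)

TUMOUR_RADIUS_MM = (3.0 * 15.9e3 / (4.0 * np.pi)) ** (1.0 / 3.0)  # 15.58 mm


@pytest.fixture(scope="module")
def ellipsoid_phantom():
    grid = np.zeros((70, 50, 30), dtype=np.uint8)
    c = ph._ellipsoid_mask(grid.shape, 1.0, (35, 25, 15), (30, 20, 10))
    grid[c] = 1
    return ph.load_voxel_phantom(grid, (1, 1, 1), {1: ("ellipsoid", "other")})


class TestExtractSurface:
    def test_ellipsoid_volume_closed_form(self, ellipsoid_phantom):
        m = me.extract_surface(ellipsoid_phantom, 1)
        true = 4.0 / 3.0 * np.pi * 30 * 20 * 10 / 1000.0  # 25.13 mL
        assert me.mesh_volume(m) == pytest.approx(true, rel=0.02)

    def test_empty_region_errors(self, ellipsoid_phantom):
        ellipsoid_phantom.organ_table[2] = ph.Organ("ghost", "other")
        with pytest.raises(EmptyRegionError):
            me.extract_surface(ellipsoid_phantom, 2)

    def test_all_organs_watertight_and_volume_matches_voxels(self, phantom2mm):
        for lab, org in phantom2mm.organ_table.items():
            m = me.extract_surface(phantom2mm, lab)
            assert m.is_watertight, org.role
            vox = phantom2mm.voxel_count(lab) * phantom2mm.voxel_volume_mL
            if phantom2mm.voxel_count(lab) >= 1000:
                assert me.mesh_volume(m) == pytest.approx(vox, rel=0.03), org.role


class TestLaplacianSmooth:
    def test_zero_iterations_is_identity(self, phantom2mm):
        m = me.extract_surface(phantom2mm, phantom2mm.label_for_role("tumour"))
        out = me.laplacian_smooth(m, iterations=0)
        assert np.array_equal(out.vertices, m.vertices)
        assert np.array_equal(out.faces, m.faces)

    def test_area_strictly_decreases_each_iteration(self, phantom2mm):
        m = me.extract_surface(phantom2mm, phantom2mm.label_for_role("tumour"))
        areas = [m.area]
        cur = m
        for _ in range(10):
            cur = me.laplacian_smooth(cur, iterations=1, step=0.5)
            areas.append(cur.area)
        assert all(a1 < a0 for a0, a1 in zip(areas, areas[1:]))

    def test_topology_preserved_and_volume_change_small(self, phantom2mm):
        liver = me.extract_surface(phantom2mm, phantom2mm.label_for_role("liver"))
        sm = me.laplacian_smooth(liver)
        assert np.array_equal(sm.faces, liver.faces)
        assert sm.is_watertight
        assert abs(sm.metadata["smooth_volume_change"]) < 0.05

    def test_displacement_converges_on_sphere(self):
        ball = me.laplacian_smooth(trimesh.creation.icosphere(3, 10.0),
                                   iterations=0)  # copy through the API
        prev = None
        cur = ball
        for _ in range(5):
            nxt = me.laplacian_smooth(cur, iterations=1, step=0.5)
            disp = np.max(np.linalg.norm(nxt.vertices - cur.vertices, axis=1))
            if prev is not None:
                assert disp <= prev * (1 + 1e-9)
            prev, cur = disp, nxt

    @pytest.mark.parametrize("step", [0.0, 1.5, -0.2])
    def test_invalid_step_rejected(self, step):
        with pytest.raises(ParameterError):
            me.laplacian_smooth(trimesh.creation.icosphere(1, 1.0), step=step)


class TestMeshVolume:
    def test_cube_exact(self):
        cube = trimesh.creation.box(extents=[10, 10, 10])
        assert me.mesh_volume(cube) == pytest.approx(1.0, abs=1e-12)

    def test_tumour_icosphere_within_02pct(self):
        ball = trimesh.creation.icosphere(5, TUMOUR_RADIUS_MM)
        assert me.mesh_volume(ball) == pytest.approx(15.9, rel=0.002)

    def test_reversed_winding_rejected(self):
        cube = trimesh.creation.box(extents=[10, 10, 10])
        cube.invert()
        with pytest.raises(InvertedWindingError):
            me.mesh_volume(cube)

    def test_open_mesh_rejected(self):
        tri = trimesh.Trimesh(vertices=[[0, 0, 0], [1, 0, 0], [0, 1, 0]],
                              faces=[[0, 1, 2]], process=False)
        with pytest.raises(WatertightError):
            me.mesh_volume(tri)


class TestExtrudeShell:
    def test_offset_sphere_volume_closed_form(self):
        ball = trimesh.creation.icosphere(4, TUMOUR_RADIUS_MM)
        shell = me.extrude_shell(ball, 2.0)
        true = 4.0 / 3.0 * np.pi * (TUMOUR_RADIUS_MM + 2.0) ** 3 / 1000.0
        assert me.mesh_volume(shell.outer) == pytest.approx(true, rel=0.01)
        assert me.mesh_volume(shell.outer) > me.mesh_volume(shell.inner)

    @pytest.mark.parametrize("thickness", [0.0, -1.0])
    def test_nonpositive_thickness_rejected(self, thickness):
        with pytest.raises(ParameterError):
            me.extrude_shell(trimesh.creation.icosphere(2, 10.0), thickness)

    def test_medulla_wall_1mm(self, phantom2mm):
        med = me.laplacian_smooth(
            me.extract_surface(phantom2mm, phantom2mm.label_for_role("medulla-L")))
        shell = me.extrude_shell(med, 1.0)
        assert me.wall_distances(shell).mean() == pytest.approx(1.0, rel=0.05)

    def test_liver_wall_2mm(self, liver_shell):
        assert me.wall_distances(liver_shell).mean() == pytest.approx(2.0,
                                                                      rel=0.05)
        assert liver_shell.outer.is_watertight


class TestResolveOverlap:
    def test_already_clear_needs_no_translation(self):
        a = trimesh.creation.icosphere(3, 10.0)
        b = trimesh.creation.icosphere(3, 10.0)
        b.apply_translation([21.0, 0, 0])
        moved, offset = me.resolve_overlap(a, b, [1, 0, 0])
        assert offset == 0.0

    def test_overlapping_spheres_sphere_pair_geometry(self):
        # radius-10 spheres 15 mm apart: clearing to 0.5 mm separation
        # needs ~5.5 mm of travel along x
        a = trimesh.creation.icosphere(3, 10.0)
        b = trimesh.creation.icosphere(3, 10.0)
        b.apply_translation([15.0, 0, 0])
        moved, offset = me.resolve_overlap(a, b, [1, 0, 0])
        assert offset == pytest.approx(5.5, abs=0.3)
        assert me.signed_separation(a, moved) >= 0.5
        # minimality: one step back violates the clearance
        back = moved.copy()
        back.apply_translation([-0.1, 0, 0])
        assert me.signed_separation(a, back) < 0.5

    def test_bounded_travel_errors(self):
        a = trimesh.creation.icosphere(2, 10.0)
        b = trimesh.creation.icosphere(2, 10.0)
        with pytest.raises(ResolutionError):
            me.resolve_overlap(a, b, [1, 0, 0], max_travel=1.0)


class TestAssembleScene:
    def test_valid_two_solid_scene(self):
        a = trimesh.creation.icosphere(3, 10.0)
        b = trimesh.creation.icosphere(3, 10.0)
        b.apply_translation([15.0, 0, 0])
        moved, _ = me.resolve_overlap(a, b, [1, 0, 0])
        scene = me.assemble_scene([("liver", a), ("kidney-R", moved)])
        assert set(scene.geometry) == {"liver", "kidney-R"}

    def test_single_part_identity(self):
        a = trimesh.creation.box(extents=[5, 5, 5])
        scene = me.assemble_scene([("box", a)])
        assert np.allclose(scene.geometry["box"].vertices, a.vertices)

    def test_colocated_parts_rejected(self):
        a = trimesh.creation.icosphere(2, 10.0)
        with pytest.raises(AssemblyError, match="a.*b|b.*a"):
            me.assemble_scene([("a", a), ("b", a.copy())])


class TestStlIO:
    def test_binary_round_trip_preserves_geometry(self, tmp_path):
        cube = trimesh.creation.box(extents=[10, 10, 10])
        me.write_stl(cube, tmp_path / "c.stl", "binary")
        back = me.read_stl(tmp_path / "c.stl")
        assert len(back.faces) == 12
        t0 = np.sort(np.float32(np.asarray(cube.triangles)).reshape(12, -1),
                     axis=0)
        t1 = np.sort(np.float32(np.asarray(back.triangles)).reshape(12, -1),
                     axis=0)
        assert np.array_equal(t0, t1)

    def test_ascii_and_binary_volumes_agree(self, tmp_path):
        ball = trimesh.creation.icosphere(3, 7.0)
        me.write_stl(ball, tmp_path / "b.stl", "binary")
        me.write_stl(ball, tmp_path / "a.stl", "ascii")
        vb = me.mesh_volume(me.read_stl(tmp_path / "b.stl"))
        va = me.mesh_volume(me.read_stl(tmp_path / "a.stl"))
        assert va == pytest.approx(vb, rel=1e-6)

    def test_round_trip_idempotent_after_first_write(self, tmp_path):
        ball = trimesh.creation.icosphere(2, 4.0)
        me.write_stl(ball, tmp_path / "w1.stl", "binary")
        m1 = me.read_stl(tmp_path / "w1.stl")
        me.write_stl(m1, tmp_path / "w2.stl", "binary")
        m2 = me.read_stl(tmp_path / "w2.stl")
        me.write_stl(m2, tmp_path / "w3.stl", "binary")
        assert ((tmp_path / "w2.stl").read_bytes()
                == (tmp_path / "w3.stl").read_bytes())

    def test_truncated_binary_reports_byte_offset(self, tmp_path):
        cube = trimesh.creation.box(extents=[1, 1, 1])
        me.write_stl(cube, tmp_path / "c.stl", "binary")
        raw = (tmp_path / "c.stl").read_bytes()
        (tmp_path / "bad.stl").write_bytes(raw[:-10])
        with pytest.raises(StlParseError) as exc:
            me.read_stl(tmp_path / "bad.stl")
        assert exc.value.byte_offset == len(raw) - 10

    def test_wrong_triangle_count_rejected(self, tmp_path):
        cube = trimesh.creation.box(extents=[1, 1, 1])
        me.write_stl(cube, tmp_path / "c.stl", "binary")
        raw = bytearray((tmp_path / "c.stl").read_bytes())
        raw[80:84] = (99).to_bytes(4, "little")
        (tmp_path / "bad.stl").write_bytes(bytes(raw))
        with pytest.raises(StlParseError):
            me.read_stl(tmp_path / "bad.stl")

    def test_multi_solid_ascii_scene(self, tmp_path):
        a = trimesh.creation.box(extents=[5, 5, 5])
        b = trimesh.creation.icosphere(2, 3.0)
        b.apply_translation([20, 0, 0])
        scene = me.assemble_scene([("box", a), ("ball", b)])
        me.write_stl(scene, tmp_path / "s.stl", "ascii")
        parts = me.read_stl(tmp_path / "s.stl")
        assert isinstance(parts, list) and len(parts) == 2
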