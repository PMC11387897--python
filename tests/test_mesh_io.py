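"""Mesh containers, STL/tet-mesh/VTK I/O and geometric summaries."""

import numpy as np
import pytest
import trimesh

import skullfea as sf
from skullfea.mesh_io import (
    MeshValidationError,
    read_vtk_cell_count,
)
from skullfea.fe_solver import SolutionField

from conftest import random_rotation

ASCII_FACET = """solid one
facet normal 0 0 1
  outer loop
    vertex 0 0 0
    vertex 1 0 0
    vertex 0 1 0
  endloop
endfacet
endsolid one
"""


class TestReadSTL:
    def test_ascii_single_facet(self, tmp_path):
        p = tmp_path / "one.stl"
        p.write_text(ASCII_FACET)
        m = sf.read_stl(p)
        assert len(m.vertices) == 3
        assert len(m.triangles) == 1

    def test_binary_matches_ascii(self, tmp_path):
        pa = tmp_path / "a.stl"
        pa.write_text(ASCII_FACET)
        ma = sf.read_stl(pa)
        pb = tmp_path / "b.stl"
        sf.write_stl(ma, pb, binary=True)
        mb = sf.read_stl(pb)
        assert len(mb.vertices) == 3 and len(mb.triangles) == 1
        # same triangle geometry regardless of vertex order
        assert np.isclose(sf.surface_area(ma), sf.surface_area(mb))

    def test_cube_merges_to_8_vertices(self, tmp_path):
        box = trimesh.creation.box(extents=(1, 1, 1))
        p = tmp_path / "cube.stl"
        box.export(str(p))
        m = sf.read_stl(p)
        assert len(m.vertices) == 8
        assert len(m.triangles) == 12

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            sf.read_stl(tmp_path / "nope.stl")

    def test_malformed_file(self, tmp_path):
        p = tmp_path / "bad.stl"
        p.write_bytes(b"\x00" * 10)
        with pytest.raises((MeshValidationError, Exception)):
            sf.read_stl(p)


class TestSurfaceArea:
    def test_unit_cube(self, tmp_path):
        box = trimesh.creation.box(extents=(1, 1, 1))
        m = sf.SurfaceMesh(box.vertices, box.faces)
        assert sf.surface_area(m) == pytest.approx(6.0)

    def test_single_triangle(self):
        m = sf.SurfaceMesh(
            np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0]]), np.array([[0, 1, 2]])
        )
        assert sf.surface_area(m) == pytest.approx(0.5)

    def test_icosphere_close_to_analytic(self):
        ico = trimesh.creation.icosphere(subdivisions=3, radius=1.0)
        m = sf.SurfaceMesh(ico.vertices, ico.faces)
        area = sf.surface_area(m)
        assert area < 4 * np.pi  # inscribed polyhedron
        assert abs(area - 4 * np.pi) / (4 * np.pi) < 0.01

    @pytest.mark.parametrize("seed", [0, 1])
    def test_rigid_motion_invariance(self, seed):
        rng = np.random.default_rng(seed)
        verts = rng.normal(size=(20, 3))
        tris = rng.integers(0, 20, size=(30, 3))
        m = sf.SurfaceMesh(verts, tris)
        R = random_rotation(seed)
        m2 = sf.SurfaceMesh(verts @ R.T + np.array([5.0, -3.0, 2.0]), tris)
        a1, a2 = sf.surface_area(m), sf.surface_area(m2)
        assert abs(a1 - a2) / a1 < 1e-9


class TestElementVolumes:
    def test_unit_right_tet(self, unit_tet):
        s = sf.element_volumes(unit_tet)
        assert s.element_volumes[0] == pytest.approx(1 / 6)
        assert s.total_volume == pytest.approx(s.element_volumes.sum())

    def test_cube_six_tets_conserve_volume(self, cube_mesh):
        s = sf.element_volumes(cube_mesh)
        assert s.element_count == 6
        assert s.total_volume == pytest.approx(1.0, rel=1e-12)

    def test_affine_transform_scales_by_determinant(self, unit_tet):
        rng = np.random.default_rng(3)
        A = rng.normal(size=(3, 3))
        A *= (2.0 / abs(np.linalg.det(A))) ** (1 / 3)  # det -> +/-2
        m2 = sf.TetMesh(unit_tet.nodes @ A.T, unit_tet.tets.copy())
        v1 = sf.element_volumes(unit_tet).total_volume
        v2 = sf.element_volumes(m2).total_volume
        assert v2 == pytest.approx(2.0 * v1, rel=1e-10)

    def test_zero_volume_tet_rejected(self):
        nodes = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0.5, 0.5, 0]], float)
        with pytest.raises(MeshValidationError, match="zero-volume"):
            sf.TetMesh(nodes, np.array([[0, 1, 2, 3]]))

    def test_negative_orientation_repaired(self):
        nodes = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], float)
        m = sf.TetMesh(nodes, np.array([[0, 2, 1, 3]]))  # inverted
        assert sf.element_volumes(m).element_volumes[0] == pytest.approx(1 / 6)


class TestTetMeshFormat:
    def test_round_trip(self, tmp_path, cranium):
        p = tmp_path / "m.tet"
        sf.write_tetmesh(cranium.mesh, p)
        back = sf.read_tetmesh(p)
        assert back.n_nodes == cranium.mesh.n_nodes
        np.testing.assert_array_equal(back.tets, cranium.mesh.tets)
        np.testing.assert_allclose(back.nodes, cranium.mesh.nodes)
        assert set(back.node_sets) == set(cranium.mesh.node_sets)
        for k in back.node_sets:
            np.testing.assert_array_equal(back.node_sets[k],
                                          cranium.mesh.node_sets[k])

    def test_idempotent_rewrite(self, tmp_path, cranium):
        p1, p2 = tmp_path / "a.tet", tmp_path / "b.tet"
        sf.write_tetmesh(cranium.mesh, p1)
        sf.write_tetmesh(sf.read_tetmesh(p1), p2)
        assert p1.read_text() == p2.read_text()

    def test_truncated_file(self, tmp_path):
        p = tmp_path / "bad.tet"
        p.write_text("NODES 5\n1 0 0 0\n")
        with pytest.raises(MeshValidationError):
            sf.read_tetmesh(p)


def _zero_field(mesh):
    m = mesh.n_tets
    return SolutionField(
        displacements=np.zeros((mesh.n_nodes, 3)),
        element_strain=np.zeros((m, 3, 3)),
        element_stress=np.zeros((m, 3, 3)),
        von_mises=np.zeros(m),
        max_principal_strain=np.zeros(m),
        reactions={},
        element_volumes=sf.element_volumes(mesh).element_volumes,
    )


class TestVTKExport:
    def test_single_tet_zero_field(self, tmp_path, unit_tet):
        p = tmp_path / "out.vtk"
        sf.write_results_vtk(unit_tet, _zero_field(unit_tet), p)
        text = p.read_text()
        assert "UNSTRUCTURED_GRID" in text
        assert "SCALARS von_mises" in text
        assert read_vtk_cell_count(p) == 1

    def test_round_trip_cell_count(self, tmp_path, cranium, material,
                                   cranium_field):
        p = tmp_path / "c.vtk"
        sf.write_results_vtk(cranium.mesh, cranium_field, p)
        assert read_vtk_cell_count(p) == cranium.mesh.n_tets

    def test_dimension_mismatch_rejected(self, tmp_path, unit_tet, cube_mesh):
        with pytest.raises(MeshValidationError):
            sf.write_results_vtk(cube_mesh, _zero_field(unit_tet),
                                 tmp_path / "x.vtk")

    def test_patch_test_field_uniform_cell_values(self, tmp_path):
        from skullfea.verification import patch_test

        r = patch_test()
        # all cells carry the same von Mises value in the written file
        from skullfea.verification import tet_box
        mesh = tet_box(20.0, 10.0, 10.0, 4, 2, 2)
        p = tmp_path / "patch.vtk"
        sf.write_results_vtk(mesh, r.field, p)
        lines = p.read_text().splitlines()
        i = lines.index("SCALARS von_mises double 1") + 2
        vals = {lines[i + j] for j in range(mesh.n_tets)}
        assert len(vals) == 1
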