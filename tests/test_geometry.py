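"""Mesh generators, measures, partitioning and MSH round-trips."""

import itertools

import numpy as np
import pytest

from tetrd.geometry import (TetMesh, all_faces, compute_measures, generate_box,
                            generate_cable, generate_structured_mesh,
                            partition_mesh, tet_volumes, triangle_areas)
from tetrd.msh import UnsupportedMshError, read_gmsh, write_gmsh


class TestGenerators:
    def test_unit_box_volume_exact(self, unit_box, box_measures):
        assert box_measures.total_volume == pytest.approx(1e-18, rel=1e-12)
        assert unit_box.num_tets == 6

    def test_cable_volume_matches_prism(self):
        mesh = generate_cable(1e-3, 1e-6, 200)
        meas = compute_measures(mesh)
        assert meas.total_volume == pytest.approx(
            np.pi * (0.5e-6) ** 2 * 1e-3, rel=1e-9)

    def test_cable_surface_ratio(self):
        # area-matched square section: end caps match the circle exactly,
        # lateral ratio is pi d / (4 * sqrt(pi) d / 2) = sqrt(pi)/2
        mesh = generate_cable(1e-3, 1e-6, 50)
        assert 0.85 < mesh.meta["surface_ratio"] < 0.89

    def test_interior_faces_shared_by_two_tets(self):
        mesh = generate_box((2e-6, 1e-6, 3e-6), (2, 1, 3))
        _, _, counts = all_faces(mesh.tets)
        assert set(np.unique(counts)) <= {1, 2}
        # brute-force recount by enumerating each tet's 4 faces
        seen = {}
        for tet in mesh.tets:
            for face in itertools.combinations(sorted(tet), 3):
                seen[face] = seen.get(face, 0) + 1
        assert sorted(seen.values()) == sorted(counts.tolist())

    def test_zero_resolution_rejected(self):
        with pytest.raises(ValueError):
            generate_box((1e-6,) * 3, (0, 1, 1))
        with pytest.raises(ValueError):
            generate_cable(1e-3, 1e-6, 0)

    def test_dispatch(self):
        m = generate_structured_mesh("box", (1e-6,) * 3, (1, 1, 1))
        assert m.num_tets == 6
        with pytest.raises(ValueError):
            generate_structured_mesh("sphere", (1e-6,), (1,))


class TestMeasures:
    def test_regular_tetrahedron_volume(self):
        a = 1e-6  # unit-edge regular tetrahedron, V = a^3 / (6 sqrt(2))
        verts = a * np.array([
            [0, 0, 0], [1, 0, 0], [0.5, np.sqrt(3) / 2, 0],
            [0.5, np.sqrt(3) / 6, np.sqrt(2.0 / 3.0)],
        ])
        mesh = TetMesh(verts, [[0, 1, 2, 3]], [0], ["c"],
                       np.empty((0, 3), np.int64), np.empty(0, np.int64), [])
        meas = compute_measures(mesh)
        assert meas.volumes[0] == pytest.approx(a**3 / (6 * np.sqrt(2)), rel=1e-9)

    def test_shared_face_symmetric(self, two_tets):
        meas = compute_measures(two_tets)
        assert list(meas.neighbors[0]) == [1]
        assert list(meas.neighbors[1]) == [0]
        assert meas.face_areas[0][0] == meas.face_areas[1][0]
        assert meas.face_dists[0][0] == meas.face_dists[1][0]
        assert meas.face_areas[0][0] > 0 and meas.face_dists[0][0] > 0

    def test_vertex_lumped_areas_sum_to_membrane_area(self):
        mesh = generate_cable(1e-4, 1e-6, 13)
        meas = compute_measures(mesh)
        assert meas.vertex_tri_areas.sum() == pytest.approx(
            meas.tri_areas.sum(), rel=1e-12)

    def test_measures_deterministic(self, unit_box):
        m1, m2 = compute_measures(unit_box), compute_measures(unit_box)
        assert np.array_equal(m1.volumes, m2.volumes)
        assert np.array_equal(m1.barycenters, m2.barycenters)
        assert np.array_equal(m1.face_areas.ab2c, m2.face_areas.ab2c)

    def test_degenerate_tetrahedron_named(self):
        verts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0.0]])
        with pytest.raises(ValueError, match="0"):
            TetMesh(verts, [[0, 1, 2, 3]], [0], ["c"],
                    np.empty((0, 3), np.int64), np.empty(0, np.int64), [])


class TestPartition:
    def test_single_rank_identity(self, unit_box):
        part = partition_mesh(unit_box, 1)
        assert np.all(part.owner == 0)
        assert len(part.ghosts[0]) == 0

    def test_two_tets_two_ranks(self, two_tets):
        part = partition_mesh(two_tets, 2)
        assert sorted(part.owner.tolist()) == [0, 1]
        assert [g.tolist() for g in part.ghosts] == [[part.owned(1)[0]],
                                                     [part.owned(0)[0]]]

    def test_ownership_is_a_partition(self):
        mesh = generate_box((2e-6, 2e-6, 4e-6), (2, 2, 4))
        part = partition_mesh(mesh, 4)
        owned = [set(part.owned(r).tolist()) for r in range(4)]
        assert set().union(*owned) == set(range(mesh.num_tets))
        for a, b in itertools.combinations(owned, 2):
            assert not (a & b)

    def test_ghosts_match_brute_force(self):
        mesh = generate_box((2e-6, 2e-6, 2e-6), (2, 2, 2))
        part = partition_mesh(mesh, 2)
        faces, face_tets, counts = all_faces(mesh.tets)
        inter = face_tets[counts == 2]
        for r in range(2):
            expect = set()
            for a, b in inter:
                if part.owner[a] == r and part.owner[b] != r:
                    expect.add(int(b))
                if part.owner[b] == r and part.owner[a] != r:
                    expect.add(int(a))
            assert set(part.ghosts[r].tolist()) == expect

    def test_non_power_of_two_rejected(self, unit_box):
        with pytest.raises(ValueError, match="power of 2"):
            partition_mesh(unit_box, 3)

    def test_more_ranks_than_tets_rejected(self, two_tets):
        with pytest.raises(ValueError):
            partition_mesh(two_tets, 4)


UNIT_TET_MSH = """$MeshFormat
2.2 0 8
$EndMeshFormat
$PhysicalNames
2
2 1 "skin"
3 2 "bulk"
$EndPhysicalNames
$Nodes
4
1 0 0 0
2 1 0 0
3 0 1 0
4 0 0 1
$EndNodes
$Elements
5
1 4 2 2 1 1 2 3 4
2 2 2 1 1 1 2 3
3 2 2 1 1 1 2 4
4 2 2 1 1 1 3 4
5 2 2 1 1 2 3 4
$EndElements
"""


class TestMsh:
    def test_smallest_valid_mesh(self, tmp_path):
        path = tmp_path / "tet.msh"
        path.write_text(UNIT_TET_MSH)
        mesh = read_gmsh(path)
        assert mesh.num_tets == 1
        assert mesh.num_tris == 4
        assert mesh.comp_names == ["bulk"]
        assert mesh.patch_names == ["skin"]
        assert np.all(mesh.tri_tets[:, 0] == 0)
        assert np.all(mesh.tri_tets[:, 1] == -1)

    def test_round_trip_cable(self, tmp_path):
        mesh = generate_cable(1e-4, 1e-6, 7)
        path = tmp_path / "cable.msh"
        write_gmsh(mesh, path)
        back = read_gmsh(path)
        assert np.array_equal(mesh.tets, back.tets)
        assert np.array_equal(np.sort(mesh.tris, axis=1),
                              np.sort(back.tris, axis=1))
        assert np.allclose(mesh.vertices, back.vertices, rtol=0, atol=0)
        assert back.comp_names == mesh.comp_names
        assert back.patch_names == mesh.patch_names

    def test_unsupported_version(self, tmp_path):
        path = tmp_path / "bad.msh"
        path.write_text("$MeshFormat\n4.1 0 8\n$EndMeshFormat\n")
        with pytest.raises(UnsupportedMshError, match="4.1"):
            read_gmsh(path)

    def test_missing_physical_names_warns(self, tmp_path):
        text = UNIT_TET_MSH.replace(
            '$PhysicalNames\n2\n2 1 "skin"\n3 2 "bulk"\n$EndPhysicalNames\n', "")
        path = tmp_path / "tagless.msh"
        path.write_text(text)
        with pytest.warns(UserWarning, match="tagless"):
            mesh = read_gmsh(path)
        assert mesh.num_tets == 1

    def test_non_tetrahedral_3d_rejected(self, tmp_path):
        text = UNIT_TET_MSH.replace("1 4 2 2 1 1 2 3 4",
                                    "1 5 2 2 1 1 2 3 4 1 2 3 4")
        path = tmp_path / "hex.msh"
        path.write_text(text)
        with pytest.raises(UnsupportedMshError, match="type 5"):
            read_gmsh(path)

    def test_unit_scale(self, tmp_path):
        path = tmp_path / "tet.msh"
        path.write_text(UNIT_TET_MSH)
        mesh = read_gmsh(path, unit_scale=1e-6)
        assert mesh.vertices.max() == pytest.approx(1e-6)

    def test_interior_triangles_get_two_owners(self, tmp_path):
        mesh = generate_box((1e-6, 1e-6, 2e-6), (1, 1, 2))
        faces, face_tets, counts = all_faces(mesh.tets)
        interior = faces[counts == 2][:3]
        m2 = TetMesh(mesh.vertices, mesh.tets, mesh.tet_tags, mesh.comp_names,
                     interior, np.zeros(len(interior), np.int64), ["inner"])
        assert np.all(m2.tri_tets >= 0)
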