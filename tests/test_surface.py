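"""Mesh core: I/O, repair, simplification, subdivision, curvature,
conformal parameterization and the (lambda, H) representation."""

import numpy as np
import pytest
import trimesh

from subshape import (
    ConformalGrid,
    MeshInvariantError,
    TriangleMesh,
    conformal_parameterize,
    conformal_representation,
    loop_subdivide,
    mean_curvature,
    read_mesh,
    simplify_mesh,
    write_mesh,
)
from subshape.surface import grid_mean_curvature


class TestMeshIO:
    @pytest.mark.parametrize("fmt", ["ply", "vtk"])
    def test_round_trip_preserves_arrays(self, hippo_small, tmp_path, fmt):
        mesh, _ = hippo_small
        path = tmp_path / f"m.{fmt}"
        write_mesh(mesh, path)
        back = read_mesh(path)
        assert np.allclose(back.vertices, mesh.vertices, atol=1e-9)
        assert np.array_equal(np.sort(back.faces, axis=1).ravel(),
                              np.sort(mesh.faces, axis=1).ravel())

    def test_binary_ply_round_trip_exact(self, hippo_small, tmp_path):
        mesh, _ = hippo_small
        path = tmp_path / "m.ply"
        write_mesh(mesh, path)
        back = read_mesh(path, repair=False)
        assert np.array_equal(back.vertices, mesh.vertices)
        assert np.array_equal(back.faces, mesh.faces)

    def test_inconsistent_winding_repaired(self, tmp_path):
        tm = trimesh.creation.icosphere(subdivisions=1)
        faces = np.asarray(tm.faces).copy()
        faces[0] = faces[0][::-1]          # flip one face's orientation
        mesh = TriangleMesh(np.asarray(tm.vertices), faces)
        path = tmp_path / "bad.ply"
        write_mesh(mesh, path)
        fixed = read_mesh(path)            # repair pass runs on read
        fixed.validate()

    def test_torus_rejected_by_euler_formula(self, tmp_path):
        tm = trimesh.creation.torus(major_radius=2.0, minor_radius=0.5)
        mesh = TriangleMesh(np.asarray(tm.vertices), np.asarray(tm.faces))
        path = tmp_path / "torus.ply"
        write_mesh(mesh, path)
        with pytest.raises(MeshInvariantError, match="genus"):
            read_mesh(path)


class TestSimplify:
    def test_icosphere_decimation_stays_on_sphere(self, icosphere):
        out = simplify_mesh(icosphere, 1280)
        assert abs(out.n_faces - 1280) <= 2
        out.validate()
        deviation = np.abs(np.linalg.norm(out.vertices, axis=1) - 1.0)
        assert deviation.max() < 0.01

    def test_target_equal_to_current_is_identity(self, hippo_small):
        mesh, _ = hippo_small
        out = simplify_mesh(mesh, mesh.n_faces)
        assert np.array_equal(out.vertices, mesh.vertices)
        assert np.array_equal(out.faces, mesh.faces)

    def test_simplify_then_subdivide_quadruples(self, icosphere):
        small = simplify_mesh(icosphere, 320)
        up = loop_subdivide(small, 1)
        assert up.n_faces == 4 * small.n_faces

    def test_invalid_targets_rejected(self, icosphere):
        with pytest.raises(ValueError):
            simplify_mesh(icosphere, 50)
        with pytest.raises(ValueError):
            simplify_mesh(icosphere, icosphere.n_faces + 10)


class TestLoopSubdivision:
    def test_zero_levels_identity(self, hippo_small):
        mesh, _ = hippo_small
        out = loop_subdivide(mesh, 0)
        assert np.array_equal(out.vertices, mesh.vertices)

    def test_face_count_geometric_growth(self):
        tm = trimesh.creation.icosphere(subdivisions=0)  # icosahedron
        mesh = TriangleMesh(np.asarray(tm.vertices), np.asarray(tm.faces))
        out = loop_subdivide(mesh, 3)
        assert out.n_faces == 20 * 4 ** 3
        out.validate()

    def test_icosahedron_converges_toward_limit_surface(self):
        # control points approach the limit surface; distance to a deep
        # reference subdivision shrinks monotonically with level
        from scipy.spatial import cKDTree

        tm = trimesh.creation.icosphere(subdivisions=0)
        mesh = TriangleMesh(np.asarray(tm.vertices), np.asarray(tm.faces))
        reference = cKDTree(loop_subdivide(mesh, 6).vertices)
        dists = []
        for lev in range(4):
            out = loop_subdivide(mesh, lev)
            d, _ = reference.query(out.vertices)
            dists.append(d.max())
        assert all(b < a for a, b in zip(dists, dists[1:]))


class TestMeanCurvature:
    @pytest.mark.parametrize("radius,tol", [(1.0, 0.02), (2.0, 0.01)])
    def test_sphere_curvature_is_inverse_radius(self, radius, tol):
        tm = trimesh.creation.icosphere(subdivisions=4, radius=radius)
        mesh = TriangleMesh(np.asarray(tm.vertices), np.asarray(tm.faces))
        H = mean_curvature(mesh)
        assert np.abs(H - 1.0 / radius).max() < tol

    def test_cylinder_interior_curvature(self):
        # capped unit-radius tube with well-shaped triangles; interior
        # side vertices have H = (k1 + k2)/2 = 1/(2r) = 0.5
        from subshape.synthetic import grid_to_mesh
        from subshape.surface import conformal_factor_from_positions
        nu, nv = 60, 48
        u = (np.arange(nu) + 0.5) / nu
        v = 2 * np.pi * np.arange(nv) / nv
        U, V = np.meshgrid(u, v, indexing="ij")
        pos = np.stack([np.cos(V), np.sin(V), 8.0 * (U - 0.5)], -1)
        lam = conformal_factor_from_positions(pos, 1 / nu, 2 * np.pi / nv)
        g = ConformalGrid((nu, nv), pos, lam, np.zeros((nu, nv)))
        mesh = grid_to_mesh(g, np.array([0, 0, -4.0]), np.array([0, 0, 4.0]))
        H = mean_curvature(mesh)
        sel = np.abs(mesh.vertices[:, 2]) < 2.0
        assert sel.sum() > 100
        assert np.abs(H[sel] - 0.5).max() < 0.02


class TestConformalParameterization:
    def test_straight_cylinder_lambda_constant_around(self):
        from subshape.surface import conformal_factor_from_positions
        from subshape.synthetic import grid_to_mesh
        nu, nv = 30, 40
        u = (np.arange(nu) + 0.5) / nu
        v = 2 * np.pi * np.arange(nv) / nv
        U, V = np.meshgrid(u, v, indexing="ij")
        R = 2.0 * np.sqrt(np.clip(np.sin(np.pi * U), 1e-3, None))
        pos = np.stack([R * np.cos(V), R * np.sin(V), 20.0 * (U - 0.5)], -1)
        lam = conformal_factor_from_positions(pos, 1 / nu, 2 * np.pi / nv)
        H = grid_mean_curvature(pos, 1 / nu, 2 * np.pi / nv)
        g = ConformalGrid((nu, nv), pos, lam, H)
        cyl = grid_to_mesh(g, np.array([0, 0, -11.0]), np.array([0, 0, 11.0]))
        grid = conformal_parameterize(cyl, (30, 40))
        mid = grid.conformal_factor[8:22]
        rel_spread = (mid.std(axis=1) / mid.mean(axis=1)).max()
        assert rel_spread < 0.01

    @pytest.mark.parametrize("kind", ["hippocampus_like", "amygdala_like"])
    def test_area_reproduced_by_lambda_sum(self, kind):
        from subshape import make_template_surface
        mesh, _ = make_template_surface(kind, (40, 60), seed=1)
        grid = conformal_parameterize(mesh, (40, 60))
        assert np.all(grid.conformal_factor > 0)
        rel = abs(grid.surface_area_estimate() - mesh.area()) / mesh.area()
        assert rel < 0.011

    def test_deterministic_given_mesh_and_dims(self, hippo_small):
        mesh, _ = hippo_small
        g1 = conformal_parameterize(mesh, (20, 30))
        g2 = conformal_parameterize(mesh, (20, 30))
        assert np.array_equal(g1.positions, g2.positions)
        assert np.array_equal(g1.conformal_factor, g2.conformal_factor)

    def test_grid_container_round_trip(self, hippo_small, tmp_path):
        _, grid = hippo_small
        grid.save(tmp_path / "g.npz")
        back = ConformalGrid.load(tmp_path / "g.npz")
        assert back.dims == grid.dims
        assert np.array_equal(back.positions, grid.positions)
        assert np.array_equal(back.mean_curvature, grid.mean_curvature)
        assert back.periodic_v == grid.periodic_v


class TestConformalRepresentation:
    def test_channels_standardized(self, hippo_small):
        _, grid = hippo_small
        rep, meta = conformal_representation(grid)
        assert rep.shape == (2,) + grid.dims
        assert np.allclose(rep.mean(axis=(1, 2)), 0.0, atol=1e-12)
        assert np.allclose(rep.std(axis=(1, 2)), 1.0, atol=1e-12)
        assert meta["lambda"]["std"] > 0

    def test_identical_grid_gives_identical_images(self, hippo_small):
        _, grid = hippo_small
        r1, _ = conformal_representation(grid)
        r2, _ = conformal_representation(grid)
        assert np.array_equal(r1, r2)

    def test_scaling_laws_on_raw_channels(self, hippo_small):
        # doubling the mesh scale halves H and quadruples lambda
        _, grid = hippo_small
        nu, nv = grid.dims
        from subshape.surface import conformal_factor_from_positions
        pos2 = grid.positions * 2.0
        lam2 = conformal_factor_from_positions(pos2, 1 / nu, 2 * np.pi / nv)
        H2 = grid_mean_curvature(pos2, 1 / nu, 2 * np.pi / nv)
        assert np.allclose(lam2, 4.0 * grid.conformal_factor, rtol=1e-9)
        assert np.allclose(H2, 0.5 * grid.mean_curvature, rtol=1e-6, atol=1e-9)

    def test_sphere_curvature_channel_constant(self):
        nu, nv = 40, 60
        u = (np.arange(nu) + 0.5) / nu
        v = 2 * np.pi * np.arange(nv) / nv
        U, V = np.meshgrid(u, v, indexing="ij")
        th = np.pi * U
        pos = 3.0 * np.stack([np.sin(th) * np.cos(V),
                              np.sin(th) * np.sin(V), np.cos(th)], -1)
        H = grid_mean_curvature(pos, 1 / nu, 2 * np.pi / nv)
        # the two rows nearest each pole feel the one-sided u stencil
        assert np.abs(H[2:-2] - 1.0 / 3.0).max() < 0.02
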