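"""Mesh core: data structures, I/O, smoothing and conformal parameterization.

Surfaces of subcortical structures (hippocampus, amygdala) are closed
genus-zero triangular meshes.  Vertex-wise analysis requires a common
indexing across subjects, obtained here by mapping each surface onto a
fixed regular grid over the parameter rectangle ``[0, 1] x [0, 2*pi)``:
``u`` runs along the long (medial) axis of the structure, ``v`` runs
around it and is periodic.  The map is harmonic (discretely conformal up
to the usual quasi-conformal error), and each grid node carries the 3D
position, the conformal factor ``lambda`` (local area-distortion
density) and the mean curvature ``H``.  The pair ``(lambda, H)``
determines the surface up to rigid motion and is the representation
driving inter-subject registration.
"""

from __future__ import annotations

import heapq
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
import trimesh


class MeshInvariantError(ValueError):
    """A mesh violates a structural invariant (manifoldness, genus, ...).

    ``invariant`` names the violated property so callers can branch on it.
    """

    def __init__(self, invariant: str, message: str):
        self.invariant = invariant
        super().__init__(f"{invariant}: {message}")


class ParameterizationError(RuntimeError):
    """Conformal parameterization failed (non-injective map or bad topology)."""


@dataclass
class TriangleMesh:
    """Closed oriented triangle mesh in millimetres.

    vertices : (N, 3) float array, mm
    faces    : (M, 3) int array, 0-based, counter-clockwise (outward normals)
    """

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self):
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise MeshInvariantError("shape", "vertices must be (N, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise MeshInvariantError("shape", "faces must be (M, 3)")

    # -- derived quantities -------------------------------------------------
    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(self.vertices, self.faces, process=False)

    def edges_unique(self) -> np.ndarray:
        e = np.sort(self.faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2), axis=1)
        return np.unique(e, axis=0)

    def euler_characteristic(self) -> int:
        return self.n_vertices - len(self.edges_unique()) + self.n_faces

    def area(self) -> float:
        return float(self.to_trimesh().area)

    def validate(self, *, require_genus0: bool = True) -> None:
        """Check the closed-surface invariants; raise MeshInvariantError."""
        tm = self.to_trimesh()
        e = np.sort(self.faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2), axis=1)
        uniq, counts = np.unique(e, axis=0, return_counts=True)
        if np.any(counts > 2):
            raise MeshInvariantError(
                "edge_manifold", f"{int(np.sum(counts > 2))} edges shared by >2 faces")
        if np.any(counts != 2):
            raise MeshInvariantError(
                "watertight", f"{int(np.sum(counts != 2))} boundary edges")
        if require_genus0:
            chi = self.n_vertices - len(uniq) + self.n_faces
            if chi != 2:
                raise MeshInvariantError(
                    "genus0", f"Euler characteristic {chi} != 2 (genus {(2 - chi) // 2})")
        areas = tm.area_faces
        if np.any(areas <= 0):
            raise MeshInvariantError(
                "zero_area", f"{int(np.sum(areas <= 0))} zero/negative-area faces")


@dataclass
class ConformalGrid:
    """Regular parameter-domain sampling of a tube-like closed surface.

    dims             : (nu, nv); u is the slow (axial) index
    positions        : (nu, nv, 3) surface positions, mm
    conformal_factor : (nu, nv) area-distortion density lambda > 0
    mean_curvature   : (nu, nv) mean curvature H, 1/mm
    periodic_v       : v is periodic over [0, 2*pi)
    metadata         : provenance (u samples, seam/cut choices, ...)
    """

    dims: tuple
    positions: np.ndarray
    conformal_factor: np.ndarray
    mean_curvature: np.ndarray
    periodic_v: bool = True
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        nu, nv = self.dims
        self.dims = (int(nu), int(nv))
        for name in ("positions", "conformal_factor", "mean_curvature"):
            arr = np.asarray(getattr(self, name), dtype=np.float64)
            setattr(self, name, arr)
        if self.positions.shape != (nu, nv, 3):
            raise ValueError(f"positions shape {self.positions.shape} != {(nu, nv, 3)}")
        if self.conformal_factor.shape != (nu, nv):
            raise ValueError("conformal_factor shape mismatch")
        if self.mean_curvature.shape != (nu, nv):
            raise ValueError("mean_curvature shape mismatch")

    @property
    def n_nodes(self) -> int:
        return self.dims[0] * self.dims[1]

    @property
    def du(self) -> float:
        return 1.0 / self.dims[0]

    @property
    def dv(self) -> float:
        return 2.0 * np.pi / self.dims[1]

    def surface_area_estimate(self) -> float:
        """Sum of lambda over the grid times the parameter cell area."""
        return float(np.sum(self.conformal_factor) * self.du * self.dv)

    # -- serialization ------------------------------------------------------
    def save(self, path) -> None:
        """Write as an .npz container plus a JSON metadata sidecar."""
        path = Path(path)
        np.savez(
            path,
            dims=np.array(self.dims),
            positions=self.positions,
            conformal_factor=self.conformal_factor,
            mean_curvature=self.mean_curvature,
            periodic_v=np.array(self.periodic_v),
        )
        meta_path = path.with_suffix(".json")
        meta_path.write_text(json.dumps(_jsonable(self.metadata), indent=1))

    @classmethod
    def load(cls, path) -> "ConformalGrid":
        path = Path(path)
        if not path.suffix:
            path = path.with_suffix(".npz")
        with np.load(path) as z:
            dims = tuple(int(x) for x in z["dims"])
            grid = cls(
                dims=dims,
                positions=z["positions"],
                conformal_factor=z["conformal_factor"],
                mean_curvature=z["mean_curvature"],
                periodic_v=bool(z["periodic_v"]),
            )
        meta_path = path.with_suffix(".json")
        if meta_path.exists():
            grid.metadata = json.loads(meta_path.read_text())
        return grid


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_mesh(mesh: TriangleMesh, path) -> None:
    """Write a mesh as binary little-endian PLY (.ply) or legacy VTK (.vtk)."""
    path = Path(path)
    if path.suffix.lower() == ".ply":
        path.write_bytes(_ply_binary_f64(mesh))
    elif path.suffix.lower() == ".vtk":
        _write_vtk_polydata(mesh, path)
    else:
        raise ValueError(f"unsupported mesh format: {path.suffix}")


def _ply_binary_f64(mesh: TriangleMesh) -> bytes:
    """Binary little-endian PLY with double-precision vertices.

    Written directly (rather than through a library) so the vertex
    coordinates round-trip bit-exactly; readers treat it as ordinary PLY.
    """
    header = "\n".join([
        "ply",
        "format binary_little_endian 1.0",
        f"element vertex {mesh.n_vertices}",
        "property double x",
        "property double y",
        "property double z",
        f"element face {mesh.n_faces}",
        "property list uchar int vertex_indices",
        "end_header",
    ]) + "\n"
    vbytes = np.ascontiguousarray(mesh.vertices, dtype="<f8").tobytes()
    face_rec = np.empty(mesh.n_faces,
                        dtype=[("n", "u1"), ("idx", "<i4", (3,))])
    face_rec["n"] = 3
    face_rec["idx"] = mesh.faces
    return header.encode("ascii") + vbytes + face_rec.tobytes()


def read_mesh(path, *, repair: bool = True) -> TriangleMesh:
    """Read a PLY or legacy-VTK PolyData mesh and validate invariants.

    A light repair pass merges duplicate vertices (1e-9 mm tolerance) and
    makes the face winding consistent with outward normals.  Violations
    remaining after repair raise :class:`MeshInvariantError` naming the
    invariant.
    """
    path = Path(path)
    if path.suffix.lower() == ".ply":
        tm = trimesh.load(str(path), file_type="ply", process=False)
        vertices, faces = np.asarray(tm.vertices), np.asarray(tm.faces)
    elif path.suffix.lower() == ".vtk":
        vertices, faces = _read_vtk_polydata(path)
    else:
        raise ValueError(f"unsupported mesh format: {path.suffix}")
    mesh = TriangleMesh(vertices, faces)
    if repair:
        mesh = repair_mesh(mesh)
    mesh.validate()
    return mesh


def repair_mesh(mesh: TriangleMesh) -> TriangleMesh:
    """Merge duplicate vertices and fix winding so normals point outward."""
    tm = trimesh.Trimesh(mesh.vertices, mesh.faces, process=False)
    tm.merge_vertices(digits_vertex=9)
    tm.update_faces(tm.nondegenerate_faces())
    trimesh.repair.fix_winding(tm)
    if tm.is_watertight and tm.volume < 0:
        tm.invert()
    return TriangleMesh(np.asarray(tm.vertices), np.asarray(tm.faces))


def _write_vtk_polydata(mesh: TriangleMesh, path: Path,
                        point_data: dict | None = None) -> None:
    lines = [
        "# vtk DataFile Version 3.0",
        "subshape surface",
        "ASCII",
        "DATASET POLYDATA",
        f"POINTS {mesh.n_vertices} double",
    ]
    lines += [" ".join(f"{x:.9g}" for x in v) for v in mesh.vertices]
    m = mesh.n_faces
    lines.append(f"POLYGONS {m} {4 * m}")
    lines += ["3 " + " ".join(str(i) for i in f) for f in mesh.faces]
    if point_data:
        lines.append(f"POINT_DATA {mesh.n_vertices}")
        for name, arr in point_data.items():
            arr = np.asarray(arr, dtype=float).reshape(mesh.n_vertices, -1)
            if arr.shape[1] == 1:
                lines.append(f"SCALARS {name} double 1")
                lines.append("LOOKUP_TABLE default")
                lines += [f"{x:.9g}" for x in arr[:, 0]]
            else:
                lines.append(f"FIELD fd_{name} 1")
                lines.append(f"{name} {arr.shape[1]} {mesh.n_vertices} double")
                lines += [" ".join(f"{x:.9g}" for x in row) for row in arr]
    Path(path).write_text("\n".join(lines) + "\n")


def write_vtk_with_data(mesh: TriangleMesh, path, point_data: dict) -> None:
    """Export a mesh with per-vertex arrays as legacy VTK for rendering."""
    _write_vtk_polydata(mesh, Path(path), point_data=point_data)


def _read_vtk_polydata(path: Path):
    tokens = Path(path).read_text().split()
    it = iter(range(len(tokens)))
    i = 0
    vertices = faces = None
    while i < len(tokens):
        tok = tokens[i].upper()
        if tok == "POINTS":
            n = int(tokens[i + 1])
            flat = np.array(tokens[i + 3:i + 3 + 3 * n], dtype=float)
            vertices = flat.reshape(n, 3)
            i += 3 + 3 * n
        elif tok == "POLYGONS":
            m = int(tokens[i + 1])
            size = int(tokens[i + 2])
            flat = np.array(tokens[i + 3:i + 3 + size], dtype=int)
            faces_list, j = [], 0
            while j < size:
                k = flat[j]
                if k != 3:
                    raise MeshInvariantError("triangles", f"polygon with {k} vertices")
                faces_list.append(flat[j + 1:j + 4])
                j += k + 1
            faces = np.array(faces_list, dtype=np.int64)
            i += 3 + size
        else:
            i += 1
    if vertices is None or faces is None:
        raise ValueError(f"{path}: not a VTK PolyData file")
    return vertices, faces


# ---------------------------------------------------------------------------
# Simplification (quadric edge collapse) and Loop subdivision
# ---------------------------------------------------------------------------

def simplify_mesh(mesh: TriangleMesh, target_face_count: int) -> TriangleMesh:
    """Simplify by iterative quadric-error edge collapse.

    Collapses the cheapest manifold-safe edge until the face count reaches
    ``target_face_count`` (each collapse on a closed mesh removes two
    faces).  Collapses that would break the link condition (and hence
    manifoldness or genus) are skipped; if no legal collapse remains the
    achieved count is returned early with a warning.
    """
    if target_face_count < 100:
        raise ValueError("target_face_count must be >= 100")
    if target_face_count > mesh.n_faces:
        raise ValueError("target exceeds current face count")
    if target_face_count == mesh.n_faces:
        return TriangleMesh(mesh.vertices.copy(), mesh.faces.copy())

    V = mesh.vertices.copy()
    F = mesh.faces.copy()
    nv = len(V)

    # per-vertex quadrics: sum of outer products of face plane coefficients
    quad = np.zeros((nv, 4, 4))
    tri = V[F]
    n = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    norms = np.linalg.norm(n, axis=1, keepdims=True)
    n = n / np.where(norms > 0, norms, 1.0)
    d = -np.einsum("ij,ij->i", n, tri[:, 0])
    p = np.hstack([n, d[:, None]])
    Kf = np.einsum("ij,ik->ijk", p, p)
    for c in range(3):
        np.add.at(quad, F[:, c], Kf)

    # adjacency as dict of sets
    neighbors = [set() for _ in range(nv)]
    vert_faces = [set() for _ in range(nv)]
    for fi, (a, b, c) in enumerate(F):
        neighbors[a].update((b, c)); neighbors[b].update((a, c)); neighbors[c].update((a, b))
        vert_faces[a].add(fi); vert_faces[b].add(fi); vert_faces[c].add(fi)
    alive_face = np.ones(len(F), bool)
    alive_vert = np.ones(nv, bool)
    n_faces = len(F)

    def collapse_cost(a, b):
        Q = quad[a] + quad[b]
        A = Q.copy(); A[3] = [0, 0, 0, 1]
        try:
            x = np.linalg.solve(A, np.array([0.0, 0.0, 0.0, 1.0]))
            pos = x[:3]
        except np.linalg.LinAlgError:
            pos = 0.5 * (V[a] + V[b])
        h = np.append(pos, 1.0)
        cands = [pos, V[a], V[b], 0.5 * (V[a] + V[b])]
        costs = [float(np.append(q, 1.0) @ Q @ np.append(q, 1.0)) for q in cands]
        k = int(np.argmin(costs))
        return costs[k], cands[k]

    heap = []
    version = {}
    for a in range(nv):
        for b in neighbors[a]:
            if a < b:
                cost, pos = collapse_cost(a, b)
                version[(a, b)] = 0
                heapq.heappush(heap, (cost, 0, a, b, pos))

    def link_ok(a, b):
        # link condition: common neighbours must be exactly the two
        # apex vertices of the faces sharing edge (a, b)
        shared_faces = vert_faces[a] & vert_faces[b]
        if len(shared_faces) != 2:
            return False
        apex = set()
        for fi in shared_faces:
            apex.update(F[fi])
        apex -= {a, b}
        return (neighbors[a] & neighbors[b]) == apex

    while n_faces > target_face_count and heap:
        cost, ver, a, b, pos = heapq.heappop(heap)
        key = (a, b) if a < b else (b, a)
        if not (alive_vert[a] and alive_vert[b]) or version.get(key, -1) != ver:
            continue
        if b not in neighbors[a] or not link_ok(a, b):
            continue
        # collapse b into a, move a to pos
        V[a] = pos
        quad[a] = quad[a] + quad[b]
        dead = vert_faces[a] & vert_faces[b]
        for fi in dead:
            alive_face[fi] = False
            for vtx in F[fi]:
                vert_faces[vtx].discard(fi)
            n_faces -= 1
        for fi in list(vert_faces[b]):
            F[fi][F[fi] == b] = a
            vert_faces[b].discard(fi)
            vert_faces[a].add(fi)
        alive_vert[b] = False
        for w in list(neighbors[b]):
            neighbors[w].discard(b)
            if w != a:
                neighbors[w].add(a)
                neighbors[a].add(w)
        neighbors[a].discard(a)
        neighbors[a].discard(b)
        # requeue edges around a
        for w in neighbors[a]:
            k2 = (a, w) if a < w else (w, a)
            ver2 = version.get(k2, 0) + 1
            version[k2] = ver2
            c2, p2 = collapse_cost(*k2)
            heapq.heappush(heap, (c2, ver2, k2[0], k2[1], p2))

    if n_faces > target_face_count:
        warnings.warn(
            f"simplification stopped early at {n_faces} faces "
            f"(no manifold-safe collapse left; target {target_face_count})")

    keep = np.where(alive_face)[0]
    newF = F[keep]
    used = np.unique(newF)
    remap = np.full(nv, -1, dtype=np.int64)
    remap[used] = np.arange(len(used))
    out = TriangleMesh(V[used], remap[newF])
    out.validate()
    return out


def loop_subdivide(mesh: TriangleMesh, levels: int) -> TriangleMesh:
    """Loop subdivision with the standard valence-dependent weights.

    ``levels = 0`` is the identity; each level quadruples the face count.
    """
    if levels < 0:
        raise ValueError("levels must be >= 0")
    if levels == 0:
        return TriangleMesh(mesh.vertices.copy(), mesh.faces.copy())
    tm = mesh.to_trimesh().subdivide_loop(iterations=levels)
    return TriangleMesh(np.asarray(tm.vertices), np.asarray(tm.faces))


# ---------------------------------------------------------------------------
# Curvature
# ---------------------------------------------------------------------------

_MIN_ANGLE_RAD = np.deg2rad(0.5)


def mean_curvature(mesh: TriangleMesh, *, return_flags: bool = False):
    """Discrete mean curvature via the cotangent Laplacian (Meyer et al.).

    The mean-curvature normal at vertex i is
    ``K_i = (1 / 2A_i) * sum_j (cot a_ij + cot b_ij) (x_i - x_j)``
    over the one-ring, with A_i the mixed Voronoi area; ``H = |K| / 2``
    signed so that a sphere with outward normals has H = +1/r.  Vertices
    touching near-degenerate triangles (min angle < 0.5 deg) are flagged
    and replaced by their one-ring average.
    """
    V, F = mesh.vertices, mesh.faces
    nv = len(V)
    tri = V[F]
    # internal angles, cotangents
    e = np.empty((len(F), 3, 3))
    e[:, 0] = tri[:, 2] - tri[:, 1]   # opposite vertex 0
    e[:, 1] = tri[:, 0] - tri[:, 2]
    e[:, 2] = tri[:, 1] - tri[:, 0]
    l2 = np.einsum("fij,fij->fi", e, e)
    area2 = np.linalg.norm(np.cross(e[:, 1], e[:, 2]), axis=1)  # 2 * area
    area2 = np.where(area2 > 1e-300, area2, 1e-300)
    # cot of angle at corner c = (l_a^2 + l_b^2 - l_c^2) / (4 * area)
    cot = np.empty((len(F), 3))
    for c in range(3):
        a, b = (c + 1) % 3, (c + 2) % 3
        cot[:, c] = (l2[:, a] + l2[:, b] - l2[:, c]) / (2.0 * area2)

    angles = np.arccos(np.clip(cot / np.sqrt(1.0 + cot ** 2), -1, 1))
    degenerate_face = angles.min(axis=1) < _MIN_ANGLE_RAD

    # mixed Voronoi areas
    A = np.zeros(nv)
    obtuse = cot < 0.0   # angle > 90 deg at that corner
    any_obtuse = obtuse.any(axis=1)
    tri_area = 0.5 * area2
    for c in range(3):
        a, b = (c + 1) % 3, (c + 2) % 3
        vor = 0.125 * (l2[:, a] * cot[:, a] + l2[:, b] * cot[:, b])
        contrib = np.where(
            any_obtuse,
            np.where(obtuse[:, c], 0.5 * tri_area, 0.25 * tri_area),
            vor)
        np.add.at(A, F[:, c], contrib)

    # mean curvature normal accumulation
    K = np.zeros((nv, 3))
    for c in range(3):
        a, b = (c + 1) % 3, (c + 2) % 3
        # edge (F[:,a], F[:,b]) is opposite corner c; cot[:, c] weights it
        diff = V[F[:, a]] - V[F[:, b]]
        w = cot[:, c][:, None]
        np.add.at(K, F[:, a], w * diff)
        np.add.at(K, F[:, b], -w * diff)
    A = np.where(A > 1e-300, A, 1e-300)
    K /= (2.0 * A[:, None])

    normals = mesh.to_trimesh().vertex_normals
    sign = np.sign(np.einsum("ij,ij->i", K, normals))
    sign[sign == 0] = 1.0
    H = 0.5 * np.linalg.norm(K, axis=1) * sign

    flags = np.zeros(nv, bool)
    for c in range(3):
        flags[F[degenerate_face, c]] = True
    if flags.any():
        adj = sp.coo_matrix(
            (np.ones(3 * len(F)),
             (F[:, [0, 1, 2]].ravel(), F[:, [1, 2, 0]].ravel())),
            shape=(nv, nv)).tocsr()
        adj = adj + adj.T
        deg = np.asarray(adj.sum(axis=1)).ravel()
        smoothed = adj @ H / np.where(deg > 0, deg, 1)
        H = np.where(flags, smoothed, H)
    if return_flags:
        return H, flags
    return H


def _cotan_laplacian(V, F):
    """Sparse cotangent Laplacian (positive semi-definite convention)."""
    tri = V[F]
    e = np.empty((len(F), 3, 3))
    e[:, 0] = tri[:, 2] - tri[:, 1]
    e[:, 1] = tri[:, 0] - tri[:, 2]
    e[:, 2] = tri[:, 1] - tri[:, 0]
    l2 = np.einsum("fij,fij->fi", e, e)
    area2 = np.linalg.norm(np.cross(e[:, 1], e[:, 2]), axis=1)
    area2 = np.where(area2 > 1e-300, area2, 1e-300)
    rows, cols, vals = [], [], []
    for c in range(3):
        a, b = (c + 1) % 3, (c + 2) % 3
        w = (l2[:, a] + l2[:, b] - l2[:, c]) / (4.0 * area2)  # 0.5 * cot
        rows.append(F[:, a]); cols.append(F[:, b]); vals.append(w)
        rows.append(F[:, b]); cols.append(F[:, a]); vals.append(w)
    rows = np.concatenate(rows); cols = np.concatenate(cols)
    vals = np.concatenate(vals)
    W = sp.coo_matrix((vals, (rows, cols)), shape=(len(V), len(V))).tocsr()
    L = sp.diags(np.asarray(W.sum(axis=1)).ravel()) - W
    return L


# ---------------------------------------------------------------------------
# Conformal parameterization
# ---------------------------------------------------------------------------

def conformal_parameterize(mesh: TriangleMesh, dims=(100, 150),
                           periodic_v: bool = True) -> ConformalGrid:
    """Map a closed tube-like genus-0 surface onto the standard grid.

    The surface is cut at its two extremal vertices along the first
    principal axis of the vertex cloud.  ``u`` solves the Laplace
    equation with the cuts pinned to 0 and 1; ``v`` is the periodic
    conjugate-like coordinate obtained by cutting the surface along the
    shortest-path seam between the cuts and solving Laplace with a
    ``2*pi`` jump across the seam.  Positions, the conformal factor and
    the mean curvature are then resampled on the regular ``dims`` grid,
    with ``u`` sampled at cell centres (the poles are parameterization
    singularities).

    Raises :class:`ParameterizationError` when the parameter map flips
    triangles (with the flip count) or when the input is not tube-like.
    """
    nu, nv = dims
    if nu < 3 or nv < 3:
        raise ValueError("grid dims must be at least 3x3")
    mesh.validate()
    V, F = mesh.vertices, mesh.faces
    n = len(V)

    # --- poles: extremes along first principal axis
    ctr = V.mean(axis=0)
    _, _, VT = np.linalg.svd(V - ctr, full_matrices=False)
    axis = VT[0]
    proj = (V - ctr) @ axis
    pole_a, pole_b = int(np.argmin(proj)), int(np.argmax(proj))
    if pole_a == pole_b:
        raise ParameterizationError("degenerate principal axis")

    L = _cotan_laplacian(V, F)

    # --- axial coordinate u: harmonic with Dirichlet poles, then
    # relabelled by the surface-area CDF (level sets unchanged) so grid
    # rows are equal-area; the raw harmonic u crowds logarithmically
    # near the point Dirichlet poles and would starve the end rows.
    u_raw = _solve_dirichlet(L, {pole_a: 0.0, pole_b: 1.0}, n)
    u = _equalize_by_area(u_raw, V, F)

    # --- seam: shortest edge path pole_a -> pole_b
    E = mesh.edges_unique()
    w = np.linalg.norm(V[E[:, 0]] - V[E[:, 1]], axis=1)
    G = sp.coo_matrix((np.r_[w, w], (np.r_[E[:, 0], E[:, 1]],
                                     np.r_[E[:, 1], E[:, 0]])), shape=(n, n)).tocsr()
    _, pred = sp.csgraph.dijkstra(G, indices=pole_a, return_predecessors=True)
    seam = [pole_b]
    while seam[-1] != pole_a:
        p = pred[seam[-1]]
        if p < 0:
            raise ParameterizationError("poles are not connected")
        seam.append(int(p))
    seam = seam[::-1]             # pole_a ... pole_b

    v_coord, cutV, cutF, cut_orig = _solve_seam_angle(V, F, seam)

    # --- orientation: make v increase consistently with CCW faces.
    # Injectivity is checked on the raw harmonic coordinate (the area
    # relabelling is monotone, so it cannot change true injectivity).
    ucut = u[cut_orig]
    s_area = _param_signed_areas(u_raw[cut_orig], v_coord, cutF)
    ok = np.abs(s_area) > 1e-14
    if np.sum(s_area[ok] < 0) > np.sum(s_area[ok] > 0):
        v_coord = 2.0 * np.pi - v_coord
        s_area = -s_area
    flips = int(np.sum(s_area[ok] < 0))
    if flips > max(2, 0.002 * len(cutF)):
        raise ParameterizationError(
            f"parameter map not injective: {flips} flipped triangles")

    # --- resample positions and curvature on the regular grid
    H_vert = mean_curvature(mesh)
    Hcut = H_vert[cut_orig]
    u_samples = (np.arange(nu) + 0.5) / nu
    v_samples = 2.0 * np.pi * np.arange(nv) / nv
    pos, Hgrid = _resample_grid(ucut, v_coord, cutF, cutV, Hcut,
                                u_samples, v_samples)

    lam = conformal_factor_from_positions(pos, 1.0 / nu, 2.0 * np.pi / nv)
    n_repaired = 0
    bad = lam <= 0
    if bad.any():
        if bad.mean() > 0.01:
            raise ParameterizationError(
                f"{int(bad.sum())} grid nodes with non-positive area density")
        # isolated degeneracies (parallel tangents at end rows): take the
        # neighbourhood mean of the positive values
        n_repaired = int(bad.sum())
        ring = np.roll(lam, 1, axis=1) + np.roll(lam, -1, axis=1)
        cnt = (np.roll(lam, 1, axis=1) > 0).astype(float) + \
              (np.roll(lam, -1, axis=1) > 0).astype(float)
        repl = np.where(cnt > 0, ring / np.maximum(cnt, 1), lam.max())
        lam = np.where(bad, np.maximum(repl, 1e-9), lam)
    meta = {
        "repaired_lambda_nodes": n_repaired,
        "u_samples": "cell centers (i + 0.5)/nu",
        "poles": [pole_a, pole_b],
        "seam_length": len(seam),
        "flipped_triangles": flips,
        "lambda_definition": "surface area element per unit parameter area, |X_u x X_v|",
        "axes": "u: along first principal axis; v: periodic [0, 2pi)",
    }
    return ConformalGrid((nu, nv), pos, lam, Hgrid, periodic_v=periodic_v,
                         metadata=meta)


def _equalize_by_area(u, V, F):
    """Monotone relabelling of u by the cumulative surface-area fraction."""
    tri = V[F]
    areas = 0.5 * np.linalg.norm(
        np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1)
    fu = u[F].mean(axis=1)
    order = np.argsort(fu)
    cdf_u = fu[order]
    cdf_a = np.cumsum(areas[order])
    cdf_a /= cdf_a[-1]
    # strictly increasing knots for interpolation
    knots_u = np.concatenate([[0.0], cdf_u, [1.0]])
    knots_a = np.concatenate([[0.0], cdf_a, [1.0]])
    keep = np.concatenate([[True], np.diff(knots_u) > 1e-12])
    return np.interp(u, knots_u[keep], knots_a[keep])


def _solve_dirichlet(L, fixed: dict, n: int) -> np.ndarray:
    idx_fixed = np.array(sorted(fixed), dtype=int)
    vals = np.array([fixed[i] for i in idx_fixed])
    free = np.setdiff1d(np.arange(n), idx_fixed)
    Lff = L[free][:, free].tocsc()
    rhs = -L[free][:, idx_fixed] @ vals
    x = np.empty(n)
    x[idx_fixed] = vals
    x[free] = spla.spsolve(Lff, rhs)
    return x


def _solve_seam_angle(V, F, seam):
    """Cut the mesh along the seam path; solve the periodic coordinate.

    Returns (v_coord, cut_vertices, cut_faces, original_index) where the
    cut mesh duplicates interior seam vertices: the original copies carry
    v = 0, the duplicates v = 2*pi.  The two poles (seam endpoints) and
    their incident faces are removed; the coordinate is harmonic on the
    rest with natural boundary conditions at the polar holes.
    """
    n = len(V)
    interior = seam[1:-1]
    if not interior:
        raise ParameterizationError("seam too short; mesh is not tube-like")
    on_seam = np.zeros(n, bool)
    on_seam[interior] = True
    poles = {seam[0], seam[-1]}
    seam_next = {}
    for i in range(len(seam) - 1):
        seam_next[seam[i]] = seam[i + 1]

    # vertex -> incident faces
    vf = [[] for _ in range(n)]
    for fi, f in enumerate(F):
        for vtx in f:
            vf[vtx].append(fi)

    # for each interior seam vertex, split its one-ring into the two fans
    # bounded by the seam edges; one fan keeps the original index, the
    # other is rewired to a duplicate.
    dup_index = {}
    cutV = [V]
    extra = []
    face_rewire = {}   # (face, vertex) pairs to rewire
    next_id = n
    for s in interior:
        prev_s = seam[seam.index(s) - 1]  # fine: seam is short
        next_s = seam_next[s]
        # ordered fan around s via half-edge walk
        ring = _ordered_one_ring(F, vf[s], s)
        if ring is None:
            raise ParameterizationError("seam vertex with non-disk one-ring")
        order, faces_order = ring
        try:
            i_prev = order.index(prev_s)
            i_next = order.index(next_s)
        except ValueError as exc:
            raise ParameterizationError("seam path not edge-connected") from exc
        k = len(order)
        # fan of faces strictly between prev_s and next_s going one way
        side = set()
        j = i_prev
        while j % k != i_next % k:
            side.add(faces_order[j % k])
            j += 1
        dup_index[s] = next_id
        extra.append(V[s])
        for fi in side:
            face_rewire[(fi, s)] = next_id
        next_id += 1

    cutV = np.vstack([V] + [np.asarray(extra)]) if extra else V.copy()
    cutF = F.copy()
    for (fi, s), newid in face_rewire.items():
        cutF[fi][cutF[fi] == s] = newid

    # drop faces touching the poles
    keep = ~np.isin(cutF, list(poles)).any(axis=1)
    cutF = cutF[keep]
    used = np.unique(cutF)
    remap = np.full(next_id, -1, dtype=int)
    remap[used] = np.arange(len(used))
    orig_of = np.concatenate([np.arange(n), np.array(interior, dtype=int)])
    cut_orig = orig_of[used]
    cutV = cutV[used]
    cutF = remap[cutF]

    # Dirichlet: original seam copies -> 0, duplicates -> 2*pi
    fixed = {}
    for s in interior:
        i0, i1 = remap[s], remap[dup_index[s]]
        if i0 >= 0:
            fixed[int(i0)] = 0.0
        if i1 >= 0:
            fixed[int(i1)] = 2.0 * np.pi
    L = _cotan_laplacian(cutV, cutF)
    v_coord = _solve_dirichlet(L, fixed, len(cutV))
    return v_coord, cutV, cutF, cut_orig


def _ordered_one_ring(F, face_ids, center):
    """Walk faces around ``center``; return (neighbor order, face order)."""
    # local edges: for each face, the two neighbours of center in CCW order
    succ = {}
    faces_by_pair = {}
    for fi in face_ids:
        f = list(F[fi])
        i = f.index(center)
        a, b = f[(i + 1) % 3], f[(i + 2) % 3]
        succ[a] = b
        faces_by_pair[a] = fi
    start = next(iter(succ))
    order, faces_order = [], []
    cur = start
    for _ in range(len(succ)):
        order.append(cur)
        faces_order.append(faces_by_pair[cur])
        cur = succ.get(cur)
        if cur is None:
            return None
    if cur != start:
        return None
    return order, faces_order


def _param_signed_areas(u, v, F):
    p = np.stack([u, v], axis=1)[F]
    e1 = p[:, 1] - p[:, 0]
    e2 = p[:, 2] - p[:, 0]
    return 0.5 * (e1[:, 0] * e2[:, 1] - e1[:, 1] * e2[:, 0])


def _bary_weights(pa, pb, pc, pt):
    det = (pb[0] - pa[0]) * (pc[1] - pa[1]) - (pc[0] - pa[0]) * (pb[1] - pa[1])
    if abs(det) < 1e-300:
        return None
    w1 = ((pt[0] - pa[0]) * (pc[1] - pa[1]) - (pc[0] - pa[0]) * (pt[1] - pa[1])) / det
    w2 = ((pb[0] - pa[0]) * (pt[1] - pa[1]) - (pt[0] - pa[0]) * (pb[1] - pa[1])) / det
    return np.array([1.0 - w1 - w2, w1, w2])


def _resample_grid(u, v, F, positions, H, u_samples, v_samples):
    """Barycentric resampling from the (u, v) triangulation to the grid.

    Periodicity in v is handled by tiling the triangulation at v - 2*pi
    and v + 2*pi; each grid node is located by walking the triangles
    incident to its nearest parameter-domain vertices.
    """
    from scipy.spatial import cKDTree

    nvert = len(u)
    u3 = np.concatenate([u, u, u])
    v3 = np.concatenate([v - 2 * np.pi, v, v + 2 * np.pi])
    F3 = np.vstack([F, F + nvert, F + 2 * nvert])
    pos3 = np.vstack([positions] * 3)
    H3 = np.concatenate([H] * 3)
    pts = np.stack([u3, v3], axis=1)

    vert_tris = [[] for _ in range(3 * nvert)]
    for ti, f in enumerate(F3):
        for vx in f:
            vert_tris[vx].append(ti)

    tree = cKDTree(pts)
    uu, vv = np.meshgrid(u_samples, v_samples, indexing="ij")
    queries = np.stack([uu.ravel(), vv.ravel()], axis=1)
    k_near = min(12, 3 * nvert)
    _, nearest = tree.query(queries, k=k_near)
    nearest = np.atleast_2d(nearest)

    out_pos = np.empty((len(queries), 3))
    out_H = np.empty(len(queries))
    for qi, pt in enumerate(queries):
        best_w, best_t, best_pen = None, None, np.inf
        seen = set()
        for vx in nearest[qi]:
            for ti in vert_tris[vx]:
                if ti in seen:
                    continue
                seen.add(ti)
                a, b, c = F3[ti]
                w = _bary_weights(pts[a], pts[b], pts[c], pt)
                if w is None:
                    continue
                pen = -min(w.min(), 0.0)
                if pen < best_pen:
                    best_pen, best_w, best_t = pen, w, ti
                    if pen == 0.0:
                        break
            if best_pen == 0.0:
                break
        if best_w is None:
            vx = nearest[qi][0]
            out_pos[qi] = pos3[vx]
            out_H[qi] = H3[vx]
            continue
        # mild linear extrapolation (unclipped weights) keeps end rows
        # beyond the last mesh ring non-degenerate; clamp hard overshoots
        w = best_w if best_pen < 0.75 else np.clip(best_w, 0.0, None)
        w = w / w.sum()
        idx = F3[best_t]
        out_pos[qi] = w @ pos3[idx]
        out_H[qi] = w @ H3[idx]
    shape = uu.shape
    return out_pos.reshape(shape + (3,)), out_H.reshape(shape)


def conformal_factor_from_positions(positions: np.ndarray, du: float,
                                    dv: float) -> np.ndarray:
    """Area-distortion density lambda = |X_u x X_v| by central differences.

    v is treated as periodic; u uses one-sided differences at the ends.
    """
    Xu = np.empty_like(positions)
    Xu[1:-1] = (positions[2:] - positions[:-2]) / (2 * du)
    Xu[0] = (positions[1] - positions[0]) / du
    Xu[-1] = (positions[-1] - positions[-2]) / du
    Xv = (np.roll(positions, -1, axis=1) - np.roll(positions, 1, axis=1)) / (2 * dv)
    lam = np.linalg.norm(np.cross(Xu, Xv), axis=-1)
    return lam


def grid_mean_curvature(positions: np.ndarray, du: float, dv: float) -> np.ndarray:
    """Mean curvature of a parametric surface grid by finite differences.

    Uses the first and second fundamental forms; v is periodic, u clamped.
    The sign follows the X_u x X_v normal, flipped if that normal points
    inward on average (toward the per-ring centroid).
    """
    def d_u(A):
        out = np.empty_like(A)
        out[1:-1] = (A[2:] - A[:-2]) / (2 * du)
        out[0] = (A[1] - A[0]) / du
        out[-1] = (A[-1] - A[-2]) / du
        return out

    def d_v(A):
        return (np.roll(A, -1, axis=1) - np.roll(A, 1, axis=1)) / (2 * dv)

    Xu, Xv = d_u(positions), d_v(positions)
    Xuu, Xvv = d_u(Xu), d_v(Xv)
    Xuv = d_v(Xu)
    E = np.einsum("ijd,ijd->ij", Xu, Xu)
    Fff = np.einsum("ijd,ijd->ij", Xu, Xv)
    G = np.einsum("ijd,ijd->ij", Xv, Xv)
    nrm = np.cross(Xu, Xv)
    nn = np.linalg.norm(nrm, axis=-1, keepdims=True)
    nrm = nrm / np.where(nn > 1e-300, nn, 1e-300)
    Lf = np.einsum("ijd,ijd->ij", Xuu, nrm)
    Mf = np.einsum("ijd,ijd->ij", Xuv, nrm)
    Nf = np.einsum("ijd,ijd->ij", Xvv, nrm)
    denom = E * G - Fff ** 2
    denom = np.where(np.abs(denom) > 1e-300, denom, 1e-300)
    H = -(E * Nf - 2 * Fff * Mf + G * Lf) / (2 * denom)
    # orient: outward = away from the per-ring centroid (sphere -> +1/r)
    ctr = positions.mean(axis=1, keepdims=True)
    outward = positions - ctr
    if np.mean(np.einsum("ijd,ijd->ij", nrm, outward)) < 0:
        H = -H
    return H


def conformal_representation(grid: ConformalGrid):
    """Return the (lambda, H) registration channels, standardized.

    Each channel is shifted/scaled to zero mean and unit variance over
    the grid; the affine parameters are returned in the metadata dict so
    the transform is invertible.
    """
    lam, H = grid.conformal_factor, grid.mean_curvature
    if not (np.all(np.isfinite(lam)) and np.all(np.isfinite(H))):
        raise ValueError("non-finite conformal factor or curvature")
    meta = {}
    out = np.empty((2,) + grid.dims)
    for k, (name, ch) in enumerate((("lambda", lam), ("H", H))):
        mu, sd = float(ch.mean()), float(ch.std())
        sd_eff = sd if sd > 1e-12 else 1.0
        out[k] = (ch - mu) / sd_eff
        meta[name] = {"mean": mu, "std": sd}
    return out, meta
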