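"""Triangle-mesh data model, STL/PLY I/O and exact geometric queries.

Everything downstream (crown synthesis, ICP superimposition, slicing and
volume differencing) moves :class:`SurfaceMesh` objects around.  Units are
millimetres throughout; meshes are plain indexed triangle sets with derived
per-face outward normals.

The nearest-point machinery (:class:`NearestQuery`) returns the *exact*
closest point on the surface — the kd-tree over sub-triangle centroids is a
pruning device only and never changes the answer relative to a brute-force
scan over all triangles.
"""

from __future__ import annotations

import io
import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh
from scipy.spatial import cKDTree

__all__ = [
    "RigidTransform",
    "SurfaceMesh",
    "NearestQuery",
    "NonWatertightError",
    "MeshFormatError",
    "load_mesh",
    "save_mesh",
    "nearest_surface_point",
    "signed_distance_map",
    "random_rigid_transform",
]

#: tolerance (mm) for merging duplicated vertices on load
VERTEX_MERGE_TOL = 1e-6
#: faces with area below this (mm^2) are treated as degenerate on load
DEGENERATE_AREA_TOL = 1e-12
#: tolerance (mm) for the on-boundary flag of nearest-point queries
BOUNDARY_TOL = 1e-9


class NonWatertightError(ValueError):
    """Raised when a closed mesh is required but boundary edges exist."""


class MeshFormatError(ValueError):
    """Raised for files that parse but violate the supported format subset."""


# ---------------------------------------------------------------------------
# rigid transforms
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion ``x -> R x + t`` in mm.

    ``rotation`` is a 3x3 orthonormal matrix with determinant +1 and
    ``translation`` a 3-vector.  Composition and inversion stay inside the
    group; applying a transform preserves pairwise distances.
    """

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation matrix is not orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("rotation matrix is a reflection")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_matrix(cls, matrix: np.ndarray) -> "RigidTransform":
        m = np.asarray(matrix, dtype=float).reshape(4, 4)
        return cls(m[:3, :3], m[:3, 3])

    @classmethod
    def from_rotvec(cls, rotvec, translation) -> "RigidTransform":
        from scipy.spatial.transform import Rotation

        return cls(Rotation.from_rotvec(np.asarray(rotvec, float)).as_matrix(),
                   np.asarray(translation, float))

    @property
    def matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    def apply(self, points: np.ndarray) -> np.ndarray:
        p = np.asarray(points, dtype=float)
        return p @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return ``self ∘ other`` (apply ``other`` first)."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation + self.translation)

    def inverse(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(Rt, -Rt @ self.translation)

    def rotation_angle(self) -> float:
        """Rotation magnitude in radians."""
        c = (np.trace(self.rotation) - 1.0) / 2.0
        return float(np.arccos(np.clip(c, -1.0, 1.0)))


def random_rigid_transform(rng: np.random.Generator,
                           max_angle_deg: float,
                           max_translation: float) -> RigidTransform:
    """Seeded rigid motion with uniform random axis, angle and translation."""
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = np.deg2rad(rng.uniform(0.0, max_angle_deg))
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    shift = rng.uniform(0.0, max_translation) * direction
    return RigidTransform.from_rotvec(axis * angle, shift)


# ---------------------------------------------------------------------------
# mesh cleanup helpers
# ---------------------------------------------------------------------------


def _merge_duplicate_vertices(vertices: np.ndarray, faces: np.ndarray,
                              tol: float = VERTEX_MERGE_TOL):
    """Merge vertices closer than ``tol``; remap faces.

    Uses single-linkage clustering over the close-pair graph so that chains
    of near-duplicates collapse consistently (binary STL repeats every vertex
    per facet, so in practice clusters are exact duplicates).
    """
    if len(vertices) == 0:
        return vertices, faces
    tree = cKDTree(vertices)
    pairs = tree.query_pairs(tol, output_type="ndarray")
    parent = np.arange(len(vertices))

    def find(i):
        root = i
        while parent[root] != root:
            root = parent[root]
        while parent[i] != root:
            parent[i], i = root, parent[i]
        return root

    for a, b in pairs:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)
    roots = np.array([find(i) for i in range(len(vertices))])
    uniq, inverse = np.unique(roots, return_inverse=True)
    return vertices[uniq], inverse[faces]


def _drop_degenerate_faces(vertices: np.ndarray, faces: np.ndarray):
    if len(faces) == 0:
        return faces
    distinct = ((faces[:, 0] != faces[:, 1]) & (faces[:, 1] != faces[:, 2])
                & (faces[:, 0] != faces[:, 2]))
    tri = vertices[faces]
    areas = 0.5 * np.linalg.norm(
        np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1)
    return faces[distinct & (areas > DEGENERATE_AREA_TOL)]


# ---------------------------------------------------------------------------
# SurfaceMesh
# ---------------------------------------------------------------------------


class SurfaceMesh:
    """Indexed triangle surface in mm with derived outward face normals.

    Parameters
    ----------
    vertices : (n, 3) float array
    faces : (m, 3) int array
        Triangles as vertex-index triples, counter-clockwise when viewed
        from outside for an outward-oriented mesh.
    clean : bool
        When true, merge duplicate vertices (1e-6 mm) and drop degenerate
        faces — the standard post-load cleanup.
    """

    def __init__(self, vertices, faces, clean: bool = False):
        vertices = np.ascontiguousarray(np.asarray(vertices, dtype=float).reshape(-1, 3))
        faces = np.ascontiguousarray(np.asarray(faces, dtype=np.int64).reshape(-1, 3))
        if len(faces) and (faces.min() < 0 or faces.max() >= len(vertices)):
            raise ValueError("face indices out of range")
        if clean:
            vertices, faces = _merge_duplicate_vertices(vertices, faces)
            faces = _drop_degenerate_faces(vertices, faces)
        self.vertices = vertices
        self.faces = faces
        self._cache: dict = {}

    # -- basic derived quantities ------------------------------------------

    def __len__(self) -> int:
        return len(self.faces)

    def copy(self) -> "SurfaceMesh":
        return SurfaceMesh(self.vertices.copy(), self.faces.copy())

    @property
    def triangles(self) -> np.ndarray:
        return self.vertices[self.faces]

    @property
    def face_normals(self) -> np.ndarray:
        if "face_normals" not in self._cache:
            tri = self.triangles
            n = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
            norm = np.linalg.norm(n, axis=1)
            norm[norm == 0] = 1.0
            self._cache["face_normals"] = n / norm[:, None]
        return self._cache["face_normals"]

    @property
    def face_areas(self) -> np.ndarray:
        if "face_areas" not in self._cache:
            tri = self.triangles
            self._cache["face_areas"] = 0.5 * np.linalg.norm(
                np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1)
        return self._cache["face_areas"]

    @property
    def vertex_normals(self) -> np.ndarray:
        """Area-weighted average of incident face normals, unit length."""
        if "vertex_normals" not in self._cache:
            vn = np.zeros_like(self.vertices)
            weighted = self.face_normals * self.face_areas[:, None]
            for k in range(3):
                np.add.at(vn, self.faces[:, k], weighted)
            norm = np.linalg.norm(vn, axis=1)
            norm[norm == 0] = 1.0
            self._cache["vertex_normals"] = vn / norm[:, None]
        return self._cache["vertex_normals"]

    @property
    def area(self) -> float:
        return float(self.face_areas.sum())

    # -- topology ----------------------------------------------------------

    def directed_edges(self) -> np.ndarray:
        """(3m, 2) array of directed edges in face winding order."""
        f = self.faces
        return np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])

    def boundary_edges(self) -> np.ndarray:
        """Directed edges whose reverse is not present (k, 2)."""
        if "boundary_edges" not in self._cache:
            de = self.directed_edges()
            keys = de[:, 0] * len(self.vertices) + de[:, 1]
            rev = de[:, 1] * len(self.vertices) + de[:, 0]
            has_rev = np.isin(keys, rev)
            self._cache["boundary_edges"] = de[~has_rev]
        return self._cache["boundary_edges"]

    def boundary_vertex_mask(self) -> np.ndarray:
        mask = np.zeros(len(self.vertices), dtype=bool)
        be = self.boundary_edges()
        if len(be):
            mask[be.ravel()] = True
        return mask

    @property
    def is_consistently_oriented(self) -> bool:
        """Each directed edge appears at most once (manifold winding)."""
        de = self.directed_edges()
        keys = de[:, 0] * len(self.vertices) + de[:, 1]
        return len(np.unique(keys)) == len(keys)

    @property
    def is_watertight(self) -> bool:
        return self.is_consistently_oriented and len(self.boundary_edges()) == 0

    # -- geometry ----------------------------------------------------------

    def enclosed_volume(self) -> float:
        """Signed enclosed volume (mm^3) by the divergence theorem.

        Sum of signed tetrahedron volumes against the origin; positive for
        an outward-oriented watertight mesh, negative if oriented inward.

        Raises
        ------
        NonWatertightError
            If the mesh has boundary edges (message includes the count).
        """
        nb = len(self.boundary_edges())
        if nb:
            raise NonWatertightError(
                f"mesh is not watertight: {nb} boundary edges")
        tri = self.triangles
        return float(np.einsum("ij,ij->", tri[:, 0],
                               np.cross(tri[:, 1], tri[:, 2])) / 6.0)

    def transformed(self, transform: RigidTransform) -> "SurfaceMesh":
        return SurfaceMesh(transform.apply(self.vertices), self.faces.copy())

    def bounds(self) -> np.ndarray:
        return np.array([self.vertices.min(axis=0), self.vertices.max(axis=0)])

    # -- queries (cached helpers) ------------------------------------------

    @property
    def nearest(self) -> "NearestQuery":
        if "nearest" not in self._cache:
            self._cache["nearest"] = NearestQuery(self)
        return self._cache["nearest"]

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(self.vertices.copy(), self.faces.copy(),
                               process=False)


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------


def _validate_ply_triangulated(path: Path) -> None:
    """Reject PLY files with non-triangle faces, naming the face index.

    Supports the ascii and binary_little_endian subsets of the format.
    """
    sizes = {"char": 1, "int8": 1, "uchar": 1, "uint8": 1,
             "short": 2, "int16": 2, "ushort": 2, "uint16": 2,
             "int": 4, "int32": 4, "uint": 4, "uint32": 4,
             "float": 4, "float32": 4, "double": 8, "float64": 8}
    fmt_map = {1: "b", 2: "h", 4: "i"}
    with open(path, "rb") as fh:
        header_lines = []
        while True:
            line = fh.readline()
            if not line:
                raise MeshFormatError("truncated PLY header")
            text = line.decode("ascii", errors="replace").strip()
            header_lines.append(text)
            if text == "end_header":
                break
        body_start = fh.tell()
    fmt = None
    elements = []  # (name, count, [(kind, ...)]) in declaration order
    for text in header_lines:
        parts = text.split()
        if not parts:
            continue
        if parts[0] == "format":
            fmt = parts[1]
        elif parts[0] == "element":
            elements.append([parts[1], int(parts[2]), []])
        elif parts[0] == "property" and elements:
            if parts[1] == "list":
                elements[-1][2].append(("list", sizes[parts[2]], sizes[parts[3]]))
            else:
                elements[-1][2].append(("scalar", sizes[parts[1]]))
    if fmt not in ("ascii", "binary_little_endian"):
        raise MeshFormatError(f"unsupported PLY format {fmt!r}")
    if fmt == "ascii":
        with open(path, "rb") as fh:
            fh.seek(body_start)
            lines = fh.read().decode("ascii", errors="replace").splitlines()
        cursor = 0
        for name, count, props in elements:
            if name == "face":
                for i in range(count):
                    n = int(lines[cursor + i].split()[0])
                    if n != 3:
                        raise MeshFormatError(
                            f"PLY face {i} has {n} vertices; only triangles "
                            "are supported")
            cursor += count
        return
    with open(path, "rb") as fh:
        fh.seek(body_start)
        for name, count, props in elements:
            fixed = sum(p[1] for p in props if p[0] == "scalar")
            has_list = any(p[0] == "list" for p in props)
            if not has_list:
                fh.seek(count * fixed, io.SEEK_CUR)
                continue
            for i in range(count):
                for kind, *ps in props:
                    if kind == "scalar":
                        fh.seek(ps[0], io.SEEK_CUR)
                    else:
                        csize, isize = ps
                        raw = fh.read(csize)
                        n = struct.unpack("<" + fmt_map[csize].upper()
                                          if csize == 1 else "<" + fmt_map[csize],
                                          raw)[0]
                        if name == "face" and n != 3:
                            raise MeshFormatError(
                                f"PLY face {i} has {n} vertices; only "
                                "triangles are supported")
                        fh.seek(n * isize, io.SEEK_CUR)


def load_mesh(path, file_format: str | None = None) -> SurfaceMesh:
    """Load an STL or PLY surface into a cleaned :class:`SurfaceMesh`.

    Duplicate vertices are merged at 1e-6 mm tolerance and degenerate
    (zero-area) faces dropped.  Coordinates are taken as millimetres
    verbatim (STL itself is unitless).

    Parameters
    ----------
    path : path-like
    file_format : {"stl", "ply"}, optional
        Inferred from the file suffix when omitted.
    """
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(f"mesh file not found: {path}")
    fmt = (file_format or path.suffix.lstrip(".")).lower()
    if fmt not in ("stl", "ply"):
        raise MeshFormatError(f"unsupported mesh format {fmt!r}")
    if fmt == "ply":
        _validate_ply_triangulated(path)
    try:
        tm = trimesh.load_mesh(str(path), file_type=fmt, process=False)
    except Exception as exc:  # noqa: BLE001 - normalise loader errors
        raise IOError(f"could not read {fmt} file {path}: {exc}") from exc
    if isinstance(tm, trimesh.Scene):
        tm = tm.to_mesh()
    return SurfaceMesh(np.asarray(tm.vertices, float),
                       np.asarray(tm.faces, np.int64), clean=True)


def save_mesh(mesh: SurfaceMesh, path, file_format: str | None = None) -> None:
    """Write a mesh; binary little-endian STL by default, PLY on request."""
    path = Path(path)
    fmt = (file_format or path.suffix.lstrip(".")).lower() or "stl"
    mesh.to_trimesh().export(str(path), file_type=fmt)


# ---------------------------------------------------------------------------
# exact nearest point on surface
# ---------------------------------------------------------------------------


def closest_point_on_triangles(points: np.ndarray, triangles: np.ndarray):
    """Exact closest point on each triangle for each (point, triangle) pair.

    Vectorised region-based algorithm (interior / edges / vertices of the
    triangle's barycentric decomposition).  ``points`` is (k, 3) and
    ``triangles`` (k, 3, 3); returns (closest (k, 3), squared distance (k,)).
    """
    p = np.asarray(points, float)
    a, b, c = triangles[:, 0], triangles[:, 1], triangles[:, 2]
    ab, ac, ap = b - a, c - a, p - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = p - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    result = np.empty_like(p)
    done = np.zeros(len(p), dtype=bool)

    def assign(mask, value):
        sel = mask & ~done
        result[sel] = value[sel]
        done[sel] = True

    assign((d1 <= 0) & (d2 <= 0), a)                       # vertex A
    assign((d3 >= 0) & (d4 <= d3), b)                      # vertex B
    assign((d6 >= 0) & (d5 <= d6), c)                      # vertex C

    vc = d1 * d4 - d3 * d2
    with np.errstate(invalid="ignore", divide="ignore"):
        v_ab = np.where(d1 - d3 != 0, d1 / (d1 - d3), 0.0)
    assign((vc <= 0) & (d1 >= 0) & (d3 <= 0), a + v_ab[:, None] * ab)

    vb = d5 * d2 - d1 * d6
    with np.errstate(invalid="ignore", divide="ignore"):
        w_ac = np.where(d2 - d6 != 0, d2 / (d2 - d6), 0.0)
    assign((vb <= 0) & (d2 >= 0) & (d6 <= 0), a + w_ac[:, None] * ac)

    va = d3 * d6 - d5 * d4
    denom_bc = (d4 - d3) + (d5 - d6)
    with np.errstate(invalid="ignore", divide="ignore"):
        w_bc = np.where(denom_bc != 0, (d4 - d3) / denom_bc, 0.0)
    assign((va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0),
           b + w_bc[:, None] * (c - b))

    denom = va + vb + vc
    with np.errstate(invalid="ignore", divide="ignore"):
        v = np.where(denom != 0, vb / denom, 1.0 / 3.0)
        w = np.where(denom != 0, vc / denom, 1.0 / 3.0)
    assign(np.ones(len(p), dtype=bool), a + v[:, None] * ab + w[:, None] * ac)

    d2_out = np.einsum("ij,ij->i", p - result, p - result)
    return result, d2_out


class NearestQuery:
    """Exact nearest-surface-point queries against one mesh.

    A kd-tree over centroids of (sub-divided) triangles prunes candidates;
    the distance to the nearest mesh vertex provides a certified upper
    bound, so the candidate set provably contains the globally closest
    triangle and results equal a brute-force scan.
    """

    def __init__(self, mesh: SurfaceMesh):
        if len(mesh) == 0:
            raise ValueError("cannot query an empty mesh")
        self.mesh = mesh
        tri = mesh.triangles
        centroids = tri.mean(axis=1)
        radii = np.linalg.norm(tri - centroids[:, None, :], axis=2).max(axis=1)
        # subdivide big triangles so the pruning radius stays small
        edge = np.linalg.norm(tri[:, 1] - tri[:, 0], axis=1)
        target = max(float(np.median(edge)), 1e-6)
        levels = np.maximum(1, np.ceil(radii / target).astype(int))
        pts_list, face_list, rad_list = [], [], []
        for lv in np.unique(levels):
            idx = np.flatnonzero(levels == lv)
            if lv == 1:
                pts_list.append(centroids[idx])
                face_list.append(idx)
                rad_list.append(radii[idx])
                continue
            bary = []
            L = int(lv)
            for i in range(L):
                for j in range(L - i):
                    bary.append(((i + 1 / 3) / L, (j + 1 / 3) / L))
                    if i + j < L - 1:
                        bary.append(((i + 2 / 3) / L, (j + 2 / 3) / L))
            bary = np.asarray(bary)
            u, v = bary[:, 0], bary[:, 1]
            w = 1.0 - u - v
            sub = (w[None, :, None] * tri[idx, 0][:, None, :]
                   + u[None, :, None] * tri[idx, 1][:, None, :]
                   + v[None, :, None] * tri[idx, 2][:, None, :])
            pts_list.append(sub.reshape(-1, 3))
            face_list.append(np.repeat(idx, len(bary)))
            rad_list.append(np.repeat(radii[idx] / L, len(bary)))
        self._index_points = np.concatenate(pts_list)
        self._index_face = np.concatenate(face_list)
        self._index_radius = np.concatenate(rad_list)
        self._r_max = float(self._index_radius.max())
        self._centroid_tree = cKDTree(self._index_points)
        self._vertex_tree = cKDTree(mesh.vertices)
        # boundary structures for the on-boundary flag
        be = mesh.boundary_edges()
        self._boundary_edges = be
        bmask = np.zeros(len(mesh.vertices), dtype=bool)
        if len(be):
            bmask[be.ravel()] = True
        face_has_boundary = bmask[mesh.faces].any(axis=1)
        self._faces_near_boundary = face_has_boundary
        self._boundary_vertices = np.flatnonzero(bmask)

    def query(self, points: np.ndarray):
        """Closest surface points for ``points`` (k, 3).

        Returns ``(closest (k,3), face_id (k,), distance (k,), on_boundary (k,))``.
        """
        p = np.atleast_2d(np.asarray(points, float))
        d_ub, _ = self._vertex_tree.query(p)
        radius = d_ub + self._r_max + 1e-12
        lists = self._centroid_tree.query_ball_point(p, radius)
        counts = np.fromiter((len(l) for l in lists), dtype=np.int64,
                             count=len(lists))
        flat = np.concatenate([np.asarray(l, dtype=np.int64) for l in lists]) \
            if counts.sum() else np.empty(0, np.int64)
        pt_idx = np.repeat(np.arange(len(p)), counts)
        # prune candidates whose certified lower bound exceeds the vertex
        # upper bound, then deduplicate (point, face) pairs from sub-triangles
        lower = (np.linalg.norm(p[pt_idx] - self._index_points[flat], axis=1)
                 - self._index_radius[flat])
        ok = lower <= d_ub[pt_idx] + 1e-12
        pt_idx, flat = pt_idx[ok], flat[ok]
        cand_face = self._index_face[flat]
        key = pt_idx * np.int64(len(self.mesh)) + cand_face
        uniq_key, first = np.unique(key, return_index=True)
        pt_idx = pt_idx[first]
        cand_face = cand_face[first]

        tri = self.mesh.triangles[cand_face]
        cp, d2 = closest_point_on_triangles(p[pt_idx], tri)

        # segment-wise argmin (pt_idx is sorted by construction of unique keys)
        counts2 = np.bincount(pt_idx, minlength=len(p))
        starts = np.concatenate([[0], np.cumsum(counts2)[:-1]])
        best_d2 = np.minimum.reduceat(d2, starts)
        winners = np.zeros(len(p), dtype=np.int64)
        is_best = d2 <= best_d2[pt_idx] * (1 + 1e-15) + 1e-300
        cand_pos = np.flatnonzero(is_best)
        # first best per point
        _, first_best = np.unique(pt_idx[cand_pos], return_index=True)
        winners = cand_pos[first_best]

        closest = cp[winners]
        face_id = cand_face[winners]
        dist = np.sqrt(np.maximum(d2[winners], 0.0))
        on_boundary = self._on_boundary(closest, face_id)
        return closest, face_id, dist, on_boundary

    def _on_boundary(self, closest: np.ndarray, face_id: np.ndarray):
        out = np.zeros(len(closest), dtype=bool)
        if len(self._boundary_edges) == 0:
            return out
        check = np.flatnonzero(self._faces_near_boundary[face_id])
        if len(check) == 0:
            return out
        verts = self.mesh.vertices
        bset = {(min(a, b), max(a, b)) for a, b in self._boundary_edges}
        faces = self.mesh.faces
        for i in check:
            f = faces[face_id[i]]
            c = closest[i]
            hit = False
            for k in range(3):
                a, b = int(f[k]), int(f[(k + 1) % 3])
                if (min(a, b), max(a, b)) not in bset:
                    continue
                pa, pb = verts[a], verts[b]
                t = np.dot(c - pa, pb - pa) / max(np.dot(pb - pa, pb - pa), 1e-300)
                t = min(max(t, 0.0), 1.0)
                if np.linalg.norm(c - (pa + t * (pb - pa))) <= BOUNDARY_TOL:
                    hit = True
                    break
            out[i] = hit
        return out


def nearest_surface_point(query_point, mesh: SurfaceMesh):
    """Exact nearest point on ``mesh`` for one query point.

    Returns ``(point_on_surface, face_id, distance_mm, on_boundary)``.
    """
    closest, fid, dist, onb = mesh.nearest.query(np.asarray(query_point, float))
    return closest[0], int(fid[0]), float(dist[0]), bool(onb[0])


def dominant_planar_normal(mesh: SurfaceMesh) -> np.ndarray:
    """Unit normal of the largest strictly coplanar patch of faces.

    Face normals are clustered at ~1e-6 rad resolution and the cluster with
    the largest total area wins.  For synthetic crowns the flat gingival
    base is by far the largest exactly planar region, so this recovers the
    crown's occlusal axis (as minus the returned normal) in any pose.
    """
    n = np.round(mesh.face_normals, 6)
    _, inverse = np.unique(n, axis=0, return_inverse=True)
    areas = np.bincount(inverse, weights=mesh.face_areas)
    best = int(np.argmax(areas))
    avg = np.average(mesh.face_normals[inverse == best], axis=0,
                     weights=mesh.face_areas[inverse == best])
    return avg / np.linalg.norm(avg)


def signed_distance_map(source: SurfaceMesh, target: SurfaceMesh) -> np.ndarray:
    """Per-vertex signed distance (mm) from ``source`` to ``target``'s surface.

    Positive where the source vertex lies on the outward side of the target
    surface at its closest point (sign from the target's local face normal);
    absolute values are the exact unsigned point-to-surface distances.
    """
    closest, fid, dist, _ = target.nearest.query(source.vertices)
    normals = target.face_normals[fid]
    side = np.einsum("ij,ij->i", source.vertices - closest, normals)
    return np.where(side >= 0, dist, -dist)
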