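"""Tetrahedral-mesh geometry: containers, generators, measures, partitions.

Coordinates are SI meters and indices 0-based throughout.  A mesh carries
physical tags: every tetrahedron belongs to exactly one *compartment* (volume
chemistry) and tagged surface triangles form *patches* (surface chemistry /
membranes).  Partitioning emulates a distributed mesh in one process:
tetrahedrons are assigned to ranks by recursive coordinate bisection and each
rank holds a ghost layer of face-adjacent foreign tetrahedrons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .flatmm import FlatMultimap
from .ids import RankId, TetId

# local faces of a tetrahedron (opposite each vertex)
_TET_FACES = np.array([[1, 2, 3], [0, 2, 3], [0, 1, 3], [0, 1, 2]], dtype=np.int64)

# Kuhn/Freudenthal split of a hexahedral cell into 6 tetrahedrons: each tet is
# a monotone lattice path 000 -> 111; corner index = i + 2j + 4k.
_KUHN_PATHS = [
    (0, 1, 3, 7), (0, 1, 5, 7), (0, 2, 3, 7),
    (0, 2, 6, 7), (0, 4, 5, 7), (0, 4, 6, 7),
]


@dataclass
class TetMesh:
    """Tetrahedral mesh with physical tags.

    ``tris`` holds the explicitly tagged surface triangles (patch/membrane
    candidates); ``tri_tets`` gives the owning tetrahedron(s) of each, -1 in
    the second slot for boundary triangles.
    """

    vertices: np.ndarray          # (nv, 3) float64, meters
    tets: np.ndarray              # (nt, 4) int64
    tet_tags: np.ndarray          # (nt,) int64 -> index into comp_names
    comp_names: list[str]
    tris: np.ndarray              # (ntri, 3) int64
    tri_tags: np.ndarray          # (ntri,) int64 -> index into patch_names
    patch_names: list[str]
    tri_tets: np.ndarray = None   # (ntri, 2) int64, -1 = none
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=np.float64)
        self.tets = np.asarray(self.tets, dtype=np.int64).reshape(-1, 4)
        self.tet_tags = np.asarray(self.tet_tags, dtype=np.int64)
        self.tris = np.asarray(self.tris, dtype=np.int64).reshape(-1, 3)
        self.tri_tags = np.asarray(self.tri_tags, dtype=np.int64)
        if self.tri_tets is None:
            self.tri_tets = match_triangles_to_tets(self.tets, self.tris)
        self.tri_tets = np.asarray(self.tri_tets, dtype=np.int64).reshape(-1, 2)
        vols = tet_volumes(self.vertices, self.tets)
        bad = np.flatnonzero(vols <= 0)
        if bad.size:
            raise ValueError(f"non-positive volume in tetrahedron(s) {bad[:5].tolist()}")

    @property
    def num_vertices(self) -> int:
        return len(self.vertices)

    @property
    def num_tets(self) -> int:
        return len(self.tets)

    @property
    def num_tris(self) -> int:
        return len(self.tris)

    def comp_tets(self, name: str) -> np.ndarray:
        """Tetrahedron indices of compartment ``name``."""
        return np.flatnonzero(self.tet_tags == self.comp_names.index(name))

    def patch_tris(self, name: str) -> np.ndarray:
        """Triangle indices of patch ``name``."""
        return np.flatnonzero(self.tri_tags == self.patch_names.index(name))

    def content_hash(self) -> str:
        import hashlib

        h = hashlib.sha256()
        for a in (self.vertices, self.tets, self.tet_tags, self.tris, self.tri_tags):
            h.update(np.ascontiguousarray(a).tobytes())
        h.update("|".join(self.comp_names + self.patch_names).encode())
        return h.hexdigest()


@dataclass
class MeshMeasures:
    """Geometric measures derived deterministically from a mesh.

    Neighbor tables share one flat-multimap layout: ``neighbors[i]`` lists the
    face-adjacent tets of tet ``i`` and ``face_areas``/``face_dists`` carry the
    shared-face area (m^2) and barycenter distance (m) at matching positions.
    """

    volumes: np.ndarray           # (nt,) m^3
    barycenters: np.ndarray       # (nt, 3) m
    neighbors: FlatMultimap       # tet -> neighbor tet ids
    face_areas: FlatMultimap      # tet -> shared-face areas, same layout
    face_dists: FlatMultimap      # tet -> barycenter distances, same layout
    tri_areas: np.ndarray         # (ntri,) m^2 for tagged triangles
    vertex_tri_areas: np.ndarray  # (nv,) m^2, 1/3-lumped tagged-triangle areas

    @property
    def total_volume(self) -> float:
        return float(self.volumes.sum())


@dataclass
class Partition:
    """Ownership and ghost layers for an emulated R-rank decomposition."""

    num_ranks: int
    owner: np.ndarray             # (nt,) int64 rank per tet
    ghosts: list[np.ndarray]      # per rank: non-owned tets sharing a face

    def owned(self, rank: RankId | int) -> np.ndarray:
        return np.flatnonzero(self.owner == int(rank))


# ---------------------------------------------------------------------------
# elementary measures

def tet_volumes(vertices: np.ndarray, tets: np.ndarray) -> np.ndarray:
    """Signed volumes |det|/6 with orientation folded in (positive if valid)."""
    p = vertices[tets]
    a, b, c = p[:, 1] - p[:, 0], p[:, 2] - p[:, 0], p[:, 3] - p[:, 0]
    return np.einsum("ij,ij->i", a, np.cross(b, c)) / 6.0


def triangle_areas(vertices: np.ndarray, tris: np.ndarray) -> np.ndarray:
    p = vertices[tris]
    return 0.5 * np.linalg.norm(np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]), axis=1)


def all_faces(tets: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Unique faces of a tet array.

    Returns ``(faces, face_tets, counts)``: sorted vertex triples, the one or
    two adjacent tets per face (-1 padding), and the adjacency count.  Raises
    if any face is claimed by more than two tetrahedrons.
    """
    nt = len(tets)
    faces = np.sort(tets[:, _TET_FACES].reshape(-1, 3), axis=1)
    owner = np.repeat(np.arange(nt, dtype=np.int64), 4)
    uniq, inv, counts = np.unique(faces, axis=0, return_inverse=True, return_counts=True)
    if counts.max(initial=0) > 2:
        raise ValueError("a triangle is shared by more than 2 tetrahedrons")
    face_tets = np.full((len(uniq), 2), -1, dtype=np.int64)
    order = np.argsort(inv, kind="stable")
    slot = np.zeros(len(uniq), dtype=np.int64)
    for idx in order:
        f = inv[idx]
        face_tets[f, slot[f]] = owner[idx]
        slot[f] += 1
    return uniq, face_tets, counts


def match_triangles_to_tets(tets: np.ndarray, tris: np.ndarray) -> np.ndarray:
    """Owning tetrahedron(s) of each listed triangle (-1 padding)."""
    if len(tris) == 0:
        return np.empty((0, 2), dtype=np.int64)
    faces, face_tets, _ = all_faces(tets)
    keys = np.sort(tris, axis=1)
    # locate each triangle among the unique faces
    idx = np.searchsorted(
        faces.view([("a", np.int64), ("b", np.int64), ("c", np.int64)]).ravel(),
        keys.view([("a", np.int64), ("b", np.int64), ("c", np.int64)]).ravel(),
    )
    out = np.empty((len(tris), 2), dtype=np.int64)
    for i, j in enumerate(idx):
        if j >= len(faces) or not np.array_equal(faces[j], keys[i]):
            raise ValueError(f"triangle {tris[i].tolist()} is not a face of any tetrahedron")
        out[i] = face_tets[j]
    return out


def compute_measures(mesh: TetMesh) -> MeshMeasures:
    """All geometric quantities the operators need; deterministic per mesh."""
    vols = tet_volumes(mesh.vertices, mesh.tets)
    bad = np.flatnonzero(vols <= 0)
    if bad.size:
        raise ValueError(f"degenerate tetrahedron(s) {bad[:5].tolist()}")
    bary = mesh.vertices[mesh.tets].mean(axis=1)

    faces, face_tets, counts = all_faces(mesh.tets)
    interior = counts == 2
    fa = triangle_areas(mesh.vertices, faces[interior])
    t0, t1 = face_tets[interior, 0], face_tets[interior, 1]
    fd = np.linalg.norm(bary[t0] - bary[t1], axis=1)
    if np.any(fd <= 0):
        raise ValueError("coincident barycenters across a shared face")

    pairs = [(int(a), (int(b), ar, d)) for a, b, ar, d in zip(t0, t1, fa, fd)]
    pairs += [(int(b), (int(a), ar, d)) for a, b, ar, d in zip(t0, t1, fa, fd)]
    nbr = FlatMultimap.from_pairs(((k, v[0]) for k, v in pairs), mesh.num_tets, np.int64)
    areas = FlatMultimap.from_pairs(((k, v[1]) for k, v in pairs), mesh.num_tets, np.float64)
    dists = FlatMultimap.from_pairs(((k, v[2]) for k, v in pairs), mesh.num_tets, np.float64)

    tri_areas = triangle_areas(mesh.vertices, mesh.tris) if mesh.num_tris else np.empty(0)
    vta = np.zeros(mesh.num_vertices)
    for t, a in zip(mesh.tris, tri_areas):
        vta[t] += a / 3.0
    return MeshMeasures(vols, bary, nbr, areas, dists, tri_areas, vta)


# ---------------------------------------------------------------------------
# structured generators

def _box_grid(dims, res, origin=(0.0, 0.0, 0.0)):
    nx, ny, nz = res
    xs = [np.linspace(o, o + d, n + 1) for o, d, n in zip(origin, dims, res)]
    X, Y, Z = np.meshgrid(*xs, indexing="ij")
    verts = np.stack([X, Y, Z], axis=-1).reshape(-1, 3)

    def vid(i, j, k):
        return (i * (ny + 1) + j) * (nz + 1) + k

    tets = []
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                corner = [
                    vid(i + (c & 1), j + ((c >> 1) & 1), k + ((c >> 2) & 1))
                    for c in range(8)
                ]
                for path in _KUHN_PATHS:
                    tets.append([corner[p] for p in path])
    tets = np.asarray(tets, dtype=np.int64)
    vols = tet_volumes(verts, tets)
    flip = vols < 0
    tets[flip, 0], tets[flip, 1] = tets[flip, 1], tets[flip, 0].copy()
    return verts, tets


def generate_box(
    dimensions,
    resolution,
    comp: str = "comp",
    patch: str | None = "memb",
) -> TetMesh:
    """Axis-aligned box split into 6 tets per cell (Kuhn decomposition).

    All boundary triangles are tagged ``patch`` unless ``patch`` is None.
    """
    dimensions = tuple(float(d) for d in dimensions)
    resolution = tuple(int(r) for r in resolution)
    if min(dimensions) <= 0:
        raise ValueError("dimensions must be positive")
    if min(resolution) < 1:
        raise ValueError("resolution must be >= 1 in every axis")
    verts, tets = _box_grid(dimensions, resolution)
    faces, face_tets, counts = all_faces(tets)
    boundary = faces[counts == 1]
    if patch is None:
        tris = np.empty((0, 3), dtype=np.int64)
        tri_tags = np.empty(0, dtype=np.int64)
        patches = []
    else:
        tris = boundary
        tri_tags = np.zeros(len(boundary), dtype=np.int64)
        patches = [patch]
    return TetMesh(
        verts, tets, np.zeros(len(tets), dtype=np.int64), [comp], tris, tri_tags, patches
    )


def generate_cable(
    length: float,
    diameter: float,
    axial_segments: int,
    comp: str = "cyto",
    patch: str = "memb",
) -> TetMesh:
    """Square-section prism standing in for a cylindrical cable.

    The cross-section is a square of side sqrt(pi)*d/2, area-matched to the
    nominal circular section of diameter ``d``.  The lateral surface of the
    square prism exceeds the cylinder's by a factor 4/(pi) * (pi/4)^0.5; the
    generator records ``mesh.meta['surface_ratio']`` = (ideal cylinder surface,
    lateral + both end caps) / (actual mesh surface) so membrane surface
    densities can be rescaled to match per-length cable constants.
    """
    if length <= 0 or diameter <= 0:
        raise ValueError("length and diameter must be positive")
    if axial_segments < 1:
        raise ValueError("need at least one axial segment")
    side = np.sqrt(np.pi) * diameter / 2.0
    verts, tets = _box_grid((side, side, length), (1, 1, axial_segments))
    faces, face_tets, counts = all_faces(tets)
    boundary = faces[counts == 1]
    mesh = TetMesh(
        verts,
        tets,
        np.zeros(len(tets), dtype=np.int64),
        [comp],
        boundary,
        np.zeros(len(boundary), dtype=np.int64),
        [patch],
    )
    ideal = np.pi * diameter * length + 2.0 * np.pi * (diameter / 2.0) ** 2
    actual = float(triangle_areas(verts, boundary).sum())
    mesh.meta["surface_ratio"] = ideal / actual
    mesh.meta["diameter"] = diameter
    mesh.meta["length"] = length
    return mesh


def generate_structured_mesh(shape: str, dimensions, resolution, **kw) -> TetMesh:
    """Dispatch to the box or cable generator by name."""
    if shape == "box":
        return generate_box(dimensions, resolution, **kw)
    if shape == "cable":
        length, diameter = dimensions
        (segments,) = resolution if np.iterable(resolution) else (resolution,)
        return generate_cable(length, diameter, int(segments), **kw)
    raise ValueError(f"unknown shape {shape!r} (expected 'box' or 'cable')")


# ---------------------------------------------------------------------------
# partitioning

def partition_mesh(mesh: TetMesh, ranks: int, measures: MeshMeasures | None = None) -> Partition:
    """Recursive coordinate bisection into ``ranks`` (a power of 2) parts.

    Patch triangles with two adjacent tetrahedrons are kept on one rank: the
    second adjacent tet is reassigned to the first's owner so surface kinetics
    never straddle a rank boundary.
    """
    ranks = int(ranks)
    if ranks < 1:
        raise ValueError("ranks must be >= 1")
    if ranks > mesh.num_tets:
        raise ValueError(f"cannot partition {mesh.num_tets} tets over {ranks} ranks")
    if ranks & (ranks - 1):
        raise ValueError("rank count must be a power of 2")
    bary = (measures.barycenters if measures is not None
            else mesh.vertices[mesh.tets].mean(axis=1))
    owner = np.zeros(mesh.num_tets, dtype=np.int64)

    def bisect(idx: np.ndarray, base: int, n: int):
        if n == 1:
            owner[idx] = base
            return
        pts = bary[idx]
        axis = int(np.argmax(pts.max(axis=0) - pts.min(axis=0)))
        order = np.lexsort((idx, pts[:, axis]))  # tie-break by id: deterministic
        half = len(idx) // 2
        bisect(idx[order[:half]], base, n // 2)
        bisect(idx[order[half:]], base + n // 2, n // 2)

    bisect(np.arange(mesh.num_tets, dtype=np.int64), 0, ranks)

    # keep both sides of an interior patch triangle on one rank
    for (ta, tb) in mesh.tri_tets:
        if ta >= 0 and tb >= 0 and owner[ta] != owner[tb]:
            owner[tb] = owner[ta]

    if len(np.unique(owner)) != ranks:
        raise ValueError("patch-locality constraint emptied a rank; use fewer ranks")

    _, face_tets, counts = all_faces(mesh.tets)
    inter = face_tets[counts == 2]
    ghosts = []
    for r in range(ranks):
        g = set()
        for a, b in inter:
            if owner[a] == r and owner[b] != r:
                g.add(int(b))
            elif owner[b] == r and owner[a] != r:
                g.add(int(a))
        ghosts.append(np.array(sorted(g), dtype=np.int64))
    return Partition(ranks, owner, ghosts)
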