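"""Geometry kernel for corresponding stage meshes.

A developmental stage series is stored as a list of meshes that share one
face list, so vertex ``i`` denotes the same material point at every stage
(the "shape key" representation).  Blending vertex arrays between stages
morphs the surface without any change of topology, which is what makes
lineage labels transportable: a label attached to a face stays on that face
forever.

Quads are accepted in face lists but all geometric queries run on an
internal triangulation using the fixed (0,1,2)/(0,2,3) split, applied
identically at every stage so correspondence survives.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra

__all__ = [
    "StageMesh",
    "StageSeries",
    "SurfacePoint",
    "validate_series",
    "interpolate",
    "face_area",
    "total_area",
    "locate",
    "embed",
    "geodesic_distance",
    "vertex_adjacency",
    "face_adjacency",
]

_BARY_TOL = 1e-9


@dataclass(frozen=True)
class SurfacePoint:
    """A point on a mesh surface: triangle index plus barycentric weights.

    ``tri`` indexes the mesh's internal triangulation (see
    :attr:`StageMesh.triangles`); :attr:`face` of the owning mesh maps it
    back to the original (possibly quad) face.
    """

    tri: int
    bary: tuple[float, float, float]

    def __post_init__(self) -> None:
        b = np.asarray(self.bary, dtype=float)
        if b.shape != (3,):
            raise ValueError("barycentric coordinates must have length 3")
        if np.any(b < -_BARY_TOL) or abs(b.sum() - 1.0) > 1e-9:
            raise ValueError(
                f"barycentric coordinates must be in [0,1] and sum to 1, got {self.bary}"
            )


class StageMesh:
    """A single-stage surface mesh with triangle or quad faces.

    Parameters
    ----------
    vertices : (n, 3) float array
        Vertex positions in model units.
    faces : sequence of index tuples
        Triangles and/or quads; indices into ``vertices``.
    stage_label : str
        Free-text stage name, e.g. ``"HH10"``.
    """

    def __init__(self, vertices, faces, stage_label: str = "") -> None:
        self.vertices = np.ascontiguousarray(vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be an (n, 3) array")
        self.faces: tuple[tuple[int, ...], ...] = tuple(
            tuple(int(i) for i in f) for f in faces
        )
        self.stage_label = stage_label
        self._check_faces()
        self.triangles, self.tri_face = _triangulate(self.faces)

    # -- construction helpers -------------------------------------------------

    def _check_faces(self) -> None:
        n = len(self.vertices)
        for k, f in enumerate(self.faces):
            if len(f) not in (3, 4):
                raise ValueError(f"face {k} has {len(f)} vertices; need 3 or 4")
            if any(i < 0 or i >= n for i in f):
                raise ValueError(f"face {k} references a vertex outside 0..{n - 1}")
            if len(set(f)) != len(f):
                raise ValueError(f"face {k} repeats a vertex (degenerate)")

    def with_vertices(self, vertices, stage_label: str | None = None) -> "StageMesh":
        """Same topology, new vertex positions (the shape-key operation)."""
        out = StageMesh.__new__(StageMesh)
        out.vertices = np.ascontiguousarray(vertices, dtype=float)
        if out.vertices.shape != self.vertices.shape:
            raise ValueError("replacement vertices must match in shape")
        out.faces = self.faces
        out.stage_label = self.stage_label if stage_label is None else stage_label
        out.triangles = self.triangles
        out.tri_face = self.tri_face
        return out

    # -- basic properties ------------------------------------------------------

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def tri_coords(self) -> np.ndarray:
        """(m, 3, 3) coordinates of the internal triangulation."""
        return self.vertices[self.triangles]

    def same_topology(self, other: "StageMesh") -> bool:
        return self.faces == other.faces and self.n_vertices == other.n_vertices

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"StageMesh(label={self.stage_label!r}, vertices={self.n_vertices}, "
            f"faces={self.n_faces})"
        )


def _triangulate(faces: Sequence[tuple[int, ...]]) -> tuple[np.ndarray, np.ndarray]:
    """Split quads by the fixed (0,1,2)/(0,2,3) rule; track parent faces."""
    tris: list[tuple[int, int, int]] = []
    parent: list[int] = []
    for k, f in enumerate(faces):
        if len(f) == 3:
            tris.append((f[0], f[1], f[2]))
            parent.append(k)
        else:
            tris.append((f[0], f[1], f[2]))
            tris.append((f[0], f[2], f[3]))
            parent.extend((k, k))
    return np.asarray(tris, dtype=np.intp).reshape(-1, 3), np.asarray(parent, dtype=np.intp)


@dataclass
class StageSeries:
    """An ordered list of corresponding stage meshes.

    All stages must share the face list and vertex count, so that vertex
    ``i`` corresponds across stages.  The continuous stage parameter ``s``
    spans ``[0, n_stages - 1]``; it is ordinal (uniform per stage interval),
    not developmental time.
    """

    stages: list[StageMesh]

    def __post_init__(self) -> None:
        report = validate_series(self)
        if report:
            raise ValueError("invalid stage series:\n" + "\n".join(report))

    @property
    def n_stages(self) -> int:
        return len(self.stages)

    @property
    def labels(self) -> list[str]:
        return [m.stage_label for m in self.stages]

    def __getitem__(self, k: int) -> StageMesh:
        return self.stages[k]

    def __len__(self) -> int:
        return len(self.stages)


def validate_series(series: StageSeries | Iterable[StageMesh]) -> list[str]:
    """Check stage-series invariants; returns a list of violations.

    Never raises: an empty list means the series is well-formed.
    """
    stages = list(series.stages if isinstance(series, StageSeries) else series)
    report: list[str] = []
    if len(stages) < 2:
        report.append(f"series has {len(stages)} stage(s); need at least 2")
    if not stages:
        return report
    ref = stages[0]
    labels = [m.stage_label for m in stages]
    if len(set(labels)) != len(labels):
        report.append(f"stage labels are not unique: {labels}")
    for k, m in enumerate(stages):
        if m.n_vertices != ref.n_vertices:
            report.append(
                f"stage {k}: vertex count {m.n_vertices} != stage 0 count {ref.n_vertices}"
            )
        if m.faces != ref.faces:
            report.append(f"stage {k}: face list differs from stage 0 (topology mismatch)")
        if total_area(m) <= 0:
            report.append(f"stage {k}: total surface area is not positive")
    return report


def interpolate(series: StageSeries, s: float) -> StageMesh:
    """Piecewise-linear shape-key blend at stage parameter ``s``.

    Integer ``s`` returns the stored stage bit-exactly; fractional ``s``
    blends the two bracketing stages' vertex arrays elementwise.  Faces are
    unchanged.
    """
    n = series.n_stages
    if not (0.0 <= s <= n - 1):
        raise ValueError(f"stage parameter s={s} outside [0, {n - 1}]")
    k = int(np.floor(s))
    if k == s:
        m = series[k]
        return m.with_vertices(m.vertices.copy(), stage_label=m.stage_label)
    t = s - k
    v = (1.0 - t) * series[k].vertices + t * series[k + 1].vertices
    return series[k].with_vertices(v, stage_label=f"s={s:g}")


# -- areas ---------------------------------------------------------------------


def face_area(mesh: StageMesh, face: int) -> float:
    """Area of one face; quads as the sum of their two triangles."""
    if not (0 <= face < mesh.n_faces):
        raise IndexError(f"face {face} out of range 0..{mesh.n_faces - 1}")
    tris = np.flatnonzero(mesh.tri_face == face)
    return float(_tri_areas(mesh)[tris].sum())


def _tri_areas(mesh: StageMesh) -> np.ndarray:
    p = mesh.tri_coords()
    cross = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
    return 0.5 * np.linalg.norm(cross, axis=1)


def face_areas(mesh: StageMesh) -> np.ndarray:
    """Per-face areas for all faces at once."""
    ta = _tri_areas(mesh)
    out = np.zeros(mesh.n_faces)
    np.add.at(out, mesh.tri_face, ta)
    return out


def total_area(mesh: StageMesh) -> float:
    return float(_tri_areas(mesh).sum())


# -- closest-point projection ----------------------------------------------------


def embed(mesh: StageMesh, sp: SurfacePoint) -> np.ndarray:
    """3D coordinates of a surface point on this mesh."""
    tri = mesh.triangles[sp.tri]
    return np.asarray(sp.bary) @ mesh.vertices[tri]


def locate(mesh: StageMesh, point) -> SurfacePoint:
    """Closest-point projection of an arbitrary 3D point onto the surface.

    Ties between faces are broken by the lowest triangle index, which makes
    the projection deterministic.
    """
    if mesh.n_faces == 0:
        raise ValueError("cannot locate a point on an empty mesh")
    p = np.asarray(point, dtype=float)
    closest, bary = _closest_points_all_tris(mesh, p)
    d2 = np.einsum("ij,ij->i", closest - p, closest - p)
    tri = int(np.argmin(d2))  # argmin keeps the lowest index on exact ties
    b = np.clip(bary[tri], 0.0, 1.0)
    b = b / b.sum()
    return SurfacePoint(tri=tri, bary=(float(b[0]), float(b[1]), float(b[2])))


def _closest_points_all_tris(mesh: StageMesh, p: np.ndarray):
    """Vectorised closest point on every triangle (Ericson's algorithm)."""
    t = mesh.tri_coords()
    a, b, c = t[:, 0], t[:, 1], t[:, 2]
    ab, ac, ap = b - a, c - a, p[None, :] - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p[None, :] - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = p[None, :] - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    va = d3 * d6 - d5 * d4
    vb = d5 * d2 - d1 * d6
    vc = d1 * d4 - d3 * d2

    u = np.zeros(len(t))
    v = np.zeros(len(t))

    denom_uv = vb + vc + va
    with np.errstate(divide="ignore", invalid="ignore"):
        # interior case
        u_int = np.where(denom_uv != 0, vb / denom_uv, 0.0)
        v_int = np.where(denom_uv != 0, vc / denom_uv, 0.0)
        v_ab = np.where(d1 - d3 != 0, d1 / (d1 - d3), 0.0)
        w_ac = np.where(d2 - d6 != 0, d2 / (d2 - d6), 0.0)
        num_bc = d4 - d3
        den_bc = (d4 - d3) + (d5 - d6)
        w_bc = np.where(den_bc != 0, num_bc / den_bc, 0.0)

    u[:] = u_int
    v[:] = v_int

    # region masks, evaluated in priority order as in the scalar algorithm
    r_a = (d1 <= 0) & (d2 <= 0)
    r_b = (d3 >= 0) & (d4 <= d3)
    r_c = (d6 >= 0) & (d5 <= d6)
    r_ab = (~r_a) & (~r_b) & (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    r_ac = (~r_a) & (~r_c) & (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    r_bc = (~r_b) & (~r_c) & (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)

    u = np.where(r_bc, 1.0 - np.clip(w_bc, 0, 1), u)
    v = np.where(r_bc, np.clip(w_bc, 0, 1), v)
    u = np.where(r_ac, 0.0, u)
    v = np.where(r_ac, np.clip(w_ac, 0, 1), v)
    u = np.where(r_ab, np.clip(v_ab, 0, 1), u)
    v = np.where(r_ab, 0.0, v)
    u = np.where(r_c, 0.0, u)
    v = np.where(r_c, 1.0, v)
    u = np.where(r_b, 1.0, u)
    v = np.where(r_b, 0.0, v)
    u = np.where(r_a, 0.0, u)
    v = np.where(r_a, 0.0, v)

    u = np.clip(u, 0.0, 1.0)
    v = np.clip(v, 0.0, 1.0 - u)
    closest = a + u[:, None] * ab + v[:, None] * ac
    bary = np.stack([1.0 - u - v, u, v], axis=1)
    return closest, bary


# -- adjacency & geodesics --------------------------------------------------------


def vertex_adjacency(mesh: StageMesh):
    """Sparse symmetric matrix of edge lengths on the triangulated edge graph."""
    tri = mesh.triangles
    edges = np.concatenate([tri[:, [0, 1]], tri[:, [1, 2]], tri[:, [2, 0]]])
    edges = np.unique(np.sort(edges, axis=1), axis=0)
    lengths = np.linalg.norm(
        mesh.vertices[edges[:, 0]] - mesh.vertices[edges[:, 1]], axis=1
    )
    n = mesh.n_vertices
    return coo_matrix(
        (np.concatenate([lengths, lengths]),
         (np.concatenate([edges[:, 0], edges[:, 1]]),
          np.concatenate([edges[:, 1], edges[:, 0]]))),
        shape=(n, n),
    ).tocsr()


def face_adjacency(mesh: StageMesh):
    """Edge-sharing adjacency between original faces, as a dict of sets."""
    edge_faces: dict[tuple[int, int], set[int]] = {}
    for k, f in enumerate(mesh.faces):
        for i in range(len(f)):
            e = tuple(sorted((f[i], f[(i + 1) % len(f)])))
            edge_faces.setdefault(e, set()).add(k)
    adj: dict[int, set[int]] = {k: set() for k in range(mesh.n_faces)}
    for faces in edge_faces.values():
        for a in faces:
            adj[a] |= faces - {a}
    return adj


def geodesic_distance(
    mesh: StageMesh,
    source: SurfacePoint,
    targets: Sequence[int] | None = None,
) -> np.ndarray:
    """Shortest-path distances from a surface point over the edge graph.

    The source is embedded through its triangle's three vertices: distance to
    a target vertex is ``min_i (|source - v_i| + d_graph(v_i, target))``.
    This is the edge-graph approximation to the polyhedral geodesic; its
    error is O(edge length).  Unreachable vertices get ``inf``.
    """
    g = vertex_adjacency(mesh)
    tri = mesh.triangles[source.tri]
    p = embed(mesh, source)
    offsets = np.linalg.norm(mesh.vertices[tri] - p[None, :], axis=1)
    d = dijkstra(g, directed=False, indices=tri)
    dist = np.min(d + offsets[:, None], axis=0)
    if targets is not None:
        return dist[np.asarray(targets, dtype=np.intp)]
    return dist


def geodesic_distance_from_vertices(mesh: StageMesh, sources) -> np.ndarray:
    """Distances from a vertex set (minimum over sources) to every vertex."""
    g = vertex_adjacency(mesh)
    d = dijkstra(g, directed=False, indices=np.asarray(sources, dtype=np.intp))
    return d.min(axis=0) if d.ndim == 2 else d


# -- eikonal-refined distances -------------------------------------------------------
#
# Plain edge-graph shortest paths overestimate surface distance by a
# direction-dependent "stretch" that does not vanish with refinement.  For
# quantitative uses (dye-disc areas against analytic caps) the graph
# distance is refined by solving the surface eikonal equation to first
# order: a Tsitsiklis/fast-marching local update applied in ascending
# causal (Dijkstra) order, after replacing the near-source values — where
# the linear-wavefront model is worst — by distances measured in an
# isometric unfolding of the surrounding triangle fan.  The unfolding is
# intrinsic, so it cannot shortcut through ambient space on folded
# surfaces; on developable patches (tubes) it is exact.


def eikonal_distance(
    mesh: StageMesh,
    source: SurfacePoint,
    rings: int = 8,
    passes: int = 2,
) -> np.ndarray:
    """First-order eikonal distances from a surface point to every vertex.

    Accuracy is O(edge length) with a small constant; the pure graph
    distance (:func:`geodesic_distance`) remains the metric-exact reference
    for graph-level uses.
    """
    d = geodesic_distance(mesh, source)
    for vid, dv in _unfold_init(mesh, source, rings).items():
        if dv < d[vid]:
            d[vid] = dv
    return _refine_ordered(mesh, d, passes=passes)


def _unfold_init(mesh: StageMesh, sp: SurfacePoint, rings: int) -> dict[int, float]:
    """Distances within an isometric unfolding of the source triangle fan."""
    from collections import defaultdict, deque

    tri = mesh.triangles
    V = mesh.vertices
    t0 = int(sp.tri)
    p3 = embed(mesh, sp)
    edge_tris: dict[tuple[int, int], list[int]] = defaultdict(list)
    for k, t in enumerate(tri):
        for i in range(3):
            e = (min(t[i], t[(i + 1) % 3]), max(t[i], t[(i + 1) % 3]))
            edge_tris[e].append(k)

    a, b, c = (int(x) for x in tri[t0])
    A3 = V[a]
    e1 = V[b] - A3
    e1 = e1 / np.linalg.norm(e1)
    n = np.cross(V[b] - A3, V[c] - A3)
    nn = np.linalg.norm(n)
    if nn == 0:
        return {}
    n /= nn
    e2 = np.cross(n, e1)

    def to2(q):
        return np.array([(q - A3) @ e1, (q - A3) @ e2])

    coords: dict[int, dict[int, np.ndarray]] = {t0: {a: to2(V[a]), b: to2(V[b]), c: to2(V[c])}}
    p2 = to2(p3)
    dmin: dict[int, float] = {}

    def note(vid: int, v2: np.ndarray) -> None:
        dv = float(np.linalg.norm(v2 - p2))
        if vid not in dmin or dv < dmin[vid]:
            dmin[vid] = dv

    for vid, v2 in coords[t0].items():
        note(vid, v2)
    seen = {t0}
    queue = deque([(t0, 0)])
    while queue:
        tk, depth = queue.popleft()
        if depth >= rings:
            continue
        cmap = coords[tk]
        t = tri[tk]
        for i in range(3):
            va, vb = int(t[i]), int(t[(i + 1) % 3])
            e = (min(va, vb), max(va, vb))
            for nb in edge_tris[e]:
                if nb in seen:
                    continue
                tn = [int(x) for x in tri[nb]]
                vx = next(v for v in tn if v != va and v != vb)
                A2, B2 = cmap[va], cmap[vb]
                la = np.linalg.norm(V[vx] - V[va])
                lb = np.linalg.norm(V[vx] - V[vb])
                ab = B2 - A2
                lab = np.linalg.norm(ab)
                if lab == 0:
                    continue
                u = ab / lab
                along = (la * la - lb * lb + lab * lab) / (2 * lab)
                h = np.sqrt(max(la * la - along * along, 0.0))
                perp = np.array([-u[1], u[0]])
                third = next(
                    v for v in (int(t[0]), int(t[1]), int(t[2])) if v != va and v != vb
                )
                side = (cmap[third] - A2) @ perp
                X2 = A2 + along * u + (-np.sign(side) if side != 0 else 1.0) * h * perp
                coords[nb] = {va: A2, vb: B2, vx: X2}
                note(vx, X2)
                seen.add(nb)
                queue.append((nb, depth + 1))
    return dmin


def _refine_ordered(mesh: StageMesh, d0: np.ndarray, passes: int = 2) -> np.ndarray:
    """Tsitsiklis local updates swept in ascending-distance order."""
    from math import inf, sqrt

    tri = mesh.triangles
    n = mesh.n_vertices
    inc: list[list[tuple[int, int]]] = [[] for _ in range(n)]
    for t in tri:
        a, b, c = int(t[0]), int(t[1]), int(t[2])
        inc[c].append((a, b))
        inc[a].append((b, c))
        inc[b].append((c, a))
    d = d0.astype(float).copy()
    order = np.argsort(d0, kind="stable")
    Vl = mesh.vertices.tolist()
    for _ in range(passes):
        changed = 0.0
        for ci in order:
            ci = int(ci)
            cx, cy, cz = Vl[ci]
            best = d[ci]
            for a, b in inc[ci]:
                dA = d[a]
                dB = d[b]
                ax, ay, az = Vl[a]
                bx, by, bz = Vl[b]
                if dA < inf:
                    cand = dA + sqrt((cx - ax) ** 2 + (cy - ay) ** 2 + (cz - az) ** 2)
                    if cand < best:
                        best = cand
                if dB < inf:
                    cand = dB + sqrt((cx - bx) ** 2 + (cy - by) ** 2 + (cz - bz) ** 2)
                    if cand < best:
                        best = cand
                if not (dA < inf and dB < inf):
                    continue
                ex, ey, ez = bx - ax, by - ay, bz - az
                wx, wy, wz = cx - ax, cy - ay, cz - az
                E = ex * ex + ey * ey + ez * ez
                W = wx * wx + wy * wy + wz * wz
                we = wx * ex + wy * ey + wz * ez
                u = dB - dA
                den = E - u * u
                if den > 1e-18:
                    disc = (E * W - we * we) / den
                    if disc > 0:
                        rad = abs(u) * sqrt(disc)
                        for lam in ((we + rad) / E, (we - rad) / E):
                            if 0.0 < lam < 1.0:
                                g2 = W - 2 * lam * we + lam * lam * E
                                if g2 > 0:
                                    f = dA + lam * u + sqrt(g2)
                                    if f < best:
                                        best = f
            if best < d[ci]:
                if d[ci] - best > changed:
                    changed = d[ci] - best
                d[ci] = best
        if changed < 1e-12:
            break
    return d
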