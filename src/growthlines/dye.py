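"""Digital dye: labelled surface patches transported through a stage series.

A patch is a face-granular label (a face is either dyed or not) plus a set
of barycentric sample points used for metric estimation.  Because every
stage of a series shares one face list, transporting a patch to another
stage parameter means re-evaluating the *same* face set and barycentric
samples on the interpolated vertex array.  Labels never transfer between
faces, so two disjoint patches can never mix — the in-silico analogue of
lineage labels that do not exchange cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mesh import (
    StageMesh,
    StageSeries,
    SurfacePoint,
    eikonal_distance,
    embed,
    face_areas,
    geodesic_distance,
    interpolate,
)

__all__ = ["DyePatch", "inject", "propagate"]


@dataclass
class DyePatch:
    """A contiguous dyed face set with sample points, bound to one stage mesh."""

    mesh: StageMesh
    faces: np.ndarray  # sorted original-face indices
    sample_tris: np.ndarray  # (k,) triangle indices
    sample_bary: np.ndarray  # (k, 3) barycentric weights
    seed: SurfacePoint
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.faces = np.unique(np.asarray(self.faces, dtype=np.intp))
        if len(self.faces) == 0:
            raise ValueError("a dye patch must contain at least one face")
        seed_face = int(self.mesh.tri_face[self.seed.tri])
        if seed_face not in set(self.faces.tolist()):
            raise ValueError("seed face must belong to the patch face set")

    @property
    def face_set(self) -> frozenset:
        return frozenset(int(f) for f in self.faces)

    def area(self) -> float:
        """Summed area of the dyed faces on this patch's stage mesh."""
        return float(face_areas(self.mesh)[self.faces].sum())

    def points(self) -> np.ndarray:
        """(k, 3) coordinates of the sample points on this stage mesh."""
        tri = self.mesh.triangles[self.sample_tris]
        corners = self.mesh.vertices[tri]  # (k, 3, 3)
        return np.einsum("kj,kjd->kd", self.sample_bary, corners)

    def centroid(self) -> np.ndarray:
        return self.points().mean(axis=0)

    def is_disjoint(self, other: "DyePatch") -> bool:
        return len(np.intersect1d(self.faces, other.faces)) == 0


def inject(
    mesh: StageMesh,
    seed: SurfacePoint,
    radius: float,
    samples_per_face: int = 10,
    rng_seed: int = 0,
    meta: dict | None = None,
    distance_method: str = "eikonal",
) -> DyePatch:
    """Dye a geodesic disc of ``radius`` around ``seed``.

    A face is dyed iff all of its vertices lie within geodesic ``radius`` of
    the seed; the seed's own face is always included, so the patch is never
    empty (radius 0 gives exactly the seed face).  Distances use the
    eikonal-refined solver by default (``distance_method="graph"`` selects
    plain edge-graph shortest paths).
    """
    if radius < 0:
        raise ValueError("radius must be non-negative")
    seed_face = int(mesh.tri_face[seed.tri])
    if distance_method == "eikonal":
        dist = eikonal_distance(mesh, seed)
    elif distance_method == "graph":
        dist = geodesic_distance(mesh, seed)
    else:
        raise ValueError(f"unknown distance_method {distance_method!r}")
    within = dist <= radius
    keep = [
        k
        for k, f in enumerate(mesh.faces)
        if all(within[i] for i in f)
    ]
    faces = np.unique(np.asarray(keep + [seed_face], dtype=np.intp))
    tris, bary = _sample_faces(mesh, faces, samples_per_face, rng_seed)
    return DyePatch(
        mesh=mesh,
        faces=faces,
        sample_tris=tris,
        sample_bary=bary,
        seed=seed,
        meta={"radius": radius, "rng_seed": rng_seed, **(meta or {})},
    )


def _sample_faces(mesh: StageMesh, faces, samples_per_face: int, rng_seed: int):
    """Seeded uniform barycentric samples, a fixed count per dyed face.

    Quads distribute their samples over both internal triangles in
    proportion to triangle area, so sampling density is uniform per face.
    """
    rng = np.random.default_rng(rng_seed)
    areas = _tri_area_lookup(mesh)
    tris_out: list[int] = []
    for f in faces:
        tris = np.flatnonzero(mesh.tri_face == f)
        if len(tris) == 1:
            tris_out.extend([int(tris[0])] * samples_per_face)
        else:
            w = areas[tris]
            w = w / w.sum() if w.sum() > 0 else np.full(len(tris), 1 / len(tris))
            picks = rng.choice(tris, size=samples_per_face, p=w)
            tris_out.extend(int(t) for t in picks)
    k = len(tris_out)
    u = rng.random(k)
    v = rng.random(k)
    flip = u + v > 1
    u[flip], v[flip] = 1 - u[flip], 1 - v[flip]
    bary = np.stack([1 - u - v, u, v], axis=1)
    return np.asarray(tris_out, dtype=np.intp), bary


def _tri_area_lookup(mesh: StageMesh) -> np.ndarray:
    p = mesh.tri_coords()
    return 0.5 * np.linalg.norm(
        np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]), axis=1
    )


def propagate(patch: DyePatch, series: StageSeries, s: float) -> DyePatch:
    """Transport a patch to stage parameter ``s`` of ``series``.

    The face set and barycentric samples are unchanged; only the underlying
    vertex array moves.  By construction propagation is a bijection on face
    labels, so disjoint patches stay disjoint and connected patches stay
    connected at every ``s``.
    """
    ref = series[0]
    if patch.mesh.faces != ref.faces or patch.mesh.n_vertices != ref.n_vertices:
        raise ValueError("patch topology does not match the series topology")
    mesh_s = interpolate(series, s)
    return DyePatch(
        mesh=mesh_s,
        faces=patch.faces.copy(),
        sample_tris=patch.sample_tris.copy(),
        sample_bary=patch.sample_bary.copy(),
        seed=patch.seed,
        meta={**patch.meta, "stage": s},
    )
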