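"""Synthetic embryo data: stage meshes, injections, images, count matrices.

Every downstream stage of the pipeline is exercised on data generated here,
with ground truth emitted alongside, so nothing needs downloading.  The
deformation fields emulate the three growth modes the fate-mapping model
describes:

* **directional growth** toward an attractor point (the "eye"), with a
  weight decaying linearly in geodesic distance from a marked vertex set,
* **region-wise isotropic expansion** (zones scaled about their centroid),
* **anterior translation of a midline band** (the ventral-midline movement
  that bends growth lines into V shapes at the hinge where it meets the
  directional field).

The base primitives are an open-ended tube (neural-tube analogue, quad
faces) and a hemisphere.  The deformation magnitudes are free parameters of
the generator, not claims about chick growth rates; stage count defaults to
four, mirroring the four modelled stages.  All randomness flows through one
seeded generator per call and the seed is recorded in output metadata.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .mesh import (
    StageMesh,
    StageSeries,
    SurfacePoint,
    face_areas,
    geodesic_distance_from_vertices,
    locate,
)

__all__ = [
    "tube",
    "hemisphere",
    "unit_sphere",
    "DeformationSpec",
    "SeriesTruth",
    "generate_stage_series",
    "default_deformation",
    "partition_zones",
    "default_outcome_region_faces",
    "InjectionRecord",
    "generate_injection_set",
    "PlantedDesign",
    "ExpressionTruth",
    "generate_expression_matrix",
    "ImageTruth",
    "generate_image",
]


# -- base primitives ---------------------------------------------------------------


def tube(
    n_axial: int = 24,
    n_circ: int = 16,
    length: float = 4.0,
    radius: float = 0.5,
    label: str = "stage0",
) -> StageMesh:
    """Open-ended quad-mesh tube along +x (anterior = +x by convention)."""
    xs = np.linspace(0.0, length, n_axial + 1)
    thetas = np.linspace(0.0, 2 * np.pi, n_circ, endpoint=False)
    verts = np.array(
        [[x, radius * np.cos(t), radius * np.sin(t)] for x in xs for t in thetas]
    )
    faces = []
    for i in range(n_axial):
        for j in range(n_circ):
            a = i * n_circ + j
            b = i * n_circ + (j + 1) % n_circ
            c = (i + 1) * n_circ + (j + 1) % n_circ
            d = (i + 1) * n_circ + j
            faces.append((a, b, c, d))
    return StageMesh(verts, faces, stage_label=label)


def hemisphere(
    n_lat: int = 8,
    n_lon: int = 16,
    radius: float = 1.0,
    label: str = "stage0",
) -> StageMesh:
    """Upper hemisphere: quad bands plus a triangle fan at the pole."""
    verts = [[0.0, 0.0, radius]]
    for i in range(1, n_lat + 1):
        phi = (np.pi / 2) * i / n_lat  # polar angle from +z
        for j in range(n_lon):
            th = 2 * np.pi * j / n_lon
            verts.append(
                [
                    radius * np.sin(phi) * np.cos(th),
                    radius * np.sin(phi) * np.sin(th),
                    radius * np.cos(phi),
                ]
            )
    faces: list[tuple[int, ...]] = []
    for j in range(n_lon):
        faces.append((0, 1 + j, 1 + (j + 1) % n_lon))
    for i in range(n_lat - 1):
        ring0 = 1 + i * n_lon
        ring1 = 1 + (i + 1) * n_lon
        for j in range(n_lon):
            a = ring0 + j
            b = ring0 + (j + 1) % n_lon
            c = ring1 + (j + 1) % n_lon
            d = ring1 + j
            faces.append((a, b, c, d))
    return StageMesh(np.asarray(verts), faces, stage_label=label)


def unit_sphere(subdivisions: int = 4) -> StageMesh:
    """Triangulated unit sphere (icosphere), for resolution-limit oracles."""
    import trimesh

    tm = trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
    return StageMesh(np.asarray(tm.vertices), [tuple(f) for f in tm.faces], "sphere")


# -- deformation fields -------------------------------------------------------------


@dataclass
class DeformationSpec:
    """Parametric growth fields applied cumulatively across stages.

    With zero strength, unit scales and zero translation the series is the
    identity: every stage equals the base mesh.
    """

    attractor_point: np.ndarray = field(default_factory=lambda: np.zeros(3))
    attractor_strength: float = 0.0
    attractor_origin_vertices: Optional[np.ndarray] = None  # the "optic" set
    attractor_decay_length: float = 2.0
    isotropic_zones: list[tuple[np.ndarray, Sequence[float]]] = field(default_factory=list)
    midline_band: Optional[tuple[np.ndarray, Sequence[float]]] = None
    anterior_axis: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0, 0.0]))
    n_stages: int = 4
    rng_seed: int = 0
    stage_labels: Optional[Sequence[str]] = None

    def validate(self, base: StageMesh) -> None:
        n = base.n_vertices
        if self.n_stages < 2:
            raise ValueError("n_stages must be at least 2")
        if self.attractor_strength < 0:
            raise ValueError("attractor_strength must be >= 0")
        for mask, scales in self.isotropic_zones:
            _check_vertex_ids(mask, n, "isotropic zone")
            if len(scales) != self.n_stages:
                raise ValueError("each zone needs one scale per stage")
            if any(s < 0 for s in scales):
                raise ValueError("scale factors must be >= 0")
            if scales[0] != 1:
                raise ValueError("stage-0 scale must be 1 (stage 0 is the base mesh)")
        if self.midline_band is not None:
            mask, shifts = self.midline_band
            _check_vertex_ids(mask, n, "midline band")
            if len(shifts) != self.n_stages:
                raise ValueError("midline band needs one translation per stage")
            if shifts[0] != 0:
                raise ValueError("stage-0 translation must be 0")
        if self.attractor_origin_vertices is not None:
            _check_vertex_ids(self.attractor_origin_vertices, n, "attractor origin set")


def _check_vertex_ids(ids, n: int, what: str) -> None:
    ids = np.asarray(ids)
    if ids.size and (ids.min() < 0 or ids.max() >= n):
        raise ValueError(f"{what} references vertices outside 0..{n - 1}")


@dataclass
class SeriesTruth:
    """Ground truth emitted with a generated series."""

    displacements: np.ndarray  # (n_stages, n_vertices, 3)
    attractor_weights: np.ndarray  # (n_vertices,) the linear-decay weights
    spec: DeformationSpec


def generate_stage_series(
    base: StageMesh, spec: DeformationSpec
) -> tuple[StageSeries, SeriesTruth]:
    """Deform a base mesh through ``n_stages`` corresponding stages.

    Stage ``k`` displacement of vertex ``v`` sums three independent fields,
    each ramped by the stage fraction ``f_k = k/(n_stages-1)`` or by its
    per-stage parameter:

    * attractor: ``strength * f_k * w(v) * (a - v)/|a - v|`` with ``w``
      decaying linearly in geodesic distance from the marked origin set;
    * each isotropic zone: ``(scale_k - 1) * (v - c)`` about the zone
      centroid ``c`` (base-mesh positions);
    * midline band: ``shift_k`` along the anterior axis.
    """
    spec.validate(base)
    n = base.n_vertices
    v0 = base.vertices
    labels = list(spec.stage_labels) if spec.stage_labels else [
        f"stage{k}" for k in range(spec.n_stages)
    ]
    if len(labels) != spec.n_stages or len(set(labels)) != spec.n_stages:
        raise ValueError("stage_labels must be unique, one per stage")

    weights = np.zeros(n)
    if spec.attractor_strength > 0:
        if spec.attractor_origin_vertices is not None and len(spec.attractor_origin_vertices):
            d = geodesic_distance_from_vertices(base, spec.attractor_origin_vertices)
            d = np.where(np.isfinite(d), d, np.inf)
            weights = np.clip(1.0 - d / spec.attractor_decay_length, 0.0, 1.0)
        else:
            weights = np.ones(n)

    a = np.asarray(spec.attractor_point, dtype=float)
    to_a = a[None, :] - v0
    norms = np.linalg.norm(to_a, axis=1)
    unit = np.divide(to_a, norms[:, None], out=np.zeros_like(to_a), where=norms[:, None] > 1e-12)

    disp = np.zeros((spec.n_stages, n, 3))
    for k in range(spec.n_stages):
        f = k / (spec.n_stages - 1)
        d_k = spec.attractor_strength * f * weights[:, None] * unit
        for mask, scales in spec.isotropic_zones:
            mask = np.asarray(mask, dtype=np.intp)
            c = v0[mask].mean(axis=0)
            d_k[mask] += (scales[k] - 1.0) * (v0[mask] - c)
        if spec.midline_band is not None:
            mask, shifts = spec.midline_band
            d_k[np.asarray(mask, dtype=np.intp)] += shifts[k] * np.asarray(
                spec.anterior_axis, dtype=float
            )
        disp[k] = d_k

    stages = [base.with_vertices(v0 + disp[k], stage_label=labels[k]) for k in range(spec.n_stages)]
    series = StageSeries(stages)
    return series, SeriesTruth(displacements=disp, attractor_weights=weights, spec=spec)


def default_deformation(base: StageMesh, rng_seed: int = 0) -> DeformationSpec:
    """The default study-condition fields on the standard tube.

    The attractor sits anterior-ventral of the tube (the "eye" position);
    its origin set is the anterior-ventral vertex patch.  One mid-dorsal
    zone expands isotropically (the balloon-like dorsal expansion) and the
    ventral midline band translates anteriorly (the V-shape driver).
    """
    v = base.vertices
    xmax = v[:, 0].max()
    # "optic" vertices: anterior third, ventral side (z < 0 half)
    optic = np.flatnonzero((v[:, 0] > 2 * xmax / 3) & (v[:, 2] < -0.3 * np.abs(v[:, 2]).max()))
    if optic.size == 0:
        optic = np.array([int(np.argmax(v[:, 0]))])
    attractor = np.array([xmax * 1.2, 0.0, -2.5 * np.abs(v[:, 2]).max() or -1.0])
    dorsal = np.flatnonzero(
        (v[:, 0] > xmax / 3) & (v[:, 0] < 2 * xmax / 3) & (v[:, 2] > 0.3 * np.abs(v[:, 2]).max())
    )
    midline = np.flatnonzero(v[:, 2] < -0.85 * np.abs(v[:, 2]).max())
    n_stages = 4
    fr = np.linspace(0, 1, n_stages)
    return DeformationSpec(
        attractor_point=attractor,
        attractor_strength=1.0,
        attractor_origin_vertices=optic,
        attractor_decay_length=0.6 * xmax,
        isotropic_zones=[(dorsal, list(1.0 + 0.8 * fr))],
        midline_band=(midline, list(0.9 * fr)),
        n_stages=n_stages,
        rng_seed=rng_seed,
        stage_labels=["HH10", "HH11", "HH14", "HH20"],
    )


# -- zone and region annotations -----------------------------------------------------


def partition_zones(
    mesh: StageMesh, n_axial: int = 4, n_angular: int = 3, prefix: str = ""
) -> dict[str, np.ndarray]:
    """Partition faces into ``n_axial * n_angular`` named zones (default 12).

    Face centroids are binned by axial position (x) and by angle around the
    x axis, using quantile bin edges so the zones have comparable face
    counts.  Zone names are "1".."12" (optionally prefixed).
    """
    cent = np.array([mesh.vertices[list(f)].mean(axis=0) for f in mesh.faces])
    axial = cent[:, 0]
    angle = np.arctan2(cent[:, 2], cent[:, 1])
    ax_edges = np.quantile(axial, np.linspace(0, 1, n_axial + 1))
    ax_bin = np.clip(np.searchsorted(ax_edges, axial, side="right") - 1, 0, n_axial - 1)
    ang_edges = np.linspace(-np.pi, np.pi, n_angular + 1)
    ang_bin = np.clip(np.searchsorted(ang_edges, angle, side="right") - 1, 0, n_angular - 1)
    zones: dict[str, np.ndarray] = {}
    k = 1
    for i in range(n_axial):
        for j in range(n_angular):
            faces = np.flatnonzero((ax_bin == i) & (ang_bin == j))
            if faces.size == 0:
                raise ValueError(
                    f"zone bin ({i},{j}) is empty; use a denser mesh or fewer zones"
                )
            zones[f"{prefix}{k}"] = faces
            k += 1
    return zones


#: group sizes of the 17-area vocabulary per angular sector
_REGION_GROUPS = (("T", 2), ("D", 7), ("H", 5), ("Hm", 3))


def default_outcome_region_faces(mesh: StageMesh) -> dict[str, np.ndarray]:
    """A synthetic default layout for the 17 outcome areas.

    Faces are split into four angular sectors around the x axis (one per
    major-region group) and each sector is cut axially into that group's
    area count (T: 2, D: 7, H: 5, Hm: 3) with quantile edges.  This is test
    geometry only — the label vocabulary is the real thing, the layout is
    not an anatomical claim.
    """
    cent = np.array([mesh.vertices[list(f)].mean(axis=0) for f in mesh.faces])
    angle = np.arctan2(cent[:, 2], cent[:, 1])
    sector_edges = np.linspace(-np.pi, np.pi, len(_REGION_GROUPS) + 1)
    sector = np.clip(
        np.searchsorted(sector_edges, angle, side="right") - 1, 0, len(_REGION_GROUPS) - 1
    )
    regions: dict[str, np.ndarray] = {}
    for s, (group, count) in enumerate(_REGION_GROUPS):
        faces = np.flatnonzero(sector == s)
        if faces.size < count:
            raise ValueError(f"sector {group} has too few faces for {count} areas")
        axial = cent[faces, 0]
        edges = np.quantile(axial, np.linspace(0, 1, count + 1))
        bins = np.clip(np.searchsorted(edges, axial, side="right") - 1, 0, count - 1)
        for b in range(count):
            regions[f"{group}{b + 1}"] = faces[bins == b]
    return regions


# -- injections ---------------------------------------------------------------------


@dataclass
class InjectionRecord:
    sample_id: str
    zone: str
    seed: SurfacePoint
    radius: float
    truth_areas: frozenset  # ground-truth outcome areas by exact forward mapping
    truth_faces: np.ndarray  # the dyed face set


def generate_injection_set(
    series: StageSeries,
    zones: dict[str, np.ndarray],
    n_per_zone: int = 1,
    jitter: float = 0.0,
    rng_seed: int = 0,
    radius: float = 0.35,
    regions: Optional[dict[str, np.ndarray]] = None,
    min_overlap: float = 0.05,
) -> list[InjectionRecord]:
    """Synthetic dye injections: seed points per zone with forward-map truth.

    With ``jitter == 0`` the seed is the zone's centroid projection (the
    centre of the zone face nearest the zone's area-weighted centroid).
    Jitter moves the seed to a random zone face whose centroid lies within
    ``jitter`` of that point; a jitter larger than the zone's extent is
    clamped with a warning.  Ground-truth outcome areas are computed by a
    per-face brute-force forward map onto the final stage.
    """
    from .dye import inject

    base = series[0]
    final = series[-1]
    rng = np.random.default_rng(rng_seed)
    fa0 = face_areas(base)
    cent = np.array([base.vertices[list(f)].mean(axis=0) for f in base.faces])
    if regions is None:
        regions = default_outcome_region_faces(final)
    records: list[InjectionRecord] = []

    for zone, zfaces in zones.items():
        if len(zfaces) == 0:
            raise ValueError(f"zone {zone!r} is empty")
        w = fa0[zfaces]
        zcent = (cent[zfaces] * w[:, None]).sum(axis=0) / w.sum()
        home = zfaces[int(np.argmin(np.linalg.norm(cent[zfaces] - zcent, axis=1)))]
        zone_extent = np.linalg.norm(cent[zfaces] - cent[home], axis=1).max()
        jit = jitter
        if jitter > 0 and jitter > zone_extent:
            warnings.warn(
                f"jitter {jitter} exceeds zone {zone!r} extent {zone_extent:.3g}; clamping"
            )
            jit = zone_extent
        for i in range(n_per_zone):
            if jit > 0:
                near = zfaces[np.linalg.norm(cent[zfaces] - cent[home], axis=1) <= jit]
                pick = int(rng.choice(near))
            else:
                pick = int(home)
            seed = _face_center_point(base, pick)
            patch0 = inject(base, seed, radius, rng_seed=int(rng.integers(2**31)))
            truth = _forward_map_areas(final, patch0.faces, regions, min_overlap)
            records.append(
                InjectionRecord(
                    sample_id=f"{zone}-{i}",
                    zone=zone,
                    seed=seed,
                    radius=radius,
                    truth_areas=truth,
                    truth_faces=patch0.faces.copy(),
                )
            )
    return records


def _face_center_point(mesh: StageMesh, face: int) -> SurfacePoint:
    tris = np.flatnonzero(mesh.tri_face == face)
    return SurfacePoint(tri=int(tris[0]), bary=(1 / 3, 1 / 3, 1 / 3))


def _forward_map_areas(
    final: StageMesh, patch_faces: np.ndarray, regions: dict[str, np.ndarray], min_overlap: float
) -> frozenset:
    """Brute-force per-face overlap tally on the final stage (the truth oracle)."""
    fa = face_areas(final)
    total = sum(fa[f] for f in patch_faces)
    hits = []
    best, best_ov = None, -1.0
    for name, rfaces in regions.items():
        rset = set(int(f) for f in rfaces)
        ov = sum(fa[f] for f in patch_faces if int(f) in rset) / total
        if ov >= min_overlap:
            hits.append(name)
        if ov > best_ov:
            best, best_ov = name, ov
    return frozenset(hits) if hits else frozenset({best})


# -- expression matrices --------------------------------------------------------------


@dataclass
class PlantedDesign:
    """What to plant in a synthetic count matrix.

    ``exclusion_positive`` maps a filter gene to the number of cells given
    a positive count for it; ``set_effects`` multiplies the Poisson rate of
    a gene list in one cluster.  Marker and filter genes are otherwise
    silent, so the retained set is known by construction.
    """

    n_clusters: int = 8
    retained_frac: float = 0.6
    npc_frac: float = 0.2
    exclusion_positive: dict[str, int] = field(default_factory=dict)
    set_effects: list[tuple[tuple[str, ...], int, float]] = field(default_factory=list)
    base_rate: float = 0.3
    marker_rate: float = 2.0


@dataclass
class ExpressionTruth:
    retained_mask: np.ndarray  # rule evaluation by per-cell loop
    clusters: np.ndarray
    npc_mask: np.ndarray
    planted: PlantedDesign


_FILTER_GENES = (
    "Otp", "Sim1",
    "Foxa1", "Foxa2", "Pitx2", "Shh",
    "Nr5a1", "Foxb1", "Tbr1", "Agrp", "Pomc",
)
_SCORE_GENES = (
    "Fgf15", "Six3", "Zic1", "Zic5",
    "Mfap4", "Lmo4", "Rgs4",
    "Mki67", "Top2a", "Pcna",
    "Neurod1", "Dcx", "Tubb3",
)


def generate_expression_matrix(
    n_cells: int = 500,
    n_genes: int = 300,
    planted: Optional[PlantedDesign] = None,
    rng_seed: int = 0,
):
    """Synthetic gene x cell counts with planted markers, clusters, effects.

    Returns an :class:`anndata.AnnData` (cells x genes, sparse counts) with
    ``obs['cluster']`` and ``obs['npc']``, plus an :class:`ExpressionTruth`.
    Gene names start with the preset filter and score genes, padded with
    ``Gene####`` fillers; planting genes beyond ``n_genes`` is an error.
    """
    import anndata as ad
    import scipy.sparse as sp

    planted = planted or PlantedDesign()
    named = list(_FILTER_GENES + _SCORE_GENES)
    if n_genes < len(named):
        raise ValueError(f"n_genes must be at least {len(named)} to hold the preset genes")
    genes = named + [f"Gene{i:04d}" for i in range(n_genes - len(named))]
    for g in planted.exclusion_positive:
        if g not in genes:
            raise ValueError(f"planted gene {g!r} is not among the {n_genes} gene names")
    for gene_list, cluster, _ in planted.set_effects:
        for g in gene_list:
            if g not in genes:
                raise ValueError(f"planted gene {g!r} is not among the {n_genes} gene names")
        if not (0 <= cluster < planted.n_clusters):
            raise ValueError(f"planted cluster {cluster} outside 0..{planted.n_clusters - 1}")

    rng = np.random.default_rng(rng_seed)
    gi = {g: i for i, g in enumerate(genes)}
    filler = np.asarray([gi[g] for g in genes if g not in _FILTER_GENES], dtype=np.intp)

    # per-gene baseline rates; filter genes silent unless planted
    rates = rng.lognormal(mean=np.log(planted.base_rate), sigma=0.6, size=n_genes)
    for g in _FILTER_GENES:
        rates[gi[g]] = 0.0

    clusters = rng.integers(planted.n_clusters, size=n_cells)
    lam = np.tile(rates, (n_cells, 1))
    for gene_list, cluster, mult in planted.set_effects:
        rows = clusters == cluster
        cols = [gi[g] for g in gene_list]
        lam[np.ix_(rows, cols)] *= mult

    counts = rng.poisson(lam).astype(np.int64)

    # retention markers: positive in a seeded subset of cells
    n_ret = int(round(planted.retained_frac * n_cells))
    ret_cells = rng.choice(n_cells, size=n_ret, replace=False)
    half = n_ret // 2
    counts[ret_cells[:half], gi["Otp"]] = 1 + rng.poisson(planted.marker_rate, size=half)
    counts[ret_cells[half:], gi["Sim1"]] = 1 + rng.poisson(
        planted.marker_rate, size=n_ret - half
    )
    npc_mask = rng.random(n_cells) < planted.npc_frac

    for g, k in planted.exclusion_positive.items():
        cells = rng.choice(n_cells, size=k, replace=False)
        counts[cells, gi[g]] = 1 + rng.poisson(planted.marker_rate, size=k)

    # truth retained mask: independent per-cell rule evaluation (plain loop)
    excl = [gi[g] for g in ("Foxa1", "Foxa2", "Pitx2", "Shh",
                            "Nr5a1", "Foxb1", "Tbr1", "Agrp", "Pomc")]
    retained = np.zeros(n_cells, dtype=bool)
    for c in range(n_cells):
        keep = counts[c, gi["Otp"]] > 0 or counts[c, gi["Sim1"]] > 0 or bool(npc_mask[c])
        if keep and all(counts[c, e] == 0 for e in excl):
            retained[c] = True

    import pandas as pd

    adata = ad.AnnData(
        X=sp.csr_matrix(counts),
        obs=pd.DataFrame(
            {"cluster": pd.Categorical(clusters.astype(str)), "npc": npc_mask},
            index=[f"cell{c:05d}" for c in range(n_cells)],
        ),
        var=pd.DataFrame(index=genes),
    )
    adata.uns["rng_seed"] = rng_seed
    truth = ExpressionTruth(
        retained_mask=retained, clusters=clusters, npc_mask=npc_mask, planted=planted
    )
    return adata, truth


# -- images -------------------------------------------------------------------------


@dataclass
class ImageTruth:
    signal_mask: np.ndarray
    salt_pixels: np.ndarray  # (k, 2) row/col
    signal_area_px: int


def generate_image(
    shape: tuple[int, int] = (128, 128),
    signal_polygon: Optional[np.ndarray] = None,
    signal_level: int = 1000,
    background_level: int = 100,
    salt_density: float = 0.0,
    salt_level: int = 60000,
    rng_seed: int = 0,
    roi_polygon: Optional[np.ndarray] = None,
):
    """Two-level 16-bit image with a polygonal signal region plus salt noise.

    Salt pixels are isolated single-pixel outliers: pairwise Chebyshev
    distance >= 3 and at least 2 px from the signal boundary, so a
    radius->=1 bright-outlier despeckle removes them exactly without
    touching the signal.  Returns an :class:`AnnotatedImage` (ROI = whole
    frame unless given) and the planted truth.
    """
    from skimage.draw import polygon2mask

    from .morphometry import AnnotatedImage

    h, w = shape
    if signal_polygon is None:
        signal_polygon = np.array(
            [[h * 0.25, w * 0.25], [h * 0.25, w * 0.7], [h * 0.75, w * 0.7], [h * 0.75, w * 0.25]]
        )
    signal_polygon = np.asarray(signal_polygon, dtype=float)
    if len(signal_polygon) < 3:
        raise ValueError("signal polygon is degenerate (fewer than 3 points)")
    if signal_polygon[:, 0].min() < 0 or signal_polygon[:, 0].max() > h - 1 or \
       signal_polygon[:, 1].min() < 0 or signal_polygon[:, 1].max() > w - 1:
        raise ValueError("signal polygon extends outside the image")
    mask = polygon2mask((h, w), signal_polygon)
    if not mask.any():
        raise ValueError("signal polygon rasterises to an empty mask")

    img = np.full((h, w), background_level, dtype=np.uint16)
    img[mask] = signal_level

    rng = np.random.default_rng(rng_seed)
    salt: list[tuple[int, int]] = []
    n_salt = int(round(salt_density * h * w))
    if n_salt > 0:
        import scipy.ndimage as ndi

        # keep salt away from the signal boundary so local medians stay clean
        boundary = ndi.binary_dilation(mask, iterations=2) & ~ndi.binary_erosion(
            mask, iterations=2
        )
        candidates = np.argwhere(~boundary)
        rng.shuffle(candidates)
        taken: list[tuple[int, int]] = []
        for r, c in candidates:
            if len(taken) >= n_salt:
                break
            if all(max(abs(r - tr), abs(c - tc)) >= 3 for tr, tc in taken):
                taken.append((int(r), int(c)))
        salt = taken
        for r, c in salt:
            img[r, c] = salt_level

    if roi_polygon is None:
        roi_polygon = np.array([[0, 0], [0, w - 1], [h - 1, w - 1], [h - 1, 0]], dtype=float)
    annotated = AnnotatedImage(image=img, rois=[np.asarray(roi_polygon, dtype=float)])
    truth = ImageTruth(
        signal_mask=mask,
        salt_pixels=np.asarray(salt, dtype=int).reshape(-1, 2),
        signal_area_px=int(mask.sum()),
    )
    return annotated, truth
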