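"""Outcome scoring: where did each growth line end up, and did it look right?

Final-stage territory is described by seventeen named outcome areas grouped
by major region — T1-T2 (telencephalon), D1-D7 (diencephalon excluding
hypothalamus), H1-H5 (hypothalamus) and Hm1-Hm3 (hypothalamic midline).
The label vocabulary is fixed; the face-set geometry behind each label is
an annotation input (a synthetic default layout is available from
:mod:`growthlines.synthetic`) and carries no claim about real anatomy.

Each propagated patch is assigned to every area that covers at least a
configurable fraction of the patch's area; shape conformity compares the
measured shape class against a per-area expectation, with an indeterminate
grey band pooled with non-conforming calls in summaries.  Per-zone
frequency matrices report the percentage of samples labelling each area,
and thumbnails render those frequencies with white meaning "no examples".
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .dye import DyePatch
from .mesh import StageMesh, face_areas
from .metrics import AxisFrame, ShapeThresholds, classify_shape, _project_2d, _pca_elongation

__all__ = [
    "AREA_LABELS",
    "OutcomeRegionSet",
    "OutcomeRecord",
    "Assignment",
    "Conformity",
    "FrequencyMatrix",
    "assign",
    "conformity",
    "frequency_matrix",
    "render_thumbnails",
    "frequency_to_rgb",
    "zone_key",
]

#: The 17-area outcome vocabulary, grouped by major region.
AREA_LABELS: tuple[str, ...] = (
    "T1", "T2",
    "D1", "D2", "D3", "D4", "D5", "D6", "D7",
    "H1", "H2", "H3", "H4", "H5",
    "Hm1", "Hm2", "Hm3",
)


@dataclass
class OutcomeRegionSet:
    """Named face sets on the final-stage mesh.  Regions may overlap."""

    regions: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        clean: dict[str, np.ndarray] = {}
        for name, faces in self.regions.items():
            arr = np.unique(np.asarray(faces, dtype=np.intp))
            if arr.size == 0:
                raise ValueError(f"region {name!r} has an empty face set")
            clean[name] = arr
        self.regions = clean

    @property
    def labels(self) -> list[str]:
        return list(self.regions)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.regions[name]


@dataclass(frozen=True)
class Assignment:
    """Area labels hit by a patch; ``fallback`` marks a best-overlap rescue."""

    labels: frozenset
    fallback: bool
    overlaps: Mapping[str, float]


class Conformity(enum.Enum):
    TRUE = "true"
    FALSE = "false"
    INDETERMINATE = "indeterminate"


@dataclass
class OutcomeRecord:
    sample_id: str
    zones: tuple[str, ...]  # one zone, or an adjacent-zone intersection pair
    areas: frozenset
    conformity: dict[str, Conformity] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.zones:
            raise ValueError("a record needs at least one injection zone")
        self.zones = tuple(sorted(str(z) for z in self.zones))
        self.areas = frozenset(self.areas)


def zone_key(zones: Sequence[str]) -> str:
    """Row key for a zone or a zone-intersection pair, e.g. ``"4+5"``."""
    return "+".join(sorted(str(z) for z in zones))


def assign(
    patch: DyePatch,
    regions: OutcomeRegionSet,
    min_overlap: float = 0.05,
) -> Assignment:
    """Assign a final-stage patch to outcome areas by fractional area overlap.

    An area is included iff ``area(patch ∩ region) / area(patch) >=
    min_overlap``.  If nothing passes, the single best-overlap area is
    returned with the fallback flag set, so every patch receives at least
    one label (as in manual scoring).
    """
    if len(patch.faces) == 0:
        raise ValueError("cannot assign an empty patch")
    fa = face_areas(patch.mesh)
    patch_area = float(fa[patch.faces].sum())
    if patch_area <= 0:
        raise ValueError("patch has zero area on this mesh")
    patch_set = set(patch.faces.tolist())
    overlaps: dict[str, float] = {}
    for name, rfaces in regions.regions.items():
        inter = [f for f in rfaces.tolist() if f in patch_set]
        overlaps[name] = float(fa[inter].sum()) / patch_area if inter else 0.0
    hit = frozenset(n for n, ov in overlaps.items() if ov >= min_overlap)
    if hit:
        return Assignment(labels=hit, fallback=False, overlaps=overlaps)
    best = max(overlaps, key=lambda n: (overlaps[n], -regions.labels.index(n)))
    return Assignment(labels=frozenset({best}), fallback=True, overlaps=overlaps)


def conformity(
    patch: DyePatch,
    area_label: str,
    expected_shapes: Mapping[str, str],
    frame: AxisFrame,
    thresholds: ShapeThresholds = ShapeThresholds(),
) -> Conformity:
    """Judge whether a patch's shape conforms to an area's expected shape.

    Elongations inside the configured grey band are indeterminate ("the
    location of labelling was clear but the shape was not"); summaries pool
    indeterminate with non-conforming.  An area missing from the expectation
    table is indeterminate with a warning.
    """
    import warnings

    if area_label not in expected_shapes:
        warnings.warn(f"no expected shape recorded for area {area_label!r}")
        return Conformity.INDETERMINATE
    xy, *_ = _project_2d(patch.points())
    elong = _pca_elongation(xy)
    lo, hi = thresholds.grey_band
    observed, _ = classify_shape(patch, frame, thresholds, elongation=elong, xy=xy)
    if lo <= elong <= hi and observed != "V":
        return Conformity.INDETERMINATE
    return Conformity.TRUE if observed == expected_shapes[area_label] else Conformity.FALSE


@dataclass
class FrequencyMatrix:
    """Per-zone outcome-area percentages with sample counts.

    ``pct`` holds the percentage of a zone's samples labelling each area,
    ``counts`` the underlying positive-sample counts, and ``row_n`` the
    number of samples per zone.  A zero cell means "no examples recorded".
    """

    pct: pd.DataFrame
    counts: pd.DataFrame
    row_n: pd.Series


def frequency_matrix(records: Sequence[OutcomeRecord]) -> FrequencyMatrix:
    """Tally outcome areas per injection zone (and zone intersection)."""
    if not records:
        raise ValueError("no records to tally")
    known = set(AREA_LABELS)
    extra = sorted({a for r in records for a in r.areas} - known)
    if extra:
        raise ValueError(f"records contain unknown area labels: {extra}")
    rows = sorted({zone_key(r.zones) for r in records}, key=_zone_sort_key)
    counts = pd.DataFrame(0, index=rows, columns=list(AREA_LABELS), dtype=int)
    row_n = pd.Series(0, index=rows, dtype=int)
    for r in records:
        z = zone_key(r.zones)
        row_n[z] += 1
        for a in r.areas:
            counts.loc[z, a] += 1
    pct = 100.0 * counts.div(row_n, axis=0)
    return FrequencyMatrix(pct=pct, counts=counts, row_n=row_n)


def _zone_sort_key(key: str):
    parts = key.split("+")
    def one(p: str):
        try:
            return (0, int(p), p)
        except ValueError:
            return (1, 0, p)
    return (len(parts), tuple(one(p) for p in parts))


# -- thumbnails -------------------------------------------------------------------


def frequency_to_rgb(freq_pct: float, base=(0.77, 0.05, 0.10)) -> tuple[float, float, float]:
    """Monotone white-to-colour ramp; exactly white at zero frequency."""
    f = float(np.clip(freq_pct, 0.0, 100.0)) / 100.0
    return tuple((1.0 - f) * 1.0 + f * b for b in base)


def render_thumbnails(
    matrix: FrequencyMatrix,
    regions: OutcomeRegionSet,
    mesh: StageMesh,
    outdir=None,
    dpi: int = 60,
) -> dict[str, np.ndarray]:
    """One small image per zone, faces coloured by outcome frequency.

    The mesh is flattened by principal-component projection of its
    vertices; each face takes the colour of the highest-frequency area
    containing it, with white meaning no examples.  Returns RGB arrays, and
    writes PNGs when ``outdir`` is given.
    """
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    from matplotlib.collections import PolyCollection
    from pathlib import Path

    v = mesh.vertices - mesh.vertices.mean(axis=0)
    _, _, vt = np.linalg.svd(v, full_matrices=False)
    xy = v @ vt[:2].T

    out: dict[str, np.ndarray] = {}
    for zone in matrix.pct.index:
        face_freq = np.zeros(mesh.n_faces)
        for area, faces in regions.regions.items():
            if area in matrix.pct.columns:
                f = matrix.pct.loc[zone, area]
                face_freq[faces] = np.maximum(face_freq[faces], f)
        colors = [frequency_to_rgb(f) for f in face_freq]
        polys = [xy[list(f)] for f in mesh.faces]
        fig, ax = plt.subplots(figsize=(2, 2), dpi=dpi)
        ax.add_collection(PolyCollection(polys, facecolors=colors, edgecolors="none"))
        ax.autoscale()
        ax.set_aspect("equal")
        ax.axis("off")
        fig.canvas.draw()
        buf = np.asarray(fig.canvas.buffer_rgba())[..., :3].copy()
        plt.close(fig)
        out[zone] = buf
        if outdir is not None:
            from imageio.v3 import imwrite

            Path(outdir).mkdir(parents=True, exist_ok=True)
            imwrite(Path(outdir) / f"zone_{zone.replace('+', '_')}.png", buf)
    return out
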