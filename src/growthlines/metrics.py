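"""Growth-line quantification: expansion, elongation, orientation, shape class.

A compact dye spot at an early stage becomes, after anisotropic growth, an
elongated territory.  This module measures that territory: how much it
expanded (area ratio), how stretched it is (elongation = major/minor
principal extent), in which direction relative to the anteroposterior (A-P)
reference (orientation, axis convention, degrees in [0, 180)), whether its
long axis passes near a named target such as the eye (convergence), and a
categorical shape call — spot, line, or V.

All in-plane quantities are computed after projecting the stage-t1 sample
points onto their total-least-squares best-fit plane: patches are thin
shells, and full 3D principal components would conflate surface curvature
with elongation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .dye import DyePatch

__all__ = [
    "AxisFrame",
    "ShapeThresholds",
    "GrowthLineMetrics",
    "measure",
    "classify_shape",
    "convergence",
]

# a patch is treated as isotropic (no meaningful major axis) below 1 + eps;
# sampling noise alone puts a perfect disc a few parts in 10^3 above 1
_ELONG_EPS = 0.05


@dataclass
class AxisFrame:
    """Embryo axis reference: an A-P polyline on the surface, optional target.

    The D-V direction is taken orthogonal to the local A-P tangent within
    the patch's tangent plane, so no separate D-V polyline is needed.
    """

    ap_polyline: np.ndarray  # (m, 3) points on the mesh surface
    target: Optional[np.ndarray] = None  # named point, e.g. the eye
    target_name: str = "eye"

    def __post_init__(self) -> None:
        self.ap_polyline = np.asarray(self.ap_polyline, dtype=float)
        if self.ap_polyline.ndim != 2 or self.ap_polyline.shape[1] != 3:
            raise ValueError("ap_polyline must be (m, 3)")
        if len(self.ap_polyline) < 2:
            raise ValueError("ap_polyline needs at least two points")
        if np.any(np.all(np.diff(self.ap_polyline, axis=0) == 0, axis=1)):
            raise ValueError("consecutive A-P polyline points must be distinct")
        if self.target is not None:
            self.target = np.asarray(self.target, dtype=float)

    def local_tangent(self, point: np.ndarray) -> np.ndarray:
        """Unit tangent of the A-P polyline segment nearest ``point``."""
        segs = np.diff(self.ap_polyline, axis=0)
        starts = self.ap_polyline[:-1]
        t = np.einsum("ij,ij->i", point[None, :] - starts, segs) / np.einsum(
            "ij,ij->i", segs, segs
        )
        t = np.clip(t, 0, 1)
        feet = starts + t[:, None] * segs
        d2 = np.einsum("ij,ij->i", feet - point, feet - point)
        k = int(np.argmin(d2))
        return segs[k] / np.linalg.norm(segs[k])


@dataclass(frozen=True)
class ShapeThresholds:
    """Quantitative surrogate for the visual spot/line/V taxonomy.

    ``t_line``: minimum elongation to leave the "spot" class.
    ``t_v_deg``: apex angles below this call a V.
    ``t_arm_frac``: each V arm must carry at least this fraction of the
    two-arm total length.
    ``grey_band``: elongation interval around ``t_line`` treated as
    indeterminate by conformity judgements.
    """

    t_line: float = 2.5
    t_v_deg: float = 150.0
    t_arm_frac: float = 0.25
    grey_band: tuple[float, float] = (2.0, 3.0)

    def as_dict(self) -> dict:
        return {
            "t_line": self.t_line,
            "t_v_deg": self.t_v_deg,
            "t_arm_frac": self.t_arm_frac,
            "grey_band": list(self.grey_band),
        }


@dataclass
class GrowthLineMetrics:
    area_ratio: float
    elongation: float
    orientation_deg: Optional[float]  # None when elongation ~ 1 (isotropic)
    centroid_displacement: float
    convergence_distance: Optional[float]
    shape_class: str  # "spot" | "line" | "V"
    v_angle_deg: Optional[float]


def _tangent_plane(points: np.ndarray):
    """Centroid, in-plane orthonormal basis (e1, e2), unit normal — by SVD."""
    c = points.mean(axis=0)
    q = points - c
    # right singular vectors: rows are principal directions
    _, s, vt = np.linalg.svd(q, full_matrices=False)
    return c, vt[0], vt[1], vt[2], s


def _project_2d(points: np.ndarray):
    c, e1, e2, n, s = _tangent_plane(points)
    q = points - c
    xy = np.stack([q @ e1, q @ e2], axis=1)
    return xy, c, e1, e2, n, s


def measure(
    patch_t0: DyePatch,
    patch_t1: DyePatch,
    frame: AxisFrame,
    thresholds: ShapeThresholds = ShapeThresholds(),
) -> GrowthLineMetrics:
    """Quantify how a patch changed between two stages.

    ``patch_t0`` and ``patch_t1`` must be the same patch (identical face
    set) evaluated at two stage parameters.
    """
    if patch_t0.face_set != patch_t1.face_set:
        raise ValueError("patches must share the same face set (same patch, two stages)")
    a0 = patch_t0.area()
    if a0 <= 0:
        raise ValueError("stage-t0 patch area is zero")
    area_ratio = patch_t1.area() / a0

    pts = patch_t1.points()
    xy, c, e1, e2, normal, _ = _project_2d(pts)
    sx = xy.std(axis=0, ddof=0)
    cov = np.cov(xy.T, ddof=0)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    minor = np.sqrt(max(evals[1], 0.0))
    major = np.sqrt(max(evals[0], 0.0))
    elongation = major / minor if minor > 1e-12 else np.inf
    major_axis_2d = evecs[:, 0]

    orientation = None
    if elongation > 1 + _ELONG_EPS:
        orientation = _axis_orientation(major_axis_2d, c, e1, e2, normal, frame)

    centroid_disp = float(np.linalg.norm(patch_t1.centroid() - patch_t0.centroid()))

    conv = None
    if frame.target is not None and elongation > 1 + _ELONG_EPS:
        conv = _convergence_2d(xy, major_axis_2d, c, e1, e2, frame.target)

    shape_class, v_angle = classify_shape(
        patch_t1, frame, thresholds, elongation=elongation, xy=xy
    )
    return GrowthLineMetrics(
        area_ratio=float(area_ratio),
        elongation=float(elongation),
        orientation_deg=orientation,
        centroid_displacement=centroid_disp,
        convergence_distance=conv,
        shape_class=shape_class,
        v_angle_deg=v_angle,
    )


def _axis_orientation(major_axis_2d, c, e1, e2, normal, frame: AxisFrame) -> float:
    """Orientation of the patch major axis against the local A-P tangent.

    Measured in the patch tangent plane, as an undirected axis: degrees in
    [0, 180), 0 meaning parallel to A-P.
    """
    ap = frame.local_tangent(c)
    ap_in_plane = ap - (ap @ normal) * normal
    nrm = np.linalg.norm(ap_in_plane)
    if nrm < 1e-12:
        raise ValueError("A-P tangent is perpendicular to the patch plane")
    ap_in_plane /= nrm
    ref = np.array([ap_in_plane @ e1, ap_in_plane @ e2])
    ref /= np.linalg.norm(ref)
    # signed angle of the (undirected) major axis against the reference
    cosang = major_axis_2d @ ref
    sinang = major_axis_2d[0] * ref[1] - major_axis_2d[1] * ref[0]
    ang = np.degrees(np.arctan2(-sinang, cosang)) % 180.0
    return float(ang)


def _convergence_2d(xy, major_axis_2d, c, e1, e2, target) -> float:
    w = np.asarray(target, dtype=float) - c
    w2 = np.array([w @ e1, w @ e2])
    return float(np.linalg.norm(w2 - (w2 @ major_axis_2d) * major_axis_2d))


def convergence(patch_t1: DyePatch, frame: AxisFrame) -> float:
    """Perpendicular distance from the frame target to the patch major axis.

    Defined only for elongated patches; for near-isotropic patches the major
    axis (and hence the distance) is meaningless, so an error directs the
    caller to check elongation first.
    """
    if frame.target is None:
        raise ValueError("frame has no target point")
    pts = patch_t1.points()
    xy, c, e1, e2, normal, _ = _project_2d(pts)
    cov = np.cov(xy.T, ddof=0)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    minor = np.sqrt(max(evals[order][1], 0.0))
    major = np.sqrt(max(evals[order][0], 0.0))
    elong = major / minor if minor > 1e-12 else np.inf
    if not elong > 1 + _ELONG_EPS:
        raise ValueError(
            "convergence is undefined for a near-isotropic patch: check that "
            "elongation exceeds 1 before asking for a major-axis distance"
        )
    return _convergence_2d(xy, evecs[:, order][:, 0], c, e1, e2, frame.target)


def classify_shape(
    patch_t1: DyePatch,
    frame: AxisFrame,
    thresholds: ShapeThresholds = ShapeThresholds(),
    elongation: float | None = None,
    xy: np.ndarray | None = None,
) -> tuple[str, Optional[float]]:
    """Call a patch a spot, a line, or a V.

    The V test runs first, because a bent shape can have a modest overall
    principal-axis elongation even when both arms are strongly elongated
    (two equal arms at 90 degrees have overall elongation 2 regardless of
    arm thinness).  The apex is the projected sample farthest from the chord
    joining the two extreme points along the first principal direction; the
    patch is a V when the apex-to-tip arms meet at an interior angle below
    ``t_v_deg``, each arm carries at least ``t_arm_frac`` of their total
    length, and each arm's own point subset is elongated (>= ``t_line``).
    Failing that, the patch is a spot below ``t_line`` overall elongation
    and a line otherwise.
    """
    if xy is None:
        xy, *_ = _project_2d(patch_t1.points())
    if elongation is None:
        elongation = _pca_elongation(xy)

    v_call = _fit_v(xy, thresholds)
    if v_call is not None:
        return "V", v_call
    if elongation < thresholds.t_line:
        return "spot", None
    return "line", None


def _pca_elongation(xy: np.ndarray) -> float:
    cov = np.cov(xy.T, ddof=0)
    evals = np.sort(np.linalg.eigvalsh(cov))[::-1]
    minor = np.sqrt(max(evals[1], 0.0))
    return np.sqrt(max(evals[0], 0.0)) / minor if minor > 1e-12 else np.inf


def _fit_v(xy: np.ndarray, thresholds: ShapeThresholds) -> Optional[float]:
    """Two-ray fit; apex angle in degrees if the patch qualifies as a V."""
    cov = np.cov(xy.T, ddof=0)
    evals, evecs = np.linalg.eigh(cov)
    u = evecs[:, int(np.argmax(evals))]
    proj = xy @ u
    tip1 = xy[int(np.argmin(proj))]
    tip2 = xy[int(np.argmax(proj))]
    chord = tip2 - tip1
    chord_len = np.linalg.norm(chord)
    if chord_len < 1e-12:
        return None
    chord_dir = chord / chord_len
    off = xy - tip1
    perp = np.abs(off[:, 0] * chord_dir[1] - off[:, 1] * chord_dir[0])
    apex = xy[int(np.argmax(perp))]
    a1 = tip1 - apex
    a2 = tip2 - apex
    l1, l2 = np.linalg.norm(a1), np.linalg.norm(a2)
    total = l1 + l2
    if total < 1e-12 or min(l1, l2) < thresholds.t_arm_frac * total:
        return None
    cosang = np.clip(a1 @ a2 / (l1 * l2), -1.0, 1.0)
    angle = float(np.degrees(np.arccos(cosang)))
    if angle >= thresholds.t_v_deg:
        return None
    # both arms must themselves be thin and elongated, else discs would
    # qualify (their extreme points also form two wide "arms")
    d1 = _point_segment_distance(xy, apex, tip1)
    d2 = _point_segment_distance(xy, apex, tip2)
    for arm_mask in (d1 <= d2, d2 < d1):
        pts = xy[arm_mask]
        if len(pts) < 5 or _pca_elongation(pts) < thresholds.t_line:
            return None
    return angle


def _point_segment_distance(xy: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    ab = b - a
    denom = ab @ ab
    t = np.clip((xy - a) @ ab / denom, 0, 1) if denom > 0 else np.zeros(len(xy))
    feet = a + t[:, None] * ab
    return np.linalg.norm(xy - feet, axis=1)
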