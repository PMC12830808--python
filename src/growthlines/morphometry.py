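"""Landmark morphometry and the statistics used alongside it.

Four measurement tasks on annotated 2D images of hemisected embryo heads:

* the B:A length ratio — line A joins two trackable landmarks X and Y, and
  line B runs from Y (the posterior limit of A) to the foot on A of the
  perpendicular through the optic-margin intersection — with a logarithmic
  trend ``ratio = a*ln(stage) + b`` across stages;
* angles between the ZLI (zona limitans intrathalamica) direction and
  segments from the ZLI base to tracked ventral-midline points (*A, *P);
* positive-expression area inside a region of interest after bright-outlier
  despeckling and a fixed intensity threshold;
* two-sided Student and Welch two-sample t tests, implemented from the
  closed-form statistics with p-values from the t distribution.

Stage values entering the log fit are ordinal stage numbers (HH10 -> 10),
not developmental hours.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import scipy.ndimage as ndi
from scipy import stats
from skimage.draw import polygon2mask
from skimage.morphology import disk

__all__ = [
    "LandmarkSet",
    "AnnotatedImage",
    "BARatioResult",
    "AngleResult",
    "AreaResult",
    "TTestResult",
    "ba_ratio",
    "fit_log_trend",
    "zli_angles",
    "despeckle",
    "area_positive",
    "t_test",
]


@dataclass
class LandmarkSet:
    """Named 2D points and polylines (pixels or model units)."""

    points: dict[str, np.ndarray] = field(default_factory=dict)
    polylines: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.points = {k: np.asarray(v, dtype=float) for k, v in self.points.items()}
        self.polylines = {k: np.asarray(v, dtype=float) for k, v in self.polylines.items()}
        for name, poly in self.polylines.items():
            if poly.ndim != 2 or poly.shape[0] < 2 or poly.shape[1] != 2:
                raise ValueError(f"polyline {name!r} must be (m>=2, 2)")

    def require(self, points: Sequence[str] = (), polylines: Sequence[str] = ()) -> None:
        missing = [p for p in points if p not in self.points] + [
            p for p in polylines if p not in self.polylines
        ]
        if missing:
            raise KeyError(f"landmark set is missing required names: {missing}")


@dataclass
class AnnotatedImage:
    """2D intensity image with ROI polygon(s) in (row, col) pixel coordinates."""

    image: np.ndarray
    rois: list[np.ndarray] = field(default_factory=list)
    pixel_size: Optional[float] = None  # units per pixel

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image)
        if self.image.ndim != 2:
            raise ValueError("image must be 2D")
        if not np.all(np.isfinite(self.image.astype(float))):
            raise ValueError("image intensities must be finite")
        self.rois = [np.asarray(r, dtype=float) for r in self.rois]
        h, w = self.image.shape
        for r in self.rois:
            if r.ndim != 2 or r.shape[1] != 2 or len(r) < 3:
                raise ValueError("each ROI must be an (m>=3, 2) polygon")
            if r[:, 0].min() < -0.5 or r[:, 0].max() > h - 0.5 or \
               r[:, 1].min() < -0.5 or r[:, 1].max() > w - 0.5:
                raise ValueError("ROI polygon extends outside the image bounds")

    def roi_mask(self, index: int = 0) -> np.ndarray:
        if not self.rois:
            raise ValueError("image has no ROI polygon")
        return polygon2mask(self.image.shape, self.rois[index])


# -- B:A ratio --------------------------------------------------------------------


@dataclass(frozen=True)
class BARatioResult:
    a_length: float
    b_length: float
    ratio: float
    foot: tuple[float, float]  # intersection foot on line A


def ba_ratio(landmarks: LandmarkSet) -> BARatioResult:
    """Length ratio B:A from landmarks X, Y and the optic-margin polyline.

    A runs from X to Y.  The optic margin determines a perpendicular to A:
    where the margin crosses line A (or, if it never crosses, at its closest
    point to the line), drop the perpendicular foot onto A.  B is the
    distance from Y to that foot.  The foot must fall within segment XY.
    """
    landmarks.require(points=("X", "Y"), polylines=("optic_margin",))
    x = landmarks.points["X"]
    y = landmarks.points["Y"]
    axis = y - x
    a_len = float(np.linalg.norm(axis))
    if a_len <= 0:
        raise ValueError("X and Y coincide; line A is undefined")
    u = axis / a_len
    margin = landmarks.polylines["optic_margin"]
    rel = margin - x
    along = rel @ u  # coordinate along A
    perp = rel @ np.array([-u[1], u[0]])  # signed distance from line A

    t_foot = None
    crossings = np.flatnonzero(np.signbit(perp[:-1]) != np.signbit(perp[1:]))
    exact = np.flatnonzero(perp == 0)
    if exact.size:
        t_foot = float(along[exact[0]])
    elif crossings.size:
        i = int(crossings[0])
        w = perp[i] / (perp[i] - perp[i + 1])
        t_foot = float((1 - w) * along[i] + w * along[i + 1])
    else:
        t_foot = float(along[int(np.argmin(np.abs(perp)))])

    eps = 1e-9 * a_len
    if not (-eps <= t_foot <= a_len + eps):
        raise ValueError(
            "no perpendicular through the optic margin meets line A within "
            f"segment XY (foot parameter {t_foot / a_len:.3f} of A)"
        )
    t_foot = float(np.clip(t_foot, 0.0, a_len))
    b_len = a_len - t_foot
    foot = x + t_foot * u
    return BARatioResult(
        a_length=a_len,
        b_length=b_len,
        ratio=b_len / a_len,
        foot=(float(foot[0]), float(foot[1])),
    )


def fit_log_trend(stages: Sequence[float], ratios: Sequence[float]) -> tuple[float, float]:
    """Least-squares fit of ``ratio = a*ln(stage) + b``."""
    s = np.asarray(stages, dtype=float)
    r = np.asarray(ratios, dtype=float)
    if np.any(s <= 0):
        raise ValueError("stage values must be positive for a logarithmic trend")
    if len(np.unique(s)) < 2:
        raise ValueError("need at least two distinct stage values")
    design = np.stack([np.log(s), np.ones_like(s)], axis=1)
    coef, *_ = np.linalg.lstsq(design, r, rcond=None)
    return float(coef[0]), float(coef[1])


# -- ZLI angles -------------------------------------------------------------------


@dataclass(frozen=True)
class AngleResult:
    angle_a_deg: float
    angle_p_deg: float


def zli_angles(landmarks: LandmarkSet, tls_fit: bool = False) -> AngleResult:
    """Angles between the ZLI direction and base-to-*A / base-to-*P segments.

    The ZLI direction is the first-to-last chord of the polyline (straight
    annotation lines); ``tls_fit`` switches to a total-least-squares line
    fit for curved annotations.  Angles are between vectors, in [0, 180].
    """
    landmarks.require(points=("base", "starA", "starP"), polylines=("ZLI",))
    zli = landmarks.polylines["ZLI"]
    if tls_fit:
        q = zli - zli.mean(axis=0)
        _, _, vt = np.linalg.svd(q, full_matrices=False)
        d = vt[0]
        # orient along the chord for a stable sign
        chord = zli[-1] - zli[0]
        if d @ chord < 0:
            d = -d
    else:
        d = zli[-1] - zli[0]
    base = landmarks.points["base"]
    return AngleResult(
        angle_a_deg=_angle_between(d, landmarks.points["starA"] - base),
        angle_p_deg=_angle_between(d, landmarks.points["starP"] - base),
    )


def _angle_between(v1: np.ndarray, v2: np.ndarray) -> float:
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 == 0 or n2 == 0:
        raise ValueError("zero-length segment; angle undefined")
    cosang = np.clip(v1 @ v2 / (n1 * n2), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


# -- expression-area quantification ------------------------------------------------


def despeckle(image: np.ndarray, radius: int, outlier_threshold: float) -> np.ndarray:
    """Bright-outlier removal: median-replace pixels far above their local median.

    Emulates the documented semantics of ImageJ's "Remove Outliers" tool in
    bright mode: each pixel whose value exceeds the median of its
    radius-``radius`` disk neighbourhood by more than ``outlier_threshold``
    is replaced by that median.  Only bright outliers are touched.
    """
    if radius < 1:
        return image.copy()
    footprint = disk(radius)
    med = ndi.median_filter(image, footprint=footprint, mode="nearest")
    out = image.copy()
    bright = image.astype(np.int64) - med.astype(np.int64) > outlier_threshold
    out[bright] = med[bright]
    return out


@dataclass(frozen=True)
class AreaResult:
    pixels: int
    area_units: Optional[float]  # pixels * pixel_size**2, if calibrated


def area_positive(
    image: AnnotatedImage,
    threshold: float,
    despeckle_radius: int = 0,
    outlier_threshold: float = 0.0,
    roi_index: int = 0,
) -> AreaResult:
    """Area of positive expression inside the ROI.

    Fixed pipeline order: (1) bright-outlier despeckle (skipped when
    ``despeckle_radius`` is 0), (2) binarise: positive means strictly above
    ``threshold``, (3) count positive pixels inside the ROI polygon.
    """
    img = image.image
    lo, hi = float(img.min()), float(img.max())
    if not (lo <= threshold <= hi):
        raise ValueError(f"threshold {threshold} outside intensity range [{lo}, {hi}]")
    mask = image.roi_mask(roi_index)
    if not mask.any():
        raise ValueError("ROI rasterises to an empty mask")
    clean = despeckle(img, despeckle_radius, outlier_threshold)
    positive = clean > threshold
    n = int(np.count_nonzero(positive & mask))
    units = n * image.pixel_size**2 if image.pixel_size else None
    return AreaResult(pixels=n, area_units=units)


# -- t tests ----------------------------------------------------------------------


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float
    variant: str


def t_test(group_a: Sequence[float], group_b: Sequence[float], variant: str = "student") -> TTestResult:
    """Two-sided two-sample t test from the closed-form statistics.

    ``student`` pools variances with ``df = nA + nB - 2``; ``welch`` uses
    the unpooled statistic with Welch-Satterthwaite degrees of freedom.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        raise ValueError("each group needs at least two observations")
    ma, mb = a.mean(), b.mean()
    va, vb = a.var(ddof=1), b.var(ddof=1)

    if variant == "student":
        df = na + nb - 2
        sp2 = ((na - 1) * va + (nb - 1) * vb) / df
        se = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    elif variant == "welch":
        se2 = va / na + vb / nb
        se = np.sqrt(se2)
        if se2 > 0:
            df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
        else:
            df = na + nb - 2
    else:
        raise ValueError(f"unknown variant {variant!r}; use 'student' or 'welch'")

    if se == 0:
        if ma == mb:
            return TTestResult(t=0.0, df=float(df), p=1.0, variant=variant)
        raise ValueError(
            "both groups have zero variance but different means: the t "
            "statistic is undefined (zero standard error)"
        )
    t = (ma - mb) / se
    p = 2.0 * stats.t.sf(abs(t), df)
    return TTestResult(t=float(t), df=float(df), p=float(min(p, 1.0)), variant=variant)
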