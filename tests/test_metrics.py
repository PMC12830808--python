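"""Growth-line metrics: expansion, elongation, orientation, shape calls."""

import numpy as np
import pytest

from growthlines import dye, metrics
from growthlines.mesh import StageMesh, StageSeries, SurfacePoint, locate
from growthlines.metrics import AxisFrame, ShapeThresholds


def _flat_disc_mesh(n_rings=6, n_sectors=24, radius=1.0):
    """Flat triangulated disc in the z=0 plane, centre vertex 0."""
    verts = [[0.0, 0.0, 0.0]]
    for i in range(1, n_rings + 1):
        r = radius * i / n_rings
        for j in range(n_sectors):
            th = 2 * np.pi * j / n_sectors
            verts.append([r * np.cos(th), r * np.sin(th), 0.0])
    faces = []
    for j in range(n_sectors):
        faces.append((0, 1 + j, 1 + (j + 1) % n_sectors))
    for i in range(n_rings - 1):
        r0 = 1 + i * n_sectors
        r1 = 1 + (i + 1) * n_sectors
        for j in range(n_sectors):
            a, b = r0 + j, r0 + (j + 1) % n_sectors
            c, d = r1 + (j + 1) % n_sectors, r1 + j
            faces.append((a, b, c))
            faces.append((a, c, d))
    return StageMesh(np.asarray(verts), faces, "disc")


def _disc_patch(mesh, radius=2.0):
    seed = SurfacePoint(tri=0, bary=(1 / 3, 1 / 3, 1 / 3))
    return dye.inject(mesh, seed, radius, samples_per_face=10, rng_seed=0)


def _ap_frame(target=None):
    return AxisFrame(
        ap_polyline=np.array([[-10.0, 0, 0], [10.0, 0, 0]]),
        target=target,
    )


def _stretch(mesh, kx=1.0, ky=1.0, kz=1.0, label="t1"):
    v = mesh.vertices * np.array([kx, ky, kz])
    return mesh.with_vertices(v, label)


class TestMeasure:
    def test_identity_gives_unit_ratios_and_spot(self):
        disc = _flat_disc_mesh()
        series = StageSeries([disc, disc.with_vertices(disc.vertices, "b")])
        p0 = _disc_patch(disc)
        p1 = dye.propagate(p0, series, 1.0)
        m = metrics.measure(p0, p1, _ap_frame())
        assert m.area_ratio == pytest.approx(1.0, abs=1e-12)
        assert m.elongation == pytest.approx(1.0, rel=0.1)
        assert m.shape_class == "spot"
        assert m.centroid_displacement == pytest.approx(0.0, abs=1e-9)

    def test_ap_stretch_recovers_elongation_and_orientation(self):
        """A disc stretched x4 along A-P reads elongation ~4, orientation ~0."""
        disc = _flat_disc_mesh()
        series = StageSeries([disc, _stretch(disc, kx=4.0)])
        p0 = _disc_patch(disc)
        p1 = dye.propagate(p0, series, 1.0)
        m = metrics.measure(p0, p1, _ap_frame())
        assert m.elongation == pytest.approx(4.0, rel=0.05)
        assert min(m.orientation_deg, 180 - m.orientation_deg) < 3.0
        assert m.shape_class == "line"
        assert m.area_ratio == pytest.approx(4.0, rel=1e-9)

    def test_oblique_stretch_orientation(self):
        """Stretch along y (perpendicular to A-P) reads orientation ~90 deg."""
        disc = _flat_disc_mesh()
        series = StageSeries([disc, _stretch(disc, ky=5.0)])
        p0 = _disc_patch(disc)
        p1 = dye.propagate(p0, series, 1.0)
        m = metrics.measure(p0, p1, _ap_frame())
        assert m.orientation_deg == pytest.approx(90.0, abs=3.0)

    def test_uniform_scale_k_squared_area_unit_elongation(self):
        disc = _flat_disc_mesh()
        k = 2.5
        series = StageSeries([disc, _stretch(disc, k, k, k)])
        p0 = _disc_patch(disc)
        p1 = dye.propagate(p0, series, 1.0)
        m = metrics.measure(p0, p1, _ap_frame())
        assert m.area_ratio == pytest.approx(k**2, rel=1e-6)
        assert m.elongation == pytest.approx(1.0, rel=0.1)

    def test_different_face_sets_rejected(self):
        disc = _flat_disc_mesh()
        p0 = _disc_patch(disc, radius=0.5)
        p1 = _disc_patch(disc, radius=1.5)
        with pytest.raises(ValueError, match="same face set"):
            metrics.measure(p0, p1, _ap_frame())

    def test_rigid_motion_invariance(self):
        """Elongation, ratio and shape survive a rigid rotation+translation."""
        disc = _flat_disc_mesh()
        stretched = _stretch(disc, kx=4.0)
        th = 0.7
        rot = np.array(
            [
                [np.cos(th), -np.sin(th), 0],
                [np.sin(th), np.cos(th), 0],
                [0, 0, 1.0],
            ]
        )
        shift = np.array([3.0, -2.0, 5.0])
        disc_r = disc.with_vertices(disc.vertices @ rot.T + shift, "a")
        stretched_r = stretched.with_vertices(stretched.vertices @ rot.T + shift, "b")
        frame_r = AxisFrame(ap_polyline=np.array([[-10.0, 0, 0], [10.0, 0, 0]]) @ rot.T + shift)

        m0 = metrics.measure(
            _disc_patch(disc),
            dye.propagate(_disc_patch(disc), StageSeries([disc, stretched]), 1.0),
            _ap_frame(),
        )
        p0r = _disc_patch(disc_r)
        m1 = metrics.measure(
            p0r,
            dye.propagate(p0r, StageSeries([disc_r, stretched_r]), 1.0),
            frame_r,
        )
        assert m1.elongation == pytest.approx(m0.elongation, rel=1e-6)
        assert m1.area_ratio == pytest.approx(m0.area_ratio, rel=1e-9)
        assert m1.shape_class == m0.shape_class
        # orientation is measured against the co-rotated frame; the axis wraps
        # mod 180 and its sense depends on the fitted plane normal
        diff = abs(m1.orientation_deg - m0.orientation_deg)
        assert min(diff, 180 - diff) < 0.2

    def test_stretch_monotonicity(self):
        """Raising the planted stretch never lowers measured elongation."""
        disc = _flat_disc_mesh()
        p0 = _disc_patch(disc)
        measured = []
        for k in (1.5, 2.0, 3.0, 4.5, 6.0):
            series = StageSeries([disc, _stretch(disc, kx=k)])
            p1 = dye.propagate(p0, series, 1.0)
            measured.append(metrics.measure(p0, p1, _ap_frame()).elongation)
        assert all(b >= a for a, b in zip(measured, measured[1:]))


class TestClassifyShape:
    def test_near_circular_patch_is_spot(self):
        disc = _flat_disc_mesh()
        p = _disc_patch(disc)
        cls, ang = metrics.classify_shape(p, _ap_frame())
        assert cls == "spot" and ang is None

    def test_straight_elongated_patch_is_line(self):
        disc = _flat_disc_mesh()
        series = StageSeries([disc, _stretch(disc, kx=5.0)])
        p1 = dye.propagate(_disc_patch(disc), series, 1.0)
        cls, ang = metrics.classify_shape(p1, _ap_frame())
        assert cls == "line" and ang is None

    @pytest.mark.parametrize("true_angle", [60.0, 90.0, 120.0])
    def test_chevron_recovers_apex_angle(self, true_angle):
        """Two thin arms meeting at a known angle read as a V with that angle."""
        rng = np.random.default_rng(0)
        n = 400
        t = rng.random(n)
        half = np.radians(true_angle / 2)
        arm1 = np.stack([t * np.cos(half), t * np.sin(half)], axis=1)
        arm2 = np.stack([t * np.cos(half), -t * np.sin(half)], axis=1)
        pts2 = np.concatenate([arm1, arm2]) + rng.normal(scale=0.01, size=(2 * n, 2))
        pts3 = np.concatenate([pts2, np.zeros((2 * n, 1))], axis=1)

        class _FakePatch:
            def points(self):
                return pts3

        cls, ang = metrics.classify_shape(_FakePatch(), _ap_frame())
        assert cls == "V"
        assert ang == pytest.approx(true_angle, abs=8.0)


class TestConvergence:
    def test_axis_through_target_gives_zero(self):
        disc = _flat_disc_mesh()
        series = StageSeries([disc, _stretch(disc, kx=4.0)])
        p1 = dye.propagate(_disc_patch(disc), series, 1.0)
        frame = _ap_frame(target=np.array([6.0, 0.0, 0.0]))
        assert metrics.convergence(p1, frame) == pytest.approx(0.0, abs=0.05)

    def test_parallel_offset_axis_gives_offset(self):
        disc = _flat_disc_mesh()
        series = StageSeries([disc, _stretch(disc, kx=4.0)])
        p1 = dye.propagate(_disc_patch(disc), series, 1.0)
        d = 2.75
        frame = _ap_frame(target=np.array([0.0, d, 0.0]))
        assert metrics.convergence(p1, frame) == pytest.approx(d, abs=0.05)

    def test_random_configuration_matches_point_to_line_formula(self):
        rng = np.random.default_rng(7)
        disc = _flat_disc_mesh()
        series = StageSeries([disc, _stretch(disc, kx=4.0)])
        p1 = dye.propagate(_disc_patch(disc), series, 1.0)
        pts = p1.points()[:, :2]
        centroid = pts.mean(axis=0)
        cov = np.cov(pts.T, ddof=0)
        evals, evecs = np.linalg.eigh(cov)
        u = evecs[:, int(np.argmax(evals))]
        for _ in range(10):
            target = rng.normal(scale=5, size=2)
            w = target - centroid
            oracle = abs(w[0] * u[1] - w[1] * u[0])  # closed-form point-to-line
            frame = _ap_frame(target=np.array([target[0], target[1], 0.0]))
            assert metrics.convergence(p1, frame) == pytest.approx(oracle, abs=1e-9)

    def test_isotropic_patch_raises_with_guidance(self):
        disc = _flat_disc_mesh()
        p = _disc_patch(disc)
        with pytest.raises(ValueError, match="elongation"):
            metrics.convergence(p, _ap_frame(target=np.array([1.0, 0, 0])))


class TestDirectionalFieldRecovery:
    def test_orientation_tracks_true_stretch_direction(self, default_series):
        """Dye discs under the directional-growth field elongate toward the
        attractor within a few degrees of the true displacement direction."""
        series, truth = default_series
        base = series[0]
        frame = AxisFrame(
            ap_polyline=np.array(
                [[x, base.vertices[:, 1].max(), 0.0] for x in np.linspace(0, 4, 6)]
            ),
            target=np.asarray(truth.spec.attractor_point),
        )
        errors = []
        rng = np.random.default_rng(5)
        weights = truth.attractor_weights
        strong = np.flatnonzero(weights > 0.6)
        for vid in rng.choice(strong, size=6, replace=False):
            seed = locate(base, base.vertices[vid])
            p0 = dye.inject(base, seed, 0.3, rng_seed=1)
            p1 = dye.propagate(p0, series, series.n_stages - 1)
            m = metrics.measure(p0, p1, frame)
            if m.elongation < 1.3:
                continue
            # true local stretch direction: dominant displacement difference
            disp = truth.displacements[-1][vid]
            pts = p1.points()
            xy, c, e1, e2, n, _ = metrics._project_2d(pts)
            d_in = disp - (disp @ n) * n
            if np.linalg.norm(d_in) < 1e-9:
                continue
            d2 = np.array([d_in @ e1, d_in @ e2])
            d2 /= np.linalg.norm(d2)
            cov = np.cov(xy.T, ddof=0)
            evals, evecs = np.linalg.eigh(cov)
            major = evecs[:, int(np.argmax(evals))]
            ang = np.degrees(np.arccos(np.clip(abs(major @ d2), 0, 1)))
            errors.append(ang)
        assert errors, "no elongated patches found in the strong-attractor zone"
        assert np.median(errors) < 15.0
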