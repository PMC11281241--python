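"""Shape model construction, pyramid matching, pose refinement, masking."""

import numpy as np
import pytest

from podsplit3d import (
    EdgeImage,
    Pose,
    build_shape_model,
    detect_edges,
    extract_region,
    find_matches,
    open_mask,
    refine_pose,
)


def hollow_square(size=20, canvas=40, offset=8):
    img = np.zeros((canvas, canvas))
    a, b = offset, offset + size
    img[a, a:b + 1] = 1.0
    img[b, a:b + 1] = 1.0
    img[a:b + 1, a] = 1.0
    img[a:b + 1, b] = 1.0
    return img


def ellipse_scene(a=30.0, b=14.0, shape=(120, 160), centre=(80, 60),
                  fg=200.0, bg=30.0, theta=0.0):
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    x = (xx - centre[0]) * np.cos(theta) + (yy - centre[1]) * np.sin(theta)
    y = -(xx - centre[0]) * np.sin(theta) + (yy - centre[1]) * np.cos(theta)
    mask = (x / a) ** 2 + (y / b) ** 2 <= 1.0
    return np.where(mask, fg, bg).astype(float), mask


def ellipse_contour_template(a=30.0, b=14.0, pad=4):
    th = np.linspace(0, 2 * np.pi, 400, endpoint=False)
    x = a * np.cos(th) + a + pad
    y = b * np.sin(th) + b + pad
    img = np.zeros((int(2 * b) + 2 * pad + 2, int(2 * a) + 2 * pad + 2))
    img[np.round(y).astype(int), np.round(x).astype(int)] = 1.0
    return img


class TestBuildShapeModel:
    def test_square_model_points_and_normals(self):
        model = build_shape_model(hollow_square(), pyramid_levels=1,
                                  min_area=10)
        assert len(model.levels) == 1
        pts = model.levels[0].points + model.origin
        assert pts[:, 0].min() >= 7.0 and pts[:, 0].max() <= 29.0
        # normals of an axis-aligned square are axis-aligned outward
        nrm = model.levels[0].normals
        axis_aligned = (np.abs(np.abs(nrm[:, 0]) - 1) < 0.05) | \
                       (np.abs(np.abs(nrm[:, 1]) - 1) < 0.05)
        assert axis_aligned.mean() > 0.8  # corners may be diagonal
        out = np.einsum("ij,ij->i", nrm, model.levels[0].points)
        assert (out > 0).mean() > 0.95

    def test_pyramid_levels_shrink(self):
        model = build_shape_model(ellipse_contour_template(), pyramid_levels=3,
                                  min_area=10)
        counts = [len(l.points) for l in model.levels]
        assert counts == sorted(counts, reverse=True)
        assert all(c >= 8 for c in counts)

    def test_multiple_components_rejected_with_count(self):
        img = np.zeros((60, 60))
        img[5:15, 5:15] = 1.0
        img[30:45, 30:45] = 1.0
        with pytest.raises(ValueError, match="2 components"):
            build_shape_model(img, min_area=10)

    def test_ellipse_normals_match_analytic(self):
        a, b = 30.0, 14.0
        model = build_shape_model(ellipse_contour_template(a, b),
                                  pyramid_levels=1, min_area=10)
        pts = model.levels[0].points
        nrm = model.levels[0].normals
        # analytic outward normal of x^2/a^2 + y^2/b^2 = 1 at (x, y)
        grad = np.column_stack([pts[:, 0] / a ** 2, pts[:, 1] / b ** 2])
        grad /= np.linalg.norm(grad, axis=1, keepdims=True)
        ang = np.degrees(np.arccos(np.clip(
            np.einsum("ij,ij->i", nrm, grad), -1, 1)))
        assert np.median(ang) < 5.0


class TestFindMatches:
    def test_self_match_is_near_identity(self):
        img, _ = ellipse_scene()
        model = build_shape_model(ellipse_contour_template(), pyramid_levels=3,
                                  min_area=10,
                                  angle_range=(-180, 180), angle_step=1.0,
                                  scale_range=(0.9, 1.1), scale_step=0.05)
        poses = find_matches(model, img, min_score=0.5, max_matches=2)
        assert poses
        best = poses[0]
        assert best.score >= 0.95
        # identity pose maps the model origin to the ellipse centre
        assert abs(best.tx - 80) <= 1.0 and abs(best.ty - 60) <= 1.0
        theta = np.degrees(best.theta) % 180
        assert min(theta, 180 - theta) <= 1.0
        assert abs(best.scale - 1.0) <= 0.02

    def test_pure_noise_has_no_high_score_match(self, rng):
        img = rng.uniform(0, 255, size=(100, 120))
        model = build_shape_model(ellipse_contour_template(), pyramid_levels=3,
                                  min_area=10)
        assert find_matches(model, img, min_score=0.8) == []

    def test_integer_translation_equivariance(self):
        img, _ = ellipse_scene(centre=(70, 56))
        model = build_shape_model(ellipse_contour_template(), pyramid_levels=3,
                                  min_area=10)
        p0 = find_matches(model, img, min_score=0.5, max_matches=1)[0]
        dx, dy = 16, 8  # multiples of the pyramid downscale factor
        img2 = np.roll(np.roll(img, dy, axis=0), dx, axis=1)
        p1 = find_matches(model, img2, min_score=0.5, max_matches=1)[0]
        assert p1.tx - p0.tx == pytest.approx(dx, abs=1e-9)
        assert p1.ty - p0.ty == pytest.approx(dy, abs=1e-9)

    def test_score_bounds(self):
        img, _ = ellipse_scene()
        model = build_shape_model(ellipse_contour_template(), pyramid_levels=3,
                                  min_area=10)
        for pose in find_matches(model, img, min_score=0.3, max_matches=5):
            assert 0.0 <= pose.score <= 1.0


class TestRefinePose:
    def _model_and_edges(self, shift=(0.0, 0.0), rot=0.0):
        model = build_shape_model(ellipse_contour_template(), pyramid_levels=1,
                                  min_area=10)
        pts = model.levels[0].points + model.origin
        c, s = np.cos(rot), np.sin(rot)
        moved = (pts - model.origin) @ np.array([[c, s], [-s, c]]) \
            + model.origin + np.asarray(shift)
        edges = EdgeImage(points=moved, normals=model.levels[0].normals,
                          shape=(200, 200))
        return model, edges

    def test_exact_overlap_gives_zero_update(self):
        model, edges = self._model_and_edges()
        init = Pose(theta=0.0, tx=float(model.origin[0]),
                    ty=float(model.origin[1]), scale=1.0, score=0.9)
        out = refine_pose(model, edges, init)
        assert abs(out.theta) < 1e-9
        assert abs(out.tx - init.tx) < 1e-9 and abs(out.ty - init.ty) < 1e-9

    @pytest.mark.parametrize("shift", [(2.0, 0.0), (0.0, -2.0), (3.0, 1.5)])
    def test_translation_recovered_subpixel(self, shift):
        model, edges = self._model_and_edges(shift=shift)
        init = Pose(theta=0.0, tx=float(model.origin[0]),
                    ty=float(model.origin[1]), scale=1.0, score=0.9)
        out = refine_pose(model, edges, init)
        assert abs(out.tx - init.tx - shift[0]) < 0.1
        assert abs(out.ty - init.ty - shift[1]) < 0.1
        assert abs(np.degrees(out.theta)) < 0.2

    def test_rotation_recovered(self):
        rot = np.radians(3.0)
        model, edges = self._model_and_edges(rot=rot)
        init = Pose(theta=0.0, tx=float(model.origin[0]),
                    ty=float(model.origin[1]), scale=1.0, score=0.9)
        out = refine_pose(model, edges, init, iterations=5)
        assert abs(np.degrees(out.theta) - 3.0) < 0.3

    def test_residual_never_increases(self):
        from scipy.spatial import cKDTree
        model, edges = self._model_and_edges(shift=(3.0, -2.0), rot=np.radians(2))
        init = Pose(theta=0.0, tx=float(model.origin[0]),
                    ty=float(model.origin[1]), scale=1.0, score=0.9)
        tree = cKDTree(edges.points)

        def residual(pose):
            pts = pose.apply(model.levels[0].points)
            d, j = tree.query(pts)
            nrm = model.levels[0].normals @ pose.matrix()[:, :2].T
            return float(np.mean(np.abs(
                np.einsum("ij,ij->i", edges.points[j] - pts, nrm))))

        res = [residual(init)]
        for k in range(1, 6):
            res.append(residual(refine_pose(model, edges, init, iterations=k)))
        assert all(b <= a + 1e-9 for a, b in zip(res, res[1:]))

    def test_degenerate_correspondences_flagged(self):
        model, _ = self._model_and_edges()
        far_edges = EdgeImage(points=np.array([[500.0, 500.0]]),
                              normals=np.array([[1.0, 0.0]]),
                              shape=(600, 600))
        init = Pose(theta=0.0, tx=float(model.origin[0]),
                    ty=float(model.origin[1]), scale=1.0, score=0.5)
        with pytest.warns(UserWarning, match="correspondences"):
            out = refine_pose(model, far_edges, init)
        assert out.degenerate


class TestExtractAndOpen:
    def test_square_mask_filled(self):
        model = build_shape_model(hollow_square(), pyramid_levels=1,
                                  min_area=10)
        pose = Pose(theta=0.0, tx=float(model.origin[0]),
                    ty=float(model.origin[1]), scale=1.0, score=1.0)
        mask, crop = extract_region(np.zeros((40, 40)), model, pose)
        assert 300 <= mask.sum() <= 460  # ~20x20 interior
        assert mask[18, 18]
        assert crop.shape[0] >= 18

    def test_mask_area_scales_quadratically(self):
        model = build_shape_model(hollow_square(40, canvas=120, offset=40),
                                  pyramid_levels=1, min_area=10)
        areas = {}
        for s in (0.5, 1.0):
            pose = Pose(theta=0.0, tx=60.0, ty=60.0, scale=s, score=1.0)
            mask, _ = extract_region(np.zeros((120, 120)), model, pose)
            areas[s] = mask.sum()
        assert areas[1.0] / areas[0.5] == pytest.approx(4.0, rel=0.1)

    def test_clipping_warns(self):
        model = build_shape_model(hollow_square(), pyramid_levels=1,
                                  min_area=10)
        pose = Pose(theta=0.0, tx=2.0, ty=2.0, scale=1.0, score=1.0)
        with pytest.warns(UserWarning, match="outside"):
            extract_region(np.zeros((40, 40)), model, pose)

    def test_opening_removes_isolated_pixel(self):
        m = np.zeros((20, 20), dtype=bool)
        m[10, 10] = True
        assert open_mask(m, 1).sum() == 0

    def test_opening_preserves_solid_square_bulk(self):
        # a disk element keeps every straight edge; only the four convex
        # corners can lose the few pixels the disk cannot reach
        m = np.zeros((60, 60), dtype=bool)
        m[5:55, 5:55] = True
        o = open_mask(m, 2)
        assert not np.any(o & ~m)
        lost = m.sum() - o.sum()
        assert lost <= 4 * 4  # at most ~r^2 pixels per corner
        assert np.array_equal(o[10:50, 10:50], m[10:50, 10:50])

    def test_opening_antiextensive_and_idempotent(self, rng):
        m = rng.uniform(size=(50, 50)) > 0.45
        o1 = open_mask(m, 2)
        assert not np.any(o1 & ~m)
        assert np.array_equal(open_mask(o1, 2), o1)
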