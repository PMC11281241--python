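"""Shape-based template matching of pod contours in a 2-D grayscale image.

The template is an edge-point model: contour points D_i with outward unit
normals N_i, kept over an image pyramid and searched across rotation, scale
and translation.  The similarity of a candidate pose is the mean over model
points of |N_i' . g(W D_i)| — the absolute cosine between the transformed
model normal and the unit image-gradient direction at the transformed point
(zero where the gradient is too weak).  The score lives in [0, 1] and is
tolerant to contrast polarity.

The best discrete pose is refined to sub-pixel accuracy by iterating a
3-unknown linear least squares on the point-to-tangent distance

    F = sum_i ((W(dtheta, dx, dy) . p_i - s_i) . n_i)^2

with W the small-angle rigid transform (cos t ~ 1, sin t ~ t), s_i the edge
point matched to model point p_i, and scale held fixed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter, sobel
from scipy.spatial import cKDTree

__all__ = [
    "ShapeModel",
    "Pose",
    "EdgeImage",
    "build_shape_model",
    "detect_edges",
    "find_matches",
    "refine_pose",
    "extract_region",
    "open_mask",
]


@dataclass(frozen=True)
class Pose:
    """Rigid pose + isotropic scale of a template in image coordinates."""

    theta: float            # rotation, radians
    tx: float               # template origin position, pixels
    ty: float
    scale: float = 1.0
    score: float = 0.0
    degenerate: bool = False

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("scale must be > 0")
        if not 0.0 <= self.score <= 1.0:
            raise ValueError("score must be in [0, 1]")

    def matrix(self) -> np.ndarray:
        """2x3 affine: p_image = s R(theta) p_model + t."""
        c, s = np.cos(self.theta), np.sin(self.theta)
        return np.array([[self.scale * c, -self.scale * s, self.tx],
                         [self.scale * s, self.scale * c, self.ty]])

    def apply(self, pts: np.ndarray) -> np.ndarray:
        M = self.matrix()
        return pts @ M[:, :2].T + M[:, 2]


@dataclass
class ModelLevel:
    points: np.ndarray    # (K, 2) origin-relative, in this level's pixel units
    normals: np.ndarray   # (K, 2) unit outward


@dataclass
class ShapeModel:
    """Contour edge-point template over a pyramid of resolutions."""

    levels: list[ModelLevel]          # index 0 = finest
    angle_range: tuple[float, float]  # degrees
    angle_step: float                 # degrees, at the finest level
    scale_range: tuple[float, float]
    scale_step: float
    origin: np.ndarray                # reference point, level-0 template px

    def __post_init__(self) -> None:
        for lvl in self.levels:
            if len(lvl.points) < 8:
                raise ValueError("every pyramid level needs >= 8 model points")
            if np.abs(np.linalg.norm(lvl.normals, axis=1) - 1).max() > 1e-8:
                raise ValueError("model normals must be unit")


def _outer_contour(binary: np.ndarray, min_area: float, max_area: float):
    """Preprocessing chain: components -> hole fill -> area window -> contour."""
    from scipy.ndimage import binary_fill_holes, label
    from skimage import measure

    # 8-connectivity: a 1-px digital contour is 8-connected along diagonals
    lab, n = label(binary, structure=np.ones((3, 3), dtype=int))
    kept = []
    for rid in range(1, n + 1):
        comp = binary_fill_holes(lab == rid)
        area = int(comp.sum())
        if min_area <= area <= max_area:
            kept.append(comp)
    if len(kept) != 1:
        raise ValueError(
            f"area filter kept {len(kept)} components (need exactly 1)"
        )
    filled = kept[0]
    contours = measure.find_contours(filled.astype(float), 0.5)
    contour = max(contours, key=len)       # (row, col), subpixel
    return filled, contour[:, ::-1]        # -> (x, y)


def build_shape_model(
    template: np.ndarray,
    pyramid_levels: int = 4,
    angle_range: tuple[float, float] = (-180.0, 180.0),
    angle_step: float = 1.0,
    scale_range: tuple[float, float] = (0.9, 1.1),
    scale_step: float = 0.05,
    min_area: float = 20.0,
    max_area: float = np.inf,
    max_points: int = 512,
) -> ShapeModel:
    """Build a scalable edge-point model from a (binary or gray) contour image.

    The image is thresholded, adjacent areas are connected and filled, a
    single component is retained by the area window, and its outer contour
    becomes the model: points with outward unit normals, subsampled to at
    most *max_points* on the finest level and halved in resolution (and
    count) on each coarser level.
    """
    from scipy.ndimage import binary_closing

    img = np.asarray(template, dtype=float)
    binary = img > 0.5 * img.max()
    binary = binary_closing(binary, structure=np.ones((3, 3)))
    filled, xy = _outer_contour(binary, min_area, max_area)

    # tangents on a lightly smoothed closed curve (marching-squares points
    # stair-step at pixel scale) with a widened central difference
    closed = np.allclose(xy[0], xy[-1])
    pts = xy[:-1] if closed else xy
    if len(pts) >= 16:
        kernel = np.ones(5) / 5.0
        sm = np.column_stack([
            np.convolve(np.concatenate([pts[-2:, i], pts[:, i], pts[:2, i]]),
                        kernel, mode="valid")
            for i in range(2)
        ])
    else:
        sm = pts
    w = 3 if len(pts) >= 32 else 1
    tang = np.roll(sm, -w, axis=0) - np.roll(sm, w, axis=0)
    tang /= np.maximum(np.linalg.norm(tang, axis=1, keepdims=True), 1e-12)
    normals = np.column_stack([tang[:, 1], -tang[:, 0]])
    centroid = pts.mean(axis=0)
    out = np.einsum("ij,ij->i", normals, pts - centroid)
    if np.median(out) < 0:
        normals = -normals

    step = max(1, int(np.ceil(len(pts) / max_points)))
    pts, normals = pts[::step], normals[::step]
    origin = pts.mean(axis=0)
    rel = pts - origin

    levels = []
    for lv in range(pyramid_levels):
        sub = max(1, 2 ** lv)
        p = rel[::sub] / (2.0 ** lv)
        n = normals[::sub]
        if len(p) < 8:
            break
        levels.append(ModelLevel(points=p, normals=n))
    return ShapeModel(
        levels=levels,
        angle_range=angle_range,
        angle_step=angle_step,
        scale_range=scale_range,
        scale_step=scale_step,
        origin=origin,
    )


# ---------------------------------------------------------------------------
# edges and gradient-direction fields
# ---------------------------------------------------------------------------

@dataclass
class EdgeImage:
    """Edge points with unit gradient normals, from Canny + Sobel."""

    points: np.ndarray    # (E, 2) (x, y)
    normals: np.ndarray   # (E, 2) unit
    shape: tuple[int, int]


def detect_edges(
    image: np.ndarray,
    sigma: float = 1.5,
    low_frac: float = 0.1,
    high_frac: float = 0.2,
) -> EdgeImage:
    """Canny edge pixels with unit Sobel-gradient normals."""
    from skimage.feature import canny

    img = np.asarray(image, dtype=float)
    mask = canny(img, sigma=sigma,
                 low_threshold=low_frac * img.max(),
                 high_threshold=high_frac * img.max())
    gy = sobel(gaussian_filter(img, sigma), axis=0)
    gx = sobel(gaussian_filter(img, sigma), axis=1)
    ys, xs = np.nonzero(mask)
    g = np.column_stack([gx[ys, xs], gy[ys, xs]])
    norms = np.linalg.norm(g, axis=1)
    keep = norms > 1e-12
    return EdgeImage(
        points=np.column_stack([xs, ys])[keep].astype(float),
        normals=g[keep] / norms[keep, None],
        shape=img.shape,
    )


def _direction_field(image: np.ndarray, sigma: float = 1.0,
                     mag_frac: float = 0.1):
    """Unit-gradient field (gx, gy), zeroed where |grad| < mag_frac * max."""
    sm = gaussian_filter(np.asarray(image, dtype=float), sigma)
    gx = sobel(sm, axis=1)
    gy = sobel(sm, axis=0)
    mag = np.hypot(gx, gy)
    thresh = mag_frac * mag.max()
    with np.errstate(invalid="ignore", divide="ignore"):
        ux = np.where(mag > thresh, gx / mag, 0.0)
        uy = np.where(mag > thresh, gy / mag, 0.0)
    return ux, uy


def _pool2(img: np.ndarray) -> np.ndarray:
    """2x2 mean pooling (pyramid downscale)."""
    h, w = img.shape
    h2, w2 = h // 2, w // 2
    return img[: 2 * h2, : 2 * w2].reshape(h2, 2, w2, 2).mean(axis=(1, 3))


def _score_at(ux, uy, pts, normals) -> float:
    """Score one pose: pts already transformed into this level's pixels."""
    h, w = ux.shape
    xi = np.rint(pts[:, 0]).astype(int)
    yi = np.rint(pts[:, 1]).astype(int)
    ok = (xi >= 0) & (xi < w) & (yi >= 0) & (yi < h)
    if not ok.any():
        return 0.0
    dots = np.abs(normals[ok, 0] * ux[yi[ok], xi[ok]]
                  + normals[ok, 1] * uy[yi[ok], xi[ok]])
    return float(dots.sum() / len(pts))


def _rot(theta: float) -> np.ndarray:
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, -s], [s, c]])


def find_matches(
    model: ShapeModel,
    image: np.ndarray,
    min_score: float = 0.5,
    max_matches: int = 10,
    max_overlap: float = 0.2,
) -> list[Pose]:
    """Locate the template in *image* by coarse-to-fine pyramid search.

    Candidates above a relaxed threshold at the coarsest level are tracked
    down the pyramid (translation +/-2 px, angle +/- one step — the step
    halves per level — and scale +/- one step), then greedily filtered by
    bounding-box overlap.  Returned poses are sorted by descending score.
    """
    if not 0 < min_score <= 1:
        raise ValueError("min_score must be in (0, 1]")
    img = np.asarray(image, dtype=float)
    n_levels = len(model.levels)
    pyramid = [img]
    for _ in range(n_levels - 1):
        pyramid.append(_pool2(pyramid[-1]))
    fields = [_direction_field(p) for p in pyramid]

    lo, hi = np.radians(model.angle_range[0]), np.radians(model.angle_range[1])
    step_c = np.radians(model.angle_step) * 2 ** (n_levels - 1)
    angles = np.arange(lo, hi + 1e-9, step_c) if hi > lo else np.array([lo])
    s_lo, s_hi = model.scale_range
    scales = (np.arange(s_lo, s_hi + 1e-9, model.scale_step)
              if s_hi > s_lo else np.array([s_lo]))

    # ---- exhaustive search at the coarsest level ----
    ux, uy = fields[-1]
    h, w = ux.shape
    lvl = model.levels[-1]
    cand: list[tuple[float, float, float, float, float]] = []
    score_best = np.zeros((h, w))
    pose_best = np.zeros((h, w, 2))
    for th in angles:
        R = _rot(th)
        nrm = lvl.normals @ R.T
        for sc in scales:
            pts = (lvl.points @ R.T) * sc
            dx = np.rint(pts[:, 0]).astype(int)
            dy = np.rint(pts[:, 1]).astype(int)
            nx, ny = nrm[:, 0], nrm[:, 1]
            acc = np.zeros((h, w))
            for k in range(len(pts)):
                sy0, sy1 = max(0, -dy[k]), min(h, h - dy[k])
                sx0, sx1 = max(0, -dx[k]), min(w, w - dx[k])
                if sy0 >= sy1 or sx0 >= sx1:
                    continue
                gxs = ux[sy0 + dy[k]: sy1 + dy[k], sx0 + dx[k]: sx1 + dx[k]]
                gys = uy[sy0 + dy[k]: sy1 + dy[k], sx0 + dx[k]: sx1 + dx[k]]
                acc[sy0:sy1, sx0:sx1] += np.abs(nx[k] * gxs + ny[k] * gys)
            acc /= len(pts)
            better = acc > score_best
            score_best[better] = acc[better]
            pose_best[better] = (th, sc)

    floor = max(0.25, min_score - 0.2)
    from scipy.ndimage import maximum_filter

    peaks = (score_best == maximum_filter(score_best, size=5)) & \
            (score_best >= floor)
    ys, xs = np.nonzero(peaks)
    order = np.argsort(score_best[ys, xs])[::-1][: max_matches * 4]
    for y, x in zip(ys[order], xs[order]):
        # near-symmetric shapes tie across rotations at coarse resolution;
        # spawn every angle competitive at this position and let the finer
        # levels discriminate
        best_here = float(score_best[y, x])
        per_angle: list[tuple[float, float, float]] = []
        for th in angles:
            R = _rot(th)
            nrm = lvl.normals @ R.T
            s_best, sc_best_a = 0.0, scales[0]
            for sc in scales:
                pts = (lvl.points @ R.T) * sc + (x, y)
                s = _score_at(ux, uy, pts, nrm)
                if s > s_best:
                    s_best, sc_best_a = s, sc
            per_angle.append((s_best, float(th), float(sc_best_a)))
        per_angle.sort(reverse=True)
        for s_a, th, sc in per_angle[:3]:
            if s_a >= best_here - 0.08:
                cand.append((th, float(x), float(y), sc, s_a))

    # ---- track candidates down the pyramid ----
    for lv in range(n_levels - 2, -1, -1):
        ux, uy = fields[lv]
        lvl = model.levels[lv]
        step = np.radians(model.angle_step) * 2 ** lv
        refined = []
        for th0, x0, y0, sc0, _ in cand:
            x0, y0 = 2 * x0, 2 * y0
            best = (0.0, th0, x0, y0, sc0)
            for th in (th0 - step, th0, th0 + step):
                R = _rot(th)
                nrm = lvl.normals @ R.T
                for sc in {max(s_lo, sc0 - model.scale_step), sc0,
                           min(s_hi, sc0 + model.scale_step)}:
                    base = (lvl.points @ R.T) * sc
                    for ddy in range(-2, 3):
                        for ddx in range(-2, 3):
                            pts = base + (x0 + ddx, y0 + ddy)
                            s = _score_at(ux, uy, pts, nrm)
                            if s > best[0]:
                                best = (s, th, x0 + ddx, y0 + ddy, sc)
            refined.append((best[1], best[2], best[3], best[4], best[0]))
        cand = refined

    # ---- threshold, overlap suppression ----
    results: list[Pose] = []
    lvl0 = model.levels[0]
    boxes: list[tuple[float, float, float, float]] = []
    for th, x, y, sc, s in sorted(cand, key=lambda c: -c[4]):
        if s < min_score or len(results) >= max_matches:
            continue
        pose = Pose(theta=th, tx=x, ty=y, scale=sc, score=min(1.0, s))
        pts = pose.apply(lvl0.points)
        box = (pts[:, 0].min(), pts[:, 1].min(), pts[:, 0].max(), pts[:, 1].max())
        if any(_box_overlap(box, b) > max_overlap for b in boxes):
            continue
        boxes.append(box)
        results.append(pose)
    return results


def _box_overlap(a, b) -> float:
    ix = max(0.0, min(a[2], b[2]) - max(a[0], b[0]))
    iy = max(0.0, min(a[3], b[3]) - max(a[1], b[1]))
    inter = ix * iy
    if inter == 0:
        return 0.0
    area_a = (a[2] - a[0]) * (a[3] - a[1])
    area_b = (b[2] - b[0]) * (b[3] - b[1])
    return inter / min(area_a, area_b)


def refine_pose(
    model: ShapeModel,
    edges: EdgeImage,
    init: Pose,
    iterations: int = 10,
    max_corr_dist: float = 5.0,
) -> Pose:
    """Sub-pixel pose refinement by iterated point-to-tangent least squares.

    Each iteration matches every transformed model point to its nearest edge
    point, solves the linearised 3-unknown system for (dtheta, dx, dy) and
    composes the increment; scale stays fixed.  A backtracking line search
    keeps the mean absolute normal distance non-increasing; iteration stops
    at |update| < 1e-3 (px / radians).
    """
    if len(edges.points) == 0:
        raise ValueError("edge image is empty")
    if init.score <= 0:
        raise ValueError("initial pose must have positive score")
    tree = cKDTree(edges.points)
    lvl = model.levels[0]
    M = init.matrix()

    def residual_and_system(Mcur):
        pts = lvl.points @ Mcur[:, :2].T + Mcur[:, 2]
        Rn = Mcur[:, :2] / init.scale
        nrm = lvl.normals @ Rn.T
        dist, j = tree.query(pts, distance_upper_bound=max_corr_dist)
        ok = np.isfinite(dist)
        if ok.sum() < 3:
            return None
        p, n_v, s_v = pts[ok], nrm[ok], edges.points[j[ok]]
        b = np.einsum("ij,ij->i", s_v - p, n_v)
        a = np.column_stack([p[:, 0] * n_v[:, 1] - p[:, 1] * n_v[:, 0],
                             n_v[:, 0], n_v[:, 1]])
        return a, b, float(np.mean(np.abs(b)))

    sys0 = residual_and_system(M)
    if sys0 is None:
        warnings.warn("fewer than 3 valid correspondences; returning init")
        return Pose(init.theta, init.tx, init.ty, init.scale, init.score,
                    degenerate=True)
    for _ in range(iterations):
        sys_cur = residual_and_system(M)
        if sys_cur is None:
            break
        a, b, res = sys_cur
        delta, *_ = np.linalg.lstsq(a, b, rcond=None)
        accepted = False
        for damp in (1.0, 0.5, 0.25, 0.125):
            dth, dx, dy = delta * damp
            c, s = np.cos(dth), np.sin(dth)
            dM = np.array([[c, -s, dx], [s, c, dy]])
            Mnew = np.empty((2, 3))
            Mnew[:, :2] = dM[:, :2] @ M[:, :2]
            Mnew[:, 2] = dM[:, :2] @ M[:, 2] + dM[:, 2]
            sys_new = residual_and_system(Mnew)
            if sys_new is not None and sys_new[2] <= res + 1e-15:
                M = Mnew
                accepted = True
                break
        if not accepted or np.max(np.abs(delta)) < 1e-3:
            break
    theta = float(np.arctan2(M[1, 0], M[0, 0]))
    return Pose(theta=theta, tx=float(M[0, 2]), ty=float(M[1, 2]),
                scale=init.scale, score=init.score)


def extract_region(
    image: np.ndarray, model: ShapeModel, pose: Pose
) -> tuple[np.ndarray, np.ndarray]:
    """Filled mask of the pose-transformed model contour + bbox crop."""
    from skimage.draw import polygon

    img = np.asarray(image)
    h, w = img.shape[:2]
    pts = pose.apply(model.levels[0].points)
    if (pts[:, 0].min() < -0.5 or pts[:, 1].min() < -0.5
            or pts[:, 0].max() > w - 0.5 or pts[:, 1].max() > h - 0.5):
        warnings.warn("transformed contour extends outside the image; clipping")
    rr, cc = polygon(pts[:, 1], pts[:, 0], shape=(h, w))
    mask = np.zeros((h, w), dtype=bool)
    mask[rr, cc] = True
    if not mask.any():
        return mask, img[0:0, 0:0]
    ys, xs = np.nonzero(mask)
    crop = img[ys.min(): ys.max() + 1, xs.min(): xs.max() + 1]
    return mask, crop


def open_mask(mask: np.ndarray, se_radius: int = 2) -> np.ndarray:
    """Morphological opening (erosion then dilation) with a disk element.

    Anti-extensive (result is a subset of the input) and idempotent; removes
    burrs and protrusions narrower than the structuring element.
    """
    from scipy.ndimage import binary_opening
    from skimage.morphology import disk

    if se_radius < 1:
        raise ValueError("se_radius must be >= 1")
    return binary_opening(np.asarray(mask, dtype=bool),
                          structure=disk(se_radius))
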