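"""2-D boundary extraction from a segmented pod cloud by the rolling-ball
(alpha-hull) criterion, contour ordering and template rasterisation.

A pair of projected points (A, B) with |AB| <= 2r forms a boundary edge when
at least one of the two radius-r disks passing through A and B contains no
other point strictly in its interior — the disk can "roll" around the
outside of the set and touch both points.  The two candidate centres are
O = C +/- D*H, with C the midpoint of AB, H the unit perpendicular of AB and
D = sqrt(r^2 - (L/2)^2) for chord length L.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .cloud import PointCloud

__all__ = [
    "PlanarPoints",
    "Contour2D",
    "project_to_plane",
    "rolling_ball_boundary",
    "default_ball_radius",
    "order_contour",
    "rasterize_template",
]


@dataclass
class PlanarPoints:
    """Projected 2-D points (mm) with a map back to the source cloud."""

    points2d: np.ndarray
    source_indices: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.points2d = np.asarray(self.points2d, dtype=float).reshape(-1, 2)
        if self.source_indices is None:
            self.source_indices = np.arange(len(self.points2d))
        else:
            self.source_indices = np.asarray(self.source_indices, dtype=int)

    def __len__(self) -> int:
        return len(self.points2d)


@dataclass
class Contour2D:
    """Ordered closed polygon (mm)."""

    vertices: np.ndarray
    radius_used: float
    is_closed: bool = True

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 2)
        if self.is_closed and len(self.vertices) >= 2:
            if not np.allclose(self.vertices[0], self.vertices[-1]):
                self.vertices = np.vstack([self.vertices, self.vertices[:1]])

    @property
    def area(self) -> float:
        """Signed shoelace area (positive for counter-clockwise)."""
        v = self.vertices
        return 0.5 * float(np.sum(v[:-1, 0] * v[1:, 1] - v[1:, 0] * v[:-1, 1]))


def project_to_plane(cloud: PointCloud) -> PlanarPoints:
    """Orthographic projection onto the world XY plane (top-down camera)."""
    if len(cloud) == 0:
        raise ValueError("cannot project an empty cloud")
    return PlanarPoints(points2d=cloud.points[:, :2],
                        source_indices=np.arange(len(cloud)))


def default_ball_radius(pts: PlanarPoints, factor: float = 3.0) -> float:
    """factor x the median nearest-neighbour spacing of the projected points."""
    tree = cKDTree(pts.points2d)
    d, _ = tree.query(pts.points2d, k=2)
    return factor * float(np.median(d[:, 1]))


def rolling_ball_boundary(
    pts: PlanarPoints, radius: float
) -> tuple[np.ndarray, np.ndarray]:
    """Boundary points and edges of a 2-D point set by the rolling-ball test.

    Returns
    -------
    boundary_indices : sorted array of indices into pts of boundary points.
    edges : (E, 2) array of index pairs (i < j), each a boundary edge.

    Notes
    -----
    "Strictly inside" uses distance < r - 1e-9*r so points exactly on a
    candidate circle never block an edge.  |AB| = 2r is handled seamlessly:
    D = sqrt(max(0, r^2 - (L/2)^2)) collapses the two centres into one.
    Candidate blockers are fetched from a KD-tree within 2r of the segment
    midpoint, which is equivalent to the naive all-points scan because any
    point inside either circle lies within r + L/2 <= 2r of the midpoint.
    """
    if radius <= 0:
        raise ValueError("radius must be > 0")
    P = pts.points2d
    if len(P) < 3:
        raise ValueError("need at least 3 points")
    # deduplicate exact coincident coordinates
    _, uniq_idx = np.unique(P.round(decimals=12), axis=0, return_index=True)
    if len(uniq_idx) < len(P):
        warnings.warn(f"removed {len(P) - len(uniq_idx)} duplicate points "
                      "before boundary extraction")
    active = np.sort(uniq_idx)
    Q = P[active]
    m = len(Q)
    if m < 3:
        raise ValueError("fewer than 3 distinct points")
    tree = cKDTree(Q)
    eps = 1e-9 * radius
    edges = []
    pairs = tree.query_pairs(2.0 * radius, output_type="ndarray")
    for i, j in pairs:
        A, B = Q[i], Q[j]
        C = 0.5 * (A + B)
        V = B - A
        L = np.hypot(V[0], V[1])
        H = np.array([-V[1], V[0]]) / L
        D = np.sqrt(max(0.0, radius * radius - 0.25 * L * L))
        empty = False
        for O in (C + D * H, C - D * H):
            cand = tree.query_ball_point(O, radius - eps)
            if not any(c != i and c != j for c in cand):
                empty = True
                break
        if empty:
            edges.append((active[i], active[j]))
    if not edges:
        return np.empty(0, dtype=int), np.empty((0, 2), dtype=int)
    edges = np.array(sorted((min(a, b), max(a, b)) for a, b in edges), dtype=int)
    boundary = np.unique(edges)
    return boundary, edges


def order_contour(edges: np.ndarray, pts: PlanarPoints) -> Contour2D:
    """Walk the boundary-edge graph into a single closed polygon.

    Greedy traversal: at a branch the outgoing edge with the smallest turning
    angle (straightest continuation) is taken; among all closed loops found
    from every possible start, the one enclosing the largest absolute area is
    kept.  Output orientation is normalised counter-clockwise, with exact
    duplicate consecutive vertices removed.
    """
    edges = np.asarray(edges, dtype=int)
    if len(edges) < 3:
        raise ValueError("need at least 3 boundary edges")
    P = pts.points2d
    adj: dict[int, list[int]] = {}
    for a, b in edges:
        adj.setdefault(int(a), []).append(int(b))
        adj.setdefault(int(b), []).append(int(a))

    def walk(start: int, second: int) -> list[int] | None:
        loop = [start, second]
        used = {(start, second)}
        while True:
            prev, cur = loop[-2], loop[-1]
            d_in = P[cur] - P[prev]
            best, best_turn = None, None
            for nxt in adj[cur]:
                if nxt == prev and len(adj[cur]) > 1:
                    continue
                if (cur, nxt) in used:
                    continue
                d_out = P[nxt] - P[cur]
                cross = d_in[0] * d_out[1] - d_in[1] * d_out[0]
                turn = abs(np.arctan2(cross, np.dot(d_in, d_out)))
                if best_turn is None or turn < best_turn:
                    best, best_turn = nxt, turn
            if best is None:
                return None
            used.add((cur, best))
            if best == start:
                return loop
            if best in loop:
                return None  # self-intersecting walk, reject
            loop.append(best)

    best_loop, best_area = None, 0.0
    seen_starts: set[tuple[int, int]] = set()
    for a, b in edges:
        for s, t in ((int(a), int(b)), (int(b), int(a))):
            if (s, t) in seen_starts:
                continue
            loop = walk(s, t)
            if loop is None or len(loop) < 3:
                continue
            closed = loop + [loop[0]]
            seen_starts.update(zip(closed[:-1], closed[1:]))
            v = P[np.array(loop)]
            area = abs(0.5 * np.sum(v[:, 0] * np.roll(v[:, 1], -1)
                                    - np.roll(v[:, 0], -1) * v[:, 1]))
            if area > best_area:
                best_loop, best_area = loop, area
    if best_loop is None:
        raise ValueError(
            "no closed loop in the boundary-edge graph; "
            f"edge dump: {edges.tolist()}"
        )
    verts = P[np.array(best_loop)]
    keep = np.ones(len(verts), dtype=bool)
    keep[1:] = np.any(verts[1:] != verts[:-1], axis=1)
    verts = verts[keep]
    # normalise to counter-clockwise
    area = 0.5 * np.sum(verts[:, 0] * np.roll(verts[:, 1], -1)
                        - np.roll(verts[:, 0], -1) * verts[:, 1])
    if area < 0:
        verts = verts[::-1]
    return Contour2D(vertices=verts, radius_used=np.nan, is_closed=True)


def rasterize_template(
    contour: Contour2D, mm_per_pixel: float, pad: int = 2
) -> tuple[np.ndarray, np.ndarray]:
    """Draw the contour as a 1-pixel-wide closed digital curve.

    Returns (template, origin): a binary uint8 image and the mm coordinates
    of pixel (0, 0)'s centre, so mm = origin + pixel * mm_per_pixel with
    pixel = (column, row).
    """
    from skimage.draw import line

    if mm_per_pixel <= 0:
        raise ValueError("mm_per_pixel must be > 0")
    v = contour.vertices
    if len(v) < 4 or abs(contour.area) <= 0:
        raise ValueError("degenerate (zero-area) contour")
    origin = v.min(axis=0) - pad * mm_per_pixel
    px = np.rint((v - origin) / mm_per_pixel).astype(int)
    w = int(px[:, 0].max()) + pad + 1
    h = int(px[:, 1].max()) + pad + 1
    img = np.zeros((h, w), dtype=np.uint8)
    for (c0, r0), (c1, r1) in zip(px[:-1], px[1:]):
        rr, cc = line(r0, c0, r1, c1)
        img[rr, cc] = 1
    return img, origin
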