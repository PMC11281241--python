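"""Per-point surface features and curvature-seeded region growing.

Normals come from local least-squares plane fits: for each point, the
covariance matrix S of its k-neighbourhood is diagonalised and the
eigenvector of the smallest eigenvalue is the normal.  The surface-variation
curvature rho = lambda1 / (lambda1 + lambda2 + lambda3) (eigenvalues sorted
ascending) is 0 on planes and reaches 1/3 for fully isotropic
neighbourhoods.

Region growing seeds at the globally lowest-curvature point and floods
through the k-NN graph.  A neighbour *joins* the region when the angle
between its normal and the current seed's normal (unoriented, via |n1.n2|)
is below the angle threshold; it additionally becomes a *seed* able to grow
further only when its curvature is below the curvature threshold.  Touching
pods meet in a high-curvature crease whose points may join a region but
never propagate it, which is what separates adherent objects.
"""

from __future__ import annotations

import warnings
from collections import deque
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .cloud import PointCloud

__all__ = [
    "NeighborGraph",
    "GrowthParams",
    "RegionSummary",
    "elevation_filter",
    "build_neighbor_graph",
    "estimate_normals_curvature",
    "region_growing",
]


@dataclass
class NeighborGraph:
    """k-nearest-neighbour lists, sorted by distance, ties by lower index."""

    k: int
    neighbor_indices: np.ndarray  # (N, min(k, N-1)) int

    def __len__(self) -> int:
        return len(self.neighbor_indices)


@dataclass(frozen=True)
class GrowthParams:
    """Region-growing thresholds.

    angle_thresh : max angle (degrees) between a candidate's normal and the
        current seed's normal for the candidate to join the region.
    curv_thresh : max curvature for a joined point to be promoted to seed.
    min_region : regions smaller than this are dissolved into the residual,
        and growing stops once fewer than this many points remain.
    """

    k: int = 30
    angle_thresh: float = 15.0
    curv_thresh: float = 0.08
    min_region: int = 100

    def __post_init__(self) -> None:
        if self.k < 3:
            raise ValueError("k must be >= 3")
        if not 0 < self.angle_thresh < 90:
            raise ValueError("angle_thresh must be in (0, 90) degrees")
        if not 0 <= self.curv_thresh <= 1 / 3:
            raise ValueError("curv_thresh must be in [0, 1/3]")
        if self.min_region < 1:
            raise ValueError("min_region must be >= 1")


@dataclass
class RegionSummary:
    region_id: int
    size: int
    centroid: np.ndarray


def elevation_filter(cloud: PointCloud, zmin: float, zmax: float) -> PointCloud:
    """Keep points with zmin <= Z <= zmax, order preserved.

    The scan background (table / guide platform) sits at a known height and
    is removed by this window before segmentation.
    """
    if not zmin < zmax:
        raise ValueError("zmin must be < zmax")
    mask = (cloud.points[:, 2] >= zmin) & (cloud.points[:, 2] <= zmax)
    if not mask.any():
        warnings.warn("elevation window removed every point")
    return cloud.select(mask)


def build_neighbor_graph(cloud: PointCloud, k: int) -> NeighborGraph:
    """k nearest neighbours per point via a KD-tree.

    Lists are sorted by increasing Euclidean distance; exact ties are broken
    by the lower point index; a point never lists itself.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    n = len(cloud)
    if n < 2:
        raise ValueError("need at least 2 points")
    kk = min(k, n - 1)
    tree = cKDTree(cloud.points)
    # over-query so equidistant ties beyond the k-th place are visible and
    # can be broken by index; self is dropped afterwards
    kq = min(n, kk + 3)
    dist, idx = tree.query(cloud.points, k=kq)
    dist, idx = np.atleast_2d(dist), np.atleast_2d(idx)
    out = np.empty((n, kk), dtype=int)
    for i in range(n):
        d_i, j_i = dist[i], idx[i]
        keep = j_i != i
        d_i, j_i = d_i[keep], j_i[keep]
        order = np.lexsort((j_i, d_i))  # distance, then lower index
        out[i] = j_i[order][:kk]
    return NeighborGraph(k=k, neighbor_indices=out)


def estimate_normals_curvature(
    cloud: PointCloud,
    graph: NeighborGraph,
    viewpoint: np.ndarray | None = None,
) -> PointCloud:
    """Fill normals and curvatures from neighbourhood covariance eigenanalysis.

    The neighbourhood of point i is {i} plus its graph neighbours.  Normals
    are flipped to point toward *viewpoint* (default: straight up, +Z at
    infinity, matching a camera mounted above the scene); sign is otherwise
    arbitrary from PCA.  Zero-spread neighbourhoods get curvature 0 and a +Z
    normal (flagged by a warning).
    """
    pts = cloud.points
    n = len(pts)
    nbr = graph.neighbor_indices
    if len(nbr) != n:
        raise ValueError("graph was built on a different cloud")
    if nbr.shape[1] + 1 < 3:
        raise ValueError("each neighbourhood needs at least 3 points")
    hood = np.concatenate([np.arange(n)[:, None], nbr], axis=1)  # (N, k+1)
    local = pts[hood]                     # (N, k+1, 3)
    centred = local - local.mean(axis=1, keepdims=True)
    cov = np.einsum("nki,nkj->nij", centred, centred)
    evals, evecs = np.linalg.eigh(cov)    # ascending eigenvalues
    evals = np.maximum(evals, 0.0)
    total = evals.sum(axis=1)
    degenerate = total <= 0
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} neighbourhoods have zero spread; "
            "assigning curvature 0 and +Z normals"
        )
    curv = np.where(degenerate, 0.0, evals[:, 0] / np.where(degenerate, 1.0, total))
    normals = evecs[:, :, 0].copy()
    normals[degenerate] = [0.0, 0.0, 1.0]
    if viewpoint is None:
        flip = normals[:, 2] < 0
    else:
        vp = np.asarray(viewpoint, dtype=float)
        flip = np.einsum("ij,ij->i", normals, vp - pts) < 0
    normals[flip] *= -1.0
    normals /= np.linalg.norm(normals, axis=1, keepdims=True)
    return PointCloud(
        points=pts,
        normals=normals,
        curvatures=np.clip(curv, 0.0, 1.0 / 3.0),
        labels=cloud.labels,
        frame_ids=cloud.frame_ids,
    )


def region_growing(
    cloud: PointCloud,
    graph: NeighborGraph,
    params: GrowthParams = GrowthParams(),
) -> tuple[PointCloud, list[RegionSummary]]:
    """Segment the cloud into regions of smoothly varying normals.

    Deterministic: seeds are taken in (curvature, index) order and growth is
    breadth-first (FIFO).  Returns the labelled cloud (label -1 = residual)
    and per-region summaries; region ids are dense from 0 in order of
    creation, with undersized regions dissolved back into the residual.
    """
    if cloud.normals is None or cloud.curvatures is None:
        raise ValueError("cloud needs normals and curvatures; "
                         "run estimate_normals_curvature first")
    n = len(cloud)
    normals = cloud.normals
    curv = cloud.curvatures
    nbr = graph.neighbor_indices
    cos_thresh = np.cos(np.radians(params.angle_thresh))

    labels = np.full(n, -1, dtype=int)
    unassigned = np.ones(n, dtype=bool)
    seed_order = np.lexsort((np.arange(n), curv))
    seed_ptr = 0
    regions: list[np.ndarray] = []

    while True:
        remaining = int(unassigned.sum())
        if remaining < params.min_region:
            break
        while seed_ptr < n and not unassigned[seed_order[seed_ptr]]:
            seed_ptr += 1
        if seed_ptr >= n:
            break
        seed0 = seed_order[seed_ptr]
        member = [seed0]
        unassigned[seed0] = False
        queue = deque([seed0])
        while queue:
            s = queue.popleft()
            ns = normals[s]
            cand = nbr[s]
            cand = cand[unassigned[cand]]
            if len(cand) == 0:
                continue
            ang_ok = np.abs(normals[cand] @ ns) >= cos_thresh
            joiners = cand[ang_ok]
            for j in joiners:
                unassigned[j] = False
                member.append(j)
                if curv[j] < params.curv_thresh:
                    queue.append(j)
        member_arr = np.array(member, dtype=int)
        if len(member_arr) >= params.min_region:
            regions.append(member_arr)
        # else: members keep label -1 (residual) and are not reseeded

    # dense ids in creation order
    for rid, member_arr in enumerate(regions):
        labels[member_arr] = rid
    # points grabbed by dissolved regions stay residual
    labelled = PointCloud(
        points=cloud.points,
        normals=normals,
        curvatures=curv,
        labels=labels,
        frame_ids=cloud.frame_ids,
    )
    summaries = [
        RegionSummary(region_id=rid, size=len(m), centroid=cloud.points[m].mean(axis=0))
        for rid, m in enumerate(regions)
    ]
    return labelled, summaries
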