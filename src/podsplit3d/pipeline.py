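"""End-to-end pipeline: synthetic (or captured) scene -> stripe scan ->
point cloud -> per-pod 3-D regions -> 2-D contour templates -> template
matching on the top-down image -> per-pod masks -> metrics.

This is the orchestration layer the CLI and the acceptance checks drive;
every step is an ordinary call into the corresponding module.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import contour as ct
from . import matching as mt
from . import segmentation as sg
from .cloud import PointCloud
from .evaluation import SegmentationScore, score_scene
from .reconstruction import CalibrationSet, assemble_cloud
from .synthetic import (
    PodSpec,
    SceneTruth,
    adherent_scene,
    default_calibration,
    render_topdown,
    simulate_scan,
)

__all__ = ["SceneResult", "run_scene", "segment_cloud", "match_templates"]


@dataclass
class SceneResult:
    cloud: PointCloud
    labeled: PointCloud
    regions: list
    templates: list[np.ndarray]
    models: list
    image: np.ndarray
    truth: SceneTruth
    poses: list
    masks: list[np.ndarray]
    score: SegmentationScore


def scan_calibration_for(pods: list[PodSpec], step_mm: float = 0.35,
                         margin: float = 3.0) -> tuple[CalibrationSet, int]:
    """Calibration whose sweep covers the scene, plus the frame count."""
    y_lo = min(p.position[1] - p.half_length - p._max_radius for p in pods) - margin
    y_hi = max(p.position[1] + p.half_length + p._max_radius for p in pods) + margin
    calib = default_calibration(scan_start_y=y_lo, speed=1.0,
                                frame_interval=step_mm)
    n_frames = int(np.ceil((y_hi - y_lo) / step_mm)) + 1
    return calib, n_frames


def segment_cloud(
    cloud: PointCloud,
    params: sg.GrowthParams = sg.GrowthParams(),
    z_window: tuple[float, float] | None = None,
) -> tuple[PointCloud, list[sg.RegionSummary]]:
    """Elevation pre-filter + features + region growing."""
    if z_window is not None:
        cloud = sg.elevation_filter(cloud, *z_window)
    graph = sg.build_neighbor_graph(cloud, params.k)
    cloud = sg.estimate_normals_curvature(cloud, graph)
    return sg.region_growing(cloud, graph, params)


def region_template(
    region_cloud: PointCloud,
    mm_per_pixel: float,
    max_points: int = 1800,
    radius: float | None = None,
    pad: int = 4,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, ct.Contour2D]:
    """Rolling-ball contour of one segmented pod, rasterised as a template.

    Returns (template image, mm origin of template pixel (0,0), contour).
    Large regions are subsampled before boundary extraction; the ball radius
    defaults to 3x the median nearest-neighbour spacing (at least 1.2 mm).
    """
    if len(region_cloud) > max_points:
        rng = np.random.default_rng(seed)
        keep = rng.choice(len(region_cloud), max_points, replace=False)
        region_cloud = region_cloud.select(np.sort(keep))
    pts2 = ct.project_to_plane(region_cloud)
    spacing = ct.default_ball_radius(pts2, factor=1.0)
    r = radius if radius is not None else max(3.0 * spacing, 1.2)
    _, edges = ct.rolling_ball_boundary(pts2, r)
    poly = ct.order_contour(edges, pts2)
    poly.radius_used = r
    # boundary points are interior samples of the silhouette: on average the
    # true edge lies ~half a sampling spacing further out, so offset the
    # polygon outward along its vertex normals
    poly = _offset_polygon(poly, 0.5 * spacing)
    template, origin = ct.rasterize_template(poly, mm_per_pixel, pad=pad)
    return template, origin, poly


def _offset_polygon(poly: ct.Contour2D, delta: float) -> ct.Contour2D:
    v = poly.vertices[:-1]  # drop duplicate closing vertex
    nxt = np.roll(v, -1, axis=0)
    prv = np.roll(v, 1, axis=0)
    tang = nxt - prv
    tang /= np.maximum(np.linalg.norm(tang, axis=1, keepdims=True), 1e-12)
    outward = np.column_stack([tang[:, 1], -tang[:, 0]])  # CCW polygon
    return ct.Contour2D(vertices=v + delta * outward,
                        radius_used=poly.radius_used, is_closed=True)


def match_templates(
    models: list[mt.ShapeModel],
    image: np.ndarray,
    min_score: float = 0.35,
    max_overlap: float = 0.5,
    refine: bool = True,
) -> list[mt.Pose | None]:
    """One pose per template: per-template pyramid search, then a global
    greedy assignment by descending score that keeps accepted matches from
    claiming the same image area."""
    from podsplit3d.matching import _direction_field, _score_at

    ux, uy = _direction_field(np.asarray(image, dtype=float))
    edges = mt.detect_edges(image) if refine else None

    def fine_score(ti: int, pose: mt.Pose) -> float:
        lvl = models[ti].levels[0]
        return _score_at(ux, uy, pose.apply(lvl.points),
                         lvl.normals @ pose.matrix()[:, :2].T / pose.scale)

    candidates: list[tuple[int, mt.Pose, float]] = []
    for ti, model in enumerate(models):
        for pose in mt.find_matches(model, image, min_score=min_score,
                                    max_matches=4, max_overlap=0.9):
            if refine and edges is not None:
                pose = mt.refine_pose(model, edges, pose)
            candidates.append((ti, pose, fine_score(ti, pose)))

    chosen: list[mt.Pose | None] = [None] * len(models)
    boxes: list[tuple[float, float, float, float]] = []

    def bbox(ti, pose):
        pts = pose.apply(models[ti].levels[0].points)
        return (pts[:, 0].min(), pts[:, 1].min(),
                pts[:, 0].max(), pts[:, 1].max())

    for ti, pose, s in sorted(candidates, key=lambda c: -c[2]):
        if chosen[ti] is not None:
            continue
        box = bbox(ti, pose)
        if any(mt._box_overlap(box, b) > max_overlap for b in boxes):
            continue
        chosen[ti] = pose
        boxes.append(box)
    # last resort: give unassigned templates their best remaining candidate
    for ti, model in enumerate(models):
        if chosen[ti] is None:
            own = [(s, p) for t, p, s in candidates if t == ti]
            if own:
                chosen[ti] = max(own, key=lambda c: c[0])[1]
    return chosen


def run_scene(
    pods: list[PodSpec] | list[str],
    seed: int = 0,
    mm_per_pixel: float = 0.25,
    growth: sg.GrowthParams = sg.GrowthParams(),
    noise_px: float = 0.0,
    open_radius: int = 2,
    step_mm: float = 0.35,
) -> SceneResult:
    """Run the whole pipeline on one synthetic scene and score it.

    *pods* is either a list of PodSpec or a list of morphology names, in
    which case an adherent chain is generated from the seed.
    """
    if pods and isinstance(pods[0], str):
        pods = adherent_scene(list(pods), seed=seed)
    calib, n_frames = scan_calibration_for(pods, step_mm=step_mm)
    frames, truth3d = simulate_scan(pods, 0.0, calib, n_frames,
                                    noise_px=noise_px, seed=seed)
    threshold = 1e-9 if noise_px == 0 else 10.0
    cloud = assemble_cloud(frames, calib, intensity_threshold=threshold)
    zmax = max(2 * p.rest_height for p in pods) + 2.0
    labeled, regions = segment_cloud(cloud, growth, z_window=(1.0, zmax))

    image, truth = render_topdown(pods, mm_per_pixel=mm_per_pixel, seed=seed)

    templates, models, order = [], [], []
    for reg in regions:
        sub = labeled.select(labeled.labels == reg.region_id)
        try:
            template, origin, _ = region_template(sub, mm_per_pixel, seed=seed)
            model = mt.build_shape_model(
                template,
                pyramid_levels=4,
                angle_range=(-180.0, 180.0),
                angle_step=1.0,
                scale_range=(0.92, 1.08),
                scale_step=0.04,
            )
        except ValueError as exc:
            warnings.warn(f"region {reg.region_id}: template failed ({exc})")
            continue
        templates.append(template)
        models.append(model)
        order.append(reg.region_id)

    poses = match_templates(models, image)
    masks = []
    for model, pose in zip(models, poses):
        if pose is None:
            masks.append(np.zeros(image.shape, dtype=bool))
            continue
        mask, _ = mt.extract_region(image, model, pose)
        masks.append(mt.open_mask(mask, open_radius))
    score = score_scene(masks, truth.masks)
    return SceneResult(
        cloud=cloud, labeled=labeled, regions=regions,
        templates=templates, models=models,
        image=image, truth=truth, poses=poses, masks=masks, score=score,
    )
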