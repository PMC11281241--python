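"""Line-structured-light triangulation: stripe frames -> world point cloud.

A laser sheet (the *light plane*, a·Xc + b·Yc + c·Zc + d = 0 in the camera
frame) intersects the scanned surface; the camera sees the intersection as a
bright stripe.  Each stripe pixel (u, v) fixes a viewing ray through the
pinhole model

    Zc * (u, v, 1)^T = K * (Xc, Yc, Zc)^T,   K = [[fx, 0, u0], [0, fy, v0], [0, 0, 1]],

and intersecting that ray with the light plane yields the 3-D point in
closed form.  Camera points are mapped to the world frame by the inverse
rigid transform world = R^T (camera - T), and successive frames are spliced
by the guide displacement d = v * t along the scan axis.
"""

from __future__ import annotations

import csv
import re
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .cloud import PointCloud

__all__ = [
    "CameraIntrinsics",
    "LightPlane",
    "Extrinsics",
    "CalibrationSet",
    "StripeFrame",
    "extract_stripe_centerline",
    "backproject_to_plane",
    "project_to_pixel",
    "camera_to_world",
    "assemble_cloud",
    "load_calibration",
    "save_calibration",
    "load_frames",
]

_AXES = {"x": np.array([1.0, 0.0, 0.0]), "y": np.array([0.0, 1.0, 0.0]),
         "z": np.array([0.0, 0.0, 1.0])}


@dataclass(frozen=True)
class CameraIntrinsics:
    """Pinhole intrinsics: focal lengths over pixel pitch and principal point, in pixels."""

    fx: float
    fy: float
    u0: float
    v0: float

    def __post_init__(self) -> None:
        if not (self.fx > 0 and self.fy > 0):
            raise ValueError("fx and fy must be positive")
        if not (np.isfinite(self.u0) and np.isfinite(self.v0)):
            raise ValueError("principal point must be finite")

    @property
    def matrix(self) -> np.ndarray:
        return np.array([[self.fx, 0.0, self.u0],
                         [0.0, self.fy, self.v0],
                         [0.0, 0.0, 1.0]])


@dataclass(frozen=True)
class LightPlane:
    """Laser-sheet plane a·Xc + b·Yc + c·Zc + d = 0 in the camera frame."""

    a: float
    b: float
    c: float
    d: float

    def __post_init__(self) -> None:
        if self.a == 0.0 and self.b == 0.0 and self.c == 0.0:
            raise ValueError("plane normal (a, b, c) must not be zero")

    @property
    def normal(self) -> np.ndarray:
        return np.array([self.a, self.b, self.c])


@dataclass(frozen=True)
class Extrinsics:
    """Rigid camera pose: camera = R @ world + T."""

    R: np.ndarray
    T: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "R", np.asarray(self.R, dtype=float).reshape(3, 3))
        object.__setattr__(self, "T", np.asarray(self.T, dtype=float).reshape(3))
        err = np.abs(self.R.T @ self.R - np.eye(3)).max()
        det = np.linalg.det(self.R)
        # calibration outputs are often orthonormal only to ~1e-3; warn, don't fail
        if err > 1e-6 or abs(det - 1.0) > 1e-6:
            warnings.warn(
                f"rotation matrix is not orthonormal (max |R^T R - I| = {err:.2e}, "
                f"det = {det:.6f}); using it as supplied"
            )


@dataclass(frozen=True)
class CalibrationSet:
    """Everything triangulation and splicing need."""

    intrinsics: CameraIntrinsics
    plane: LightPlane
    extrinsics: Extrinsics
    speed: float = 0.0          # guide velocity, mm/s
    frame_interval: float = 1.0  # time between frames, s
    guide_axis: str = "y"        # world axis the guide moves along

    def __post_init__(self) -> None:
        if self.speed < 0:
            raise ValueError("speed must be >= 0")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")
        if self.guide_axis not in _AXES:
            raise ValueError("guide_axis must be one of 'x', 'y', 'z'")

    @property
    def guide_direction(self) -> np.ndarray:
        return _AXES[self.guide_axis]


@dataclass
class StripeFrame:
    """One captured stripe image with its acquisition time."""

    image: np.ndarray
    timestamp: float
    index: int = 0

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image, dtype=float)
        if self.image.ndim != 2:
            raise ValueError("stripe frame image must be single-channel 2-D")
        if self.timestamp < 0:
            raise ValueError("timestamp must be >= 0")


def extract_stripe_centerline(
    frame: StripeFrame, intensity_threshold: float = 30.0
) -> np.ndarray:
    """Sub-pixel stripe centre per image column by intensity-weighted centroid.

    For every column, pixels with intensity strictly above the threshold
    contribute to a grey-gravity centroid of their row coordinates; columns
    with no pixel above threshold yield no point.

    Returns
    -------
    (M, 2) array of (u, v) pixel coordinates, u = column, v = sub-pixel row,
    0-based, pixel centres at integer coordinates.
    """
    img = frame.image
    if img.size == 0:
        raise ValueError("empty stripe image")
    if intensity_threshold < 0:
        raise ValueError("threshold must be >= 0")
    mask = img > intensity_threshold
    weights = np.where(mask, img, 0.0)
    col_sum = weights.sum(axis=0)
    has = col_sum > 0
    if not np.any(has):
        return np.empty((0, 2))
    rows = np.arange(img.shape[0], dtype=float)
    centroid = (weights * rows[:, None]).sum(axis=0)[has] / col_sum[has]
    cols = np.nonzero(has)[0].astype(float)
    return np.column_stack([cols, centroid])


def backproject_to_plane(
    pixel, intrinsics: CameraIntrinsics, plane: LightPlane
) -> np.ndarray:
    """Intersect the viewing ray(s) of pixel (u, v) with the light plane.

    Accepts a single (u, v) pair or an (M, 2) array.  Closed form: the ray is
    (Xc, Yc, Zc) = Zc * ((u-u0)/fx, (v-v0)/fy, 1), and substituting into the
    plane equation gives Zc = -d / (a(u-u0)/fx + b(v-v0)/fy + c).
    """
    px = np.asarray(pixel, dtype=float)
    single = px.ndim == 1
    px = np.atleast_2d(px)
    ray = np.column_stack([
        (px[:, 0] - intrinsics.u0) / intrinsics.fx,
        (px[:, 1] - intrinsics.v0) / intrinsics.fy,
        np.ones(len(px)),
    ])
    denom = ray @ plane.normal
    if np.any(np.abs(denom) < 1e-12):
        raise ValueError("viewing ray is parallel to the light plane")
    zc = -plane.d / denom
    pts = ray * zc[:, None]
    return pts[0] if single else pts


def project_to_pixel(point, intrinsics: CameraIntrinsics) -> np.ndarray:
    """Forward pinhole projection of camera-frame point(s) to (u, v)."""
    p = np.atleast_2d(np.asarray(point, dtype=float))
    uv = np.column_stack([
        intrinsics.fx * p[:, 0] / p[:, 2] + intrinsics.u0,
        intrinsics.fy * p[:, 1] / p[:, 2] + intrinsics.v0,
    ])
    return uv[0] if np.asarray(point).ndim == 1 else uv


def camera_to_world(point, extrinsics: Extrinsics) -> np.ndarray:
    """Map camera-frame point(s) to the world frame: world = R^T (camera - T).

    The closed-form inverse of the homogeneous transform [R T; 0 1].
    """
    p = np.asarray(point, dtype=float)
    single = p.ndim == 1
    p = np.atleast_2d(p)
    w = (p - extrinsics.T) @ extrinsics.R
    return w[0] if single else w


def world_to_camera(point, extrinsics: Extrinsics) -> np.ndarray:
    """Forward rigid map camera = R @ world + T."""
    p = np.asarray(point, dtype=float)
    single = p.ndim == 1
    w = np.atleast_2d(p) @ extrinsics.R.T + extrinsics.T
    return w[0] if single else w


def assemble_cloud(
    frames: list[StripeFrame],
    calib: CalibrationSet,
    intensity_threshold: float = 30.0,
) -> PointCloud:
    """Reconstruct and splice a stack of stripe frames into a world cloud.

    Each frame's centreline is back-projected onto the light plane, moved to
    the world frame, then shifted by the guide displacement d = v * t along
    the guide axis to undo the object's motion between frames.
    """
    if not frames:
        raise ValueError("need at least one frame")
    times = [f.timestamp for f in frames]
    if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
        raise ValueError("frame timestamps must be strictly increasing")
    pts_all: list[np.ndarray] = []
    ids_all: list[np.ndarray] = []
    axis = calib.guide_direction
    for frame in frames:
        uv = extract_stripe_centerline(frame, intensity_threshold)
        if len(uv) == 0:
            continue
        cam = backproject_to_plane(uv, calib.intrinsics, calib.plane)
        world = camera_to_world(cam, calib.extrinsics)
        world = world + calib.speed * frame.timestamp * axis
        pts_all.append(world)
        ids_all.append(np.full(len(world), frame.index, dtype=int))
    if not pts_all:
        warnings.warn("no stripe centreline found in any frame: empty cloud")
        return PointCloud(points=np.empty((0, 3)),
                          frame_ids=np.empty(0, dtype=int))
    return PointCloud(points=np.vstack(pts_all), frame_ids=np.concatenate(ids_all))


# ---------------------------------------------------------------------------
# calibration and frame-stack file I/O
# ---------------------------------------------------------------------------

def load_calibration(path: str | Path) -> CalibrationSet:
    """Read a YAML/JSON calibration file.

    Expected keys: intrinsics{fx,fy,u0,v0}, plane{a,b,c,d},
    extrinsics{R (row-major 9), T (3)}, speed, frame_interval,
    optional guide_axis.
    """
    import yaml

    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return CalibrationSet(
        intrinsics=CameraIntrinsics(**doc["intrinsics"]),
        plane=LightPlane(**doc["plane"]),
        extrinsics=Extrinsics(
            R=np.asarray(doc["extrinsics"]["R"], dtype=float).reshape(3, 3),
            T=np.asarray(doc["extrinsics"]["T"], dtype=float),
        ),
        speed=float(doc.get("speed", 0.0)),
        frame_interval=float(doc.get("frame_interval", 1.0)),
        guide_axis=str(doc.get("guide_axis", "y")),
    )


def save_calibration(path: str | Path, calib: CalibrationSet) -> None:
    import yaml

    doc = {
        "intrinsics": {k: float(getattr(calib.intrinsics, k))
                       for k in ("fx", "fy", "u0", "v0")},
        "plane": {k: float(getattr(calib.plane, k))
                  for k in ("a", "b", "c", "d")},
        "extrinsics": {"R": [float(x) for x in calib.extrinsics.R.ravel()],
                       "T": [float(x) for x in calib.extrinsics.T]},
        "speed": float(calib.speed),
        "frame_interval": float(calib.frame_interval),
        "guide_axis": calib.guide_axis,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh)


def load_frames(
    directory: str | Path, frame_interval: float = 1.0
) -> list[StripeFrame]:
    """Load a frame_%05d.png/.tif stack; timestamps from a sidecar
    timestamps.csv (index,timestamp) when present, else index * frame_interval."""
    import imageio.v3 as iio

    directory = Path(directory)
    files = sorted(
        p for p in directory.iterdir()
        if re.fullmatch(r"frame_\d+\.(png|tif|tiff)", p.name, re.IGNORECASE)
    )
    if not files:
        raise FileNotFoundError(f"no frame_* images in {directory}")
    stamps: dict[int, float] = {}
    sidecar = directory / "timestamps.csv"
    if sidecar.exists():
        with open(sidecar) as fh:
            for row in csv.reader(fh):
                if row and not row[0].strip().lstrip("-").startswith("index"):
                    stamps[int(row[0])] = float(row[1])
    frames = []
    for i, f in enumerate(files):
        img = np.asarray(iio.imread(f), dtype=float)
        if img.ndim == 3:
            img = img.mean(axis=2)
        frames.append(StripeFrame(image=img,
                                  timestamp=stamps.get(i, i * frame_interval),
                                  index=i))
    return frames
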