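"""Point-cloud container and PLY / CSV-XYZ I/O.

The cloud lives in world coordinates (millimetres).  Optional per-point
channels carry the quantities the pipeline computes along the way: unit
normals, surface-variation curvature (rho = lambda1 / (lambda1 + lambda2 +
lambda3), hence in [0, 1/3]), region labels (-1 = unassigned residual) and
the index of the stripe frame each point came from.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["PointCloud", "read_cloud", "write_cloud"]

_CURV_MAX = 1.0 / 3.0


@dataclass
class PointCloud:
    """N 3-D points with optional per-point attributes.

    Parameters
    ----------
    points : (N, 3) float array, millimetres, world frame.
    normals : (N, 3) float array or None; unit vectors.
    curvatures : (N,) float array or None; values in [0, 1/3].
    labels : (N,) int array or None; region ids, -1 for unassigned.
    frame_ids : (N,) int array or None; originating stripe-frame index.
    """

    points: np.ndarray
    normals: np.ndarray | None = None
    curvatures: np.ndarray | None = None
    labels: np.ndarray | None = None
    frame_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        n = len(self.points)
        if self.normals is not None:
            self.normals = np.asarray(self.normals, dtype=float).reshape(n, 3)
            norms = np.linalg.norm(self.normals, axis=1)
            bad = np.abs(norms - 1.0) > 1e-8
            if np.any(bad & (norms > 0)):
                raise ValueError(
                    f"{int(np.sum(bad))} normals are not unit length (tol 1e-8)"
                )
        if self.curvatures is not None:
            self.curvatures = np.asarray(self.curvatures, dtype=float).reshape(n)
            if np.any(self.curvatures < -1e-12) or np.any(
                self.curvatures > _CURV_MAX + 1e-12
            ):
                raise ValueError("curvatures must lie in [0, 1/3]")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int).reshape(n)
            if np.any(self.labels < -1):
                raise ValueError("labels must be >= -1")
        if self.frame_ids is not None:
            self.frame_ids = np.asarray(self.frame_ids, dtype=int).reshape(n)

    def __len__(self) -> int:
        return len(self.points)

    def select(self, mask_or_indices) -> "PointCloud":
        """Sub-cloud keeping every optional channel, order preserved."""
        idx = np.asarray(mask_or_indices)
        return PointCloud(
            points=self.points[idx],
            normals=None if self.normals is None else self.normals[idx],
            curvatures=None if self.curvatures is None else self.curvatures[idx],
            labels=None if self.labels is None else self.labels[idx],
            frame_ids=None if self.frame_ids is None else self.frame_ids[idx],
        )


# ---------------------------------------------------------------------------
# ASCII PLY with optional float properties nx,ny,nz,curvature and int label.
# Written by hand: the point-cloud PLY writers available in this stack do not
# round-trip custom per-vertex properties.
# ---------------------------------------------------------------------------

def write_cloud(path: str | Path, cloud: PointCloud) -> None:
    """Write *cloud* as ASCII PLY (or CSV-XYZ when the suffix is .csv/.xyz)."""
    path = Path(path)
    if path.suffix.lower() in (".csv", ".xyz"):
        np.savetxt(path, cloud.points, delimiter=",", fmt="%.9g")
        return
    props = ["property float x", "property float y", "property float z"]
    cols: list[np.ndarray] = [cloud.points]
    if cloud.normals is not None:
        props += ["property float nx", "property float ny", "property float nz"]
        cols.append(cloud.normals)
    if cloud.curvatures is not None:
        props.append("property float curvature")
        cols.append(cloud.curvatures[:, None])
    fmt = ["%.9g"] * sum(c.shape[1] for c in cols)
    if cloud.labels is not None:
        props.append("property int label")
        cols.append(cloud.labels[:, None].astype(float))
        fmt.append("%d")
    if cloud.frame_ids is not None:
        props.append("property int frame")
        cols.append(cloud.frame_ids[:, None].astype(float))
        fmt.append("%d")
    header = (
        "ply\nformat ascii 1.0\n"
        f"element vertex {len(cloud)}\n" + "\n".join(props) + "\nend_header\n"
    )
    data = np.hstack(cols)
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, data, fmt=" ".join(fmt))


def read_cloud(path: str | Path) -> PointCloud:
    """Read a cloud from ASCII PLY or CSV-XYZ."""
    path = Path(path)
    if path.suffix.lower() in (".csv", ".xyz"):
        pts = np.loadtxt(path, delimiter=",", ndmin=2)
        return PointCloud(points=pts[:, :3])
    with open(path) as fh:
        first = fh.readline().strip()
        if first != "ply":
            raise ValueError(f"{path}: not a PLY file")
        n_vertex = 0
        in_vertex = False
        names: list[str] = []
        for line in fh:
            tok = line.split()
            if not tok:
                continue
            if tok[0] == "format" and tok[1] != "ascii":
                raise ValueError("only ASCII PLY is supported")
            if tok[0] == "element":
                in_vertex = tok[1] == "vertex"
                if in_vertex:
                    n_vertex = int(tok[2])
                elif int(tok[2]) > 0:
                    warnings.warn(f"ignoring PLY element {tok[1]}")
            elif tok[0] == "property" and in_vertex:
                names.append(tok[-1])
            elif tok[0] == "end_header":
                break
        rows = np.loadtxt(fh, max_rows=n_vertex, ndmin=2)
    col = {name: rows[:, i] for i, name in enumerate(names)}
    pts = np.column_stack([col["x"], col["y"], col["z"]])
    normals = None
    if "nx" in col:
        normals = np.column_stack([col["nx"], col["ny"], col["nz"]])
        # float storage in the file erodes unit norm below container tolerance
        norms = np.linalg.norm(normals, axis=1)
        normals = np.where(norms[:, None] > 0, normals / np.maximum(norms, 1e-300)[:, None], normals)
    return PointCloud(
        points=pts,
        normals=normals,
        curvatures=np.clip(col["curvature"], 0.0, _CURV_MAX) if "curvature" in col else None,
        labels=col["label"].astype(int) if "label" in col else None,
        frame_ids=col["frame"].astype(int) if "frame" in col else None,
    )
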