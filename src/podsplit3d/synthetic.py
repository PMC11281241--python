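"""Ground-truthed synthetic scenes: parametric pods, simulated stripe scans
and rendered top-down images.

Pods are modelled as height fields over a table plane.  A pod is a
surface of revolution of a two-lobed profile — two circles of radii r1, r2
whose centres sit `separation` apart along the pod axis, joined by a smooth
maximum — pinched at the middle by a Gaussian so that the mid-section girth
is exactly `waist` times the lobe girth.  A small sinusoidal bump texture
modulates the radial profile.  The five classic pod morphologies (common,
axe-shaped, cocoon, wasp-waist, lollipop) are presets of these parameters.

The scan simulator reproduces the physics the reconstruction module
inverts: at frame time t the laser sheet (given in the camera frame by the
calibration) cuts the scene displaced by d = v*t along the guide axis; the
intersection curve is projected through the pinhole model and rendered as a
Gaussian-profile stripe, one sub-pixel centre per image column, keeping the
surface point nearest the camera where the curve folds (occlusion).  With
zero noise the stripe centre is exact to machine precision, so
reconstruction errors measure the pipeline, not the simulator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cloud import PointCloud
from .reconstruction import (
    CalibrationSet,
    CameraIntrinsics,
    Extrinsics,
    LightPlane,
    StripeFrame,
    project_to_pixel,
)

__all__ = [
    "MORPHOLOGIES",
    "PodSpec",
    "SceneTruth",
    "pod_spec",
    "make_pod_surface",
    "simulate_scan",
    "render_topdown",
    "default_calibration",
    "adherent_scene",
    "adherent_pod_cloud",
]

MORPHOLOGIES = ("common", "axe", "cocoon", "wasp_waist", "lollipop")

# canonical (r1, r2, separation, waist) per morphology, millimetres
_MORPH_DEFAULTS = {
    "common": (7.0, 7.0, 9.0, 0.85),
    "axe": (8.5, 6.0, 9.0, 0.80),
    "cocoon": (6.5, 6.5, 4.0, 0.95),
    "wasp_waist": (7.0, 7.0, 11.0, 0.50),
    "lollipop": (7.5, 5.0, 11.5, 0.65),
}

_SMOOTH_EPS = 0.5  # mm, smooth-max blending of the two lobes


@dataclass
class PodSpec:
    """Parametric pod: two pinched lobes of revolution resting on the table."""

    morphology: str
    r1: float
    r2: float
    separation: float
    waist: float = 0.85
    bump_amp: float = 0.08   # mm, radial texture amplitude
    bump_freq: float = 1.2   # rad/mm along the axis
    bump_azim: int = 6       # azimuthal bump lobes
    position: tuple[float, float] = (0.0, 0.0)  # table-plane centre, mm
    yaw: float = 0.0         # radians, axis direction in the table plane

    def __post_init__(self) -> None:
        if self.morphology not in MORPHOLOGIES:
            raise ValueError(f"unknown morphology {self.morphology!r}; "
                             f"choose from {MORPHOLOGIES}")
        if self.r1 <= 0 or self.r2 <= 0:
            raise ValueError("lobe radii must be positive")
        if not 0 < self.waist <= 1:
            raise ValueError("waist factor must be in (0, 1]")
        if self.separation < 0 or self.separation >= self.r1 + self.r2:
            raise ValueError("lobes must overlap: 0 <= separation < r1 + r2")
        if self.bump_amp >= min(self.r1, self.r2) / 4:
            raise ValueError("bump amplitude must be < min(r1, r2) / 4")
        self._calibrate_pinch()

    # -- profile -----------------------------------------------------------
    def _lobes(self, xi: np.ndarray) -> np.ndarray:
        c1, c2 = -self.separation / 2.0, self.separation / 2.0
        p1 = np.sqrt(np.maximum(0.0, self.r1 ** 2 - (xi - c1) ** 2))
        p2 = np.sqrt(np.maximum(0.0, self.r2 ** 2 - (xi - c2) ** 2))
        # smooth maximum, C1; the eps/2 baseline is subtracted so the profile
        # is exactly 0 outside both lobes (and exact where the lobes agree)
        return 0.5 * (p1 + p2 + np.sqrt((p1 - p2) ** 2 + _SMOOTH_EPS ** 2)
                      - _SMOOTH_EPS)

    def _calibrate_pinch(self) -> None:
        """Build the smoothed profile grid and choose the pinch depth so the
        mid girth is exactly waist * max girth.

        The raw lobe union has a V-shaped kink where the circles cross;
        real pod necks are smooth, so the profile is low-pass filtered along
        the axis (Gaussian, sigma 0.8 mm) before pinching.
        """
        self._sigma_w = max(0.30 * self.separation, 0.75)
        lo, hi = self.axis_span
        xi = np.linspace(lo, hi, 2001)
        base = self._lobes(xi)
        dxi = xi[1] - xi[0]
        sig = 0.8 / dxi
        from scipy.ndimage import gaussian_filter1d

        base = gaussian_filter1d(base, sig, mode="constant")
        base[base < 1e-6] = 0.0
        amp = 1.0 - self.waist
        for _ in range(40):
            w = 1.0 - amp * np.exp(-(xi ** 2) / (2 * self._sigma_w ** 2))
            prof = base * w
            target_mid = self.waist * prof.max()
            mid = base[np.argmin(np.abs(xi))]
            if mid <= 0:
                break
            new_amp = 1.0 - target_mid / mid
            if abs(new_amp - amp) < 1e-12:
                break
            amp = new_amp
        self._pinch_amp = amp
        self._xi_grid = xi
        self._base_grid = base
        self._max_radius = float((base * (1.0 - amp *
                                  np.exp(-(xi ** 2) / (2 * self._sigma_w ** 2)))).max())

    @property
    def axis_span(self) -> tuple[float, float]:
        return (-self.separation / 2.0 - self.r1,
                self.separation / 2.0 + self.r2)

    @property
    def rest_height(self) -> float:
        """Axis height above the table: the pod rests on its widest girth."""
        return self._max_radius

    @property
    def half_length(self) -> float:
        return max(-self.axis_span[0], self.axis_span[1])

    def profile(self, xi: np.ndarray) -> np.ndarray:
        """Unbumped radial profile rho(xi) along the axis (smoothed grid)."""
        xi = np.asarray(xi, dtype=float)
        w = 1.0 - self._pinch_amp * np.exp(-(xi ** 2) / (2 * self._sigma_w ** 2))
        base = np.interp(xi, self._xi_grid, self._base_grid, left=0.0, right=0.0)
        return base * w

    # -- height field ------------------------------------------------------
    def local_coords(self, x, y):
        c, s = np.cos(self.yaw), np.sin(self.yaw)
        dx = np.asarray(x, dtype=float) - self.position[0]
        dy = np.asarray(y, dtype=float) - self.position[1]
        return c * dx + s * dy, -s * dx + c * dy

    def height(self, x, y, table_z: float = 0.0) -> np.ndarray:
        """Upper-surface height at table coordinates (x, y); NaN off the pod.

        The bump texture modulates the radial profile using a one-step
        azimuth estimate so the surface stays an explicit height field.
        """
        xi, eta = self.local_coords(x, y)
        rho = self.profile(xi)
        with np.errstate(invalid="ignore", divide="ignore"):
            phi = np.arcsin(np.clip(np.where(rho > 0, eta / np.maximum(rho, 1e-12), 2.0),
                                    -1.0, 1.0))
            r_eff = rho * (1.0 + (self.bump_amp / max(self._max_radius, 1e-9))
                           * np.sin(self.bump_freq * xi)
                           * np.cos(self.bump_azim * phi))
            h2 = r_eff ** 2 - eta ** 2
        h = np.where((rho > 0) & (np.abs(eta) <= r_eff) & (h2 >= 0),
                     table_z + self.rest_height + np.sqrt(np.maximum(h2, 0.0)),
                     np.nan)
        return h


def pod_spec(morphology: str, position=(0.0, 0.0), yaw: float = 0.0,
             size: float = 1.0, bump_amp: float | None = None) -> PodSpec:
    """Canonical PodSpec for a morphology, optionally scaled by *size*."""
    r1, r2, sep, waist = _MORPH_DEFAULTS[morphology]
    return PodSpec(
        morphology=morphology,
        r1=r1 * size, r2=r2 * size, separation=sep * size, waist=waist,
        bump_amp=0.08 * size if bump_amp is None else bump_amp,
        position=tuple(position), yaw=yaw,
    )


@dataclass
class SceneTruth:
    """Ground truth for one synthetic scene."""

    pods: list[PodSpec]
    table_z: float = 0.0
    masks: list[np.ndarray] | None = None          # per-pod boolean images
    image_origin: np.ndarray | None = None         # mm of pixel (0, 0) centre
    mm_per_pixel: float | None = None

    @property
    def poses(self) -> list[tuple[float, float, float]]:
        """(x, y, yaw) per pod."""
        return [(p.position[0], p.position[1], p.yaw) for p in self.pods]

    def scene_height(self, x, y) -> np.ndarray:
        h = np.full(np.broadcast(np.asarray(x), np.asarray(y)).shape,
                    self.table_z, dtype=float)
        for pod in self.pods:
            hp = pod.height(x, y, self.table_z)
            h = np.fmax(h, np.where(np.isnan(hp), -np.inf, hp))
        return h

    def label_points(self, points: np.ndarray, tol: float = 1.0) -> np.ndarray:
        """Assign each 3-D point to a pod id, or -1 for the table/unknown.

        A point belongs to the pod whose upper surface is vertically nearest,
        provided the gap is below *tol* mm or the point lies between the
        pod's upper and mirrored lower surface (flank points).
        """
        pts = np.asarray(points, dtype=float)
        n = len(pts)
        best = np.full(n, np.inf)
        lab = np.full(n, -1, dtype=int)
        for i, pod in enumerate(self.pods):
            h = pod.height(pts[:, 0], pts[:, 1], self.table_z)
            in_sil = ~np.isnan(h)
            hv = np.nan_to_num(h, nan=-np.inf)
            # the pod occupies the column under its height field (silhouette
            # walls included); points above the surface by > tol are rejected,
            # points below prefer the pod whose surface is nearest above
            cand = in_sil & (pts[:, 2] <= hv + tol) & \
                (pts[:, 2] >= self.table_z - tol)
            score = np.where(pts[:, 2] > hv, (pts[:, 2] - hv) * 1e6,
                             hv - pts[:, 2])
            score = np.where(cand, score, np.inf)
            better = score < best
            lab[better] = i
            best[better] = score[better]
        return lab


def make_pod_surface(
    spec: PodSpec, samples: int = 2000, seed: int = 0
) -> tuple[np.ndarray, "callable"]:
    """Sample the pod's visible (upper) surface.

    Points are drawn by rejection sampling of (x, y) in the pod's bounding
    box and lifted to z = height(x, y), so every point lies exactly on the
    analytic surface function that is returned alongside.
    """
    if samples < 500:
        raise ValueError("samples must be >= 500")
    rng = np.random.default_rng(seed)
    hl = spec.half_length + spec.bump_amp
    hw = spec._max_radius + spec.bump_amp

    def surface(x, y):
        return spec.height(x, y)

    pts = []
    need = samples
    c, s = np.cos(spec.yaw), np.sin(spec.yaw)
    while need > 0:
        draw = max(2 * need, 1000)
        xi = rng.uniform(-hl, hl, draw)
        eta = rng.uniform(-hw, hw, draw)
        x = spec.position[0] + c * xi - s * eta
        y = spec.position[1] + s * xi + c * eta
        z = spec.height(x, y)
        ok = ~np.isnan(z)
        pts.append(np.column_stack([x[ok], y[ok], z[ok]]))
        need -= int(ok.sum())
    out = np.vstack(pts)[:samples]
    return out, surface


# ---------------------------------------------------------------------------
# scan simulation
# ---------------------------------------------------------------------------

def default_calibration(
    camera_height: float = 300.0,
    focal_px: float = 900.0,
    image_shape: tuple[int, int] = (700, 800),
    tilt_deg: float = 25.0,
    scan_start_y: float = -40.0,
    speed: float = 1.0,
    frame_interval: float = 0.35,
) -> CalibrationSet:
    """Synthetic rig: camera *camera_height* mm above the table looking
    straight down, laser sheet tilted *tilt_deg* about the world X axis and
    crossing the table at y = *scan_start_y* when t = 0, guide along +Y."""
    h, w = image_shape
    R = np.diag([1.0, -1.0, -1.0])
    T = np.array([0.0, 0.0, camera_height])
    alpha = np.radians(tilt_deg)
    # world plane cos(a)(y - y0) + sin(a) z = 0 expressed in the camera frame
    a, b, c = 0.0, -np.cos(alpha), -np.sin(alpha)
    d = -np.cos(alpha) * scan_start_y + np.sin(alpha) * camera_height
    return CalibrationSet(
        intrinsics=CameraIntrinsics(fx=focal_px, fy=focal_px,
                                    u0=w / 2.0, v0=h / 2.0),
        plane=LightPlane(a=a, b=b, c=c, d=d),
        extrinsics=Extrinsics(R=R, T=T),
        speed=speed,
        frame_interval=frame_interval,
        guide_axis="y",
    )


def simulate_scan(
    pods: list[PodSpec],
    table_z: float,
    calib: CalibrationSet,
    n_frames: int,
    noise_px: float = 0.0,
    seed: int = 0,
    image_shape: tuple[int, int] = (700, 800),
    stripe_sigma: float = 1.5,
    stripe_peak: float = 200.0,
    samples_per_frame: int = 500,
) -> tuple[list[StripeFrame], SceneTruth]:
    """Render the stripe-frame stack a line-laser scan of the scene produces.

    Per frame, the laser sheet's intersection with the scene height field is
    found by bracketing + bisection along the sheet, projected through the
    pinhole model, interpolated to one sub-pixel stripe centre per integer
    image column (keeping the branch nearest the camera where the curve
    folds), and rendered as a full-column Gaussian intensity profile.
    noise_px jitters each column's stripe centre (sigma in pixels).
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    rng = np.random.default_rng(seed)
    truth = SceneTruth(pods=list(pods), table_z=table_z)
    H, W = image_shape
    Rm, T = calib.extrinsics.R, calib.extrinsics.T
    n_cam = calib.plane.normal
    n_w = Rm.T @ n_cam
    e_w = float(n_cam @ T + calib.plane.d)
    g = calib.guide_direction
    nh = np.hypot(n_w[0], n_w[1])
    if nh <= abs(n_w[2]):
        raise ValueError("light plane must be mostly vertical in the world frame")
    t_hat = np.array([-n_w[1], n_w[0]]) / nh
    nh_hat = np.array([n_w[0], n_w[1]]) / nh
    nz = n_w[2]

    # scene extents for sampling along the sheet
    if pods:
        ext = max(p.half_length + p._max_radius for p in pods) + 5.0
        cx = np.array([p.position for p in pods])
        lo = cx.min(axis=0) - ext
        hi = cx.max(axis=0) + ext
    else:
        span = 0.6 * W * 300.0 / 900.0
        lo, hi = np.array([-span, -span]), np.array([span, span])
    corners = np.array([[lo[0], lo[1]], [lo[0], hi[1]],
                        [hi[0], lo[1]], [hi[0], hi[1]]])
    s_vals = corners @ t_hat
    s_grid = np.linspace(s_vals.min(), s_vals.max(), samples_per_frame)

    zmax = table_z + (max(2 * p.rest_height for p in pods) if pods else 0.0) + 1.0
    zmin = table_z - 1.0
    w_lo = min(-nz * zmin / nh, -nz * zmax / nh) - 0.5
    w_hi = max(-nz * zmin / nh, -nz * zmax / nh) + 0.5
    w_grid = np.linspace(w_lo, w_hi, 80)

    def fval(e_shift: float, s: np.ndarray, wv: np.ndarray) -> np.ndarray:
        xy = (s[..., None] * t_hat + wv[..., None] * nh_hat
              - (e_shift / nh) * nh_hat)
        return nh * wv + nz * truth.scene_height(xy[..., 0], xy[..., 1])

    def solve_curve(e_shift: float, s: np.ndarray):
        """Topmost sheet/surface intersection per s value: (xy, z)."""
        F = fval(e_shift, s[:, None], w_grid[None, :])  # (S, W)
        sign_change = F[:, :-1] * F[:, 1:] <= 0
        z_at = -nh * w_grid / nz if nz != 0 else np.zeros_like(w_grid)
        # choose, per s, the bracket whose z is largest (nearest the camera)
        zb = np.where(sign_change, z_at[:-1][None, :], -np.inf)
        has_root = sign_change.any(axis=1)
        kbest = np.argmax(zb, axis=1)
        srt = s[has_root]
        k = kbest[has_root]
        lo_w = w_grid[k].copy()
        hi_w = w_grid[k + 1].copy()
        f_lo = F[has_root, k]
        for _ in range(48):
            mid = 0.5 * (lo_w + hi_w)
            f_mid = fval(e_shift, srt, mid)
            left = f_lo * f_mid <= 0
            hi_w = np.where(left, mid, hi_w)
            lo_w = np.where(left, lo_w, mid)
            f_lo = np.where(left, f_lo, f_mid)
        w_sol = 0.5 * (lo_w + hi_w)
        xy = (srt[:, None] * t_hat + w_sol[:, None] * nh_hat
              - (e_shift / nh) * nh_hat)
        z = (-(nh * w_sol) / nz if nz != 0
             else truth.scene_height(xy[:, 0], xy[:, 1]))
        return srt, xy, z

    frames: list[StripeFrame] = []
    any_lit = False
    for idx in range(n_frames):
        t = idx * calib.frame_interval
        d = calib.speed * t
        e_shift = e_w - d * float(n_w @ g)
        s_cur, xy, z = solve_curve(e_shift, s_grid)
        # adaptively subdivide steep segments so that only true surface
        # discontinuities (silhouette drops) remain as large z jumps
        for _ in range(8):
            if len(s_cur) < 2:
                break
            dz = np.abs(np.diff(z))
            ds = np.diff(s_cur)
            flag = (dz > 1.0) & (ds > 0.02)
            if not flag.any():
                break
            mids = 0.5 * (s_cur[:-1][flag] + s_cur[1:][flag])
            sm, xym, zm = solve_curve(e_shift, mids)
            s_cur = np.concatenate([s_cur, sm])
            xy = np.vstack([xy, xym])
            z = np.concatenate([z, zm])
            order = np.argsort(s_cur)
            s_cur, xy, z = s_cur[order], xy[order], z[order]
        p_obj = np.column_stack([xy, z])
        # project the (moved) world point into the camera
        p_world = p_obj - d * g
        cam = p_world @ Rm.T + T
        uv = np.column_stack([
            calib.intrinsics.fx * cam[:, 0] / cam[:, 2] + calib.intrinsics.u0,
            calib.intrinsics.fy * cam[:, 1] / cam[:, 2] + calib.intrinsics.v0,
        ])
        img = np.zeros((H, W))
        if len(uv) >= 2:
            centre = np.full(W, np.nan)
            depth = np.full(W, np.inf)
            du = np.diff(uv[:, 0])
            dz = np.diff(z)
            ok_seg = (np.abs(dz) <= 1.0) & (np.abs(du) > 1e-12) & (np.abs(du) < 10.0)
            for a_i in np.nonzero(ok_seg)[0]:
                u0, u1 = uv[a_i, 0], uv[a_i + 1, 0]
                v0, v1 = uv[a_i, 1], uv[a_i + 1, 1]
                z0, z1 = cam[a_i, 2], cam[a_i + 1, 2]
                ulo, uhi = (u0, u1) if u0 <= u1 else (u1, u0)
                for u in range(max(0, int(np.ceil(ulo))),
                               min(W - 1, int(np.floor(uhi))) + 1):
                    f = (u - u0) / (u1 - u0)
                    zc = z0 + f * (z1 - z0)
                    if zc < depth[u]:
                        depth[u] = zc
                        centre[u] = v0 + f * (v1 - v0)
            cols = np.nonzero(np.isfinite(centre)
                              & (centre > -5 * stripe_sigma)
                              & (centre < H + 5 * stripe_sigma))[0]
            if len(cols):
                any_lit = True
                jitter = (rng.normal(0.0, noise_px, len(cols))
                          if noise_px > 0 else 0.0)
                vc = centre[cols] + jitter
                rows = np.arange(H, dtype=float)
                img[:, cols] = stripe_peak * np.exp(
                    -((rows[:, None] - vc[None, :]) ** 2) / (2 * stripe_sigma ** 2))
        frames.append(StripeFrame(image=img, timestamp=t, index=idx))
    if not any_lit:
        import warnings

        warnings.warn("light plane never intersected the scene: all frames dark")
    return frames, truth


# ---------------------------------------------------------------------------
# top-down rendering
# ---------------------------------------------------------------------------

def render_topdown(
    pods: list[PodSpec],
    mm_per_pixel: float = 0.25,
    illumination: float = 1.0,
    seed: int = 0,
    table_z: float = 0.0,
    padding_mm: float = 6.0,
    noise_sigma: float = 2.0,
    background: float = 30.0,
) -> tuple[np.ndarray, SceneTruth]:
    """Orthographic top-down grayscale rendering with per-pod truth masks.

    Pod pixels are shaded by surface height (the bump texture is part of the
    height field), scaled linearly by *illumination* and clipped to [0, 255];
    the table is flat background.  Masks come from the same geometry, are
    pairwise disjoint (ties go to the taller pod) and align exactly with the
    rendered silhouettes.
    """
    if mm_per_pixel <= 0:
        raise ValueError("mm_per_pixel must be > 0")
    rng = np.random.default_rng(seed)
    if pods:
        ext = np.array([[p.position[0] - p.half_length - p._max_radius,
                         p.position[1] - p.half_length - p._max_radius,
                         p.position[0] + p.half_length + p._max_radius,
                         p.position[1] + p.half_length + p._max_radius]
                        for p in pods])
        x0, y0 = ext[:, 0].min() - padding_mm, ext[:, 1].min() - padding_mm
        x1, y1 = ext[:, 2].max() + padding_mm, ext[:, 3].max() + padding_mm
    else:
        x0 = y0 = -20.0
        x1 = y1 = 20.0
    nx = int(np.ceil((x1 - x0) / mm_per_pixel))
    ny = int(np.ceil((y1 - y0) / mm_per_pixel))
    xs = x0 + mm_per_pixel * np.arange(nx)
    ys = y0 + mm_per_pixel * np.arange(ny)
    X, Y = np.meshgrid(xs, ys)

    heights = np.full((len(pods), ny, nx), -np.inf)
    for i, pod in enumerate(pods):
        h = pod.height(X, Y, table_z)
        heights[i] = np.where(np.isnan(h), -np.inf, h)
    _check_interpenetration(pods, X, Y, table_z)

    if pods:
        owner = np.argmax(heights, axis=0)
        any_pod = np.isfinite(heights).any(axis=0)
        hmax = np.max(heights, axis=0)
    else:
        any_pod = np.zeros((ny, nx), dtype=bool)
        owner = np.zeros((ny, nx), dtype=int)
        hmax = np.full((ny, nx), table_z)

    img = np.full((ny, nx), background)
    if any_pod.any():
        zrange = max(hmax[any_pod].max() - table_z, 1e-9)
        shade = 90.0 + 130.0 * (hmax - table_z) / zrange
        img = np.where(any_pod, shade, img)
    img = np.clip(illumination * img, 0.0, 255.0)
    if noise_sigma > 0:
        img = np.clip(img + rng.normal(0.0, noise_sigma, img.shape), 0.0, 255.0)

    masks = [(any_pod & (owner == i)) for i in range(len(pods))]
    truth = SceneTruth(
        pods=list(pods), table_z=table_z, masks=masks,
        image_origin=np.array([x0, y0]), mm_per_pixel=mm_per_pixel,
    )
    return img, truth


def _check_interpenetration(pods, X, Y, table_z, tol: float = 0.5) -> None:
    """Two resting pods interpenetrate when, somewhere, both solids overlap
    in z by more than *tol* (solids taken symmetric about their axis height)."""
    for i in range(len(pods)):
        hi_ = pods[i].height(X, Y, table_z)
        for j in range(i + 1, len(pods)):
            hj = pods[j].height(X, Y, table_z)
            both = ~np.isnan(hi_) & ~np.isnan(hj)
            if not both.any():
                continue
            axis_i = table_z + pods[i].rest_height
            axis_j = table_z + pods[j].rest_height
            low_i = 2 * axis_i - hi_[both]
            low_j = 2 * axis_j - hj[both]
            depth = np.minimum(hi_[both], hj[both]) - np.maximum(low_i, low_j)
            if np.any(depth > tol):
                raise ValueError(
                    f"pods {i} and {j} interpenetrate by up to "
                    f"{float(depth.max()):.2f} mm (> {tol} mm)"
                )


# ---------------------------------------------------------------------------
# scene presets
# ---------------------------------------------------------------------------

def _silhouette_x_extent(spec: PodSpec, grid_mm: float = 0.05) -> tuple[float, float]:
    """Measured min/max x of the pod silhouette (pod at its own position)."""
    r = spec.half_length + spec._max_radius + 1.0
    xs = np.arange(spec.position[0] - r, spec.position[0] + r, grid_mm)
    ys = np.arange(spec.position[1] - r, spec.position[1] + r, grid_mm)
    X, Y = np.meshgrid(xs, ys)
    inside = ~np.isnan(spec.height(X, Y))
    cols = inside.any(axis=0)
    return float(xs[cols].min()), float(xs[cols].max())


def adherent_scene(
    morphologies: list[str], seed: int = 0, clearance: float = 0.15
) -> list[PodSpec]:
    """Place pods in a touching chain along +X with jittered yaw.

    Consecutive pods are laid tip-to-tip with *clearance* mm between their
    measured silhouettes — below the rendering pixel size, so the rendered
    blobs touch (adherent) while the convex 3-D solids never interpenetrate.
    """
    rng = np.random.default_rng(seed)
    pods: list[PodSpec] = []
    right_edge = 0.0
    for i, morph in enumerate(morphologies):
        yaw = float(rng.uniform(-0.25, 0.25))
        y = float(rng.uniform(-1.5, 1.5))
        spec = pod_spec(morph, position=(0.0, y), yaw=yaw)
        x_lo, x_hi = _silhouette_x_extent(spec)
        x = 0.0 if not pods else right_edge + clearance - x_lo
        spec = pod_spec(morph, position=(x, y), yaw=yaw)
        right_edge = x + x_hi
        pods.append(spec)
    cx = float(np.mean([p.position[0] for p in pods]))
    return [pod_spec(p.morphology, position=(p.position[0] - cx, p.position[1]),
                     yaw=p.yaw) for p in pods]


def adherent_pod_cloud(
    pods: list[PodSpec], n_points: int = 20000, seed: int = 0,
    table_z: float = 0.0,
) -> tuple[PointCloud, np.ndarray]:
    """Directly sampled upper-surface cloud of touching pods + truth labels.

    The per-pod point budget is proportional to silhouette area so sampling
    density is uniform across the scene.
    """
    rng = np.random.default_rng(seed)
    areas = np.array([p.half_length * p._max_radius for p in pods])
    budget = np.maximum((n_points * areas / areas.sum()).astype(int), 500)
    pts_all, lab_all = [], []
    for i, (pod, m) in enumerate(zip(pods, budget)):
        pts, _ = make_pod_surface(pod, samples=int(m),
                                  seed=int(rng.integers(2 ** 31)))
        pts[:, 2] += table_z
        pts_all.append(pts)
        lab_all.append(np.full(len(pts), i, dtype=int))
    return (PointCloud(points=np.vstack(pts_all)),
            np.concatenate(lab_all))
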