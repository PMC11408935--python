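"""Thermal camera model and LiDAR–thermal sensor fusion.

A pinhole camera (optional radial distortion) projects the 3D cloud into the
thermal frame; per-point temperatures (T_Raw) are sampled from the nearest
pixel with a per-pixel z-buffer so occluded points stay unannotated.
Extrinsics can be estimated from ≥6 3D–2D correspondences (direct linear
transform initialisation, reprojection least-squares refinement); the target
detection that produces such correspondences is out of scope — they are
inputs.

Nearest-pixel sampling is deliberate: thermal pixels are radiometric
readings, and interpolating across a fruit/sky edge would invent mixed-pixel
temperatures that exist nowhere on the scene.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial.transform import Rotation

from .cloud import PointCloud

#: default sentinel for sky / unseen pixels (never a legal temperature)
SKY = np.nan


class DegenerateGeometryError(ValueError):
    """Correspondence configuration too degenerate to fix a pose."""


@dataclass
class CameraModel:
    """Pinhole thermal camera with optional k1/k2 radial distortion.

    ``rotation`` and ``translation`` map cloud-frame coordinates into the
    camera frame (x right, y down, z forward): ``Xc = R @ X + t``.
    """

    fx: float
    fy: float
    cx: float
    cy: float
    width: int = 640
    height: int = 480
    k1: float = 0.0
    k2: float = 0.0
    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        if not (self.fx > 0 and self.fy > 0):
            raise ValueError("focal lengths must be positive")
        if not (self.width > 0 and self.height > 0):
            raise ValueError("image size must be positive")
        self.rotation = np.asarray(self.rotation, dtype=np.float64).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=np.float64).reshape(3)
        err = np.abs(self.rotation @ self.rotation.T - np.eye(3)).max()
        if err > 1e-8:
            raise ValueError(f"rotation not orthonormal (max deviation {err:.2e})")

    @property
    def diagonal_px(self) -> float:
        return float(np.hypot(self.width, self.height))

    def to_json(self, path) -> None:
        d = {"fx": self.fx, "fy": self.fy, "cx": self.cx, "cy": self.cy,
             "width": self.width, "height": self.height,
             "k1": self.k1, "k2": self.k2,
             "rotation": self.rotation.tolist(),
             "translation": self.translation.tolist()}
        Path(path).write_text(json.dumps(d, indent=1))

    @classmethod
    def from_json(cls, path) -> "CameraModel":
        d = json.loads(Path(path).read_text())
        return cls(**{k: (np.asarray(v) if k in ("rotation", "translation") else v)
                      for k, v in d.items()})


@dataclass
class ThermalFrame:
    """Single-band thermal raster in °C; NaN marks sky / unseen pixels."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("thermal frame must be a 2-D raster")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_csv(self, path) -> None:
        np.savetxt(path, self.values, delimiter=",", fmt="%.17g")

    @classmethod
    def from_csv(cls, path) -> "ThermalFrame":
        return cls(np.loadtxt(path, delimiter=",", ndmin=2))

    def to_tiff(self, path) -> None:
        import tifffile
        tifffile.imwrite(path, self.values.astype(np.float32))

    @classmethod
    def from_tiff(cls, path) -> "ThermalFrame":
        import tifffile
        return cls(tifffile.imread(path).astype(np.float64))


def project_points(cloud: PointCloud, camera: CameraModel
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Project every point into the image plane.

    Returns ``(uv, depth, visible)`` where ``uv`` is (n, 2) pixel coordinates
    (continuous; NaN where the point is behind the camera), ``depth`` is the
    camera-frame z, and ``visible`` flags points in front of the camera whose
    nearest pixel lies inside the frame. Never raises on geometry — points
    are flagged, not rejected.
    """
    Xc = cloud.xyz @ camera.rotation.T + camera.translation
    depth = Xc[:, 2]
    with np.errstate(divide="ignore", invalid="ignore"):
        x = Xc[:, 0] / depth
        y = Xc[:, 1] / depth
    r2 = x * x + y * y
    distort = 1.0 + camera.k1 * r2 + camera.k2 * r2 * r2
    u = camera.fx * x * distort + camera.cx
    v = camera.fy * y * distort + camera.cy
    uv = np.column_stack([u, v])
    in_front = depth > 0
    col = np.rint(u).astype(np.int64, copy=False)
    row = np.rint(v).astype(np.int64, copy=False)
    with np.errstate(invalid="ignore"):
        in_frame = (in_front
                    & (u >= -0.5) & (u <= camera.width - 0.5)
                    & (v >= -0.5) & (v <= camera.height - 0.5))
    uv[~in_front] = np.nan
    return uv, depth, in_frame


def _pixel_indices(uv: np.ndarray, visible: np.ndarray, shape: tuple[int, int]
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Nearest-pixel (row, col) for visible points."""
    col = np.clip(np.rint(uv[visible, 0]).astype(np.int64), 0, shape[1] - 1)
    row = np.clip(np.rint(uv[visible, 1]).astype(np.int64), 0, shape[0] - 1)
    return row, col


def render_thermal_image(cloud: PointCloud, camera: CameraModel,
                         background: float = SKY) -> ThermalFrame:
    """Z-buffered projection of per-point temperature into the pixel grid.

    Each pixel takes the temperature of the nearest point that projects into
    it; pixels seen by no point take the ``background`` sentinel. Used to
    close the loop on the synthetic scene: a cloud annotated against its own
    rendering must recover the true temperatures of visible points.
    """
    if cloud.temperature is None:
        raise ValueError("cloud has no temperature channel to render")
    if len(cloud) == 0:
        raise ValueError("cannot render an empty cloud")
    shape = (camera.height, camera.width)
    frame = np.full(shape, background, dtype=np.float64)
    uv, depth, visible = project_points(cloud, camera)
    visible = visible & np.isfinite(cloud.temperature)
    if not visible.any():
        warnings.warn("no visible points; rendered frame is all background")
        return ThermalFrame(frame)
    row, col = _pixel_indices(uv, visible, shape)
    flat = row * shape[1] + col
    d = depth[visible]
    t = cloud.temperature[visible]
    # nearest point wins: sort by depth descending so the last write is nearest
    order = np.argsort(-d, kind="stable")
    out = frame.ravel()
    out[flat[order]] = t[order]
    return ThermalFrame(frame)


def annotate_temperature(cloud: PointCloud, frame: ThermalFrame,
                         camera: CameraModel, depth_tolerance: float = 0.10
                         ) -> tuple[PointCloud, float]:
    """Annotate the cloud with T_Raw sampled from the thermal frame.

    Visible points sample their nearest pixel. A per-pixel z-buffer built from
    the cloud itself resolves occlusion: only points within ``depth_tolerance``
    metres of the nearest point on their pixel are annotated. Occluded,
    out-of-frame, and sky-pixel points keep a missing temperature. Returns the
    annotated cloud and the annotation coverage fraction.
    """
    if frame.shape != (camera.height, camera.width):
        raise ValueError(
            f"frame shape {frame.shape} does not match camera "
            f"({camera.height}, {camera.width})")
    n = len(cloud)
    temperature = (np.full(n, np.nan) if cloud.temperature is None
                   else cloud.temperature.copy())
    out = cloud.copy()
    out.temperature = temperature
    if n == 0:
        return out, 0.0
    if not np.isfinite(frame.values).any():
        warnings.warn("thermal frame is entirely background; nothing annotated")
        return out, 0.0
    uv, depth, visible = project_points(cloud, camera)
    if not visible.any():
        return out, 0.0
    row, col = _pixel_indices(uv, visible, frame.shape)
    flat = row * frame.shape[1] + col
    d = depth[visible]
    # per-pixel nearest depth among cloud points
    zbuf = np.full(frame.values.size, np.inf)
    np.minimum.at(zbuf, flat, d)
    front = d <= zbuf[flat] + depth_tolerance
    sampled = frame.values.ravel()[flat]
    ok = front & np.isfinite(sampled)
    idx = np.flatnonzero(visible)[ok]
    temperature[idx] = sampled[ok]
    coverage = len(idx) / n
    return out, coverage


def estimate_extrinsics(points3d: np.ndarray, pixels: np.ndarray,
                        camera: CameraModel
                        ) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Recover camera extrinsics from 3D–2D correspondences.

    Direct linear transform on intrinsics-normalised image coordinates,
    followed by least-squares refinement of the pixel reprojection error
    (including any configured radial distortion). Requires ≥6 non-coplanar
    correspondences.

    Returns ``(rotation, translation, rmse_px, rmse_pct_diagonal)`` where the
    last value is the RMSE as a percentage of the image diagonal.
    """
    X = np.asarray(points3d, dtype=np.float64).reshape(-1, 3)
    px = np.asarray(pixels, dtype=np.float64).reshape(-1, 2)
    if len(X) != len(px):
        raise ValueError("points3d and pixels must pair up")
    if len(X) < 6:
        raise DegenerateGeometryError(
            f"need at least 6 correspondences, got {len(X)}")
    centered = X - X.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-9 * max(1.0, np.abs(X).max())) < 3:
        raise DegenerateGeometryError("correspondences are coplanar/collinear")

    # DLT with distortion ignored (refined below)
    xn = (px[:, 0] - camera.cx) / camera.fx
    yn = (px[:, 1] - camera.cy) / camera.fy
    n = len(X)
    A = np.zeros((2 * n, 12))
    Xh = np.column_stack([X, np.ones(n)])
    A[0::2, 0:4] = Xh
    A[0::2, 8:12] = -xn[:, None] * Xh
    A[1::2, 4:8] = Xh
    A[1::2, 8:12] = -yn[:, None] * Xh
    _, s, Vt = np.linalg.svd(A)
    if s[-2] < 1e-12 * s[0]:
        raise DegenerateGeometryError("rank-deficient correspondence system")
    P = Vt[-1].reshape(3, 4)
    M = P[:, :3]
    # fix sign so depths are positive, then project M onto SO(3)
    if np.median(Xh @ P[2]) < 0:
        P = -P
        M = -M
    U, sv, Vt3 = np.linalg.svd(M)
    R0 = U @ Vt3
    if np.linalg.det(R0) < 0:
        U[:, -1] *= -1
        R0 = U @ Vt3
    t0 = P[:, 3] / sv.mean()

    def residual(params: np.ndarray) -> np.ndarray:
        cam = CameraModel(camera.fx, camera.fy, camera.cx, camera.cy,
                          camera.width, camera.height, camera.k1, camera.k2,
                          rotation=Rotation.from_rotvec(params[:3]).as_matrix(),
                          translation=params[3:])
        uv, _, _ = project_points(PointCloud(X), cam)
        return (uv - px).ravel()

    x0 = np.concatenate([Rotation.from_matrix(R0).as_rotvec(), t0])
    sol = least_squares(residual, x0, method="lm", xtol=1e-14, ftol=1e-14)
    R = Rotation.from_rotvec(sol.x[:3]).as_matrix()
    t = sol.x[3:]
    rmse_px = float(np.sqrt(np.mean(np.sum(sol.fun.reshape(-1, 2) ** 2, axis=1))))
    rmse_pct = rmse_px / camera.diagonal_px * 100.0
    return R, t, rmse_px, rmse_pct
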