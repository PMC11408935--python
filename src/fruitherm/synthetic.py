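"""Seeded synthetic slender-spindle orchard scenes with ground truth.

Stands in for field data: each tree has a vertical trunk (noisy cylinder),
oblique branch cylinders, leaves as small planar disks, and fruit as sphere
shells of sampled diameter attached within the crown. Per-point 905-nm return
intensity is drawn from class-conditional Gaussians (fruit the brightest,
wood the darkest by default) and per-point true temperature follows a
parametric field::

    T(point) = air_T + class_offset[class] + vertical_gradient * (z - z0) + noise

A rendered thermal image of the scene (z-buffered projection of true
temperatures) closes the loop for fusion testing, and a diel sinusoidal
weather series feeds the stress-index computations. Everything is driven by
one mandatory seed; identical seeds give bit-identical scenes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .cloud import PointCloud, WOOD, LEAF, FRUIT
from .fusion import CameraModel, ThermalFrame, SKY, render_thermal_image

__all__ = [
    "SceneSpec", "TemperatureFieldSpec", "GroundTruth",
    "generate_tree", "generate_scene", "make_weather",
    "render_thermal_image", "default_scene_camera",
]


@dataclass(frozen=True)
class SceneSpec:
    """Geometry and reflectance of a synthetic slender-spindle row.

    Defaults reflect a commercial 'Gala' planting: 0.95 m between trees,
    2.8 m tree height, fruit around 7 cm diameter at late growth stages.
    Reflectance means (percent at 905 nm) are configurable per class; fruit
    is set apart from foliage, which is what makes intensity a usable
    segmentation feature.
    """

    n_trees: int = 1
    planting_distance: float = 0.95
    tree_height: float = 2.8
    n_fruit_per_tree: int = 12
    fruit_diameter_mean: float = 0.07
    fruit_diameter_sd: float = 0.005
    leaf_density: float = 3000.0          # points per m^3 of crown
    reflectance_by_class: dict = field(
        default_factory=lambda: {"wood": 20.0, "leaf": 40.0, "fruit": 60.0})
    reflectance_sd: float = 5.0
    noise_sd_geometry: float = 0.002
    seed: int = 0
    # plumbing defaults, documented in the methods note
    trunk_radius: float = 0.02
    trunk_points: int = 700
    branch_count: int = 8
    branch_points: int = 110
    leaf_diameter: float = 0.06
    points_per_leaf: int = 20
    points_per_fruit: int = 220
    crown_radius: float = 0.33
    crown_z: tuple = (0.9, 2.7)

    def __post_init__(self) -> None:
        for name in ("planting_distance", "tree_height", "fruit_diameter_mean",
                     "trunk_radius", "leaf_diameter", "crown_radius"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        for name in ("n_trees", "n_fruit_per_tree", "trunk_points",
                     "branch_count", "points_per_fruit"):
            if getattr(self, name) < 0 or (name == "n_trees" and self.n_trees < 1):
                raise ValueError(f"{name} must be non-negative (n_trees >= 1)")
        if self.fruit_diameter_sd < 0 or self.noise_sd_geometry < 0:
            raise ValueError("standard deviations must be non-negative")
        for cls, refl in self.reflectance_by_class.items():
            if not 0.0 <= refl <= 100.0:
                raise ValueError(f"reflectance for {cls!r} outside [0, 100]")


@dataclass(frozen=True)
class TemperatureFieldSpec:
    """Parametric canopy temperature field.

    ``class_offsets`` shift each structural class from air temperature
    (wood slightly warm, shaded leaves cool, sunlit fruit warm);
    ``vertical_gradient`` (°C per metre, negative = cooler canopy top)
    adds height structure; ``noise_sd`` is i.i.d. per point. The sky
    sentinel is a reserved non-finite value, never a legal temperature.
    """

    air_t: float = 20.0
    class_offsets: dict = field(
        default_factory=lambda: {"wood": 0.6, "leaf": -1.7, "fruit": 1.5})
    vertical_gradient: float = -0.8
    noise_sd: float = 0.15
    background_value: float = SKY
    reference_z: float = 0.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if np.isfinite(self.background_value):
            raise ValueError("sky sentinel must be non-finite")


@dataclass
class GroundTruth:
    """Per-point class labels / fruit ids and the per-fruit truth table."""

    label: np.ndarray          # class code per point
    fruit_id: np.ndarray       # 0 = not fruit; ids contiguous from 1
    fruit: pd.DataFrame        # fruit_id, x, y, z, diameter_m, mean_t_c

    def __post_init__(self) -> None:
        self.label = np.asarray(self.label, dtype=np.int64)
        self.fruit_id = np.asarray(self.fruit_id, dtype=np.int64)
        if len(self.label) != len(self.fruit_id):
            raise ValueError("label and fruit_id must have equal length")
        on_fruit = self.fruit_id[self.label == FRUIT]
        if on_fruit.size and (on_fruit <= 0).any():
            raise ValueError("fruit-class points must carry fruit_id > 0")
        ids = np.unique(self.fruit_id[self.fruit_id > 0])
        if ids.size and not np.array_equal(ids, np.arange(1, ids.size + 1)):
            raise ValueError("fruit ids must be contiguous from 1")

    @property
    def n_fruit(self) -> int:
        return len(self.fruit)

    def to_json(self, path) -> None:
        d = {"label": self.label.tolist(),
             "fruit_id": self.fruit_id.tolist(),
             "fruit": self.fruit.to_dict(orient="list")}
        Path(path).write_text(json.dumps(d))

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        return cls(np.asarray(d["label"]), np.asarray(d["fruit_id"]),
                   pd.DataFrame(d["fruit"]))


_CLASS_NAME = {WOOD: "wood", LEAF: "leaf", FRUIT: "fruit"}


def _cylinder(rng, base, axis, length, radius, n) -> np.ndarray:
    """Points on a cylinder surface from ``base`` along unit ``axis``."""
    t = rng.uniform(0.0, length, n)
    theta = rng.uniform(0.0, 2 * np.pi, n)
    # orthonormal frame around the axis
    a = np.asarray(axis, dtype=float)
    a = a / np.linalg.norm(a)
    helper = np.array([1.0, 0.0, 0.0]) if abs(a[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = np.cross(a, helper)
    u /= np.linalg.norm(u)
    v = np.cross(a, u)
    return (np.asarray(base) + t[:, None] * a
            + radius * np.cos(theta)[:, None] * u
            + radius * np.sin(theta)[:, None] * v)


def _disk(rng, center, normal, diameter, n) -> np.ndarray:
    nrm = np.asarray(normal, dtype=float)
    nrm /= np.linalg.norm(nrm)
    helper = np.array([1.0, 0.0, 0.0]) if abs(nrm[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = np.cross(nrm, helper)
    u /= np.linalg.norm(u)
    v = np.cross(nrm, u)
    r = diameter / 2.0 * np.sqrt(rng.uniform(0.0, 1.0, n))
    theta = rng.uniform(0.0, 2 * np.pi, n)
    return (np.asarray(center) + r[:, None] * np.cos(theta)[:, None] * u
            + r[:, None] * np.sin(theta)[:, None] * v)


def _sphere_shell(rng, center, diameter, n) -> np.ndarray:
    vec = rng.normal(size=(n, 3))
    vec /= np.linalg.norm(vec, axis=1, keepdims=True)
    return np.asarray(center) + (diameter / 2.0) * vec


def _fruit_centers(rng, spec: SceneSpec, origin_x: float) -> np.ndarray:
    """Fruit centres inside the crown with a minimum mutual separation."""
    min_sep = max(2.0 * spec.fruit_diameter_mean, 0.12)
    centers: list[np.ndarray] = []
    attempts = 0
    while len(centers) < spec.n_fruit_per_tree and attempts < 4000:
        attempts += 1
        r = spec.crown_radius * np.sqrt(rng.uniform())
        theta = rng.uniform(0.0, 2 * np.pi)
        z = rng.uniform(*spec.crown_z)
        c = np.array([origin_x + r * np.cos(theta), r * np.sin(theta), z])
        if all(np.linalg.norm(c - p) >= min_sep for p in centers):
            centers.append(c)
    if len(centers) < spec.n_fruit_per_tree:
        raise ValueError(
            f"could not place {spec.n_fruit_per_tree} fruit with separation "
            f"{min_sep:.2f} m in the crown; reduce count or diameter")
    return np.asarray(centers)


def _generate_one_tree(rng, spec: SceneSpec, field_spec: TemperatureFieldSpec,
                       origin_x: float, fruit_id_offset: int
                       ) -> tuple[np.ndarray, np.ndarray, np.ndarray, pd.DataFrame]:
    pts: list[np.ndarray] = []
    labels: list[np.ndarray] = []
    fids: list[np.ndarray] = []

    base = np.array([origin_x, 0.0, 0.0])
    trunk = _cylinder(rng, base, [0, 0, 1], spec.tree_height,
                      spec.trunk_radius, spec.trunk_points)
    pts.append(trunk)
    labels.append(np.full(len(trunk), WOOD))
    fids.append(np.zeros(len(trunk), dtype=np.int64))

    for _ in range(spec.branch_count):
        z0 = rng.uniform(spec.crown_z[0], spec.crown_z[1] - 0.2)
        azimuth = rng.uniform(0.0, 2 * np.pi)
        elev = rng.uniform(np.deg2rad(5), np.deg2rad(35))
        axis = np.array([np.cos(azimuth) * np.cos(elev),
                         np.sin(azimuth) * np.cos(elev), np.sin(elev)])
        length = rng.uniform(0.2, min(0.45, spec.crown_radius + 0.1))
        br = _cylinder(rng, base + [0, 0, z0], axis, length, 0.008,
                       spec.branch_points)
        pts.append(br)
        labels.append(np.full(len(br), WOOD))
        fids.append(np.zeros(len(br), dtype=np.int64))

    crown_height = spec.crown_z[1] - spec.crown_z[0]
    crown_volume = np.pi * spec.crown_radius ** 2 * crown_height
    n_leaf_points = int(round(spec.leaf_density * crown_volume))
    n_leaves = max(0, n_leaf_points // spec.points_per_leaf)
    for _ in range(n_leaves):
        r = spec.crown_radius * np.sqrt(rng.uniform())
        theta = rng.uniform(0.0, 2 * np.pi)
        z = rng.uniform(*spec.crown_z)
        center = base + [r * np.cos(theta), r * np.sin(theta), z]
        normal = rng.normal(size=3)
        leaf = _disk(rng, center, normal, spec.leaf_diameter, spec.points_per_leaf)
        pts.append(leaf)
        labels.append(np.full(len(leaf), LEAF))
        fids.append(np.zeros(len(leaf), dtype=np.int64))

    fruit_rows = []
    if spec.n_fruit_per_tree > 0:
        centers = _fruit_centers(rng, spec, origin_x)
        for j, c in enumerate(centers):
            diameter = float(rng.normal(spec.fruit_diameter_mean,
                                        spec.fruit_diameter_sd))
            diameter = max(diameter, 0.2 * spec.fruit_diameter_mean)
            shell = _sphere_shell(rng, c, diameter, spec.points_per_fruit)
            fid = fruit_id_offset + j + 1
            pts.append(shell)
            labels.append(np.full(len(shell), FRUIT))
            fids.append(np.full(len(shell), fid, dtype=np.int64))
            fruit_rows.append({"fruit_id": fid, "x": c[0], "y": c[1], "z": c[2],
                               "diameter_m": diameter})

    xyz = np.vstack(pts)
    if spec.noise_sd_geometry > 0:
        xyz = xyz + rng.normal(0.0, spec.noise_sd_geometry, xyz.shape)
    return (xyz, np.concatenate(labels), np.concatenate(fids),
            pd.DataFrame(fruit_rows,
                         columns=["fruit_id", "x", "y", "z", "diameter_m"]))


def generate_scene(spec: SceneSpec, field_spec: TemperatureFieldSpec | None = None,
                   rng_seed: int | None = None) -> tuple[PointCloud, GroundTruth]:
    """Generate a row of ``spec.n_trees`` trees with labels and temperatures.

    Trees sit at ``x = i * planting_distance``; fruit ids are contiguous
    across the whole scene. The same (spec, seed) always yields a
    bit-identical scene.
    """
    field_spec = field_spec or TemperatureFieldSpec()
    seed = spec.seed if rng_seed is None else rng_seed
    rng = np.random.default_rng(seed)

    parts = []
    fruit_tables = []
    offset = 0
    for i in range(spec.n_trees):
        xyz, lab, fid, fruit = _generate_one_tree(
            rng, spec, field_spec, origin_x=i * spec.planting_distance,
            fruit_id_offset=offset)
        offset += len(fruit)
        parts.append((xyz, lab, fid))
        fruit_tables.append(fruit)

    xyz = np.vstack([p[0] for p in parts])
    label = np.concatenate([p[1] for p in parts])
    fruit_id = np.concatenate([p[2] for p in parts])
    fruit = pd.concat(fruit_tables, ignore_index=True) if fruit_tables else \
        pd.DataFrame(columns=["fruit_id", "x", "y", "z", "diameter_m"])

    # class-conditional return intensity
    refl = spec.reflectance_by_class
    means = np.choose(label, [0.0, refl["wood"], refl["leaf"], refl["fruit"]])
    intensity = np.clip(rng.normal(means, spec.reflectance_sd), 0.0, 100.0)

    # parametric temperature field
    offsets = field_spec.class_offsets
    class_offset = np.choose(
        label, [0.0, offsets["wood"], offsets["leaf"], offsets["fruit"]])
    temperature = (field_spec.air_t + class_offset
                   + field_spec.vertical_gradient * (xyz[:, 2] - field_spec.reference_z))
    if field_spec.noise_sd > 0:
        temperature = temperature + rng.normal(0.0, field_spec.noise_sd, len(xyz))

    if len(fruit):
        mean_t = [float(np.mean(temperature[fruit_id == f]))
                  for f in fruit["fruit_id"]]
        fruit = fruit.assign(mean_t_c=mean_t)
    else:
        fruit = fruit.assign(mean_t_c=pd.Series(dtype=float))

    cloud = PointCloud(xyz, intensity=intensity, temperature=temperature,
                       label=label.copy(), fruit_id=fruit_id.copy())
    return cloud, GroundTruth(label, fruit_id, fruit)


def generate_tree(spec: SceneSpec, field_spec: TemperatureFieldSpec | None = None,
                  rng_seed: int | None = None) -> tuple[PointCloud, GroundTruth]:
    """Single-tree convenience wrapper around :func:`generate_scene`."""
    if spec.n_trees != 1:
        spec = SceneSpec(**{**asdict(spec), "n_trees": 1})
    return generate_scene(spec, field_spec, rng_seed)


def default_scene_camera(spec: SceneSpec, distance: float = 3.0,
                         width: int = 640, height: int = 480,
                         focal_px: float = 480.0) -> CameraModel:
    """Thermal camera facing the row centre from ``distance`` metres.

    World frame: x along the row, z up. The camera sits at canopy mid-height
    on the -y side looking in +y (image x right along the row, image y down).
    """
    cam_pos = np.array([(spec.n_trees - 1) * spec.planting_distance / 2.0,
                        -distance, spec.tree_height / 2.0])
    R = np.array([[1.0, 0.0, 0.0],
                  [0.0, 0.0, -1.0],
                  [0.0, 1.0, 0.0]])
    t = -R @ cam_pos
    return CameraModel(fx=focal_px, fy=focal_px,
                       cx=(width - 1) / 2.0, cy=(height - 1) / 2.0,
                       width=width, height=height, rotation=R, translation=t)


def make_weather(day_length_h: float = 24.0,
                 t_range: tuple[float, float] = (12.0, 28.0),
                 rh_range: tuple[float, float] = (45.0, 95.0),
                 step_min: int = 15, seed: int = 0,
                 noise_sd_t: float = 0.2, noise_sd_rh: float = 1.0,
                 start: str = "2022-09-21 00:00") -> pd.DataFrame:
    """Diel sinusoidal weather series at sub-hourly cadence.

    Air temperature runs from its minimum near 05:00 to its maximum near
    17:00; relative humidity moves in antiphase. Columns: ``timestamp``
    (ISO-8601), ``t_air_c``, ``rh_pct``. Deterministic for a given seed.
    """
    if 60 % step_min != 0:
        raise ValueError("step_min must divide 60")
    if t_range[1] < t_range[0] or rh_range[1] < rh_range[0]:
        raise ValueError("ranges must be (min, max) with min <= max")
    rng = np.random.default_rng(seed)
    n = int(round(day_length_h * 60 / step_min))
    ts = pd.date_range(start=start, periods=n, freq=f"{step_min}min")
    hours = ts.hour + ts.minute / 60.0
    phase = np.sin(2 * np.pi * (hours - 11.0) / 24.0)  # max at 17:00, min at 05:00
    t_mid = (t_range[0] + t_range[1]) / 2.0
    t_amp = (t_range[1] - t_range[0]) / 2.0
    rh_mid = (rh_range[0] + rh_range[1]) / 2.0
    rh_amp = (rh_range[1] - rh_range[0]) / 2.0
    t_air = t_mid + t_amp * phase
    rh = rh_mid - rh_amp * phase
    if noise_sd_t > 0:
        t_air = t_air + rng.normal(0.0, noise_sd_t, n)
    if noise_sd_rh > 0:
        rh = rh + rng.normal(0.0, noise_sd_rh, n)
    return pd.DataFrame({"timestamp": ts,
                         "t_air_c": t_air,
                         "rh_pct": np.clip(rh, 0.0, 100.0)})
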