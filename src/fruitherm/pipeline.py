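"""End-to-end orchestration: scene → thermal fusion → trees → fruit →
calibration → stress indices → summaries.

``run_pipeline`` drives every stage from one :class:`RunConfig` (one root
seed, every module parameter with a package default), writes per-stage
outputs into the run directory, and returns a manifest recording versions,
seeds, all parameter values actually used and per-stage counts. Reruns with
the same config are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cloud import PointCloud, FRUIT, write_cloud
from .synthetic import (SceneSpec, TemperatureFieldSpec, generate_scene,
                        make_weather, default_scene_camera, render_thermal_image)
from .fusion import annotate_temperature
from .canopy import detect_stems, crop_tree
from .fruit import (compute_eigen_features, derive_thresholds, segment_wood,
                    segment_fruit_candidates, cluster_fruit, score_detection,
                    clusters_to_frame)
from .calibration import blockwise_split, fit_calibration, apply_calibration
from .indices import air_temp_avg, vpd, index_records, summarize


class PipelineStageError(RuntimeError):
    """A stage failed; the stage name prefixes the message and partial
    outputs written so far are retained."""


@dataclass
class RunConfig:
    """Every knob of the pipeline, with defaults matching the module docs."""

    out_dir: str = "fruitherm_run"
    seed: int = 0
    # synthetic scene (ignored when cloud_path is given)
    scene: SceneSpec = field(default_factory=SceneSpec)
    tfield: TemperatureFieldSpec = field(default_factory=TemperatureFieldSpec)
    # real inputs (optional)
    cloud_path: str | None = None
    frame_path: str | None = None
    camera_path: str | None = None
    weather_path: str | None = None
    # fusion
    camera_distance: float = 3.0
    depth_tolerance: float = 0.10
    # canopy
    bin_size: float = 0.10
    crop_diameter: float = 0.95
    # fruit segmentation
    k_neighbors: int = 30
    eps: float | None = None          # default: fruit_diameter_mean / 2
    min_neighbors: int = 10
    # calibration
    run_calibration: bool = True
    cal_fraction: float = 0.8
    dafb: int = 153
    # indices
    use_weather: bool = True
    measurement_hour: int = 13
    air_offset_c: float = 5.0
    weather_t_range: tuple = (12.0, 28.0)
    weather_rh_range: tuple = (45.0, 95.0)

    def to_json(self, path) -> None:
        d = asdict(self)
        Path(path).write_text(json.dumps(d, indent=1, default=str))

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        if path.suffix == ".toml":
            import tomllib
            d = tomllib.loads(path.read_text())
        else:
            d = json.loads(path.read_text())
        if "scene" in d and isinstance(d["scene"], dict):
            d["scene"] = SceneSpec(**{k: (tuple(v) if isinstance(v, list) else v)
                                      for k, v in d["scene"].items()})
        if "tfield" in d and isinstance(d["tfield"], dict):
            d["tfield"] = TemperatureFieldSpec(**d["tfield"])
        for key in ("weather_t_range", "weather_rh_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - annotate and re-raise
                raise PipelineStageError(f"[{name}] {exc}") from exc
        return inner
    return wrap


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full chain and return the run manifest (also written as
    ``manifest.json`` in the output directory)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    def log(stage: str, msg: str) -> None:
        log_lines.append(f"[{stage}] {msg}")
        (out / "run.log").write_text("\n".join(log_lines) + "\n")

    manifest: dict = {
        "package": "fruitherm", "version": __version__,
        "numpy": np.__version__,
        "seed": config.seed,
        "parameters": json.loads(json.dumps(asdict(config), default=str)),
        "stages": {},
    }

    # --- scene -------------------------------------------------------------
    if config.cloud_path is None:
        scene_spec = dataclasses.replace(config.scene, seed=config.seed)
        cloud, truth = _stage("simulate")(generate_scene)(scene_spec, config.tfield)
        write_cloud(cloud, out / "scene.ply")
        truth.to_json(out / "truth.json")
        log("simulate", f"{len(cloud)} points, {truth.n_fruit} fruit")
    else:
        from .cloud import read_cloud
        cloud = _stage("load")(read_cloud)(config.cloud_path)
        truth = None
        log("load", f"{len(cloud)} points from {config.cloud_path}")
    manifest["stages"]["scene"] = {"n_points": len(cloud),
                                   "n_fruit_truth": truth.n_fruit if truth else None}

    # --- weather -----------------------------------------------------------
    weather = None
    if config.use_weather:
        if config.weather_path:
            weather = pd.read_csv(config.weather_path)
        else:
            weather = make_weather(t_range=config.weather_t_range,
                                   rh_range=config.weather_rh_range,
                                   seed=config.seed + 1)
            weather.to_csv(out / "weather.csv", index=False)
        log("weather", f"{len(weather)} records")

    # --- thermal fusion ----------------------------------------------------
    if config.frame_path and config.camera_path:
        from .fusion import ThermalFrame, CameraModel
        frame = ThermalFrame.from_csv(config.frame_path)
        camera = CameraModel.from_json(config.camera_path)
    else:
        camera = default_scene_camera(config.scene, distance=config.camera_distance)
        frame = _stage("fuse")(render_thermal_image)(cloud, camera)
        frame.to_csv(out / "frame.csv")
        camera.to_json(out / "camera.json")
    observed = cloud.copy()
    observed.temperature = None  # T_Raw must come from the frame, not the truth
    annotated, coverage = _stage("fuse")(annotate_temperature)(
        observed, frame, camera, depth_tolerance=config.depth_tolerance)
    write_cloud(annotated, out / "annotated.ply")
    log("fuse", f"coverage {coverage:.3f}")
    manifest["stages"]["fusion"] = {"coverage": coverage}

    # --- trees -------------------------------------------------------------
    stems = _stage("segment-trees")(detect_stems)(
        annotated, bin_size=config.bin_size,
        planting_distance=config.scene.planting_distance)
    trees = [crop_tree(annotated, pos, diameter=config.crop_diameter)
             for pos in stems.positions]
    stems.ppt = np.array([len(t) for t in trees])
    stems.to_csv(out / "stems.csv")
    log("segment-trees", f"{len(stems)} stems, PPT {stems.ppt.tolist()}")
    manifest["stages"]["trees"] = {"n_stems": len(stems),
                                   "ppt": stems.ppt.tolist()}

    # --- fruit segmentation -------------------------------------------------
    eps = config.eps if config.eps is not None else config.scene.fruit_diameter_mean / 2
    fruit_frames = []
    tp = fp = fn = 0
    n_candidates = 0
    for i, tree in enumerate(trees):
        if len(tree) < config.k_neighbors + 1:
            warnings.warn(f"tree {i + 1} too small for features; skipped")
            continue
        feats = _stage("detect-fruit")(compute_eigen_features)(
            tree, k=config.k_neighbors)
        fruit_ref = (tree.label == FRUIT) if tree.label is not None else None
        thresholds = _stage("detect-fruit")(derive_thresholds)(
            tree, feats, fruit_reference=fruit_ref)
        _, remainder, rem_feats = segment_wood(tree, feats, thresholds)
        cand = segment_fruit_candidates(remainder, rem_feats, thresholds)
        n_candidates += int(cand.sum())
        clusters = cluster_fruit(remainder, cand, eps=eps,
                                 min_neighbors=config.min_neighbors)
        if remainder.fruit_id is not None:
            s = score_detection(clusters, remainder.fruit_id, len(remainder))
            tp, fp, fn = tp + s.true_positives, fp + s.false_positives, fn + s.false_negatives
        frame_i = clusters_to_frame(clusters, tree_id=i + 1)
        if remainder.fruit_id is not None and len(frame_i):
            # ground-truth mean fruit temperature of the majority-matched fruit,
            # used as the manual reference in the calibration stage
            refs = []
            for c in clusters:
                ids = remainder.fruit_id[c.indices]
                ids = ids[ids > 0]
                if ids.size and truth is not None:
                    best = np.bincount(ids).argmax()
                    row = truth.fruit.loc[truth.fruit.fruit_id == best, "mean_t_c"]
                    refs.append(float(row.iloc[0]) if len(row) else np.nan)
                else:
                    refs.append(np.nan)
            frame_i["t_ref_c"] = refs
        fruit_frames.append(frame_i)
    fruit_table = (pd.concat(fruit_frames, ignore_index=True) if fruit_frames
                   else clusters_to_frame([]))
    fruit_table.to_csv(out / "fruit.csv", index=False, float_format="%.17g")
    n_detected = len(fruit_table)
    from .fruit import DetectionScore
    score = DetectionScore(tp, fp, fn)
    log("detect-fruit", f"{n_detected} fruit, F1 {score.f1:.3f}")
    manifest["stages"]["fruit"] = {
        "eps": eps, "n_candidates": n_candidates,
        "n_fruit_detected": n_detected,
        "precision": score.precision, "recall": score.recall, "f1": score.f1}

    # --- calibration --------------------------------------------------------
    t_est_col = fruit_table["t_raw_mean"].to_numpy(float) if n_detected else np.empty(0)
    cal_metrics = None
    if (config.run_calibration and n_detected >= 5
            and "t_ref_c" in fruit_table.columns
            and fruit_table["t_ref_c"].notna().sum() >= 5):
        records = fruit_table.loc[
            fruit_table["t_ref_c"].notna() & fruit_table["t_raw_mean"].notna(),
            ["t_raw_mean", "t_ref_c"]].rename(columns={"t_raw_mean": "t_raw_c"})
        records["dafb"] = config.dafb
        assignment = blockwise_split(records, cal_fraction=config.cal_fraction,
                                     seed=config.seed + 2)
        model = _stage("calibrate")(fit_calibration)(records, assignment)
        model.to_json(out / "calibration.json")
        t_est_col = apply_calibration(model, fruit_table["t_raw_mean"].to_numpy(float))
        cal_metrics = model.metrics
        log("calibrate", f"slope {model.slope:.3f} intercept {model.intercept:.3f}")
    manifest["stages"]["calibration"] = cal_metrics

    # --- indices ------------------------------------------------------------
    n_index_rows = 0
    if n_detected >= 2 and np.isfinite(t_est_col).sum() >= 2:
        fruit_temps = pd.DataFrame({
            "fruit_id": fruit_table["fruit_id"],
            "t_est_c": t_est_col,
            "height_m": fruit_table["z"],
        })
        fruit_temps = fruit_temps[np.isfinite(fruit_temps["t_est_c"])]
        t_a = vpd_kpa = None
        if weather is not None:
            ts = pd.to_datetime(weather["timestamp"])
            t_a = _stage("indices")(air_temp_avg)(weather, config.measurement_hour)
            at_hour = weather[ts.dt.hour == config.measurement_hour]
            if len(at_hour):
                vpd_kpa = float(vpd(at_hour["t_air_c"].mean(),
                                    at_hour["rh_pct"].mean()))
            day = ts.dt.normalize().iloc[0]
            fruit_temps["timestamp"] = day + pd.Timedelta(hours=config.measurement_hour)
        records = _stage("indices")(index_records)(
            fruit_temps, t_a=t_a, vpd_kpa=vpd_kpa, offset=config.air_offset_c)
        records.to_csv(out / "indices.csv", index=False, float_format="%.17g")
        n_index_rows = len(records)
        summary = summarize(records, by="height_bin",
                            height_range=(0.0, config.scene.tree_height + 0.1))
        summary.to_csv(out / "summary_height.csv", index=False, float_format="%.17g")
        log("indices", f"{n_index_rows} index records")
    manifest["stages"]["indices"] = {"n_rows": n_index_rows}

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return manifest
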