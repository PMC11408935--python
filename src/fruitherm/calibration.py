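"""Calibration of remote fruit temperatures against manual references.

Remote readings (T_Raw, from the temperature-annotated cloud) are regressed
on manual infrared-thermometer references (T_Ref) with an ordinary
least-squares line fitted on a date-blockwise 80/20 calibration /
cross-validation split: within each measuring-date block, floor(0.8·n)
records are drawn into the calibration partition by a seeded shuffle. The
fitted line maps any raw temperature to its estimate, T_Est = a·T_Raw + b,
and r², RMSE (°C and % of the partition's mean reference) and bias are
reported separately for both partitions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import linregress

CAL, VAL = "cal", "val"


def blockwise_split(records: pd.DataFrame, cal_fraction: float = 0.8,
                    seed: int = 0, block_col: str = "dafb") -> np.ndarray:
    """Assign each record to calibration or validation, blockwise.

    Within every block, ``floor(cal_fraction · n_block)`` records go to
    calibration via a seeded shuffle; the remainder validate. Returns an
    array of ``"cal"`` / ``"val"`` aligned with ``records``.
    """
    if block_col not in records.columns:
        raise ValueError(f"records lack a {block_col!r} block column")
    blocks = records[block_col]
    if blocks.isna().any():
        raise ValueError("records with missing block id: "
                         f"rows {records.index[blocks.isna()].tolist()}")
    if not 0.0 < cal_fraction < 1.0:
        raise ValueError("cal_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    out = np.full(len(records), VAL, dtype=object)
    pos = {idx: i for i, idx in enumerate(records.index)}
    for block, grp in records.groupby(block_col, sort=True):
        if len(grp) == 0:
            raise ValueError(f"empty block {block!r}")
        n_cal = int(np.floor(cal_fraction * len(grp)))
        order = rng.permutation(len(grp))
        chosen = grp.index[order[:n_cal]]
        for idx in chosen:
            out[pos[idx]] = CAL
    return out.astype(str)


@dataclass
class CalibrationModel:
    """Affine T_Raw → T_Est map with per-partition goodness-of-fit."""

    slope: float = np.nan
    intercept: float = np.nan
    metrics: dict = field(default_factory=dict)  # per partition
    fitted: bool = False

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(
            {"slope": self.slope, "intercept": self.intercept,
             "metrics": self.metrics}, indent=1))


def _partition_metrics(t_raw: np.ndarray, t_ref: np.ndarray,
                       slope: float, intercept: float) -> dict:
    t_est = slope * t_raw + intercept
    resid = t_est - t_ref
    rmse = float(np.sqrt(np.mean(resid ** 2)))
    mean_ref = float(np.mean(t_ref))
    r = np.corrcoef(t_raw, t_ref)[0, 1] if len(t_raw) > 1 else np.nan
    return {
        "n": int(len(t_raw)),
        "r2": float(r ** 2),
        "rmse_c": rmse,
        "rmse_pct": rmse / mean_ref * 100.0 if mean_ref else np.nan,
        "bias_c": float(np.mean(resid)),
    }


def fit_calibration(records: pd.DataFrame, assignment: np.ndarray,
                    raw_col: str = "t_raw_c", ref_col: str = "t_ref_c"
                    ) -> CalibrationModel:
    """OLS of T_Ref on T_Raw over the calibration partition.

    Metrics (r², RMSE in °C and in % of mean reference, bias) are computed
    on each partition with the single calibration-fitted line.
    """
    assignment = np.asarray(assignment)
    cal = records.loc[assignment == CAL]
    if len(cal) < 3:
        raise ValueError(f"need at least 3 calibration records, got {len(cal)}")
    x = cal[raw_col].to_numpy(dtype=float)
    y = cal[ref_col].to_numpy(dtype=float)
    if np.std(x) == 0:
        raise ValueError("zero variance in T_Raw: singular fit")
    fit = linregress(x, y)
    model = CalibrationModel(slope=float(fit.slope),
                             intercept=float(fit.intercept), fitted=True)
    for part in (CAL, VAL):
        sub = records.loc[assignment == part]
        if len(sub):
            model.metrics[part] = _partition_metrics(
                sub[raw_col].to_numpy(float), sub[ref_col].to_numpy(float),
                model.slope, model.intercept)
    return model


def apply_calibration(model: CalibrationModel, values) -> np.ndarray:
    """Apply the fitted affine map; missing (NaN) stays missing.

    Accepts an array of temperatures or a cloud-like object with a
    ``temperature`` channel (returned as a new array, the input untouched).
    """
    if not model.fitted:
        raise ValueError("calibration model is not fitted")
    temps = values.temperature if hasattr(values, "temperature") else values
    temps = np.asarray(temps, dtype=np.float64)
    out = model.slope * temps + model.intercept
    return out
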