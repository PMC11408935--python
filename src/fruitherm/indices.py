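"""Fruit water stress indices, VPD, and grouped summaries.

Three dimensionless indices rate a fruit surface temperature T_Est against
reference temperatures of the same measuring day:

* Irmak-style:    FWSI_I = (T_Est − minT_Est) / (T_a + 5 − minT_Est),
  where T_a is the mean air temperature over the four full hours ending two
  hours before the measurement hour and the +5 °C offset follows the
  original crop-water-stress formulation;
* Jones-style:    FWSI_J = (T_Est − wetT) / (dryT − wetT), anchored on a
  fully transpiring (soap-water) and a non-transpiring (Vaseline-coated)
  reference fruit — retained for completeness but *not recommended*: the
  wet/dry references fail in practice on apple;
* normalized:     FWSI_N = (T_Est − minT_Est) / (maxT_Est − minT_Est),
  with the day's own extremes over all segmented fruit points, hence in
  [0, 1] by construction.

ΔT = T_Est − T_a and the vapour pressure deficit VPD = (1 − RH/100)·SVP
(SVP in Pa via the 610.7 · 10^(7.5·T/(237.3+T)) Magnus form, VPD reported in
kPa) complete the record.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

AIR_OFFSET_C = 5.0  #: default upper-reference offset added to T_a


class MissingDataError(ValueError):
    """Weather hours required by the averaging window are absent."""


def svp(t_c) -> np.ndarray | float:
    """Saturated vapour pressure in Pa (Magnus form), valid for T > −237.3 °C."""
    t = np.asarray(t_c, dtype=np.float64)
    if np.any(t <= -237.3):
        raise ValueError("temperature at or below -237.3 °C is outside the "
                         "Magnus-form domain")
    out = 610.7 * 10.0 ** (7.5 * t / (237.3 + t))
    return float(out) if np.isscalar(t_c) else out


def vpd(t_c, rh_pct) -> np.ndarray | float:
    """Vapour pressure deficit in kPa: (1 − RH/100) · SVP(T)."""
    rh = np.asarray(rh_pct, dtype=np.float64)
    if np.any((rh < 0.0) | (rh > 100.0)):
        raise ValueError("relative humidity must lie in [0, 100] %")
    out = (1.0 - rh / 100.0) * np.asarray(svp(t_c)) / 1000.0
    return float(out) if np.isscalar(t_c) and np.isscalar(rh_pct) else out


def air_temp_avg(weather: pd.DataFrame, measurement_hour: int,
                 date=None) -> float:
    """Mean air temperature of the four full hours n−5 … n−2.

    ``weather`` needs ``timestamp`` and ``t_air_c`` columns at sub-hourly
    cadence; hourly means are formed first, then averaged over the window.
    The window deliberately ends two hours before the measurement hour so
    the fruit, with its thermal inertia, is compared against the air it
    equilibrated to. Raises :class:`MissingDataError` naming absent hours.
    """
    w = weather.copy()
    ts = pd.to_datetime(w["timestamp"])
    if date is not None:
        day = pd.Timestamp(date).date()
        keep = ts.dt.date == day
        w, ts = w[keep], ts[keep]
    hours_needed = [measurement_hour - 5, measurement_hour - 4,
                    measurement_hour - 3, measurement_hour - 2]
    hourly = w.groupby(ts.dt.hour)["t_air_c"].mean()
    missing = [h for h in hours_needed if h not in hourly.index]
    if missing:
        raise MissingDataError(
            f"weather series lacks hour(s) {missing} needed for the "
            f"T_a window of measurement hour {measurement_hour}")
    return float(hourly.loc[hours_needed].mean())


def fwsi_irmak(t_est, min_t_est: float, t_a: float,
               offset: float = AIR_OFFSET_C):
    """Irmak-style index: (T_Est − minT_Est) / (T_a + offset − minT_Est)."""
    denom = t_a + offset - min_t_est
    if denom == 0:
        raise ZeroDivisionError(
            "degenerate day: air reference equals the day's minimum fruit "
            "temperature")
    t = np.asarray(t_est, dtype=np.float64)
    out = (t - min_t_est) / denom
    return float(out) if np.isscalar(t_est) else out


def fwsi_jones(t_est, wet_t: float, dry_t: float, tolerance: float = 0.1):
    """Jones-style index against wet/dry reference fruit.

    Values outside [0, 1] are legal (and common — the references are
    unreliable on apple) but trigger a warning.
    """
    if abs(dry_t - wet_t) <= tolerance:
        raise ValueError(
            f"wet ({wet_t}) and dry ({dry_t}) references within {tolerance} °C: "
            "degenerate reference pair")
    t = np.asarray(t_est, dtype=np.float64)
    out = (t - wet_t) / (dry_t - wet_t)
    if np.any((out < 0.0) | (out > 1.0)):
        warnings.warn("Jones index outside [0, 1]: wet/dry references "
                      "inconsistent with the fruit temperatures")
    return float(out) if np.isscalar(t_est) else out


def fwsi_norm(t_est, min_t_est: float, max_t_est: float):
    """Normalized index on the day's own extremes; in [0, 1] when t_est is
    drawn from the set that produced the extremes."""
    if not max_t_est > min_t_est:
        raise ValueError("degenerate day: max fruit temperature must exceed min")
    t = np.asarray(t_est, dtype=np.float64)
    out = (t - min_t_est) / (max_t_est - min_t_est)
    return float(out) if np.isscalar(t_est) else out


def delta_t(t_est, t_a):
    """Fruit-minus-air temperature difference, °C."""
    t = np.asarray(t_est, dtype=np.float64)
    out = t - t_a
    return float(out) if np.isscalar(t_est) and np.isscalar(t_a) else out


def index_records(fruit_temps: pd.DataFrame, t_a: float | None = None,
                  vpd_kpa: float | None = None,
                  wet_t: float | None = None, dry_t: float | None = None,
                  offset: float = AIR_OFFSET_C) -> pd.DataFrame:
    """Per-record stress indices from a fruit-temperature table.

    ``fruit_temps`` needs columns ``fruit_id``, ``t_est_c`` and optionally
    ``height_m`` / ``timestamp``. The day extremes are taken over the
    table's own finite temperatures (day-scoped extremes). FWSI_I, ΔT and
    VPD appear only when ``t_a`` (and ``vpd_kpa``) are supplied; FWSI_J only
    with both wet and dry references. FWSI_J carries a "not recommended"
    marker in the frame attrs.
    """
    t = fruit_temps["t_est_c"].to_numpy(dtype=float)
    finite = t[np.isfinite(t)]
    if finite.size < 2 or finite.min() == finite.max():
        raise ValueError("need at least two distinct finite fruit temperatures")
    t_min, t_max = float(finite.min()), float(finite.max())
    out = fruit_temps.copy()
    out["fwsi_n"] = fwsi_norm(t, t_min, t_max)
    if t_a is not None:
        out["fwsi_i"] = fwsi_irmak(t, t_min, t_a, offset=offset)
        out["delta_t_c"] = delta_t(t, t_a)
        out["t_a_c"] = t_a
    if vpd_kpa is not None:
        out["vpd_kpa"] = vpd_kpa
    if wet_t is not None and dry_t is not None:
        out["fwsi_j"] = fwsi_jones(t, wet_t, dry_t)
        out.attrs["fwsi_j_note"] = ("not recommended: wet/dry reference "
                                    "surfaces are unreliable on apple fruit")
    return out


def summarize(records: pd.DataFrame, by: str,
              height_bin_width: float = 0.35,
              height_range: tuple[float, float] = (0.7, 3.0)) -> pd.DataFrame:
    """Grouped descriptive statistics (mean, SD, min, max, n).

    ``by`` is one of ``"date"``, ``"hour"`` (both need a ``timestamp``
    column) or ``"height_bin"`` (needs ``height_m``; bins of
    ``height_bin_width`` metres spanning ``height_range``).
    """
    value_cols = [c for c in ("fwsi_i", "fwsi_j", "fwsi_n", "delta_t_c",
                              "t_est_c", "vpd_kpa") if c in records.columns]
    if by == "date":
        key = pd.to_datetime(records["timestamp"]).dt.date
    elif by == "hour":
        key = pd.to_datetime(records["timestamp"]).dt.hour
    elif by == "height_bin":
        edges = np.arange(height_range[0],
                          height_range[1] + height_bin_width / 2, height_bin_width)
        key = pd.cut(records["height_m"], bins=edges)
    else:
        raise ValueError(f"unknown grouping key {by!r} "
                         "(expected 'date', 'hour' or 'height_bin')")
    grouped = records.groupby(key, observed=True)[value_cols]
    table = grouped.agg(["mean", "std", "min", "max", "count"])
    table.columns = [f"{col}_{stat if stat != 'count' else 'n'}"
                     for col, stat in table.columns]
    table.index.name = by
    return table.reset_index()
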