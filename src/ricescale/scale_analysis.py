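"""Scale statistics, area-ratio analysis and field sensitivity fits.

Quantifies how the monitored characteristic (WRT, root dry weight)
responds to coarsening the LAI observation scale:

* per-scale window statistics of WRT pooled over rice pixels and days of
  the plateau window (DOY 221-236 by default);
* the absolute relative change of each statistic against the 8 m base,
  delta_i = |WRT_i - WRT_8m| / WRT_8m, and its normalization
  Delta_i = delta_i / max_i |delta_i| * 100%;
* the daily two-area ratio Ratio(A/B) = mean WRT over A / mean WRT over
  B at each scale (A is the severely stressed area, so the ratio sits at
  or below 1 once stress differentiates growth);
* soil pollution indices s_i / b_i against regional background values;
* quadratic dose-response fits of field biomarkers on metal
  concentration, whose R^2 ordering identifies WRT as the most
  stress-sensitive characteristic;
* heuristic rules locating the characteristic scale bracket and turning
  point from the Delta profiles and the ratio-by-scale curve.

Standard deviations use the population convention (divide by n).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grids import valid_mask
from .synthetic_data import FieldPlotSample

#: soil concentrations s_i, regional backgrounds b_i (mg kg-1) and severity
#: levels of the two study areas, as published for the field campaign
STUDY_AREA_POLLUTION = {
    "A": {"level": "II-severe",
          "soil": {"Cd": 3.27, "Hg": 0.51, "Pb": 109.93, "As": 18.15}},
    "B": {"level": "I-light",
          "soil": {"Cd": 2.25, "Hg": 0.29, "Pb": 89.67, "As": 18.33}},
}
BACKGROUND_VALUES = {"Cd": 1.43, "Hg": 0.2, "Pb": 82.78, "As": 19.11}


@dataclass
class ScaleStatRecord:
    """One statistic of WRT at one scale with its relative changes."""

    scale_m: float
    stat_name: str
    wrt_i: float
    delta_i: float
    delta_norm_pct: float | None = None

    def __post_init__(self) -> None:
        if self.delta_i < 0:
            raise ValueError("delta must be >= 0")


@dataclass
class RatioRecord:
    """Daily two-area WRT ratio at one scale."""

    doy: int
    scale_m: float
    ratio: float
    m_pixels: int
    n_pixels: int


@dataclass
class PollutionRecord:
    """Soil pollution index of one metal: s_i / b_i."""

    metal: str
    soil_conc: float
    background: float
    index: float
    level: str | None = None


def window_stats(wrt_stack: np.ndarray, doy: np.ndarray,
                 window: tuple[int, int], stat: str = "mean") -> float:
    """One statistic of WRT pooled over all defined pixels and window days.

    ``wrt_stack`` is (n_days, ...) with nodata marking off-field pixels;
    ``stat`` is one of mean/min/max/sd (sd is the population standard
    deviation).  On the WRT plateau the statistic is insensitive to
    whether days or pixels are pooled first.
    """
    doy = np.asarray(doy)
    w0, w1 = window
    sel = (doy >= w0) & (doy <= w1)
    if not np.any(sel):
        raise ValueError(f"empty window DOY {w0}..{w1}")
    values = np.asarray(wrt_stack)[sel]
    values = values[valid_mask(values)]
    if values.size == 0:
        raise ValueError("no defined pixels in window")
    funcs = {"mean": np.mean, "min": np.min, "max": np.max,
             "sd": lambda v: float(np.std(v))}
    if stat not in funcs:
        raise ValueError(f"unknown statistic {stat!r}")
    return float(funcs[stat](values))


def delta(wrt_i: float, wrt_8m: float) -> float:
    """Absolute relative change of a WRT metric against the 8 m base."""
    if wrt_8m == 0:
        raise ValueError("base-scale statistic is zero")
    return abs(wrt_i - wrt_8m) / abs(wrt_8m)


def normalize_delta(deltas) -> np.ndarray:
    """Normalize per-scale deltas to percent of the largest: max is 100%.

    An all-zero profile (perfectly scale-stable statistic) maps to all
    zeros rather than raising.
    """
    d = np.asarray(list(deltas), dtype=float)
    if d.size < 1:
        raise ValueError("need at least one delta")
    peak = np.max(np.abs(d))
    if peak == 0:
        return np.zeros_like(d)
    return d / peak * 100.0


def scale_stat_table(wrt_stacks: dict[float, np.ndarray],
                     doy: np.ndarray, window: tuple[int, int],
                     base_scale_m: float = 8.0) -> list[ScaleStatRecord]:
    """Per-scale, per-statistic WRT records with delta and Delta columns."""
    scales = sorted(wrt_stacks)
    if base_scale_m not in wrt_stacks:
        raise ValueError("base scale missing from stacks")
    records: list[ScaleStatRecord] = []
    for stat in ("mean", "min", "max", "sd"):
        vals = {s: window_stats(wrt_stacks[s], doy, window, stat)
                for s in scales}
        base = vals[base_scale_m]
        if base == 0:
            raise ValueError(f"base-scale {stat} is zero")
        ds = [delta(vals[s], base) for s in scales]
        norm = normalize_delta(ds)
        records += [ScaleStatRecord(s, stat, vals[s], d, n)
                    for s, d, n in zip(scales, ds, norm)]
    return records


def stat_records_frame(records: list[ScaleStatRecord]) -> pd.DataFrame:
    return pd.DataFrame({
        "scale_m": [r.scale_m for r in records],
        "stat": [r.stat_name for r in records],
        "value": [r.wrt_i for r in records],
        "delta": [r.delta_i for r in records],
        "delta_norm_pct": [r.delta_norm_pct for r in records],
    })


def ratio_series(wrt_a: np.ndarray, wrt_b: np.ndarray, doy: np.ndarray,
                 scale_m: float) -> list[RatioRecord]:
    """Daily Ratio(A/B): spatial mean WRT over area A / over area B.

    Both stacks are (n_days, ...) at the same scale and dates.
    """
    wrt_a, wrt_b = np.asarray(wrt_a), np.asarray(wrt_b)
    doy = np.asarray(doy)
    if wrt_a.shape[0] != wrt_b.shape[0] or wrt_a.shape[0] != doy.size:
        raise ValueError("stacks must share dates")
    records = []
    for d in range(doy.size):
        va = wrt_a[d][valid_mask(wrt_a[d])]
        vb = wrt_b[d][valid_mask(wrt_b[d])]
        if va.size < 1 or vb.size < 1:
            raise ValueError("empty area at some date")
        mb = float(np.mean(vb))
        if mb == 0:
            raise ValueError("zero denominator: area B mean WRT is 0")
        records.append(RatioRecord(doy=int(doy[d]), scale_m=scale_m,
                                   ratio=float(np.mean(va)) / mb,
                                   m_pixels=int(va.size),
                                   n_pixels=int(vb.size)))
    return records


def ratio_frame(records: list[RatioRecord]) -> pd.DataFrame:
    return pd.DataFrame({
        "doy": [r.doy for r in records],
        "scale_m": [r.scale_m for r in records],
        "ratio": [r.ratio for r in records],
        "m_pixels": [r.m_pixels for r in records],
        "n_pixels": [r.n_pixels for r in records],
    })


def pollution_index(s_i: float, b_i: float, metal: str = "",
                    level: str | None = None) -> PollutionRecord:
    """Pollution index s_i / b_i (reported at 2-decimal rounding)."""
    if b_i <= 0:
        raise ValueError("background value must be positive")
    if s_i < 0:
        raise ValueError("soil concentration must be >= 0")
    return PollutionRecord(metal=metal, soil_conc=s_i, background=b_i,
                           index=round(s_i / b_i, 2), level=level)


def pollution_table() -> pd.DataFrame:
    """Pollution indices of the two study areas from the published
    soil and background concentrations."""
    rows = []
    for area, info in STUDY_AREA_POLLUTION.items():
        for metal, s in info["soil"].items():
            rec = pollution_index(s, BACKGROUND_VALUES[metal], metal,
                                  info["level"])
            rows.append({"area": area, "metal": metal, "soil": s,
                         "background": rec.background, "index": rec.index,
                         "level": rec.level})
    return pd.DataFrame(rows)


def sensitivity_fit(samples: list[FieldPlotSample], biomarker: str,
                    metal: str) -> tuple[np.ndarray, float]:
    """OLS quadratic dose-response: biomarker ~ conc + conc^2.

    Returns (coefficients [intercept, linear, quadratic], R^2).  Across
    biomarkers the R^2 ranking reflects their stress sensitivity; on the
    synthetic plots WRT couples most strongly.
    """
    if len(samples) < 4:
        raise ValueError("need at least 4 samples")
    names = {"lai": "lai", "chlorophyll": "chlorophyll", "wrt": "wrt_g",
             "wrt_g": "wrt_g"}
    if biomarker not in names:
        raise ValueError(f"unknown biomarker {biomarker!r}")
    y = np.array([getattr(s, names[biomarker]) for s in samples])
    c = np.array([getattr(s, {"as": "as_conc"}.get(metal, metal))
                  for s in samples])
    X = np.column_stack([np.ones_like(c), c, c**2])
    if np.linalg.matrix_rank(X) < 3:
        raise ValueError("rank-deficient design: concentrations degenerate")
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    return coef, r2


def find_characteristic_scale(delta_profiles: dict[str, np.ndarray],
                              scales_m, ratio_by_scale=None,
                              stability_threshold_pct: float = 10.0
                              ) -> dict:
    """Locate the characteristic-scale bracket from Delta profiles.

    Rules (explicit, configurable heuristics):

    * lower bound: the largest scale up to which the mean-statistic
      Delta stays within ``stability_threshold_pct`` at every scale;
    * turning point: the scale with the largest consecutive Delta jump
      of the mean statistic (None when the profile is flat);
    * upper bound: the scale following the turning point (the bracket's
      open end);
    * additionally the scale minimizing the end-of-window A/B ratio,
      when a ratio-by-scale curve is given.
    """
    scales = np.asarray(list(scales_m), dtype=float)
    mean_delta = np.asarray(delta_profiles["mean"], dtype=float)
    if mean_delta.size != scales.size:
        raise ValueError("profile and scale list must align")

    stable = mean_delta <= stability_threshold_pct
    lower = None
    for i in range(scales.size):
        if stable[: i + 1].all():
            lower = float(scales[i])
    jumps = np.diff(mean_delta)
    if mean_delta.size < 2 or np.all(jumps == 0):
        turning = None
        upper = None
        flat = True
    else:
        k = int(np.argmax(jumps)) + 1
        turning = float(scales[k])
        upper = float(scales[k + 1]) if k + 1 < scales.size else float(
            scales[k])
        flat = False
    out = {"lower_bound_m": lower, "upper_bound_m": upper,
           "turning_point_m": turning, "flat_profile": flat,
           "rule": {"stability_threshold_pct": stability_threshold_pct,
                    "turning": "largest consecutive jump of mean Delta",
                    "lower": "largest scale with all mean Delta below "
                             "threshold"}}
    if ratio_by_scale is not None:
        ratios = np.asarray(list(ratio_by_scale), dtype=float)
        out["ratio_argmin_m"] = float(scales[int(np.argmin(ratios))])
    return out
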