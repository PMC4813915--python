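"""Synthetic study inputs: weather, stress fields, scenes and field plots.

The real campaign (two 1.28 km x 1.28 km rice paddies in a subtropical
industrial region, 8 m multispectral imagery on DOY 166/199/240, 40
field plots per area) is not publicly deposited, so every input is
emulated here:

* ``generate_meteo`` - a seasonal sinusoid with seeded daily noise
  matching a subtropical monsoon station (annual mean ~17.5 degC,
  summer daily means in the high 20s).
* ``generate_stress_field`` - spatially correlated stress-factor grids
  at two severity presets.  The study never prints its recovered
  per-pixel factors, so the preset means (combined factor ~0.72 severe,
  ~0.90 light) are synthetic conventions inside the admissible
  (0.65, 1) range, chosen to separate the two areas' root-growth curves.
* ``scene_from_lai`` - the exact forward model of the retrieval chain:
  invert the exponential LAI transfer to GBNDVI, fix green/blue band
  baselines, and solve the index equation for NIR.  With zero noise the
  retrieval round-trip reproduces the input LAI to machine precision.
* ``generate_field_plots`` - plot samples whose LAI / root dry weight /
  chlorophyll respond quadratically (negative trend) to lognormal metal
  concentrations, calibrated so large-sample moments match the field
  campaign (LAI mean 3.09 sd 1.43; WRT mean 12.12 g sd 4.70 g;
  chlorophyll spanning 5.85-45.82 ug cm-2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, optimize

from .grids import ReflectanceScene, StressField
from .lai_retrieval import TransferFunction
from .meteo import MeteoSeries

# ---------------------------------------------------------------------------
# meteorology

#: climate presets: (annual mean degC, seasonal amplitude degC, DOY of peak,
#: diurnal range degC, radiation mean/amplitude MJ m-2)
CLIMATE_PRESETS = {
    "zhuzhou": dict(t_mean=17.5, t_amp=11.5, t_peak_doy=205, dtr=8.0,
                    rad_mean=13.0, rad_amp=7.0, rad_peak_doy=172),
}

SEASON_START_DOY = 150
SEASON_END_DOY = 280


def generate_meteo(year_profile: str = "zhuzhou", n_days: int = 365,
                   seed: int = 0, noise_sd_t: float = 1.5,
                   noise_sd_rad: float = 2.0) -> MeteoSeries:
    """Seeded daily weather for one year from a sinusoidal climate preset."""
    if year_profile not in CLIMATE_PRESETS:
        raise ValueError(f"unknown climate preset {year_profile!r}")
    if n_days < SEASON_END_DOY:
        raise ValueError("season not covered: need n_days >= "
                         f"{SEASON_END_DOY} (rice season DOY "
                         f"{SEASON_START_DOY}-{SEASON_END_DOY})")
    p = CLIMATE_PRESETS[year_profile]
    rng = np.random.default_rng(seed)
    doy = np.arange(1, n_days + 1)
    tmean = p["t_mean"] + p["t_amp"] * np.cos(
        2 * np.pi * (doy - p["t_peak_doy"]) / 365.0)
    tmean = tmean + noise_sd_t * rng.standard_normal(n_days)
    rad = p["rad_mean"] + p["rad_amp"] * np.cos(
        2 * np.pi * (doy - p["rad_peak_doy"]) / 365.0)
    rad = np.maximum(0.5, rad + noise_sd_rad * rng.standard_normal(n_days))
    half = 0.5 * p["dtr"]
    return MeteoSeries(doy, tmean - half, tmean + half, rad)


# ---------------------------------------------------------------------------
# stress fields

#: severity presets: target spatial mean of the combined factor f_comb
STRESS_PRESETS = {"severe": 0.72, "light": 0.90}


def _correlated_field(shape: tuple[int, int], corr_length_px: int,
                      rng: np.random.Generator) -> np.ndarray:
    """Zero-mean unit-variance field with moving-average correlation."""
    z = rng.standard_normal(shape)
    if corr_length_px > 1:
        z = ndimage.uniform_filter(z, size=corr_length_px, mode="reflect")
    sd = z.std()
    if sd > 0:
        z = (z - z.mean()) / sd
    return z


def generate_stress_field(shape: tuple[int, int], area_level: str,
                          corr_length_px: int = 5, seed: int = 0,
                          sd: float = 0.03, pixel_size_m: float = 8.0,
                          area_label: str | None = None) -> StressField:
    """Spatially correlated stress factors at a severity preset.

    Each factor grid is smoothed seeded Gaussian noise, affinely mapped
    to mean sqrt(target f_comb) with standard deviation ``sd`` and
    clamped into [0.65, 1]; the product grid then has spatial mean close
    to the preset target (0.72 severe, 0.90 light).  ``sd = 0`` gives a
    constant field at the preset mean.
    """
    if area_level not in STRESS_PRESETS:
        raise ValueError(f"unknown area level {area_level!r}; "
                         f"use one of {sorted(STRESS_PRESETS)}")
    if corr_length_px < 1:
        raise ValueError("corr_length_px must be >= 1")
    h, w = shape
    if h <= 0 or w <= 0:
        raise ValueError("shape must be positive")
    mu = float(np.sqrt(STRESS_PRESETS[area_level]))
    rng = np.random.default_rng(seed)
    grids = []
    for _ in range(2):
        if sd == 0:
            grids.append(np.full(shape, mu))
        else:
            z = _correlated_field(shape, corr_length_px, rng)
            grids.append(np.clip(mu + sd * z, 0.65, 1.0))
    label = area_label or ("A" if area_level == "severe" else "B")
    return StressField(grids[0], grids[1], area_label=label,
                       pixel_size_m=pixel_size_m)


# ---------------------------------------------------------------------------
# reflectance scenes

#: fixed band baselines for scene synthesis (green, blue reflectance)
BAND_BASELINES = {"green": 0.08, "blue": 0.06, "red": 0.05}


def scene_from_lai(lai_grid: np.ndarray, doy: int, pixel_size_m: float = 8.0,
                   transfer: TransferFunction | None = None,
                   band_baselines: dict | None = None,
                   noise_sd: float = 0.0, seed: int = 0) -> ReflectanceScene:
    """Forward model: reflectance scene whose retrieval returns ``lai_grid``.

    The exponential transfer is inverted exactly, x = ln(y/a)/b, and NIR
    solved from the index definition with fixed green/blue baselines:
    NIR = (G + B)(1 + x)/(1 - x).  Optional Gaussian reflectance noise is
    added to every band and clipped to [0, 1].
    """
    tf = transfer or TransferFunction()
    bb = dict(BAND_BASELINES, **(band_baselines or {}))
    lai = np.asarray(lai_grid, dtype=float)
    if np.any(lai < tf.min_lai):
        raise ValueError("LAI below the transfer's minimum representable "
                         f"value {tf.min_lai:.4g} (GBNDVI would be < -1)")
    x = tf.inverse(lai)
    gb = bb["green"] + bb["blue"]
    if np.any(x >= 1) or np.any(gb * (1 + x) / (1 - x) > 1):
        raise ValueError("LAI too large for baselines: required NIR "
                         "reflectance exceeds 1")
    nir = gb * (1 + x) / (1 - x)
    bands = {"blue": np.full_like(lai, bb["blue"]),
             "green": np.full_like(lai, bb["green"]),
             "red": np.full_like(lai, bb["red"]),
             "nir": nir}
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        for k in bands:
            bands[k] = np.clip(
                bands[k] + noise_sd * rng.standard_normal(lai.shape), 0, 1)
    return ReflectanceScene(doy=doy, pixel_size_m=pixel_size_m, **bands)


# ---------------------------------------------------------------------------
# field plots

#: large-sample target moments of the field campaign
FIELD_MOMENTS = {
    "lai": (3.09, 1.43),
    "wrt_g": (12.12, 4.70),
    "chlorophyll": (25.84, 8.0),   # centre/scale of the 5.85-45.82 range
}

#: lognormal parameters (mu, sigma of log) for tissue metal concentrations,
#: spanning the two areas' printed tissue means (e.g. Cd 3.23-5.9 mg/kg)
TISSUE_LOGNORMAL = {
    "cd": (np.log(4.0), 0.5),
    "hg": (np.log(0.05), 0.5),
    "pb": (np.log(23.0), 0.4),
    "as_conc": (np.log(6.6), 0.3),
}

#: soil concentrations (lognormal) and fixed regional background values
SOIL_LOGNORMAL = {
    "cd": (np.log(2.7), 0.3), "hg": (np.log(0.38), 0.4),
    "pb": (np.log(98.0), 0.2), "as_conc": (np.log(18.2), 0.15),
}
BACKGROUND = {"cd": 1.43, "hg": 0.2, "pb": 82.78, "as_conc": 19.11}

#: default quadratic dose-response (b1, b2) on the Cd dose and the
#: correlation strength of each biomarker with the dose response; the
#: root dry weight is the most strongly coupled biomarker
DEFAULT_STRESS_RESPONSE = {"b1": -1.0, "b2": -0.15}
BIOMARKER_COUPLING = {"wrt_g": 0.90, "lai": 0.75, "chlorophyll": 0.60}


@dataclass
class FieldPlotSample:
    """One field plot: biomarkers plus tissue/soil metal concentrations."""

    plot_id: int
    lai: float
    chlorophyll: float   # ug cm-2
    wrt_g: float         # g per plant
    cd: float            # tissue concentrations, mg kg-1
    hg: float
    pb: float
    as_conc: float
    soil_conc: dict = field(default_factory=dict)    # mg kg-1 per metal
    background: dict = field(default_factory=dict)   # mg kg-1 per metal

    def __post_init__(self) -> None:
        for v in (self.lai, self.chlorophyll, self.wrt_g, self.cd,
                  self.hg, self.pb, self.as_conc):
            if v < 0:
                raise ValueError("concentrations and biomarkers must be >= 0")


def _truncated_with_moments(latent: np.ndarray, mean: float,
                            sd: float) -> np.ndarray:
    """max(0, m + s*latent) with (m, s) solved so the truncated sample
    matches the target mean and (population) sd.

    Truncation at zero otherwise biases the moments (upward mean,
    shrunken sd), noticeably so for the left-skewed dose response.
    Falls back to the naive affine map when the latent is degenerate or
    the solver cannot match (e.g. extreme targets).
    """
    if latent.std() == 0:
        return np.maximum(0.0, mean + sd * latent)

    def resid(x):
        y = np.maximum(0.0, x[0] + x[1] * latent)
        return [y.mean() - mean, y.std() - sd]

    sol, info, ok, _ = optimize.fsolve(resid, [mean, sd], full_output=True)
    if not ok or sol[1] <= 0:
        return np.maximum(0.0, mean + sd * latent)
    return np.maximum(0.0, sol[0] + sol[1] * latent)


def generate_field_plots(n_plots: int,
                         stress_response: dict | None = None,
                         seed: int = 0,
                         noise_sd: float = 1.0) -> list[FieldPlotSample]:
    """Seeded field-plot samples with quadratic metal dose-response.

    Tissue metals are lognormal (Cd and Hg share a common latent
    pollution factor so both correlate with the biomarkers); each
    biomarker mixes the sample-standardized quadratic Cd response with
    independent unit noise at its coupling strength, then is rescaled
    to the campaign's moments and truncated at zero.  Sample moments
    therefore converge to the configured moments as n grows (truncation
    contributes a small upward mean bias, well under the biomarkers'
    sampling error at n = 10^4).  ``noise_sd``
    scales the biomarkers' idiosyncratic noise relative to its
    calibrated level; at 0 with zero quadratic terms every plot gets
    identical biomarkers.
    """
    if n_plots < 2:
        raise ValueError("need at least 2 plots")
    sr = dict(DEFAULT_STRESS_RESPONSE, **(stress_response or {}))
    b1, b2 = sr["b1"], sr["b2"]
    rng = np.random.default_rng(seed)

    # shared pollution factor induces cross-metal correlation
    common = rng.standard_normal(n_plots)
    tissue = {}
    for metal, (mu, sigma) in TISSUE_LOGNORMAL.items():
        own = rng.standard_normal(n_plots)
        z = np.sqrt(0.6) * common + np.sqrt(0.4) * own
        tissue[metal] = np.exp(mu + sigma * z)
    soil = {m: np.exp(mu + sigma * rng.standard_normal(n_plots))
            for m, (mu, sigma) in SOIL_LOGNORMAL.items()}

    c = tissue["cd"]
    q = b1 * c + b2 * c**2
    q_sd = q.std()
    qz = (q - q.mean()) / q_sd if q_sd > 0 else np.zeros(n_plots)

    bio = {}
    for name, (mean, sd) in FIELD_MOMENTS.items():
        alpha = BIOMARKER_COUPLING[name]
        eps = rng.standard_normal(n_plots)
        latent = alpha * qz + noise_sd * np.sqrt(1 - alpha**2) * eps
        bio[name] = _truncated_with_moments(latent, mean, sd)

    return [FieldPlotSample(
        plot_id=i, lai=float(bio["lai"][i]),
        chlorophyll=float(bio["chlorophyll"][i]),
        wrt_g=float(bio["wrt_g"][i]), cd=float(tissue["cd"][i]),
        hg=float(tissue["hg"][i]), pb=float(tissue["pb"][i]),
        as_conc=float(tissue["as_conc"][i]),
        soil_conc={m: float(soil[m][i]) for m in soil},
        background=dict(BACKGROUND)) for i in range(n_plots)]


def field_plots_frame(plots: list[FieldPlotSample]) -> pd.DataFrame:
    """Tabulate plots with the standard CSV column layout."""
    return pd.DataFrame({
        "plot_id": [p.plot_id for p in plots],
        "lai": [p.lai for p in plots],
        "chlorophyll_ug_cm2": [p.chlorophyll for p in plots],
        "wrt_g": [p.wrt_g for p in plots],
        "cd": [p.cd for p in plots],
        "hg": [p.hg for p in plots],
        "pb": [p.pb for p in plots],
        "as": [p.as_conc for p in plots],
    })
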