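# Methods

## Overview

The package asks at which spatial resolution a crop characteristic simulated
through remote-sensing data assimilation — here the dry weight of roots
(WRT) of rice under heavy-metal stress — remains a stable, informative
monitoring signal. Because the original imagery and field campaign are not
publicly available, the pipeline runs on synthetic inputs generated to match
the documented study conditions; the package's claims are therefore about
the *method chain* (retrieval → upscaling → assimilation → scale
statistics), not about reproducing field magnitudes.

## Crop model

A reduced-form daily simulator in the WOFOST tradition, potential-production
mode (growth limited by temperature and radiation only):

* **Phenology.** Development stage DVS accumulates effective temperature
  `max(0, (Tmax+Tmin)/2 − T_base)` from the day after emergence;
  DVS = TSUM/TSUM1 up to anthesis (DVS 1), then 1 + (TSUM−TSUM1)/TSUM2,
  capped at 2 (maturity).
* **Assimilation.** Gross daily assimilation uses a light-use-efficiency
  form with Beer's-law interception:
  `E_gp = ε_g · 0.5·R_g · (1 − e^{−k·LAI})` (g CH₂O m⁻² d⁻¹), with PAR
  taken as half of global radiation. This replaces WOFOST's three-point
  Gaussian canopy integration: none of the original model's internals are
  published in the source material, and the reduced form keeps every term
  unit-checked and testable while preserving the structure the stress
  factors act on. It is a deliberate simplification; absolute magnitudes of
  organ weights are not claimed to match any field axis.
* **Maintenance respiration.** Q10 form,
  `R_m = q10^{(T−25)/10} Σ c_o W_o`, with small organ coefficients
  (0.010/0.006/0.004/0.003 g CH₂O g⁻¹ d⁻¹ for leaf/stem/root/storage).
  Maintenance is what makes the two stress factors not perfectly
  confounded; the coefficients are kept small so the product `f_comb`
  dominates (see identifiability below).
* **Growth and partitioning.** Net CH₂O `max(0, E_gs − R_m)` converts to dry
  matter with efficiency `y_g = 0.7` and is split over roots / leaves /
  stems / storage organs by a DVS-indexed table (linear interpolation
  between knots; rows sum to 1). The root fraction is zero from anthesis
  on, so WRT rises monotonically and then holds a constant maximum — the
  plateau on which the scale statistics are computed.
* **Leaf area and senescence.** `LAI = SLA · W_leaf` (SLA 0.025 m² g⁻¹). A
  linear LAI drain of 0.08 d⁻¹ starts once DVS exceeds 1.3, moving leaf
  mass into a dead pool (mass is conserved exactly; the conservation
  identity is asserted to 1e−10 per day in tests).
* **Stress.** `E_gs = f_g·E_gp` and the conversion step is scaled by `f_c`,
  both factors constant over the season per pixel, bounds treated as the
  closed box [0.65, 1] so the optimizer has attainable extremes.

Default phenology (T_base 8 °C, TSUM1 1200 °C·d, TSUM2 550 °C·d, emergence
DOY 155) places anthesis near DOY 217 under the synthetic subtropical
weather, so the WRT plateau covers the DOY 221–236 analysis window with
margin for weather-seed variation.

## Synthetic inputs

* **Weather** — sinusoidal annual cycles for temperature (mean 17.5 °C,
  amplitude 11.5 °C, peak DOY 205, diurnal range 8 °C) and radiation (13 ±
  7 MJ m⁻² d⁻¹) with seeded Gaussian daily noise (sd 1.5 °C / 2 MJ),
  emulating a subtropical monsoon station; summer (DOY 170–240) daily means
  fall in 24–32 °C.
* **Stress fields** — per-factor grids of moving-average-smoothed white
  noise (correlation length 5 px), standardized, mapped to mean
  `sqrt(target f_comb)` with sd 0.03 and clamped to [0.65, 1]. The severity
  presets (mean `f_comb` 0.72 severe / 0.90 light) are **synthetic
  conventions**: the original study never prints its recovered per-pixel
  factors, so the presets are chosen inside the admissible range to
  produce clearly separated WRT curves. Clamping (not resampling) keeps
  generation deterministic and order-independent.
* **Scenes** — the retrieval chain inverted exactly: `x = ln(y/a)/b`, green
  and blue reflectance fixed at 0.08/0.06, `NIR = (G+B)(1+x)/(1−x)`, red
  constant (no equation uses it). With zero added noise the retrieval
  round-trip is the identity to machine precision, so "noiseless
  observations" in tests mean exactly that.
* **Field plots** — tissue metal concentrations are lognormal (positive,
  right-skewed; Cd and Hg share a latent pollution factor), biomarkers are
  negative quadratic responses to the Cd dose plus independent noise,
  mixed at per-biomarker coupling strengths (WRT 0.90 > LAI 0.75 >
  chlorophyll 0.60) so the dose–response R² ranking puts WRT first. The
  pre-truncation location/scale of each biomarker is solved numerically so
  that the zero-truncated sample matches the campaign moments (LAI
  3.09/1.43; WRT 12.12/4.70 g; chlorophyll centred on its 5.85–45.82
  µg cm⁻² range) — naive truncation would bias the mean up and shrink the
  sd, noticeably so for the left-skewed dose response.

What the generator does **not** emulate: sensor PSF/MTF, atmospheric and
georeferencing effects, mixed land-cover pixels, within-season variation of
the stress factors, and any spatial structure beyond stationary
moving-average correlation. Passing tests therefore demonstrate the internal
consistency and recovery behaviour of the method chain under idealized
observation conditions, not performance on real imagery.

## Assimilation

The cost is the mean squared LAI misfit over the observation dates. Each
scale is assimilated **independently** (the per-scale reading of the
multi-scale cost): separate per-scale WRT maps require per-scale optima; a
joint objective over all scales would return a single factor pair and no
scale differentiation.

PSO: 20 particles, 50 iterations, inertia 0.72, cognitive = social = 1.49,
velocities initialized to zero, positions clamped to the box, early stop at
cost ≤ 1e−6. All randomness is pre-drawn per pixel from
`seed + row-major flat index`, which makes the raster path exactly equal to
running the scalar optimizer per pixel and independent of visiting order.
The vectorized implementation runs every pixel's swarm in lock-step through
the daily model (a converged pixel's swarm freezes), which is what makes
per-pixel assimilation at six scales tractable on one CPU.

**Identifiability.** `f_g` and `f_c` act nearly multiplicatively on growth;
only maintenance respiration separates them. Recovery claims are therefore
made for `f_comb` only (±0.02 on noiseless observations for ≥95 % of
pixels, verified against a 0.005-step exhaustive grid search), and a paired
run with swapped factors (0.8, 0.9) vs (0.9, 0.8) changes final WRT by
under 2 %.

## Scale analysis

Statistics (mean/min/max/sd, population convention for sd) pool all rice
pixels × all days of the DOY 221–236 window; because WRT is exactly constant
on the plateau, the pooling order is numerically inert (asserted in tests).
`δᵢ` is the absolute relative change against the 8 m base; `Δᵢ` normalizes
by the per-statistic maximum so every profile peaks at exactly 100 % (an
all-zero profile is returned as all zeros and flagged). The two-area ratio
uses area A (severe) in the numerator, so it sits at or below 1 once stress
differentiates growth.

The characteristic-scale rules are explicit heuristics, configurable rather
than fitted: lower bound = largest scale up to which the mean-statistic Δ
stays within 10 %; turning point = scale with the largest consecutive Δ
jump; upper bound = the next scale after the turning point; plus the argmin
of the window-mean ratio across scales. On the original field data these
rules bracket 64–256 m with a 128 m turning point; on clean synthetic data
the Δ profile is dominated by tiny recovery residuals, so the verdict is
reported with the rule used rather than claimed as a field result.

Pollution indices are computed exactly as soil concentration / regional
background and reported at 2 decimals; ratios at 2 decimals and Δ at 1
decimal match the conventional reporting precision.

## Numerical choices

* Nodata sentinel −9999 everywhere, propagated through every per-pixel map;
  block means average the defined cells of a block and are nodata only for
  all-nodata blocks (avoids eroding field edges).
* Upscaling is a single hop from the 8 m base for every scale — identical
  to cascaded 2× aggregation for block means (asserted to 1e−12) with
  simpler provenance. Row-major grids, origin top-left, factor-of-two
  scales only.
* The transfer fit log-linearizes (OLS of ln LAI on the index): closed-form
  and deterministic; R² is reported on the original LAI scale, where the
  calibration quality is conventionally quoted. Whether the original
  calibration used log-linear or nonlinear least squares is not documented.
* The desk-scale default grid is 32 × 32 base pixels — the smallest grid
  divisible by every aggregation factor up to 32, so all six scales exist;
  the documented full setting is 160 × 160. Tests and the acceptance
  checks use 8×8–40×40 grids accordingly.
* Rasters are float32 TIFFs with pixel size / DOY / nodata / band order in
  a JSON description tag — a deliberately minimal raster convention
  sufficient for regular single-extent grids.

## Known limitations

* The crop model is structural, not calibrated to a cultivar; organ-weight
  magnitudes are arbitrary to within the parameter defaults.
* Constant-in-time stress factors; no water, nutrient, pest or senescence
  stress pathways beyond the leaf drain.
* The characteristic-scale verdict on synthetic data reflects the synthetic
  spatial structure; it validates the machinery, not the field bracket.
* Individual `f_g`/`f_c` are not identifiable from LAI alone; only their
  product is interpreted.
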