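# ricescale

Characteristic spatial scale for monitoring heavy-metal stress in rice by
crop-model data assimilation.

## The problem

Heavy-metal contamination of paddy soils depresses rice growth, and the dry
weight of roots (WRT) is one of the most stress-sensitive plant
characteristics — roots are the first organ in contact with the polluted
soil. WRT cannot be observed from space, but the leaf area index (LAI) can:
retrievals from multispectral imagery can be assimilated into a daily crop
growth model that carries a WRT state. Because satellite products come at
many pixel sizes, the practical question is *at which spatial scale WRT-based
stress monitoring is still reliable, and where it breaks down* — the
**characteristic scale** of the monitored quantity.

`ricescale` implements that analysis end to end on synthetic data that
emulate the original field setting (two 1.28 km × 1.28 km rice areas in a
subtropical industrial region, one severely and one lightly polluted,
observed on DOY 166, 199 and 240):

1. **LAI retrieval** — the green–blue normalized difference vegetation index
   `GBNDVI = (NIR − (G + B)) / (NIR + G + B)` is mapped to LAI by the
   calibrated exponential transfer `y = 1.682·e^{3.276·x}` (R² = 0.841 in the
   original calibration).
2. **Upscaling** — retrieved 8 m LAI is aggregated by block mean to 16, 32,
   64, 128 and 256 m ("retrieve-then-aggregate", the exact-LAI scheme).
3. **Crop model** — a daily-step, WOFOST-style potential-production rice
   simulator in which heavy-metal stress enters as two multiplicative
   factors on gross assimilation and on the carbohydrate→dry-matter
   conversion:
   `E_gs(t) = f_g · E_gp(t)`, `E_cs(t) = f_c · E_cp(t)`,
   `f_comb = f_g · f_c`, with `f_g, f_c ∈ [0.65, 1]`.
4. **Assimilation** — per pixel, particle-swarm optimization (PSO) finds the
   `(f_g, f_c)` minimizing the LAI cost
   `C = (1/N) Σᵢ (LAI_obs(tᵢ) − LAI_sim(tᵢ))²` over the N observation
   dates; the model re-run at the optimum yields daily WRT per pixel.
5. **Scale analysis** — per-scale WRT statistics over the plateau window
   (DOY 221–236), their absolute relative change against the 8 m base
   `δᵢ = |WRTᵢ − WRT₈ₘ| / WRT₈ₘ`, the normalized profile
   `Δᵢ = δᵢ / maxᵢ|δᵢ| × 100 %`, and the daily two-area ratio
   `Ratio(A/B) = mean WRT over A / mean WRT over B`, from which the
   characteristic-scale bracket and turning point are derived. Soil
   pollution indices `sᵢ/bᵢ` and quadratic biomarker dose–response fits
   round out the field analysis.

## Worked example

```python
from ricescale import RunConfig, run_experiment

report = run_experiment(RunConfig(seed=1, out_dir="results/experiment"))
print(report["ratio_window_mean_by_scale"]["8"])   # 0.646...
print(report["characteristic_scale"]["ratio_argmin_m"])
```

This runs the default desk-scale experiment (32 × 32 base pixels at 8 m, all
six scales, ~25 s). With seed 1 it prints, among other things:

```
area A (severe): truth mean f_comb 0.720
area B (light):  truth mean f_comb 0.899
area A scale   8 m: recovered mean f_comb 0.720
area B scale   8 m: recovered mean f_comb 0.899
window-mean Ratio(A/B) by scale: {8: 0.646, 16: 0.646, 32: 0.646, 64: 0.646, 128: 0.646, 256: 0.647}
```

The severely stressed area recovers a combined stress factor of 0.72 versus
0.90 for the lightly stressed one — exactly the synthetic truth — and its
plateau WRT is ~65 % of the healthy area's at every scale. On noiseless
synthetic observations the per-pixel `f_comb` is recovered within ±0.02
almost everywhere; the individual `f_g` and `f_c` are only weakly
identifiable (their product drives growth), which is expected and tested as
such.

The same pipeline can be run stage by stage as numbered scripts:

```
python analysis/01_simulate_scenes.py      # weather, stress fields, scenes
python analysis/02_retrieve_and_upscale.py # GBNDVI -> LAI -> pyramid
python analysis/03_assimilate.py           # per-pixel PSO at all 6 scales
python analysis/04_scale_analysis.py       # delta/Delta, ratios, verdict
python analysis/05_field_sensitivity.py    # plot moments, R^2 ranking, indices
```

or from the shell via the `ricescale` console script (`simulate-scene`,
`retrieve-lai`, `upscale`, `assimilate`, `run`).

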