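"""Stage 1 - synthesize the study inputs.

Generates one year of daily weather for the subtropical study region,
spatially correlated stress-factor fields for the severely (A) and
lightly (B) polluted areas, runs the stressed crop model per pixel, and
forward-models 4-band reflectance scenes at the three observation dates
(DOY 166, 199, 240).  Writes everything under results/experiment/.
"""

import logging
from pathlib import Path

import numpy as np

from ricescale.grids import write_raster, write_scene
from ricescale.pipeline import RunConfig, simulate_observations

logging.basicConfig(level=logging.INFO, format="%(message)s")

OUT = Path("results/experiment")


def main() -> None:
    cfg = RunConfig(seed=1, out_dir=OUT)
    OUT.mkdir(parents=True, exist_ok=True)
    sim = simulate_observations(cfg)
    sim["meteo"].to_csv(OUT / "meteo.csv")
    summer = sim["meteo"].slice_doy(170, 240).tmean_c.mean()
    print(f"meteo: {len(sim['meteo'])} days, summer mean {summer:.1f} degC")
    for label, area in sim["areas"].items():
        truth = area["truth"]
        write_raster(OUT / f"truth_fg_{label}.tif", truth.fg_grid,
                     cfg.base_pixel_m)
        write_raster(OUT / f"truth_fc_{label}.tif", truth.fc_grid,
                     cfg.base_pixel_m)
        for t, scene in area["scenes"].items():
            write_scene(OUT / f"scene_{label}_doy{t}.tif", scene)
        lai166 = area["lai8"][166].grid
        print(f"area {label} ({area['level']}): truth mean f_comb "
              f"{truth.fcomb_grid.mean():.3f}, LAI@166 "
              f"{lai166.mean():.2f}, LAI@199 "
              f"{area['lai8'][199].grid.mean():.2f}, LAI@240 "
              f"{np.mean(area['lai8'][240].grid):.2f}")


if __name__ == "__main__":
    main()
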