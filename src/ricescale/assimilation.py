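"""Per-pixel stress-factor inversion by particle swarm optimization.

For every rice pixel the pair (f_g, f_c) is sought that minimizes the
squared-LAI cost over the N observation dates,

    C = (1/N) * sum_i (LAI_obs(t_i) - LAI_sim(t_i))^2,

with the simulated LAI read from the crop model run under the candidate
factors.  Each spatial scale is assimilated independently (one scale per
run), which is what yields per-scale WRT maps.  The optimizer is a
standard global-best particle swarm with inertia/cognitive/social
velocity terms, positions clamped to the admissible box [0.65, 1]^2.

Only the combined factor f_comb = f_g * f_c is claimed recoverable: the
two factors act nearly multiplicatively on growth (maintenance
respiration breaks the symmetry only weakly), so the cost surface has a
ridge of near-constant f_comb.

Per-pixel seeds are the run seed plus the pixel's row-major flat index,
so results do not depend on pixel visiting order, and the scalar
single-pixel optimizer and the vectorized raster path are exactly
equivalent (all swarm randomness is pre-drawn in a fixed order).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .crop_model import STRESS_MAX, STRESS_MIN, CropParams, simulate_batch
from .grids import NODATA, LAIRaster, StressField, valid_mask
from .meteo import MeteoSeries

#: default plateau analysis window (day-of-year, inclusive)
DEFAULT_WINDOW = (221, 236)


@dataclass
class CostEvaluation:
    """One evaluation of the assimilation cost."""

    c_value: float
    n_dates: int
    dates: tuple[int, ...]
    scale_m: float | None = None

    def __post_init__(self) -> None:
        if self.c_value < 0:
            raise ValueError("cost must be >= 0")


@dataclass
class PSOConfig:
    """Swarm settings; defaults are the package's reference configuration."""

    n_particles: int = 20
    n_iter: int = 50
    inertia: float = 0.72
    c1: float = 1.49
    c2: float = 1.49
    bounds: tuple[tuple[float, float], tuple[float, float]] = (
        (STRESS_MIN, STRESS_MAX), (STRESS_MIN, STRESS_MAX))
    seed: int = 0
    tol: float = 1e-6

    def __post_init__(self) -> None:
        if self.n_particles < 2:
            raise ValueError("need at least 2 particles")
        for lo, hi in self.bounds:
            if lo < STRESS_MIN or hi > STRESS_MAX or lo >= hi:
                raise ValueError("bounds must lie within [0.65, 1]")


@dataclass
class AssimilationResult:
    """Recovered stress field plus simulated root-weight rasters."""

    stress: StressField
    cost_map: np.ndarray
    wrt_daily: np.ndarray          # (n_days, H, W), nodata off-field
    doy: np.ndarray                # (n_days,)
    wrt_window: np.ndarray         # window-mean WRT raster (H, W)
    window: tuple[int, int]
    scale_m: float


def _lai_at_dates(params: CropParams, meteo: MeteoSeries,
                  f_g: np.ndarray, f_c: np.ndarray,
                  dates: tuple[int, ...]) -> np.ndarray:
    """Simulated LAI (n_dates, n) at the observation dates."""
    out = simulate_batch(params, meteo, f_g, f_c)
    doy = out["doy"]
    idx = []
    for t in dates:
        if not (doy[0] <= t <= doy[-1]):
            raise ValueError(f"observation date DOY {t} outside simulated "
                             f"season {doy[0]}..{doy[-1]}")
        idx.append(int(t - doy[0]))
    return out["lai"][idx, :]


def cost(observed, dates, params: CropParams, meteo: MeteoSeries,
         f_g: float, f_c: float,
         scale_m: float | None = None) -> CostEvaluation:
    """Mean squared LAI misfit over the observation dates for one pixel."""
    observed = np.asarray(observed, dtype=float)
    dates = tuple(int(t) for t in np.atleast_1d(dates))
    if observed.shape != (len(dates),) or len(dates) < 1:
        raise ValueError("need one observed LAI per observation date")
    sim = _lai_at_dates(params, meteo, np.array([f_g]), np.array([f_c]),
                        dates)[:, 0]
    c = float(np.mean((observed - sim) ** 2))
    return CostEvaluation(c_value=c, n_dates=len(dates), dates=dates,
                          scale_m=scale_m)


def make_cost_function(observed, dates, params: CropParams,
                       meteo: MeteoSeries):
    """Vectorized cost callable (f_g array, f_c array) -> cost array."""
    observed = np.asarray(observed, dtype=float).reshape(-1, 1)
    dates = tuple(int(t) for t in np.atleast_1d(dates))

    def fn(f_g: np.ndarray, f_c: np.ndarray) -> np.ndarray:
        sim = _lai_at_dates(params, meteo, f_g, f_c, dates)
        return np.mean((observed - sim) ** 2, axis=0)

    return fn


def _predraw(rng: np.random.Generator, cfg: PSOConfig
             ) -> tuple[np.ndarray, np.ndarray]:
    """Initial positions and per-iteration (r1, r2) draws, fixed order."""
    lo = np.array([b[0] for b in cfg.bounds])
    hi = np.array([b[1] for b in cfg.bounds])
    pos = rng.uniform(lo, hi, size=(cfg.n_particles, 2))
    r = rng.uniform(size=(cfg.n_iter, 2, cfg.n_particles, 2))
    return pos, r


def pso_minimize(cost_fn, config: PSOConfig | None = None
                 ) -> tuple[float, float, float]:
    """Global-best PSO over (f_g, f_c); returns (f_g*, f_c*, C*).

    ``cost_fn`` must accept two equal-length 1-D arrays (candidate f_g
    and f_c values) and return the corresponding cost array; seeded runs
    are deterministic and stop early once the best cost reaches ``tol``.
    """
    cfg = config or PSOConfig()
    rng = np.random.default_rng(cfg.seed)
    pos, r = _predraw(rng, cfg)
    lo = np.array([b[0] for b in cfg.bounds])
    hi = np.array([b[1] for b in cfg.bounds])
    vel = np.zeros_like(pos)

    costs = np.asarray(cost_fn(pos[:, 0], pos[:, 1]), dtype=float)
    pbest, pbest_cost = pos.copy(), costs.copy()
    g = int(np.argmin(pbest_cost))
    gbest, gbest_cost = pbest[g].copy(), float(pbest_cost[g])

    for it in range(cfg.n_iter):
        if gbest_cost <= cfg.tol:
            break
        r1, r2 = r[it, 0], r[it, 1]
        vel = (cfg.inertia * vel + cfg.c1 * r1 * (pbest - pos)
               + cfg.c2 * r2 * (gbest - pos))
        pos = np.clip(pos + vel, lo, hi)
        costs = np.asarray(cost_fn(pos[:, 0], pos[:, 1]), dtype=float)
        better = costs < pbest_cost
        pbest[better] = pos[better]
        pbest_cost[better] = costs[better]
        g = int(np.argmin(pbest_cost))
        if pbest_cost[g] < gbest_cost:
            gbest, gbest_cost = pbest[g].copy(), float(pbest_cost[g])
    return float(gbest[0]), float(gbest[1]), gbest_cost


def _batch_pso(obs_values: np.ndarray, dates: tuple[int, ...],
               params: CropParams, meteo: MeteoSeries, cfg: PSOConfig,
               pixel_seeds: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Independent per-pixel swarms run in lock-step.

    ``obs_values`` is (n_dates, P).  Returns (gbest (P, 2), gbest_cost (P,)).
    Exactly mirrors :func:`pso_minimize` run per pixel with the given
    seeds, including early stopping (a converged pixel's swarm freezes).
    """
    n_dates, P = obs_values.shape
    K = cfg.n_particles
    lo = np.array([b[0] for b in cfg.bounds])
    hi = np.array([b[1] for b in cfg.bounds])

    pos = np.empty((P, K, 2))
    r = np.empty((P, cfg.n_iter, 2, K, 2))
    for p in range(P):
        rng = np.random.default_rng(int(pixel_seeds[p]))
        pos[p], r[p] = _predraw(rng, cfg)
    vel = np.zeros_like(pos)

    def eval_costs(positions: np.ndarray) -> np.ndarray:
        flat = positions.reshape(P * K, 2)
        sim = _lai_at_dates(params, meteo, flat[:, 0], flat[:, 1], dates)
        sim = sim.reshape(n_dates, P, K)
        return np.mean((obs_values[:, :, None] - sim) ** 2, axis=0)

    costs = eval_costs(pos)                      # (P, K)
    pbest, pbest_cost = pos.copy(), costs.copy()
    g = np.argmin(pbest_cost, axis=1)
    gbest = pbest[np.arange(P), g]               # (P, 2)
    gbest_cost = pbest_cost[np.arange(P), g]

    for it in range(cfg.n_iter):
        active = gbest_cost > cfg.tol
        if not np.any(active):
            break
        r1, r2 = r[:, it, 0], r[:, it, 1]
        new_vel = (cfg.inertia * vel + cfg.c1 * r1 * (pbest - pos)
                   + cfg.c2 * r2 * (gbest[:, None, :] - pos))
        new_pos = np.clip(pos + new_vel, lo, hi)
        a = active[:, None, None]
        vel = np.where(a, new_vel, vel)
        pos = np.where(a, new_pos, pos)
        costs = eval_costs(pos)
        better = (costs < pbest_cost) & active[:, None]
        pbest = np.where(better[:, :, None], pos, pbest)
        pbest_cost = np.where(better, costs, pbest_cost)
        g = np.argmin(pbest_cost, axis=1)
        cand_cost = pbest_cost[np.arange(P), g]
        improve = (cand_cost < gbest_cost) & active
        gbest = np.where(improve[:, None], pbest[np.arange(P), g], gbest)
        gbest_cost = np.where(improve, cand_cost, gbest_cost)
    return gbest, gbest_cost


def assimilate_raster(obs: dict[int, LAIRaster], params: CropParams,
                      meteo: MeteoSeries, config: PSOConfig | None = None,
                      window: tuple[int, int] = DEFAULT_WINDOW,
                      area_label: str = "A") -> AssimilationResult:
    """Invert (f_g, f_c) for every defined pixel of a multi-date LAI stack.

    All observation rasters must share shape and pixel size; pixels
    where any date is nodata are skipped.  Returns the recovered stress
    field, the per-pixel final cost, the daily WRT stack simulated at
    the optimum, and its mean over the analysis window.
    """
    cfg = config or PSOConfig()
    dates = tuple(sorted(int(t) for t in obs))
    rasters = [obs[t] for t in dates]
    shapes = {r.grid.shape for r in rasters}
    scales = {float(r.pixel_size_m) for r in rasters}
    if len(shapes) != 1 or len(scales) != 1:
        raise ValueError("observation rasters must share shape and scale")
    (H, W), scale_m = shapes.pop(), scales.pop()

    stack = np.stack([r.grid for r in rasters])          # (n_dates, H, W)
    ok = np.all([valid_mask(r.grid) for r in rasters], axis=0)
    flat_idx = np.flatnonzero(ok.ravel())
    obs_values = stack.reshape(len(dates), -1)[:, flat_idx]
    pixel_seeds = cfg.seed + flat_idx

    gbest, gbest_cost = _batch_pso(obs_values, dates, params, meteo, cfg,
                                   pixel_seeds)

    def to_grid(values: np.ndarray) -> np.ndarray:
        out = np.full(H * W, NODATA)
        out[flat_idx] = values
        return out.reshape(H, W)

    stress = StressField(to_grid(gbest[:, 0]), to_grid(gbest[:, 1]),
                         area_label=area_label, pixel_size_m=scale_m)
    run = simulate_batch(params, meteo, gbest[:, 0], gbest[:, 1])
    doy, wrt = run["doy"], run["wrt"]                    # (nd, P)
    wrt_daily = np.stack([to_grid(wrt[d]) for d in range(len(doy))])
    w0, w1 = window
    in_win = (doy >= w0) & (doy <= w1)
    if not np.any(in_win):
        raise ValueError("analysis window outside simulated season")
    wrt_window = to_grid(wrt[in_win].mean(axis=0))
    return AssimilationResult(stress=stress, cost_map=to_grid(gbest_cost),
                              wrt_daily=wrt_daily, doy=doy,
                              wrt_window=wrt_window, window=(w0, w1),
                              scale_m=scale_m)


def grid_search(cost_fn, step: float = 0.005,
                bounds: tuple[tuple[float, float], tuple[float, float]] = (
                    (STRESS_MIN, STRESS_MAX), (STRESS_MIN, STRESS_MAX))
                ) -> tuple[float, float, float]:
    """Exhaustive reference minimizer on a regular (f_g, f_c) lattice.

    Serves as a brute-force oracle for the swarm optimizer in tests.
    """
    g = np.linspace(bounds[0][0], bounds[0][1],
                    int(round((bounds[0][1] - bounds[0][0]) / step)) + 1)
    c = np.linspace(bounds[1][0], bounds[1][1],
                    int(round((bounds[1][1] - bounds[1][0]) / step)) + 1)
    gg, cc = np.meshgrid(g, c, indexing="ij")
    costs = np.asarray(cost_fn(gg.ravel(), cc.ravel()))
    k = int(np.argmin(costs))
    return float(gg.ravel()[k]), float(cc.ravel()[k]), float(costs[k])
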