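"""Daily-step potential-production rice simulator with heavy-metal stress.

A reduced-form, WOFOST-style light-use-efficiency model: canopy gross
assimilation follows Beer's-law light interception, maintenance
respiration a Q10 form, and daily net carbohydrate is converted to dry
matter and partitioned over roots, leaves, stems and storage organs by
development stage.  Heavy-metal stress enters through two multiplicative
factors, both restricted to [0.65, 1]:

* ``f_g`` scales daily gross assimilation:      E_gs(t) = f_g * E_gp(t)
* ``f_c`` scales the carbohydrate-to-dry-matter
  conversion coefficient:                       E_cs(t) = f_c * E_cp(t)

and their product ``f_comb = f_g * f_c`` is the combined stress level.
The factors are constant over the season for a pixel; the simulated leaf
area index (LAI) is the observable assimilated against remote-sensing
retrievals, and the dry weight of roots (WRT, g m-2) is the monitored
characteristic.  Because root partitioning ceases at anthesis (DVS = 1),
WRT holds a constant maximum through grain filling - the plateau that
the scale statistics are computed on.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .meteo import MeteoSeries

STRESS_MIN = 0.65
STRESS_MAX = 1.0

# DVS knots -> (FR, FL, FS, FO) partition fractions; rows sum to 1 and
# FR = 0 from anthesis on, which produces the WRT plateau.
_DEFAULT_PARTITION = np.array([
    [0.0, 0.50, 0.30, 0.20, 0.00],
    [0.4, 0.30, 0.45, 0.25, 0.00],
    [0.8, 0.10, 0.40, 0.50, 0.00],
    [1.0, 0.00, 0.10, 0.30, 0.60],
    [1.2, 0.00, 0.00, 0.05, 0.95],
    [2.0, 0.00, 0.00, 0.00, 1.00],
])


@dataclass
class CropParams:
    """Rice parameter set for the reduced-form simulator.

    Defaults are rice-typical values chosen so that, with the synthetic
    subtropical meteorology, anthesis falls shortly before DOY 221 and
    the WRT plateau spans the DOY 221-236 analysis window.
    """

    tbase_c: float = 8.0          # base temperature for development, degC
    tsum1: float = 1200.0         # thermal time emergence -> anthesis, degC d
    tsum2: float = 550.0          # thermal time anthesis -> maturity, degC d
    k_ext: float = 0.6            # canopy light extinction coefficient
    eps_g: float = 3.0            # gross assimilation, g CH2O per MJ PAR
    y_g: float = 0.7              # conversion efficiency, g DM per g CH2O
    q10: float = 2.0              # maintenance temperature response
    maint_coeffs: dict = field(default_factory=lambda: {
        "wlv": 0.010, "wst": 0.006, "wrt": 0.004, "wso": 0.003,
    })                            # g CH2O per g organ per day at 25 degC
    sla: float = 0.025            # specific leaf area, m2 leaf per g leaf
    partition_table: np.ndarray = field(
        default_factory=lambda: _DEFAULT_PARTITION.copy())
    emergence_doy: int = 155
    season_end_doy: int = 280
    # initial organ weights at emergence, g m-2 (LAI0 = sla * wlv0 = 0.1)
    wrt0: float = 1.0
    wlv0: float = 4.0
    wst0: float = 1.0
    wso0: float = 0.0
    # leaf senescence: linear LAI drain per day once DVS exceeds the onset
    senescence_dvs: float = 1.3
    sen_lai_per_day: float = 0.08

    def __post_init__(self) -> None:
        tab = np.asarray(self.partition_table, dtype=float)
        if tab.ndim != 2 or tab.shape[1] != 5:
            raise ValueError("partition table needs columns dvs,FR,FL,FS,FO")
        if not np.allclose(tab[:, 1:].sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("partition fractions must sum to 1 at every DVS")
        if np.any(tab[tab[:, 0] >= 1.0, 1] != 0.0):
            raise ValueError("root fraction must be 0 for DVS >= 1")
        self.partition_table = tab

    def partition(self, dvs: np.ndarray | float) -> np.ndarray:
        """Interpolated (FR, FL, FS, FO) at development stage(s)."""
        dvs = np.asarray(dvs, dtype=float)
        knots = self.partition_table[:, 0]
        return np.stack([np.interp(dvs, knots, self.partition_table[:, j])
                         for j in range(1, 5)], axis=-1)

    def to_yaml(self, path: str | Path) -> None:
        d = {k: (v.tolist() if isinstance(v, np.ndarray) else v)
             for k, v in self.__dict__.items()}
        Path(path).write_text(yaml.safe_dump(d))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CropParams":
        d = yaml.safe_load(Path(path).read_text())
        if "partition_table" in d:
            d["partition_table"] = np.asarray(d["partition_table"], float)
        return cls(**d)


@dataclass
class DailyState:
    """Crop state on one day (weights g m-2, assimilation g CH2O m-2 d-1)."""

    doy: int
    dvs: float
    lai: float
    wrt: float
    wlv: float
    wst: float
    wso: float
    egp: float = 0.0   # potential daily gross assimilation
    egs: float = 0.0   # stressed daily gross assimilation
    wlv_dead: float = 0.0  # cumulative senesced leaf mass


@dataclass
class Trajectory:
    """Ordered daily states from emergence to season end."""

    states: list[DailyState]

    def __post_init__(self) -> None:
        doys = [s.doy for s in self.states]
        if doys and list(doys) != list(range(doys[0], doys[-1] + 1)):
            raise ValueError("trajectory days must be contiguous")

    def __len__(self) -> int:
        return len(self.states)

    def __iter__(self):
        return iter(self.states)

    def series(self, name: str) -> np.ndarray:
        return np.array([getattr(s, name) for s in self.states])

    def at_doy(self, doy: int) -> DailyState:
        first = self.states[0].doy
        if not (first <= doy <= self.states[-1].doy):
            raise ValueError(f"DOY {doy} outside simulated season")
        return self.states[doy - first]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({c: self.series(c) for c in
                             ("doy", "dvs", "lai", "wrt", "wlv", "wst", "wso")})

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def fcomb(f_g: float, f_c: float) -> float:
    """Combined stress factor f_comb = f_g * f_c."""
    for f in (f_g, f_c):
        if not (STRESS_MIN <= f <= STRESS_MAX):
            raise ValueError(f"stress factor {f} outside [0.65, 1]")
    return f_g * f_c


def develop(params: CropParams, meteo: MeteoSeries) -> np.ndarray:
    """Development stage per day from emergence to season end.

    Daily effective temperature max(0, Tmean - tbase) accumulates from
    the day after emergence; DVS is thermal time scaled piecewise by
    tsum1 (to anthesis, DVS 1) and tsum2 (to maturity, DVS 2).
    """
    m = meteo.slice_doy(params.emergence_doy,
                        min(params.season_end_doy, int(meteo.doy[-1])))
    teff = np.maximum(0.0, m.tmean_c - params.tbase_c)
    tsum = np.concatenate([[0.0], np.cumsum(teff[1:])])
    dvs = np.where(tsum <= params.tsum1, tsum / params.tsum1,
                   1.0 + (tsum - params.tsum1) / params.tsum2)
    return np.minimum(dvs, 2.0)


def _run_arrays(params: CropParams, meteo: MeteoSeries,
                f_g: np.ndarray, f_c: np.ndarray,
                potential: bool = False) -> dict[str, np.ndarray]:
    """Vectorized season run for parallel stress-factor candidates.

    ``f_g``/``f_c`` are 1-D arrays of length n; returns per-day arrays of
    shape (n_days, n).  This kernel backs single runs, per-pixel rasters
    and the swarms of the assimilation optimizer alike.
    """
    f_g = np.atleast_1d(np.asarray(f_g, dtype=float))
    f_c = np.atleast_1d(np.asarray(f_c, dtype=float))
    if f_g.shape != f_c.shape:
        raise ValueError("f_g and f_c must share shape")
    if not potential and (np.any((f_g < STRESS_MIN) | (f_g > STRESS_MAX))
                          or np.any((f_c < STRESS_MIN) | (f_c > STRESS_MAX))):
        raise ValueError("stress factors outside [0.65, 1]")
    n = f_g.size

    dvs = develop(params, meteo)
    m = meteo.slice_doy(params.emergence_doy,
                        params.emergence_doy + len(dvs) - 1)
    nd = len(dvs)
    frac = params.partition(dvs)                       # (nd, 4)
    q10f = params.q10 ** ((m.tmean_c - 25.0) / 10.0)   # (nd,)
    par = 0.5 * m.rad_mj
    c = params.maint_coeffs

    shape = (nd, n)
    out = {k: np.zeros(shape) for k in
           ("lai", "wrt", "wlv", "wst", "wso", "egp", "egs", "wlv_dead")}
    wrt = np.full(n, params.wrt0)
    wlv = np.full(n, params.wlv0)
    wst = np.full(n, params.wst0)
    wso = np.full(n, params.wso0)
    dead = np.zeros(n)

    for d in range(nd):
        lai = params.sla * wlv
        egp = params.eps_g * par[d] * (1.0 - np.exp(-params.k_ext * lai))
        egs = egp if potential else f_g * egp
        rm = q10f[d] * (c["wlv"] * wlv + c["wst"] * wst
                        + c["wrt"] * wrt + c["wso"] * wso)
        net = np.maximum(0.0, egs - rm)
        growth = params.y_g * net if potential else f_c * (params.y_g * net)
        for k, v in (("lai", lai), ("wrt", wrt), ("wlv", wlv), ("wst", wst),
                     ("wso", wso), ("egp", egp), ("egs", egs),
                     ("wlv_dead", dead)):
            out[k][d] = v
        if d == nd - 1:
            break
        wrt = wrt + growth * frac[d, 0]
        wlv = wlv + growth * frac[d, 1]
        wst = wst + growth * frac[d, 2]
        wso = wso + growth * frac[d, 3]
        if dvs[d] > params.senescence_dvs:
            drop = np.minimum(wlv, params.sen_lai_per_day / params.sla)
            wlv = wlv - drop
            dead = dead + drop

    out["dvs"] = dvs
    out["doy"] = np.arange(params.emergence_doy, params.emergence_doy + nd)
    return out


def step_day(state: DailyState, params: CropParams, tmin_c: float,
             tmax_c: float, rad_mj: float,
             stress: tuple[float, float] = (1.0, 1.0),
             dvs_next: float | None = None,
             potential: bool = False) -> DailyState:
    """Advance the crop one day under the given weather and stress.

    Returns the next day's state; ``dvs_next`` may be supplied from a
    precomputed development series, otherwise thermal time is advanced
    incrementally from the current DVS.
    """
    f_g, f_c = stress
    if not potential:
        for f in (f_g, f_c):
            if not (STRESS_MIN <= f <= STRESS_MAX):
                raise ValueError("stress factors must lie in [0.65, 1]")
    tmean = 0.5 * (tmin_c + tmax_c)
    egp = params.eps_g * 0.5 * rad_mj * (
        1.0 - np.exp(-params.k_ext * state.lai))
    egs = egp if potential else f_g * egp
    c = params.maint_coeffs
    rm = params.q10 ** ((tmean - 25.0) / 10.0) * (
        c["wlv"] * state.wlv + c["wst"] * state.wst
        + c["wrt"] * state.wrt + c["wso"] * state.wso)
    net = max(0.0, egs - rm)
    growth = params.y_g * net if potential else f_c * (params.y_g * net)
    fr, fl, fs, fo = params.partition(state.dvs)
    wrt = state.wrt + growth * fr
    wlv = state.wlv + growth * fl
    wst = state.wst + growth * fs
    wso = state.wso + growth * fo
    dead = state.wlv_dead
    if state.dvs > params.senescence_dvs:
        drop = min(wlv, params.sen_lai_per_day / params.sla)
        wlv -= drop
        dead += drop
    if dvs_next is None:
        teff = max(0.0, tmean - params.tbase_c)
        tsum = (state.dvs * params.tsum1 if state.dvs <= 1.0
                else params.tsum1 + (state.dvs - 1.0) * params.tsum2) + teff
        dvs_next = min(2.0, tsum / params.tsum1 if tsum <= params.tsum1
                       else 1.0 + (tsum - params.tsum1) / params.tsum2)
    return DailyState(doy=state.doy + 1, dvs=float(dvs_next),
                      lai=params.sla * wlv, wrt=wrt, wlv=wlv, wst=wst,
                      wso=wso, egp=float(egp), egs=float(egs), wlv_dead=dead)


def simulate(params: CropParams, meteo: MeteoSeries,
             stress: tuple[float, float] = (1.0, 1.0),
             potential: bool = False) -> Trajectory:
    """Run a full season for one pixel; see :func:`_run_arrays`."""
    f_g, f_c = stress
    out = _run_arrays(params, meteo, np.array([f_g]), np.array([f_c]),
                      potential=potential)
    states = [DailyState(doy=int(out["doy"][d]), dvs=float(out["dvs"][d]),
                         lai=float(out["lai"][d, 0]),
                         wrt=float(out["wrt"][d, 0]),
                         wlv=float(out["wlv"][d, 0]),
                         wst=float(out["wst"][d, 0]),
                         wso=float(out["wso"][d, 0]),
                         egp=float(out["egp"][d, 0]),
                         egs=float(out["egs"][d, 0]),
                         wlv_dead=float(out["wlv_dead"][d, 0]))
              for d in range(len(out["dvs"]))]
    return Trajectory(states)


def simulate_batch(params: CropParams, meteo: MeteoSeries,
                   f_g: np.ndarray, f_c: np.ndarray,
                   potential: bool = False) -> dict[str, np.ndarray]:
    """Season run for many (f_g, f_c) pairs at once.

    Returns {'doy': (nd,), 'dvs': (nd,), 'lai': (nd, n), 'wrt': (nd, n), ...}.
    """
    return _run_arrays(params, meteo, f_g, f_c, potential=potential)
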