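"""Daily meteorology container used to drive the crop simulator."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class MeteoSeries:
    """Daily weather: day of year, min/max air temperature (degC) and
    global radiation (MJ m-2 d-1).

    Days must be contiguous and strictly increasing, with tmin <= tmax
    and non-negative radiation everywhere.
    """

    doy: np.ndarray
    tmin_c: np.ndarray
    tmax_c: np.ndarray
    rad_mj: np.ndarray

    def __post_init__(self) -> None:
        self.doy = np.asarray(self.doy, dtype=int)
        self.tmin_c = np.asarray(self.tmin_c, dtype=float)
        self.tmax_c = np.asarray(self.tmax_c, dtype=float)
        self.rad_mj = np.asarray(self.rad_mj, dtype=float)
        n = len(self.doy)
        if not (len(self.tmin_c) == len(self.tmax_c) == len(self.rad_mj) == n):
            raise ValueError("meteo columns must share length")
        if n and not np.all(np.diff(self.doy) == 1):
            raise ValueError("doy must be contiguous and strictly increasing")
        if np.any(self.tmin_c > self.tmax_c):
            raise ValueError("tmin must not exceed tmax")
        if np.any(self.rad_mj < 0):
            raise ValueError("radiation must be >= 0")

    def __len__(self) -> int:
        return len(self.doy)

    @property
    def tmean_c(self) -> np.ndarray:
        return 0.5 * (self.tmin_c + self.tmax_c)

    def slice_doy(self, start: int, end: int) -> "MeteoSeries":
        """Inclusive DOY window; raises if not fully covered."""
        if start < self.doy[0] or end > self.doy[-1]:
            raise ValueError(f"meteo does not cover DOY {start}..{end}")
        i0 = int(start - self.doy[0])
        i1 = int(end - self.doy[0]) + 1
        return MeteoSeries(self.doy[i0:i1], self.tmin_c[i0:i1],
                           self.tmax_c[i0:i1], self.rad_mj[i0:i1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"doy": self.doy, "tmin_c": self.tmin_c,
                             "tmax_c": self.tmax_c, "rad_mj": self.rad_mj})

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "MeteoSeries":
        df = pd.read_csv(path)
        return cls(df["doy"].to_numpy(), df["tmin_c"].to_numpy(),
                   df["tmax_c"].to_numpy(), df["rad_mj"].to_numpy())
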