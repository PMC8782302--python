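"""Daily weather series container.

A :class:`WeatherSeries` is the boundary condition for every simulation in
this package: daily maximum/minimum air temperature, precipitation, global
solar radiation and (optionally) wind speed and relative humidity.  It wraps
a :class:`pandas.DataFrame` with one row per calendar day and enforces the
physical invariants every downstream component relies on (monotone daily
dates without gaps, ``tmax >= tmin``, non-negative precipitation and
radiation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: canonical column order for text export
COLUMNS = ["date", "tmax", "tmin", "precip", "srad", "wind", "rh"]

REQUIRED = ["date", "tmax", "tmin", "precip", "srad"]


@dataclass
class WeatherSeries:
    """Daily meteorological driver record for one site.

    Parameters
    ----------
    site_id : str
        Free-form site label.
    data : pandas.DataFrame
        Columns ``date`` (datetime64), ``tmax``, ``tmin`` (deg C),
        ``precip`` (mm/d), ``srad`` (MJ m-2 d-1) and optionally ``wind``
        (m/s) and ``rh`` (%).
    """

    site_id: str
    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.data.copy()
        missing = [c for c in REQUIRED if c not in df.columns]
        if missing:
            raise ValueError(f"weather data missing columns: {missing}")
        df["date"] = pd.to_datetime(df["date"])
        df = df.reset_index(drop=True)
        self.data = df
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        df = self.data
        if len(df) == 0:
            raise ValueError("weather series is empty")
        deltas = df["date"].diff().dropna()
        if len(deltas) and not (deltas == pd.Timedelta(days=1)).all():
            raise ValueError("dates must be strictly increasing with a daily step and no gaps")
        if (df["tmax"].to_numpy() < df["tmin"].to_numpy()).any():
            raise ValueError("tmax < tmin encountered")
        if (df["precip"].to_numpy() < 0).any():
            raise ValueError("negative precipitation encountered")
        if (df["srad"].to_numpy() < 0).any():
            raise ValueError("negative solar radiation encountered")
        if "rh" in df.columns:
            rh = df["rh"].dropna().to_numpy()
            if len(rh) and ((rh < 0) | (rh > 100)).any():
                raise ValueError("relative humidity outside [0, 100]")

    # -- convenience ------------------------------------------------------
    def __len__(self) -> int:
        return len(self.data)

    @property
    def years(self) -> np.ndarray:
        return self.data["date"].dt.year.unique()

    @property
    def tmean(self) -> np.ndarray:
        return 0.5 * (self.data["tmax"].to_numpy() + self.data["tmin"].to_numpy())

    def year_slice(self, year: int) -> pd.DataFrame:
        df = self.data
        return df[df["date"].dt.year == year].reset_index(drop=True)

    def monthly_mean(self, variable: str) -> pd.Series:
        """Mean of *variable* per calendar month (pooled over years)."""
        df = self.data
        return df.groupby(df["date"].dt.month)[variable].mean()

    def monthly_total(self, variable: str = "precip") -> pd.Series:
        """Mean per-year monthly total of *variable* (mm for precip)."""
        df = self.data
        per_year = df.groupby([df["date"].dt.year, df["date"].dt.month])[variable].sum()
        return per_year.groupby(level=1).mean()

    def replace(self, **columns: np.ndarray) -> "WeatherSeries":
        """Return a copy with the given columns replaced."""
        df = self.data.copy()
        for name, values in columns.items():
            df[name] = values
        return WeatherSeries(self.site_id, df)

    # -- text IO ----------------------------------------------------------
    def to_csv(self, path) -> None:
        df = self.data.copy()
        for c in COLUMNS:
            if c not in df.columns:
                df[c] = np.nan
        df["date"] = df["date"].dt.strftime("%Y-%m-%d")
        df[COLUMNS].to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, site_id: str | None = None) -> "WeatherSeries":
        df = pd.read_csv(path, parse_dates=["date"])
        return cls(site_id or str(path), df)
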