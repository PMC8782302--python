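"""Crop management: planting window and rainfall-triggered planting rule.

The planting window is the mean +/- 2 SD of the calibration-period planting
dates (day-of-year, rounded outward).  Within the window, planting is
triggered on the first day with >= 20 mm rain within a 3-day period and no
dry spell longer than 10 days in the following 30 days; if no day qualifies
the last day of the window is planted.  "Dry" uses a 1 mm/day threshold (a
conventional agro-climatology cutoff; configurable).  The 3-day sum is
forward-looking from the candidate day and the 30-day dry-spell check starts
the day after the candidate; candidates are restricted to days whose 3-day
sum lies fully inside the available data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .weather import WeatherSeries


@dataclass
class ManagementPlan:
    planting_window: tuple[int, int] = (150, 190)  # day of year
    plant_density: float = 200.0  # plants/m2 (wheat-like default)
    fertilizer_splits: tuple[tuple[int, float], ...] = ((0, 0.5), (30, 0.5))
    kc: float = 1.05  # single crop coefficient
    initial_water_fraction: float = 0.8  # of plant-available water
    initial_no3: float = 10.0  # kg N/ha over the profile, annual reset
    latitude: float = 9.0
    elevation: float = 2200.0

    def __post_init__(self) -> None:
        start, end = self.planting_window
        if start > end:
            raise ValueError("planting window start after end")
        if self.plant_density <= 0:
            raise ValueError("plant density must be positive")
        total = sum(f for _, f in self.fertilizer_splits)
        if self.fertilizer_splits and not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError("fertilizer split fractions must sum to 1")


def planting_window(planting_doys) -> tuple[int, int]:
    """Mean +/- 2 SD of historical planting days, rounded outward."""
    doys = np.asarray(list(planting_doys), dtype=float)
    if len(doys) == 0:
        raise ValueError("need at least one planting date")
    mean = doys.mean()
    sd = doys.std(ddof=1) if len(doys) >= 2 else 0.0
    return int(np.floor(mean - 2 * sd)), int(np.ceil(mean + 2 * sd))


def planting_date(weather: WeatherSeries, window: tuple[int, int], year: int,
                  rain_sum_mm: float = 20.0, rain_window: int = 3,
                  dry_spell_max: int = 10, lookahead: int = 30,
                  dry_day_mm: float = 1.0) -> int:
    """Day of year on which the rainfall rule triggers planting.

    Scans from the window start; a candidate day ``d`` qualifies if the
    precipitation of days ``d .. d+2`` sums to at least 20 mm and the 30
    days after ``d`` contain no run of more than 10 consecutive days each
    below the dry-day threshold.  Falls back to the window's last day.
    """
    df = weather.year_slice(year)
    if len(df) == 0:
        raise ValueError(f"no weather for year {year}")
    precip = df["precip"].to_numpy()
    doys = df["date"].dt.dayofyear.to_numpy()
    start, end = window
    if start < doys[0] or end > doys[-1]:
        raise ValueError("planting window outside the year's data")
    if end + rain_window - 1 + lookahead > doys[-1]:
        raise ValueError(
            "weather series too short for the planting rule: need data to day "
            f"{end + rain_window - 1 + lookahead}, have {doys[-1]}")

    by_doy = dict(zip(doys.tolist(), precip.tolist()))
    for d in range(start, end + 1):
        s = sum(by_doy.get(d + i, 0.0) for i in range(rain_window))
        if s < rain_sum_mm:
            continue
        # dry-spell check over the following `lookahead` days
        run = 0
        ok = True
        for i in range(1, lookahead + 1):
            if by_doy.get(d + i, 0.0) < dry_day_mm:
                run += 1
                if run > dry_spell_max:
                    ok = False
                    break
            else:
                run = 0
        if ok:
            return d
    return end
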