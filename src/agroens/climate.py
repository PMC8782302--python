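"""Bias correction, scenario perturbations and climate-change summaries.

Bias correction is empirical (non-parametric) quantile-quantile mapping
fitted per calendar month: sample quantiles of the model's historical run
are mapped onto the same quantiles of the observations, with linear
interpolation between sample quantiles and constant offset extrapolation
beyond the training range.  Temperature is mapped additively in value space;
precipitation is mapped on wet days only (threshold 0.1 mm) after a
frequency-adjustment step that zeroes the smallest model wet days until
wet-day counts match the observations, and is floored at zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .weather import WeatherSeries

WET_THRESHOLD = 0.1  # mm
MIN_MONTH_SAMPLE = 20

VALID_VARIABLES = ("tmax", "tmin", "precip")


@dataclass(frozen=True)
class PerturbationSpec:
    """One sensitivity-analysis treatment: climate offsets plus management."""

    dT: float = 0.0  # deg C additive offset on tmax and tmin
    dP: float = 0.0  # fractional precipitation change
    co2: float = 360.0  # ppm
    n_fert: float = 100.0  # kg N/ha season total

    def __post_init__(self) -> None:
        if self.dP <= -1:
            raise ValueError("dP must exceed -1")
        if self.co2 <= 0:
            raise ValueError("co2 must be positive")
        if self.n_fert < 0:
            raise ValueError("n_fert must be >= 0")

    @property
    def label(self) -> str:
        return f"dT{self.dT:+g}_dP{self.dP:+g}_co2{self.co2:g}_N{self.n_fert:g}"


def apply_perturbation(weather: WeatherSeries, spec: PerturbationSpec) -> WeatherSeries:
    """Shift temperatures by ``dT`` and scale precipitation by ``1 + dP``.

    Radiation, wind and humidity are passed through unchanged; CO2 and N
    rate are scenario metadata consumed by the crop and nitrogen modules.
    """
    df = weather.data
    return weather.replace(
        tmax=df["tmax"].to_numpy() + spec.dT,
        tmin=df["tmin"].to_numpy() + spec.dT,
        precip=df["precip"].to_numpy() * (1.0 + spec.dP),
    )


# ---------------------------------------------------------------------------
# Quantile-quantile mapping
# ---------------------------------------------------------------------------
def _transfer(raw: np.ndarray, src_sorted: np.ndarray, dst_sorted: np.ndarray) -> np.ndarray:
    """Map values through the empirical src -> dst quantile transfer.

    Linear interpolation between matched sample quantiles; beyond the
    training range the edge offset is held constant, which keeps the mapping
    monotone everywhere.
    """
    p = np.linspace(0, 1, len(src_sorted))
    q = np.linspace(0, 1, len(dst_sorted))
    dst_at_p = np.interp(p, q, dst_sorted)
    corrected = np.interp(raw, src_sorted, dst_at_p)
    low = raw < src_sorted[0]
    high = raw > src_sorted[-1]
    corrected[low] = raw[low] + (dst_at_p[0] - src_sorted[0])
    corrected[high] = raw[high] + (dst_at_p[-1] - src_sorted[-1])
    return corrected


def quantile_map(model_hist: WeatherSeries, obs: WeatherSeries,
                 model_target: WeatherSeries, variable: str) -> WeatherSeries:
    """Quantile-quantile bias correction of ``model_target``.

    Transfer functions are fitted per calendar month between the model's
    historical run and the observations, then applied to the target series.
    To correct the historical run itself, pass it as ``model_target`` too.
    """
    if variable not in VALID_VARIABLES:
        raise ValueError(f"variable must be one of {VALID_VARIABLES}")
    for ws in (model_hist, obs, model_target):
        if variable not in ws.data.columns:
            raise ValueError(f"variable {variable!r} absent from series {ws.site_id!r}")
    if len(model_hist) < 365 or len(obs) < 365:
        raise ValueError("model_hist and obs must overlap at least one full year")

    hist_m = model_hist.data["date"].dt.month.to_numpy()
    obs_m = obs.data["date"].dt.month.to_numpy()
    tgt_m = model_target.data["date"].dt.month.to_numpy()
    hist_v = model_hist.data[variable].to_numpy()
    obs_v = obs.data[variable].to_numpy()
    out = model_target.data[variable].to_numpy().astype(float).copy()

    for m in range(1, 13):
        h = hist_v[hist_m == m]
        o = obs_v[obs_m == m]
        sel = tgt_m == m
        if not sel.any():
            continue
        if len(h) < MIN_MONTH_SAMPLE or len(o) < MIN_MONTH_SAMPLE:
            raise ValueError(f"month {m} has fewer than {MIN_MONTH_SAMPLE} values; "
                             "insufficient quantile support")
        raw = out[sel]
        if variable == "precip":
            hw = np.sort(h[h >= WET_THRESHOLD])
            ow = np.sort(o[o >= WET_THRESHOLD])
            wet = raw >= WET_THRESHOLD
            # frequency adjustment: if the model rains too often, zero the
            # smallest model wet days until frequencies match
            f_obs = len(ow) / len(o)
            f_mod = len(hw) / len(h)
            if f_mod > f_obs > 0:
                cut = np.quantile(h[h >= WET_THRESHOLD], 1.0 - f_obs / f_mod)
                wet = wet & (raw >= cut)
            elif f_obs == 0:
                wet = np.zeros_like(wet)
            mapped = np.zeros_like(raw)
            if wet.any() and len(hw) >= 2 and len(ow) >= 2:
                mapped[wet] = np.maximum(0.0, _transfer(raw[wet], hw, ow))
            elif wet.any():
                mapped[wet] = raw[wet]
            out_sel = mapped
        else:
            out_sel = _transfer(raw, np.sort(h), np.sort(o))
        out[sel] = out_sel

    df = model_target.data.copy()
    df[variable] = out
    if variable == "tmax":
        df["tmin"] = np.minimum(df["tmin"].to_numpy(), out)
    elif variable == "tmin":
        df["tmax"] = np.maximum(df["tmax"].to_numpy(), out)
    return WeatherSeries(model_target.site_id + ":qm", df)


def bias_correct(model_hist: WeatherSeries, obs: WeatherSeries,
                 model_target: WeatherSeries,
                 variables: tuple[str, ...] = ("tmax", "tmin", "precip")) -> WeatherSeries:
    """Apply quantile mapping for several variables in sequence."""
    corrected = model_target
    for v in variables:
        corrected = quantile_map(model_hist, obs, corrected, v)
    return corrected


# ---------------------------------------------------------------------------
# Change summaries
# ---------------------------------------------------------------------------
@dataclass
class ChangeSummary:
    """Monthly and annual baseline -> future change signals."""

    d_tmax: np.ndarray  # deg C per month
    d_tmin: np.ndarray
    d_precip_pct: np.ndarray  # %, NaN where the baseline month is dry

    @property
    def annual_d_tmax(self) -> float:
        return float(np.mean(self.d_tmax))

    @property
    def annual_d_tmin(self) -> float:
        return float(np.mean(self.d_tmin))

    @property
    def annual_d_precip_pct(self) -> float:
        return float(np.nanmean(self.d_precip_pct))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "month": np.arange(1, 13),
            "d_tmax": self.d_tmax,
            "d_tmin": self.d_tmin,
            "d_precip_pct": self.d_precip_pct,
        })


def summarize_change(baseline: WeatherSeries, future: WeatherSeries) -> ChangeSummary:
    """Monthly future-minus-baseline temperature and precipitation changes."""
    if len(baseline) < 365 or len(future) < 365:
        raise ValueError("both series must cover at least one full year")
    d_tmax = (future.monthly_mean("tmax") - baseline.monthly_mean("tmax"))
    d_tmin = (future.monthly_mean("tmin") - baseline.monthly_mean("tmin"))
    pb = baseline.monthly_total("precip")
    pf = future.monthly_total("precip")
    with np.errstate(divide="ignore", invalid="ignore"):
        dp = 100.0 * (pf - pb) / pb
    dp = dp.where(pb > 0)  # undefined, not infinite, in dry months
    idx = np.arange(1, 13)
    return ChangeSummary(
        d_tmax.reindex(idx).to_numpy(),
        d_tmin.reindex(idx).to_numpy(),
        dp.reindex(idx).to_numpy(),
    )
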