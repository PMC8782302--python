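"""Calibration performance metrics and Taylor-diagram statistics.

For simulated values ``sim`` and observations ``obs``:

* r — Pearson correlation coefficient,
* RMSE — root mean square error, in the units of the variable,
* PBIAS — 100 * sum(sim - obs) / sum(obs),
* NSE — Nash-Sutcliffe efficiency, 1 - SSE / SS(obs about its mean);
  1 is a perfect match, 0 means the observation mean predicts as well as
  the simulation, negative values worse than the mean.

Taylor statistics normalize by the observation standard deviation (so the
reference has SD 1) and use the centered RMSE (means removed before the RMSE,
then normalized), which satisfies the law-of-cosines identity
``cRMSE^2 = sigma_sim^2 + 1 - 2 sigma_sim r``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class MetricsReport:
    r: float
    rmse: float
    pbias: float
    nse: float
    n: int

    def __post_init__(self) -> None:
        if not (math.isnan(self.r) or -1.0 - 1e-9 <= self.r <= 1.0 + 1e-9):
            raise ValueError("r outside [-1, 1]")
        if self.rmse < 0:
            raise ValueError("RMSE negative")


@dataclass(frozen=True)
class TaylorStats:
    sigma: float  # SD of simulation, normalized by SD of observations
    r: float
    crmse: float  # centered RMSE, normalized

    def __post_init__(self) -> None:
        # law-of-cosines identity of the Taylor diagram
        if not math.isnan(self.r):
            expected = self.sigma ** 2 + 1.0 - 2.0 * self.sigma * self.r
            if abs(self.crmse ** 2 - expected) > 1e-9:
                raise ValueError("inconsistent Taylor statistics: "
                                 "cRMSE^2 != sigma^2 + 1 - 2 sigma r")


def metrics(sim, obs) -> MetricsReport:
    sim = np.asarray(sim, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if sim.shape != obs.shape:
        raise ValueError(f"length mismatch: sim {sim.shape}, obs {obs.shape}")
    n = len(sim)
    if n < 2:
        raise ValueError("need at least 2 value pairs")
    err = sim - obs
    rmse = float(np.sqrt(np.mean(err ** 2)))
    obs_sum = obs.sum()
    pbias = float(100.0 * err.sum() / obs_sum) if obs_sum != 0 else float("nan")
    ss_obs = float(np.sum((obs - obs.mean()) ** 2))
    if ss_obs == 0:
        r = float("nan")
        nse = float("nan")
    else:
        sd_sim = sim.std()
        r = float(np.corrcoef(sim, obs)[0, 1]) if sd_sim > 0 else float("nan")
        nse = float(1.0 - np.sum(err ** 2) / ss_obs)
    return MetricsReport(r=r, rmse=rmse, pbias=pbias, nse=nse, n=n)


def taylor_stats(sim, obs) -> TaylorStats:
    sim = np.asarray(sim, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if sim.shape != obs.shape:
        raise ValueError("length mismatch")
    sd_obs = obs.std()
    if sd_obs == 0:
        raise ValueError("observations have zero variance")
    sigma = float(sim.std() / sd_obs)
    sim_c = sim - sim.mean()
    obs_c = obs - obs.mean()
    crmse = float(np.sqrt(np.mean((sim_c - obs_c) ** 2)) / sd_obs)
    r = float(np.corrcoef(sim, obs)[0, 1]) if sim.std() > 0 else float("nan")
    return TaylorStats(sigma=sigma, r=r, crmse=crmse)
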