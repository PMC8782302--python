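"""Climate-change impact statistics and the CV uncertainty decomposition.

The impact of a scenario on a simulated variable Z is the relative change of
medians,

    dZ(%) = 100 * (median(Z_future) - median(Z_baseline)) / median(Z_baseline).

Projection uncertainty is attributed to the ensemble axes (crop model, soil
water model, SOM model, soil heat model, climate model) by a coefficient of
variation procedure: for one target factor, the sample standard deviation of
dZ over that factor's levels is computed within every fixed combination of
the remaining factors, and each SD is normalized by the absolute overall
mean change |dZbar| and expressed as a percentage.  The per-factor CVs are
not a variance partition and need not sum to 100%.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd

from .climate import PerturbationSpec


@dataclass
class ImpactResult:
    variable: str
    median_future: float
    median_baseline: float
    change_pct: float | None  # None when the baseline median is zero

    @property
    def defined(self) -> bool:
        return self.change_pct is not None


def relative_change(future_values, baseline_values, variable: str = "yield") -> ImpactResult:
    """Percent change of medians between future and baseline samples."""
    fut = np.asarray(list(future_values), dtype=float)
    base = np.asarray(list(baseline_values), dtype=float)
    if len(fut) == 0 or len(base) == 0:
        raise ValueError("both samples must be non-empty")
    mf = float(np.median(fut))
    mb = float(np.median(base))
    change = 100.0 * (mf - mb) / mb if mb != 0 else None
    return ImpactResult(variable, mf, mb, change)


@dataclass
class UncertaintyDecomposition:
    factor: str
    sigmas: np.ndarray  # SD of dZ over the target factor, per fixed combination
    overall_mean: float  # dZbar over all cells
    cvs: np.ndarray  # % per fixed combination

    @property
    def median_cv(self) -> float:
        return float(np.median(self.cvs))


def cv_decomposition(results: pd.DataFrame, target_factor: str,
                     value_col: str = "dZ",
                     factor_cols: tuple[str, ...] | None = None,
                     use_variance: bool = False,
                     mean_floor: float = 1e-9) -> UncertaintyDecomposition:
    """CV of the change attributable to one factor, all others held fixed.

    ``results`` must contain one row per factorial cell with the factor
    columns and the change value; the factorial must be complete over the
    target factor within every combination of the other factors.
    ``use_variance`` reports the variance instead of the SD (the printed
    formula's literal reading); the default is the sample SD.
    """
    if factor_cols is None:
        factor_cols = tuple(c for c in ("crop_model", "water_model", "som_model",
                                        "heat_model", "climate_id")
                            if c in results.columns)
    if target_factor not in factor_cols:
        raise ValueError(f"target_factor {target_factor!r} not among {factor_cols}")
    others = [c for c in factor_cols if c != target_factor]
    levels = sorted(results[target_factor].unique())
    if len(levels) < 1:
        raise ValueError("no levels for target factor")

    # completeness check
    missing = []
    if others:
        grouped = results.groupby(others, sort=True)
        for key, g in grouped:
            have = set(g[target_factor])
            lost = [lv for lv in levels if lv not in have]
            if lost:
                missing.append((key, lost))
    if missing:
        raise ValueError(f"incomplete factorial over {target_factor!r}: "
                         f"missing {missing[:5]}")

    overall_mean = float(results[value_col].mean())
    denom = max(abs(overall_mean), mean_floor)

    sigmas = []
    if others:
        for _, g in results.groupby(others, sort=True):
            vals = g.groupby(target_factor)[value_col].mean().to_numpy()
            sigmas.append(np.var(vals, ddof=1) if use_variance
                          else np.std(vals, ddof=1))
    else:
        vals = results.groupby(target_factor)[value_col].mean().to_numpy()
        sigmas.append(np.var(vals, ddof=1) if use_variance else np.std(vals, ddof=1))
    sigmas = np.asarray(sigmas, dtype=float)
    cvs = 100.0 * sigmas / denom
    return UncertaintyDecomposition(target_factor, sigmas, overall_mean, cvs)


def sensitivity_design(fert_levels=(0.0, 40.0, 80.0, 120.0, 160.0),
                       co2_levels=(360.0, 450.0, 540.0, 630.0, 720.0),
                       dT_levels=(0.0, 2.0, 4.0, 6.0),
                       dP_levels=(-0.50, -0.25, 0.0, 0.25, 0.50),
                       n_cross=(0.0, 80.0, 160.0),
                       reference_n: float = 100.0,
                       deduplicate: bool = True) -> list[PerturbationSpec]:
    """Treatment grid of the sensitivity analysis.

    Fertilizer-only scenarios at the reference climate, plus
    one-factor-at-a-time CO2 / temperature / precipitation scenarios, each
    crossed with the N-cross fertilizer levels.  With ``deduplicate`` the
    repeated reference points are removed; ordering is deterministic.
    """
    for name, lv in (("fert_levels", fert_levels), ("co2_levels", co2_levels),
                     ("dT_levels", dT_levels), ("dP_levels", dP_levels),
                     ("n_cross", n_cross)):
        if not len(lv):
            raise ValueError(f"{name} is empty")
    specs: list[PerturbationSpec] = []
    for f in fert_levels:
        specs.append(PerturbationSpec(dT=0.0, dP=0.0, co2=360.0, n_fert=f))
    for c, n in product(co2_levels, n_cross):
        specs.append(PerturbationSpec(dT=0.0, dP=0.0, co2=c, n_fert=n))
    for t, n in product(dT_levels, n_cross):
        specs.append(PerturbationSpec(dT=t, dP=0.0, co2=360.0, n_fert=n))
    for p, n in product(dP_levels, n_cross):
        specs.append(PerturbationSpec(dT=0.0, dP=p, co2=360.0, n_fert=n))
    if deduplicate:
        seen = set()
        unique = []
        for s in specs:
            if s not in seen:
                seen.add(s)
                unique.append(s)
        return unique
    return specs


def plot_taylor(stats_by_label: dict, ax=None):
    """Polar-style Taylor scatter of normalized SD vs correlation.

    ``stats_by_label`` maps a label to a :class:`~agroens.metrics.TaylorStats`.
    Needs matplotlib (not a core dependency).
    """
    import matplotlib.pyplot as plt
    if ax is None:
        _, ax = plt.subplots(subplot_kw={"projection": "polar"})
    for label, t in stats_by_label.items():
        ax.plot(np.arccos(np.clip(t.r, -1, 1)), t.sigma, "o", label=label)
    ax.plot(0.0, 1.0, "g*", markersize=12, label="observation")
    ax.set_thetamin(0)
    ax.set_thetamax(90)
    ax.legend(fontsize="x-small", loc="upper right")
    return ax


def plot_exceedance(curves: dict, ax=None):
    """Probability-of-exceedance curves, one line per label."""
    import matplotlib.pyplot as plt
    if ax is None:
        _, ax = plt.subplots()
    for label, values in curves.items():
        pts = probability_of_exceedance(values)
        v, p = zip(*pts)
        ax.plot(v, p, label=str(label))
    ax.set_xlabel("value")
    ax.set_ylabel("P(exceedance)")
    ax.legend(fontsize="x-small")
    return ax


def probability_of_exceedance(values) -> list[tuple[float, float]]:
    """Empirical exceedance curve with the Weibull plotting position.

    Values are sorted descending; the i-th largest value gets
    P = i / (n + 1), so the curve is non-increasing in the value.
    """
    vals = sorted((float(v) for v in values), reverse=True)
    if not vals:
        raise ValueError("need at least one value")
    n = len(vals)
    return [(v, (i + 1) / (n + 1)) for i, v in enumerate(vals)]
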