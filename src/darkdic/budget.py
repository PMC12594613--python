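"""Depth integration, yield regressions and the four-term metabolism budget.

The budget partitions depth-integrated dark DIC fixation into four terms:

* ammonia-fuelled chemoautotrophy — measured directly as the inhibitor
  difference, integrated over depth;
* nitrite-fuelled chemoautotrophy — measured nitrite oxidation scaled by the
  nitrite-oxidizer culture yield (0.036 mol C per mol N);
* sulfur-fuelled chemoautotrophy — scaled from the ammonia-fuelled term via
  the particulate N:S ratio (17:1) and the sulfide-/ammonia-oxidizer yield
  ratio (0.35 / measured yield);
* heterotrophic DIC fixation — a fixed fraction (10%) of measured
  heterotrophic production.

Integration is the trapezoidal rule over the sampled depth range only;
1 nM d-1 integrated over 1 m equals 1 umol m-2 d-1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import statsmodels.api as sm

from .core import DEFAULT_CONSTANTS, Constants, logger
from .inhibition import TreatmentComparison
from .isotope import RateEstimate


@dataclass
class DepthIntegratedRate:
    """A depth-integrated rate (umol m-2 d-1) over an explicit depth range."""

    value: float
    z_top: float
    z_bottom: float
    method: str = "trapezoid"
    source: str = ""

    def __post_init__(self) -> None:
        if not self.z_top < self.z_bottom:
            raise ValueError("z_top must be shallower than z_bottom")


@dataclass
class YieldFit:
    """OLS fit summary; the slope is the environmental DIC fixation yield."""

    slope: float
    intercept: float
    r_squared: float
    f_statistic: float
    p_value: float
    n: int
    through_origin: bool = False


@dataclass
class StationBudget:
    """Four-term metabolism budget for one station (umol m-2 d-1).

    Components are kept at full precision; ``rounded()`` produces the
    integer report values.  Percentages are relative to the measured total;
    they are NaN when the total is zero.
    """

    station: str
    total_measured: float
    ammonia_fuelled: float
    nitrite_fuelled: float
    sulfur_fuelled: float
    heterotrophic: float
    all_metabolisms: float = field(init=False)
    percentages: dict[str, float] = field(init=False)

    def __post_init__(self) -> None:
        for name in ("total_measured", "ammonia_fuelled", "nitrite_fuelled",
                     "sulfur_fuelled", "heterotrophic"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        self.all_metabolisms = (self.ammonia_fuelled + self.nitrite_fuelled
                                + self.sulfur_fuelled + self.heterotrophic)
        denom = self.total_measured
        if denom == 0.0:
            logger.warning("station %s: zero measured total, percentages undefined",
                           self.station)
        self.percentages = {
            name: (100.0 * getattr(self, name) / denom if denom > 0 else np.nan)
            for name in ("ammonia_fuelled", "nitrite_fuelled", "sulfur_fuelled",
                         "heterotrophic", "all_metabolisms")
        }

    def rounded(self) -> dict[str, float]:
        """Report-style values: integer umol m-2 d-1 and integer percent."""
        out = {name: round(getattr(self, name))
               for name in ("total_measured", "ammonia_fuelled", "nitrite_fuelled",
                            "sulfur_fuelled", "heterotrophic", "all_metabolisms")}
        out.update({f"{k}_pct": (round(v) if np.isfinite(v) else np.nan)
                    for k, v in self.percentages.items()})
        return out


def integrate_profile(
    depths: Sequence[float],
    rates: Sequence[float],
    clip_negative: bool = False,
    source: str = "",
) -> DepthIntegratedRate:
    """Trapezoidal depth integral of a volumetric rate profile.

    Input rates in nM d-1 against depths in m give umol m-2 d-1 directly.
    No extrapolation beyond the shallowest/deepest sample; negative point
    rates (below-detection noise) may optionally be clipped to zero first.
    """
    z = np.asarray(depths, dtype=float)
    r = np.asarray(rates, dtype=float)
    if z.size < 2 or z.size != r.size:
        raise ValueError("need >= 2 matching depth/rate pairs")
    if np.any(np.diff(z) <= 0):
        raise ValueError("depths must be strictly increasing")
    if clip_negative:
        r = np.clip(r, 0.0, None)
    value = float(np.trapezoid(r, z))
    return DepthIntegratedRate(value=value, z_top=float(z[0]),
                               z_bottom=float(z[-1]), source=source)


def _ols(x: np.ndarray, y: np.ndarray, through_origin: bool) -> YieldFit:
    if x.size < 3:
        raise ValueError("need >= 3 points for a regression")
    if np.ptp(x) == 0.0:
        raise ValueError("zero variance in x")
    design = x[:, None] if through_origin else sm.add_constant(x)
    fit = sm.OLS(y, design).fit()
    slope = float(fit.params[-1])
    intercept = 0.0 if through_origin else float(fit.params[0])
    return YieldFit(slope=slope, intercept=intercept,
                    r_squared=float(fit.rsquared),
                    f_statistic=float(fit.fvalue),
                    p_value=float(fit.f_pvalue),
                    n=int(x.size), through_origin=through_origin)


def fit_yield(
    ammonia_oxidation: Sequence[RateEstimate],
    ammonia_fuelled_dic: Sequence[TreatmentComparison],
    include_only_significant: bool = True,
    through_origin: bool = False,
) -> YieldFit:
    """Regress ammonia-fuelled DIC fixation on ammonia oxidation rate.

    The slope is the environmental DIC fixation yield (mol C per mol N).
    By default only experiments with a significant inhibitor effect enter
    the fit, mirroring how paired inhibitor experiments are screened.
    """
    if len(ammonia_oxidation) != len(ammonia_fuelled_dic):
        raise ValueError("paired inputs must have equal length")
    pairs = [
        (ao.mean, comp.difference)
        for ao, comp in zip(ammonia_oxidation, ammonia_fuelled_dic)
        if (comp.significant or not include_only_significant)
    ]
    if len(pairs) < 3:
        raise ValueError("fewer than 3 qualifying experiments")
    x, y = map(np.asarray, zip(*pairs))
    fit = _ols(x.astype(float), y.astype(float), through_origin)
    logger.info("yield fit: slope=%.4f R2=%.3f n=%d", fit.slope, fit.r_squared, fit.n)
    return fit


def regress_rates(
    x: Sequence[RateEstimate] | Sequence[float],
    y: Sequence[RateEstimate] | Sequence[float],
    through_origin: bool = False,
) -> YieldFit:
    """OLS of one rate set on another (e.g. DIC fixation on heterotrophic
    production), with F-test of the model fit; no significance filter."""
    xv = np.asarray([v.mean if isinstance(v, RateEstimate) else v for v in x], float)
    yv = np.asarray([v.mean if isinstance(v, RateEstimate) else v for v in y], float)
    if xv.size != yv.size:
        raise ValueError("x and y must have equal length")
    return _ols(xv, yv, through_origin)


def sulfur_scaling(
    ammonia_fuelled: float,
    yield_aoa_measured: float = 0.05,
    constants: Constants = DEFAULT_CONSTANTS,
) -> float:
    """Sulfur-fuelled chemoautotrophy scaled from the ammonia-fuelled term.

    sulfur = ammonia_fuelled * (1 / N:S) * (yield_SOX / yield_AOA): the
    particulate organic matter delivers ~17x less S than N, but each mole of
    S oxidized fixes more C (0.35 vs the measured ~0.05 for ammonia).
    """
    if ammonia_fuelled < 0:
        raise ValueError("ammonia_fuelled must be >= 0")
    if not yield_aoa_measured > 0:
        raise ValueError("measured ammonia-oxidizer yield must be > 0")
    return ammonia_fuelled / constants.n_to_s * (constants.yield_sox / yield_aoa_measured)


def build_station_budget(
    station: str,
    total: float,
    ammonia_fuelled: float,
    nitrite_oxidation_integrated: float,
    hetero_production_integrated: float,
    yield_aoa_measured: float = 0.05,
    constants: Constants = DEFAULT_CONSTANTS,
) -> StationBudget:
    """Assemble the four-term budget from depth-integrated inputs.

    ``nitrite_oxidation_integrated`` is in umol N m-2 d-1 and
    ``hetero_production_integrated`` in umol C m-2 d-1; the remaining
    inputs are umol (C) m-2 d-1.
    """
    for name, v in (("total", total), ("ammonia_fuelled", ammonia_fuelled),
                    ("nitrite_oxidation", nitrite_oxidation_integrated),
                    ("hetero_production", hetero_production_integrated)):
        if v < 0:
            raise ValueError(f"{name} must be >= 0")
    return StationBudget(
        station=station,
        total_measured=total,
        ammonia_fuelled=ammonia_fuelled,
        nitrite_fuelled=constants.yield_nob * nitrite_oxidation_integrated,
        sulfur_fuelled=sulfur_scaling(ammonia_fuelled, yield_aoa_measured, constants),
        heterotrophic=constants.hetero_dic_fraction * hetero_production_integrated,
    )


def nitrifier_combined_contribution(
    ammonia_fuelled: Sequence[float],
    nitrite_oxidation: Sequence[float],
    total: Sequence[float],
    zones: Sequence[str],
    constants: Constants = DEFAULT_CONSTANTS,
) -> dict[str, tuple[float, float, int]]:
    """Combined nitrifier share of dark DIC fixation per zone.

    Per depth: (ammonia_fuelled + yield_NOB * nitrite_oxidation) / total * 100
    (all volumetric, nM d-1); depths with non-positive totals are excluded
    with a log notice.  Returns zone -> (mean %, s.d. %, n).
    """
    af = np.asarray(ammonia_fuelled, float)
    no = np.asarray(nitrite_oxidation, float)
    tot = np.asarray(total, float)
    if not (af.size == no.size == tot.size == len(zones)):
        raise ValueError("inputs must have equal length")
    groups: dict[str, list[float]] = {}
    for a, nox, t, zone in zip(af, no, tot, zones):
        if not t > 0:
            logger.info("depth with non-positive total excluded from nitrifier share")
            continue
        groups.setdefault(zone, []).append(100.0 * (a + constants.yield_nob * nox) / t)
    return {
        z: (float(np.mean(v)), float(np.std(v, ddof=1)) if len(v) > 1 else 0.0, len(v))
        for z, v in groups.items()
    }
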