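"""Stable-isotope tracer rate estimation.

Ammonia and nitrite oxidation rates follow the classic source/product-pool
tracer bookkeeping: the heavy-isotope atom fraction of the product pool
(NO2-+NO3- for ammonia oxidation, NO3- for nitrite oxidation) rises linearly
while the tracer transfers, so the volumetric rate is

    rate = d(AF_excess)/dt * [product pool] / f_label

where ``f_label`` is the heavy-isotope atom fraction of the substrate pool
after tracer addition.  The product pool is assumed constant at its initial
value and tracer dilution by remineralisation is ignored — the standard
simplification, which the synthetic generator mirrors so that recovery tests
are well-posed.

13C-bicarbonate DIC fixation uses the analogous particulate-organic-carbon
bookkeeping: C fixed = (rise in POC 13C atom fraction) / (labelling excess of
the DIC pool) * [POC].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import DEFAULT_CONSTANTS, Constants, logger

HOURS_PER_DAY = 24.0


class IncubationError(ValueError):
    """Raised for malformed or degenerate incubation series."""


@dataclass
class RateEstimate:
    """A volumetric rate with replicate statistics and a detection limit.

    ``mean`` and ``sd`` are in nM d-1 (N or C depending on ``method``);
    ``sd`` is the sample standard deviation over biological replicates (0
    when only one replicate exists).  Negative means are reported as
    computed, never clipped here; ``below_detection`` flags means smaller
    than the detection limit.
    """

    mean: float
    sd: float
    n: int
    detection_limit: float = np.nan
    method: str = ""
    below_detection: bool = field(init=False)

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if np.isfinite(self.sd) and self.sd < 0:
            raise ValueError("sd must be >= 0")
        self.below_detection = bool(
            np.isfinite(self.detection_limit) and self.mean < self.detection_limit
        )


@dataclass
class IncubationSeries:
    """Timepointed product-pool atom fractions for one tracer experiment.

    ``af_product`` has shape (n_replicates, n_timepoints); entries may be
    NaN for lost samples.  A replicate without a 0 h measurement is dropped
    from the rate estimate (its atom-fraction excess is undefined).
    """

    experiment_id: str
    station: str
    depth: float
    treatment: str
    tracer: str                       # "15NH4" or "15NO2"
    timepoints_h: np.ndarray
    af_product: np.ndarray
    product_pool_nm: float
    substrate_label_fraction: float

    def __post_init__(self) -> None:
        self.timepoints_h = np.asarray(self.timepoints_h, dtype=float)
        self.af_product = np.atleast_2d(np.asarray(self.af_product, dtype=float))
        if self.timepoints_h.size < 2 or 0.0 not in self.timepoints_h:
            raise IncubationError("need >= 2 timepoints including 0 h")
        if self.af_product.shape[1] != self.timepoints_h.size:
            raise IncubationError("af_product columns must match timepoints")
        if self.af_product.shape[0] < 1:
            raise IncubationError("need >= 1 replicate")
        finite = self.af_product[np.isfinite(self.af_product)]
        if np.any((finite < 0) | (finite > 1)):
            raise IncubationError("atom fractions must lie in [0, 1]")


def delta_to_atom_fraction(delta, reference_ratio: float) -> np.ndarray | float:
    """Convert delta notation (per mil) to heavy-isotope atom fraction.

    AF = R/(1+R) with R = R_ref * (delta/1000 + 1).  delta must exceed
    -1000 per mil (R would be non-positive otherwise).
    """
    delta = np.asarray(delta, dtype=float)
    if np.any(delta <= -1000.0):
        raise ValueError("delta values must be > -1000 per mil")
    r = reference_ratio * (delta / 1000.0 + 1.0)
    out = r / (1.0 + r)
    return float(out) if out.ndim == 0 else out


def atom_fraction_to_delta(af, reference_ratio: float) -> np.ndarray | float:
    """Exact inverse of :func:`delta_to_atom_fraction`."""
    af = np.asarray(af, dtype=float)
    if np.any((af <= 0) | (af >= 1)):
        raise ValueError("atom fraction must lie in (0, 1)")
    r = af / (1.0 - af)
    out = (r / reference_ratio - 1.0) * 1000.0
    return float(out) if out.ndim == 0 else out


def _replicate_slopes_per_day(
    timepoints_h: np.ndarray, af: np.ndarray
) -> np.ndarray:
    """OLS slope of atom-fraction excess vs time (d-1), one per replicate.

    The 0 h measurement of each replicate defines its own baseline;
    replicates missing that baseline yield NaN and are excluded upstream.
    """
    t_d = timepoints_h / HOURS_PER_DAY
    i0 = int(np.flatnonzero(timepoints_h == 0.0)[0])
    slopes = np.full(af.shape[0], np.nan)
    for r in range(af.shape[0]):
        row = af[r]
        if not np.isfinite(row[i0]):
            logger.warning("replicate %d lacks a 0 h sample; excluded", r)
            continue
        excess = row - row[i0]
        ok = np.isfinite(excess)
        if ok.sum() < 2:
            continue
        slopes[r] = np.polyfit(t_d[ok], excess[ok], 1)[0]
    return slopes


def dugdale_goering_rate(series: IncubationSeries) -> RateEstimate:
    """Source/product tracer rate estimate for one incubation series.

    Each replicate gets its own OLS slope of product-pool atom-fraction
    excess versus time; the slope is scaled by pool size over labelling
    fraction.  Mean and s.d. are taken across replicates (not a pooled
    regression), matching how replicate incubations are usually reported.
    """
    if not series.substrate_label_fraction > 0:
        raise IncubationError("substrate label fraction must be > 0")
    slopes = _replicate_slopes_per_day(series.timepoints_h, series.af_product)
    rates = slopes * series.product_pool_nm / series.substrate_label_fraction
    rates = rates[np.isfinite(rates)]
    if rates.size == 0:
        raise IncubationError("no replicate with usable timepoints")
    sd = float(np.std(rates, ddof=1)) if rates.size > 1 else 0.0
    method = "15N-" + ("ammonia-oxidation" if series.tracer == "15NH4"
                       else "nitrite-oxidation")
    return RateEstimate(mean=float(np.mean(rates)), sd=sd, n=int(rates.size),
                        method=method)


def nitrification_detection_limit(
    t0_af: np.ndarray,
    duration_h: float,
    product_pool_nm: float,
    substrate_label_fraction: float,
) -> float:
    """Minimum resolvable rate from the scatter of time-zero measurements.

    The detection limit is the rate that would shift the product-pool atom
    fraction by three standard deviations of the T0 replicates over the full
    incubation, pushed through the same transformation as the rate itself:

        DL = 3 * sd(AF_T0) / duration * pool / f_label        (nM d-1)
    """
    t0_af = np.asarray(t0_af, dtype=float)
    if t0_af.size < 2:
        raise IncubationError("need >= 2 T0 replicate measurements")
    if not (duration_h > 0 and product_pool_nm >= 0 and substrate_label_fraction > 0):
        raise IncubationError("invalid detection-limit geometry")
    sd0 = float(np.std(t0_af, ddof=1))
    duration_d = duration_h / HOURS_PER_DAY
    return 3.0 * sd0 / duration_d * product_pool_nm / substrate_label_fraction


def c13_dic_fixation_rate(
    poc_af_t: np.ndarray,
    poc_af_0: float,
    dic_label_af: float,
    dic_ambient_af: float,
    poc_um: float,
    duration_d: float,
    t0_af: np.ndarray | None = None,
) -> RateEstimate:
    """DIC fixation rate from 13C enrichment of particulate organic carbon.

    rate = (AF_POC,t - AF_POC,0) / (AF_DIC,label - AF_DIC,ambient)
           * [POC] / duration, in nM C d-1 with [POC] in uM.

    ``poc_af_t`` holds one endpoint atom fraction per replicate.  If T0
    replicate atom fractions are given, the detection limit is the rate
    producing a POC atom-fraction change of 3 * sd(T0) over the incubation.
    """
    excess = dic_label_af - dic_ambient_af
    if not excess > 0:
        raise IncubationError("DIC labelling excess must be positive")
    if not duration_d > 0:
        raise IncubationError("duration must be positive")
    poc_nm = poc_um * 1000.0
    rates = (np.asarray(poc_af_t, dtype=float) - poc_af_0) / excess * poc_nm / duration_d
    rates = rates[np.isfinite(rates)]
    if rates.size == 0:
        raise IncubationError("no finite replicate measurement")
    sd = float(np.std(rates, ddof=1)) if rates.size > 1 else 0.0
    dl = np.nan
    if t0_af is not None and np.size(t0_af) >= 2:
        dl = 3.0 * float(np.std(np.asarray(t0_af, float), ddof=1)) / excess \
            * poc_nm / duration_d
    return RateEstimate(mean=float(np.mean(rates)), sd=sd, n=int(rates.size),
                        detection_limit=dl, method="13C-DIC-fixation")


def dic_labeling_atom_fraction(
    addition_fraction: float,
    tracer_af: float = 0.99,
    constants: Constants = DEFAULT_CONSTANTS,
) -> float:
    """13C atom fraction of a DIC pool after a fractional tracer addition.

    A spike of ``addition_fraction`` (e.g. 0.2 for a 20% addition of the
    ambient bicarbonate pool) at tracer atom fraction ``tracer_af`` mixes
    with natural-abundance DIC.
    """
    if not addition_fraction > 0:
        raise ValueError("addition fraction must be > 0")
    a_nat = constants.a_nat_13c
    return (addition_fraction * tracer_af + a_nat) / (1.0 + addition_fraction)
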