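"""Paired control-vs-inhibitor comparisons.

Phenylacetylene irreversibly inhibits the ammonia monooxygenase enzyme, so
the control-minus-inhibited difference of dark DIC fixation isolates the
ammonia-fuelled fraction.  This module computes those differences with
propagated replicate uncertainty, Student's t-tests (pooled variance by
default, Welch by flag), Bonferroni adjustment and per-zone summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .core import ZoneLabel, logger


@dataclass
class TreatmentComparison:
    """Control vs treated rates with propagated error and test outcome.

    ``difference`` is control minus treated (the inhibitor-sensitive rate),
    ``propagated_sd`` the quadrature sum of the two group s.d.s, and
    ``percent_inhibition`` the difference as a percentage of the control
    mean (NaN when the control mean is not a usable denominator, e.g. a
    below-detection control).
    """

    control_mean: float
    control_sd: float
    n_control: int
    treated_mean: float
    treated_sd: float
    n_treated: int
    difference: float
    propagated_sd: float
    percent_inhibition: float
    t_statistic: float
    p_value: float
    sidedness: str
    p_adjusted: float = np.nan
    significant: bool = False
    zone: ZoneLabel | None = None
    label: str = ""


def compare_treatments(
    control_reps: Sequence[float],
    treated_reps: Sequence[float],
    sidedness: str = "one",
    alpha: float = 0.05,
    welch: bool = False,
    control_below_detection: bool = False,
    label: str = "",
) -> TreatmentComparison:
    """Compare replicate rates between a control and an inhibited treatment.

    One-sided tests take H1: control > treated (inhibition); two-sided tests
    detect both inhibition and stimulation.  When both groups have zero
    variance and equal means the p value is 1 by convention.  ``significant``
    is set from the raw p here and re-evaluated after Bonferroni adjustment
    by :func:`adjust_bonferroni_comparisons`.
    """
    c = np.asarray(control_reps, dtype=float)
    t = np.asarray(treated_reps, dtype=float)
    if c.size < 2 or t.size < 2:
        raise ValueError("need >= 2 replicates per group")
    if sidedness not in ("one", "two"):
        raise ValueError("sidedness must be 'one' or 'two'")

    c_mean, t_mean = float(np.mean(c)), float(np.mean(t))
    c_sd = float(np.std(c, ddof=1))
    t_sd = float(np.std(t, ddof=1))
    diff = c_mean - t_mean
    prop_sd = float(np.hypot(c_sd, t_sd))

    if c_sd == 0.0 and t_sd == 0.0:
        if diff == 0.0:
            logger.info("zero variance and equal means: p = 1 by convention")
            t_stat, p = 0.0, 1.0
        else:
            t_stat = np.inf if diff > 0 else -np.inf
            p = 0.0 if (sidedness == "two" or diff > 0) else 1.0
    else:
        alternative = "greater" if sidedness == "one" else "two-sided"
        res = stats.ttest_ind(c, t, equal_var=not welch, alternative=alternative)
        t_stat, p = float(res.statistic), float(res.pvalue)

    if control_below_detection or c_mean == 0.0:
        pct = np.nan
    else:
        pct = 100.0 * diff / c_mean

    return TreatmentComparison(
        control_mean=c_mean, control_sd=c_sd, n_control=int(c.size),
        treated_mean=t_mean, treated_sd=t_sd, n_treated=int(t.size),
        difference=diff, propagated_sd=prop_sd, percent_inhibition=pct,
        t_statistic=t_stat, p_value=p, sidedness=sidedness,
        p_adjusted=p, significant=bool(p < alpha), label=label,
    )


def compare_treatments_summary(
    control_mean: float, control_sd: float, n_control: int,
    treated_mean: float, treated_sd: float, n_treated: int,
    sidedness: str = "one",
    alpha: float = 0.05,
    control_below_detection: bool = False,
    label: str = "",
) -> TreatmentComparison:
    """Pooled-variance Student's t-test from per-arm summary statistics.

    Equivalent to :func:`compare_treatments` when only mean/sd/n per arm are
    available (e.g. from a rates table).
    """
    if n_control < 2 or n_treated < 2:
        raise ValueError("need >= 2 replicates per group")
    if sidedness not in ("one", "two"):
        raise ValueError("sidedness must be 'one' or 'two'")
    diff = control_mean - treated_mean
    df = n_control + n_treated - 2
    pooled_var = ((n_control - 1) * control_sd ** 2
                  + (n_treated - 1) * treated_sd ** 2) / df
    se = np.sqrt(pooled_var * (1.0 / n_control + 1.0 / n_treated))
    if se == 0.0:
        t_stat = 0.0 if diff == 0.0 else np.copysign(np.inf, diff)
        if diff == 0.0:
            p = 1.0
        else:
            p = 0.0 if (sidedness == "two" or diff > 0) else 1.0
    else:
        t_stat = diff / se
        sf = float(stats.t.sf(t_stat, df))
        p = sf if sidedness == "one" else 2.0 * float(stats.t.sf(abs(t_stat), df))
    pct = np.nan if (control_below_detection or control_mean == 0.0) \
        else 100.0 * diff / control_mean
    return TreatmentComparison(
        control_mean=float(control_mean), control_sd=float(control_sd),
        n_control=int(n_control), treated_mean=float(treated_mean),
        treated_sd=float(treated_sd), n_treated=int(n_treated),
        difference=float(diff), propagated_sd=float(np.hypot(control_sd, treated_sd)),
        percent_inhibition=pct, t_statistic=float(t_stat), p_value=float(p),
        sidedness=sidedness, p_adjusted=float(p), significant=bool(p < alpha),
        label=label,
    )


def adjust_bonferroni(p_values: Sequence[float]) -> np.ndarray:
    """Bonferroni family-wise adjustment: p_adj = min(1, m * p)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value family")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    return np.minimum(1.0, p.size * p)


def adjust_bonferroni_comparisons(
    comparisons: Sequence[TreatmentComparison], alpha: float = 0.05
) -> list[TreatmentComparison]:
    """Adjust a batch of comparisons as one Bonferroni family (in place).

    The family is simply the batch submitted together; callers control
    family membership by what they pass.
    """
    logger.info("Bonferroni family of size %d at alpha=%g", len(comparisons), alpha)
    adj = adjust_bonferroni([c.p_value for c in comparisons])
    for comp, pa in zip(comparisons, adj):
        comp.p_adjusted = float(pa)
        comp.significant = bool(pa < alpha)
    return list(comparisons)


def normality_check(replicates: Sequence[float]) -> tuple[float, float]:
    """Shapiro-Wilk W and p for one replicate set (advisory only).

    Requires 3 <= n <= 50 and a non-constant sample; the result never gates
    the t-test, it is just logged alongside it.
    """
    x = np.asarray(replicates, dtype=float)
    if not 3 <= x.size <= 50:
        raise ValueError("Shapiro-Wilk check requires 3 <= n <= 50")
    if np.ptp(x) == 0.0:
        raise ValueError("Shapiro-Wilk undefined for a constant sample")
    res = stats.shapiro(x)
    logger.info("Shapiro-Wilk W=%.4f p=%.4f (n=%d)", res.statistic, res.pvalue, x.size)
    return float(res.statistic), float(res.pvalue)


def zone_inhibition_summary(
    comparisons: Iterable[TreatmentComparison],
) -> dict[str, tuple[float, float, int]]:
    """Mean, s.d. and count of percent inhibition per vertical zone.

    Comparisons without a zone label or with undefined percent inhibition
    are skipped with a log notice; zones with a single comparison report
    s.d. 0.
    """
    groups: dict[str, list[float]] = {}
    for comp in comparisons:
        if comp.zone is None or not np.isfinite(comp.percent_inhibition):
            logger.info("comparison %r skipped in zone summary", comp.label)
            continue
        groups.setdefault(comp.zone.zone, []).append(comp.percent_inhibition)
    out = {}
    for zone, vals in groups.items():
        arr = np.asarray(vals)
        sd = float(np.std(arr, ddof=1)) if arr.size > 1 else 0.0
        out[zone] = (float(np.mean(arr)), sd, int(arr.size))
    return out
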