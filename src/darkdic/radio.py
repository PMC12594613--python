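"""Radiotracer rate estimation: 14C-bicarbonate DIC fixation and 3H-leucine
heterotrophic production from scintillation counts.

Both assays share the same skeleton: subtract the killed-control blank from
the live disintegrations per minute (DPM), convert net DPM to moles via the
added activity, and normalise by incubation time (and volume for leucine).
No isotope-discrimination factor is applied to 14C by default; a multiplier
is exposed for users who want one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import DEFAULT_CONSTANTS, MOLAR_MASS_C, Constants, logger
from .isotope import IncubationError, RateEstimate


@dataclass
class RadioIncubation:
    """Per-bottle scintillation observables for one radiotracer experiment.

    For 14C, ``dpm_total_added`` is the total activity added per bottle and
    ``dic_um`` the in situ DIC concentration.  For 3H-leucine,
    ``sa_ci_per_mmol`` (specific activity) and ``sample_volume_l`` convert
    net DPM to a volumetric leucine incorporation rate.
    """

    experiment_id: str
    station: str
    depth: float
    treatment: str
    isotope: str                      # "14C" or "3H"
    dpm_live: np.ndarray
    dpm_killed: np.ndarray
    duration_d: float
    dpm_total_added: float = np.nan   # 14C
    dic_um: float = np.nan            # 14C
    sa_ci_per_mmol: float = np.nan    # 3H
    sample_volume_l: float = np.nan   # 3H
    dpm_t0: np.ndarray | None = None  # optional T0 bottles for detection limit

    def __post_init__(self) -> None:
        self.dpm_live = np.atleast_1d(np.asarray(self.dpm_live, dtype=float))
        self.dpm_killed = np.atleast_1d(np.asarray(self.dpm_killed, dtype=float))
        if self.isotope not in ("14C", "3H"):
            raise IncubationError(f"unknown isotope {self.isotope!r}")
        if self.dpm_killed.size < 1:
            raise IncubationError("need at least one killed control")
        if np.any(self.dpm_live < 0) or np.any(self.dpm_killed < 0):
            raise IncubationError("DPM must be >= 0")
        if not self.duration_d > 0:
            raise IncubationError("duration must be > 0")


def _blank(inc: RadioIncubation) -> tuple[float, float, int]:
    """Mean, s.d. and n of the killed-control blank (s.d. 0 for n = 1)."""
    n = inc.dpm_killed.size
    mean = float(np.mean(inc.dpm_killed))
    sd = float(np.std(inc.dpm_killed, ddof=1)) if n > 1 else 0.0
    return mean, sd, n


def _replicate_stats(
    rates: np.ndarray, blank_rate_sd_of_mean: float
) -> tuple[float, float, int]:
    """Replicate mean/s.d., with the blank-mean uncertainty (already in rate
    units) folded into the s.d. in quadrature when available."""
    mean = float(np.mean(rates))
    sd = float(np.std(rates, ddof=1)) if rates.size > 1 else 0.0
    sd = float(np.hypot(sd, blank_rate_sd_of_mean))
    return mean, sd, int(rates.size)


def c14_dic_fixation_rate(
    inc: RadioIncubation, discrimination: float = 1.0
) -> RateEstimate:
    """DIC fixation rate from 14C-bicarbonate incorporation.

    rate = (DPM_live - mean(DPM_killed)) / DPM_total * [DIC] / duration
    in nM C d-1 with [DIC] in uM.  The detection limit is the rate producing
    a net DPM change of 3 * sd of the T0 bottles (killed controls when no
    T0 bottles exist; requires >= 2 such measurements, else NaN).

    The blank-mean uncertainty is propagated into the replicate s.d. when
    two or more killed controls exist.
    """
    if inc.isotope != "14C":
        raise IncubationError("c14_dic_fixation_rate requires a 14C incubation")
    if not inc.dpm_total_added > 0:
        raise IncubationError("total added activity must be > 0")
    blank_mean, blank_sd, n_blank = _blank(inc)
    dic_nm = inc.dic_um * 1000.0
    to_rate = dic_nm / inc.dpm_total_added / inc.duration_d * discrimination
    rates = (inc.dpm_live - blank_mean) * to_rate
    blank_term = blank_sd / np.sqrt(n_blank) * to_rate if n_blank > 1 else 0.0
    mean, sd, n = _replicate_stats(rates, blank_term)

    ref = inc.dpm_t0 if inc.dpm_t0 is not None and np.size(inc.dpm_t0) >= 2 \
        else (inc.dpm_killed if n_blank >= 2 else None)
    dl = np.nan
    if ref is not None:
        dl = 3.0 * float(np.std(np.asarray(ref, float), ddof=1)) * to_rate
    return RateEstimate(mean=mean, sd=sd, n=n, detection_limit=dl,
                        method="14C-DIC-fixation")


def total_activity_check(
    measured_total_dpm: float,
    nominal_uci: float,
    tolerance: float = 0.10,
    constants: Constants = DEFAULT_CONSTANTS,
) -> float:
    """Relative deviation of measured total activity from the nominal spike.

    deviation = measured / (nominal_uCi * DPM_per_Ci * 1e-6) - 1; a warning
    is logged when |deviation| exceeds ``tolerance``.
    """
    if not nominal_uci > 0:
        raise ValueError("nominal activity must be > 0")
    expected_dpm = nominal_uci * constants.dpm_per_ci * 1e-6
    deviation = measured_total_dpm / expected_dpm - 1.0
    if abs(deviation) > tolerance:
        logger.warning(
            "total activity deviates %.1f%% from nominal %.1f uCi",
            100 * deviation, nominal_uci,
        )
    return deviation


def leucine_rate(
    inc: RadioIncubation, constants: Constants = DEFAULT_CONSTANTS
) -> tuple[RateEstimate, float]:
    """Heterotrophic production from 3H-leucine incorporation.

    Net DPM are converted to moles of leucine via the specific activity
    (DPM_per_Ci * Ci mol-1), to a volumetric incorporation rate over sample
    volume and duration, and to carbon units with the empirical
    1.5 kg C per mol leucine factor (then nM C d-1 via 12.011 g mol-1 C).

    Returns the carbon-unit estimate and the native incorporation rate of
    the replicate mean in pmol leucine l-1 h-1.
    """
    if inc.isotope != "3H":
        raise IncubationError("leucine_rate requires a 3H incubation")
    if not inc.sa_ci_per_mmol > 0:
        raise IncubationError("specific activity must be > 0")
    if not inc.sample_volume_l > 0:
        raise IncubationError("sample volume must be > 0")
    blank_mean, blank_sd, n_blank = _blank(inc)
    sa_ci_per_mol = inc.sa_ci_per_mmol * 1000.0
    # mol leucine per net DPM
    mol_per_dpm = 1.0 / (constants.dpm_per_ci * sa_ci_per_mol)
    # nM C d-1 per net DPM: mol leu -> kg C -> mol C -> nmol C, per l per d
    to_c_rate = (
        mol_per_dpm * constants.leucine_to_c * 1000.0 / MOLAR_MASS_C
        * 1e9 / inc.sample_volume_l / inc.duration_d
    )
    rates_c = (inc.dpm_live - blank_mean) * to_c_rate
    blank_term = blank_sd / np.sqrt(n_blank) * to_c_rate if n_blank > 1 else 0.0
    mean, sd, n = _replicate_stats(rates_c, blank_term)

    ref = inc.dpm_t0 if inc.dpm_t0 is not None and np.size(inc.dpm_t0) >= 2 \
        else (inc.dpm_killed if n_blank >= 2 else None)
    dl = np.nan
    if ref is not None:
        dl = 3.0 * float(np.std(np.asarray(ref, float), ddof=1)) * to_c_rate

    mean_net_dpm = float(np.mean(inc.dpm_live)) - blank_mean
    native_pmol_l_h = (
        mean_net_dpm * mol_per_dpm * 1e12 / inc.sample_volume_l
        / (inc.duration_d * 24.0)
    )
    est = RateEstimate(mean=mean, sd=sd, n=n, detection_limit=dl,
                       method="3H-leucine")
    return est, native_pmol_l_h
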