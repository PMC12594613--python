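"""Synthetic station and incubation generator with known ground truth.

The generator emulates the depth structure of a tropical-Pacific station:
a subsurface chlorophyll maximum, an ammonia-oxidation peak near the base of
the euphotic zone with an exponential decline below, nitrite oxidation
proportional to ammonia oxidation, heterotrophic production decaying
exponentially from the surface, and (optionally) an oxygen-deficient layer.
True total dark DIC fixation is composed exactly as the budget model
assumes:

    F(z) = y_AOA * R_AO(z) + y_NOB * R_NO(z) + f_het * P_het(z) + background

Raw incubation observables are obtained by inverting the rate estimators:
product-pool atom fractions grow linearly, net DPM grow linearly, and the
phenylacetylene treatment removes exactly the ammonia-fuelled term.  Noise
is multiplicative lognormal on replicate rates plus small additive
measurement noise (atom fraction / DPM counts, floored at zero for DPM), so
biological replicate scatter dominates and all rates remain positive.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .core import DEFAULT_CONSTANTS, Constants, DepthSample, StationProfile
from .isotope import HOURS_PER_DAY, IncubationSeries
from .radio import RadioIncubation

CONTROL = "control"
PA = "+PA"
DMSO = "+DMSO"
KILLED = "killed"
TREATMENTS = (CONTROL, PA, DMSO, KILLED)

#: DPM in a 50 uCi spike (50e-6 Ci * 2.22e12 DPM/Ci)
DPM_50_UCI = 1.11e8


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground-truth configuration of a synthetic station.

    Defaults reflect the study conditions the estimators are meant for:
    triplicate bottles, 70-200 nM 15N additions at 98-99 atom%, a 50 uCi
    14C spike (specific activity 56 mCi mmol-1), 20 nM 3H-leucine at
    44.9 Ci mmol-1, 0/12/24 h nitrification timepoints, and an
    ammonia-oxidation peak (default 30 nM d-1, within the observed
    0.4-64 nM d-1 span) at the euphotic-zone base.
    """

    seed: int = 0
    depths: tuple[float, ...] = (20, 40, 60, 80, 100, 120, 150, 200, 250, 300, 450, 600)
    euphotic_depth_true: float = 90.0
    ao_peak_rate: float = 30.0          # nM N d-1
    ao_peak_depth: float | None = None  # m; defaults to the euphotic base
    ao_peak_width: float = 20.0         # m (Gaussian sigma)
    ao_deep_tail: float = 1.0           # nM N d-1 at the peak depth
    ao_tail_decay: float = 150.0        # m e-folding of the deep tail
    no_rate_scale: float = 1.0          # nitrite oxidation relative to R_AO
    hetero_surface_rate: float = 20.0   # nM C d-1 at the surface
    hetero_decay: float = 100.0         # m e-folding
    yield_aoa_true: float = 0.05        # mol C per mol N
    background_dic_fix: float = 0.3     # nM C d-1
    replicate_cv: float = 0.10
    n_replicates: int = 3
    tracer_add_15n: float = 100.0       # nM
    label_atom_fraction: float = 0.99
    dpm_total_14c: float = DPM_50_UCI
    sa_14c: float = 56.0                # mCi mmol-1
    sa_3h: float = 44.9                 # Ci mmol-1
    incubation_times_h: tuple[float, ...] = (0.0, 12.0, 24.0)
    duration_14c_d: float = 1.0
    duration_3h_h: float = 2.0
    leu_volume_l: float = 1.6e-3
    af_measurement_sd: float = 4e-6     # atom-fraction analytical noise
    dpm_count_sd: float = 5.0           # additive DPM counting noise
    killed_dpm_14c: float = 50.0
    killed_dpm_3h: float = 40.0
    n_killed: int = 2
    n_t0: int = 3
    include_odz: bool = True

    def __post_init__(self) -> None:
        for name in ("ao_peak_rate", "ao_deep_tail", "hetero_surface_rate",
                     "background_dic_fix", "no_rate_scale"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.replicate_cv < 0:
            raise ValueError("replicate_cv must be >= 0")
        # yield 0 is admitted as the no-inhibition null configuration
        if not 0.0 <= self.yield_aoa_true < 0.2:
            raise ValueError("yield_aoa_true must lie in [0, 0.2)")
        if not 70.0 <= self.tracer_add_15n <= 200.0:
            raise ValueError("tracer_add_15n must lie in [70, 200] nM")
        if not 0.0 < self.label_atom_fraction <= 1.0:
            raise ValueError("label_atom_fraction must lie in (0, 1]")

    @property
    def peak_depth(self) -> float:
        return self.euphotic_depth_true if self.ao_peak_depth is None else self.ao_peak_depth

    def noise_free(self) -> "SyntheticTruth":
        """Copy with every noise source switched off (for identity tests)."""
        return replace(self, replicate_cv=0.0, af_measurement_sd=0.0,
                       dpm_count_sd=0.0)

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


# ---------------------------------------------------------------------------
# True rate and environmental profiles
# ---------------------------------------------------------------------------

def ammonia_oxidation_profile(truth: SyntheticTruth, z) -> np.ndarray:
    """True ammonia oxidation rate (nM N d-1): Gaussian peak + deep tail."""
    z = np.asarray(z, dtype=float)
    peak = truth.peak_depth
    gauss = truth.ao_peak_rate * np.exp(-0.5 * ((z - peak) / truth.ao_peak_width) ** 2)
    tail = truth.ao_deep_tail * np.exp(-np.maximum(z - peak, 0.0) / truth.ao_tail_decay)
    return gauss + tail


def nitrite_oxidation_profile(truth: SyntheticTruth, z) -> np.ndarray:
    """True nitrite oxidation rate (nM N d-1), coupled to ammonia oxidation."""
    return truth.no_rate_scale * ammonia_oxidation_profile(truth, z)


def hetero_production_profile(truth: SyntheticTruth, z) -> np.ndarray:
    """True heterotrophic production (nM C d-1), exponential decline."""
    z = np.asarray(z, dtype=float)
    return truth.hetero_surface_rate * np.exp(-z / truth.hetero_decay)


def dic_fixation_profile(
    truth: SyntheticTruth, z, constants: Constants = DEFAULT_CONSTANTS
) -> np.ndarray:
    """True total dark DIC fixation (nM C d-1): the four-term composition."""
    return (
        truth.yield_aoa_true * ammonia_oxidation_profile(truth, z)
        + constants.yield_nob * nitrite_oxidation_profile(truth, z)
        + constants.hetero_dic_fraction * hetero_production_profile(truth, z)
        + truth.background_dic_fix
    )


def _env(truth: SyntheticTruth, z: np.ndarray) -> dict[str, np.ndarray]:
    """Deterministic environmental context profiles."""
    z_eu = truth.euphotic_depth_true
    # chlorophyll: Gaussian whose 10%-of-max level sits at the euphotic base
    sigma = 15.0
    chl_peak = z_eu - sigma * np.sqrt(2.0 * np.log(10.0))
    fluor = np.exp(-0.5 * ((z - chl_peak) / sigma) ** 2)
    if truth.include_odz:
        o2 = np.interp(z, [0, 60, 120, 150, 400, 500, 600],
                       [210, 210, 50, 5, 5, 15, 40])
    else:
        o2 = np.interp(z, [0, 600], [210, 150])
    nh4 = 10.0 + 50.0 * np.exp(-0.5 * ((z - 0.8 * z_eu) / 20.0) ** 2)
    no2 = 10.0 + 240.0 * np.exp(-0.5 * ((z - z_eu) / 20.0) ** 2)
    no3 = np.interp(z, [0, 50, 100, 200, 300, 600], [1, 5, 15, 25, 32, 38])
    dic = 2000.0 + 0.05 * z
    poc = 0.2 + 2.3 * np.exp(-z / 150.0)
    temp = 4.0 + 21.0 * np.exp(-z / 150.0)
    return {"temperature": temp, "oxygen": o2, "fluorescence": fluor,
            "nh4": nh4, "no2": no2, "no3": no3, "dic": dic, "poc": poc}


def generate_station(
    truth: SyntheticTruth,
    station_id: str = "SYN-1",
    constants: Constants = DEFAULT_CONSTANTS,
) -> tuple[StationProfile, dict[str, np.ndarray]]:
    """Build the environmental profile and the true rate profiles.

    Both are deterministic functions of the configuration (noise enters
    only at the incubation-observable level).
    """
    z = np.asarray(truth.depths, dtype=float)
    env = _env(truth, z)
    samples = [
        DepthSample(depth=float(zi),
                    **{k: float(env[k][i]) for k in env})
        for i, zi in enumerate(z)
    ]
    profile = StationProfile(station_id=station_id, cruise="SYN", samples=samples)
    rates = {
        "depths": z,
        "ammonia_oxidation": ammonia_oxidation_profile(truth, z),
        "nitrite_oxidation": nitrite_oxidation_profile(truth, z),
        "hetero_production": hetero_production_profile(truth, z),
        "dic_fixation_total": dic_fixation_profile(truth, z, constants),
    }
    rates["dic_fixation_ammonia"] = truth.yield_aoa_true * rates["ammonia_oxidation"]
    return profile, rates


# ---------------------------------------------------------------------------
# Tracer bookkeeping
# ---------------------------------------------------------------------------

def labeling_fraction(
    added_nm: float,
    added_af: float,
    ambient_nm: float,
    constants: Constants = DEFAULT_CONSTANTS,
) -> float:
    """Heavy-isotope atom fraction of the substrate pool after the spike.

    f_label = (added * a_label + ambient * a_nat) / (added + ambient),
    the tracer mixing with natural-abundance substrate.
    """
    if not added_nm > 0:
        raise ValueError("added tracer must be > 0")
    if ambient_nm < 0:
        raise ValueError("ambient concentration must be >= 0")
    a_nat = constants.a_nat_15n
    return (added_nm * added_af + ambient_nm * a_nat) / (added_nm + ambient_nm)


def _rate_multipliers(rng: np.random.Generator, n: int, cv: float) -> np.ndarray:
    """Mean-one lognormal replicate multipliers with the given CV."""
    if cv == 0.0:
        return np.ones(n)
    sigma2 = np.log1p(cv ** 2)
    return rng.lognormal(mean=-0.5 * sigma2, sigma=np.sqrt(sigma2), size=n)


def _check_treatment(treatment: str) -> None:
    if treatment not in TREATMENTS:
        raise ValueError(f"unknown treatment {treatment!r}; expected one of {TREATMENTS}")


# ---------------------------------------------------------------------------
# Incubation observables
# ---------------------------------------------------------------------------

def generate_nitrification_series(
    truth: SyntheticTruth,
    depth: float,
    treatment: str = CONTROL,
    tracer: str = "15NH4",
    rng: np.random.Generator | None = None,
    constants: Constants = DEFAULT_CONSTANTS,
) -> IncubationSeries:
    """Simulate a 15N tracer incubation series at one depth.

    The product-pool atom fraction grows linearly at the replicate's true
    rate: AF(t) = a_nat + R * f_label * t / pool, plus analytical noise.
    Phenylacetylene zeroes ammonia oxidation (15NH4 series) but leaves
    nitrite oxidation untouched; killed bottles have zero rate.
    """
    _check_treatment(treatment)
    rng = truth.rng() if rng is None else rng
    env = _env(truth, np.array([depth]))
    if tracer == "15NH4":
        rate = float(ammonia_oxidation_profile(truth, depth))
        if treatment in (PA, KILLED):
            rate = 0.0
        ambient = float(env["nh4"][0])
        pool = float(env["no2"][0] + env["no3"][0] * 1000.0)  # NO2- + NO3-, nM
    elif tracer == "15NO2":
        rate = float(nitrite_oxidation_profile(truth, depth))
        if treatment == KILLED:
            rate = 0.0
        ambient = float(env["no2"][0])
        pool = float(env["no3"][0] * 1000.0)                  # NO3-, nM
    else:
        raise ValueError(f"unknown tracer {tracer!r}")

    f_label = labeling_fraction(truth.tracer_add_15n, truth.label_atom_fraction,
                                ambient, constants)
    t_h = np.asarray(truth.incubation_times_h, dtype=float)
    mult = _rate_multipliers(rng, truth.n_replicates, truth.replicate_cv)
    slope_per_day = mult * rate * f_label / pool
    af = (constants.a_nat_15n
          + slope_per_day[:, None] * (t_h / HOURS_PER_DAY)[None, :])
    if truth.af_measurement_sd > 0:
        af = af + rng.normal(0.0, truth.af_measurement_sd, size=af.shape)
    return IncubationSeries(
        experiment_id=f"{tracer}-{depth:g}m-{treatment}",
        station="SYN-1", depth=depth, treatment=treatment, tracer=tracer,
        timepoints_h=t_h, af_product=np.clip(af, 0.0, 1.0),
        product_pool_nm=pool, substrate_label_fraction=f_label,
    )


def _dic_components(
    truth: SyntheticTruth, depth: float, treatment: str, constants: Constants
) -> np.ndarray:
    """Expected per-process DIC fixation terms (nM C d-1) for one bottle.

    Order: ammonia-fuelled, nitrite-fuelled, heterotrophic, background.
    Phenylacetylene removes exactly the ammonia-fuelled term; killed
    bottles fix nothing.
    """
    if treatment == KILLED:
        return np.zeros(4)
    comps = np.array([
        truth.yield_aoa_true * float(ammonia_oxidation_profile(truth, depth)),
        constants.yield_nob * float(nitrite_oxidation_profile(truth, depth)),
        constants.hetero_dic_fraction * float(hetero_production_profile(truth, depth)),
        truth.background_dic_fix,
    ])
    if treatment == PA:
        comps[0] = 0.0
    return comps


def generate_dic_incubation(
    truth: SyntheticTruth,
    depth: float,
    treatment: str = CONTROL,
    rng: np.random.Generator | None = None,
    constants: Constants = DEFAULT_CONSTANTS,
) -> RadioIncubation:
    """Simulate a 14C-bicarbonate incubation at one depth.

    DPM_live = blank + R * duration * DPM_total / [DIC], with lognormal
    replicate scatter applied independently to each metabolic component of
    R (the populations carrying out the different processes fluctuate
    independently between bottles) and additive counting noise on every
    bottle.
    """
    _check_treatment(treatment)
    rng = truth.rng() if rng is None else rng
    dic_um = float(_env(truth, np.array([depth]))["dic"][0])
    comps = _dic_components(truth, depth, treatment, constants)
    mult = np.stack([
        _rate_multipliers(rng, truth.n_replicates, truth.replicate_cv)
        for _ in comps
    ], axis=1)
    rate_reps = mult @ comps
    net = rate_reps * truth.duration_14c_d * truth.dpm_total_14c / (dic_um * 1000.0)
    live = truth.killed_dpm_14c + net
    killed = np.full(truth.n_killed, truth.killed_dpm_14c)
    t0 = np.full(truth.n_t0, truth.killed_dpm_14c)
    if truth.dpm_count_sd > 0:
        live = live + rng.normal(0.0, truth.dpm_count_sd, live.shape)
        killed = killed + rng.normal(0.0, truth.dpm_count_sd, killed.shape)
        t0 = t0 + rng.normal(0.0, truth.dpm_count_sd, t0.shape)
    return RadioIncubation(
        experiment_id=f"14C-{depth:g}m-{treatment}",
        station="SYN-1", depth=depth, treatment=treatment, isotope="14C",
        dpm_live=np.clip(live, 0.0, None), dpm_killed=np.clip(killed, 0.0, None),
        duration_d=truth.duration_14c_d, dpm_total_added=truth.dpm_total_14c,
        dic_um=dic_um, dpm_t0=np.clip(t0, 0.0, None),
    )


def generate_leucine_incubation(
    truth: SyntheticTruth,
    depth: float,
    treatment: str = CONTROL,
    rng: np.random.Generator | None = None,
    constants: Constants = DEFAULT_CONSTANTS,
) -> RadioIncubation:
    """Simulate a 3H-leucine incubation at one depth.

    Net DPM are the exact inverse of the leucine-to-carbon unit chain, so
    the estimator recovers the configured heterotrophic production rate.
    Phenylacetylene and DMSO do not affect heterotrophic production.
    """
    _check_treatment(treatment)
    rng = truth.rng() if rng is None else rng
    rate_c = float(hetero_production_profile(truth, depth))  # nM C d-1
    if treatment == KILLED:
        rate_c = 0.0
    duration_d = truth.duration_3h_h / HOURS_PER_DAY
    sa_ci_per_mol = truth.sa_3h * 1000.0
    to_c = (1.0 / (constants.dpm_per_ci * sa_ci_per_mol)
            * constants.leucine_to_c * 1000.0 / 12.011
            * 1e9 / truth.leu_volume_l / duration_d)  # nM C d-1 per net DPM
    mult = _rate_multipliers(rng, truth.n_replicates, truth.replicate_cv)
    net = mult * rate_c / to_c
    live = truth.killed_dpm_3h + net
    killed = np.full(truth.n_killed, truth.killed_dpm_3h)
    if truth.dpm_count_sd > 0:
        live = live + rng.normal(0.0, truth.dpm_count_sd, live.shape)
        killed = killed + rng.normal(0.0, truth.dpm_count_sd, killed.shape)
    return RadioIncubation(
        experiment_id=f"3H-{depth:g}m-{treatment}",
        station="SYN-1", depth=depth, treatment=treatment, isotope="3H",
        dpm_live=np.clip(live, 0.0, None), dpm_killed=np.clip(killed, 0.0, None),
        duration_d=duration_d, sa_ci_per_mmol=truth.sa_3h,
        sample_volume_l=truth.leu_volume_l,
    )


def generate_incubations(
    truth: SyntheticTruth,
    depth: float,
    treatment: str = CONTROL,
    rng: np.random.Generator | None = None,
    constants: Constants = DEFAULT_CONSTANTS,
) -> dict[str, IncubationSeries | RadioIncubation]:
    """All incubation types for one depth and treatment, one RNG stream."""
    _check_treatment(treatment)
    rng = truth.rng() if rng is None else rng
    return {
        "15NH4": generate_nitrification_series(truth, depth, treatment, "15NH4", rng, constants),
        "15NO2": generate_nitrification_series(truth, depth, treatment, "15NO2", rng, constants),
        "14C": generate_dic_incubation(truth, depth, treatment, rng, constants),
        "3H": generate_leucine_incubation(truth, depth, treatment, rng, constants),
    }


# ---------------------------------------------------------------------------
# End-to-end study harnesses
# ---------------------------------------------------------------------------

def simulate_yield_study(
    truth: SyntheticTruth,
    n_experiments: int = 12,
    rate_range: tuple[float, float] = (2.0, 60.0),
    rng: np.random.Generator | None = None,
    constants: Constants = DEFAULT_CONSTANTS,
):
    """Simulate paired inhibitor experiments spanning a range of ammonia
    oxidation rates and push them through the full estimator chain.

    Each experiment is an incubation at the ammonia-oxidation peak of a
    station whose peak rate is one of ``n_experiments`` log-spaced levels
    across ``rate_range`` (emulating the cross-station spread of ammonia
    oxidation).  Station productivity co-varies: heterotrophic production,
    the deep tail and the background term scale with the ammonia peak, as
    they do across real stations where all rates track overall productivity.
    This keeps the inhibitor-sensitive fraction of every experiment large
    enough that each would register as significant — i.e. these are the
    qualifying experiments.  Returns (ammonia-oxidation estimates,
    control-vs-+PA DIC fixation comparisons) ready for the yield regression.
    """
    from .inhibition import compare_treatments
    from .isotope import dugdale_goering_rate

    rng = truth.rng() if rng is None else rng
    levels = np.geomspace(rate_range[0], rate_range[1], n_experiments)
    ao_estimates, comparisons = [], []
    for peak_rate in levels:
        scale = float(peak_rate) / truth.ao_peak_rate
        t = replace(truth, ao_peak_rate=float(peak_rate),
                    ao_deep_tail=truth.ao_deep_tail * scale,
                    hetero_surface_rate=truth.hetero_surface_rate * scale,
                    background_dic_fix=truth.background_dic_fix * scale)
        depth = t.peak_depth
        series = generate_nitrification_series(t, depth, CONTROL, "15NH4", rng, constants)
        ao_estimates.append(dugdale_goering_rate(series))
        ctrl, inhib = generate_paired_dic_incubations(t, depth, rng, constants)
        to_rate = ctrl.dic_um * 1000.0 / ctrl.dpm_total_added / ctrl.duration_d
        blank = np.mean(ctrl.dpm_killed)
        comparisons.append(compare_treatments(
            control_reps=(ctrl.dpm_live - blank) * to_rate,
            treated_reps=(inhib.dpm_live - blank) * to_rate,
            sidedness="one",
            label=f"yield-{peak_rate:.3g}",
        ))
    return ao_estimates, comparisons


def generate_paired_dic_incubations(
    truth: SyntheticTruth,
    depth: float,
    rng: np.random.Generator | None = None,
    constants: Constants = DEFAULT_CONSTANTS,
) -> tuple[RadioIncubation, RadioIncubation]:
    """Control and +PA 14C incubations from one bottle set.

    Mirrors the actual incubation design: the live control and live +PA
    bottles at one depth share the same killed-control bottles, so the
    blank (and its noise) is common to both arms and cancels in the
    treatment difference.
    """
    rng = truth.rng() if rng is None else rng
    ctrl = generate_dic_incubation(truth, float(depth), CONTROL, rng, constants)
    inhib = generate_dic_incubation(truth, float(depth), PA, rng, constants)
    inhib = RadioIncubation(
        experiment_id=inhib.experiment_id, station=inhib.station,
        depth=inhib.depth, treatment=inhib.treatment, isotope=inhib.isotope,
        dpm_live=inhib.dpm_live, dpm_killed=ctrl.dpm_killed.copy(),
        duration_d=inhib.duration_d, dpm_total_added=inhib.dpm_total_added,
        dic_um=inhib.dic_um, dpm_t0=ctrl.dpm_t0,
    )
    return ctrl, inhib


def simulate_null_inhibition_family(
    truth: SyntheticTruth,
    depths: Sequence[float] | None = None,
    alpha: float = 0.05,
    rng: np.random.Generator | None = None,
    constants: Constants = DEFAULT_CONSTANTS,
):
    """One Bonferroni family of control-vs-+PA comparisons under the null.

    ``truth`` should carry ``yield_aoa_true = 0`` so phenylacetylene removes
    nothing; the returned comparisons then probe pure replicate noise.
    """
    from .inhibition import adjust_bonferroni_comparisons, compare_treatments
    from .radio import c14_dic_fixation_rate

    rng = truth.rng() if rng is None else rng
    if depths is None:
        depths = truth.depths[:7]
    comparisons = []
    for depth in depths:
        ctrl, inhib = generate_paired_dic_incubations(truth, float(depth), rng, constants)
        blank = float(np.mean(ctrl.dpm_killed))
        to_rate = ctrl.dic_um * 1000.0 / ctrl.dpm_total_added / ctrl.duration_d
        comparisons.append(compare_treatments(
            control_reps=(ctrl.dpm_live - blank) * to_rate,
            treated_reps=(inhib.dpm_live - blank) * to_rate,
            sidedness="one", alpha=alpha,
            label=f"null-{depth:g}m",
        ))
    return adjust_bonferroni_comparisons(comparisons, alpha=alpha)


# ---------------------------------------------------------------------------
# Tidy tables (CLI / CSV interchange)
# ---------------------------------------------------------------------------

def incubation_tables(
    truth: SyntheticTruth,
    treatments: Sequence[str] = (CONTROL, PA),
    constants: Constants = DEFAULT_CONSTANTS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Long-format isotope and radiotracer observable tables for a station.

    Columns follow the interchange schemas:
    isotope: experiment_id,station,depth_m,treatment,tracer,replicate,
             timepoint_h,af_product,pool_nm,f_label
    radio:   experiment_id,station,depth_m,treatment,isotope,replicate,
             dpm_live,dpm_killed,dpm_total,duration_d,dic_um,volume_l,sa
    """
    rng = truth.rng()
    iso_rows, radio_rows = [], []
    for depth in truth.depths:
        for treatment in treatments:
            incs = generate_incubations(truth, float(depth), treatment, rng, constants)
            for tracer in ("15NH4", "15NO2"):
                s = incs[tracer]
                for r in range(s.af_product.shape[0]):
                    for j, t in enumerate(s.timepoints_h):
                        iso_rows.append({
                            "experiment_id": s.experiment_id, "station": s.station,
                            "depth_m": s.depth, "treatment": s.treatment,
                            "tracer": s.tracer, "replicate": r,
                            "timepoint_h": t, "af_product": s.af_product[r, j],
                            "pool_nm": s.product_pool_nm,
                            "f_label": s.substrate_label_fraction,
                        })
            for iso in ("14C", "3H"):
                inc = incs[iso]
                killed_mean = float(np.mean(inc.dpm_killed))
                for r, dpm in enumerate(inc.dpm_live):
                    radio_rows.append({
                        "experiment_id": inc.experiment_id, "station": inc.station,
                        "depth_m": inc.depth, "treatment": inc.treatment,
                        "isotope": iso, "replicate": r, "dpm_live": dpm,
                        "dpm_killed": killed_mean,
                        "dpm_total": inc.dpm_total_added,
                        "duration_d": inc.duration_d, "dic_um": inc.dic_um,
                        "volume_l": inc.sample_volume_l,
                        "sa": inc.sa_ci_per_mmol if iso == "3H" else np.nan,
                    })
    return pd.DataFrame(iso_rows), pd.DataFrame(radio_rows)
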