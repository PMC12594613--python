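"""Shared domain model: constants, station profiles, zone logic, tabular I/O.

Depth convention is meters, positive downward.  Oceanographic zones are
defined operationally: the euphotic zone reaches to the depth below the
chlorophyll-a maximum where fluorescence has fallen to 10% of its maximum;
the upper mesopelagic lies between the euphotic base and 200 m; everything
at or below 200 m counts as lower mesopelagic.  Oxygen-deficient-zone (ODZ)
water is O2 <= 10 uM and anoxic water O2 < 1 uM.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("darkdic")

# Zone names
EUPHOTIC = "euphotic"
UPPER_MESOPELAGIC = "upper_mesopelagic"
LOWER_MESOPELAGIC = "lower_mesopelagic"

#: depth (m) separating upper from lower mesopelagic
MESOPELAGIC_SPLIT_M = 200.0
#: O2 (uM) at or below which water is oxygen-deficient
ODZ_O2_UM = 10.0
#: O2 (uM) below which water is anoxic
ANOXIC_O2_UM = 1.0

#: grams of carbon per mole
MOLAR_MASS_C = 12.011


class ProfileError(ValueError):
    """Raised for invalid station profiles or profile tables."""


@dataclass(frozen=True)
class Constants:
    """Physical reference ratios and literature conversion factors.

    ``r15_air`` and ``r13_vpdb`` are the standard isotope reference ratios
    (atmospheric N2 and VPDB); they are community conventions rather than
    measured quantities of any particular study.  The yield factors convert
    moles of N or S oxidized into moles of inorganic C fixed.
    """

    #: 15N/14N of atmospheric N2
    r15_air: float = 0.0036765
    #: 13C/12C of the VPDB standard
    r13_vpdb: float = 0.011180
    #: disintegrations per minute per curie
    dpm_per_ci: float = 2.22e12
    #: kg C produced per mol leucine incorporated
    leucine_to_c: float = 1.5
    #: mol C fixed per mol NO2- oxidized (nitrite-oxidizer cultures)
    yield_nob: float = 0.036
    #: mol C fixed per mol S oxidized (sulfide-oxidizer cultures)
    yield_sox: float = 0.35
    #: molar N:S of sinking particulate organic matter
    n_to_s: float = 17.0
    #: fraction of heterotrophic production attributable to DIC uptake
    hetero_dic_fraction: float = 0.10
    #: mol C per mol N for ammonia-oxidizer cultures
    yield_aoa_culture: float = 0.09

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not v > 0:
                raise ValueError(f"constant {f.name} must be strictly positive")
        if not 0.15 <= self.yield_sox <= 0.35:
            raise ValueError("yield_sox outside literature range [0.15, 0.35]")
        if not 0.01 <= self.hetero_dic_fraction <= 0.10:
            raise ValueError("hetero_dic_fraction outside range [0.01, 0.10]")

    @property
    def a_nat_15n(self) -> float:
        """Natural-abundance 15N atom fraction, R/(1+R) of air N2."""
        return self.r15_air / (1.0 + self.r15_air)

    @property
    def a_nat_13c(self) -> float:
        """Natural-abundance 13C atom fraction of VPDB."""
        return self.r13_vpdb / (1.0 + self.r13_vpdb)


DEFAULT_CONSTANTS = Constants()


@dataclass
class DepthSample:
    """Environmental context at one depth; any measurement may be NaN."""

    depth: float                      # m
    temperature: float = np.nan       # degC
    oxygen: float = np.nan            # uM
    fluorescence: float = np.nan      # relative chl-a units
    nh4: float = np.nan               # nM
    no2: float = np.nan               # nM
    no3: float = np.nan               # uM
    dic: float = np.nan               # uM
    poc: float = np.nan               # uM

    def __post_init__(self) -> None:
        if not self.depth >= 0:
            raise ProfileError(f"depth must be >= 0, got {self.depth}")
        for name in ("oxygen", "fluorescence", "nh4", "no2", "no3", "dic", "poc"):
            v = getattr(self, name)
            if np.isfinite(v) and v < 0:
                raise ProfileError(f"{name} must be >= 0 when present, got {v}")


@dataclass
class StationProfile:
    """Ordered depth samples for one station of one cruise."""

    station_id: str
    cruise: str = ""
    latitude: float = np.nan
    longitude: float = np.nan
    samples: list[DepthSample] = field(default_factory=list)
    euphotic_depth: float | None = None

    def __post_init__(self) -> None:
        if len(self.samples) < 2:
            raise ProfileError("a profile needs at least 2 samples")
        depths = self.depths
        if np.any(np.diff(depths) <= 0):
            raise ProfileError("sample depths must be strictly increasing")
        if self.euphotic_depth is not None and not (
            depths[0] <= self.euphotic_depth <= depths[-1]
        ):
            raise ProfileError("euphotic_depth outside sampled depth range")

    @property
    def depths(self) -> np.ndarray:
        return np.array([s.depth for s in self.samples], dtype=float)

    def column(self, name: str) -> np.ndarray:
        return np.array([getattr(s, name) for s in self.samples], dtype=float)


@dataclass(frozen=True)
class ZoneLabel:
    """Vertical-zone assignment with oxygen-regime flags."""

    zone: str
    odz: bool
    anoxic: bool

    def __post_init__(self) -> None:
        if self.zone not in (EUPHOTIC, UPPER_MESOPELAGIC, LOWER_MESOPELAGIC):
            raise ValueError(f"unknown zone {self.zone!r}")
        if self.anoxic and not self.odz:
            raise ValueError("anoxic water is by definition oxygen-deficient")


def estimate_euphotic_depth(profile: StationProfile) -> float:
    """Euphotic-zone depth from the chlorophyll fluorescence profile.

    The euphotic base is taken as the shallowest depth below the global
    fluorescence maximum where fluorescence first falls to 10% of the
    maximum, linearly interpolated between the bracketing samples.  Ties in
    the maximum go to the shallowest sample.

    Raises
    ------
    ProfileError
        If fewer than two samples carry fluorescence, or the profile never
        drops below the 10% level beneath the maximum.
    """
    depths = profile.depths
    fluor = profile.column("fluorescence")
    ok = np.isfinite(fluor)
    if ok.sum() < 2:
        raise ProfileError("need >= 2 samples with fluorescence data")
    depths, fluor = depths[ok], fluor[ok]
    imax = int(np.argmax(fluor))  # argmax returns the shallowest of ties
    threshold = 0.1 * fluor[imax]
    for i in range(imax + 1, len(fluor)):
        if fluor[i] <= threshold:
            f_hi, f_lo = fluor[i - 1], fluor[i]
            if f_hi == f_lo:  # flat segment already at/below threshold
                return float(depths[i])
            frac = (f_hi - threshold) / (f_hi - f_lo)
            return float(depths[i - 1] + frac * (depths[i] - depths[i - 1]))
    raise ProfileError(
        "fluorescence never reaches 10% of its maximum below the maximum"
    )


def classify_zone(
    depth: float, euphotic_depth: float, oxygen: float | None = None
) -> ZoneLabel:
    """Assign a vertical zone and oxygen-regime flags to one depth.

    The euphotic boundary is inclusive (depth == euphotic base is euphotic)
    and 200 m belongs to the lower mesopelagic.  ``oxygen`` may be None/NaN,
    in which case both oxygen flags are False.
    """
    if depth < 0 or not euphotic_depth > 0:
        raise ValueError("depth must be >= 0 and euphotic_depth > 0")
    if depth <= euphotic_depth:
        zone = EUPHOTIC
    elif depth < MESOPELAGIC_SPLIT_M:
        zone = UPPER_MESOPELAGIC
    else:
        zone = LOWER_MESOPELAGIC
    if oxygen is None or not np.isfinite(oxygen):
        odz = anoxic = False
    else:
        if oxygen < 0:
            raise ValueError("oxygen must be >= 0")
        odz = oxygen <= ODZ_O2_UM
        anoxic = oxygen < ANOXIC_O2_UM
    return ZoneLabel(zone=zone, odz=odz, anoxic=anoxic)


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------

PROFILE_COLUMNS = [
    "station", "cruise", "latitude", "longitude", "depth_m",
    "temp_c", "o2_um", "fluor", "nh4_nm", "no2_nm", "no3_um", "dic_um", "poc_um",
]

_COLUMN_TO_FIELD = {
    "depth_m": "depth", "temp_c": "temperature", "o2_um": "oxygen",
    "fluor": "fluorescence", "nh4_nm": "nh4", "no2_nm": "no2",
    "no3_um": "no3", "dic_um": "dic", "poc_um": "poc",
}

_MANDATORY = ("station", "cruise", "depth_m")


def read_profile_table(path) -> list[StationProfile]:
    """Read station profiles from a CSV file with the standard schema.

    Rows are grouped by (station, cruise) and sorted by depth.  Missing
    measurement columns become NaN.  Duplicate station-depth rows and a
    missing/non-numeric depth column are errors.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in _MANDATORY if c not in df.columns]
    if missing:
        raise ProfileError(f"profile table missing mandatory columns: {missing}")
    depth = pd.to_numeric(df["depth_m"], errors="coerce")
    if depth.isna().any():
        raise ProfileError("non-numeric depth_m values in profile table")
    df = df.assign(depth_m=depth)
    if df.duplicated(subset=["station", "cruise", "depth_m"]).any():
        raise ProfileError("duplicate station-depth rows in profile table")

    profiles = []
    for (station, cruise), grp in df.groupby(["station", "cruise"], sort=True):
        grp = grp.sort_values("depth_m")
        samples = []
        for _, row in grp.iterrows():
            kwargs = {
                f: float(row[c]) if c in grp.columns and pd.notna(row[c]) else np.nan
                for c, f in _COLUMN_TO_FIELD.items()
            }
            samples.append(DepthSample(**kwargs))
        profiles.append(
            StationProfile(
                station_id=str(station),
                cruise=str(cruise),
                latitude=float(grp["latitude"].iloc[0]) if "latitude" in grp else np.nan,
                longitude=float(grp["longitude"].iloc[0]) if "longitude" in grp else np.nan,
                samples=samples,
            )
        )
    logger.info("read %d profiles from %s", len(profiles), path)
    return profiles


def write_profile_table(profiles: Iterable[StationProfile], path) -> None:
    """Write profiles back to CSV; numeric values round-trip exactly.

    pandas serialises floats with ``repr``-shortest text, so read-after-write
    reproduces every value bit-for-bit.
    """
    rows = []
    for p in profiles:
        for s in p.samples:
            row = {"station": p.station_id, "cruise": p.cruise,
                   "latitude": p.latitude, "longitude": p.longitude}
            row.update({c: getattr(s, f) for c, f in _COLUMN_TO_FIELD.items()})
            rows.append(row)
    pd.DataFrame(rows, columns=PROFILE_COLUMNS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Run-level options: constant overrides, test level, integration flags."""

    constants: Constants = field(default_factory=Constants)
    alpha: float = 0.05
    clip_negative_rates: bool = True
    significant_only_integration: bool = False
    seed: int = 0


def load_config(path) -> RunConfig:
    """Load a YAML run configuration; absent keys keep their defaults."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    constants = replace(Constants(), **raw.get("constants", {}))
    cfg = RunConfig(
        constants=constants,
        alpha=float(raw.get("alpha", 0.05)),
        clip_negative_rates=bool(raw.get("clip_negative_rates", True)),
        significant_only_integration=bool(raw.get("significant_only_integration", False)),
        seed=int(raw.get("seed", 0)),
    )
    logger.info("loaded config from %s: %s", path, cfg)
    return cfg
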