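"""Daily climate forcing and the activity modifiers that drive decomposition.

The decomposition engine consumes two dimensionless daily modifiers in
[0, 1]: a Gaussian temperature response per decomposer guild (with a hard
activity threshold for the ectotherm guilds, termites and beetles), and a
unimodal moisture response computed from a single-bucket wood-moisture
index. Forcing comes either from a daily climate CSV
(``date,tmin_C,tmax_C,precip_mm``) or from a seeded synthetic generator
parameterised by site mean annual temperature (MAT) and precipitation
(MAP).

The bucket model is intentionally simple: throughfall (precipitation
attenuated by canopy leaf area) recharges the index, temperature-driven
drying depletes it proportionally, and standing logs dry at twice the rate
of downed logs because they lack ground contact. Snowfall (precipitation
at freezing mean temperature) accumulates in a snowpack and recharges the
bucket on melt days via a degree-day melt.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import TYPE_CHECKING, Optional

import numpy as np
import pandas as pd

from .domain_core import Position

if TYPE_CHECKING:  # pragma: no cover
    from .engine import GuildParameterSet

logger = logging.getLogger("cwddat")

__all__ = [
    "ClimateSeries",
    "SiteDescription",
    "MoistureState",
    "read_climate_csv",
    "synthesize_climate",
    "temperature_modifier",
    "update_moisture",
    "moisture_modifier",
]

# Bucket-model coefficients (per day). The bucket index is dimensionless in
# [0, 1]; BUCKET_CAPACITY_MM converts throughfall depth into index units.
BUCKET_CAPACITY_MM = 40.0
DRYING_COEFF_PER_DAY = 0.04       # fractional drying per day at the 20 C reference
DRYING_REFERENCE_C = 20.0
STANDING_DRYING_FACTOR = 2.0      # snags dry twice as fast as downed logs
CANOPY_EXTINCTION = 0.5           # Beer-Lambert throughfall attenuation per unit LAI
DEGREE_DAY_MELT_MM = 4.0          # snowpack melt per degree-day above 0 C

#: Bucket index at which the moisture response peaks; wetter than this the
#: response declines (waterlogging limits aeration), reaching 0.5 at saturation.
MOISTURE_OPTIMUM = 0.6
MOISTURE_SATURATED_RESPONSE = 0.5


@dataclass(frozen=True)
class SiteDescription:
    """Static descriptors of a study site."""

    name: str
    latitude_deg: float
    longitude_deg: float
    elevation_m: float
    MAT_C: float
    MAP_mm: float
    LAI_m2_m2: float
    annual_litterfall: Optional[float] = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.LAI_m2_m2 <= 10.0):
            raise ValueError(f"LAI {self.LAI_m2_m2} outside [0, 10] m^2 m^-2")
        if self.MAP_mm <= 0:
            raise ValueError("MAP must be positive")


@dataclass(frozen=True)
class ClimateSeries:
    """Validated daily climate forcing with strictly increasing, gap-free dates."""

    frame: pd.DataFrame  # columns: date (datetime64), tmin_C, tmax_C, precip_mm

    def __post_init__(self) -> None:
        df = self.frame
        required = ["date", "tmin_C", "tmax_C", "precip_mm"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"climate frame missing columns {missing}")
        if len(df) == 0:
            raise ValueError("climate series is empty")
        deltas = df["date"].diff().dropna()
        if not (deltas == pd.Timedelta(days=1)).all():
            raise ValueError("climate dates must be strictly increasing daily with no gaps")
        bad = df.index[df["tmin_C"] > df["tmax_C"]]
        if len(bad):
            raise ValueError(f"tmin > tmax on row(s) {list(bad[:5])}")
        if (df["precip_mm"] < 0).any():
            raise ValueError("negative precipitation")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def tmean_C(self) -> np.ndarray:
        return 0.5 * (self.frame["tmin_C"].to_numpy() + self.frame["tmax_C"].to_numpy())

    @property
    def precip_mm(self) -> np.ndarray:
        return self.frame["precip_mm"].to_numpy(dtype=float)

    @property
    def n_years(self) -> float:
        return len(self.frame) / 365.25


@dataclass(frozen=True)
class MoistureState:
    """Bucket proxy for wood water content, plus accumulated snowpack depth."""

    wood_moisture_index: float
    snowpack_mm: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.wood_moisture_index <= 1.0):
            raise ValueError("wood moisture index must lie in [0, 1]")
        if self.snowpack_mm < 0:
            raise ValueError("snowpack must be >= 0")


# Daymet export headers mapped onto the canonical schema.
_DAYMET_COLUMN_MAP = {
    "tmin (deg c)": "tmin_C",
    "tmax (deg c)": "tmax_C",
    "prcp (mm/day)": "precip_mm",
}


def read_climate_csv(path, daymet_columns: bool = False) -> ClimateSeries:
    """Read and validate a daily climate CSV.

    Expected columns: ``date,tmin_C,tmax_C,precip_mm`` (ISO dates). With
    ``daymet_columns=True`` Daymet export headers are mapped first. Isolated
    missing days (more than one calendar day between consecutive rows) are
    filled by linear interpolation with a logged count; more than 5% missing
    is an error.
    """
    df = pd.read_csv(path)
    if daymet_columns:
        df = df.rename(columns={k: v for k, v in _DAYMET_COLUMN_MAP.items() if k in df.columns})
    required = ["date", "tmin_C", "tmax_C", "precip_mm"]
    missing_cols = [c for c in required if c not in df.columns]
    if missing_cols:
        raise ValueError(f"climate CSV {path} missing columns {missing_cols}")
    try:
        df["date"] = pd.to_datetime(df["date"], format="ISO8601")
    except ValueError as exc:
        raise ValueError(f"climate CSV {path}: unparseable date ({exc})") from exc
    for col in ("tmin_C", "tmax_C", "precip_mm"):
        bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
        if len(bad):
            raise ValueError(f"climate CSV {path}: malformed value in column {col!r}, "
                             f"row {int(bad[0]) + 2} (1-based, incl. header)")
        df[col] = pd.to_numeric(df[col])
    bad = df.index[df["tmin_C"] > df["tmax_C"]]
    if len(bad):
        raise ValueError(f"climate CSV {path}: tmin > tmax on data row {int(bad[0]) + 2}")

    full = pd.DataFrame({"date": pd.date_range(df["date"].iloc[0], df["date"].iloc[-1])})
    n_missing = len(full) - len(df)
    if n_missing < 0 or df["date"].duplicated().any():
        raise ValueError(f"climate CSV {path}: duplicate or unsorted dates")
    if n_missing > 0.05 * len(full):
        raise ValueError(
            f"climate CSV {path}: {n_missing} missing days exceeds 5% of the record"
        )
    if n_missing:
        logger.warning("climate CSV %s: interpolating %d missing day(s)", path, n_missing)
        df = full.merge(df, on="date", how="left")
        df[["tmin_C", "tmax_C", "precip_mm"]] = df[
            ["tmin_C", "tmax_C", "precip_mm"]
        ].interpolate(method="linear")
    return ClimateSeries(df.reset_index(drop=True))


def synthesize_climate(site: SiteDescription, years: int, seed: int) -> ClimateSeries:
    """Generate a reproducible daily climate series from MAT/MAP.

    Daily mean temperature is MAT plus a seasonal sinusoid (amplitude from a
    latitude heuristic, ~10 C at mid latitudes) plus AR(1) day-to-day noise;
    tmin/tmax are the mean -/+ half an 8 C diurnal range. Precipitation is a
    Bernoulli wet-day occurrence with gamma-distributed wet-day amounts whose
    expected annual total equals MAP. Identical (site, years, seed) inputs
    yield identical series.
    """
    if years < 1:
        raise ValueError("years must be >= 1")
    rng = np.random.default_rng(seed)
    dates = pd.date_range("2000-01-01", periods=int(round(years * 365.25)), freq="D")
    n = len(dates)
    doy = dates.day_of_year.to_numpy()

    # seasonal amplitude heuristic: ~4 C in the tropics to ~16 C at high latitude
    amplitude = float(np.clip(3.0 + 0.25 * abs(site.latitude_deg), 4.0, 16.0))
    phase = 1.0 if site.latitude_deg >= 0 else -1.0  # southern hemisphere flips seasons
    seasonal = -phase * amplitude * np.cos(2.0 * np.pi * (doy - 15.0) / 365.25)

    ar = np.empty(n)
    rho, sigma = 0.7, 2.0
    eps = rng.normal(0.0, sigma * np.sqrt(1.0 - rho**2), size=n)
    ar[0] = rng.normal(0.0, sigma)
    for i in range(1, n):
        ar[i] = rho * ar[i - 1] + eps[i]
    tmean = site.MAT_C + seasonal + ar

    p_wet = 0.30
    wet = rng.random(n) < p_wet
    shape = 0.7
    mean_wet_amount = site.MAP_mm / (365.25 * p_wet)
    amounts = rng.gamma(shape, mean_wet_amount / shape, size=n)
    precip = np.where(wet, amounts, 0.0)

    half_diurnal = 4.0
    frame = pd.DataFrame(
        {
            "date": dates,
            "tmin_C": tmean - half_diurnal,
            "tmax_C": tmean + half_diurnal,
            "precip_mm": precip,
        }
    )
    return ClimateSeries(frame)


def temperature_modifier(tmean_C, guild: "GuildParameterSet"):
    """Gaussian temperature response of a decomposer guild, in [0, 1].

    ``exp(-(T - T_opt)^2 / (2 sigma^2))``, equal to 1 at the optimum. Guilds
    with an activity threshold (termites, beetles) are fully inactive below
    it. Accepts scalars or arrays.
    """
    t = np.asarray(tmean_C, dtype=float)
    f = np.exp(-((t - guild.T_opt_C) ** 2) / (2.0 * guild.T_sigma_C**2))
    if guild.T_threshold_C is not None:
        f = np.where(t < guild.T_threshold_C, 0.0, f)
    if np.ndim(tmean_C) == 0:
        return float(f)
    return f


def update_moisture(
    state: MoistureState,
    precip_mm: float,
    tmean_C: float,
    LAI: float,
    position: Position,
) -> MoistureState:
    """Advance the wood-moisture bucket by one day.

    Throughfall (canopy-attenuated rain plus any degree-day snowmelt)
    recharges the index; drying removes a temperature-scaled fraction of the
    current index, at twice the rate for standing logs. The index is clamped
    to [0, 1].
    """
    snow = state.snowpack_mm
    if tmean_C <= 0.0:
        snow += precip_mm
        rain = 0.0
    else:
        melt = min(snow, DEGREE_DAY_MELT_MM * tmean_C)
        snow -= melt
        rain = precip_mm + melt
    throughfall = rain * np.exp(-CANOPY_EXTINCTION * LAI)
    gain = throughfall / BUCKET_CAPACITY_MM
    dry_rate = DRYING_COEFF_PER_DAY * max(tmean_C, 2.0) / DRYING_REFERENCE_C
    if position is Position.STANDING:
        dry_rate *= STANDING_DRYING_FACTOR
    index = state.wood_moisture_index * (1.0 - min(dry_rate, 1.0)) + gain
    return MoistureState(float(np.clip(index, 0.0, 1.0)), float(snow))


def moisture_modifier(state) -> float:
    """Unimodal moisture response of decomposition, in [0, 1].

    Zero in bone-dry wood, peaking at 1.0 at the optimum bucket index (0.6)
    and declining to 0.5 at saturation (waterlogging limits aeration).
    Accepts a MoistureState or a bare index (scalar/array).
    """
    x = state.wood_moisture_index if isinstance(state, MoistureState) else state
    x = np.asarray(x, dtype=float)
    rising = x / MOISTURE_OPTIMUM
    falling = 1.0 - (1.0 - MOISTURE_SATURATED_RESPONSE) * (x - MOISTURE_OPTIMUM) / (
        1.0 - MOISTURE_OPTIMUM
    )
    f = np.clip(np.where(x <= MOISTURE_OPTIMUM, rising, falling), 0.0, 1.0)
    if f.ndim == 0:
        return float(f)
    return f


def moisture_index_series(
    climate: ClimateSeries,
    LAI: float,
    position: Position,
    initial_index: float = 0.3,
) -> np.ndarray:
    """Run the bucket model over a whole climate series; returns the daily index."""
    tmean = climate.tmean_C
    precip = climate.precip_mm
    n = len(tmean)
    out = np.empty(n)
    state = MoistureState(initial_index)
    for i in range(n):
        state = update_moisture(state, precip[i], tmean[i], LAI, position)
        out[i] = state.wood_moisture_index
    return out
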