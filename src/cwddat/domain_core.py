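"""Domain types and field mass-loss bookkeeping for coarse woody debris (CWD).

Conventions used throughout the package:

* Diameters are centimetres, masses kilograms (per log) or Mg ha^-1 (per
  cohort), wood density g cm^-3, areal carbon g C m^-2.
* Species groups follow the two-code convention of the log inventory:
  1 = hardwood, 2 = softwood.
* Size classes partition the diameter range [4.5, 45.0) cm into six
  half-open 7.5 cm bands.

Two independent estimates of log mass loss are supported as comparison
bases for the simulator: *measured* log mass loss (MLML, whole-log field
weight corrected to dry weight with disk moisture) and *calculated* log
mass loss (CLML, disk wood-density change applied to the log volume).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, Iterable, Tuple

logger = logging.getLogger("cwddat")

__all__ = [
    "SpeciesGroup",
    "SizeClass",
    "Position",
    "LogSpecimen",
    "CWDCohort",
    "MassLossRecord",
    "SIZE_CLASS_BOUNDS",
    "classify_size",
    "size_class_midpoint",
    "measured_mass_loss_fraction",
    "calculated_mass_loss_fraction",
    "cohort_total",
    "mgha_to_gm2",
    "WOOD_CARBON_FRACTION",
]

#: Default wood carbon fraction (g C per g dry wood).
WOOD_CARBON_FRACTION = 0.492

#: Half-open diameter bounds [lower, upper) in cm for the six CWD size classes.
SIZE_CLASS_BOUNDS: Dict[int, Tuple[float, float]] = {
    1: (4.5, 7.5),
    2: (7.5, 15.0),
    3: (15.0, 22.5),
    4: (22.5, 30.0),
    5: (30.0, 37.5),
    6: (37.5, 45.0),
}


class SpeciesGroup(Enum):
    """Wood species group: 1 = hardwood (aspen/birch), 2 = softwood (pine)."""

    HARDWOOD = 1
    SOFTWOOD = 2

    @classmethod
    def from_code(cls, code: int) -> "SpeciesGroup":
        try:
            return cls(int(code))
        except ValueError:
            raise ValueError(f"species code must be 1 (hardwood) or 2 (softwood), got {code!r}")


class Position(Enum):
    """Log position: downed (ground contact) or standing (snag, no contact)."""

    DOWNED = "down"
    STANDING = "stand"

    @classmethod
    def from_label(cls, label: str) -> "Position":
        key = str(label).strip().lower()
        aliases = {"down": cls.DOWNED, "downed": cls.DOWNED, "horizontal": cls.DOWNED,
                   "stand": cls.STANDING, "standing": cls.STANDING, "vertical": cls.STANDING}
        if key not in aliases:
            raise ValueError(f"unknown position {label!r}; expected one of down/stand")
        return aliases[key]


@dataclass(frozen=True)
class SizeClass:
    """One of six diameter classes; the interval is half-open: [lower, upper)."""

    index: int
    lower_cm: float = field(init=False)
    upper_cm: float = field(init=False)

    def __post_init__(self) -> None:
        if self.index not in SIZE_CLASS_BOUNDS:
            raise ValueError(f"size-class index must be 1..6, got {self.index}")
        lo, hi = SIZE_CLASS_BOUNDS[self.index]
        object.__setattr__(self, "lower_cm", lo)
        object.__setattr__(self, "upper_cm", hi)

    @property
    def midpoint_cm(self) -> float:
        return 0.5 * (self.lower_cm + self.upper_cm)

    def __contains__(self, diameter_cm: float) -> bool:
        return self.lower_cm <= diameter_cm < self.upper_cm


def classify_size(diameter_cm: float) -> SizeClass:
    """Assign a diameter (cm) to its CWD size class.

    The classes are half-open on the upper bound, so a boundary diameter
    (e.g. 7.5 cm) belongs to the larger class.

    Raises
    ------
    ValueError
        If the diameter lies outside [4.5, 45.0) cm.
    """
    d = float(diameter_cm)
    if not (4.5 <= d < 45.0) or not math.isfinite(d):
        raise ValueError(
            f"diameter {diameter_cm} cm outside the CWD size-class range [4.5, 45.0) cm"
        )
    # the first class is narrower (4.5-7.5 cm); classes 2..6 are 7.5 cm wide
    index = 1 if d < 7.5 else int((d - 7.5) // 7.5) + 2
    return SizeClass(index)


def size_class_midpoint(index: int) -> float:
    """Midpoint diameter (cm) of a size class, used in cohort mode."""
    return SizeClass(index).midpoint_cm


@dataclass(frozen=True)
class LogSpecimen:
    """A single experimental log with its initial (time-zero) properties."""

    site_id: str
    position: Position
    species: SpeciesGroup
    size_class: SizeClass
    diameter_cm: float
    mass_kg: float
    density_g_cm3: float
    length_m: float

    def __post_init__(self) -> None:
        if not (0.05 < self.density_g_cm3 < 1.2):
            raise ValueError(f"wood density {self.density_g_cm3} g cm^-3 outside (0.05, 1.2)")
        if self.mass_kg <= 0:
            raise ValueError("log mass must be positive")
        if self.diameter_cm not in self.size_class:
            raise ValueError(
                f"diameter {self.diameter_cm} cm not within size class {self.size_class.index} "
                f"[{self.size_class.lower_cm}, {self.size_class.upper_cm}) cm"
            )


CohortKey = Tuple[Position, SpeciesGroup, int]


@dataclass
class CWDCohort:
    """CWD standing stock by (position, species, size class), in Mg ha^-1."""

    entries: Dict[CohortKey, float]

    def __post_init__(self) -> None:
        for key, mass in self.entries.items():
            position, species, size_index = key
            if not isinstance(position, Position) or not isinstance(species, SpeciesGroup):
                raise TypeError(f"malformed cohort key {key!r}")
            SizeClass(size_index)  # validates the index
            if mass < 0 or not math.isfinite(mass):
                raise ValueError(f"cohort mass for {key} must be finite and >= 0, got {mass}")

    @property
    def total(self) -> float:
        return cohort_total(self)

    def items(self) -> Iterable[Tuple[CohortKey, float]]:
        return self.entries.items()


def cohort_total(cohort: CWDCohort) -> float:
    """Total cohort mass (Mg ha^-1): the exact sum of all entries."""
    return float(sum(cohort.entries.values()))


def mgha_to_gm2(mass_mg_ha: float) -> float:
    """Convert Mg ha^-1 to g m^-2 (1 Mg ha^-1 = 100 g m^-2)."""
    if mass_mg_ha < 0:
        raise ValueError("mass must be >= 0")
    return float(mass_mg_ha) * 100.0


@dataclass(frozen=True)
class MassLossRecord:
    """Field measurements for one log at deployment (T0) and resampling (T6).

    ``disk_moisture_fraction`` is the wet-basis moisture content averaged
    over the two end disks; it converts the whole-log field weight to a
    dry-weight basis.
    """

    initial_dry_mass_kg: float
    field_weight_kg: float
    disk_moisture_fraction: float
    disk_density_T0: float
    disk_density_T6: float
    log_volume_m3: float

    def __post_init__(self) -> None:
        if self.initial_dry_mass_kg <= 0:
            raise ValueError("initial dry mass must be positive")
        if not (0.0 <= self.disk_moisture_fraction <= 0.9):
            raise ValueError("disk moisture fraction must lie in [0, 0.9]")
        if self.disk_density_T0 <= 0 or self.disk_density_T6 <= 0:
            raise ValueError("disk densities must be positive")
        if self.field_weight_kg < 0 or self.log_volume_m3 <= 0:
            raise ValueError("field weight must be >= 0 and log volume positive")


def measured_mass_loss_fraction(rec: MassLossRecord) -> float:
    """Measured log mass loss (MLML): dry-weight difference T0 -> T6.

    The T6 dry mass is the whole-log field weight corrected with the disk
    moisture fraction. The result is clamped to [0, 1]; apparent mass gains
    (wet logs, measurement error) clamp to 0 with a logged warning.
    """
    dry_t6 = rec.field_weight_kg * (1.0 - rec.disk_moisture_fraction)
    if dry_t6 > rec.initial_dry_mass_kg * 1.10:
        raise ValueError(
            f"T6 dry mass {dry_t6:.2f} kg exceeds initial {rec.initial_dry_mass_kg:.2f} kg "
            "by more than 10%; check moisture correction"
        )
    frac = (rec.initial_dry_mass_kg - dry_t6) / rec.initial_dry_mass_kg
    if frac < 0.0:
        logger.warning("measured mass loss %.4f < 0; clamping to 0", frac)
        return 0.0
    return min(frac, 1.0)


def calculated_mass_loss_fraction(rec: MassLossRecord) -> float:
    """Calculated log mass loss (CLML) from disk wood-density change.

    With the log volume held constant between T0 and T6 the volume cancels
    and the loss fraction is ``1 - density_T6 / density_T0``. Density gains
    beyond 10% clamp to zero loss with a logged warning.
    """
    if rec.disk_density_T6 > rec.disk_density_T0 * 1.10:
        logger.warning(
            "T6 disk density %.3f exceeds T0 density %.3f by >10%%; clamping loss to 0",
            rec.disk_density_T6, rec.disk_density_T0,
        )
        return 0.0
    frac = 1.0 - rec.disk_density_T6 / rec.disk_density_T0
    return min(max(frac, 0.0), 1.0)
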