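"""Domain types for DOSI population assessments.

The Dispersal-Origin-Status-Impact (DOSI) scheme classifies a single
*population* of a non-native species — one (species, site) pair — along four
axes:

* **Dispersal** — how the population spreads: assisted by humans (deliberate
  release or accidental escape) or independently of direct human intervention
  (unaided, or facilitated by human-made corridors such as canals). A
  population may hold the capability for both.
* **Origin** — allochthonous (not from the region of interest) or
  autochthonous (a local species moving within the region of focus).
* **Status** — the trend of the population's abundance and range size:
  expanding, static, or shrinking.
* **Impact** — harm exerted locally on four sectors (ecology, economy,
  culture, human health), graded from benign through little and moderate to
  extensive.

Types in this module are deliberately permissive at construction time:
cross-field consistency (e.g. a dispersal record must claim at least one
capability) is checked by :func:`validate_assessment`, which reports
violations as data rather than raising, so that partially inconsistent
records read from files can be diagnosed row by row.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

__all__ = [
    "Severity",
    "Trend",
    "Mechanism",
    "OriginClass",
    "Rank",
    "Panel",
    "HarmoniaLabel",
    "Species",
    "Site",
    "DispersalRecord",
    "OriginRecord",
    "StatusRecord",
    "ImpactRecord",
    "PopulationAssessment",
    "PriorityRank",
    "validate_assessment",
]


class Severity(str, enum.Enum):
    """Ordinal harm level for one impact sector.

    ``unknown`` is stored distinctly rather than coerced to a level, so that
    reports can flag expert-knowledge gap-filling; it never counts as harm.
    """

    BENIGN = "benign"
    LITTLE = "little"
    MODERATE = "moderate"
    EXTENSIVE = "extensive"
    UNKNOWN = "unknown"

    @property
    def level(self) -> int | None:
        """Numeric harm level (0..3), or None for unknown."""
        return _SEVERITY_LEVELS[self]


_SEVERITY_LEVELS = {
    Severity.BENIGN: 0,
    Severity.LITTLE: 1,
    Severity.MODERATE: 2,
    Severity.EXTENSIVE: 3,
    Severity.UNKNOWN: None,
}


class Trend(str, enum.Enum):
    """Direction of change of a population's abundance or range."""

    EXPANDING = "expanding"
    STATIC = "static"
    SHRINKING = "shrinking"
    UNKNOWN = "unknown"


class Mechanism(str, enum.Enum):
    """Primary dispersal mechanism of a population."""

    ASSISTED_DELIBERATE = "assisted_deliberate"
    ASSISTED_ACCIDENTAL = "assisted_accidental"
    INDEPENDENT_UNAIDED = "independent_unaided"
    INDEPENDENT_FACILITATED = "independent_facilitated"

    @property
    def is_assisted(self) -> bool:
        return self in (Mechanism.ASSISTED_DELIBERATE, Mechanism.ASSISTED_ACCIDENTAL)


class OriginClass(str, enum.Enum):
    ALLOCHTHONOUS = "allochthonous"
    AUTOCHTHONOUS = "autochthonous"


class Rank(enum.IntEnum):
    """Management-priority rank: the ordinal output lattice Low < Medium < High < Highest."""

    LOW = 1
    MEDIUM = 2
    HIGH = 3
    HIGHEST = 4

    @property
    def label(self) -> str:
        return self.name.capitalize()

    @classmethod
    def from_label(cls, label: str) -> "Rank":
        try:
            return cls[label.strip().upper()]
        except KeyError:
            raise ValueError(f"unknown priority rank label: {label!r}") from None


class Panel(str, enum.Enum):
    """Which priority-ranking panel a population is reported under.

    Panel A covers populations dispersing primarily without human assistance,
    panel B populations dependent on human assistance.
    """

    A_INDEPENDENT = "A_independent"
    B_ASSISTED = "B_assisted"


class HarmoniaLabel(str, enum.Enum):
    """Published national risk-screening category used only for concordance."""

    POTENTIALLY_INVASIVE = "potentially_invasive"
    MODERATELY_INVASIVE = "moderately_invasive"
    NOT_ASSESSED = "not_assessed"


@dataclass(frozen=True)
class Species:
    scientific_name: str
    common_name: str = ""
    origin_region: str = ""


@dataclass(frozen=True)
class Site:
    site_id: str
    name: str = ""
    length_km: float | None = None
    catchment_km2: float | None = None


@dataclass(frozen=True)
class DispersalRecord:
    """Primary mechanism plus the population's capability flags.

    A population capable of both assisted and independent spread is ranked
    higher than one with a single dependency, so the capabilities are stored
    separately from the primary mechanism.
    """

    primary_mechanism: Mechanism
    can_assisted: bool
    can_independent: bool


@dataclass(frozen=True)
class OriginRecord:
    origin_class: OriginClass
    note: str = ""


@dataclass(frozen=True)
class StatusRecord:
    abundance_trend: Trend
    range_trend: Trend


@dataclass(frozen=True)
class ImpactRecord:
    """Per-sector harm severities with a local-evidence flag.

    ``locally_evidenced`` is True only when harm has been confirmed in the
    assessed water body itself; harm suspected from the literature elsewhere
    is recorded in the sector severities with the flag left False, and does
    not count toward the priority rank.
    """

    ecology: Severity
    economy: Severity
    culture: Severity
    human_health: Severity
    locally_evidenced: bool = False

    @property
    def sectors(self) -> dict[str, Severity]:
        return {
            "ecology": self.ecology,
            "economy": self.economy,
            "culture": self.culture,
            "human_health": self.human_health,
        }

    @property
    def max_severity_level(self) -> int:
        """Maximum known harm level across sectors (unknown ignored)."""
        return max((s.level for s in self.sectors.values() if s.level is not None), default=0)


@dataclass(frozen=True)
class PopulationAssessment:
    """One (species, site) population with all four DOSI axes."""

    species: Species
    site: Site
    dispersal: DispersalRecord
    origin: OriginRecord
    status: StatusRecord
    impact: ImpactRecord
    notes: str = ""

    @property
    def key(self) -> tuple[str, str]:
        return (self.species.scientific_name, self.site.site_id)

    def replace(self, **changes) -> "PopulationAssessment":
        return replace(self, **changes)


@dataclass(frozen=True)
class PriorityRank:
    """A ranked population: the ordinal rank, its panel, and a rule trace.

    ``rationale`` records every rule applied, in firing order, so a rank is
    auditable back to the attributes that produced it.
    """

    rank: Rank
    panel: Panel
    rationale: tuple[str, ...] = field(default_factory=tuple)

    @property
    def rationale_text(self) -> str:
        return "; ".join(self.rationale)


def validate_assessment(record: PopulationAssessment) -> list[str]:
    """Check every cross-field invariant; return a list of violation messages.

    Validation is total: any syntactically well-formed record yields a
    (possibly empty) list, never an exception. Each message names the
    offending component type and field.
    """
    violations: list[str] = []

    if not record.species.scientific_name.strip():
        violations.append("Species.scientific_name: must be non-empty")
    if not record.site.site_id.strip():
        violations.append("Site.site_id: must be non-empty")
    for attr in ("length_km", "catchment_km2"):
        value = getattr(record.site, attr)
        if value is not None and value < 0:
            violations.append(f"Site.{attr}: must be non-negative, got {value}")

    d = record.dispersal
    if not (d.can_assisted or d.can_independent):
        violations.append(
            "DispersalRecord: at least one of can_assisted/can_independent must be true"
        )
    # mechanism consistency is only meaningful once some capability is claimed
    elif d.primary_mechanism.is_assisted and not d.can_assisted:
        violations.append(
            "DispersalRecord.primary_mechanism: assisted mechanism requires can_assisted=true"
        )
    elif not d.primary_mechanism.is_assisted and not d.can_independent:
        violations.append(
            "DispersalRecord.primary_mechanism: independent mechanism requires can_independent=true"
        )

    if record.impact.locally_evidenced and record.impact.max_severity_level == 0:
        violations.append(
            "ImpactRecord.locally_evidenced: may be true only if at least one "
            "sector severity exceeds benign"
        )

    return violations
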