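"""Reading and writing assessment tables.

One CSV row per (species, site) population, with a fixed column order,
lower-case snake_case enumeration tokens, ``true``/``false`` booleans, UTF-8
and LF line endings — chosen so fixtures diff cleanly and round-trip
bit-exactly. A JSON mirror of the same schema carries nested records (and
site/species metadata the flat CSV omits).
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Iterable

from .core import (
    DispersalRecord,
    ImpactRecord,
    Mechanism,
    OriginClass,
    OriginRecord,
    PopulationAssessment,
    PriorityRank,
    Severity,
    Site,
    Species,
    StatusRecord,
    Trend,
    validate_assessment,
)

__all__ = [
    "COLUMNS",
    "RANK_COLUMNS",
    "ParseError",
    "read_assessments",
    "write_assessments",
    "write_ranks",
    "assessment_to_dict",
    "assessment_from_dict",
    "read_assessments_json",
    "write_assessments_json",
]

COLUMNS = [
    "species",
    "common_name",
    "site",
    "primary_mechanism",
    "can_assisted",
    "can_independent",
    "origin_class",
    "abundance_trend",
    "range_trend",
    "impact_ecology",
    "impact_economy",
    "impact_culture",
    "impact_health",
    "impact_locally_evidenced",
    "notes",
]

RANK_COLUMNS = ["species", "common_name", "site", "panel", "rank", "rationale"]


class ParseError(ValueError):
    """A table failed schema validation; the message locates the first error."""


def _parse_enum(enum_cls, token: str, row: int, column: str):
    try:
        return enum_cls(token)
    except ValueError:
        valid = ", ".join(m.value for m in enum_cls)
        raise ParseError(
            f"row {row}, column {column!r}: invalid token {token!r} (expected one of: {valid})"
        ) from None


def _parse_bool(token: str, row: int, column: str) -> bool:
    if token == "true":
        return True
    if token == "false":
        return False
    raise ParseError(
        f"row {row}, column {column!r}: invalid boolean {token!r} (expected true/false)"
    )


def _row_to_assessment(fields: dict[str, str], row: int) -> PopulationAssessment:
    return PopulationAssessment(
        species=Species(
            scientific_name=fields["species"], common_name=fields["common_name"]
        ),
        site=Site(site_id=fields["site"]),
        dispersal=DispersalRecord(
            primary_mechanism=_parse_enum(
                Mechanism, fields["primary_mechanism"], row, "primary_mechanism"
            ),
            can_assisted=_parse_bool(fields["can_assisted"], row, "can_assisted"),
            can_independent=_parse_bool(fields["can_independent"], row, "can_independent"),
        ),
        origin=OriginRecord(
            origin_class=_parse_enum(OriginClass, fields["origin_class"], row, "origin_class")
        ),
        status=StatusRecord(
            abundance_trend=_parse_enum(Trend, fields["abundance_trend"], row, "abundance_trend"),
            range_trend=_parse_enum(Trend, fields["range_trend"], row, "range_trend"),
        ),
        impact=ImpactRecord(
            ecology=_parse_enum(Severity, fields["impact_ecology"], row, "impact_ecology"),
            economy=_parse_enum(Severity, fields["impact_economy"], row, "impact_economy"),
            culture=_parse_enum(Severity, fields["impact_culture"], row, "impact_culture"),
            human_health=_parse_enum(Severity, fields["impact_health"], row, "impact_health"),
            locally_evidenced=_parse_bool(
                fields["impact_locally_evidenced"], row, "impact_locally_evidenced"
            ),
        ),
        notes=fields["notes"],
    )


def read_assessments(path: str | Path) -> list[PopulationAssessment]:
    """Parse and validate an assessment CSV; report the first error's location.

    Raises :class:`ParseError` on a missing/misordered column, a bad
    enumeration token, a record violating a domain invariant, or a duplicate
    (species, site) pair.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(f"{path}: empty file, expected header row") from None
        if header != COLUMNS:
            missing = [c for c in COLUMNS if c not in header]
            detail = f"missing column(s) {missing}" if missing else f"got {header}"
            raise ParseError(f"{path}: header mismatch, {detail}")

        records: list[PopulationAssessment] = []
        seen: set[tuple[str, str]] = set()
        for i, row in enumerate(reader, start=2):
            if len(row) != len(COLUMNS):
                raise ParseError(f"row {i}: expected {len(COLUMNS)} fields, got {len(row)}")
            record = _row_to_assessment(dict(zip(COLUMNS, row)), i)
            violations = validate_assessment(record)
            if violations:
                raise ParseError(f"row {i}: {violations[0]}")
            if record.key in seen:
                raise ParseError(f"row {i}: duplicate (species, site) pair {record.key}")
            seen.add(record.key)
            records.append(record)
    return records


def _assessment_row(a: PopulationAssessment) -> list[str]:
    return [
        a.species.scientific_name,
        a.species.common_name,
        a.site.site_id,
        a.dispersal.primary_mechanism.value,
        "true" if a.dispersal.can_assisted else "false",
        "true" if a.dispersal.can_independent else "false",
        a.origin.origin_class.value,
        a.status.abundance_trend.value,
        a.status.range_trend.value,
        a.impact.ecology.value,
        a.impact.economy.value,
        a.impact.culture.value,
        a.impact.human_health.value,
        "true" if a.impact.locally_evidenced else "false",
        a.notes,
    ]


def write_assessments(records: Iterable[PopulationAssessment], path: str | Path) -> None:
    """Write records in input order with the fixed column order; stable across runs."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(COLUMNS)
        for record in records:
            writer.writerow(_assessment_row(record))


def write_ranks(
    ranked: Iterable[tuple[PopulationAssessment, PriorityRank]], path: str | Path
) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(RANK_COLUMNS)
        for assessment, rank in ranked:
            writer.writerow(
                [
                    assessment.species.scientific_name,
                    assessment.species.common_name,
                    assessment.site.site_id,
                    rank.panel.value,
                    rank.rank.label,
                    rank.rationale_text,
                ]
            )


# -- JSON mirror -------------------------------------------------------------


def assessment_to_dict(a: PopulationAssessment) -> dict:
    return {
        "species": {
            "scientific_name": a.species.scientific_name,
            "common_name": a.species.common_name,
            "origin_region": a.species.origin_region,
        },
        "site": {
            "site_id": a.site.site_id,
            "name": a.site.name,
            "length_km": a.site.length_km,
            "catchment_km2": a.site.catchment_km2,
        },
        "dispersal": {
            "primary_mechanism": a.dispersal.primary_mechanism.value,
            "can_assisted": a.dispersal.can_assisted,
            "can_independent": a.dispersal.can_independent,
        },
        "origin": {"origin_class": a.origin.origin_class.value, "note": a.origin.note},
        "status": {
            "abundance_trend": a.status.abundance_trend.value,
            "range_trend": a.status.range_trend.value,
        },
        "impact": {
            "ecology": a.impact.ecology.value,
            "economy": a.impact.economy.value,
            "culture": a.impact.culture.value,
            "human_health": a.impact.human_health.value,
            "locally_evidenced": a.impact.locally_evidenced,
        },
        "notes": a.notes,
    }


def assessment_from_dict(data: dict) -> PopulationAssessment:
    return PopulationAssessment(
        species=Species(**data["species"]),
        site=Site(**data["site"]),
        dispersal=DispersalRecord(
            primary_mechanism=Mechanism(data["dispersal"]["primary_mechanism"]),
            can_assisted=data["dispersal"]["can_assisted"],
            can_independent=data["dispersal"]["can_independent"],
        ),
        origin=OriginRecord(
            origin_class=OriginClass(data["origin"]["origin_class"]),
            note=data["origin"].get("note", ""),
        ),
        status=StatusRecord(
            abundance_trend=Trend(data["status"]["abundance_trend"]),
            range_trend=Trend(data["status"]["range_trend"]),
        ),
        impact=ImpactRecord(
            ecology=Severity(data["impact"]["ecology"]),
            economy=Severity(data["impact"]["economy"]),
            culture=Severity(data["impact"]["culture"]),
            human_health=Severity(data["impact"]["human_health"]),
            locally_evidenced=data["impact"]["locally_evidenced"],
        ),
        notes=data.get("notes", ""),
    )


def write_assessments_json(records: Iterable[PopulationAssessment], path: str | Path) -> None:
    Path(path).write_text(
        json.dumps([assessment_to_dict(r) for r in records], indent=2) + "\n",
        encoding="utf-8",
    )


def read_assessments_json(path: str | Path) -> list[PopulationAssessment]:
    data = json.loads(Path(path).read_text(encoding="utf-8"))
    return [assessment_from_dict(d) for d in data]
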