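"""Packaged three-river case study: Pilica, Bzura and Skrwa Prawa.

Eighteen population assessments of eight non-native fish species in three
Vistula tributaries, encoded from the published occurrence matrix, the
per-river priority ranks, and the per-population narrative, together with
the national Harmonia+PL screening labels consumed as data for concordance.

Attributes the narrative does not state verbatim are back-filled to the
minimal values consistent with the published rank and flagged ``inferred``
in the record notes — the fixture is explicit about what the tables supply
versus what the narrative implies.

The fixture files are immutable: loading verifies a SHA-256 checksum and
fails loudly on any edit.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, replace
from importlib import resources

import pandas as pd

from .core import HarmoniaLabel, PopulationAssessment, Rank, Site, Species
from .io import ParseError, read_assessments
from .ruleset import DispersalClass, classify_dispersal

__all__ = [
    "CaseStudyDataset",
    "FixtureIntegrityError",
    "load_polish_rivers",
    "occurrence_matrix",
    "dispersal_partition",
    "SITE_ORDER",
]

_ASSESSMENTS_SHA256 = "3b485c746fdb6ad89935bd4ae81093468bba7f44dc0b54a3e29004ee678ca700"
_META_SHA256 = "37a496fe5dbb7bb989c7c6f974c74baf5a04fee98f3b774d0e8c61479b807629"

SITE_ORDER = ["pilica", "bzura", "skrwa_prawa"]


class FixtureIntegrityError(RuntimeError):
    """The packaged fixture files do not match their recorded checksum."""


@dataclass(frozen=True)
class CaseStudyDataset:
    """The 18 assessments plus the published labels they are checked against."""

    assessments: list[PopulationAssessment]
    expected_ranks: dict[tuple[str, str], Rank]
    harmonia_labels: dict[str, HarmoniaLabel]
    sites: dict[str, Site]

    @property
    def species_names(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.assessments:
            seen.setdefault(a.species.scientific_name, None)
        return list(seen)

    @property
    def fixture_checksum(self) -> str:
        return _ASSESSMENTS_SHA256


def _read_packaged(name: str, expected_sha: str) -> bytes:
    data = (resources.files("dosi") / "data" / name).read_bytes()
    digest = hashlib.sha256(data).hexdigest()
    if digest != expected_sha:
        raise FixtureIntegrityError(
            f"packaged fixture {name!r} fails its integrity check "
            f"(sha256 {digest}, expected {expected_sha}); the fixture is immutable"
        )
    return data


def load_polish_rivers() -> CaseStudyDataset:
    """Load the checksummed three-river fixture.

    Returns the 18 population assessments (7 Pilica + 7 Bzura + 4 Skrwa
    Prawa, 8 distinct species) with site metadata and species origin regions
    attached, the published per-river rank for each population, and the
    Harmonia+PL species labels.
    """
    import tempfile
    from pathlib import Path

    csv_bytes = _read_packaged("polish_rivers_assessments.csv", _ASSESSMENTS_SHA256)
    meta = json.loads(_read_packaged("polish_rivers_meta.json", _META_SHA256))

    with tempfile.TemporaryDirectory() as tmp:
        path = Path(tmp) / "assessments.csv"
        path.write_bytes(csv_bytes)
        try:
            records = read_assessments(path)
        except ParseError as exc:
            raise FixtureIntegrityError(f"packaged fixture failed to parse: {exc}") from exc

    sites = {
        site_id: Site(site_id=site_id, **fields) for site_id, fields in meta["sites"].items()
    }
    regions = meta["species_origin_regions"]
    enriched = [
        replace(
            a,
            site=sites[a.site.site_id],
            species=Species(
                scientific_name=a.species.scientific_name,
                common_name=a.species.common_name,
                origin_region=regions.get(a.species.scientific_name, ""),
            ),
        )
        for a in records
    ]

    expected = {
        (row["species"], row["site"]): Rank.from_label(row["rank"])
        for row in meta["expected_ranks"]
    }
    harmonia = {name: HarmoniaLabel(label) for name, label in meta["harmonia_labels"].items()}

    occurrence = meta["occurrence"]
    present = {a.key for a in enriched}
    for species, by_site in occurrence.items():
        for site_id, is_present in by_site.items():
            if ((species, site_id) in present) != is_present:
                raise FixtureIntegrityError(
                    f"fixture occurrence disagrees with assessments for ({species}, {site_id})"
                )
    if set(expected) != present:
        raise FixtureIntegrityError("fixture expected_ranks do not cover the assessments 1:1")

    return CaseStudyDataset(
        assessments=enriched,
        expected_ranks=expected,
        harmonia_labels=harmonia,
        sites=sites,
    )


def occurrence_matrix(ds: CaseStudyDataset) -> pd.DataFrame:
    """Boolean species x site presence table (rows in fixture order)."""
    if not ds.assessments:
        return pd.DataFrame()
    site_ids = [s for s in SITE_ORDER if s in ds.sites] or sorted(
        {a.site.site_id for a in ds.assessments}
    )
    present = {a.key for a in ds.assessments}
    return pd.DataFrame(
        [[(sp, site) in present for site in site_ids] for sp in ds.species_names],
        index=ds.species_names,
        columns=site_ids,
        dtype=bool,
    )


def dispersal_partition(ds: CaseStudyDataset) -> dict[DispersalClass, int]:
    """Species-level (not population-level) counts by dispersal class.

    Each species is counted once under the class of its recorded dispersal
    capabilities; in the packaged fixture every species carries the same
    dispersal record at every site.
    """
    by_species: dict[str, DispersalClass] = {}
    for a in ds.assessments:
        by_species.setdefault(a.species.scientific_name, classify_dispersal(a.dispersal))
    counts = {cls: 0 for cls in DispersalClass}
    for cls in by_species.values():
        counts[cls] += 1
    return counts
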