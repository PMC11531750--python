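"""Tallies, per-river ranking reports, and cross-protocol concordance.

The population-level priority ranks produced by the lattice are summarised
three ways: counts per rank (overall and per site), a species x site rank
matrix, and a row-by-row comparison against species-level labels from a
national screening protocol (Harmonia+PL), which the scheme is not formally
commensurable with — hence the label-to-rank mapping used for the
concordance direction is configuration, not doctrine.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import pandas as pd

from .core import HarmoniaLabel, PopulationAssessment, PriorityRank, Rank

__all__ = [
    "RankTally",
    "Direction",
    "ConcordanceRow",
    "ConcordanceConfigError",
    "DEFAULT_HARMONIA_ORDER",
    "rank_tally",
    "cross_site_table",
    "protocol_concordance",
    "river_report",
]

Ranked = list[tuple[PopulationAssessment, PriorityRank]]

ABSENT = "-"  # cell marker for a species not assessed at a site


@dataclass(frozen=True)
class RankTally:
    per_rank: dict[Rank, int]
    per_site_per_rank: dict[tuple[str, Rank], int]
    total: int


def rank_tally(ranked: Ranked) -> RankTally:
    """Exact counts per rank and per (site, rank); conserves the total."""
    per_rank = {rank: 0 for rank in Rank}
    per_site: dict[tuple[str, Rank], int] = {}
    for assessment, priority in ranked:
        per_rank[priority.rank] += 1
        key = (assessment.site.site_id, priority.rank)
        per_site[key] = per_site.get(key, 0) + 1
    return RankTally(per_rank=per_rank, per_site_per_rank=per_site, total=len(ranked))


def cross_site_table(ranked: Ranked, site_order: list[str] | None = None) -> pd.DataFrame:
    """Species x site matrix of rank labels, with '-' where a species is absent."""
    if not ranked:
        return pd.DataFrame()
    species_order: dict[str, None] = {}
    sites_seen: dict[str, None] = {}
    cells: dict[tuple[str, str], str] = {}
    for assessment, priority in ranked:
        sp, site = assessment.key
        species_order.setdefault(sp, None)
        sites_seen.setdefault(site, None)
        cells[(sp, site)] = priority.rank.label
    sites = site_order if site_order is not None else list(sites_seen)
    return pd.DataFrame(
        [[cells.get((sp, site), ABSENT) for site in sites] for sp in species_order],
        index=list(species_order),
        columns=sites,
    )


class Direction(str, enum.Enum):
    DOSI_HIGHER = "dosi_higher"
    DOSI_LOWER = "dosi_lower"
    SIMILAR = "similar"
    NOT_COMPARABLE = "not_comparable"


@dataclass(frozen=True)
class ConcordanceRow:
    species: str
    site: str
    dosi_rank: Rank
    harmonia_label: HarmoniaLabel
    direction: Direction


class ConcordanceConfigError(ValueError):
    """A label appears in the data but not in the configured ordering."""


# Mapping of screening labels onto the priority-rank scale for direction
# only: 'potentially invasive' sits at the Low level, 'moderately invasive'
# at the Medium level. Chosen so Medium vs moderately reads as similar, Low
# vs moderately as dosi_lower, and High/Highest vs potentially as
# dosi_higher; override to explore other alignments of the two instruments.
DEFAULT_HARMONIA_ORDER: dict[HarmoniaLabel, int] = {
    HarmoniaLabel.POTENTIALLY_INVASIVE: int(Rank.LOW),
    HarmoniaLabel.MODERATELY_INVASIVE: int(Rank.MEDIUM),
}


def concordance_direction(primary_level: int, other_level: int) -> Direction:
    """Sign comparison of two ordinal protocol levels on a shared scale.

    Antisymmetric: swapping the two protocols' levels flips higher/lower and
    fixes similar.
    """
    if primary_level > other_level:
        return Direction.DOSI_HIGHER
    if primary_level < other_level:
        return Direction.DOSI_LOWER
    return Direction.SIMILAR


def protocol_concordance(
    ranked: Ranked,
    harmonia_labels: dict[str, HarmoniaLabel],
    label_order: dict[HarmoniaLabel, int] | None = None,
) -> list[ConcordanceRow]:
    """Compare each population's rank with its species' screening label.

    A species without a screening label is ``not_comparable``; otherwise the
    direction is the sign of (population rank - mapped label level).
    """
    order = DEFAULT_HARMONIA_ORDER if label_order is None else label_order
    rows = []
    for assessment, priority in ranked:
        sp, site = assessment.key
        label = harmonia_labels.get(sp, HarmoniaLabel.NOT_ASSESSED)
        if label is HarmoniaLabel.NOT_ASSESSED:
            direction = Direction.NOT_COMPARABLE
        else:
            if label not in order:
                raise ConcordanceConfigError(
                    f"label {label.value!r} missing from the configured label ordering"
                )
            direction = concordance_direction(int(priority.rank), order[label])
        rows.append(
            ConcordanceRow(
                species=sp,
                site=site,
                dosi_rank=priority.rank,
                harmonia_label=label,
                direction=direction,
            )
        )
    return rows


def river_report(ranked: Ranked, site: str) -> pd.DataFrame:
    """Ordered management listing for one site.

    Populations sorted by descending priority, ties broken alphabetically by
    scientific name. Raises ``KeyError`` for a site absent from the input.
    """
    rows = [
        (a.species.scientific_name, a.species.common_name, p.rank)
        for a, p in ranked
        if a.site.site_id == site
    ]
    if not rows:
        known = sorted({a.site.site_id for a, _ in ranked})
        raise KeyError(f"site {site!r} not present in ranked input (known sites: {known})")
    rows.sort(key=lambda r: (-int(r[2]), r[0]))
    return pd.DataFrame(
        [(sp, common, rank.label) for sp, common, rank in rows],
        columns=["species", "common_name", "rank"],
    )
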