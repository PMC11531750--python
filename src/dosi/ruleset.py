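"""The DOSI priority lattice.

A population's priority rank is a pure function of three classified
attributes:

* its **dispersal class** — independent spread only (panel A), assisted
  spread only (panel B), or the capability for both ("dual");
* its **trend class** — derived from the abundance and range trends:
  declining < static < one_expanding < both_expanding;
* whether a **locally evidenced impact** is present.

The default base table assigns, with impact absent::

    declining -> Low    static -> Medium    one_expanding -> High
    both_expanding -> High

and a present local impact lifts the base rank one level (capped at
Highest). A population capable of both assisted and independent spread is
bumped one further level, reflecting its greater invasion potential; no
worked case-study population exercises that modifier, so it is toggleable.

The base table is a reconstruction: it is the simplest table consistent with
all eighteen worked population assessments of the three-river case study,
and :func:`check_ruleset_consistency` turns that derivation into an
executable check. Alternative tables load from YAML/JSON config.
"""

from __future__ import annotations

import enum
import json
from collections import deque
from dataclasses import dataclass, field, replace
from pathlib import Path

import yaml

from .core import (
    DispersalRecord,
    ImpactRecord,
    Panel,
    PopulationAssessment,
    PriorityRank,
    Rank,
    Severity,
    StatusRecord,
    Trend,
)

__all__ = [
    "DispersalClass",
    "TrendClass",
    "RuleSet",
    "RulesetError",
    "MalformedAssessmentError",
    "default_ruleset",
    "classify_dispersal",
    "classify_trend",
    "impact_present",
    "rank_priority",
    "check_ruleset_consistency",
    "rank_flip_distance",
    "Mismatch",
    "FlipResult",
]


class RulesetError(ValueError):
    """A ruleset is incomplete or otherwise misconfigured."""


class MalformedAssessmentError(ValueError):
    """An assessment violates an invariant required for classification."""


class DispersalClass(str, enum.Enum):
    A_INDEPENDENT = "A_independent"
    B_ASSISTED = "B_assisted"
    DUAL = "dual"


class TrendClass(enum.IntEnum):
    """Joint classification of the abundance and range trends."""

    DECLINING = -1
    STATIC = 0
    ONE_EXPANDING = 1
    BOTH_EXPANDING = 2


def classify_dispersal(d: DispersalRecord) -> DispersalClass:
    """Classify a dispersal record into panel A, panel B, or dual capability."""
    if d.can_assisted and d.can_independent:
        return DispersalClass.DUAL
    if d.can_independent:
        return DispersalClass.A_INDEPENDENT
    if d.can_assisted:
        return DispersalClass.B_ASSISTED
    raise MalformedAssessmentError(
        "DispersalRecord claims neither assisted nor independent capability"
    )


def _effective(trend: Trend) -> Trend:
    # unknown trends are ranked as static but flagged in the rationale
    return Trend.STATIC if trend is Trend.UNKNOWN else trend


def classify_trend(s: StatusRecord) -> TrendClass:
    """Map the (abundance, range) trend pair onto the ordinal trend class.

    Both trends expanding -> BOTH_EXPANDING; exactly one expanding ->
    ONE_EXPANDING (expansion dominates a shrinking partner, for precaution);
    no expansion with at least one shrinking -> DECLINING; otherwise STATIC.
    Unknown trends are treated as static.
    """
    trends = (_effective(s.abundance_trend), _effective(s.range_trend))
    n_expanding = sum(t is Trend.EXPANDING for t in trends)
    if n_expanding == 2:
        return TrendClass.BOTH_EXPANDING
    if n_expanding == 1:
        return TrendClass.ONE_EXPANDING
    if Trend.SHRINKING in trends:
        return TrendClass.DECLINING
    return TrendClass.STATIC


def impact_present(i: ImpactRecord) -> bool:
    """True iff harm is locally evidenced and at least 'little' in some sector.

    Literature-suspected harm without local confirmation does not count.
    """
    return i.locally_evidenced and i.max_severity_level >= 1


_TABLE_CELLS = [(tc, imp) for tc in TrendClass for imp in (False, True)]


@dataclass(frozen=True)
class RuleSet:
    """A complete priority-ranking configuration.

    ``base_table`` must be total over TrendClass x {impact absent, present}.
    ``dual_capability_bump`` lifts dual-capability populations one level;
    ``cap`` bounds every lift (default Highest).
    """

    base_table: dict[tuple[TrendClass, bool], Rank]
    dual_capability_bump: bool = True
    cap: Rank = Rank.HIGHEST
    name: str = "default"

    def validate(self) -> None:
        missing = [cell for cell in _TABLE_CELLS if cell not in self.base_table]
        if missing:
            tc, imp = missing[0]
            raise RulesetError(
                f"ruleset {self.name!r} is missing cell "
                f"(trend={tc.name}, impact={'present' if imp else 'absent'})"
                + (f" and {len(missing) - 1} more" if len(missing) > 1 else "")
            )

    # -- config round-trip ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "dual_capability_bump": self.dual_capability_bump,
            "cap": self.cap.label,
            "base_table": [
                {
                    "trend": tc.name.lower(),
                    "impact": "present" if imp else "absent",
                    "rank": rank.label,
                }
                for (tc, imp), rank in sorted(self.base_table.items())
            ],
        }

    @classmethod
    def from_dict(cls, data: dict) -> "RuleSet":
        try:
            table = {
                (TrendClass[cell["trend"].upper()], cell["impact"] == "present"): Rank.from_label(
                    cell["rank"]
                )
                for cell in data["base_table"]
            }
            rs = cls(
                base_table=table,
                dual_capability_bump=bool(data.get("dual_capability_bump", True)),
                cap=Rank.from_label(data.get("cap", "Highest")),
                name=data.get("name", "custom"),
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise RulesetError(f"malformed ruleset config: {exc}") from exc
        rs.validate()
        return rs

    def save(self, path: str | Path) -> None:
        path = Path(path)
        text = (
            json.dumps(self.to_dict(), indent=2) + "\n"
            if path.suffix == ".json"
            else yaml.safe_dump(self.to_dict(), sort_keys=False)
        )
        path.write_text(text, encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "RuleSet":
        path = Path(path)
        data = (
            json.loads(path.read_text(encoding="utf-8"))
            if path.suffix == ".json"
            else yaml.safe_load(path.read_text(encoding="utf-8"))
        )
        return cls.from_dict(data)


def _bump(rank: Rank, cap: Rank) -> Rank:
    return Rank(min(rank + 1, cap))


def default_ruleset(impact_lift: bool = True, dual_bump: bool = True) -> RuleSet:
    """Build the default lattice.

    ``impact_lift=False`` yields a variant whose impact-present column equals
    the impact-absent one, useful for showing that the impact modifier is
    load-bearing for the case-study fixtures.
    """
    base = {
        TrendClass.DECLINING: Rank.LOW,
        TrendClass.STATIC: Rank.MEDIUM,
        TrendClass.ONE_EXPANDING: Rank.HIGH,
        TrendClass.BOTH_EXPANDING: Rank.HIGH,
    }
    table = {}
    for tc, rank in base.items():
        table[(tc, False)] = rank
        table[(tc, True)] = _bump(rank, Rank.HIGHEST) if impact_lift else rank
    return RuleSet(
        base_table=table,
        dual_capability_bump=dual_bump,
        name="default" if impact_lift else "default-no-impact-lift",
    )


def rank_priority(a: PopulationAssessment, r: RuleSet | None = None) -> PriorityRank:
    """Rank one population; the rationale records every rule applied, in order."""
    if r is None:
        r = default_ruleset()
    r.validate()

    rationale: list[str] = []

    dclass = classify_dispersal(a.dispersal)
    if dclass is DispersalClass.DUAL:
        panel = Panel.A_INDEPENDENT
        rationale.append("dispersal: dual capability (assisted and independent); reported under panel A")
    elif dclass is DispersalClass.A_INDEPENDENT:
        panel = Panel.A_INDEPENDENT
        rationale.append("dispersal: independent spread only -> panel A")
    else:
        panel = Panel.B_ASSISTED
        rationale.append("dispersal: human-assisted spread only -> panel B")

    s = a.status
    for name, trend in (("abundance", s.abundance_trend), ("range", s.range_trend)):
        if trend is Trend.UNKNOWN:
            rationale.append(f"status: {name} trend unknown, treated as static (flagged)")
    tclass = classify_trend(s)
    rationale.append(
        f"status: abundance={s.abundance_trend.value}, range={s.range_trend.value} "
        f"-> {tclass.name.lower()}"
    )

    has_impact = impact_present(a.impact)
    if has_impact:
        rationale.append(
            f"impact: locally evidenced, max sector level {a.impact.max_severity_level} -> present"
        )
    elif a.impact.max_severity_level >= 1:
        rationale.append("impact: harm recorded but not locally evidenced -> absent")
    else:
        rationale.append("impact: no known local impact -> absent")

    rank = r.base_table[(tclass, has_impact)]
    rationale.append(
        f"base table[{tclass.name.lower()}, impact "
        f"{'present' if has_impact else 'absent'}] = {rank.label}"
    )

    if dclass is DispersalClass.DUAL and r.dual_capability_bump:
        bumped = _bump(rank, r.cap)
        if bumped is not rank:
            rationale.append(f"dual-capability modifier: {rank.label} -> {bumped.label}")
        else:
            rationale.append(f"dual-capability modifier: already at cap {r.cap.label}")
        rank = bumped

    return PriorityRank(rank=rank, panel=panel, rationale=tuple(rationale))


@dataclass(frozen=True)
class Mismatch:
    species: str
    site: str
    expected: Rank
    got: Rank


def check_ruleset_consistency(
    r: RuleSet,
    labelled: list[tuple[PopulationAssessment, Rank]],
) -> list[Mismatch]:
    """Evaluate a ruleset against labelled assessments; list every mismatch.

    An empty return means the ruleset reproduces every label. An incomplete
    ruleset raises :class:`RulesetError` naming the missing cell.
    """
    if not labelled:
        raise ValueError("labelled assessment list must be non-empty")
    r.validate()
    mismatches = []
    for assessment, expected in labelled:
        got = rank_priority(assessment, r).rank
        if got is not expected:
            mismatches.append(
                Mismatch(
                    species=assessment.species.scientific_name,
                    site=assessment.site.site_id,
                    expected=expected,
                    got=got,
                )
            )
    return mismatches


# -- flip distance -----------------------------------------------------------

_TREND_LADDER = [Trend.SHRINKING, Trend.STATIC, Trend.EXPANDING]


def _trend_moves(trend: Trend) -> list[tuple[Trend, str]]:
    pos = 1 if trend is Trend.UNKNOWN else _TREND_LADDER.index(trend)
    moves = []
    if pos > 0:
        moves.append((_TREND_LADDER[pos - 1], f"{trend.value} -> {_TREND_LADDER[pos - 1].value}"))
    if pos < 2:
        moves.append((_TREND_LADDER[pos + 1], f"{trend.value} -> {_TREND_LADDER[pos + 1].value}"))
    return moves


def _single_edits(a: PopulationAssessment) -> list[tuple[PopulationAssessment, str]]:
    """All admissible one-attribute edits of an assessment."""
    edits: list[tuple[PopulationAssessment, str]] = []

    for new, desc in _trend_moves(a.status.abundance_trend):
        edits.append(
            (a.replace(status=replace(a.status, abundance_trend=new)), f"abundance_trend: {desc}")
        )
    for new, desc in _trend_moves(a.status.range_trend):
        edits.append(
            (a.replace(status=replace(a.status, range_trend=new)), f"range_trend: {desc}")
        )

    if impact_present(a.impact):
        edits.append(
            (
                a.replace(impact=replace(a.impact, locally_evidenced=False)),
                "impact: locally_evidenced -> false",
            )
        )
    else:
        new_impact = replace(a.impact, locally_evidenced=True)
        if new_impact.max_severity_level == 0:
            new_impact = replace(new_impact, ecology=Severity.LITTLE)
        edits.append((a.replace(impact=new_impact), "impact: evidenced local harm added"))

    d = a.dispersal
    if not d.can_assisted:
        edits.append(
            (a.replace(dispersal=replace(d, can_assisted=True)), "dispersal: can_assisted -> true")
        )
    if not d.can_independent:
        edits.append(
            (
                a.replace(dispersal=replace(d, can_independent=True)),
                "dispersal: can_independent -> true",
            )
        )
    # a capability may be dropped only if the other remains and the primary
    # mechanism stays consistent
    if d.can_assisted and d.can_independent:
        if not d.primary_mechanism.is_assisted:
            edits.append(
                (
                    a.replace(dispersal=replace(d, can_assisted=False)),
                    "dispersal: can_assisted -> false",
                )
            )
        else:
            edits.append(
                (
                    a.replace(dispersal=replace(d, can_independent=False)),
                    "dispersal: can_independent -> false",
                )
            )
    return edits


@dataclass(frozen=True)
class FlipResult:
    distance: int
    edits: tuple[str, ...]
    new_rank: Rank


def _state_key(a: PopulationAssessment):
    return (
        a.status.abundance_trend,
        a.status.range_trend,
        impact_present(a.impact),
        a.dispersal.can_assisted,
        a.dispersal.can_independent,
    )


def rank_flip_distance(a: PopulationAssessment, r: RuleSet | None = None) -> FlipResult:
    """Minimal number of single-attribute edits that changes the rank.

    Breadth-first search over one-step edits (one trend level at a time, the
    impact-presence toggle, one capability flag), reported with a witnessing
    edit sequence. Useful as a management-sensitivity aid: a distance of 1
    marks a population one observation away from a different priority.
    """
    if r is None:
        r = default_ruleset()
    base_rank = rank_priority(a, r).rank
    seen = {_state_key(a)}
    queue: deque[tuple[PopulationAssessment, tuple[str, ...]]] = deque([(a, ())])
    while queue:
        current, path = queue.popleft()
        for edited, desc in _single_edits(current):
            key = _state_key(edited)
            if key in seen:
                continue
            seen.add(key)
            new_path = path + (desc,)
            new_rank = rank_priority(edited, r).rank
            if new_rank is not base_rank:
                return FlipResult(distance=len(new_path), edits=new_path, new_rank=new_rank)
            queue.append((edited, new_path))
    raise RuntimeError("no attribute edit changes the rank")  # unreachable on sane rulesets
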