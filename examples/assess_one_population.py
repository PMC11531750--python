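"""Assess a single population and audit how its rank was derived.

Builds one assessment record in code — an independently dispersing
population with both abundance and range expanding and a locally evidenced
ecological impact — ranks it, prints the fired rules in order, and then asks
how fragile the rank is: the flip distance is the minimal number of
single-attribute changes (one trend level, the impact flag, a capability
flag) that would move the population to a different priority class.
"""

from dosi import (
    DispersalRecord,
    ImpactRecord,
    Mechanism,
    OriginClass,
    OriginRecord,
    PopulationAssessment,
    Severity,
    Site,
    Species,
    StatusRecord,
    Trend,
    rank_priority,
    validate_assessment,
)
from dosi.ruleset import rank_flip_distance

population = PopulationAssessment(
    species=Species("Neogobius melanostomus", "round goby", "Ponto-Caspian"),
    site=Site(site_id="oder_lower", name="Lower Oder"),
    dispersal=DispersalRecord(Mechanism.INDEPENDENT_UNAIDED, can_assisted=False, can_independent=True),
    origin=OriginRecord(OriginClass.ALLOCHTHONOUS),
    status=StatusRecord(abundance_trend=Trend.EXPANDING, range_trend=Trend.EXPANDING),
    impact=ImpactRecord(
        ecology=Severity.MODERATE,
        economy=Severity.BENIGN,
        culture=Severity.BENIGN,
        human_health=Severity.BENIGN,
        locally_evidenced=True,
    ),
)

assert validate_assessment(population) == []

result = rank_priority(population)
print(f"{population.species.scientific_name} @ {population.site.name}: "
      f"{result.rank.label} (panel {result.panel.value})")
print("rule trace:")
for step in result.rationale:
    print(f"  - {step}")

flip = rank_flip_distance(population)
print(f"\nflip distance: {flip.distance} edit(s) -> {flip.new_rank.label}")
for edit in flip.edits:
    print(f"  * {edit}")
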