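import pytest

from dosi.core import (
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
)


def build_assessment(
    species="Neogobius fluviatilis",
    site="pilica",
    mechanism=Mechanism.INDEPENDENT_UNAIDED,
    can_assisted=False,
    can_independent=True,
    abundance=Trend.EXPANDING,
    range_=Trend.EXPANDING,
    ecology=Severity.BENIGN,
    economy=Severity.BENIGN,
    culture=Severity.BENIGN,
    human_health=Severity.BENIGN,
    locally_evidenced=False,
    notes="",
) -> PopulationAssessment:
    """Assessment builder with sensible defaults for tests."""
    return PopulationAssessment(
        species=Species(scientific_name=species),
        site=Site(site_id=site),
        dispersal=DispersalRecord(
            primary_mechanism=mechanism,
            can_assisted=can_assisted,
            can_independent=can_independent,
        ),
        origin=OriginRecord(origin_class=OriginClass.ALLOCHTHONOUS),
        status=StatusRecord(abundance_trend=abundance, range_trend=range_),
        impact=ImpactRecord(
            ecology=ecology,
            economy=economy,
            culture=culture,
            human_health=human_health,
            locally_evidenced=locally_evidenced,
        ),
        notes=notes,
    )


@pytest.fixture
def make_assessment():
    return build_assessment


@pytest.fixture(scope="session")
def dataset():
    from dosi.casestudy import load_polish_rivers

    return load_polish_rivers()


@pytest.fixture(scope="session")
def ranked(dataset):
    from dosi.ruleset import default_ruleset, rank_priority

    rs = default_ruleset()
    return [(a, rank_priority(a, rs)) for a in dataset.assessments]
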