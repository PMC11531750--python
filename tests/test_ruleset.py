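"""The priority lattice: classification, ranking, totality, monotonicity."""

import pytest

from dosi.core import Mechanism, Panel, Rank, Severity, StatusRecord, Trend
from dosi.ruleset import (
    DispersalClass,
    MalformedAssessmentError,
    Mismatch,
    RuleSet,
    RulesetError,
    TrendClass,
    check_ruleset_consistency,
    classify_dispersal,
    classify_trend,
    default_ruleset,
    impact_present,
    rank_flip_distance,
    rank_priority,
)
from dosi.synthio import enumerate_state_space


class TestClassifyDispersal:
    @pytest.mark.parametrize(
        "can_assisted,can_independent,expected",
        [
            (False, True, DispersalClass.A_INDEPENDENT),  # e.g. monkey goby
            (True, False, DispersalClass.B_ASSISTED),  # e.g. gibel carp
            (True, True, DispersalClass.DUAL),
        ],
    )
    def test_classes(self, make_assessment, can_assisted, can_independent, expected):
        mech = Mechanism.ASSISTED_ACCIDENTAL if can_assisted else Mechanism.INDEPENDENT_UNAIDED
        a = make_assessment(
            mechanism=mech, can_assisted=can_assisted, can_independent=can_independent
        )
        assert classify_dispersal(a.dispersal) is expected

    def test_no_capability_is_malformed(self, make_assessment):
        a = make_assessment(can_assisted=False, can_independent=False)
        with pytest.raises(MalformedAssessmentError):
            classify_dispersal(a.dispersal)

class TestClassifyTrend:
    @pytest.mark.parametrize(
        "abundance,range_,expected",
        [
            (Trend.EXPANDING, Trend.EXPANDING, TrendClass.BOTH_EXPANDING),
            (Trend.STATIC, Trend.STATIC, TrendClass.STATIC),
            (Trend.SHRINKING, Trend.SHRINKING, TrendClass.DECLINING),
            (Trend.EXPANDING, Trend.STATIC, TrendClass.ONE_EXPANDING),
            (Trend.EXPANDING, Trend.SHRINKING, TrendClass.ONE_EXPANDING),
            (Trend.STATIC, Trend.SHRINKING, TrendClass.DECLINING),
            (Trend.UNKNOWN, Trend.UNKNOWN, TrendClass.STATIC),
            (Trend.EXPANDING, Trend.UNKNOWN, TrendClass.ONE_EXPANDING),
            (Trend.UNKNOWN, Trend.SHRINKING, TrendClass.DECLINING),
        ],
    )
    def test_pairs(self, abundance, range_, expected):
        assert classify_trend(StatusRecord(abundance, range_)) is expected

    def test_exhaustively_total(self):
        """Every (abundance, range) pair maps to exactly one trend class."""
        for a in Trend:
            for r in Trend:
                assert classify_trend(StatusRecord(a, r)) in TrendClass

class TestImpactPresent:
    def test_evidenced_harm_counts(self, make_assessment):
        a = make_assessment(ecology=Severity.LITTLE, locally_evidenced=True)
        assert impact_present(a.impact)

    def test_all_benign_absent(self, make_assessment):
        assert not impact_present(make_assessment().impact)

    def test_suspected_but_unevidenced_absent(self, make_assessment):
        # racer-goby-in-Pilica situation: literature harm, no local confirmation
        a = make_assessment(ecology=Severity.LITTLE, locally_evidenced=False)
        assert not impact_present(a.impact)

class TestRankPriority:
    """The six worked population examples from the three-river study."""

    @pytest.mark.parametrize(
        "kwargs,expected_rank,expected_panel",
        [
            # monkey goby, Pilica: independent, both expanding, evidenced impact
            (
                dict(abundance=Trend.EXPANDING, range_=Trend.EXPANDING,
                     ecology=Severity.LITTLE, locally_evidenced=True),
                Rank.HIGHEST, Panel.A_INDEPENDENT,
            ),
            # western tubenose goby: independent, both expanding, no impact
            (
                dict(abundance=Trend.EXPANDING, range_=Trend.EXPANDING),
                Rank.HIGH, Panel.A_INDEPENDENT,
            ),
            # topmouth gudgeon, Pilica: independent, static, no impact
            (
                dict(abundance=Trend.STATIC, range_=Trend.STATIC),
                Rank.MEDIUM, Panel.A_INDEPENDENT,
            ),
            # brown bullhead, Pilica: assisted, declining, no impact
            (
                dict(mechanism=Mechanism.ASSISTED_DELIBERATE, can_assisted=True,
                     can_independent=False, abundance=Trend.SHRINKING, range_=Trend.SHRINKING),
                Rank.LOW, Panel.B_ASSISTED,
            ),
            # Chinese sleeper, Skrwa Prawa: abundance increasing rather than static
            (
                dict(abundance=Trend.EXPANDING, range_=Trend.STATIC),
                Rank.HIGH, Panel.A_INDEPENDENT,
            ),
            # gibel carp, Pilica: assisted, both expanding, evidenced impact
            (
                dict(mechanism=Mechanism.ASSISTED_ACCIDENTAL, can_assisted=True,
                     can_independent=False, abundance=Trend.EXPANDING, range_=Trend.EXPANDING,
                     ecology=Severity.LITTLE, locally_evidenced=True),
                Rank.HIGHEST, Panel.B_ASSISTED,
            ),
        ],
    )
    def test_worked_examples(self, make_assessment, kwargs, expected_rank, expected_panel):
        result = rank_priority(make_assessment(**kwargs))
        assert result.rank is expected_rank
        assert result.panel is expected_panel

    def test_dual_capability_bumps_one_level(self, make_assessment):
        single = make_assessment(abundance=Trend.STATIC, range_=Trend.STATIC)
        dual = make_assessment(
            abundance=Trend.STATIC, range_=Trend.STATIC, can_assisted=True, can_independent=True
        )
        assert rank_priority(single).rank is Rank.MEDIUM
        assert rank_priority(dual).rank is Rank.HIGH
        assert rank_priority(dual).panel is Panel.A_INDEPENDENT

    def test_dual_bump_caps_at_highest(self, make_assessment):
        a = make_assessment(
            can_assisted=True, can_independent=True,
            abundance=Trend.EXPANDING, range_=Trend.EXPANDING,
            ecology=Severity.EXTENSIVE, locally_evidenced=True,
        )
        assert rank_priority(a).rank is Rank.HIGHEST

    def test_deterministic_with_identical_rationale(self, make_assessment):
        a = make_assessment(ecology=Severity.MODERATE, locally_evidenced=True)
        assert rank_priority(a) == rank_priority(a)

    def test_unknown_trend_flagged_in_rationale(self, make_assessment):
        a = make_assessment(abundance=Trend.UNKNOWN, range_=Trend.STATIC)
        result = rank_priority(a)
        assert result.rank is Rank.MEDIUM
        assert any("unknown" in step for step in result.rationale)

    def test_rationale_records_every_step(self, make_assessment):
        result = rank_priority(make_assessment())
        text = result.rationale_text
        for fragment in ("dispersal", "status", "impact", "base table"):
            assert fragment in text

    def test_incomplete_ruleset_names_missing_cell(self, make_assessment):
        broken = RuleSet(base_table={(TrendClass.STATIC, False): Rank.MEDIUM}, name="broken")
        with pytest.raises(RulesetError, match="missing cell"):
            rank_priority(make_assessment(), broken)

class TestLatticeProperties:
    """Brute-force verification over the full 24-cell input domain."""

    def test_totality_over_all_cells(self):
        cells = enumerate_state_space()
        rs = default_ruleset()
        assert len(cells) == 24
        for assessment in cells.values():
            assert rank_priority(assessment, rs).rank in Rank

    def test_monotonic_upgrades_never_lower_rank(self):
        """Raising one trend a level, adding evidenced impact, or adding a
        second dispersal capability never lowers the priority rank."""
        cells = enumerate_state_space()
        rs = default_ruleset()
        rank_of = {key: rank_priority(a, rs).rank for key, a in cells.items()}
        trend_order = list(TrendClass)
        for (dclass, tclass, impact), rank in rank_of.items():
            i = trend_order.index(tclass)
            if i + 1 < len(trend_order):
                assert rank_of[(dclass, trend_order[i + 1], impact)] >= rank
            if not impact:
                assert rank_of[(dclass, tclass, True)] >= rank
            if dclass is not DispersalClass.DUAL:
                assert rank_of[(DispersalClass.DUAL, tclass, impact)] >= rank

    def test_lattice_boundaries(self):
        cells = enumerate_state_space()
        rs = default_ruleset()
        low = rank_priority(cells[(DispersalClass.B_ASSISTED, TrendClass.DECLINING, False)], rs)
        assert low.rank is Rank.LOW
        for dclass in DispersalClass:
            top = rank_priority(cells[(dclass, TrendClass.BOTH_EXPANDING, True)], rs)
            assert top.rank >= Rank.HIGH

class TestConsistencyChecker:
    def test_default_ruleset_reproduces_fixture_labels(self, dataset):
        labelled = [(a, dataset.expected_ranks[a.key]) for a in dataset.assessments]
        assert check_ruleset_consistency(default_ruleset(), labelled) == []

    def test_disabling_impact_lift_breaks_fixtures(self, dataset):
        labelled = [(a, dataset.expected_ranks[a.key]) for a in dataset.assessments]
        mismatches = check_ruleset_consistency(default_ruleset(impact_lift=False), labelled)
        assert mismatches, "impact modifier is load-bearing"
        monkey = [m for m in mismatches if m.species == "Neogobius fluviatilis"]
        assert monkey and all(m.expected is Rank.HIGHEST for m in monkey)

    def test_empty_labelled_list_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            check_ruleset_consistency(default_ruleset(), [])

    def test_incomplete_table_is_configuration_error(self, make_assessment):
        broken = RuleSet(base_table={}, name="empty")
        with pytest.raises(RulesetError):
            check_ruleset_consistency(broken, [(make_assessment(), Rank.HIGH)])

    def test_mismatch_reports_location(self, make_assessment):
        a = make_assessment(abundance=Trend.STATIC, range_=Trend.STATIC)
        [m] = check_ruleset_consistency(default_ruleset(), [(a, Rank.HIGHEST)])
        assert m == Mismatch(
            species=a.species.scientific_name, site=a.site.site_id,
            expected=Rank.HIGHEST, got=Rank.MEDIUM,
        )

class TestFlipDistance:
    def test_static_medium_one_edit_from_high(self, make_assessment):
        # topmouth-gudgeon-like population
        a = make_assessment(abundance=Trend.STATIC, range_=Trend.STATIC)
        result = rank_flip_distance(a)
        assert result.distance == 1
        assert result.new_rank is not Rank.MEDIUM

    def test_declining_low_one_edit_away(self, make_assessment):
        # bullhead-like population: one observation (evidenced impact or a
        # recovering trend) changes its priority
        a = make_assessment(
            mechanism=Mechanism.ASSISTED_DELIBERATE, can_assisted=True, can_independent=False,
            abundance=Trend.SHRINKING, range_=Trend.SHRINKING,
        )
        result = rank_flip_distance(a)
        assert result.distance == 1

    def test_maximal_assessment_flips_downward(self, make_assessment):
        a = make_assessment(
            can_assisted=True, can_independent=True,
            abundance=Trend.EXPANDING, range_=Trend.EXPANDING,
            ecology=Severity.EXTENSIVE, locally_evidenced=True,
        )
        assert rank_priority(a).rank is Rank.HIGHEST
        result = rank_flip_distance(a)
        assert result.new_rank < Rank.HIGHEST
        assert result.distance >= 1

    def test_witness_edit_reproduces_the_flip(self, make_assessment):
        a = make_assessment(abundance=Trend.STATIC, range_=Trend.STATIC)
        result = rank_flip_distance(a)
        assert len(result.edits) == result.distance

class TestRulesetConfig:
    @pytest.mark.parametrize("suffix", [".yaml", ".json"])
    def test_round_trip_is_bit_exact(self, tmp_path, suffix):
        rs = default_ruleset(dual_bump=False)
        path = tmp_path / f"ruleset{suffix}"
        rs.save(path)
        loaded = RuleSet.load(path)
        assert loaded == rs
        loaded.save(tmp_path / f"again{suffix}")
        assert (tmp_path / f"again{suffix}").read_bytes() == path.read_bytes()

    def test_malformed_config_rejected(self, tmp_path):
        path = tmp_path / "bad.yaml"
        path.write_text("base_table: [{trend: static, impact: absent, rank: Galactic}]\n")
        with pytest.raises(RulesetError):
            RuleSet.load(path)
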