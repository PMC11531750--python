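"""Synthetic assessments and exhaustive state-space enumeration.

The generator draws random-but-valid population assessments so that every
ruleset property can be exercised without the case-study fixtures;
:func:`enumerate_state_space` lists all 24 distinct
(dispersal class, trend class, impact flag) cells, the complete input domain
of the priority lattice, and is the oracle behind the totality and
monotonicity checks.

Reproducibility: one root seed is split per record index with numpy's
``SeedSequence``, so any subset of a generated batch can be regenerated
independently of the rest.

The generator does not model ecologically realistic co-occurrence between
attributes (e.g. expanding populations being likelier to show impact); draws
across axes are independent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core import (
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
from .ruleset import DispersalClass, TrendClass

__all__ = ["GeneratorConfig", "generate_assessments", "enumerate_state_space"]

_TRENDS = [Trend.EXPANDING, Trend.STATIC, Trend.SHRINKING, Trend.UNKNOWN]
_HARM = [Severity.LITTLE, Severity.MODERATE, Severity.EXTENSIVE]


@dataclass(frozen=True)
class GeneratorConfig:
    """Sampling configuration.

    trend_weights are the draw probabilities for
    (expanding, static, shrinking, unknown), applied independently to the
    abundance and range trends; impact_prob is the probability of an
    evidenced local impact; dual_prob the probability of dual dispersal
    capability (the remainder splits evenly between independent-only and
    assisted-only).
    """

    n: int
    seed: int = 0
    trend_weights: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    impact_prob: float = 0.3
    dual_prob: float = 0.1
    origin_class: OriginClass = OriginClass.ALLOCHTHONOUS

    def validate(self) -> None:
        if self.n < 0:
            raise ValueError(f"n must be non-negative, got {self.n}")
        if len(self.trend_weights) != 4 or any(w < 0 for w in self.trend_weights):
            raise ValueError("trend_weights must be 4 non-negative probabilities")
        if not math.isclose(sum(self.trend_weights), 1.0, abs_tol=1e-9):
            raise ValueError(
                f"trend_weights must sum to 1 (got {sum(self.trend_weights)!r})"
            )
        for name in ("impact_prob", "dual_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")


def _draw_one(rng: np.random.Generator, cfg: GeneratorConfig, index: int) -> PopulationAssessment:
    u = rng.random()
    if u < cfg.dual_prob:
        can_assisted = can_independent = True
    elif u < cfg.dual_prob + (1 - cfg.dual_prob) / 2:
        can_assisted, can_independent = False, True
    else:
        can_assisted, can_independent = True, False
    mechanisms = [
        m
        for m in Mechanism
        if (m.is_assisted and can_assisted) or (not m.is_assisted and can_independent)
    ]
    mechanism = mechanisms[rng.integers(len(mechanisms))]

    abundance, range_ = (
        _TRENDS[i] for i in rng.choice(4, size=2, p=np.asarray(cfg.trend_weights))
    )

    if rng.random() < cfg.impact_prob:
        sectors = [Severity.BENIGN] * 4
        sectors[rng.integers(4)] = _HARM[rng.integers(3)]
        impact = ImpactRecord(*sectors, locally_evidenced=True)
    else:
        impact = ImpactRecord(
            Severity.BENIGN, Severity.BENIGN, Severity.BENIGN, Severity.BENIGN,
            locally_evidenced=False,
        )

    return PopulationAssessment(
        species=Species(scientific_name=f"Synthetica specimen{index}", common_name=f"synthetic {index}"),
        site=Site(site_id=f"site_{index}"),
        dispersal=DispersalRecord(
            primary_mechanism=mechanism,
            can_assisted=can_assisted,
            can_independent=can_independent,
        ),
        origin=OriginRecord(origin_class=cfg.origin_class),
        status=StatusRecord(abundance_trend=abundance, range_trend=range_),
        impact=impact,
        notes="synthetic",
    )


def generate_assessments(cfg: GeneratorConfig) -> list[PopulationAssessment]:
    """Draw ``cfg.n`` valid assessments; identical config => identical output."""
    cfg.validate()
    root = np.random.SeedSequence(cfg.seed)
    return [
        _draw_one(np.random.Generator(np.random.PCG64(child)), cfg, i)
        for i, child in enumerate(root.spawn(cfg.n))
    ]


# -- exhaustive enumeration --------------------------------------------------

_TREND_REPS = {
    TrendClass.DECLINING: (Trend.SHRINKING, Trend.SHRINKING),
    TrendClass.STATIC: (Trend.STATIC, Trend.STATIC),
    TrendClass.ONE_EXPANDING: (Trend.EXPANDING, Trend.STATIC),
    TrendClass.BOTH_EXPANDING: (Trend.EXPANDING, Trend.EXPANDING),
}

_DISPERSAL_REPS = {
    DispersalClass.A_INDEPENDENT: DispersalRecord(Mechanism.INDEPENDENT_UNAIDED, False, True),
    DispersalClass.B_ASSISTED: DispersalRecord(Mechanism.ASSISTED_ACCIDENTAL, True, False),
    DispersalClass.DUAL: DispersalRecord(Mechanism.INDEPENDENT_UNAIDED, True, True),
}


def enumerate_state_space() -> dict[
    tuple[DispersalClass, TrendClass, bool], PopulationAssessment
]:
    """All 24 (dispersal class, trend class, impact flag) cells with a representative.

    Every representative passes validation, and the mapping's keys cover the
    full input domain of :func:`dosi.ruleset.rank_priority`.
    """
    cells = {}
    for dclass, dispersal in _DISPERSAL_REPS.items():
        for tclass, (abundance, range_) in _TREND_REPS.items():
            for has_impact in (False, True):
                impact = ImpactRecord(
                    ecology=Severity.LITTLE if has_impact else Severity.BENIGN,
                    economy=Severity.BENIGN,
                    culture=Severity.BENIGN,
                    human_health=Severity.BENIGN,
                    locally_evidenced=has_impact,
                )
                cells[(dclass, tclass, has_impact)] = PopulationAssessment(
                    species=Species(
                        scientific_name=f"Cellus {dclass.value.lower()}_{tclass.name.lower()}_"
                        f"{'impact' if has_impact else 'noimpact'}"
                    ),
                    site=Site(site_id="cell"),
                    dispersal=dispersal,
                    origin=OriginRecord(origin_class=OriginClass.ALLOCHTHONOUS),
                    status=StatusRecord(abundance_trend=abundance, range_trend=range_),
                    impact=impact,
                    notes="state-space representative",
                )
    return cells
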