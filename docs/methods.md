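# Methods

## The model

DOSI is an ordinal, rule-based classifier, not a fitted model. Its input
domain is deliberately small: a population is reduced to

* a **dispersal class** — independent-only (panel A), assisted-only
  (panel B), or dual capability;
* a **trend class** — a joint classification of the abundance and range
  trends: `declining < static < one_expanding < both_expanding`;
* an **impact flag** — whether locally evidenced harm of at least "little"
  severity exists in any sector.

That gives 3 × 4 × 2 = 24 distinct input cells, so every global property of
the ranking function (totality, monotonicity, boundary behaviour) is
verified by exhaustive enumeration rather than sampling
(`dosi.synthio.enumerate_state_space`).

The default base table assigns, with impact absent:
declining → Low, static → Medium, one_expanding → High,
both_expanding → High. A present local impact lifts the base rank one
level; dual dispersal capability lifts one further level; all lifts are
capped at Highest.

### Why this table

The published description of the scheme is graphical, not tabular, so the
base table here is a *reconstruction*: the simplest table consistent with
all eighteen worked population assessments of the three-river case study.
The derivation is executable — `check_ruleset_consistency(default_ruleset(),
labelled)` over the packaged fixtures returns zero mismatches, and
disabling the impact lift demonstrably breaks the monkey-goby populations
(expected Highest, computed High). Two consequences of the reconstruction:

* `(both_expanding, no impact) → High` rather than Highest is forced by the
  tubenose goby (both trends expanding, no observed impact, ranked High in
  all three rivers) against the monkey goby (same trends plus evidenced
  impact, Highest). Impact, not trend saturation, is what separates the top
  two ranks.
* `(declining, impact) → Medium` is an extrapolation: no case-study
  population is declining *and* locally harmful. It follows from applying
  the same one-level impact lift uniformly.

Alternative tables load from YAML/JSON config (`RuleSet.load`), and panels
A and B share the default table because the worked examples show identical
trend/impact behaviour across panels (e.g. the assisted gibel carp mirrors
the independent gobies cell for cell); per-panel tables can be expressed as
two configs if a user needs them.

## Modelling choices on ambiguous inputs

* **Mixed trends** `(expanding, shrinking)` classify as `one_expanding`:
  expansion dominates for precaution, consistent with ranking "one static
  and one expanding" above fully static.
* **Unknown trends** rank as static but are flagged in the rationale, so
  expert gap-filling stays auditable instead of silently optimistic or
  pessimistic.
* **Impact aggregation** across the four sectors is the maximum severity:
  harm to *any* sector counts. `unknown` severities are ignored (never
  treated as harm), and only *locally evidenced* harm moves the rank —
  harm suspected from studies elsewhere is stored in the severities but
  deliberately inert, which is exactly what separates the racer goby's High
  (Pilica, impact unconfirmed) from its Highest (Skrwa Prawa, native
  declines observed).
* **Origin** is recorded but does not modify the rank: every case-study
  population is allochthonous, so no worked example constrains an
  origin-dependent rule, and inventing one would be unfalsifiable here.
* **Dual capability** (+1 level) is exercised by no case-study population;
  it is config-toggleable and covered by the enumeration tests instead.
* **Severity scale**: four ordered harm levels (benign, little, moderate,
  extensive) plus unknown — the minimal ordinal scale covering the
  endpoints the scheme names and the "moderate" language used by the
  comparison protocol.

## The case-study fixture

`dosi/data/` packages the 18 assessments (7 Pilica + 7 Bzura + 4 Skrwa
Prawa, 8 distinct species), the published per-river rank for each
population, the occurrence matrix, and the national Harmonia+PL screening
labels. Attributes the published narrative states directly (e.g. the
bullhead's shrinking range and abundance, the Skrwa Prawa sleeper's
increasing abundance) are encoded verbatim; attributes it does not state
(e.g. the racer goby's Bzura trends) are back-filled to the *minimal*
values consistent with the published rank and carry an `inferred` note in
the CSV. The fixture files are immutable: loading verifies SHA-256
checksums and raises on any edit, so a silently modified fixture cannot
make the headline reproduction pass vacuously.

One documented discrepancy: the study's summary prose counts six Medium
populations overall, but its rank table contains seven Medium cells (and
six High). The implementation reports the table-derived counts — Medium=7,
High=6 — because the table is the cell-by-cell ground truth the fixtures
encode.

## Protocol concordance

DOSI ranks populations; the national screening protocol labels species.
The two scales are not formally commensurable, so the comparison direction
is computed through an explicit, configurable alignment: by default
`potentially_invasive` sits at the Low level and `moderately_invasive` at
the Medium level, and the direction is the sign of (population rank −
mapped label). This alignment reproduces the three qualitative relations
the case study reports (gobies above their national label, brown bullhead
below, topmouth gudgeon and Chinese sleeper similar); other alignments can
be passed to `protocol_concordance`. The direction function is
antisymmetric — swapping which protocol is primary flips higher/lower —
which is property-tested. No significance testing is attempted at n=18.

## The synthetic generator

`generate_assessments` draws valid records with independent axes: each
trend from a configurable 4-vector over (expanding, static, shrinking,
unknown), uniform by default; an evidenced impact with probability 0.3
(one random sector at a random harm level); dual dispersal capability with
probability 0.1, the remainder split evenly between independent-only and
assisted-only; origin fixed allochthonous by default, matching the
case-study populations. Defaults were chosen once as a plausibly mixed
screening workload — impacts evidenced in a minority of populations, dual
capability rare — and are not tuned to any output.

Randomness uses one root `SeedSequence` split per record index, so the
first *k* records of any batch equal the *k*-record batch from the same
seed (prefix stability, tested). What the generator does **not** emulate:
correlation between axes in real data (expanding populations are likelier
to have detectable impact), species identity shared across sites, or
site-level co-occurrence structure. Passing property tests on synthetic
data therefore demonstrates the lattice's formal properties (totality,
monotonicity, determinism, round-trip safety) — not that the scheme's
rankings are ecologically correct, which only the encoded case study and
future field applications speak to.

## Numerics and problem sizes

There is no floating-point model to speak of; the only tolerances are the
1e-9 absolute check on generator weight sums and exact equality everywhere
else. The test suite exercises the full 24-cell enumeration, 10,000-record
validation totality, and 200-example hypothesis runs (derandomised); the
acceptance script ranks the 18 fixtures, enumerates the 24 cells, and
generates 10,000 synthetic records with a 500-record CSV round-trip. The
whole suite completes in a few seconds on one CPU.

## Known limitations

* The base table is a reconstruction constrained by 18 examples; cells no
  example reaches (notably declining-with-impact and all dual-capability
  cells) are extrapolations, clearly marked as such above.
* Ranks consume whatever trend/impact attributions the assessor supplies;
  the scheme has no mechanism to weigh evidence quality beyond the single
  locally-evidenced flag.
* Feasibility and cost of management actions are out of scope by design, as
  is forecasting spread beyond currently occupied sites.
* Facilitated vs unaided independent dispersal are recorded but ranked
  identically; no worked example distinguishes them.
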