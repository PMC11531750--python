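# dosi

Population-level prioritisation of non-native species with the
**Dispersal-Origin-Status-Impact (DOSI)** assessment scheme.

Most invasive-species screening protocols assign one risk label per species
per country or continent. That granularity hides the fact that the same
species can be an expanding, damaging invader in one river and a static,
harmless straggler in the next. DOSI instead classifies each *population* —
one (species, site) pair — along four axes and maps it onto an ordinal
management priority, so that managers with limited resources can decide
*which populations, where* to act on first. This package implements the
scheme as a tested library with a thin command-line layer, and packages the
three-river Polish case study (18 populations of 8 non-native fish species
in the Pilica, Bzura and Skrwa Prawa, tributaries of the Vistula) that the
scheme was first applied to.

## The scheme

Each population is described by:

* **D**ispersal — whether it spreads with human assistance (deliberate
  release or accidental escape), independently (unaided, or facilitated by
  human-made corridors such as canals), or holds the capability for both;
* **O**rigin — allochthonous vs autochthonous relative to the spatial scale
  of interest (recorded for nomenclature; it does not move the rank);
* **S**tatus — the trend of abundance and of range size: expanding, static,
  or shrinking;
* **I**mpact — harm to four sectors (ecology, economy, culture, human
  health) on the ordinal scale benign < little < moderate < extensive, with
  a flag saying whether the harm is evidenced *locally*.

The rank lattice `Low < Medium < High < Highest` is computed as:

```
trend class  =  declining | static | one_expanding | both_expanding
base rank    =  Low       | Medium | High          | High
impact present (locally evidenced, ≥ little in some sector): base rank + 1
dual dispersal capability (assisted AND independent):        + 1
all lifts capped at Highest
```

Every rank carries a machine-generated rationale tracing the rules that
fired, and `rank_flip_distance` reports how many single-attribute changes
would move a population to a different priority — a useful fragility check
before committing management effort.

## Worked example

```python
from dosi import load_polish_rivers, rank_priority, cross_site_table

ds = load_polish_rivers()
ranked = [(a, rank_priority(a)) for a in ds.assessments]
print(cross_site_table(ranked, site_order=list(ds.sites)))
```

prints the species × river priority matrix:

```
                            pilica    bzura skrwa_prawa
Babka gymnotrachelus          High   Medium     Highest
Neogobius fluviatilis      Highest  Highest           -
Proterorhinus semilunaris     High     High        High
Perccottus glenii           Medium   Medium        High
Ameiurus nebulosus             Low        -           -
Carassius gibelio          Highest   Medium        High
Pseudorasbora parva         Medium   Medium           -
Cyprinus carpio                  -   Medium           -
```

Each cell is the management priority of that river's population ('-' =
species not recorded there). Note the population-level signal: the racer
goby (*Babka gymnotrachelus*) spans three different priorities across three
rivers, and the gibel carp is Highest in the Pilica — where its expansion
coincides with evidenced harm to native biota — but only Medium in the
Bzura. Across all 18 populations the tally is 4 Highest, 6 High, 7 Medium
and 1 Low (the declining brown bullhead).

More narrative walk-throughs live in `examples/`:

* `rank_three_rivers.py` — the matrix and tally above;
* `assess_one_population.py` — build a record in code, audit the rule
  trace, measure the flip distance;
* `compare_with_screening.py` — concordance of the population ranks with
  the national species-level screening labels (Harmonia+PL);
* `synthetic_assessments.py` — the seeded generator and the full 24-cell
  lattice state space.

The same operations are available from the shell:

```sh
dosi casestudy --export assessments.csv
dosi assess assessments.csv --out ranks.csv
dosi tally assessments.csv
dosi report assessments.csv --site skrwa_prawa
dosi synth --n 100 --seed 1 --out synthetic.csv
```

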