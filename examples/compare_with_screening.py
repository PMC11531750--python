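"""Compare population-level ranks with national species-level screening labels.

The case-study species were previously screened at the national scale
(Harmonia+PL), which labels a whole species 'potentially invasive' or
'moderately invasive'. Ranking the same species per population shows where
the two scales disagree: a direction of dosi_higher means the local
population outranks its national label (a locally underestimated threat),
dosi_lower the reverse, similar that the two agree, and not_comparable that
the species was never screened nationally.
"""

from collections import Counter

from dosi import load_polish_rivers, protocol_concordance, rank_priority

ds = load_polish_rivers()
ranked = [(a, rank_priority(a)) for a in ds.assessments]
rows = protocol_concordance(ranked, ds.harmonia_labels)

for r in rows:
    print(f"{r.species:28s} {r.site:12s} {r.dosi_rank.label:8s} "
          f"vs {r.harmonia_label.value:22s} -> {r.direction.value}")

counts = Counter(r.direction.value for r in rows)
print("\ndirections:", dict(counts))
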