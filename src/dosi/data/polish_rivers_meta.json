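{
  "sites": {
    "pilica": {"name": "Pilica", "length_km": 332.5, "catchment_km2": 9258},
    "bzura": {"name": "Bzura", "length_km": 166, "catchment_km2": 7788},
    "skrwa_prawa": {"name": "Skrwa Prawa", "length_km": 117.6, "catchment_km2": 1704}
  },
  "species_origin_regions": {
    "Babka gymnotrachelus": "Ponto-Caspian",
    "Neogobius fluviatilis": "Ponto-Caspian",
    "Proterorhinus semilunaris": "Ponto-Caspian",
    "Perccottus glenii": "Eastern Asia",
    "Ameiurus nebulosus": "North America",
    "Carassius gibelio": "Eastern Asia",
    "Pseudorasbora parva": "Eastern Asia",
    "Cyprinus carpio": "Danube catchment"
  },
  "occurrence": {
    "Babka gymnotrachelus": {"pilica": true, "bzura": true, "skrwa_prawa": true},
    "Neogobius fluviatilis": {"pilica": true, "bzura": true, "skrwa_prawa": false},
    "Proterorhinus semilunaris": {"pilica": true, "bzura": true, "skrwa_prawa": true},
    "Perccottus glenii": {"pilica": true, "bzura": true, "skrwa_prawa": true},
    "Ameiurus nebulosus": {"pilica": true, "bzura": false, "skrwa_prawa": false},
    "Carassius gibelio": {"pilica": true, "bzura": true, "skrwa_prawa": true},
    "Pseudorasbora parva": {"pilica": true, "bzura": true, "skrwa_prawa": false},
    "Cyprinus carpio": {"pilica": false, "bzura": true, "skrwa_prawa": false}
  },
  "expected_ranks": [
    {"species": "Babka gymnotrachelus", "site": "pilica", "rank": "High"},
    {"species": "Babka gymnotrachelus", "site": "bzura", "rank": "Medium"},
    {"species": "Babka gymnotrachelus", "site": "skrwa_prawa", "rank": "Highest"},
    {"species": "Neogobius fluviatilis", "site": "pilica", "rank": "Highest"},
    {"species": "Neogobius fluviatilis", "site": "bzura", "rank": "Highest"},
    {"species": "Proterorhinus semilunaris", "site": "pilica", "rank": "High"},
    {"species": "Proterorhinus semilunaris", "site": "bzura", "rank": "High"},
    {"species": "Proterorhinus semilunaris", "site": "skrwa_prawa", "rank": "High"},
    {"species": "Perccottus glenii", "site": "pilica", "rank": "Medium"},
    {"species": "Perccottus glenii", "site": "bzura", "rank": "Medium"},
    {"species": "Perccottus glenii", "site": "skrwa_prawa", "rank": "High"},
    {"species": "Ameiurus nebulosus", "site": "pilica", "rank": "Low"},
    {"species": "Carassius gibelio", "site": "pilica", "rank": "Highest"},
    {"species": "Carassius gibelio", "site": "bzura", "rank": "Medium"},
    {"species": "Carassius gibelio", "site": "skrwa_prawa", "rank": "High"},
    {"species": "Pseudorasbora parva", "site": "pilica", "rank": "Medium"},
    {"species": "Pseudorasbora parva", "site": "bzura", "rank": "Medium"},
    {"species": "Cyprinus carpio", "site": "bzura", "rank": "Medium"}
  ],
  "harmonia_labels": {
    "Babka gymnotrachelus": "potentially_invasive",
    "Neogobius fluviatilis": "potentially_invasive",
    "Proterorhinus semilunaris": "potentially_invasive",
    "Perccottus glenii": "moderately_invasive",
    "Ameiurus nebulosus": "moderately_invasive",
    "Carassius gibelio": "not_assessed",
    "Pseudorasbora parva": "moderately_invasive",
    "Cyprinus carpio": "not_assessed"
  }
}
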