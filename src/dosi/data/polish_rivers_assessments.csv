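species,common_name,site,primary_mechanism,can_assisted,can_independent,origin_class,abundance_trend,range_trend,impact_ecology,impact_economy,impact_culture,impact_health,impact_locally_evidenced,notes
Babka gymnotrachelus,racer goby,pilica,independent_unaided,false,true,allochthonous,expanding,expanding,little,benign,benign,benign,false,extending range and abundance; impact suspected from literature but not confirmed locally
Babka gymnotrachelus,racer goby,bzura,independent_unaided,false,true,allochthonous,static,static,benign,benign,benign,benign,false,trends inferred: minimal values consistent with published Medium rank
Babka gymnotrachelus,racer goby,skrwa_prawa,independent_unaided,false,true,allochthonous,expanding,expanding,moderate,benign,benign,benign,true,extending range and abundance; local declines of white-finned gudgeon golden loach and European bullhead
Neogobius fluviatilis,monkey goby,pilica,independent_unaided,false,true,allochthonous,expanding,expanding,little,benign,benign,benign,true,increasing range and abundance; competitive pressure on native species
Neogobius fluviatilis,monkey goby,bzura,independent_unaided,false,true,allochthonous,expanding,expanding,little,benign,benign,benign,true,increasing range and abundance; competitive pressure on native species
Proterorhinus semilunaris,western tubenose goby,pilica,independent_unaided,false,true,allochthonous,expanding,expanding,benign,benign,benign,benign,false,continually extending range and abundance; no negative impact observed yet
Proterorhinus semilunaris,western tubenose goby,bzura,independent_unaided,false,true,allochthonous,expanding,expanding,benign,benign,benign,benign,false,continually extending range and abundance; no negative impact observed yet
Proterorhinus semilunaris,western tubenose goby,skrwa_prawa,independent_unaided,false,true,allochthonous,expanding,expanding,benign,benign,benign,benign,false,continually extending range and abundance; no negative impact observed yet
Perccottus glenii,Chinese sleeper,pilica,independent_unaided,false,true,allochthonous,static,static,benign,benign,benign,benign,false,ephemeral riverine presence; no abundance growth or local impact
Perccottus glenii,Chinese sleeper,bzura,independent_unaided,false,true,allochthonous,static,static,benign,benign,benign,benign,false,ephemeral riverine presence; no abundance growth or local impact
Perccottus glenii,Chinese sleeper,skrwa_prawa,independent_unaided,false,true,allochthonous,expanding,static,benign,benign,benign,benign,false,abundance increasing rather than static
Ameiurus nebulosus,brown bullhead,pilica,assisted_deliberate,true,false,allochthonous,shrinking,shrinking,benign,benign,benign,benign,false,decreasing range and abundance in less suitable riverine habitat
Carassius gibelio,gibel carp,pilica,assisted_accidental,true,false,allochthonous,expanding,expanding,little,benign,benign,benign,true,range extension and abundance increase; negative effect on native biota at this site
Carassius gibelio,gibel carp,bzura,assisted_accidental,true,false,allochthonous,static,static,benign,benign,benign,benign,false,no influence at this site; trends inferred: minimal values consistent with published Medium rank
Carassius gibelio,gibel carp,skrwa_prawa,assisted_accidental,true,false,allochthonous,expanding,expanding,benign,benign,benign,benign,false,trends inferred: minimal values consistent with published High rank; no local impact evidenced
Pseudorasbora parva,topmouth gudgeon,pilica,independent_unaided,false,true,allochthonous,static,static,benign,benign,benign,benign,false,static range and abundance; only single individuals caught
Pseudorasbora parva,topmouth gudgeon,bzura,independent_unaided,false,true,allochthonous,static,static,benign,benign,benign,benign,false,static range and abundance; only single individuals caught
Cyprinus carpio,common carp,bzura,assisted_deliberate,true,false,allochthonous,static,static,benign,benign,benign,benign,false,trends inferred: minimal values consistent with published Medium rank
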