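# Default phase-I biotransformation catalogs, one per structural class.
#
# Each rule is a named net elemental delta ("+O -H2" style terms), the
# structural blocks it can act on ("any" = whole molecule), and the maximum
# number of times it may be applied along one pathway.  Hydroxylation allows
# two applications (dihydroxylation is observed); all other rules one.
# Composite one-step reactions (ketone, carboxylic acid, lactone) are listed
# alongside their multi-step equivalents; the enumerator collapses duplicate
# formulas keeping the shallowest pathway.
classes:
  morpholinoethyl-indole:
    - {name: hydroxylation, delta: "+O", blocks: any, max_applications: 2}
    - {name: dehydrogenation, delta: "-H2", blocks: any, max_applications: 1}
    - {name: dihydrodiol_formation, delta: "+H2O2", blocks: [head, core], max_applications: 1}
    - {name: oxidation_to_ketone, delta: "+O -H2", blocks: any, max_applications: 1}
    - {name: oxidation_to_carboxylic_acid, delta: "+O2 -H2", blocks: any, max_applications: 1}
    - {name: morpholine_N_dealkylation, delta: "-C4H6O", blocks: [tail], max_applications: 1}
    - {name: oxidative_morpholine_cleavage, delta: "-C4H7N", blocks: [tail], max_applications: 1}
    - {name: oxidative_morpholine_opening_A, delta: "-C2H2", blocks: [tail], max_applications: 1}
    - {name: oxidative_morpholine_opening_B, delta: "-CH2 +O", blocks: [tail], max_applications: 1}
  indazole-carboxamide-ester:
    - {name: hydroxylation, delta: "+O", blocks: any, max_applications: 2}
    - {name: dehydrogenation, delta: "-H2", blocks: any, max_applications: 1}
    - {name: dihydrodiol_formation, delta: "+H2O2", blocks: [core], max_applications: 1}
    - {name: oxidation_to_ketone, delta: "+O -H2", blocks: any, max_applications: 1}
    - {name: oxidation_to_carboxylic_acid, delta: "+O2 -H2", blocks: any, max_applications: 1}
    - {name: ester_hydrolysis, delta: "-C2H4", blocks: [sidechain], max_applications: 1}
    - {name: oxidative_defluorination, delta: "-F +O +H", blocks: [tail], max_applications: 1}
    - {name: lactone_formation, delta: "-C2H4 -H2", blocks: [sidechain], max_applications: 1}
    - {name: N_dealkylation, delta: "-C5H9F", blocks: [tail], max_applications: 1}
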