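# Shipped compound definitions: elemental formulas, structural blocks, and
# curated fragment templates (even-electron cation compositions) with the
# literature m/z each template must reproduce to within 0.0005 u.
#
# Block formulas are the compositions each block contributes to the neutral
# molecule; together with `linkage_hydrogens` they sum exactly to the parent
# formula.  Template `blocks` list which blocks a fragment retains, which is
# what modification localization reasons over.
compounds:
  JWH-200:
    formula: C25H24N2O2
    parent_class: morpholinoethyl-indole
    linkage_hydrogens: 1
    blocks:
      head: {formula: C11H7O, description: naphthoyl}
      core: {formula: C8H4N, description: indole}
      tail: {formula: C6H12NO, description: morpholinoethyl}
    templates:
      - {label: naphthoyl_acylium, formula: C11H7O, blocks: [head], mz: 155.0491}
      - {label: naphthoyl_hydrate, formula: C10H9O, blocks: [head], mz: 145.0647}
      - {label: morpholinoethyl, formula: C6H12NO, blocks: [tail], mz: 114.0913}
      - {label: morpholine_iminium, formula: C4H8N, blocks: [tail], mz: 70.0651}
      - {label: protonated_molecule, formula: C25H25N2O2, blocks: [head, core, tail], mz: 385.1910}
  A-796260:
    formula: C22H30N2O2
    parent_class: morpholinoethyl-indole
    linkage_hydrogens: 1
    blocks:
      head: {formula: C8H13O, description: tetramethylcyclopropyl-carbonyl}
      core: {formula: C8H4N, description: indole}
      tail: {formula: C6H12NO, description: morpholinoethyl}
    templates:
      - {label: tmcp_acylium, formula: C8H13O, blocks: [head], mz: 125.0960}
      - {label: tmcp_cation, formula: C7H13, blocks: [head], mz: 97.1011}
      - {label: morpholinoethyl, formula: C6H12NO, blocks: [tail], mz: 114.0913}
      - {label: indole_carbonyl_hydroxyethyl, formula: C11H10NO2, blocks: [core, tail], mz: 188.0706}
      - {label: protonated_molecule, formula: C22H31N2O2, blocks: [head, core, tail], mz: 355.2380}
  5F-EMB-PINACA:
    formula: C20H28FN3O3
    parent_class: indazole-carboxamide-ester
    linkage_hydrogens: 1
    blocks:
      core: {formula: C8H4N2O, description: indazole-3-carbonyl}
      tail: {formula: C5H10F, description: 5-fluoropentyl}
      sidechain: {formula: C7H13NO2, description: ethyl-methylbutanoate (ester-valine)}
    templates:
      - {label: indazole_carbonyl_fluoropentyl, formula: C13H14FN2O, blocks: [core, tail], mz: 233.1084}
      - {label: rearranged_hydrate, formula: C13H16FN2O2, blocks: [core, tail], mz: 251.1190}
      - {label: indazole_carbonyl, formula: C8H5N2O, blocks: [core], mz: 145.0396}
      - {label: indazole_carbonyl_hydrate, formula: C8H7N2O2, blocks: [core], mz: 163.0502}
      - {label: acyl_fluoride, formula: C9H6FN2O, blocks: [core], mz: 177.0458}
      - {label: pentenyl, formula: C5H9, blocks: [tail], mz: 69.0698}
      - {label: lactone, formula: C5H7O2, blocks: [sidechain], mz: 99.0440}
      - {label: protonated_molecule, formula: C20H29FN3O3, blocks: [core, tail, sidechain], mz: 378.2187}
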