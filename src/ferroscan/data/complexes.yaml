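# Shipped porin-cytochrome complex and conserved gene-cluster definitions.
# Heme constraints reflect the characterized subunit stoichiometries:
# Cyc2 is a fused monoheme cytochrome-porin; MtoA and MtrC are decaheme
# outer-membrane cytochromes; the PCC3 periplasmic subunit carries >=20
# hemes and its extracellular partner 10-35; the Uet complex pairs an
# undecaheme (UetJ) with a tetraheme (UetA) and three trihemes (UetDEG);
# the Slit_1321-1325 cluster is a conserved periplasmic cytochrome locus.
# Porins and other non-cytochrome subunits are matched by similarity only.
complexes:
  - name: Cyc2
    window: 15
    roles:
      - {role: Cyc2, required: true, min_hemes: 1, max_hemes: 1}
  - name: MtoAB
    window: 15
    roles:
      - {role: MtoA, required: true, min_hemes: 10, max_hemes: 10}
      - {role: MtoB, required: true}
      - {role: MtoC, required: false}
      - {role: MtoD, required: false, min_hemes: 1, max_hemes: 1}
      - {role: CymA, required: false, min_hemes: 4, max_hemes: 4}
  - name: MtrC
    window: 15
    roles:
      - {role: MtrC, required: true, min_hemes: 10, max_hemes: 10}
  - name: PCC3
    window: 15
    roles:
      - {role: PCC3-periplasmic, required: true, min_hemes: 20, variant_on_extra_copy: true}
      - {role: PCC3-extracellular, required: true, min_hemes: 10, max_hemes: 35}
      - {role: PCC3-porin, required: true}
      - {role: PCC3-inner-membrane, required: true}
  - name: Uet
    window: 15
    roles:
      - {role: UetA, required: true, min_hemes: 4, max_hemes: 4}
      - {role: UetJ, required: true, min_hemes: 11, max_hemes: 12}
      - {role: UetD, required: true, min_hemes: 3, max_hemes: 3}
      - {role: UetE, required: true, min_hemes: 3, max_hemes: 3}
      - {role: UetG, required: true, min_hemes: 3, max_hemes: 3}
      - {role: UetB, required: true}
      - {role: UetH, required: true}
      - {role: UetI, required: true}
      - {role: UetC, required: false}
  - name: Slit_cluster
    window: 15
    roles:
      - {role: Slit_1321, required: true}
      - {role: Slit_1323, required: true, min_hemes: 1, max_hemes: 1}
      - {role: Slit_1324, required: true, min_hemes: 2, max_hemes: 2}
      - {role: Slit_1322, required: false}
      - {role: Slit_1325, required: false}
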