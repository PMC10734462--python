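# Shipped metabolic marker definitions: each marker is a set of subunit
# roles searched against the reference catalog; the marker is present in a
# genome when the required fraction of subunits (rule, default all) has at
# least one qualifying homolog.  The set covers iron oxidation (cyc2,
# mtoA), nitrite oxidation (nxrAB), microaerobic respiration (ccoN),
# denitrification and N assimilation (narGH, napAB, nasA, nirK, nirS,
# nirBD, norBC, nosZ), sulfur (sqr, dsrAB), carbon fixation (cbbLS),
# stalk formation (sfz) and organic utilization (gtsABC, lutABCP).
markers:
  - {name: cyc2, subunits: [Cyc2]}
  - {name: mtoA, subunits: [MtoA]}
  - {name: nxrAB, subunits: [NxrA, NxrB]}
  - {name: ccoN, subunits: [CcoN]}
  - {name: narGH, subunits: [NarG, NarH]}
  - {name: napAB, subunits: [NapA, NapB]}
  - {name: nasA, subunits: [NasA]}
  - {name: nirK, subunits: [NirK]}
  - {name: nirS, subunits: [NirS]}
  - {name: nirBD, subunits: [NirB, NirD]}
  - {name: norBC, subunits: [NorB, NorC]}
  - {name: nosZ, subunits: [NosZ]}
  - {name: sqr, subunits: [Sqr]}
  - {name: dsrAB, subunits: [DsrA, DsrB]}
  - {name: cbbLS, subunits: [CbbL, CbbS]}
  - {name: sfz, subunits: [Sfz]}
  - {name: gtsABC, subunits: [GtsA, GtsB, GtsC]}
  - {name: lutABCP, subunits: [LutA, LutB, LutC, LutP], rule: 0.75}
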