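# Cryptophyte profile: four translating compartments including the
# periplastid compartment (PPC), whose nucleomorph genome encodes serRS.
# The mitochondrial genome lacks tRNA-lys and the nucleomorph lacks tRNA-glu,
# so under the charged-tRNA-import hypothesis those compartments do not
# require the corresponding synthetase. No amidotransferase subunits are
# present, so glnRS is required in every compartment.
name: Guillardia theta
compartments: [cytosol, mitochondrion, plastid, ppc]
organelle_trna_presence:
  mitochondrion:
    missing: [lys]
  plastid:
    missing: []
  nucleomorph:
    missing: [glu]
organelle_encoded_aars:
  - aars_type: serRS
    subunit_kind: standard
    organelle: nucleomorph
transamidation: []
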