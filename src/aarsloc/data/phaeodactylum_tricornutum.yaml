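# Diatom profile: three translating compartments, no PPC translation.
# The plastid genome encodes the prokaryote-type pheRS beta subunit (syfB);
# both glu-tRNA(gln) amidotransferase subunits carry mitochondrial presequences,
# so the mitochondrion can transamidate instead of importing a glnRS.
name: Phaeodactylum tricornutum
compartments: [cytosol, mitochondrion, plastid]
organelle_trna_presence:
  mitochondrion:
    missing: []
  plastid:
    missing: []
organelle_encoded_aars:
  - aars_type: pheRS
    subunit_kind: beta
    organelle: plastid
transamidation:
  - compartment: mitochondrion
    subunits: [gatA, gatB]
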