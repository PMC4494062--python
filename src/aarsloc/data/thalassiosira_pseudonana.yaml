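# Diatom profile: three translating compartments, no PPC translation.
# Unlike P. tricornutum this plastid genome carries no pheRS subunit; the
# plastid is served by a nuclear monomer-type pheRS instead.
name: Thalassiosira pseudonana
compartments: [cytosol, mitochondrion, plastid]
organelle_trna_presence:
  mitochondrion:
    missing: []
  plastid:
    missing: []
organelle_encoded_aars: []
transamidation:
  - compartment: mitochondrion
    subunits: [gatA, gatB]
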