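# Maturation-protein detection profiles.
#
# Each profile lists the conserved-signature slots a homology hit must
# satisfy.  A slot references motif-catalog roles:
#   roles          - patterns accepted as canonical evidence (any one suffices)
#   variant_roles  - atypical patterns: matching only these demotes the
#                    call to candidate_atypical instead of detected
#   required       - a required slot with no canonical or variant match
#                    makes the protein undetectable at this locus
# min_identity (percent) and max_evalue gate the homology hit for
# profiles whose detection rests on homology alone (the HypA-F
# carbonyl/nickel-insertion machinery, whose individual signatures are
# not modelled here).
# length_range constrains the candidate's residue count where family
# length is diagnostic (HydG ~450 aa).

profiles:
  HydE:
    slots:
      - name: radical_sam_core
        roles: [radical_sam]
        required: true
      - name: cterm_fes
        roles: [hyde_cterm]
        required: false   # dispensable cluster; presence does not change activity
  HydG:
    length_range: [350, 550]
    slots:
      - name: radical_sam_core
        roles: [radical_sam]
        required: true
      - name: cterm_fes
        roles: [hydg_cterm]
        variant_roles: [hydg_cterm_variant]
        required: true
  HydF:
    slots:
      - name: ploop
        roles: [hydf_ploop]
        required: true
      - name: switch
        roles: [hydf_switch]
        required: true
      - name: nkxd
        roles: [hydf_nkxd]
        required: true
      - name: cterm_fes
        roles: [hydf_cterm]
        required: true
  HypA:
    min_identity: 50.0
    max_evalue: 0.01
    slots: []
  HypB:
    min_identity: 50.0
    max_evalue: 0.01
    slots:
      - name: ploop
        roles: [hypb_ploop]
        required: false   # optional; a match raises the GTPase flag
  HypC:
    min_identity: 50.0
    max_evalue: 0.01
    slots: []
  HypD:
    min_identity: 50.0
    max_evalue: 0.01
    slots: []
  HypE:
    min_identity: 50.0
    max_evalue: 0.01
    slots: []
  HypF:
    min_identity: 50.0
    max_evalue: 0.01
    slots: []
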