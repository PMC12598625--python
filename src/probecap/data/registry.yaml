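# Default gene-family registry: 14 marker genes of inorganic nitrogen and
# methane cycling.  Archaeal and bacterial ammonia monooxygenase variants are
# sub-clades of the single amoA entry.
families:
  - name: nifH
    pathway: N_fixation
  - name: amoA
    pathway: nitrification
    homolog_group: amo_pmo
    sub_clades: [archaeal, bacterial]
  - name: nxrB
    pathway: nitrification
    homolog_group: nxr_nar
  - name: hzoA
    pathway: anammox
  - name: nrfA
    pathway: DNRA
    homolog_group: nap_nar_nrf
  - name: napA
    pathway: denitrification
    homolog_group: nap_nar_nrf
  - name: narG
    pathway: denitrification
    homolog_group: nap_nar_nrf
  - name: nirK
    pathway: denitrification
  - name: nirS
    pathway: denitrification
  - name: norB
    pathway: denitrification
  - name: nosZ
    pathway: denitrification
  - name: pmoA
    pathway: methanotrophy
    homolog_group: amo_pmo
  - name: mmoX
    pathway: methanotrophy
  - name: mcrA
    pathway: methanogenesis

# Decoy labels: non-target homologs that cross-hit members of the named
# groups and participate in competitive disambiguation, but are never
# counted as detections.
decoys:
  - name: narH
    homolog_groups: [nap_nar_nrf, nxr_nar]
  - name: fdhA
    homolog_groups: [nap_nar_nrf]
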