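name: tdnrl_rc
# The TD(N\R)L + RC derivation: from the ancestral arthropod gene order to
# the Polydesmus sp. GZCS-2019 arrangement.
start_order: ../orders/ancestral_arthropod.order
target_order: ../orders/polydesmus_gzcs2019.order
events:
  - kind: whole_genome_duplication
    description: >-
      Tandem duplication of the entire mitogenome into a circular
      head-to-tail dimer of two identical monomers.
  - kind: polarity_loss
    rule: {"+": 1, "-": 2}
    description: >-
      Non-random loss predetermined by transcriptional polarity: monomer 1
      keeps every plus-strand gene, monomer 2 every minus-strand gene.
  - kind: recombination_join
    mode: 3p-3p
    description: >-
      3'-3' recombination join: monomer 2's gene sequence is reversed and
      its transcription polarity flipped, fusing the monomers into a
      single-stranded circular product.
  - kind: tdrl_translocation
    segment: [trnT, nad4]
    keep: {trnT: 2}
    default_keep: 1
    description: >-
      Tandem duplication-random loss over the circular span from trnT to
      nad4 (covering the nad4L/trnP neighbourhood); keeping the second trnT
      copy relocates trnT to between nad4 and trnH, the local reading
      trnT-nad4-nad4L.
  - kind: tdrl_translocation
    segment: [trnC, trnQ]
    keep: {trnC: 2, trnQ: 1}
    description: >-
      Recombination-mediated trnC/trnQ position swap (duplication-excision
      of the two-gene span). Orientation-preserving, so the product stays
      entirely on the plus strand; a signed inversion of the pair would
      instead flip both genes to the minus strand.
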