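# Monomer 1 survivors as printed in the source publication: the plus-strand
# genes retained after polarity-based non-random loss (linear monomer,
# dimer cut at the CR-trnI junction).
trnI
trnM
nad2
trnW
cox1
cox2
trnK
trnD
atp8
atp6
cox3
trnG
nad3
trnA
trnR
trnN
trnS1
trnE
trnT
nad6
cob
trnS2
CR
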