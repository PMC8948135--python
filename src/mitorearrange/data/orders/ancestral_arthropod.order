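# Ancestral arthropod mitochondrial gene order (Limulus polyphemus ground
# pattern), written starting at trnI so the dimer cut falls at the CR-trnI
# junction. Leading '-' marks minus-strand genes.
trnI
-trnQ
trnM
nad2
trnW
-trnC
-trnY
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
-trnF
-nad5
-trnH
-nad4
-nad4L
trnT
-trnP
nad6
cob
trnS2
-nad1
-trnL2
-trnL1
-rrnL
-trnV
-rrnS
CR
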