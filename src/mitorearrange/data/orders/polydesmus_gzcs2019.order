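# Polydesmus sp. GZCS-2019 gene order, read off the published annotation
# table in start-coordinate order; every gene on the + strand.
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
nad6
cob
trnS2
CR
rrnS
trnV
rrnL
trnL1
trnL2
nad1
trnP
nad4L
nad4
trnT
trnH
nad5
trnF
trnY
trnQ
trnC
trnI
trnM
nad2
trnW
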