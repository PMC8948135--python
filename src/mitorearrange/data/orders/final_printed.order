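# Final gene arrangement exactly as printed in the source publication
# (before its stated polarity reversal of the minus-strand block).
# Verbatim transcription, anomalies preserved:
#  - nad4L appears twice; nad1 is absent (the first nad4L is a typo for nad1);
#  - the minus signs reflect the printed strand typography; the text then
#    states the minus-strand polarities are reversed.
# Not a valid gene order: read with read_gene_list().
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
nad6
cob
trnS2
CR
-rrnS
-trnV
-rrnL
-trnL1
-trnL2
-nad4L
-trnP
-nad4L
-nad4
-trnT
-trnH
-nad5
-trnF
-trnY
-trnQ
-trnC
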