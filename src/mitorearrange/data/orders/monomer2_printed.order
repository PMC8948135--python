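# Monomer 2 survivors exactly as printed (reversed reading direction,
# minus-strand genes). Verbatim transcription, anomalies preserved:
#  - trnY is omitted although it is a minus-strand survivor;
#  - the first "nad4L" sits where the ancestral order has nad1 (typo);
#  - nad4L therefore appears twice, so this list is NOT a valid gene order
#    and must be read with read_gene_list().
-rrnS
-trnV
-rrnL
-trnL1
-trnL2
-nad4L
-trnP
-nad4L
-nad4
-trnH
-nad5
-trnF
-trnC
-trnQ
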