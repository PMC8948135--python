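# Feature table of the Polydesmus sp. GZCS-2019 mitogenome (GenBank MZ677220),
# transcribed from the published annotation. 1-based inclusive coordinates.
# The nad1 stop is the truncated single "T"; its length follows from the
# coordinates (925 bp).
# genome_length=15036
name	category	start	end	strand	start_codon	stop_codon	anticodon
cox1	PCG	1	1533	+	ATG	TAA	.
cox2	PCG	1537	2214	+	ATG	TAA	.
trnK	tRNA	2215	2278	+	.	.	AAG
trnD	tRNA	2282	2346	+	.	.	GAC
atp8	PCG	2347	2505	+	ATG	TAG	.
atp6	PCG	2502	3165	+	ATA	T	.
cox3	PCG	3166	3951	+	ATG	TAA	.
trnG	tRNA	3953	4017	+	.	.	GGA
nad3	PCG	4025	4369	+	ATG	TAG	.
trnA	tRNA	4378	4439	+	.	.	GCA
trnR	tRNA	4440	4505	+	.	.	CGA
trnN	tRNA	4509	4574	+	.	.	AAC
trnS1	tRNA	4575	4632	+	.	.	AGC
trnE	tRNA	4636	4697	+	.	.	GAA
nad6	PCG	4698	5166	+	ATG	T	.
cob	PCG	5167	6271	+	ATG	T	.
trnS2	tRNA	6297	6353	+	.	.	TCA
CR	control_region	6354	6790	+	.	.	.
rrnS	rRNA	6791	7598	+	.	.	.
trnV	tRNA	7596	7659	+	.	.	GTA
rrnL	rRNA	7834	8887	+	.	.	.
trnL1	tRNA	8903	8966	+	.	.	CTA
trnL2	tRNA	8977	9042	+	.	.	TTA
nad1	PCG	9044	9968	+	ATG	T	.
trnP	tRNA	9969	10033	+	.	.	CCA
nad4L	PCG	10028	10315	+	ATC	TAG	.
nad4	PCG	10309	11650	+	ATG	T	.
trnT	tRNA	11651	11717	+	.	.	ACA
trnH	tRNA	11789	11857	+	.	.	CAC
nad5	PCG	11851	13550	+	ATG	TA	.
trnF	tRNA	13559	13625	+	.	.	TTC
trnY	tRNA	13626	13688	+	.	.	TAC
trnQ	tRNA	13691	13756	+	.	.	CAA
trnC	tRNA	13766	13831	+	.	.	TGC
trnI	tRNA	13833	13898	+	.	.	ATC
trnM	tRNA	13900	13963	+	.	.	ATG
nad2	PCG	13970	14972	+	GTG	T	.
trnW	tRNA	14973	15035	+	.	.	TGA
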