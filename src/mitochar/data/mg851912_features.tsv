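# Feature annotation of the Hyporhamphus quoyi mitogenome (GenBank MG851912.1).
# Coordinates are 1-based inclusive on the H strand. Duplicate Leu/Ser tRNAs are
# numbered by coordinate order (first occurrence -> 1).
# genome_length: 16525
# circular: true
feature	class	strand	start	end	start_codon	stop_codon
trnF	tRNA	H	1	69
rrnS	rRNA	H	69	1012
trnV	tRNA	H	1012	1085
rrnL	rRNA	H	1085	2771
trnL1	tRNA	H	2772	2845
nad1	PCG	H	2846	3820	ATG	TAA
trnI	tRNA	H	3824	3895
trnQ	tRNA	L	3894	3964
trnM	tRNA	H	3963	4034
nad2	PCG	H	4034	5080	ATG	TAG
trnW	tRNA	H	5079	5151
trnA	tRNA	L	5153	5221
trnN	tRNA	L	5223	5295
OL	OL	L	5296	5333
trnC	tRNA	L	5334	5400
trnY	tRNA	L	5401	5471
cox1	PCG	H	5473	7026	GTG	TAA
trnS1	tRNA	L	7033	7101
trnD	tRNA	H	7107	7180
cox2	PCG	H	7185	7875	ATG	T
trnK	tRNA	H	7876	7950
atp8	PCG	H	7951	8118	ATG	TAA
atp6	PCG	H	8108	8791	ATG	TAA
cox3	PCG	H	8791	9576	ATG	TAA
trnG	tRNA	H	9576	9646
nad3	PCG	H	9647	9997	ATG	TAA
trnR	tRNA	H	9995	10065
nad4l	PCG	H	10065	10361	ATG	TAA
nad4	PCG	H	10355	11732	ATG	T
trnH	tRNA	H	11733	11801
trnS2	tRNA	H	11801	11870
trnL2	tRNA	H	11873	11947
nad5	PCG	H	11947	13785	ATG	TAA
nad6	PCG	L	13782	14303	ATG	TAA
trnE	tRNA	L	14304	14372
cytb	PCG	H	14376	15516	ATG	T
trnT	tRNA	H	15517	15589
trnP	tRNA	L	15590	15659
CR	CR	H	15660	16525
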