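Gene	Start	Stop	Strand	Length	Interval	Start Coding	Stop Coding
trnP(tgg)	1	70	+	70	3
trnT(tgt)	74	146	−	73	0
cytb	147	1287	−	1141	5	ATG	ACT
trnE(ttc)	1293	1361	+	69	0
nad6	1362	1883	+	522	−4	ATG	TAA
nad5	1880	3721	−	1842	0	ATG	TAA
trnL1(tag)	3722	3794	−	73	1
trnS1(gct)	3796	3863	−	68	0
trnH(gtg)	3864	3932	−	69	0
nad4	3933	5313	−	1381	−7	ATG	TCT
nad4L	5307	5603	−	297	0	ATG	TAA
trnR(tcg)	5604	5673	−	70	−2
nad3	5672	6022	−	351	0	ATG	TAG
trnG(tcc)	6023	6094	−	72	−1
cox3	6094	6879	−	786	−1	ATG	TAA
atp6	6879	7562	−	684	−10	ATG	TAA
atp8	7553	7720	−	168	1	ATG	TAA
trnK(ttt)	7722	7795	−	74	0
cox2	7796	8486	−	691	14	ATG	CCT
trnD(gtc)	8501	8572	−	72	8
trnS2(tga)	8581	8651	+	71	−9
cox1	8643	10,238	−	1596	1	GTG	AGG
trnY(gta)	10,240	10,310	+	71	0
trnC(gca)	10,311	10,378	+	68	37
trnN(gtt)	10,416	10,487	+	72	1
trnA(tgc)	10,489	10,557	+	69	1
trnW(tca)	10,559	10,630	−	72	−2
nad2	10,629	11,675	−	1047	0	ATG	TAG
trnM(cat)	11,676	11,744	−	69	−1
trnQ(ttg)	11,744	11,814	+	71	−1
trnI(gat)	11,814	11,885	−	72	8
nad1	11,894	12,868	−	975	0	ATG	TAA
trnL2(taa)	12,869	12,943	−	75	0
rrnL	12,944	14,606	−	1663	39
trnV(tac)	14,646	14,717	−	72	0
rrnS	14,718	15,674	−	957	0
trnF(gaa)	15,675	15,744	−	70	0
D-loop	15,745	16,712		968
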