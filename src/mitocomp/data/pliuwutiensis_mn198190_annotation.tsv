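gene	strand	start	end	category	start_codon	stop_codon
trna-pro	+	1	66	tRNA
trna-gln	-	63	132	tRNA
trna-asn	+	139	207	tRNA
trna-leu(tag)	+	210	282	tRNA
trna-ala	-	282	348	tRNA
trna-trp	+	350	419	tRNA
trna-cys	+	420	484	tRNA
trna-val	-	486	555	tRNA
trna-asp	-	560	624	tRNA
trna-met	+	682	750	tRNA
trna-tyr	+	758	826	tRNA
trna-gly	+	826	896	tRNA
trna-leu(taa)	+	897	967	tRNA
nad1	+	968	1939	PCG	GTG	TAA
trna-ile	+	1945	2012	tRNA
nad2	+	2015	3055	PCG	ATG	TAA
16S	+	3056	4403	rRNA
cox1	+	4534	6087	PCG	ATG	TAA
trna-arg	+	6089	6153	tRNA
nad4L	+	6154	6450	PCG	ATG	TAA
cox2	+	6451	7140	PCG	ATG	TAA
trna-lys	+	7143	7206	tRNA
atp8	+	7207	7371	PCG	ATG	TAA
atp6	+	7365	8048	PCG	ATG	TAA
cox3	+	8051	8833	PCG	ATG	TAA
trna-ser(tga)	-	8833	8903	tRNA
nad3	+	8943	9287	PCG	ATG	TAA
nad4	+	9291	10652	PCG	ATG	TAG
trna-his	+	10643	10710	tRNA
trna-ser(gct)	+	10712	10778	tRNA
nad5	+	10776	12605	PCG	TTG	TAA
nad6	-	12619	13107	PCG	CTA	CAT
cytb	+	13116	14255	PCG	ATG	TAA
trna-phe	+	14257	14327	tRNA
12S	+	14328	15128	rRNA
trna-glu	+	15129	15196	tRNA
trna-thr	+	15197	15266	tRNA
putative CR	+	15267	15969	control_region
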