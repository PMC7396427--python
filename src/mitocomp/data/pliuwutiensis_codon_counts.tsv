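codon	aa_label	count	printed_rscu
UUU	F	171	1.14
UUC	F	130	0.86
UUA	L	169	1.76
UUG	L	61	0.64
CUU	L	134	1.40
CUC	L	73	0.76
CUA	L	112	1.17
CUG	L	27	0.28
AUU	I	124	1.15
AUC	I	74	0.69
AUA	M	126	1.17
AUG	M	71	1.00
GUU	V	43	1.29
GUC	V	27	0.81
GUA	V	55	1.65
GUG	V	8	0.24
UCU	S	162	1.83
UCC	S	121	1.36
UCA	S	97	1.09
UCG	S	18	0.20
CCU	P	141	1.50
CCC	P	99	1.05
CCA	P	107	1.14
CCG	P	29	0.31
ACU	T	81	1.01
ACC	T	101	1.26
ACA	T	104	1.30
ACG	T	34	0.43
GCU	A	40	1.23
GCC	A	55	1.69
GCA	A	31	0.95
GCG	A	4	0.12
UAU	Y	212	1.39
UAC	Y	92	0.61
UAA	*	244	1.71
UAG	*	111	0.78
CAU	H	96	1.19
CAC	H	65	0.81
CAA	Q	151	1.43
CAG	Q	60	0.57
AAU	N	153	1.13
AAC	N	118	0.87
AAA	K	340	1.53
AAG	K	104	0.47
GAU	D	76	1.11
GAC	D	61	0.89
GAA	E	127	1.53
GAG	E	39	0.47
UGU	C	30	1.07
UGC	C	26	0.93
UGA	W	74	0.52
UGG	W	32	1.00
CGU	R	19	0.50
CGC	R	16	0.42
CGA	R	27	0.71
CGG	R	12	0.31
AGU	S	57	0.64
AGC	S	77	0.87
AGA	S	94	2.46
AGG	S	61	1.60
GGU	G	25	0.83
GGC	G	12	0.40
GGA	G	66	2.20
GGG	G	17	0.57
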