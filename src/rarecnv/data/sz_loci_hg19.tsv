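name	chrom	start	end	type
1q21.1 del	1	146.57	147.39	del
1q21.1 dup	1	146.57	147.39	dup
NRXN1 del	2	50.15	51.26	del
3q29 del	3	195.73	197.34	del
WBS dup	7	72.74	74.14	dup
VIPR2 dup	7	158.82	158.94	dup
15q11.2 del	15	22.80	23.09	del
AS/PWS dup	15	24.82	28.43	dup
15q13.3 del	15	31.13	32.48	del
16p13.11 dup	16	15.51	16.30	dup
16p11.2 distal del	16	28.82	29.05	del
16p11.2 dup	16	29.64	30.20	dup
17p12 del	17	14.16	15.43	del
17q12 del	17	34.81	36.20	del
22q11.2 del	22	19.02	20.26	del
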