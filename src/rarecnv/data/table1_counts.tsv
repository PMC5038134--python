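locus	type	bdrn_carriers	bdrn_total	bd_carriers	bd_total	control_carriers	control_total
1q21.1 del	del	1	2591	3	8968	17	81821
1q21.1 dup	dup	1	2591	8	8084	24	64046
NRXN1 del	del	0	2591	0	4288	10	51161
3q29 del	del	0	2591	2	8084	1	69965
WBS dup	dup	0	2591	0	7250	2	34455
VIPR2 dup	dup	0	2591	2	8084	17	24812
15q11.2 del	del	7	2591	15	8966	227	81802
AS/PWS dup	dup	0	2591	0	8084	3	47686
15q13.3 del	del	0	2591	2	8084	15	80422
16p13.11 dup	dup	6	2591	9	8084	93	69289
16p11.2 distal del	del	0	2591	0	4288	5	27045
16p11.2 dup	dup	3	2591	12	9129	19	63068
17p12 del	del	1	2591	4	8132	17	65402
17q12 del	del	0	2591	0	7250	4	74447
22q11.2 del	del	0	2591	1	8084	0	77055
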