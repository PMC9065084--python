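protein_id	display_name	let7_pd_ratio	let7_pd_sc	mir58_pd_ratio	mir58_pd_sc	mir2_pd_ratio	mir2_pd_sc	alg1_ip_ratio	alg1_ip_sc	description
F48F7.1	ALG-1	6	88	19	328	8	73	573	229	Argonaute, miRISC component
C06G1.4	AIN-1	5	25	16	83	11	28	125	122	miRISC component (GW182 homolog)
C04E6.11	C04E6.11	6	86	5	35	5	7	.	.	Unknown
T07D3.7	ALG-2	115	70	293	292	105	47	.	.	Argonaute
B0261.2	LET-363	5	8	9	8	47	24	.	.	C. elegans Mtor
T23F6.4	RBD-1	20	124	5	55	27	28	.	.	rRNA processing
M88.5	IMPH-1	9	310	10	237	.	.	23	39	KH domain, RNA binding protein
F26B1.2	HRPK-1	146	19	44	4	.	.	8	14	KH domain, RNA binding protein
R10E4.2	SUP-26	139	20.5	43	5	.	.	113	29	Translational regulation
Y48G8AL.6	SMG-2	6	43	45	17	.	.	9	4	NMD protein
B0041.2	AIN-2	22	6	87	83	.	.	.	.	miRISC component
Y49E10.15	SNR-6	7	41	5	19	.	.	.	.	Small nuclear ribonucleoprotein
Y71F9B.4	SNR-7	8	42	260	14	.	.	.	.	Small nuclear ribonucleoprotein
W08E3.1	SNR-2	9	48	5	19	.	.	.	.	Small nuclear ribonucleoprotein
Y116A8C.42	SNR-1	10	55	4	10	.	.	.	.	Small nuclear ribonucleoprotein
C52E4.3	SNR-4	381	31	4	13	.	.	.	.	Small nuclear ribonucleoprotein
F43H9.3	F43H9.3	4	23	52	8	.	.	.	.	Predicted to enable nucleotidyltransferase activity
ZC373.2	ZC373.2	56	5	43	5	.	.	.	.	Unknown
W07E6.1	NSUN-1	12	5	67	12	.	.	.	.	Nop2 (NOP2)/SUN domain family member
Y38C9A.2	CGP-1	61	22	52	8	.	.	.	.	Predicted to enable GTPase activity
K10D2.3	CID-1	16	53	14	6	.	.	.	.	RNA 3' uridylation
W05F2.6	W05F2.6	139	21	114	14	.	.	.	.	Unknown
T01H10.8	LYST-1	41	38	15	12	.	.	.	.	Lysosomal trafficking regulator protein
K04G7.10	RNP-7	36	14	66	5	.	.	.	.	RNA binding protein
Y37H2A.1	Y37H2A.1	147	25	65	8	.	.	.	.	Predicted to enable hydrolase activity
F56B3.5	ECH-5	94	20	64	12	.	.	.	.	Enoyl-CoA hydratase
F57H12.6	F57H12.6	166	12	4	9	.	.	.	.	Unknown
F42A6.7	HRPA-1	30	5	14	4	.	.	.	.	RNA binding protein
F25B5.7	NONO-1	84	14	100	13	.	.	.	.	Conserved nuclear protein
H20J04.8	MOG-2	161	34	.	.	114	6	.	.	Enables U2 snRNA binding activity
W02F12.5	DLST-1	88	75	.	.	.	.	18	12	DihydroLipoamide S-SuccinylTransferase
F33D11.10	F33D11.10	16	7	.	.	.	.	29	4	RNA helicase activity
ZC434.5	EARS-1	14	9	.	.	.	.	7	4	Glutamate-tRNA ligase activity
H05C05.1	H05C05.1	32	9	.	.	.	.	12	4	Predicted to enable RNA strand annealing activity
Y47D3B.10	DPY-18	.	.	15	9	.	.	23	5	Procollagen-proline 4-dioxygenase activity
K02F2.1	DPF-3	.	.	58	14	.	.	42	15	Serine-type peptidase
F52B5.3	F52B5.3	6	40	.	.	.	.	6	4	Predicted to enable ATP binding activity
F18H3.3	PAB-2	.	.	20	9	.	.	5	69	Poly-A-binding protein
K12H4.8	DCR-1	.	.	153	84	27	10	6	5	Small RNA processor
F37C12.11	RPS-21	.	.	.	.	89	4	39	33	Ribosomal protein
Y71F9AL.9	Y71F9AL.9	.	.	.	.	45	6	37	7	Unknown
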