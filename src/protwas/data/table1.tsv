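protein	full_name	somamer_id	gene	method	n_snps	n_cis	n_trans	cv_r2	external_r2	z	p	distance_kb
TBCA	Tubulin-specific chaperone A	TBCA.12501.10.3	TBCA	blup	470	0	470	0.54	0.51	-50.90	<1.09e-298	9236.20
S100A13	Protein S100-A13	S100A13.7223.60.3	S100A13	blup	528	0	528	0.56	0.54	-39.10	<1.09e-298	7564.12
DCK	Deoxycytidine kinase	DCK.9836.20.3	DCK	lasso	5	0	5	0.04	0.02	19.80	7.23e-87	31660.52
PSME1	Proteasome activator complex subunit 1	PSME1.5918.5.3	PSME1	lasso	13	0	13	0.19	0.11	-19.00	8.12e-81	28693.45
SYVC	Valine--tRNA ligase	VARS.13083.18.3	VARS	enet	69	0	69	0.38	0.27	16.90	2.71e-64	833.24
PSG5	Pregnancy-specific beta-1-glycoprotein 5	PSG5.9314.9.3	PSG5	enet	50	16	34	0.07	0.05	16.90	8.68e-64	1740.05
UBP21	Ubiquitin carboxyl-terminal hydrolase 21	USP21.12681.63.3	USP21	enet	39	0	39	0.14	0.08	15.90	3.69e-57	26.10
SURF1	Surfeit locus protein 1	SURF1.8009.121.3	SURF1	enet	68	0	68	0.06	0.05	15.80	1.62e-56	28552.64
RPAC1	DNA-directed RNA polymerases I and III subunit RPAC1	POLR1C.12939.1.3	POLR1C	enet	44	0	44	0.03	0.01	15.30	6.67e-53	2542.63
P5I11	Tumor protein p53-inducible protein 11	TP53I11.13022.20.3	TP53I11	enet	19	0	19	0.06	0.05	15.20	2.25e-52	2426.44
NRBP	Nuclear receptor-binding protein	NRBP1.12616.45.3	NRBP1	enet	40	11	29	0.07	0.02	14.90	3.56e-50	9881.28
MO2R2	Cell surface glycoprotein CD200 receptor 2	CD200R1L.8980.19.3	CD200R1L	top1	1	0	1	0.09	0.03	-13.30	4.44e-40	42252.95
APBB2	Amyloid beta A4 precursor protein-binding family B member 2	APBB2.12753.6.3	APBB2	top1	1	0	1	0.05	0.03	-13.20	8.33e-40	613.20
MUCDL	Cadherin-related family member 5	CDHR5.9962.1.3	CDHR5	top1	1	0	1	0.03	0.02	13.10	2.66e-39	46763.76
TM59L	Transmembrane protein 59-like	TMEM59L.9959.60.3	TMEM59L	enet	47	0	47	0.05	0.01	12.40	2.48e-35	16869.43
EMAP-2	Endothelial monocyte-activating polypeptide 2	AIMP1.2714.78.2	AIMP1	lasso	4	0	4	0.06	0.03	11.50	1.51e-30	67037.86
MED4	Mediator of RNA polymerase II transcription subunit 4	MED4.14021.81.3	MED4	top1	1	0	1	0.09	0.05	11.10	7.48e-29	NA
QORL1	Quinone oxidoreductase-like protein 1	CRYZL1.9207.60.3	CRYZL1	enet	18	0	18	0.16	0.13	11.10	7.76e-29	7440.72
GST M1-1	Glutathione S-transferase Mu 1	GSTM1.7239.9.3	GSTM1	enet	20	6	14	0.03	0.05	10	1.03e-23	342.01
XRCC4	DNA repair protein XRCC4	XRCC4.9886.28.3	XRCC4	lasso	4	0	4	0.05	0.03	9.43	3.98e-21	3849.83
Cofilin-1	Cofilin-1	CFL1.4203.50.2	CFL1	lasso	6	0	6	0.11	0.08	9.04	1.59e-19	5600.20
MAPK5	MAP kinase-activated protein kinase 5	MAPKAPK5.8382.47.3	MAPKAPK5	lasso	21	0	21	0.48	0.49	8.79	1.48e-18	1439.76
SULT 1E	Estrogen sulfotransferase	SULT1E1.9878.3.3	SULT1E1	lasso	10	0	10	0.11	0.05	-8.08	6.54e-16	30508.08
Testican-1	Testican-1	SPOCK1.5490.53.3	SPOCK1	enet	24	0	24	0.05	0.01	7.38	1.63e-13	14121.40
LRTM2	Leucine-rich repeat and transmembrane domain-containing protein 2	LRTM2.8906.60.3	LRTM2	enet	49	0	49	0.04	0.01	6.70	2.03e-11	111790.06
APRV1	Retroviral-like aspartic protease 1	ASPRV1.13023.8.3	ASPRV1	enet	42	0	42	0.14	0.12	6.59	4.26e-11	32627.91
PRPC	Salivary acidic proline-rich phosphoprotein 1/2	PRH1.10502.15.3	PRH1	enet	38	21	17	0.05	0.04	6.53	6.52e-11	102686.22
Furin	Furin	FURIN.6276.16.3	FURIN	enet	43	0	43	0.07	0.05	6.51	7.76e-11	12182.62
SL9B2	Mitochondrial sodium/hydrogen exchanger 9B2	SLC9B2.9088.20.3	SLC9B2	lasso	4	0	4	0.02	0.02	6.48	9.02e-11	63740.34
Gc-Globulin, Mixed Type	Vitamin D-binding protein	GC.6581.50.3	GC	enet	30	0	30	0.17	0.16	6.40	1.53e-10	32408.56
PRB4	Basic salivary proline-rich protein 4	PRB4.12590.67.3	PRB4	top1	1	0	1	0.02	0.03	-6.29	3.21e-10	102259.78
CR026	Dynactin-associated protein	DYNAP.10692.48.3	DYNAP	top1	1	0	1	0.02	0.02	6.29	3.21e-10	3934.47
CCNC	Cyclin-C	CCNC.7817.36.3	CCNC	top1	1	0	1	0.02	0.03	6.11	1.01e-9	14622.63
CLC4E	C-type lectin domain family 4 member E	CLEC4E.7077.9.4	CLEC4E	top1	1	0	1	0.02	0.02	6.11	1.01e-9	105033.89
CEACAM1	Carcinoembryonic antigen-related cell adhesion molecule 1	CEACAM1.8031.11.3	CEACAM1	enet	21	0	21	0.23	0.26	5.94	2.91e-9	2400.48
AT1A1	Sodium/potassium-transporting ATPase subunit alpha-1	ATP1A1.11993.227.3	ATP1A1	enet	15	0	15	0.06	0.07	5.91	3.52e-9	7027.43
CF226	Uncharacterized protein C6orf226	C6orf226.8078.15.3	C6orf226	lasso	7	0	7	0.07	0.07	5.74	9.61e-9	1915.81
AXIN2	Axin-2	AXIN2.8429.16.3	AXIN2	enet	18	0	18	0.40	0.44	5.57	2.48e-8	1978.90
TRML4	Trem-like transcript 4 protein	TREML4.11139.4.3	TREML4	lasso	9	0	9	0.21	0.20	-5.57	2.51e-8	253.89
DAF	Complement decay-accelerating factor	CD55.5069.9.3	CD55	lasso	11	1	10	0.11	0.07	-5.57	2.55e-8	197.03
EVI2B	Protein EVI2B	EVI2B.13028.2.3	EVI2B	enet	11	0	11	0.07	0.05	-5.52	3.30e-8	11571.33
TMIE	Transmembrane inner ear expressed protein	TMIE.7992.3.3	TMIE	enet	7	0	7	0.04	0.05	5.47	4.46e-8	10490.88
AMBN	Ameloblastin	AMBN.6522.57.3	AMBN	lasso	11	0	11	0.15	0.07	-5.47	4.52e-8	31259.13
SLAF5	SLAM family member 5	CD84.8770.136.3	CD84	blup	46	0	46	0.05	0.08	5.46	4.65e-8	644.50
SG1C1	Secretoglobin family 1C member 1	SCGB1C1.5960.49.3	SCGB1C1	enet	25	0	25	0.18	0.10	-5.42	5.84e-8	47187.26
KCNE2	Potassium voltage-gated channel subfamily E member 2	KCNE2.10427.2.3	KCNE2	enet	33	0	33	0.26	0.26	-5.38	7.55e-8	8215.37
FA20A	Pseudokinase FAM20A	FAM20A.6433.57.3	FAM20A	enet	30	17	13	0.04	0.03	-5.36	8.43e-8	4985.48
SHSA3	Protein shisa-3 homolog	SHISA3.7057.18.3	SHISA3	enet	22	0	22	0.23	0.16	-5.20	2.01e-7	2200.66
NPTX2	Neuronal pentraxin-2	NPTX2.6521.35.3	NPTX2	enet	30	0	30	0.04	0.05	5.20	2.01e-7	1685.45
ILT-4	Leukocyte immunoglobulin-like receptor subfamily B member 2	LILRB2.5633.65.3	LILRB2	lasso	8	6	2	0.21	0.22	5.19	2.15e-7	6.22
DIAC	Di-N-acetylchitobiase	CTBS.6115.40.3	CTBS	enet	20	0	20	0.14	0.09	-5.11	3.23e-7	24873.14
IGFL4	Insulin growth factor-like family member 4	IGFL4.6353.60.3	IGFL4	enet	18	0	18	0.10	0.05	-4.95	7.47e-7	300.60
NAP-2	Neutrophil-activating peptide 2	PPBP.2790.54.2	PPBP	enet	22	0	22	0.03	0.01	-4.93	8.04e-7	34653.31
MCFD2	Multiple coagulation factor deficiency protein 2	MCFD2.10476.23.3	MCFD2	blup	744	0	744	0.53	0.60	4.92	8.62e-7	9597.07
SLUR1	Secreted Ly-6/uPAR-related protein 1	SLURP1.6401.73.3	SLURP1	lasso	4	0	4	0.06	0.03	-4.86	1.17e-6	1285.78
SGCB	Beta-sarcoglycan	SGCB.7034.4.3	SGCB	enet	16	0	16	0.10	0.06	-4.84	1.30e-6	12688.03
RN165	RING finger protein 165	RNF165.11561.32.3	RNF165	enet	18	0	18	0.15	0.11	-4.84	1.32e-6	12275.48
PSD2	PH and SEC7 domain-containing protein 2	PSD2.9118.7.3	PSD2	enet	43	0	43	0.15	0.16	-4.74	2.14e-6	11257.00
ICOS	Inducible T-cell costimulator	ICOS.14084.191.3	ICOS	enet	27	0	27	0.17	0.12	-4.72	2.41e-6	1058.05
SHPS1	Tyrosine-protein phosphatase non-receptor type substrate 1	SIRPA.5430.66.3	SIRPA	blup	2563	2506	57	0.63	0.62	4.63	3.71e-6	1480.84
FKBP6	Inactive peptidyl-prolyl cis-trans isomerase FKBP6	FKBP6.12529.32.3	FKBP6	blup	1593	0	1593	0.49	0.53	4.54	5.53e-6	17800.84
Cathepsin H	Cathepsin H	CTSH.8465.52.3	CTSH	lasso	13	12	1	0.30	0.28	4.51	6.58e-6	15.80
Siglec-3	Myeloid cell surface antigen CD33	CD33.3166.92.1	CD33	enet	98	92	6	0.41	0.45	4.47	7.78e-6	0.37
SPA9	Serpin A9	SERPINA9.7266.4.3	SERPINA9	lasso	4	0	4	0.02	0.02	4.46	8.02e-6	1990.20
B3GN1	Beta-1,4-glucuronyltransferase 1	B3GNT1.8259.25.3	B3GNT1	enet	50	0	50	0.15	0.17	4.40	1.09e-5	6090.90
APBB2	Amyloid beta A4 precursor protein-binding family B member 2	APBB2.12761.12.3	APBB2	lasso	9	6	3	0.03	0.01	4.24	2.26e-5	613.20
TMM85	ER membrane protein complex subunit 4	EMC4.13516.46.3	EMC4	enet	73	0	73	0.21	0.20	-4.20	2.63e-5	24505.40
Siglec-9	Sialic acid-binding Ig-like lectin 9	SIGLEC9.3007.7.2	SIGLEC9	blup	618	580	38	0.72	0.73	4.19	2.75e-5	99.83
ADSV	Adseverin	SCIN.12684.5.3	SCIN	lasso	4	0	4	0.03	0.02	4.17	3.01e-5	340.75
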