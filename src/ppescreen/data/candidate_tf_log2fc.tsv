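gene_id	accession	fc_six1	fc_eya1	fc_six1_eya1
Six2	NM_001100275.1	5	3.5	5.9
Sox17	AJ001730.1	3.6	2.6	4.8
MyoD1	BC041190.1	3.5	2.7	4.7
Hes8	XM_002933849.2	2.8	1.7	3.6
Gfi1a	XM_002933803.2	1.8	1.8	3.2
Pou3f2b	NM_001096751.1	3	2.3	2.9
Mab21l2b	NM_001096770.1		2.8	2.9
Tlx1	XM_002936768.2	2.6	2.3	2.6
Emx1.2	NM_001093430.1	2.6	1.9	1.1
Sox1	EF672727.1		2.6	2.1
Sim1	XM_004914545.1		1.4	2.4
Six1	AF279254.1	1.4	1.2	2.3
Fbxo41	NM_001079043.1	1.3	0.6	2
Tbx15	XM_002940981.2	2	1	1.8
Ripply3	AB455086.1	0.9	1.1	2
Egr3	XM_002932703.2	1.6	0.8	1.9
Sox2	NM_213704.3	1.1	1.3	1.9
Pou4f1.2	NM_001097307.1	1.3	1	1.9
Hes9.1a	AJ009282.1	1.7	1.6
Isl2	NM_001166041.1	1.5		1.7
Tbx6	DQ355794.1	1.4	1.7	1
FosB	XM_004916957.1		1.7	1.4
Hes2	BC084134.1	1.7	0.9	1.3
Crem	XM_002935162.2		1.4	1.5
Znf214	NM_001097042.1	1.2	0.8	1.5
Sox21	NM_001172213.1	1.2	0.6	1.5
Atoh1	XM_004911085.1	0.9	1.1	1.5
Ets2a	BC133183.1	1.3	1	1.4
Mafa	NM_001032304.1	1.4	0.9	1.1
Lhx5	BC084744.1	1.1		1.1
Ngn1	NM_001123423.1	0.8	0.9	0.8
Sox3	BC072222.1	0.5		0.9
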