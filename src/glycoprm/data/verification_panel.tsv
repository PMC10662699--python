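peptide_id	gene	quant_mode	planted_fc_pca_vs_bph	planted_fc_ag_vs_nag
GVNFNVSK	KLKB1	IS	2.42	1.0
VLNFTTK	C6	IS	2.13	1.2
YAEDKFNETTEK	AFM	IS	2.11	1.0
VYKPSAGNNSLYR	APOH	IS	1.81	1.0
GLNLTEDTYKPR	LGALS3BP	IS	1.73	1.2
HANWTLTPLK	PON1	IS	1.48	1.0
QDFNITDISLLEHR	UMOD	IS	1.21	1.0
DFEDLYTPVNGSIVIVR	TFRC	IS	1.20	1.0
LSDTTSQSNSTAK	LAMB1	IS	1.15	1.2
NISSEEK	NCAM1	IS	1.11	1.0
NINYTER	GPLD1	IS	1.11	1.0
SNDTAASEYK	PTPRJ	IS	1.09	1.0
AGPNGTLFVADAYK	APMAP	IS	1.0	1.0
ISGVNLTQK	CHL1	IS	1.0	1.2
IIPSNNSGTFR	CHL1	IS	1.0	1.2
LDPTVLDAGELANR	CSPG4	IS	1.0	1.0
GSLSYLNVTR	CTSD	IS	1.0	1.0
VVLGAHNLSR	ELANE	IS	1.0	1.0
VELEDFNGNR	FCN3	IS	1.0	1.2
LTVNLTNDR	IL6ST	IS	1.0	1.0
VQPFNVTQGK	LAMP2	IS	1.0	1.0
NGSDCPDKFCLFQSETK	LTF	IS	1.0	1.0
VTPACNTSLPAQR	MRC2	IS	1.0	1.0
EVNDTLLVNELK	POSTN	IS	1.0	1.2
SNSSMHITDCR	RNASE1	IS	1.0	1.0
FVGTPEVNQTTLYQR	TIMP1	IS	1.0	1.0
MTGSGIYAPNSSR	VNN1	IS	1.0	1.0
LTGVAGNYTVCQK	VNN1	IS	1.0	1.0
NNLTTYK	MASP1	IS	1.0	1.0
FVDVTVTPEDQCRPNNVCTGVLTR	AZU1	label_free	1.0	1.2
LHINHNDLTESVGPLPK	LUM	label_free	1.31	1.0
DGQLLPSSNYSNIK	NCAM1	label_free	1.11	1.0
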