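gene	protein_name	sequence	charge	source_experiment	blood_conc_ng_ml	glycosite
RNASE1	Ribonuclease pancreatic	SNSSMHITDCR	3	3D	1100	2
MRC2	C-type mannose receptor 2	VTPACNTSLPAQR	2	3D	36	6
ELANE	Neutrophil elastase	VVLGAHNLSR	3	3D	0.37	7
VNN1	Pantetheinase	MTGSGIYAPNSSR	2	3D	980	10
CHL1	Neural cell adhesion molecule L1-like protein	ISGVNLTQK	2	3D	5800	5
CHL1	Neural cell adhesion molecule L1-like protein	IIPSNNSGTFR	2	3D	5800	5
VNN1	Pantetheinase	LTGVAGNYTVCQK	2	3D	980	7
IL6ST	Interleukin-6 receptor subunit beta	LTVNLTNDR	2	3D	160	4
LAMP2	Lysosome-associated membrane glycoprotein 2	VQPFNVTQGK	2	3D	520	5
FCN3	Ficolin-3	VELEDFNGNR	2	3D	18000	9
CTSD	Cathepsin D	GSLSYLNVTR	2	3D	370	7
TIMP1	Metalloproteinase inhibitor 1	FVGTPEVNQTTLYQR	2	3D	110	8
AZU1	Azurocidin	FVNVTVTPEDQCRPNNVCTGVLTR	3	3D	0.32	3
LTF	Lactotransferrin	NGSDCPDKFCLFQSETK	3	3D	350	1
APMAP	Adipocyte plasma membrane-associated protein	AGPNGTLFVADAYK	2	3D	130	4
POSTN	Periostin	EVNDTLLVNELK	2	3D	660	3
CSPG4	Chondroitin sulfate proteoglycan 4	LDPTVLDAGELANR	2	3D	48	13
MASP1	Mannan-binding lectin serine protease 1	NNLTTYK	2	3D	9400	2
AFM	Afamin	YAEDKFNETTEK	2	TMT-A	47000	7
APOH	Beta-2-glycoprotein 1	VYKPSAGNNSLYR	3	TMT-A	280000	8
KLKB1	Plasma kallikrein	GVNFNVSK	2	TMT-A	29000	5
LGALS3BP	Galectin-3-binding protein	GLNLTEDTYKPR	3	TMT-A	7100	3
LUM	Lumican	LHINHNNLTESVGPLPK	2	TMT-A	29000	7
PON1	Serum paraoxonase/arylesterase 1	HANWTLTPLK	2	TMT-A and B	79000	3
C6	Complement component C6	VLNFTTK	2	TMT-A	45000	3
LAMB1	Laminin subunit beta-1	LSDTTSQSNSTAK	2	TMT-B	250	9
PTPRJ	Receptor-type tyrosine-protein phosphatase eta	SNDTAASEYK	2	TMT-B	670	2
PZP	Pregnancy-zone protein	QEVCEEFSQQLNSNGCITQQVHTK	4	TMT-B	15000	14
PZP	Pregnancy-zone protein	TFSSMTCASGANVSEQLSLK	3	TMT-B	15000	12
ENG	Endoglin	QNGTWPR	2	TMT-B	280	2
NCAM1	Neural cell adhesion molecule 1	NISSEEK	2	TMT-B	2300	1
GPLD1	Phosphatidylinositol-glycan-specific phospholipase D	NINYTER	2	TMT-B	110000	3
UMOD	Uromodulin	QDFNITDISLLEHR	3	TMT-B	66	4
TFRC	Transferrin receptor protein 1	DFEDLYTPVNGSIVIVR	2	TMT-B	1300	10
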