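gene	protein_accession	protein_name	sequence	charge	glycosite	source_experiment	literature_flag	literature_ref
APMAP	Q9HDC9	Adipocyte plasma membrane-associated protein	AGPNGTLFVADAYK	2	4	3D	True	CR30
AZU1	P20160	Azurocidin	FVNVTVTPEDQCRPNNVCTGVLTR	3	3	3D	True	CR25
CHL1	O00533	Neural cell adhesion molecule L1-like protein	ISGVNLTQK	2	5	3D	True	BioGPS
CHL1	O00533	Neural cell adhesion molecule L1-like protein	IIPSNNSGTFR	2	5	3D	True	BioGPS
CSPG4	Q6UVK1	Chondroitin sulfate proteoglycan 4	LDPTVLDAGELANR	2	13	3D	True	BioGPS
CTSD	P07339	Cathepsin D	GSLSYLNVTR	2	7	3D	True	CR30
ELANE	P08246	Neutrophil elastase	VVLGAHNLSR	3	7	3D	True	CR25
FCN3	O75636	Ficolin-3	VELEDFNGNR	2	9	3D	True	CR16
IL6ST	P40189	Interleukin-6 receptor subunit beta	LTVNLTNDR	2	4	3D	True	CR30
LAMP2	P13473	Lysosome-associated membrane glycoprotein 2	VQPFNVTQGK	2	5	3D	True	CR30
LTF	P02788	Lactotransferrin	NGSDCPDKFCLFQSETK	3	1	3D	True	CR25
MRC2	Q9UBG0	C-type mannose receptor 2	VTPACNTSLPAQR	2	6	3D	True	CR16
POSTN	Q15063	Periostin	EVNDTLLVNELK	2	3	3D	True	CR30
RNASE1	P07998	Ribonuclease pancreatic	SNSSMHITDCR	3	2	3D	True	CR16
TIMP1	P01033	Metalloproteinase inhibitor 1	FVGTPEVNQTTLYQR	2	8	3D	True	CR30
VNN1	O95497	Pantetheinase	MTGSGIYAPNSSR	2	10	3D	True	BioGPS
VNN1	O95497	Pantetheinase	LTGVAGNYTVCQK	2	7	3D	True	BioGPS
MASP1	P48740	Mannan-binding lectin serine protease 1	NNLTTYK	2	2	3D	True	BioGPS
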