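gene	protein_accession	sequence	fold_change	charge	p_value	glycosite	source_experiment	literature_flag	literature_ref
PZP	P20742	QEVCEEFSQQLNSNGCITQQVHTK	1.53	4	0.052	14	TMT-B	False
PZP	P20742	TFSSMTCASGANVSEQLSLK	1.41	3	0.077	12	TMT-B	False
ENG	P17813	QNGTWPR	1.22	2	0.014	2	TMT-B	False
UMOD	P07911	QDFNITDISLLEHR	1.21	3	0.085	4	TMT-B	False
PON1	P27169	HANWTLTPLK	1.20	2	0.096	3	TMT-B	False
TFRC	G3V0E5	DFEDLYTPVNGSIVIVR	1.20	2	0.095	10	TMT-B	False
LAMB1	P07942	LSDTTSQSNSTAK	1.15	2	0.090	9	TMT-B	True	CR27
NCAM1	H7BYX6	NISSEEK	1.11	2	0.082	1	TMT-B	True	CR14
GPLD1	P80108	NINYTER	1.11	2	0.098	3	TMT-B	True	CR28
PTPRJ	Q12913	SNDTAASEYK	1.09	2	0.031	2	TMT-B	True	CR29
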