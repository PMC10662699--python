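gene	protein_accession	sequence	fold_change	charge	p_value	glycosite	source_experiment	literature_flag
KLKB1	P03952	GVNFNVSK	2.42	2	0.026	5	TMT-A	False
C6	P13671	VLNFTTK	2.13	2	0.013	3	TMT-A	False
AFM	P43652	YAEDKFNETTEK	2.11	2	0.006	7	TMT-A	False
APOH	P02749	VYKPSAGNNSLYR	1.81	3	0.005	8	TMT-A	False
LGALS3BP	Q08380	GLNLTEDTYKPR	1.73	3	0.055	3	TMT-A	False
PON1	P27169	HANWTLTPLK	1.48	2	0.077	3	TMT-A	False
LUM	P51884	LHINHNNLTESVGPLPK	1.31	2	0.097	7	TMT-A	False
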