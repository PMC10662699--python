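feature	pearson	chi2	rfe	logistic_l1	random_forest
ftPSA	True	True	True	True	True
Prostate dimension (cc)	True	True	True	True	True
ProPSA	True	True	True	True	True
tPSA	True	True	True	False	True
fPSA	True	True	True	False	True
VQPFNVTQGK	True	True	True	True	False
SNSSMHITDCR	True	True	True	False	True
NNLTTYK	True	True	True	True	False
NINYTER	True	True	True	True	False
LHINHNNLTESVGPLPK	True	True	True	True	False
DGQLLPSSNYSNIK	True	True	True	True	False
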