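gene	chromosome	tissue	p_value	z_score	autoimmune
PVRL2	19	Brain (CMC) RNA-seq	4.92E-34	-12.1626	Yes
TOMM40	19	Whole Blood (YFS) RNA Array	1.13E-25	10.4749
CLPTM1	19	Brain (CMC) RNA-seq	5.73E-17	-8.37061
CLU	8	Brain (CMC) RNA-seq splicing	1.45E-16	-8.26075
CR1	1	Brain (CMC) RNA-seq	4.08E-15	7.8523	Yes
CEACAM19	19	Adipose (METSIM) RNA-seq	3.38E-11	6.62905	Yes
MS4A6A	11	Whole Blood (YFS) RNA Array	2.92E-10	6.30316
TRPC4AP	20	Brain (CMC) RNA-seq splicing	9.43E-10	6.1188
MLH3	14	Brain (CMC) RNA-seq splicing	7.86E-09	-5.77148	Yes
MS4A6A	11	Peripheral Blood (NTR) RNA Array	5.72E-08	5.4272
PTK2B	8	Peripheral Blood (NTR) RNA Array	9.93E-08	5.32809
PVR	19	Brain (CMC) RNA-seq	2.05E-07	-5.19443	Yes
PICALM	11	Peripheral Blood (NTR) RNA Array	2.84E-07	5.1337	Yes
MS4A4A	11	Adipose (METSIM) RNA-seq	6.11E-07	4.99
BIN1	2	Whole Blood (YFS) RNA Array	1.18E-06	4.859114
FNBP4	11	Whole Blood (YFS) RNA Array	1.49E-06	-4.81307
PTK2B	8	Whole Blood (YFS) RNA Array	2.89E-06	4.6784	Yes
BIN1	2	Peripheral Blood (NTR) RNA Array	3.24E-06	4.65503	Yes
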