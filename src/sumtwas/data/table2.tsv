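gene	chromosome	tissue	p_value	z_score	previously_identified
PHACTR1	6	Whole Blood (YFS) RNA Array	3.41E-06	-4.64434
PTPMT1	11	Whole Blood (YFS) RNA Array	4.45E-06	4.58895
MTCH2	11	Peripheral Blood (NTR) RNA Array	5.76E-06	4.535
C1QTNF4	11	Adipose (METSIM) RNA-seq	8.82E-06	4.44
FAM180B	11	Brain (CMC) RNA-seq	1.09E-05	-4.39814	Yes
DMWD	19	Whole Blood (YFS) RNA Array	1.22E-05	4.3733
ELL	19	Whole Blood (YFS) RNA Array	1.89E-05	4.277	Yes
ZNF740	12	Brain (CMC) RNA-seq splicing	2.08E-05	4.25599
NYAP1	7	Adipose (METSIM) RNA-seq	2.47E-05	-4.21777
SDAD1	4	Whole Blood (YFS) RNA Array	3.04E-05	-4.17062
MTSS1L	16	Brain (CMC) RNA-seq splicing	3.35E-05	4.14833
PHKB	16	Brain (CMC) RNA-seq	3.70E-05	-4.1257	Yes
SLC39A13	11	Brain (CMC) RNA-seq splicing	4.01E-05	-4.10667	Yes
CD33	19	Whole Blood (YFS) RNA Array	4.04E-05	4.1051	Yes
AP2A2	11	Brain (CMC) RNA-seq	4.28E-05	-4.09193	Yes
ZYX	7	Adipose (METSIM) RNA-seq	4.56E-05	-4.07718
ZNF232	17	Brain (CMC) RNA-seq splicing	4.73E-05	-4.0688
ZNF232	17	Brain (CMC) RNA-seq splicing	4.76E-05	4.0671
DLST	14	Peripheral Blood (NTR) RNA Array	5.26E-05	4.0436	Yes
TBC1D7	6	Adipose (METSIM) RNA-seq	5.34E-05	4.0403
ELL	19	Adipose (METSIM) RNA-seq	5.48E-05	4.03401
SLC39A13	11	Brain (CMC) RNA-seq splicing	5.79E-05	-4.02128	Yes
TMCO6	5	Whole Blood (YFS) RNA Array	6.50E-05	3.9938
CEL	9	Whole Blood (YFS) RNA Array	6.99E-05	3.97671	Yes
MYBPC3	11	Adipose (METSIM) RNA-seq	7.05E-05	3.97	Yes
TBC1D7	6	Brain (CMC) RNA-seq splicing	7.48E-05	-3.96063
LRRC25	19	Peripheral Blood (NTR) RNA Array	7.74E-05	-3.9523
TBC1D7	6	Brain (CMC) RNA-seq splicing	8.37E-05	3.93351
KIR3DX1	19	Peripheral Blood (NTR) RNA Array	8.87E-05	3.9195
SIX5	19	Peripheral Blood (NTR) RNA Array	9.32E-05	3.9076
HBEGF	5	Whole Blood (YFS) RNA Array	9.92E-05	-3.8926	Yes
NUP88	17	Peripheral Blood (NTR) RNA Array	1.60E-04	-3.7748
FAM105B	5	Whole Blood (YFS) RNA Array	1.61E-04	3.773
ARL6IP4	12	Peripheral Blood (NTR) RNA Array	2.10E-04	3.707
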