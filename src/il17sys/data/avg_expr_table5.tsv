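gene	disease	avg_expr
CXCL2	psoriasis	7.143566
S100A8	psoriasis	13.03884
S100A9	psoriasis	11.57422
LCN2	psoriasis	10.42698
CCL20	psoriasis	7.295939
CXCL8	psoriasis	7.35222
FOSL1	psoriasis	6.836052
IL1B	psoriasis	7.299115
CXCL1	psoriasis	7.507195
S100A7	psoriasis	13.38452
MMP1	psoriasis	7.214311
IFNG	psoriasis	5.405429
CXCL10	psoriasis	8.052625
MAPK14	psoriasis	8.921881
CCL2	psoriasis	9.811309
MMP9	psoriasis	8.010812
IL17D	psoriasis	9.42729
MAPK13	psoriasis	11.11599
TAB3	psoriasis	5.693991
IL17A	psoriasis	3.848178
CCL7	psoriasis	4.973044
IL17F	psoriasis	5.032107
IKBKE	psoriasis	6.796894
IL17RE	psoriasis	8.205539
ANAPC5	psoriasis	7.907747
FOS	psoriasis	8.704977
SRSF1	cSCC	11.30402
TNF	cSCC	3.775442
S100A8	cSCC	10.50457
ELAVL1	cSCC	7.146701
TRAF6	cSCC	5.351013
LCN2	cSCC	5.506456
MAPK11	cSCC	4.413777
CXCL3	cSCC	4.455207
DEFB4A	cSCC	7.363343
JUN	cSCC	9.363052
DEFB4B	cSCC	7.363343
IKBKG	cSCC	6.876049
TRAF3IP2	cSCC	3.874313
FOSL1	cSCC	4.520605
MAPK3	cSCC	7.049278
S100A9	cSCC	8.624269
IL1B	cSCC	3.671266
CCL20	cSCC	4.261092
MAPK10	cSCC	4.192857
MAPK9	cSCC	4.239504
TRAF2	cSCC	5.059843
S100A7	cSCC	10.17163
JUND	cSCC	3.783349
HSP90AA1	cSCC	11.51992
MAPK14	cSCC	5.104123
MMP3	cSCC	4.519938
MAP3K7	cSCC	7.460711
MMP13	cSCC	4.249849
TRADD	cSCC	8.777471
MMP9	cSCC	6.08175
MMP1	cSCC	5.822357
CXCL8	cSCC	3.900222
CXCL1	cSCC	4.924705
IKBKE	cSCC	6.151091
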