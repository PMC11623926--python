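gene	hgvs_p_pattern	recurrence_count	predefined
DNMT3A	p.Arg882	500	yes
TET2	p.Gln1523	40	no
ASXL1	p.Gly646fs	120	yes
PPM1D	p.Arg552	35	yes
TP53	p.Arg175His	60	no
JAK2	p.Val617Phe	1000	yes
SF3B1	p.Lys700Glu	210	yes
SRSF2	p.Pro95	150	yes
IDH2	p.Arg140Gln	90	no
GNB1	p.Lys57Glu	25	no
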