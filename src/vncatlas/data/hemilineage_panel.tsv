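hemilineage	fan	markers
23B	ACh	acj6,unc-4
8B	ACh	acj6,Lim3
7B	ACh	unc-4,TfAP-2
12A	ACh	unc-4,vvl
11A	ACh	ey,sens
17A	ACh	D,unc-4
0A	GABA	Dbx,hth
19A	GABA	Dbx,dac
13A	GABA	vg,dac
6B	GABA	en,sens
9B	Glu	acj6,Lim3,tup
8A	Glu	ems,ey
24B	Glu	ems,toy
15B	Glu	eve,grn
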