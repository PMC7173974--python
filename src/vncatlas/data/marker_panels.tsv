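gene	panel	role
elav	neuronal	neuronal
nSyb	neuronal	neuronal
para	neuronal	neuronal
VAChT	neuronal	neuronal
ChAT	neuronal	neuronal
Gad1	neuronal	neuronal
VGAT	neuronal	neuronal
VGlut	neuronal	neuronal
noe	neuronal	neuronal
repo	glial	glial
alrm	glial	glial
wrapper	glial	glial
Indy	glial	glial
VAChT	fan	FAN:ACh
ChAT	fan	FAN:ACh
VGlut	fan	FAN:Glu
Gad1	fan	FAN:GABA
VGAT	fan	FAN:GABA
Antp	hox	hox
Ubx	hox	hox
abd-A	hox	hox
Abd-B	hox	hox
sNPF	neuropeptide	neuropeptide
spab	neuropeptide	neuropeptide
MIP	neuropeptide	neuropeptide
CCHa1	neuropeptide	neuropeptide
CCHa2	neuropeptide	neuropeptide
Ilp7	neuropeptide	neuropeptide
Proc	neuropeptide	neuropeptide
AstA	neuropeptide	neuropeptide
AstC	neuropeptide	neuropeptide
Lk	neuropeptide	neuropeptide
Orcokinin	neuropeptide	neuropeptide
Gpa2	neuropeptide	neuropeptide
Gpb5	neuropeptide	neuropeptide
Dh31	neuropeptide	neuropeptide
Dh44	neuropeptide	neuropeptide
Tk	neuropeptide	neuropeptide
NPF	neuropeptide	neuropeptide
Ms	neuropeptide	neuropeptide
Dsk	neuropeptide	neuropeptide
Burs	neuropeptide	neuropeptide
Pburs	neuropeptide	neuropeptide
CCAP	neuropeptide	neuropeptide
Crz	neuropeptide	neuropeptide
FMRFa	neuropeptide	neuropeptide
Hug	neuropeptide	neuropeptide
Nplp1	neuropeptide	neuropeptide
SIFa	neuropeptide	neuropeptide
Capa	neuropeptide	neuropeptide
Vmat	monoamine	monoamine:pan
DAT	monoamine	monoamine:DA
SerT	monoamine	monoamine:5-HT
Hdc	monoamine	monoamine:HA
Tdc2	monoamine	monoamine:OA/TA
Tbh	monoamine	monoamine:OA/TA
alrm	glial_subtype	glia:astrocyte
Indy	glial_subtype	glia:surface
wrapper	glial_subtype	glia:cortex
Eaat2	glial_subtype	glia:ensheathing
Sgs1	salivary	contaminant:salivary
Sgs3	salivary	contaminant:salivary
Sgs4	salivary	contaminant:salivary
Sgs5	salivary	contaminant:salivary
Sgs7	salivary	contaminant:salivary
Sgs8	salivary	contaminant:salivary
Eig71Ee	salivary	contaminant:salivary
ng1	salivary	contaminant:salivary
ng2	salivary	contaminant:salivary
ng3	salivary	contaminant:salivary
dj	sperm	contaminant:sperm
Mst35Ba	sperm	contaminant:sperm
Mst35Bb	sperm	contaminant:sperm
Mst57Da	sperm	contaminant:sperm
Mst84Da	sperm	contaminant:sperm
Mst84Db	sperm	contaminant:sperm
Mst98Ca	sperm	contaminant:sperm
Mst98Cb	sperm	contaminant:sperm
ocn	sperm	contaminant:sperm
S-Lap1	sperm	contaminant:sperm
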