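# Synthetic stand-in human codon-usage table (representative fractions; the
# per-amino-acid argmax matches the standard preferred human codons, which is
# the only property this package consumes).
codon	amino_acid	fraction
GCC	A	0.40
GCT	A	0.26
GCA	A	0.23
GCG	A	0.11
AGA	R	0.21
AGG	R	0.20
CGG	R	0.20
CGC	R	0.18
CGA	R	0.11
CGT	R	0.08
AAC	N	0.53
AAT	N	0.47
GAC	D	0.54
GAT	D	0.46
TGC	C	0.54
TGT	C	0.46
CAG	Q	0.73
CAA	Q	0.27
GAG	E	0.58
GAA	E	0.42
GGC	G	0.34
GGA	G	0.25
GGG	G	0.25
GGT	G	0.16
CAC	H	0.58
CAT	H	0.42
ATC	I	0.47
ATT	I	0.36
ATA	I	0.17
CTG	L	0.40
CTC	L	0.20
CTT	L	0.13
TTG	L	0.13
TTA	L	0.07
CTA	L	0.07
AAG	K	0.57
AAA	K	0.43
ATG	M	1.00
TTC	F	0.54
TTT	F	0.46
CCC	P	0.32
CCT	P	0.29
CCA	P	0.28
CCG	P	0.11
AGC	S	0.24
TCC	S	0.22
TCT	S	0.18
TCA	S	0.15
AGT	S	0.15
TCG	S	0.06
ACC	T	0.36
ACA	T	0.28
ACT	T	0.25
ACG	T	0.11
TGG	W	1.00
TAC	Y	0.56
TAT	Y	0.44
GTG	V	0.46
GTC	V	0.24
GTT	V	0.18
GTA	V	0.12
TGA	*	0.47
TAA	*	0.30
TAG	*	0.23
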