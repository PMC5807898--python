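name	rank	parent	na_type	genome_min_kb	genome_max_kb
root	root
Viruses	superkingdom	root
ssDNA viruses	other	Viruses	ssDNA	1.8	24.9
dsDNA viruses	other	Viruses	dsDNA	50	50
Caudovirales	order	dsDNA viruses	dsDNA
Circoviridae	family	ssDNA viruses	ssDNA	1.8	2.1
Microviridae	family	ssDNA viruses	ssDNA	4.4	6.1
Inoviridae	family	ssDNA viruses	ssDNA	5.5	10.6
Siphoviridae	family	Caudovirales	dsDNA	22	121
Podoviridae	family	Caudovirales	dsDNA	40	42
Myoviridae	family	Caudovirales	dsDNA	33	244
Phycodnaviridae	family	dsDNA viruses	dsDNA	100	560
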