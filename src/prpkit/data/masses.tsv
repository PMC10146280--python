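# prpkit monoisotopic mass table v1 (IUPAC/CODATA)
# kind	symbol	monoisotopic_mass	formula
element	H	1.00782503207	H
element	C	12.0	C
element	N	14.0030740048	N
element	O	15.9949146196	O
element	S	31.972071	S
residue	A	71.03711378474999	C3H5NO
residue	C	103.00918478474999	C3H5NOS
residue	D	115.02694302395	C4H5NO3
residue	E	129.04259308809	C5H7NO3
residue	F	147.06841391303	C9H9NO
residue	G	57.02146372061	C2H3NO
residue	H	137.05891185849	C6H7N3O
residue	I	113.08406397716999	C6H11NO
residue	K	128.09496301404	C6H12N2O
residue	L	113.08406397716999	C6H11NO
residue	M	131.04048491303	C5H9NOS
residue	N	114.04292744122	C4H6N2O2
residue	P	97.05276384889	C5H7NO
residue	Q	128.05857750536	C5H8N2O2
residue	R	156.10111102364	C6H12N4O
residue	S	87.03202840435	C3H5NO2
residue	T	101.04767846849	C4H7NO2
residue	V	99.06841391303	C5H9NO
residue	W	186.0793129499	C11H10N2O
residue	Y	163.06332853263	C9H9NO2
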