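# Protein-level TRIO (Trio-9, NP_009049.2) mutation list underlying the
# packaged domain tally.  DH1-region case records (positions 1312, 1329,
# 1368, 1428, 1431, 1461, the 1149-1889 CNV deletion) and the PH1 control
# record S1575N carry published positions; positions of the remaining
# case/control/inherited records were not published at residue resolution
# and are synthetic placeholders placed inside the correct domain so the
# per-domain tallies are reproduced cell-for-cell.
gene	position	end_position	ref_aa	alt	dna_change	mclass	cohort	diagnosis
TRIO	732	.	A	T	.	missense	case_de_novo	ASD
TRIO	955	.	R	W	.	missense	case_de_novo	ASD
TRIO	1312	.	R	W	c.C3757T	missense	case_de_novo	ASD-related
TRIO	1368	.	D	V	c.A3926T	missense	case_de_novo	ID
TRIO	1428	.	R	Q	c.G4106A	missense	case_de_novo	ASD-related
TRIO	1431	.	K	M	c.A4115T	missense	case_de_novo	ASD/ID
TRIO	1461	.	P	T	c.C4204A	missense	case_de_novo	NDD
TRIO	1461	.	P	L	c.C4205T	missense	case_de_novo	NDD
TRIO	2215	.	T	I	.	missense	case_de_novo	ASD
TRIO	1329	.	I	HLAL*	c.T3809_	lof	case_de_novo	ASD
TRIO	1149	1889	.	deleted	g.5:14380988-14463257(deleted)	lof	case_de_novo	ASD
TRIO	300	.	S	L	.	missense	inherited	.
TRIO	400	.	T	M	.	missense	inherited	.
TRIO	430	.	A	V	.	missense	inherited	.
TRIO	520	.	R	H	.	missense	inherited	.
TRIO	600	.	V	I	.	missense	inherited	.
TRIO	640	.	P	S	.	missense	inherited	.
TRIO	680	.	E	K	.	missense	inherited	.
TRIO	700	.	D	N	.	missense	inherited	.
TRIO	740	.	G	S	.	missense	inherited	.
TRIO	780	.	R	C	.	missense	inherited	.
TRIO	1000	.	M	V	.	missense	inherited	.
TRIO	1980	.	L	F	.	missense	inherited	.
TRIO	2000	.	A	G	.	missense	inherited	.
TRIO	2050	.	R	Q	.	missense	inherited	.
TRIO	2100	.	S	N	.	missense	inherited	.
TRIO	2140	.	T	A	.	missense	inherited	.
TRIO	200	.	Q	R	.	missense	control	.
TRIO	320	.	H	Y	.	missense	control	.
TRIO	450	.	N	S	.	missense	control	.
TRIO	480	.	I	V	.	missense	control	.
TRIO	500	.	K	R	.	missense	control	.
TRIO	550	.	E	D	.	missense	control	.
TRIO	580	.	G	R	.	missense	control	.
TRIO	850	.	R	W	.	missense	control	.
TRIO	920	.	V	M	.	missense	control	.
TRIO	950	.	P	L	.	missense	control	.
TRIO	980	.	D	E	.	missense	control	.
TRIO	1010	.	A	T	.	missense	control	.
TRIO	1100	.	S	C	.	missense	control	.
TRIO	1575	.	S	N	.	missense	control	.
TRIO	1660	.	Y	H	.	missense	control	.
TRIO	1700	.	R	K	.	missense	control	.
TRIO	2020	.	F	L	.	missense	control	.
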