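row	Sec14	SR1	SR2	SR3	SR4	SR5	SR6	SR7	SR8	SR9	DH1	PH1	SH3	DH2	PH2	inter-domain
case_dn_missense	0	0	0	0	0	0	1	0	1	0	6	0	0	0	1	0
case_dn_lof	0	0	0	0	0	0	0	0	0	0	2	0	0	0	0	0
inherited_missense	0	0	1	2	1	3	3	0	1	0	0	0	0	5	0	0
inherited_lof	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
control_missense	0	1	1	1	4	0	0	1	4	1	0	1	2	1	0	0
control_lof	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
total_case	0	0	0	0	0	0	1	0	1	0	8	0	0	0	1	0
total_control	0	1	2	3	5	3	3	1	5	1	0	1	2	6	0	0
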