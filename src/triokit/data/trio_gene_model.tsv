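# gene_symbol = TRIO
# protein_length_aa = 3097
# reference_accession = NP_009049.2
# Domain boundaries for the Trio-9 isoform. The DH1 interval is fixed at
# [1290, 1464] (175 aa); the remaining boundaries follow the canonical
# Sec14 / nine-spectrin-repeat / DH1-PH1 / SH3 / DH2-PH2 architecture and
# are user-overridable data, not code.
name	start	end
Sec14	23	140
SR1	150	255
SR2	256	365
SR3	366	475
SR4	476	585
SR5	586	695
SR6	696	805
SR7	806	915
SR8	916	1025
SR9	1026	1135
DH1	1290	1464
PH1	1480	1610
SH3	1655	1715
DH2	1965	2145
PH2	2160	2285
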