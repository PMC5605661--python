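# Predicted free-energy changes (kcal/mol) for TRIO GEF1/DH1-region
# mutations: ddg_bind is the change in Trio-GEF1/Rac1 binding free energy,
# ddg_stability the change in DH1 folding stability.  'starred' flags the
# upstream prediction of Rac1-activation inhibition; '-' marks values not
# defined for interface-eliminating truncation/deletion events.
mutation_protein	mutation_dna	ddg_bind	ddg_stability	starred	mclass	note
p.1149-1889 (deleted)	g.5:14380988-14463257(deleted)	-	-	1	lof	Entire Rac1 interface is eliminated
p.I1329HLAL*	c.T3809_	-	-	1	lof	Entire Rac1 interface is eliminated
p.R1312W	c.C3757T	0.9	3.1	1	missense	Disruption of the salt bridge to D1316
p.D1368V	c.A3926T	1	-0.3	0	missense	No significant effect on Rac1 binding
p.R1428Q	c.G4106A	1.2	3.2	1	missense	Disruption of the salt bridge to E1304; disruption of the hydrogen bonds to T1303 and L1308
p.K1431M	c.A4115T	3.2	-1.1	1	missense	Disruption of the hydrogen bonds with Rac1 A59 backbone; disruption of water-mediated interactions with Rac1 T35, F37 and D57 backbone
p.P1461T	c.C4204A	2.2	-1.3	1	missense	Distortion of alpha-helix
p.P1461L	c.C4205T	7.8	0.04	1	missense	Distortion of alpha-helix
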