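REMARK   1 SYNTHETIC two-chain toy complex for interface-distance tests.
REMARK   1 Chain A residue 1 sits 5.0 A (3-4-5 triangle) from the nearest
REMARK   1 heavy atom of chain B; chain A residue 2 sits 7.0 A away.
REMARK   1 Chain B carries one hydrogen 0.5 A from A/1 to exercise the
REMARK   1 heavy-atom-only rule.
ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      2  CB  ALA A   1       0.000   0.000  -2.000  1.00  0.00           C
ATOM      3  CA  ALA A   2      20.000   0.000   0.000  1.00  0.00           C
TER       4      ALA A   2
ATOM      5  CA  GLY B   1       3.000   4.000   0.000  1.00  0.00           C
ATOM      6  HA  GLY B   1       0.500   0.000   0.000  1.00  0.00           H
ATOM      7  CA  GLY B   2      20.000   0.000   7.000  1.00  0.00           C
TER       8      GLY B   2
END
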