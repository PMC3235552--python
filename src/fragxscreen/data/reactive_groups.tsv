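# Reactive / electrophilic functional groups excluded from fragment libraries.
# Columns: name <TAB> SMARTS.  Extend by appending rows; order defines the
# deterministic match-report order.
aldehyde	[CX3H1]=[OX1]
acyl_halide	[CX3](=[OX1])[F,Cl,Br,I]
alkyl_halide	[CX4][Cl,Br,I]
michael_acceptor	[CX3]=[CX3][CX3]=[OX1]
epoxide_aziridine	[#6;r3]1[#8,#7;r3][#6;r3]1
isocyanate	[NX2]=[CX2]=[OX1,SX1]
anhydride	[CX3](=[OX1])[OX2][CX3]=[OX1]
sulfonyl_halide	[SX4](=[OX1])(=[OX1])[F,Cl,Br,I]
diazo	[NX2]=[NX2,NX1]
thiol	[SX2H1]
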